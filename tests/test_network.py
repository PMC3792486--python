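"""Catalog loading, matrix assembly, boundary vector and atom audits."""

from __future__ import annotations

import numpy as np
import pytest

import neurofba as nf
from neurofba.catalog import ModelError, Species
from neurofba.compartments import ADJACENT_PAIRS, BLOOD, CELLS, COMPARTMENTS, ECS

# Independent tally of the reaction table: (rows, compartments per row).
# 4 glycolytic steps x 3 cytosols, 13 three-compartment enzymes, PAG in the
# two neuronal cytosols, AAT in all six cell compartments, GS and PC once,
# 7 TCA steps x 3 mitochondria, 2 vesicular packing reactions.
EXPECTED_N = 4 * 3 + 13 * 3 + 2 + 6 + 1 + 1 + 7 * 3 + 2  # = 84

# Transport tally: 8 blood<->ECS rows; ECS<->cytosol for 9 species x 3 cells
# plus astrocyte-only Glu and GABA uptake (29); cytosol<->mitochondria for
# 10 species x 3 cells plus astrocyte-only Leu and KIC carriers (32); OGC and
# AGC1 per cell (6); 2 vesicular effluxes.
EXPECTED_K = 8 + (9 * 3 + 2) + (10 * 3 + 2) + 6 + 2  # = 77


@pytest.fixture(scope="module")
def document():
    return nf.packaged_model_document()


@pytest.fixture(scope="module")
def catalogs(document):
    return (
        nf.load_reaction_catalog(document),
        nf.load_transport_catalog(document),
    )


class TestReactionCatalog:
    def test_mark_count_matches_independent_tally(self, catalogs):
        reactions, _ = catalogs
        assert len(reactions) == EXPECTED_N

    def test_glutamine_synthetase_is_astrocytic_and_irreversible(self, catalogs):
        reactions, _ = catalogs
        gs = [r for r in reactions if r.id.startswith("GS@")]
        assert len(gs) == 1
        (gs,) = gs
        assert gs.compartment == "astrocyte-cytosol"
        assert not gs.reversible
        assert gs.stoichiometry == {
            "Glu": -1, "NH4+": -1, "ATP": -1, "Gln": 1, "ADP": 1, "Pi": 1,
        }

    def test_pyruvate_carboxylase_astrocyte_mitochondria_only(self, catalogs):
        reactions, _ = catalogs
        pc = [r for r in reactions if r.id.startswith("PC@")]
        assert [r.compartment for r in pc] == ["astrocyte-mitochondria"]

    def test_gaba_packing_costs_eight_atp(self, catalogs):
        reactions, _ = catalogs
        (vgaba,) = [r for r in reactions if r.id.startswith("VGABA@")]
        assert vgaba.compartment == "GABAergic-cytosol"
        assert vgaba.stoichiometry["ATP"] == -8
        assert vgaba.stoichiometry["GABA_vesicular"] == 1

    def test_unknown_compartment_mark_rejected(self, document):
        bad = {**document, "reactions": [
            {"id": "X", "stoichiometry": {"Glc": -1, "Pyr": 1},
             "reversible": False, "compartments": ["nucleus"]},
        ]}
        with pytest.raises(ModelError, match="compartment"):
            nf.load_reaction_catalog(bad)

    def test_unknown_metabolite_rejected(self, document):
        bad = {**document, "reactions": [
            {"id": "X", "stoichiometry": {"Unobtainium": -1},
             "reversible": False, "compartments": ["astrocyte-cytosol"]},
        ]}
        with pytest.raises(ModelError, match="metabolite"):
            nf.load_reaction_catalog(bad)


class TestTransportCatalog:
    def test_count_matches_independent_tally(self, catalogs):
        _, transports = catalogs
        assert len(transports) == EXPECTED_K

    def test_glucose_expansion(self, catalogs):
        _, transports = catalogs
        glc = [t for t in transports if t.species_moved == "Glc"]
        ids = {t.id for t in glc}
        assert f"Glc/{BLOOD}->{ECS}" in ids
        assert all(t.direction == "unidirectional" for t in glc)
        assert len(glc) == 4  # blood->ECS plus one uptake per cell

    def test_agc1_antiporter_stoichiometry(self, catalogs):
        _, transports = catalogs
        agc = [t for t in transports if t.id == "AGC1@glutamatergic"]
        assert len(agc) == 1
        st = agc[0].species_stoichiometry
        cyto, mito = "glutamatergic-cytosol", "glutamatergic-mitochondria"
        assert st[Species("Glu", cyto)] == -1
        assert st[Species("Glu", mito)] == 1
        assert st[Species("Asp", mito)] == -1
        assert st[Species("Asp", cyto)] == 1

    def test_glutamine_leaks_to_blood_only(self, catalogs):
        _, transports = catalogs
        (leak,) = [
            t for t in transports
            if t.species_moved == "Gln" and BLOOD in (t.from_compartment, t.to_compartment)
        ]
        assert leak.from_compartment == ECS and leak.to_compartment == BLOOD
        assert leak.direction == "unidirectional"

    def test_astrocytic_uptake_carries_atp_cost(self, catalogs):
        _, transports = catalogs
        ast = "astrocyte-cytosol"
        for species in ("Glu", "GABA"):
            (up,) = [
                t for t in transports
                if t.species_moved == species and t.to_compartment == ast
            ]
            st = up.species_stoichiometry
            assert st[Species("ATP", ast)] == -1
            assert st[Species("ADP", ast)] == 1

    def test_vesicular_efflux_releases_free_transmitter(self, catalogs):
        _, transports = catalogs
        (ves,) = [t for t in transports if t.species_moved == "GABA_vesicular"]
        st = ves.species_stoichiometry
        assert st[Species("GABA_vesicular", "GABAergic-cytosol")] == -1
        assert st[Species("GABA", ECS)] == 1

    def test_all_transports_connect_adjacent_compartments(self, catalogs):
        _, transports = catalogs
        for t in transports:
            pair = (t.from_compartment, t.to_compartment)
            assert pair in ADJACENT_PAIRS or pair[::-1] in ADJACENT_PAIRS

    def test_non_adjacent_transport_rejected(self):
        with pytest.raises(ModelError, match="not adjacent"):
            nf.TransportSpec(
                id="bad", species_moved="Glc", from_compartment=BLOOD,
                to_compartment="astrocyte-cytosol", direction="unidirectional",
            )


class TestAssembly:
    def test_empty_catalogs_give_zero_columns(self):
        system = nf.assemble_system([], [])
        assert system.matrix.shape == (0, 0)
        assert system.n == system.k == 0

    def test_gad_column_in_gabaergic_cytosol(self, model):
        s = model.system
        col = s.matrix[:, s.col("GAD@GABAergic-cytosol")]
        cyto = "GABAergic-cytosol"
        expect = {
            Species("Glu", cyto): -1.0,
            Species("GABA", cyto): 1.0,
            Species("CO2", cyto): 1.0,
        }
        for i, sp in enumerate(s.species_index):
            assert col[i] == expect.get(sp, 0.0)

    def test_every_reaction_column_round_trips(self, model):
        s = model.system
        for rx in s.reactions:
            col = s.matrix[:, s.col(rx.id)]
            expect = rx.species_stoichiometry
            for i, sp in enumerate(s.species_index):
                assert col[i] == expect.get(sp, 0.0), (rx.id, sp)

    def test_assembled_counts_match_tally(self, model):
        assert model.system.n == EXPECTED_N
        assert model.system.k == EXPECTED_K

    def test_species_are_per_compartment(self, model):
        names = {}
        for sp in model.system.species_index:
            names.setdefault(sp.name, set()).add(sp.compartment)
        # glutamate appears as a distinct species in six compartments
        assert len(names["Glu"]) == 7  # ECS + six cell compartments
        assert len(set(model.system.species_index)) == len(model.system.species_index)

    def test_zero_flux_vector_closes_internal_rows(self, model):
        s = model.system
        assert np.all(s.matrix @ np.zeros(s.n_fluxes) == 0)

    def test_duplicate_flux_ids_rejected(self, model):
        rx = model.system.reactions[0]
        with pytest.raises(ModelError, match="duplicate"):
            nf.assemble_system([rx, rx], [])


class TestBoundaryVector:
    def test_rates_from_printed_differences(self, model):
        b = model.boundary
        assert b.rates["Glc"] == pytest.approx(0.55 * 0.54)   # 0.297
        assert b.rates["Lac"] == pytest.approx(0.55 * -0.18)  # -0.099
        assert b.sigmas["Glc"] == pytest.approx(0.55 * 0.05)

    def test_ammonium_zero_mean_with_printed_uncertainty(self, model):
        b = model.boundary
        assert b.rates["NH4+"] == 0.0
        assert b.sigmas["NH4+"] == pytest.approx(0.11)

    def test_estimated_venous_species_get_loose_sigma(self, model):
        b = model.boundary
        for sp in ("O2", "CO2"):
            assert b.rates[sp] == 0.0
            assert b.sigmas[sp] == b.sigma_loose

    def test_full_rhs_zero_on_internal_rows(self, model):
        rhs, sigma = model.boundary.rhs_and_sigma(model.system)
        for i, sp in enumerate(model.system.species_index):
            if sp.compartment != BLOOD:
                assert rhs[i] == 0.0
                assert sigma[i] == model.boundary.sigma_default

    def test_blood_rows_carry_uptake_rates(self, model):
        rhs, sigma = model.boundary.rhs_and_sigma(model.system)
        i = model.system.row(Species("Glc", BLOOD))
        # supply enters the blood row with opposite sign (see system module)
        assert rhs[i] == pytest.approx(-0.297)
        assert sigma[i] == pytest.approx(0.0275)

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(ModelError):
            nf.boundary_vector({"Glc": {"difference": 0.5, "pm": 0.1}}, Q=0.0, F=1.0)

    def test_nonpositive_uncertainty_rejected(self):
        with pytest.raises(ModelError, match="sigma"):
            nf.boundary_vector({"Glc": {"difference": 0.5, "pm": 0.0}}, Q=0.55, F=1.0)


class TestAtomAudit:
    def test_gad_and_gs_exactly_balanced(self, model):
        report = {
            e.reaction_id: e
            for e in nf.audit_atom_balance(model.system.reactions, model.atoms)
        }
        for rid in ("GAD@GABAergic-cytosol", "GS@astrocyte-cytosol"):
            assert report[rid].carbon_imbalance == 0
            assert report[rid].nitrogen_imbalance == 0

    def test_bckdh_lumped_carbon_deficit_flagged_not_failed(self, model):
        report = nf.audit_atom_balance(model.system.reactions, model.atoms)
        bckdh = [e for e in report if e.reaction_id.startswith("BCKDH@")]
        assert bckdh and all(e.carbon_imbalance == -3 for e in bckdh)
        assert all(e.flagged_lumped for e in bckdh)
        assert nf.audit_failures(report) == []

    def test_missing_metabolite_raises(self, model):
        atoms = nf.AtomTable(
            counts={}, cofactors=model.atoms.cofactors, lumped_whitelist=frozenset()
        )
        with pytest.raises(ModelError, match="missing"):
            nf.audit_atom_balance(model.system.reactions[:1], atoms)
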