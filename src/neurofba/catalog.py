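"""Reaction and transport catalogs of the compartmentalized network.

The packaged model document (``data/brain_model.json``) transcribes the
reaction table row-by-row (one stoichiometry per row, with the list of
compartments carrying the enzyme and the arrow type) and the transport
table interface-by-interface.  The loaders below expand those rows into
per-compartment :class:`ReactionSpec` and per-(species, interface, cell)
:class:`TransportSpec` instances.

Cell-assignment policy for transports: every ECS<->cytosol and
cytosol<->mitochondria row is instantiated for all three cell types except
where enzyme localisation dictates otherwise -- the Leu/KIC mitochondrial
carriers exist in the astrocyte only (neuronal branched-chain
aminotransferase is cytosolic), and each vesicular efflux exists only in
its own neuron type.  Astrocytic uptake of transmitter glutamate and GABA
carries one coupled ATP hydrolysis (recycling cost).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, NamedTuple

from .compartments import (
    BLOOD,
    CELLS,
    COMPARTMENTS,
    ECS,
    are_adjacent,
    cytosol_of,
    mitochondria_of,
)

#: metabolite vocabulary of the model
METABOLITES = frozenset(
    [
        "Glc", "Lac", "Pyr", "Glu", "Gln", "GABA", "GABA_vesicular",
        "Glu_vesicular", "AKG", "OAA", "Mal", "Fum", "Suc", "SSA", "CIT",
        "SCoA", "ACoA", "CoA", "Asp", "Ala", "Leu", "KIC", "NH4+", "O2",
        "CO2", "ATP", "ADP", "Pi", "NAD+", "NADH", "G6P", "GA3P", "BPG",
    ]
)


class Species(NamedTuple):
    """A metabolite in a specific compartment.

    The same metabolite appearing in several compartments is a distinct
    species in each.
    """

    name: str
    compartment: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.name}@{self.compartment}"


class ModelError(ValueError):
    """Malformed model document or catalog."""


@dataclass(frozen=True)
class ReactionSpec:
    """One enzymatic step in one compartment.

    ``stoichiometry`` maps metabolite names (all residing in
    ``compartment``) to signed coefficients, reactants negative.
    """

    id: str
    compartment: str
    stoichiometry: Mapping[str, float]
    reversible: bool
    group: str | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelError(f"{self.id}: unknown compartment {self.compartment!r}")
        for name in self.stoichiometry:
            if name not in METABOLITES:
                raise ModelError(f"{self.id}: unknown metabolite {name!r}")
        if not self.stoichiometry:
            raise ModelError(f"{self.id}: empty stoichiometry")

    @property
    def species_stoichiometry(self) -> dict[Species, float]:
        return {
            Species(name, self.compartment): coef
            for name, coef in self.stoichiometry.items()
        }


@dataclass(frozen=True)
class TransportSpec:
    """Movement of one species (or an antiport pair) between two adjacent
    compartments.

    The positive flux direction is ``from_compartment -> to_compartment``;
    bidirectional transports may take negative values.  ``coupled_cost``
    attaches extra species turnover in the destination compartment (the
    astrocytic transmitter-uptake ATP cost).
    """

    id: str
    species_moved: str | tuple[str, str]
    from_compartment: str
    to_compartment: str
    direction: str  # "unidirectional" | "bidirectional"
    #: for antiporters: the counter-transported species (moved to -> from)
    counter_species: str | None = None
    coupled_cost: Mapping[str, float] | None = None
    #: species name delivered on the far side when it differs from the one
    #: removed (vesicular pools release the free transmitter into ECS)
    species_delivered: str | None = None

    def __post_init__(self) -> None:
        if not are_adjacent(self.from_compartment, self.to_compartment):
            raise ModelError(
                f"{self.id}: {self.from_compartment} and {self.to_compartment} "
                "are not adjacent compartments"
            )
        if self.direction not in ("unidirectional", "bidirectional"):
            raise ModelError(f"{self.id}: bad direction {self.direction!r}")

    @property
    def species_stoichiometry(self) -> dict[Species, float]:
        moved = self.species_moved
        if isinstance(moved, tuple):
            raise ModelError(f"{self.id}: ambiguous antiport pair")
        delivered = self.species_delivered or moved
        st: dict[Species, float] = {
            Species(moved, self.from_compartment): -1.0,
            Species(delivered, self.to_compartment): 1.0,
        }
        if self.counter_species is not None:
            st[Species(self.counter_species, self.to_compartment)] = -1.0
            st[Species(self.counter_species, self.from_compartment)] = 1.0
        if self.coupled_cost:
            for name, coef in self.coupled_cost.items():
                sp = Species(name, self.to_compartment)
                st[sp] = st.get(sp, 0.0) + coef
        return st


# ---------------------------------------------------------------------------
# model document


def packaged_model_document() -> dict:
    """The shipped network-definition document (parsed JSON)."""
    with resources.files("neurofba.data").joinpath("brain_model.json").open() as fh:
        return json.load(fh)


def packaged_boundary_document() -> dict:
    with resources.files("neurofba.data").joinpath("boundary.json").open() as fh:
        return json.load(fh)


def load_reaction_catalog(document: Mapping) -> list[ReactionSpec]:
    """Expand the reaction rows of a model document.

    Returns one :class:`ReactionSpec` per (row, marked compartment) pair,
    in document order.
    """
    reactions: list[ReactionSpec] = []
    for row in document["reactions"]:
        if not row.get("compartments"):
            raise ModelError(f"reaction {row.get('id')!r}: no compartments marked")
        for comp in row["compartments"]:
            if comp not in COMPARTMENTS:
                raise ModelError(f"reaction {row['id']}: unknown compartment {comp!r}")
            reactions.append(
                ReactionSpec(
                    id=f"{row['id']}@{comp}",
                    compartment=comp,
                    stoichiometry=dict(row["stoichiometry"]),
                    reversible=bool(row["reversible"]),
                    group=row.get("group"),
                )
            )
    return reactions


_ARROWS = {"->", "<-", "<->"}


def _interface_transport(
    species: str, frm: str, to: str, arrow: str, cost: Mapping[str, float] | None = None
) -> TransportSpec:
    if arrow not in _ARROWS:
        raise ModelError(f"bad arrow {arrow!r} for {species} {frm}->{to}")
    if arrow == "<-":
        frm, to = to, frm
    return TransportSpec(
        id=f"{species}/{frm}->{to}",
        species_moved=species,
        from_compartment=frm,
        to_compartment=to,
        direction="bidirectional" if arrow == "<->" else "unidirectional",
        coupled_cost=dict(cost) if cost else None,
    )


def load_transport_catalog(document: Mapping) -> list[TransportSpec]:
    """Expand transport rows, carriers, vesicular effluxes and uptake costs."""
    costs: dict[tuple[str, str], float] = {}
    for entry in document.get("uptake_costs", []):
        costs[(entry["species"], entry["cell"])] = float(entry["atp"])

    transports: list[TransportSpec] = []
    for row in document["transports"]:
        species = row["species"]
        if species not in METABOLITES:
            raise ModelError(f"transport row: unknown species {species!r}")
        if row.get("blood_ecs"):
            transports.append(
                _interface_transport(species, BLOOD, ECS, row["blood_ecs"])
            )
        if row.get("ecs_cytosol"):
            for cell in row.get("cytosol_cells", CELLS):
                cost = None
                atp = costs.get((species, cell))
                if atp:
                    cost = {"ATP": -atp, "ADP": atp, "Pi": atp}
                transports.append(
                    _interface_transport(
                        species, ECS, cytosol_of(cell), row["ecs_cytosol"], cost
                    )
                )
        if row.get("cytosol_mitochondria"):
            for cell in row.get("mitochondria_cells", CELLS):
                transports.append(
                    _interface_transport(
                        species,
                        cytosol_of(cell),
                        mitochondria_of(cell),
                        row["cytosol_mitochondria"],
                    )
                )

    for carrier in document.get("carriers", []):
        imported, exported = carrier["imports"], carrier["exports"]
        for cell in carrier["cells"]:
            transports.append(
                TransportSpec(
                    id=f"{carrier['id']}@{cell}",
                    species_moved=imported,
                    from_compartment=cytosol_of(cell),
                    to_compartment=mitochondria_of(cell),
                    direction="unidirectional",
                    counter_species=exported,
                )
            )

    for ves in document.get("vesicular_effluxes", []):
        cell = ves["cell"]
        vesicular = ves["species"]
        free = vesicular.replace("_vesicular", "")
        transports.append(
            TransportSpec(
                id=f"{vesicular}/{cytosol_of(cell)}->{ECS}",
                species_moved=vesicular,
                from_compartment=cytosol_of(cell),
                to_compartment=ECS,
                direction="unidirectional",
                species_delivered=free,
            )
        )
    _check_unique([t.id for t in transports])
    return transports


def _check_unique(ids: Iterable[str]) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ModelError(f"duplicate flux id {i!r}")
        seen.add(i)
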