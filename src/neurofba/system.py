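"""Assembly of the stoichiometric matrix, the boundary vector and audits.

At steady state every species balance reads ``(A u)_row = rhs_row`` where
``A`` stacks the stoichiometric columns of all reactions and transports and
``rhs`` is non-zero only for blood species.  The tissue uptake rate of a
blood-borne species is ``r_j = Q/F (Ca_j - Cv_j)`` (arteriovenous
difference times flow); with standard stoichiometric columns (a transport
leaving the blood depletes the blood species), the circulation term enters
the blood row as ``(A u)_row = -r_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .catalog import (
    ModelError,
    ReactionSpec,
    Species,
    TransportSpec,
)
from .compartments import BLOOD, COMPARTMENTS


@dataclass
class StoichiometricSystem:
    """The m-by-(n+k) stoichiometric matrix with its row/column indices."""

    matrix: np.ndarray
    species_index: list[Species]
    flux_index: list[str]
    n: int  # reaction count
    k: int  # transport count
    reactions: list[ReactionSpec] = field(default_factory=list)
    transports: list[TransportSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = len(self.species_index)
        if self.matrix.shape != (m, self.n + self.k):
            raise ModelError(
                f"matrix shape {self.matrix.shape} != ({m}, {self.n + self.k})"
            )
        self._col = {fid: j for j, fid in enumerate(self.flux_index)}
        self._row = {sp: i for i, sp in enumerate(self.species_index)}
        if len(self._col) != len(self.flux_index):
            raise ModelError("duplicate flux ids")

    @property
    def n_fluxes(self) -> int:
        return self.n + self.k

    def col(self, flux_id: str) -> int:
        try:
            return self._col[flux_id]
        except KeyError:
            raise KeyError(f"unknown flux id {flux_id!r}") from None

    def row(self, species: Species) -> int:
        try:
            return self._row[species]
        except KeyError:
            raise KeyError(f"unknown species {species}") from None

    def has_flux(self, flux_id: str) -> bool:
        return flux_id in self._col

    def value(self, u: np.ndarray, flux_id: str) -> float:
        """Flux value by id from a flux-transport vector (or sample mean)."""
        return float(u[self.col(flux_id)])

    @property
    def spec_by_id(self) -> dict[str, ReactionSpec | TransportSpec]:
        out: dict[str, ReactionSpec | TransportSpec] = {}
        for rx in self.reactions:
            out[rx.id] = rx
        for tr in self.transports:
            out[tr.id] = tr
        return out

    def reversibility(self) -> np.ndarray:
        """Boolean mask over flux_index: True where the flux may be negative."""
        rev = np.zeros(self.n_fluxes, dtype=bool)
        for rx in self.reactions:
            rev[self.col(rx.id)] = rx.reversible
        for tr in self.transports:
            rev[self.col(tr.id)] = tr.direction == "bidirectional"
        return rev

    def to_frame(self):
        """Labeled DataFrame view of A (rows = species, columns = fluxes)."""
        import pandas as pd

        return pd.DataFrame(
            self.matrix,
            index=[str(sp) for sp in self.species_index],
            columns=self.flux_index,
        )


def assemble_system(
    reactions: Sequence[ReactionSpec], transports: Sequence[TransportSpec]
) -> StoichiometricSystem:
    """Build the stoichiometric matrix from validated catalogs.

    Rows enumerate every (metabolite, compartment) species referenced by
    any catalog entry, grouped in compartment order; column ``i`` is the
    stoichiometric vector of flux ``i`` (reactions first, then transports).
    """
    columns: list[dict[Species, float]] = [
        rx.species_stoichiometry for rx in reactions
    ] + [tr.species_stoichiometry for tr in transports]
    flux_index = [rx.id for rx in reactions] + [tr.id for tr in transports]
    if len(set(flux_index)) != len(flux_index):
        dupes = sorted({f for f in flux_index if flux_index.count(f) > 1})
        raise ModelError(f"duplicate flux ids: {dupes}")

    # deterministic species order: compartment order, then first reference
    seen: dict[Species, None] = {}
    for col in columns:
        for sp in col:
            seen.setdefault(sp)
    order = {c: i for i, c in enumerate(COMPARTMENTS)}
    species_index = sorted(
        seen, key=lambda sp: (order[sp.compartment], list(seen).index(sp))
    )

    m = len(species_index)
    A = np.zeros((m, len(columns)))
    row = {sp: i for i, sp in enumerate(species_index)}
    for j, col in enumerate(columns):
        for sp, coef in col.items():
            A[row[sp], j] = coef

    system = StoichiometricSystem(
        matrix=A,
        species_index=species_index,
        flux_index=flux_index,
        n=len(reactions),
        k=len(transports),
        reactions=list(reactions),
        transports=list(transports),
    )
    # isolated rows: a species only produced or only consumed by a single
    # flux and not blood-exchanged is legal (its balance pins that flux),
    # but a species row with no entries at all cannot happen by construction;
    # guard against all-zero rows from cancelling coefficients anyway.
    zero_rows = np.where(np.abs(A).sum(axis=1) == 0)[0]
    if zero_rows.size:
        bad = [str(species_index[i]) for i in zero_rows]
        raise ModelError(f"isolated species rows: {bad}")
    return system


# ---------------------------------------------------------------------------
# boundary vector


@dataclass
class BoundaryVector:
    """Blood-exchange rates and per-equation standard deviations.

    ``rates[name]`` is the net tissue uptake r_j = Q/F (Ca - Cv) in
    umol/min/g (negative = net release, e.g. lactate); ``sigmas[name]`` the
    corresponding standard deviation Q/F * (printed +-).  Species with only
    an estimated venous value get rate 0 and the loose sigma, leaving their
    metabolic rate an output of the sampling.
    """

    rates: dict[str, float]
    sigmas: dict[str, float]
    Q: float
    F: float
    av_table: Mapping[str, Mapping]
    sigma_default: float = 0.005
    sigma_loose: float = 10.0

    def rhs_and_sigma(self, system: StoichiometricSystem) -> tuple[np.ndarray, np.ndarray]:
        """Full-length right-hand side and sigma vectors for ``A u = rhs``.

        Blood rows receive ``-rates`` (supply + internal change = 0, see
        module docstring) and their Table uncertainties; all other species
        rows are internal: rhs 0 and the default sigma.
        """
        m = len(system.species_index)
        rhs = np.zeros(m)
        sigma = np.full(m, self.sigma_default)
        for i, sp in enumerate(system.species_index):
            if sp.compartment == BLOOD:
                if sp.name not in self.rates:
                    raise ModelError(f"no boundary entry for blood species {sp.name!r}")
                rhs[i] = -self.rates[sp.name]
                sigma[i] = self.sigmas[sp.name]
        if np.any(sigma <= 0):
            raise ModelError("non-positive sigma in boundary vector")
        return rhs, sigma


def boundary_vector(
    av_table: Mapping[str, Mapping],
    Q: float,
    F: float,
    sigma_default: float = 0.005,
    sigma_loose: float = 10.0,
) -> BoundaryVector:
    """Convert an arteriovenous-difference table into exchange rates.

    ``av_table`` entries carry either a printed difference ``Ca - Cv`` with
    its ``pm`` uncertainty, or an arterial value with ``venous:
    "estimated"`` (O2/CO2), which yields an unconstrained exchange (rate 0,
    loose sigma) whose direction is fixed elsewhere by the transport arrow.
    """
    if Q <= 0 or F <= 0:
        raise ModelError("Q and F must be positive")
    rates: dict[str, float] = {}
    sigmas: dict[str, float] = {}
    for name, entry in av_table.items():
        if entry.get("venous") == "estimated" or "difference" not in entry:
            rates[name] = 0.0
            sigmas[name] = sigma_loose
            continue
        rates[name] = Q / F * float(entry["difference"])
        if entry.get("pm") is None:
            # exchanged species without a printed uncertainty: the blood
            # equation keeps the default model-equation sigma
            sigmas[name] = sigma_default
            continue
        sig = Q / F * float(entry["pm"])
        if sig <= 0:
            raise ModelError(f"non-positive sigma for {name!r}")
        sigmas[name] = sig
    return BoundaryVector(
        rates=rates,
        sigmas=sigmas,
        Q=Q,
        F=F,
        av_table=dict(av_table),
        sigma_default=sigma_default,
        sigma_loose=sigma_loose,
    )


# ---------------------------------------------------------------------------
# atom audit


@dataclass
class AtomTable:
    """Carbon/nitrogen counts per metabolite; cofactors are audited out."""

    counts: Mapping[str, tuple[int, int]]
    cofactors: frozenset[str]
    lumped_whitelist: frozenset[str]

    @classmethod
    def from_document(cls, document: Mapping) -> "AtomTable":
        atoms = document["atoms"]
        return cls(
            counts={k: tuple(v) for k, v in atoms["counts"].items()},
            cofactors=frozenset(atoms["cofactors"]),
            lumped_whitelist=frozenset(atoms["lumped_whitelist"]),
        )


@dataclass
class AtomAuditEntry:
    reaction_id: str
    carbon_imbalance: float
    nitrogen_imbalance: float
    flagged_lumped: bool

    @property
    def balanced(self) -> bool:
        return self.carbon_imbalance == 0 and self.nitrogen_imbalance == 0


def audit_atom_balance(
    reactions: Iterable[ReactionSpec], atoms: AtomTable
) -> list[AtomAuditEntry]:
    """Per-reaction net C and N imbalance (products minus reactants).

    Whitelisted lumped steps (the branched-chain ketoacid dehydrogenase,
    transcribed as printed with unaccounted carbons) are flagged rather
    than failed; any other metabolite missing from the table is an error.
    """
    report = []
    for rx in reactions:
        dc = dn = 0.0
        base = rx.id.split("@")[0]
        for name, coef in rx.stoichiometry.items():
            if name in atoms.cofactors:
                continue
            if name not in atoms.counts:
                raise ModelError(f"{rx.id}: metabolite {name!r} missing from atom table")
            c, n = atoms.counts[name]
            dc += coef * c
            dn += coef * n
        report.append(
            AtomAuditEntry(
                reaction_id=rx.id,
                carbon_imbalance=dc,
                nitrogen_imbalance=dn,
                flagged_lumped=base in atoms.lumped_whitelist,
            )
        )
    return report


def audit_failures(report: Iterable[AtomAuditEntry]) -> list[AtomAuditEntry]:
    return [e for e in report if not e.balanced and not e.flagged_lumped]
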