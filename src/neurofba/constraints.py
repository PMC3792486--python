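"""Hard linear inequality constraints ``C u >= c`` on the flux vector.

Three sources: (i) irreversibility of one-way reactions and transports
(thermodynamic direction, from the arrow type of the catalog), (ii)
scenario toggles restricting glutamate dehydrogenase to its oxidative
direction and/or leucine transport into the astrocyte, and (iii) a global
magnitude bound |u_i| <= Vmax that makes the feasible polytope bounded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .catalog import ModelError
from .compartments import CELLS, ECS, cytosol_of, mitochondria_of
from .system import StoichiometricSystem

DEFAULT_VMAX = 10.0  # umol/min/g; "possibly large" upper magnitude bound


@dataclass
class ConstraintSystem:
    """Row-wise inequality system C u >= c with per-row provenance labels."""

    C: np.ndarray
    c: np.ndarray
    labels: list[str]
    flux_index: list[str]

    def __post_init__(self) -> None:
        p = len(self.c)
        if self.C.shape != (p, len(self.flux_index)):
            raise ModelError(f"C shape {self.C.shape} inconsistent with c/flux index")
        if len(self.labels) != p:
            raise ModelError("one label per constraint row required")

    @property
    def n_rows(self) -> int:
        return len(self.c)

    def satisfied(self, u: np.ndarray, tol: float = 1e-9) -> bool:
        if self.n_rows == 0:
            return True
        return bool(np.all(self.C @ u - self.c >= -tol))

    def slack(self, u: np.ndarray) -> np.ndarray:
        return self.C @ u - self.c

    @classmethod
    def empty(cls, flux_index: Sequence[str]) -> "ConstraintSystem":
        d = len(flux_index)
        return cls(np.zeros((0, d)), np.zeros(0), [], list(flux_index))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.C, columns=self.flux_index)
        df.insert(0, "label", self.labels)
        df["c"] = self.c
        return df


@dataclass
class Scenario:
    """A named set of direction toggles plus target-flux controls.

    * S1: GDH oxidative-only in every cell and leucine transported from
      ECS into the astrocyte only.
    * S2: GDH bidirectional, leucine constraint kept.
    * S3: both constraints removed (leucine direction free).

    Every scenario carries the inhibitory-activity target: vesicular GABA
    efflux 0.13 umol/min with control width w = 0.005 umol/min.
    """

    id: str
    gdh_oxidative_only: bool
    leucine_into_astrocyte_only: bool
    targets: list[tuple[str, float, float]] = field(default_factory=list)

    GABA_EFFLUX_ID = "GABA_vesicular/GABAergic-cytosol->ECS"

    @classmethod
    def preset(cls, scenario_id: str) -> "Scenario":
        toggles = {
            "S1": (True, True),
            "S2": (False, True),
            "S3": (False, False),
        }
        key = scenario_id.split("-")[0].upper()
        if key not in toggles:
            raise ModelError(f"unknown scenario {scenario_id!r}")
        gdh, leu = toggles[key]
        return cls(
            id=key,
            gdh_oxidative_only=gdh,
            leucine_into_astrocyte_only=leu,
            targets=[(cls.GABA_EFFLUX_ID, 0.13, 0.005)],
        )


def _single_row(d: int, j: int, sign: float = 1.0) -> np.ndarray:
    row = np.zeros(d)
    row[j] = sign
    return row


def irreversibility_constraints(system: StoichiometricSystem) -> ConstraintSystem:
    """One row u_i >= 0 per irreversible reaction / unidirectional transport."""
    d = system.n_fluxes
    rev = system.reversibility()
    rows, labels = [], []
    for j, fid in enumerate(system.flux_index):
        if not rev[j]:
            rows.append(_single_row(d, j))
            labels.append(f"irreversibility:{fid}")
    C = np.vstack(rows) if rows else np.zeros((0, d))
    return ConstraintSystem(C, np.zeros(len(rows)), labels, list(system.flux_index))


def scenario_constraints(
    scenario: Scenario, system: StoichiometricSystem
) -> ConstraintSystem:
    """Rows for the active scenario toggles.

    GDH oxidative-only contributes one row per cell type; the leucine
    prior-direction bound contributes a single row on the ECS->astrocyte
    leucine transport.
    """
    d = system.n_fluxes
    rows, labels = [], []
    if scenario.gdh_oxidative_only:
        for cell in CELLS:
            fid = f"GDH@{mitochondria_of(cell)}"
            if not system.has_flux(fid):
                raise ModelError(f"scenario {scenario.id}: flux {fid!r} absent")
            rows.append(_single_row(d, system.col(fid)))
            labels.append(f"scenario:{fid}>=0")
    if scenario.leucine_into_astrocyte_only:
        fid = f"Leu/{ECS}->{cytosol_of('astrocyte')}"
        if not system.has_flux(fid):
            raise ModelError(f"scenario {scenario.id}: flux {fid!r} absent")
        rows.append(_single_row(d, system.col(fid)))
        labels.append(f"scenario:{fid}>=0")
    C = np.vstack(rows) if rows else np.zeros((0, d))
    return ConstraintSystem(C, np.zeros(len(rows)), labels, list(system.flux_index))


def vmax_bounds(
    system: StoichiometricSystem, vmax: float = DEFAULT_VMAX
) -> ConstraintSystem:
    """Magnitude bounds making the polytope bounded.

    Upper bounds -u_i >= -vmax for every flux; lower bounds u_i >= -vmax
    for reversible fluxes only (irreversible ones already have u_i >= 0).
    """
    if vmax <= 0:
        raise ModelError("vmax must be positive")
    d = system.n_fluxes
    rev = system.reversibility()
    rows, cs, labels = [], [], []
    for j, fid in enumerate(system.flux_index):
        rows.append(_single_row(d, j, -1.0))
        cs.append(-vmax)
        labels.append(f"vmax:{fid}<= {vmax}")
        if rev[j]:
            rows.append(_single_row(d, j, 1.0))
            cs.append(-vmax)
            labels.append(f"vmax:{fid}>= -{vmax}")
    return ConstraintSystem(
        np.vstack(rows), np.asarray(cs, dtype=float), labels, list(system.flux_index)
    )


def merge_constraints(parts: Sequence[ConstraintSystem]) -> ConstraintSystem:
    """Concatenate constraint systems sharing one flux index, de-duplicating
    identical rows (same coefficients and right-hand side)."""
    parts = [p for p in parts]
    if not parts:
        raise ModelError("nothing to merge")
    flux_index = parts[0].flux_index
    for p in parts[1:]:
        if p.flux_index != flux_index:
            raise ModelError("incompatible flux indices in merge")
    rows, cs, labels = [], [], []
    seen: set[bytes] = set()
    for p in parts:
        for i in range(p.n_rows):
            key = np.ascontiguousarray(
                np.concatenate([p.C[i], [p.c[i]]])
            ).tobytes()
            if key in seen:
                continue
            seen.add(key)
            rows.append(p.C[i])
            cs.append(p.c[i])
            labels.append(p.labels[i])
    C = np.vstack(rows) if rows else np.zeros((0, len(flux_index)))
    return ConstraintSystem(C, np.asarray(cs, dtype=float), labels, list(flux_index))


def build_scenario_constraints(
    system: StoichiometricSystem,
    scenario: Scenario,
    vmax: float = DEFAULT_VMAX,
) -> ConstraintSystem:
    """Irreversibility + scenario toggles + Vmax box, merged."""
    return merge_constraints(
        [
            irreversibility_constraints(system),
            scenario_constraints(scenario, system),
            vmax_bounds(system, vmax),
        ]
    )


def polytope_is_feasible(constraints: ConstraintSystem) -> bool:
    """LP feasibility of {u : C u >= c} (soft equations ignored)."""
    d = len(constraints.flux_index)
    res = linprog(
        c=np.zeros(d),
        A_ub=-constraints.C,
        b_ub=-constraints.c,
        bounds=[(None, None)] * d,
        method="highs",
    )
    return bool(res.success)


def coordinate_range(
    constraints: ConstraintSystem, flux_id: str
) -> tuple[float, float]:
    """LP min/max of one coordinate over the polytope (boundedness probe)."""
    d = len(constraints.flux_index)
    j = constraints.flux_index.index(flux_id)
    obj = np.zeros(d)
    obj[j] = 1.0
    lo = linprog(obj, A_ub=-constraints.C, b_ub=-constraints.c,
                 bounds=[(None, None)] * d, method="highs")
    hi = linprog(-obj, A_ub=-constraints.C, b_ub=-constraints.c,
                 bounds=[(None, None)] * d, method="highs")
    if not (lo.success and hi.success):
        raise ModelError(f"coordinate range LP failed for {flux_id!r} (unbounded?)")
    return float(lo.fun), float(-hi.fun)
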