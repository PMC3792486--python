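"""The truncated-Gaussian flux density and its quadratic form.

The sampling target is

    pi(u)  ∝  H(Cu - c) · exp(-1/2 (Au - r)^T Sigma^-1 (Au - r))
                        · prod_l exp(-1/(2 w_l^2) (u_l - t_l)^2)

with H the indicator of the inequality polytope, Sigma the diagonal
covariance of the soft steady-state equations, and optional target-flux
controls pulling selected coordinates toward prescribed values.  The
Gaussian part is the quadratic form with precision

    P = A^T Sigma^-1 A + diag(w^-2 on targeted coordinates)

and linear term h = A^T Sigma^-1 r + w^-2 t, so that
log pi(u) = -1/2 u^T P u + h^T u + const on the feasible set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .catalog import ModelError
from .constraints import ConstraintSystem
from .system import BoundaryVector, StoichiometricSystem


@dataclass(frozen=True)
class TargetControl:
    """Soft control pulling flux ``flux_id`` toward ``target`` with sd ``weight``."""

    flux_id: str
    target: float
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ModelError(f"target weight must be positive ({self.flux_id})")


@dataclass
class DensityModel:
    """Quadratic-form representation of the truncated Gaussian flux density."""

    system: StoichiometricSystem
    boundary: BoundaryVector
    constraints: ConstraintSystem
    targets: list[TargetControl]
    precision: np.ndarray          # P, (n+k) x (n+k)
    shift: np.ndarray              # h, length n+k
    rhs: np.ndarray                # full-length r (per species row)
    sigma: np.ndarray              # per-equation standard deviations
    #: constant completing log pi = -1/2 u^T P u + h^T u + log_const_offset
    log_const_offset: float = 0.0

    @property
    def dim(self) -> int:
        return self.system.n_fluxes

    def log_density(self, u: np.ndarray) -> float:
        """Unnormalized log density; -inf outside the polytope.

        Evaluated directly from the residual form so it stays exact even
        where the quadratic form loses precision.
        """
        u = np.asarray(u, dtype=float)
        if not self.constraints.satisfied(u):
            return -np.inf
        resid = (self.system.matrix @ u - self.rhs) / self.sigma
        val = -0.5 * float(resid @ resid)
        for t in self.targets:
            j = self.system.col(t.flux_id)
            val += -0.5 * ((u[j] - t.target) / t.weight) ** 2
        return val


def build_density(
    system: StoichiometricSystem,
    boundary: BoundaryVector,
    constraints: ConstraintSystem,
    targets: Sequence[TargetControl] = (),
) -> DensityModel:
    """Assemble precision matrix and linear shift for the flux density."""
    if constraints.flux_index != system.flux_index:
        raise ModelError("constraint system indexed over a different flux set")
    rhs, sigma = boundary.rhs_and_sigma(system)
    if np.any(sigma <= 0):
        raise ModelError("non-positive sigma")
    A = system.matrix
    Aw = A / sigma[:, None]
    P = Aw.T @ Aw
    h = Aw.T @ (rhs / sigma)
    for t in targets:
        j = system.col(t.flux_id)
        P[j, j] += 1.0 / t.weight**2
        h[j] += t.target / t.weight**2
    return DensityModel(
        system=system,
        boundary=boundary,
        constraints=constraints,
        targets=list(targets),
        precision=P,
        shift=h,
        rhs=rhs,
        sigma=sigma,
    )


def feasible_point(
    constraints: ConstraintSystem, margin: float = 1.0
) -> np.ndarray:
    """Chebyshev-center style interior point of {u : C u >= c}.

    Maximizes the uniform slack s subject to C u - c >= ||row|| * s and
    s <= margin; an infeasible polytope raises with the LP status and, when
    identifiable, a small violated row subset.
    """
    d = len(constraints.flux_index)
    C, c = constraints.C, constraints.c
    if C.shape[0] == 0:
        return np.zeros(d)
    norms = np.linalg.norm(C, axis=1)
    norms[norms == 0] = 1.0
    # variables: (u, s); maximize s
    A_ub = np.hstack([-C, norms[:, None]])
    b_ub = -c
    obj = np.zeros(d + 1)
    obj[-1] = -1.0
    res = linprog(
        obj,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * d + [(None, margin)],
        method="highs",
    )
    if not res.success:
        raise ModelError(
            "infeasible constraint polytope: "
            + _describe_infeasibility(constraints)
        )
    u = res.x[:d]
    if not constraints.satisfied(u, tol=1e-7):
        raise ModelError("Chebyshev LP returned an infeasible point")
    return u


def coordinate_bounds(
    constraints: ConstraintSystem,
) -> tuple[np.ndarray, np.ndarray] | None:
    """(lo, hi) per coordinate if every row bounds a single coordinate,
    else None (general polytope)."""
    d = len(constraints.flux_index)
    lo = np.full(d, -np.inf)
    hi = np.full(d, np.inf)
    for i in range(constraints.n_rows):
        row = constraints.C[i]
        nz = np.nonzero(row)[0]
        if nz.size != 1:
            return None
        j = nz[0]
        coef = row[j]
        bound = constraints.c[i] / coef
        if coef > 0:
            lo[j] = max(lo[j], bound)
        else:
            hi[j] = min(hi[j], bound)
    return lo, hi


def posterior_mode(density: DensityModel) -> np.ndarray:
    """Constrained maximizer of the density (sampler initialization).

    When the hard constraints are pure coordinate bounds (the full model:
    irreversibility + Vmax box) this is an exact box-constrained least
    squares solve; otherwise falls back to the Chebyshev center.  Starting
    the chain on the soft-balance manifold removes an otherwise very long
    burn-in transient.
    """
    from scipy.optimize import lsq_linear

    box = coordinate_bounds(density.constraints)
    if box is None:
        return feasible_point(density.constraints)
    lo, hi = box
    sys_ = density.system
    rows = [sys_.matrix / density.sigma[:, None]]
    rhs = [density.rhs / density.sigma]
    d = sys_.n_fluxes
    for t in density.targets:
        e = np.zeros((1, d))
        e[0, sys_.col(t.flux_id)] = 1.0 / t.weight
        rows.append(e)
        rhs.append(np.array([t.target / t.weight]))
    res = lsq_linear(
        np.vstack(rows), np.concatenate(rhs), bounds=(lo, hi), tol=1e-12,
        max_iter=300,
    )
    u = np.clip(res.x, lo, hi)
    if not density.constraints.satisfied(u, tol=1e-9):  # pragma: no cover
        return feasible_point(density.constraints)
    return u


def _describe_infeasibility(constraints: ConstraintSystem) -> str:
    """Greedy search for a small mutually infeasible row subset."""
    C, c, labels = constraints.C, constraints.c, constraints.labels
    d = C.shape[1]
    active: list[int] = []
    culprit: list[int] | None = None
    for i in range(C.shape[0]):
        active.append(i)
        res = linprog(
            np.zeros(d),
            A_ub=-C[active],
            b_ub=-c[active],
            bounds=[(None, None)] * d,
            method="highs",
        )
        if not res.success:
            culprit = list(active)
            break
    if culprit is None:
        return "no violated subset identified"
    # prune: drop rows whose removal keeps the subset infeasible
    keep = list(culprit)
    for i in list(keep):
        trial = [j for j in keep if j != i]
        if not trial:
            continue
        res = linprog(
            np.zeros(d),
            A_ub=-C[trial],
            b_ub=-c[trial],
            bounds=[(None, None)] * d,
            method="highs",
        )
        if not res.success:
            keep = trial
    return "irreducible violated subset: " + ", ".join(labels[i] for i in keep)
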