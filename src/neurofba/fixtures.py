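"""Small synthetic stoichiometric systems and brute-force oracles.

These fixtures reproduce the statistical structure of the full analysis --
soft Gaussian equality constraints on a stoichiometric balance, hard
linear inequalities, optional target controls -- at dimensions small
enough (<= 6 fluxes) that exact rejection sampling is tractable, so the
MCMC kernels can be validated against an independent oracle.  They make
no attempt at biological realism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.optimize import minimize

from .catalog import ModelError, Species
from .constraints import ConstraintSystem
from .density import DensityModel, build_density
from .sampler import FluxSample
from .system import StoichiometricSystem


@dataclass
class ExplicitBoundary:
    """Boundary with directly prescribed right-hand side and sigmas."""

    rhs: np.ndarray
    sigma: np.ndarray

    def rhs_and_sigma(self, system: StoichiometricSystem):
        if len(self.rhs) != len(system.species_index):
            raise ModelError("boundary length mismatch")
        if np.any(self.sigma <= 0):
            raise ModelError("non-positive sigma")
        return np.asarray(self.rhs, float), np.asarray(self.sigma, float)


@dataclass
class ToySystem:
    system: StoichiometricSystem
    boundary: ExplicitBoundary
    constraints: ConstraintSystem
    #: analytic description of the target density's moments where available
    closed_form: Mapping | None = None

    def density(self, targets=()) -> DensityModel:
        return build_density(self.system, self.boundary, self.constraints, targets)


def _bare_system(A: np.ndarray, flux_ids: list[str]) -> StoichiometricSystem:
    m = A.shape[0]
    species = [Species(f"X{i + 1}", "ECS") for i in range(m)]
    return StoichiometricSystem(
        matrix=A, species_index=species, flux_index=flux_ids, n=len(flux_ids), k=0
    )


def _box_constraints(
    flux_ids: list[str], lo: np.ndarray, hi: np.ndarray
) -> ConstraintSystem:
    d = len(flux_ids)
    C = np.vstack([np.eye(d), -np.eye(d)])
    c = np.concatenate([lo, -hi])
    labels = [f"box:{f}>={v:g}" for f, v in zip(flux_ids, lo)] + [
        f"box:{f}<={v:g}" for f, v in zip(flux_ids, hi)
    ]
    return ConstraintSystem(C, c, labels, list(flux_ids))


def toy_chain_system(
    length: int, influx: float, sigma: float, vmax: float = 10.0
) -> ToySystem:
    """Linear pathway X1 -> X2 -> ... with boundary influx at X1.

    Fluxes f_i carry X_i to X_{i+1} (the last one out of the system); the
    soft balances pin every flux to the influx.  All fluxes are
    irreversible (f_i >= 0) and bounded above by ``vmax``.  With influx 0
    the length-1 marginal is the half-normal with scale sigma.
    """
    if length < 1:
        raise ModelError("length must be >= 1")
    if sigma <= 0:
        raise ModelError("non-positive sigma")
    A = np.zeros((length, length))
    for i in range(length):
        A[i, i] = -1.0
        if i > 0:
            A[i, i - 1] = 1.0
    flux_ids = [f"f{i + 1}" for i in range(length)]
    system = _bare_system(A, flux_ids)
    # external supply `influx` into X1: (A u)_1 = -influx
    rhs = np.zeros(length)
    rhs[0] = -influx
    boundary = ExplicitBoundary(rhs=rhs, sigma=np.full(length, sigma))
    constraints = _box_constraints(
        flux_ids, np.zeros(length), np.full(length, vmax)
    )
    closed_form: dict | None = None
    if length == 1:
        # single flux ~ N(influx, sigma^2) truncated to [0, vmax]
        closed_form = {"truncnorm": {"mean": influx, "sd": sigma, "lo": 0.0, "hi": vmax}}
    return ToySystem(system, boundary, constraints, closed_form)


def random_polytope_system(
    n_fluxes: int, n_equations: int, seed: int, sigma: float = 0.1
) -> ToySystem:
    """Random sparse balance system with box constraints.

    The right-hand side is A @ u0 for an interior u0, so the soft
    equations are exactly satisfiable and the box-bounded polytope is
    never empty.  Rank-deficient draws are redrawn (bounded retries).
    """
    if n_fluxes > 6:
        raise ModelError("fixture dimension capped at 6 fluxes")
    if not 0 < n_equations < n_fluxes:
        raise ModelError("need 0 < n_equations < n_fluxes")
    rng = np.random.default_rng(seed)
    for _ in range(50):
        mask = rng.random((n_equations, n_fluxes)) < 0.7
        A = np.where(mask, np.round(rng.normal(size=mask.shape) * 2) / 2, 0.0)
        if np.linalg.matrix_rank(A, tol=1e-8) == n_equations and not np.any(
            np.abs(A).sum(axis=1) == 0
        ):
            break
    else:  # pragma: no cover - essentially impossible
        raise ModelError("could not draw a full-rank system")
    flux_ids = [f"f{i + 1}" for i in range(n_fluxes)]
    system = _bare_system(A, flux_ids)
    u0 = rng.uniform(0.2, 1.0, n_fluxes)
    boundary = ExplicitBoundary(
        rhs=A @ u0, sigma=np.full(n_equations, sigma)
    )
    constraints = _box_constraints(
        flux_ids, np.full(n_fluxes, -1.5), np.full(n_fluxes, 2.5)
    )
    return ToySystem(system, boundary, constraints)


# ---------------------------------------------------------------------------
# rejection oracle


def _log_density_batch(density: DensityModel, X: np.ndarray) -> np.ndarray:
    """Vectorized unnormalized log density over rows of X (no H factor)."""
    resid = (X @ density.system.matrix.T - density.rhs) / density.sigma
    val = -0.5 * np.einsum("ij,ij->i", resid, resid)
    for t in density.targets:
        j = density.system.col(t.flux_id)
        val = val - 0.5 * ((X[:, j] - t.target) / t.weight) ** 2
    return val


def _bounding_box(constraints: ConstraintSystem) -> tuple[np.ndarray, np.ndarray]:
    from .constraints import coordinate_range

    lo, hi = [], []
    for fid in constraints.flux_index:
        a, b = coordinate_range(constraints, fid)
        lo.append(a)
        hi.append(b)
    return np.asarray(lo), np.asarray(hi)


def rejection_oracle(
    density: DensityModel,
    N: int,
    seed: int,
    acceptance_floor: float = 1e-4,
) -> FluxSample:
    """Exact independent draws from the truncated Gaussian density.

    Uniform proposals on the polytope's coordinate bounding box are
    accepted with probability proportional to the Gaussian factor, scaled
    by its maximum over the box (convex quadratic maximization; verified
    by grid search at dimension <= 3).  Exact in distribution but only
    tractable for tiny systems.
    """
    d = density.dim
    if d > 6:
        raise ModelError("rejection oracle limited to <= 6 fluxes")
    lo, hi = _bounding_box(density.constraints)
    # maximum of the smooth log density over the box
    def neg(x):
        return -_log_density_batch(density, x[None, :])[0]

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(5):
        x0 = rng.uniform(lo, hi)
        res = minimize(neg, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        best = min(best, float(res.fun))
    if d <= 3:
        axes = [np.linspace(a, b, 41) for a, b in zip(lo, hi)]
        grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, d)
        best = min(best, float(-_log_density_batch(density, grid).max()))
    log_max = -best

    draws = np.empty((N, d))
    got = 0
    proposed = 0
    batch = max(4 * N, 10_000)
    while got < N:
        X = rng.uniform(lo, hi, size=(batch, d))
        logp = _log_density_batch(density, X)
        ok = np.log(rng.random(batch)) <= logp - log_max
        # enforce the hard constraints (H factor)
        if density.constraints.n_rows:
            ok &= np.all(
                X @ density.constraints.C.T - density.constraints.c >= -1e-12,
                axis=1,
            )
        proposed += batch
        acc = X[ok]
        take = min(N - got, acc.shape[0])
        draws[got : got + take] = acc[:take]
        got += take
        if proposed >= 50_000 and got / proposed < acceptance_floor:
            raise ModelError(
                f"rejection acceptance rate {got / proposed:.2e} below floor; "
                "use a smaller toy system"
            )
    return FluxSample(
        vectors=draws,
        flux_index=list(density.system.flux_index),
        meta={"method": "rejection-oracle", "seed": seed, "N": N},
    )


def perturbed_boundary_table(base: Mapping[str, Mapping], seed: int) -> dict:
    """Arteriovenous table with differences jittered by their printed +-.

    Zero-mean Gaussian noise at the printed uncertainty scale; entries with
    estimated venous values are passed through unchanged.  Sign conventions
    are respected only through the density, never by clipping.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}
    for name, entry in base.items():
        e = dict(entry)
        if "difference" in e and e.get("venous") != "estimated":
            e["difference"] = float(e["difference"]) + rng.normal(
                0.0, float(e.get("pm") or 0.0)
            )
        out[name] = e
    return out
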