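"""MCMC sampling of the truncated-Gaussian flux density.

The default method ("gibbs") runs exact truncated-normal Gibbs sweeps in
the eigenbasis of the precision matrix: there the Gaussian factor is
diagonal, so the full conditionals are independent apart from the polytope
constraints, and the chain mixes across the stiff soft-equation directions
and the flat null-space directions alike.  "gibbs-coordinate" sweeps the
raw flux coordinates (the textbook scheme; very slow mixing when the
equation standard deviations are orders of magnitude below the flux
scale), and "hit-and-run" serves as an independent cross-check kernel.
All methods are exact MCMC for the same density and are bit-reproducible
from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import _kernels
from .catalog import ModelError
from .density import DensityModel, posterior_mode

#: conditional precisions below FLAT_TOL * max diagonal entry are treated
#: as flat (null-space) directions and drawn uniformly on the feasible
#: interval
FLAT_TOL = 1e-12

DEFAULT_BURN_IN = 10_000

_METHODS = ("gibbs", "gibbs-coordinate", "hit-and-run")


@dataclass
class FluxSample:
    """An ordered MCMC sample of flux-transport vectors with provenance."""

    vectors: np.ndarray  # (N, n+k)
    flux_index: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] < 1:
            raise ModelError("sample must hold at least one vector")
        if self.vectors.shape[1] != len(self.flux_index):
            raise ModelError("sample width inconsistent with flux index")

    @property
    def n(self) -> int:
        return self.vectors.shape[0]

    def column(self, flux_id: str) -> np.ndarray:
        return self.vectors[:, self.flux_index.index(flux_id)]


def mcmc_sample(
    density: DensityModel,
    start: np.ndarray | None = None,
    N: int = 10_000,
    burn_in: int = DEFAULT_BURN_IN,
    thinning: int = 1,
    seed: int = 0,
    method: str = "gibbs",
) -> FluxSample:
    """Draw N post-burn-in flux vectors from the truncated Gaussian.

    ``start`` defaults to the constrained posterior mode.  Every stored
    vector is verified against the hard constraints before the sample is
    returned.
    """
    if method not in _METHODS:
        raise ModelError(f"unknown method {method!r}; expected one of {_METHODS}")
    if N < 1:
        raise ModelError("N must be >= 1")
    if thinning < 1 or burn_in < 0:
        raise ModelError("bad burn-in/thinning")
    if start is None:
        start = posterior_mode(density)
    start = np.asarray(start, dtype=float)
    if not density.constraints.satisfied(start, tol=1e-9):
        raise ModelError("start point violates the hard constraints")

    P = density.precision
    h = density.shift
    C = np.ascontiguousarray(density.constraints.C, dtype=float)
    c = np.ascontiguousarray(density.constraints.c, dtype=float)
    seed = int(seed) % (2**31)

    if method == "gibbs":
        # rotate to the precision eigenbasis
        lam, V = np.linalg.eigh(P)
        lam = np.maximum(lam, 0.0)
        Pv = np.diag(lam)
        hv = V.T @ h
        Cv = np.ascontiguousarray(C @ V)
        v0 = V.T @ start
        out_v = _kernels.gibbs_kernel(
            Pv, hv, Cv, c, v0, N, burn_in, thinning, seed, FLAT_TOL
        )
        vectors = out_v @ V.T
    elif method == "gibbs-coordinate":
        vectors = _kernels.gibbs_kernel(
            np.ascontiguousarray(P),
            h,
            C,
            c,
            start,
            N,
            burn_in,
            thinning,
            seed,
            FLAT_TOL,
        )
    else:  # hit-and-run
        vectors = _kernels.hitandrun_kernel(
            np.ascontiguousarray(P),
            h,
            C,
            c,
            start,
            N,
            burn_in,
            thinning,
            seed,
            FLAT_TOL,
        )

    _assert_feasible(density, vectors)
    meta = {
        "method": method,
        "seed": seed,
        "burn_in": burn_in,
        "thinning": thinning,
        "N": N,
        "targets": [
            {"flux_id": t.flux_id, "target": t.target, "weight": t.weight}
            for t in density.targets
        ],
    }
    return FluxSample(
        vectors=vectors, flux_index=list(density.system.flux_index), meta=meta
    )


def _assert_feasible(density: DensityModel, vectors: np.ndarray) -> None:
    """Hard-constraint preservation check on every stored vector."""
    C, c = density.constraints.C, density.constraints.c
    if C.shape[0] == 0:
        return
    slack = vectors @ C.T - c
    worst = float(slack.min())
    if worst < -1e-8:
        i, j = np.unravel_index(np.argmin(slack), slack.shape)
        raise ModelError(
            f"sampled vector {i} violates constraint "
            f"{density.constraints.labels[j]!r} by {-worst:.3e}"
        )


def sample_mean(sample: FluxSample) -> np.ndarray:
    """Coordinate-wise arithmetic mean of the sample."""
    return sample.vectors.mean(axis=0)


def sample_spread(
    sample: FluxSample, interval: float = 0.9
) -> Mapping[str, np.ndarray]:
    """Per-flux sd (unbiased) and central empirical credible interval."""
    if sample.n < 2:
        raise ModelError("spread requires at least two vectors")
    lo_q = 0.5 * (1.0 - interval)
    lo, hi = np.quantile(sample.vectors, [lo_q, 1.0 - lo_q], axis=0)
    return {
        "sd": sample.vectors.std(axis=0, ddof=1),
        "lower": lo,
        "upper": hi,
    }


def effective_sample_size(x: np.ndarray) -> float:
    """ESS of a scalar chain via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    var = float(x @ x) / n
    if var == 0.0:
        return 1.0
    # FFT autocovariance
    nf = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, nf)
    acov = np.fft.irfft(f * np.conj(f), nf)[:n].real / n
    rho = acov / acov[0]
    # Geyer initial positive sequence over pair sums
    s = 0.0
    for k in range(1, n // 2):
        pair = rho[2 * k - 1] + rho[2 * k]
        if pair < 0:
            break
        s += pair
    tau = max(1.0, 1.0 + 2.0 * s)
    return n / tau


def chain_diagnostics(
    sample: FluxSample, ess_floor: float = 100.0
) -> dict:
    """Per-flux ESS and split-chain convergence statistic.

    Fluxes with ESS below ``ess_floor`` or split-Rhat above 1.1 are
    flagged; the report is informational and never raises.
    """
    if sample.n < 100:
        raise ModelError("diagnostics require at least 100 vectors")
    X = sample.vectors
    n, d = X.shape
    half = n // 2
    ess = np.empty(d)
    rhat = np.empty(d)
    for j in range(d):
        col = X[:, j]
        ess[j] = effective_sample_size(col)
        a, b = col[:half], col[half : 2 * half]
        w = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
        if w <= 0:
            rhat[j] = 1.0
        else:
            bvar = half * ((a.mean() - col[: 2 * half].mean()) ** 2
                           + (b.mean() - col[: 2 * half].mean()) ** 2)
            rhat[j] = np.sqrt(((half - 1) / half * w + bvar / half) / w)
    flagged = [
        sample.flux_index[j]
        for j in range(d)
        if ess[j] < ess_floor or rhat[j] > 1.1
    ]
    return {
        "ess": ess,
        "split_rhat": rhat,
        "flagged": flagged,
        "ess_floor": ess_floor,
    }
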