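"""Shared fixtures: the assembled brain model and scenario sampling runs.

The sampling fixtures are session-scoped; their sizes are chosen so the
whole suite stays within a few minutes on one CPU while leaving enough
effective samples for the statistical assertions.
"""

from __future__ import annotations

import numpy as np
import pytest

import neurofba as nf

ACCEPT_SEED = 20131008  # fixed seed for the reproduction runs


@pytest.fixture(scope="session")
def model() -> nf.BrainModel:
    return nf.build_brain_model()


@pytest.fixture(scope="session")
def s1_sample(model):
    """Scenario S1 (oxidative GDH, leucine into astrocyte) posterior sample."""
    scenario = nf.Scenario.preset("S1")
    constraints = nf.build_scenario_constraints(model.system, scenario)
    targets = [nf.TargetControl(f, t, w) for f, t, w in scenario.targets]
    density = nf.build_density(model.system, model.boundary, constraints, targets)
    sample = nf.mcmc_sample(
        density, N=30_000, burn_in=10_000, seed=ACCEPT_SEED, method="gibbs"
    )
    sample.meta["scenario"] = "S1"
    return {"sample": sample, "density": density, "constraints": constraints}


@pytest.fixture(scope="session")
def s2_sample(model):
    """Scenario S2 (bidirectional GDH) posterior sample."""
    scenario = nf.Scenario.preset("S2")
    constraints = nf.build_scenario_constraints(model.system, scenario)
    targets = [nf.TargetControl(f, t, w) for f, t, w in scenario.targets]
    density = nf.build_density(model.system, model.boundary, constraints, targets)
    sample = nf.mcmc_sample(
        density, N=30_000, burn_in=10_000, seed=ACCEPT_SEED + 1, method="gibbs"
    )
    sample.meta["scenario"] = "S2"
    return {"sample": sample, "density": density, "constraints": constraints}


def batch_se(values: np.ndarray, n_batches: int = 25) -> float:
    """Monte Carlo standard error of the mean by the batch-means method
    (robust to autocorrelation)."""
    values = np.asarray(values, dtype=float)
    n = values.size // n_batches
    if n < 1:
        return float(values.std(ddof=1) / np.sqrt(values.size))
    batches = values[: n * n_batches].reshape(n_batches, n).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))


def batch_se_stat(sample, stat, n_batches: int = 25) -> float:
    """Batch-means standard error of an arbitrary statistic of the sample
    mean (e.g. a flux ratio): evaluate the statistic on per-batch means."""
    X = sample.vectors
    n = X.shape[0] // n_batches
    vals = np.array(
        [stat(X[i * n : (i + 1) * n].mean(axis=0)) for i in range(n_batches)]
    )
    return float(vals.std(ddof=1) / np.sqrt(n_batches))
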