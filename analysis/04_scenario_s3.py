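#!/usr/bin/env python
"""Scenario S3: can leucine replace glutamine as a transmitter precursor?

With the bound on the leucine transport direction removed, the constraint
polytope admits steady states in which leucine flows astrocyte -> ECS ->
neuron while every GDH remains oxidative: leucine then plays the role of
glutamine, replenishing the neuronal glutamate pool by transamination with
no return traffic of ammonia.  This script verifies the existence of such
a state (constrained least-squares residual within the equation
tolerances) and samples the unconstrained S3 density to measure how often
the reversed leucine direction occurs among feasible steady states.

Writes the existence certificate and sample summaries to results/s3/.
"""

import json
from pathlib import Path

import numpy as np
from scipy.optimize import lsq_linear

import neurofba as nf
from neurofba.compartments import CELLS, mitochondria_of
from neurofba.density import coordinate_bounds

OUT = Path("results/s3")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = nf.build_brain_model()
    sys = model.system
    scenario = nf.Scenario.preset("S3")
    cons = nf.build_scenario_constraints(sys, scenario)

    # existence: pin leucine astrocyte->ECS and ECS->neuron, GDH oxidative
    lo, hi = coordinate_bounds(cons)
    for cell in CELLS:
        j = sys.col(f"GDH@{mitochondria_of(cell)}")
        lo[j] = max(lo[j], 0.0)
    hi[sys.col("Leu/ECS->astrocyte-cytosol")] = -0.01
    lo[sys.col("Leu/ECS->glutamatergic-cytosol")] = 0.01
    rhs, sigma = model.boundary.rhs_and_sigma(sys)
    d = sys.n_fluxes
    rows = [sys.matrix / sigma[:, None]]
    bs = [rhs / sigma]
    for fid, t, w in scenario.targets:
        e = np.zeros((1, d))
        e[0, sys.col(fid)] = 1.0 / w
        rows.append(e)
        bs.append([t / w])
    res = lsq_linear(np.vstack(rows), np.concatenate(bs), bounds=(lo, hi),
                     tol=1e-12, max_iter=400)
    resid = np.abs((sys.matrix @ res.x - rhs) / sigma)
    print(f"leucine-reversed steady state: max residual "
          f"{resid.max():.2f} sigma (exists: {resid.max() <= 4})")

    targets = [nf.TargetControl(f, t, w) for f, t, w in scenario.targets]
    dens = nf.build_density(sys, model.boundary, cons, targets)
    sample = nf.mcmc_sample(dens, N=30_000, burn_in=10_000, seed=3)
    la = sample.column("Leu/ECS->astrocyte-cytosol")
    ln = [sample.column(f"Leu/ECS->{c}-cytosol") for c in
          ("glutamatergic", "GABAergic")]
    reversed_frac = float(np.mean((la < 0) & ((ln[0] > 0) | (ln[1] > 0))))
    print(f"unconstrained S3 sample: {100 * reversed_frac:.1f}% of states "
          "run leucine astrocyte->neuron")
    summary = {
        "existence_max_residual_sigma": float(resid.max()),
        "reversed_leucine_fraction": reversed_frac,
        "leu_ecs_to_astrocyte_mean": float(la.mean()),
    }
    (OUT / "s3_summary.json").write_text(json.dumps(summary, indent=1) + "\n")
    print(f"wrote {OUT}/s3_summary.json")


if __name__ == "__main__":
    main()
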