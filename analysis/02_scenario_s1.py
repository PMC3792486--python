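#!/usr/bin/env python
"""Scenario S1: oxidative-only GDH with leucine entering the astrocyte.

Samples the truncated-Gaussian flux density under the inhibition-state
target (vesicular GABA efflux 0.13 umol/min, w = 0.005) and writes the
sample archive, mean-flux table and the ammonium/glutamine, GABA-precursor,
glutamate-oxidation and ATP-turnover reports to results/s1/.

Key quantities to look for in the reports: GAD activity about twice the
glutamine influx of the GABAergic neuron, vesicular glutamate efflux near
0.08 umol/min, the GABA shunt just below half of the succinate
dehydrogenase flux, and the small offset between astrocytic glutamine
efflux and ammonium influx that leucine uptake covers.
"""

import json

import neurofba as nf
from neurofba.pipeline import RunConfig, configure_logging, run_scenario


def main() -> None:
    configure_logging()
    manifest = run_scenario(
        RunConfig(scenario="S1", N=50_000, burn_in=10_000, seed=1,
                  out_dir="results/s1")
    )
    print(json.dumps({k: manifest[k] for k in
                      ("scenario", "seed", "N", "model_hash",
                       "max_residual_in_sigmas", "diagnostics")}, indent=1))
    for name in ("gaba_precursors", "oxidation_fractions",
                 "ammonium_glutamine", "atp_turnover"):
        rpt = json.loads(open(f"results/s1/{name}.json").read())
        print(f"\n== {rpt['title']} ==")
        for k, v in rpt["entries"].items():
            print(f"  {k}: {v:.4g} {rpt['units'][k]}")


if __name__ == "__main__":
    main()
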