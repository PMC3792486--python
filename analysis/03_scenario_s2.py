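#!/usr/bin/env python
"""Scenario S2: bidirectional GDH and the amino-group shuttles.

With the oxidative-only bound removed, the sampled steady states balance
reductive GDH in the neurons against oxidative GDH in the astrocyte (the
three means sum to about zero).  The full-sample shuttle report shows the
astrocyte liberating ammonium from alanine and leucine; restricting the
sample to states whose net NH4+ flux runs ECS -> astrocyte (the
physiologically expected direction) collapses the GABAergic GDH toward
zero and leaves roughly a fifth of the glutamine synthetase ammonium
demand covered by astrocytic GDH, the rest by diffusion from ECS.

Writes sample, smoothed GDH histograms, and shuttle reports (full and
subsampled) to results/s2/.
"""

import json

import neurofba as nf
from neurofba.pipeline import RunConfig, configure_logging, run_scenario


def main() -> None:
    configure_logging()
    manifest = run_scenario(
        RunConfig(scenario="S2", N=50_000, burn_in=10_000, seed=2,
                  out_dir="results/s2")
    )
    gm = manifest["gdh_means"]
    print("GDH means (umol/min): "
          + ", ".join(f"{k} {v:+.4f}" for k, v in gm.items()))
    print(f"neuronal sum {gm['glutamatergic'] + gm['GABAergic']:+.4f} vs "
          f"astrocyte {gm['astrocyte']:+.4f}")
    print(f"NH4+->astrocyte subsample retained "
          f"{manifest['nh4_subsample_retained']} vectors")
    for name in ("shuttle", "shuttle_nh4_subsample"):
        rpt = json.loads(open(f"results/s2/{name}.json").read())
        print(f"\n== {rpt['title']} ({name}) ==")
        for k, v in rpt["entries"].items():
            print(f"  {k}: {v:.4g} {rpt['units'][k]}")


if __name__ == "__main__":
    main()
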