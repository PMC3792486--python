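# Methods

## The model

`neurofba` performs statistical flux balance analysis of neurotransmitter
cycling in brain tissue. The network spans eight compartments — blood,
extracellular space (ECS, including the synaptic cleft), and separate
cytosolic and mitochondrial compartments for astrocytes, glutamatergic
neurons and GABAergic neurons. Each cell carries glycolysis, lactate
dehydrogenase, the TCA cycle, oxidative phosphorylation, the complete
malate–aspartate shuttle (OGC and AGC1 carriers plus cytosolic and
mitochondrial MDH/AAT), the GABA shunt (GABA-T, SSADH), and the
transaminases ALT and BCAT that implement the lactate–alanine and
branched-chain amino acid shuttles. Astrocyte-specific enzymes are
glutamine synthetase (cytosol) and pyruvate carboxylase (mitochondria);
malic enzyme is cytosolic in the astrocyte and mitochondrial in neurons;
BCAT is mitochondrial in the astrocyte and cytosolic in neurons. Vesicular
transmitter pools are species tags in the neuronal cytosols: packing one
glutamate costs 25 ATP and one GABA costs 8 ATP, lumping the full
energetic cost of a transmission cycle into the packing flux.

A reaction or transport `i` contributes a stoichiometric column `s^i`
(units produced or depleted per unit flux) to the matrix `A`; a metabolite
in several compartments is a distinct species (row) in each. The steady
state is `A u = r`, where the flux-transport vector `u` stacks the 84
reaction fluxes and 77 transport rates (all in μmol/min per g tissue), and
`r` holds the blood exchange rates `r_j = Q/F (Ca_j − Cv_j)` from
arteriovenous differences with blood flow Q = 0.55 ml/min/g and F = 1:
glucose uptake 0.297, lactate release 0.099, and zero-mean entries for
NH4+, leucine and glutamine with their printed uncertainties. Oxygen and
CO2 have only estimated venous values, so their exchange rows are kept
loose (sigma 10 μmol/min) and the oxygen consumption rate is an output;
their directions are fixed by the transport arrows instead.

### Sign conventions

Transports are oriented positively into the tissue / into the cell / into
the mitochondria (unidirectional rows as printed, e.g. CO2 outward). With
standard stoichiometric columns, a transport leaving the blood depletes
the blood species, so the supply term enters the blood row of the
right-hand side with a sign flip: `(A u)_row = −r_j`. The per-species
uptake rates are stored in the positive-uptake convention the source
tables print.

### Localization choices

Two localization decisions are not forced by the transport table alone and
were made on the physiology stated in the model description:

* Transmitter clearance is astrocytic: the Glu and GABA ECS↔cytosol
  transports exist only for the astrocyte. Neuronal cytosolic glutamate
  reaches ECS only through vesicular release. Allowing neuronal
  re-uptake admits a 2-ATP glutamine futile cycle that is nearly flat
  under the density below and inflates the posterior mean glutaminase
  flux roughly threefold.
* The Leu/KIC mitochondrial carriers exist in the astrocyte only, since
  neuronal BCAT is cytosolic. A consequence kept as printed: neuronal
  BCKDH has no mitochondrial KIC source and its steady-state flux is
  pinned to ≈0.
* The astrocytic uptake of glutamate and GABA carries one coupled ATP
  hydrolysis, so uptake plus glutamine synthetase totals ≈2 ATP per
  transmitter recycled without double counting.

### Atom audit

Every reaction is checked for carbon and nitrogen closure from a
metabolite atom table (cofactors excluded; acyl-CoA species count acyl
carbons). The lumped branched-chain ketoacid dehydrogenase
(KIC + CoA → ACoA + CO2) drops three carbons as printed and is
whitelisted, not repaired. All other reactions balance exactly.

## The flux density and sampler

Feasible steady states are explored through the truncated Gaussian

    π(u) ∝ H(Cu − c) · exp(−½ (Au − r)ᵀ Σ⁻¹ (Au − r)) · exp(−(u_ℓ − t)²/2w²)

with diagonal Σ (sigma 0.005 μmol/min for every balance except the blood
rows, which use the table uncertainties), hard inequalities `Cu ≥ c`
(irreversibility and unidirectional-transport positivity, scenario rows,
and a global magnitude bound |u_i| ≤ Vmax = 10 μmol/min/g that keeps the
polytope bounded — roughly 30× the glucose uptake, and inactive at every
sampled mean), and a target control pinning the vesicular GABA efflux to
0.13 μmol/min with w = 0.005 (the simulated inhibition state). The
Gaussian part is the quadratic form with precision
`P = AᵀΣ⁻¹A + w⁻²·e_ℓe_ℓᵀ`.

Scenarios: S1 adds oxidative-only GDH rows in all three cells plus a
positivity bound on the ECS→astrocyte leucine transport; S2 drops the GDH
rows; S3 drops both.

### Sampling

The default sampler is Gibbs with exact univariate truncated-normal full
conditionals, run in the eigenbasis of `P`. In that basis the Gaussian
factor is diagonal, so the conditionals are independent apart from the
polytope, and the chain traverses both the stiff balance directions
(conditional sd ≈ sigma) and the flat null-space directions (17 of 161
dimensions; conditional precision ≈ 0, drawn uniformly on the feasible
interval) in a single sweep. A raw coordinate sweep ("gibbs-coordinate")
is retained for reference — its steps along near-null directions are
limited to the 0.005 scale and it needs orders of magnitude more sweeps —
and hit-and-run with exact 1-D chord conditionals is the independent
cross-check kernel. All kernels maintain `g = Pu` and `Cu` incrementally,
draw truncated normals by exact rejection (naive, uniform-envelope, or
shifted-exponential depending on the standardized interval), and are
bit-reproducible from the seed.

Chains start at the constrained posterior mode (a box-constrained least
squares solve, exact because all hard rows bound single coordinates),
which sits on the balance manifold and removes an otherwise ~10⁴-sweep
transient; burn-in defaults to 10,000 sweeps with no thinning. Every
stored vector is re-checked against `Cu ≥ c` (tolerance 1e−8, covering
round-off from the basis rotation). Conditional intervals that collapse
through rounding keep the current value. Diagnostics report per-flux
effective sample size (initial-positive-sequence estimator) and a
split-chain convergence statistic.

### Oracles

The synthetic fixtures reproduce the statistical structure at ≤6 fluxes:
linear chains with closed-form truncated-normal marginals, and random
sparse balance systems with a right-hand side constructed inside the
polytope. The rejection oracle draws uniform proposals on the polytope's
coordinate bounding box and accepts against the Gaussian factor scaled by
its box maximum (convex quadratic maximization, cross-checked by grid
search at ≤3 dimensions) — exact in distribution, and the standard against
which both MCMC kernels must hold 1-D marginal KS distance < 0.02 at
N = 50,000. The fixtures are machinery validation only and make no claim
of biological realism.

## Reported quantities

All reports evaluate the sample-mean flux vector. ATP turnover per cell
is the consumption-side sum max(0, −coef_ATP·u_i) over the cell's net
ATP coefficients (intra-cell ATP transports cancel; packing costs count
in the neuron that pays them). Smoothed histograms are Gaussian KDEs with
Silverman bandwidth on a grid padded by three bandwidths. Subsampling by
direction (e.g. net NH4+ ECS→astrocyte positive) filters membership
without altering vectors. Percentages that are shares of a whole are
validated to [0, 100]; ratios to a different base (glutamine influx as a
share of GABA efflux, GDH over PAG) may exceed 100.

## Problem sizes

The test suite samples 30,000 post-burn-in vectors per scenario fixture
and the acceptance script 200,000 (the sample size the analysis is
designed around); at these sizes the batch-means Monte Carlo standard
errors of the headline quantities are below 0.002 μmol/min (fluxes) and
0.5 points (percentages). A full 220,000-sweep S1 chain runs in about two
minutes on one CPU.

## Known limitations

* The posterior mean is the centroid of the near-feasible set. Several
  amino-group transport cycles (glutamine/leucine/alanine exchange
  between cells) are almost flat directions of the density: their means
  are set by polytope volume, not by any strongly pinned balance, and
  two long half-chains agree on those means to three digits. Where a
  published mean-flux configuration corresponds to a lower-throughput
  corner of that flat set (small glutaminase flux in the GABAergic
  neuron, leucine uptake equal to its blood influx), the centroid can
  sit measurably away from it; the affected comparisons are reported
  as computed, not adjusted.
* Steady state only: no kinetics, no regulation, no thermodynamic
  (ΔG-based) direction inference beyond the printed arrows.
* No charge or proton balancing; oxidative phosphorylation is lumped at
  6 ATP per O2 with 2 NADH as printed.
* The flux scale is per gram of generic tissue with prescribed activity;
  the model does not represent whole-brain cell-type proportions.
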