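# Methods

## Model

One construct is a fixed set of `n_cells` points placed uniformly and
independently in a slab of volume 5 µL and thickness 100 µm (footprint
derived as volume/thickness and modelled as a square; cells in the real
system can neither divide nor migrate, so positions are static for the
whole run).  Two cells interact iff their Euclidean distance is at most
`lambda_int`; the graph is built once per run with a k-d tree and is exact
(identical to the all-pairs construction).  There is no periodic wrapping:
cells near the slab faces simply have fewer neighbours, as in a real
construct.

Each step of `dt` days applies, in order:

1. **Intrinsic failure.**  Every functional cell i fails with probability
   `q_i = 1 − (1 − d·σ)^(exp(−β·s_i)·dt)` where the support score is
   `s_i = c_i·(f_i + w·G)`: `f_i` is the fraction of i's neighbours that is
   functional (0 for isolated cells), `G` the shared-medium factor level,
   `c_i` reception competence.  With β = 0 this is exactly `d·σ` per day.
2. **Threshold cascade.**  Synchronous sweeps: every functional cell with
   at least one neighbour and functional-neighbour fraction `< θ` fails;
   sweeps repeat to a fixed point.  Synchronous updating makes the fixed
   point independent of cell order.  θ = 0 disables cascades.
3. **Repair.**  Each failed cell revives with probability `r·dt`
   (default r = 0: the hydrogel system has no proliferation, and `r` is
   kept only for theory exploration).
4. **Medium update.**  `G ← G·(1 − δ·dt) + dt·Σ_functional p_i / n_ref`,
   with `p_i` the per-cell production competence and `n_ref = 10⁵` a fixed
   reference count.  Normalizing by a *fixed* count (rather than each
   construct's own `n_cells`) makes the factor concentration proportional
   to the number of functional producers in the constant 5 µL volume, so a
   sparse construct conditions its medium ~100× more weakly than a dense
   one — the density mechanism the experiment manipulates.  The `dt`
   scaling makes sub-daily stepping compound to the same daily update.

One uniform variate is drawn per cell per step regardless of state, so runs
that differ only in θ or β are pathwise coupled under a shared seed; this
underlies the monotonicity tests (raising θ can only shorten a replicate's
life, raising β only lengthen it).

A run ends when at most 2% of the seeded population is alive, or at `t_max`
(the trajectory is then flagged right-censored).

### Aging, stress, media

* **Age classes.**  Young cells have reception and production competences
  c = p = 1.  Pre-aged cells carry a class-wide competence deficit of 0.005
  in *reception* under the reception-loss hypothesis (the experimentally
  supported one) or in *production* under the production-loss hypothesis.
  The deficit is applied to every pre-aged cell, not only the
  senescence-marker-positive subset: pre-aging elevates DNA damage across
  the whole population, and a deficit confined to a marker-positive subset
  would leave the remaining cells fully rescuable by conditioned media,
  which is not what the transfer experiments show.  Marker-positive flags
  are still drawn per cell (60% of pre-aged, 0.5% of young) and carried as
  metadata.  An optional multiplier on the intrinsic rate for pre-aged
  cells (`d_aged_factor`) defaults to 1.0 because sparse young and pre-aged
  constructs die at indistinguishable rates — age acts through interaction
  competence, not the intrinsic rate.
* **Stress.**  Oxidative stress multiplies `d` by `sigma_stress = 2.0` for
  the whole run.
* **Media regimes.**  Experimental arms replace the medium at every daily
  staining, so baseline arms run with G reset to 0 at each day boundary.
  Conditioned-media arms instead set G each day to a donor harvest: donors
  (100K constructs) accumulate factor for a 2-day conditioning period, the
  first harvest carries that medium, and each later harvest carries one
  day's conditioning (fresh medium after every harvest).  Controls receive
  non-conditioned medium on the same schedule.  Conditioned-media arms
  share per-replicate seed streams with their controls, so each comparison
  is a pure medium perturbation.

### Default parameters

| parameter | value | units | role |
|---|---|---|---|
| d | 0.2 | /day | intrinsic damage rate |
| r | 0 | /day | repair |
| lambda_int | 40 | µm | interaction radius (≈5.4 mean neighbours at 100K, ≈0.05 at 1K) |
| theta | 0.05 | – | cascade threshold |
| beta | 0.8 | – | cooperative hazard reduction |
| w_global | 2.0 | – | medium-factor weight in support |
| delta | 0.3 | /day | medium factor decay |
| sigma_stress | 2.0 | – | oxidative-stress multiplier on d |
| competence_deficit | 0.005 | – | residual c (or p) of pre-aged cells |
| dt | 1 (1/12 for 1K) | day | step; 2 h steps support the 1K sub-daily staining schedule |
| t_max | 60 | day | censoring horizon |

The experiment provides no rate constants, so these are calibrated once to
reproduce its *orderings and trend labels*, never absolute days: dense
young constructs live ~19 days vs ~12 for dense pre-aged; sparse constructs
~15–16 days regardless of age; denser young constructs outlive their 100×
dilution; m(n) classifies cooperative at 100K and non-interacting at 1K;
and the conditioned-media matrix discriminates the two aging hypotheses.
`beta` is deliberately moderate: a protected isolated pair then dies at
roughly the isolated rate (`exp(−0.8) ≈ 0.45`, two cells at ~half hazard),
so chance pairs at 1K do not open a spurious young-vs-aged gap.  `w_global`
sets the strength of conditioned-media transfer only — baseline arms wash G
daily, and after the `n_ref` normalization a 1K construct's
self-conditioning is ~0.01 — and is set so the weakest real rescue (young
1K receiving media from short-lived pre-aged donors) is resolvable at 20
replicates.

## Measurement emulation

The emulator reproduces the imaging protocol, not pixels: per day and per
construct it takes `n_stacks = 3` stack footprints each covering 1/8 of the
gel footprint (disjoint squares at seeded offsets, with a full-height strip
fallback for configurations where disjoint squares cannot be packed),
splits the thickness into 10 equal slices, and counts the cells that died
since the previous imaging inside each footprint, each detected with
probability `detection_gain` (default 1) plus optional Poisson jitter.
Dense constructs report the middle 3 slices per stack (9 counts/day);
sparse (1K) constructs report one maximum-projection count per stack.  1K
constructs are additionally imaged at 2, 4, 6 and 20 h on day 1.

The counting pipeline applies the published arithmetic: slice mode
estimates mean(9 counts)·n_slices·8; projection mode mean(stacks)·8; an
affine calibration (identity by default, as the experimental calibration
curve is not published) precedes the scaling.  Live counts start at the
theoretical seeded number and subtract each day's estimate cumulatively,
clamped at zero (live counts cannot be negative; over-estimates otherwise
propagate).  The lifetime is the first time live % ≤ 2.

What the emulator does *not* model: optical point-spread, bleed-through,
segmentation error, re-staining of previously counted dead cells (records
are deaths-since-last-imaging, matching the pipeline's subtraction
arithmetic), or non-uniform dead-cell density across slices — the
slice-mode estimator assumes uniformity, a known bias source near slab
faces.  Passing tests therefore validate the counting arithmetic and
sampling statistics, not image analysis on real micrographs.

## Analysis

* `mortality_rate`: discrete per-capita rate m_t = −Δn/(n_t·Δt); intervals
  with n_t = 0 are dropped (never treated as infinite rates).
* `fit_null`: OLS of ln n on t; exact exponentials are recovered to
  machine precision.
* `probability_of_death`: p_t = m_t·Δt, identically 1 − n_{t+1}/n_t.
* `classify_m_vs_n`: least-squares slope of m on n/n₀ with a 1000-resample
  percentile bootstrap CI (α = 0.05, matching the study's significance
  convention); CI below zero → cooperative, above → competitive, spanning
  zero → non-interacting.  n is normalized by n₀ so slopes are comparable
  across densities.  When applied to pipeline-estimated series, the fit
  uses the daily points and intervals starting at ≥10% live: sub-daily day-1
  intervals and the late tail are high-leverage points dominated by
  sampling noise and the cumulative-subtraction error random walk, and
  would otherwise produce spurious per-replicate slopes.
* `normalize_time`: linear interpolation onto a fixed 21-point t/T grid;
  refuses censored lifetimes.
* `compare_groups`: two-sided Student's t (equal variances), significance
  at p < 0.05; two degenerate zero-variance groups with equal means give
  p = 1 by convention.  Pairwise tests are reported without
  multiple-comparison correction, as in the experimental analysis.

### Conditioned-media hypothesis discrimination

Four predicates, each a two-group t-test on lifetimes (rescue = significant
increase over the paired control): pre-aged dense not rescued by young
conditioned media; pre-aged sparse not rescued; young sparse rescued by
young conditioned media; young sparse rescued by pre-aged conditioned
media.  A hypothesis matches only if all four hold.  Under defaults the
reception-loss hypothesis matches and the production-loss hypothesis
violates three predicates (pre-aged recipients are rescued, and pre-aged
donors provide no functional factor).

## Problem sizes

Reference computations (`tissuefail.benchmarks`, used by the acceptance
script and end-to-end tests) run: 100 replicates at n₀ = 10⁴ for the
non-interacting null; 50 emulated 10K replicates for pipeline error; 20
replicates per arm for the density × age matrix (1K and 100K); 20 paired
replicates per arm, both hypotheses, for the conditioned-media matrix; 4 ×
2000 points for the planar nearest-neighbour check.  These sizes give the
t-tests and majority votes comfortable resolution at the effect sizes the
default parameters produce.

## Known limitations

* The interaction radius, cooperation strength and cascade threshold are
  not identifiable from the published measurements; only orderings and
  trend labels are calibrated, so absolute simulated lifetimes (19 vs 25
  days for dense young constructs) should not be read quantitatively.
* Support uses the *fraction* of functional neighbours, so very small
  clusters are proportionally as protected as dense tissue; the moderate β
  default bounds the resulting tail effects at sparse density.
* The measured per-plane nearest-neighbour means at sparse density are not
  reproducible from the stated geometry under any slice thickness; the
  distance module therefore targets the ordering across densities and the
  planar Poisson closed form, not the measured values.
* Finite stack footprints bias per-plane nearest-neighbour distances
  slightly upward (a cell's true nearest neighbour may lie outside the
  field of view); the subsampling test bounds this at a few percent.
* No diffusion: the medium factor is a single well-mixed pool, and no
  spatial gradient of secreted factors exists within a construct.
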