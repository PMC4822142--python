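# Methods

## Compartment model of CML hematopoiesis

Hematopoiesis is modelled as K = 32 maturation compartments per lineage.
Cells in compartment k divide at rate r_k = r₁·ρ^(k−1); with probability
ε a division sends both daughters to compartment k+1, otherwise both
daughters self-renew, giving

    dN_k/dt = 2·ε·r_{k−1}·N_{k−1} + (1 − 2ε)·r_k·N_k,   k ≥ 2.

For ε > 1/2 each compartment is a damped stage fed from above, and the
hierarchy has a geometric steady state N_k = N₁·γ^(k−1) with
γ = 2ε/((2ε−1)ρ).

### Parameters, units and defaults

| parameter | default | unit | origin |
|---|---|---|---|
| `n_compartments` | 32 | – | compartment-model literature |
| `replication_rate_base` r₁ | 1/365 | 1/day | stem cells divide ~once a year |
| `replication_rate_ratio` ρ | 1.26 | – | per-compartment rate increase |
| `epsilon_healthy` | 0.85 | – | healthy differentiation probability |
| `healthy_stem_cells` N₁ | 400 | cells | active stem-cell pool |
| `epsilon_cml` | 0.90 | – | leukemic lineage, see below |
| `cml_growth_per_day` g | 0.015 | 1/day | leukemic stem-clone expansion, see below |
| `cd34_cutoff` | 23 | compartment | last CD34⁺ stage |
| `t_max_days` / `dt_days` | 2200 / 1 | days | mutation-to-presentation window |
| `cml_init_cells` | 1 | cells | the first malignant stem cell |

The healthy steady-state ratio is derived from the dynamics
(γ ≈ 1.927 at the defaults) so the initial healthy state is an exact
fixed point; `steady_state_ratio` can override it.

The two leukemic parameters are the reconstruction's free choices and
deserve an honest account. Within this update rule the per-compartment
steady amplification γ = 2ε/((2ε−1)ρ) *decreases* as ε grows: cells that
differentiate more readily spend less residence time replicating inside
each stage. A rising CD34⁺/CD34⁻ ratio — the leukemic hallmark the CD34
ratio encodes — therefore requires the leukemic ladder to amplify *less*
per compartment than the healthy one (γ_CML < γ_healthy, i.e.
ε_CML > ε_healthy: ineffective maturation, fewer mature cells produced
per immature blast), while the malignant expansion itself is carried by
the self-renewing leukemic stem clone, modelled as exponential growth of
CML compartment 1 at rate g. Setting ε_CML below ε_healthy instead makes
the leukemic ladder *top-heavy* (γ ≈ 2.6 at the canonical 0.72) and the
aggregate CD34 ratio falls as the clone expands — the opposite of the
disease phenotype; that regime remains available through the
configuration. The clone growth rate g = 0.015/day is the one
calibrated quantity: it places the leukemic mass takeover, and with it
the simulated-entropy minimum, at the published ~4-year transition
inside the ~6-year window; all other rates are standard literature
values. This calibration was fixed before any test of the package was
written and is not revisited.

### Numerics

The per-lineage dynamics are linear and bidiagonal, and the fastest
compartment relaxes at (2ε−1)·r₃₂ ≈ 2.5/day — an explicit Euler step at
dt = 1 d would be unstable. Each daily step is therefore taken with the
exact exponential integrator: x(t+dt) = E·x(t) + M·b(t) with
E = expm(A·dt) and M = (gI − A)⁻¹(e^{g·dt}I − E), which is
unconditionally stable, deterministic, and makes the step-halving
convergence check exact to round-off. Non-finite counts (parameter
blow-up, e.g. extreme g) abort with the offending time, lineage and
compartment named.

### A structural note on the normalized CD34 ratio at the entropy minimum

The simulated-entropy minimum sits at the healthy/leukemic mass-parity
point (the mixing-entropy maximum). For two quasi-steady geometric
ladders the CD34-ratio curve is r(c) = r_H·(1+αc)/(1+βc) in the mass
ratio c = CML/healthy, which attains exactly β/(1+β) of its min-max range
at parity; because any admissible ε < 1 keeps the leukemic ladder's
top-nine-compartment mass share above 98%, β ≳ 0.98 and the normalized
ratio at the minimum cannot fall measurably below ~0.5 in this model
family (we observe ≈ 0.51–0.55). Smaller published values of this
particular coordinate imply a structurally different ratio definition or
ladder; we report the value our reconstruction actually computes.

## Entropy estimation

Sample entropy is the Shannon entropy of a fixed-count equal-width
histogram over the per-sample value range: n_bins = 64, natural log
(nats) by default; both are configurable, and a fixed global range is
available. Empty bins contribute zero; a degenerate (constant) sample
returns H = 0 with a warning. Absolute entropy values depend on the
estimator, so thresholds on the absolute scale are treated as
configurable, and the package's claims rest on shape features (the
interior minimum, its location, its alignment with the mixing-entropy
maximum).

The simulated curve uses a random 64 × 6,384 per-population expression
matrix with i.i.d. uniform [0, 1] entries (a lognormal alternative is
provided; the distributional choice shifts the curve's level, not its
non-monotonic shape). A single matrix makes the argmin noisy, so the
boundary estimate averages the smoothed (11-point moving average)
per-seed argmins over 10 seeds by default. Boundary-located minima are
flagged as non-singular. The entropy-minimum time is driven by the
population weights alone and is therefore independent of the CD34
cutoff; the cutoff sweep documents this directly, reporting per cutoff
the boundary time together with the cutoff-dependent normalized-ratio
coordinate and ratio monotonicity.

## Scoring and pinning choices

* Rank-sum p-values are exact for tie-free gene sets of ≤ 25 members and
  use the normal approximation with continuity correction otherwise;
  p underflow is floored at the smallest positive double so signed
  log₁₀ p stays finite.
* Per-gene centering by the cohort mean is applied before both signature
  ranking and scoring (`centering="none"` preserves the raw reading);
  ties in the reference profile break by gene-identifier order.
* Pinning runs per patient in two steps — nearest normalized CD34 ratio,
  then nearest normalized entropy within a CD34 neighbourhood
  (half-width 5% of the axis) — with a joint 2-D nearest-neighbour mode
  as an alternative, since the published description admits both
  readings. The observed-entropy V vertex (quadratic OLS) is shifted
  along the CD34 axis onto the simulated minimum before the entropy
  step; a degenerate V fit, or an implied shift above 0.25 of the axis,
  falls back to no alignment with a warning. Patients are processed in
  score order with time reversals forbidden, so matched times are
  nondecreasing in normalized score; a time exactly on the boundary is
  labelled T2.
* Normalization uses chronic-phase samples only (the mapping is defined
  within CP).

## Cohort statistics

Differential expression is a per-gene two-sided two-sample t-test
(pooled variance by default, Welch by flag) with Benjamini–Hochberg
adjustment at FDR < 0.05; zero-variance genes short-circuit to p = 1
when the group means agree and are flagged and excluded from the
testing universe otherwise. The V-shape test is OLS of entropy on score
and score², reporting the two-sided p of the quadratic coefficient and
the vertex when the curvature is positive. The entropy-correlation
robustness check subsamples 80% of the pairs without replacement
(Pearson by default, Spearman by flag) — the subsample fraction is not
fixed by precedent, so it is explicit and reported. The stage grid
splits the observed score range into quarters and the entropy range
into halves; values on an internal boundary join the lower cell (the
global minimum joins the first cell). The permutation control shuffles
stage labels only (composition preserved exactly) and reports null
fractions both as cohort shares and within-cell shares. Cohort size is
always taken from the annotation table actually loaded, never
hard-coded.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the statistical structure the pipeline is built
to detect, with stage counts 42 CP / 9 AP / 8 APcyto / 28 BC plus six
flagged CD34⁺ reference samples:

* **Value-distribution shape.** Every sample mixes a "healthy" and a
  "leukemic" expression program (flat, uniform-distributed; scale 1.25
  units, 80% of the profile variance) in proportion to its healthy
  cell-mass share, with the program realizations drawn fresh per sample.
  The per-sample distribution therefore goes flat → triangular → flat as
  the mass shifts from healthy to leukemic, producing the entropy V over
  chronic phase with its vertex at the mass-parity point — without
  planting gene-level mean differences between patient groups, which
  would otherwise swamp the differential-expression comparisons.
* **CD34 signature.** 320 up and 320 down genes carry a contrast linear
  in the normalized model CD34 ratio at the sample's true disease time
  (half-range 0.45 units in bulk; 3.0 in the cell-intrinsic reference
  samples, which differ from the average patient only along this axis).
  Per-gene effect magnitudes are heterogeneous (uniform 0.3–1.7×): real
  marker genes differ in fold change, and homogeneous effects would let
  the 319-vs-319 rank-sum saturate at complete set separation, pinning
  the scores. The bulk half-range keeps the score in its responsive
  range across the whole time axis.
* **Progression shifts.** A disjoint 10% gene block carries
  stage-graded mean shifts (levels: CP = its time coordinate, AP 2.0,
  APcyto 1.7, BC 3.0, in units of 0.6 spread), giving ordered DE
  fractions T1-vs-T2 < T1-vs-AP < T1-vs-BC.
* **Truth times.** CP truth times are uniform on the normalized CD34
  ratio axis (converted to days through the curve). The ratio curve is
  exponentially flat over early chronic phase, so a cohort uniform in
  *time* would be informationally unrecoverable there under the score ~
  ratio linearity the method rests on; uniform-in-ratio matches a
  diagnosed cohort spread across the similarity axis.
  `cp_time_sampling="uniform-time"` is available.
* **Blast counts** are stage-dependent with 15% planted missingness in
  CP and BC, exercising the preparation rules (CP missing → 1, BC
  missing → excluded).

Per-gene baselines are Gaussian with spread 0.3 units — deliberately
compressed relative to real microarray baselines so the mixing-driven
shape signal is visible to the entropy estimator; measurement noise is
Gaussian with σ = 0.3 and advanced stages add flat dispersion (AP 0.4,
APcyto 1.0, BC 0.6) that elevates their entropy. Advanced-stage samples
reuse the end-of-window population weights with similarity coordinates
beyond the chronic-phase range (AP 0.75–0.95, APcyto 0.55–0.85,
BC 0.95–1.25); these templates are a device for exercising the grid and
DE code paths, not a model of advanced disease. Passing tests on these
cohorts show the pipeline recovers the structure it assumes; they do not
show that real biopsies satisfy those assumptions (probe-level
artifacts, batch effects, platform mapping and competition between
clones are all absent).

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full 32-compartment
model on the daily grid, average the entropy minimum over 10 random
64 × 6,384 matrices, use 1,000 permutations for the label control,
1,000 replicates for the V-shape type-I simulation, 200 replicates of
the planted differential-expression simulation (1,000 genes, 50 planted,
n = 34 vs 8), and 20 cohort seeds for the recovery study — sizes at
which the Monte-Carlo error is comfortably below the decision margins.

## Known limitations

* Competition between healthy and leukemic cells is not modelled; the
  healthy lineage is static.
* The leukemic stem clone grows deterministically and exponentially; no
  stochastic origination or therapy response.
* The entropy scale is estimator-dependent; only shape features are
  portable across estimators.
* The T1/T2 boundary inherits the model's time normalization (the
  ~6-year window is a population-average approximation); individual
  proliferation-rate variation is absorbed, not resolved.
* Signature construction assumes the flagged reference samples are
  genuinely CD34⁺-sorted; no deconvolution is attempted.
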