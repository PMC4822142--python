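# cml-chronos

Staging chronic myeloid leukemia (CML) patients on a disease-evolutionary
time axis by combining a population-dynamics model of leukemic
hematopoiesis with two genomic scores computed from bulk expression
profiles.

## Who this is for

Computational biologists working with retrospective, non-longitudinal CML
expression cohorts (CP / AP / APcyto / BC staging) who want a quantitative
estimate of *how far along* each chronic-phase patient is — information
that blast counts alone do not resolve — and a reproducible synthetic
test bed for the whole procedure.

## The model and scores

**Compartment model.** Hematopoiesis is a hierarchy of K = 32
replication/differentiation compartments; cells in compartment *k* divide
at rate r_k = r₁·ρ^(k−1) and differentiate (both daughters advance) with
probability ε per division, giving the mean-field update

    dN_k/dt = 2·ε·r_{k−1}·N_{k−1} + (1 − 2ε)·r_k·N_k ,  k ≥ 2.

A healthy lineage sits at its geometric steady state; a CML lineage grows
from one malignant stem cell, C₁(t) = exp(g·t), with its own
differentiation probability. Compartments 1..23 are CD34⁺
(stem/progenitor/precursor); the **CD34 ratio** CD34⁺/CD34⁻ rises
monotonically as the clone takes over the ~6-year (2,200-day) window from
the initiating mutation to clinical presentation.

**CD34⁺ similarity score.** From flagged CD34⁺ reference samples the top
5% most up- and down-regulated genes form a signature; each sample's
score is the signed log₁₀ p-value of a two-sided Wilcoxon rank-sum test
between its up-set and down-set expression values. Positive = more
CD34⁺-like = more advanced.

**Expression entropy.** Shannon entropy H = −Σ_b p_b·log p_b of the
64-bin histogram of a sample's expression values over the
low-information-ratio gene universe (~6,384 genes). A model-side
("simulated") entropy curve s_t is built by mixing a random
per-population expression matrix (64 × 6,384) with the time-dependent
population weights: s_t dips to a singular minimum exactly where the
population mixture is most heterogeneous (the mixing-entropy maximum).

**Pinning and T1/T2.** Patient scores and the model CD34 ratio are
independently normalized to [0, 1]; each CP patient is matched to the day
with the nearest normalized CD34 ratio, then refined by nearest entropy
within a CD34 neighbourhood after aligning the observed-entropy V minimum
with the simulated-entropy minimum. Patients pinned before the entropy
minimum (~4 years) are "early CP" (T1), the rest "late CP" (T2) — a
candidate progression-risk marker.

## Worked example

```python
import pandas as pd
import cml_chronos as cc

params = cc.ModelParams()                      # literature compartment model
traj = cc.simulate_trajectories(params)        # 0..2200 d, healthy + CML
minimum = cc.simulated_entropy_minimum(params, n_seeds=10, base_seed=1,
                                       trajectory=traj)
print(f"entropy minimum: {minimum.t_min:.0f} days")

# synthetic four-stage cohort (42 CP / 9 AP / 8 APcyto / 28 BC) with truth
cfg = cc.SyntheticCohortConfig(rng_seed=0)
expression, annotations, truth = cc.make_cohort(cfg, params=params, traj=traj)
refs = list(annotations.index[annotations["is_cd34_reference"]])
signature = cc.build_signature(expression, reference_samples=refs)
scores = cc.score_cohort(expression, signature)
entropies = pd.Series(cc.matrix_entropy(expression.T.to_numpy()),
                      index=expression.columns)

cp = [s for s in annotations.index if annotations.loc[s, "stage"] == "CP"
      and not annotations.loc[s, "is_cd34_reference"]]
curve = cc.simulated_entropy_curve(cc.generate_sgem(6384, 11), traj)
mapper = cc.DiseaseTimeMapper(boundary_time=minimum.t_min).fit(curve)
mapping = mapper.map_cohort(pd.DataFrame({"score": scores.loc[cp, "score"],
                                          "entropy": entropies.loc[cp]}))
print(mapping["phase_label"].value_counts().to_dict())
```

Output:

```
entropy minimum: 1460 days
{'T1': 30, 'T2': 12}
```

The simulated-entropy minimum lands at 1,460 days (~4.0 years after the
first malignant stem cell) and splits the 42 chronic-phase patients into
30 early and 12 late. On this cohort the entropy V over CD34⁺ similarity
is strongly significant (quadratic-term p ≈ 4·10⁻⁵) and the pinned times
rank-correlate with the generation-time truth at Spearman ρ ≈ 0.97.

The same steps are available from a shell:

```bash
cml-chronos synth --seed 0 --out-dir cohort/
cml-chronos score cohort/expression.tsv cohort/annotations.tsv --out-dir out/
cml-chronos run --seed 0 --out-dir results/   # full pipeline + manifest
```

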