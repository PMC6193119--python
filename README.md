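# dynconn

Static and dynamic brain-connectivity analysis with group statistics
and brain–behavior regression, for cohorts split into abdominal and
non-abdominal obesity groups by the waist–hip ratio (WHR > 0.9 for
males, > 0.85 for females).

The package is aimed at researchers who have already extracted
node-level data from neuroimaging — per-subject node-by-time series
(e.g., independent-component time courses from resting-state fMRI) and
per-subject directed fiber-probability matrices (from probabilistic
tractography) — and want the downstream network analysis: connectivity
construction, brain-state discovery, centrality, permutation group
tests, and regression of centrality against Eating Disorder
Examination Questionnaire (EDE-Q) subscales. All inputs and outputs
are plain TSV; no imaging formats are read. A synthetic-cohort
generator with planted ground truth makes the whole chain verifiable
without any imaging data.

## What it computes

**Structural.** Degree centrality on the weighted directed
fiber-probability network: `DC_i = Σ_j w_ij + Σ_j w_ji` (out- plus
in-strength, diagonal excluded).

**Static functional.** Per subject: Pearson correlation `r_ij` of the
full time series → unsigned soft threshold
`w_ij = ((r_ij + 1)/2)^β` with β = 6 → Fisher z = atanh(w) with zeroed
diagonal → undirected DC (column sums).

**Dynamic functional.** Gaussian-tapered sliding windows (default
length `round((1/f_min)/TR)` = 172 TRs at TR = 0.645 s, f_min =
0.009 Hz) → per-window graphical lasso, maximizing
`log det θ − tr(Sθ) − λ‖θ‖₁` (off-diagonal penalty; λ selected per
subject by contiguous-block cross-validation) → partial-correlation
matrices → K-means brain states (k chosen by per-subject silhouette
voting), greedy participant-to-group state matching, per-state DC.
Hub nodes of a state have mean-normalized betweenness centrality
> 1.5 (edge length = 1/weight).

**Statistics.** Node-wise permutation tests of group DC differences
(label shuffles, two-sided add-one p, Benjamini–Hochberg FDR),
demographic-table tests (Pearson chi-square, summary t-tests), and OLS
regressions `EDEQ = Σ β_k·DC_k + age + C` with the FDR family spanning
regions/networks × the four EDE-Q subscales.

## Worked example

Generate a synthetic cohort with a planted effect (edges touching
nodes 0 and 1 strengthened in the abdominal group, EDE-Q scores built
from structural DC with β = 0.5 plus an age effect), then recover the
planted regression:

```python
import numpy as np
from dynconn.synthetic import SyntheticCohortConfig, generate_cohort
from dynconn.structural import structural_dc
from dynconn.stats import fit_edeq_regression

cfg = SyntheticCohortConfig(n_per_group=100, p=10, t=20, k_states=1,
                            edeq_beta=0.5, edeq_noise_sd=0.1, seed=17)
cohort = generate_cohort(cfg)
dc = np.array([structural_dc(cohort.fiber_matrices[s.id]).values[[0, 1]].mean()
               for s in cohort.subjects])
age = np.array([s.age for s in cohort.subjects])
edeq = np.array([s.edeq_r for s in cohort.subjects])
res = fit_edeq_regression(edeq, {"dc": dc}, age)
print(f"beta_dc = {res.coefficients['dc']:.3f}  (planted 0.5)")
print(f"beta_age = {res.coefficients['age']:.4f}  (planted 0.01)")
print(f"R^2 = {res.r_squared:.3f},  model p = {res.model_p:.2e}")
```

prints

```
beta_dc = 0.509  (planted 0.5)
beta_age = 0.0096  (planted 0.01)
R^2 = 0.941,  model p = 8.38e-122
```

The fitted DC coefficient and age coefficient match the planted values
(0.5 and 0.01) within sampling error, and the model explains ~94% of
the score variance at the planted noise level.

The same chain is available from the shell:

```bash
dynconn simulate --out-dir cohort --n-per-group 20 --nodes 10 --seed 1
dynconn structural --fiber-dir cohort --subjects cohort/subjects.tsv --out dc_structural.tsv
dynconn static --ts-dir cohort --subjects cohort/subjects.tsv --out dc_static.tsv
dynconn stats --dc dc_static.tsv --subjects cohort/subjects.tsv --n-perm 5000 --seed 1 --out perm.tsv
dynconn run --ts-dir cohort --fiber-dir cohort --subjects cohort/subjects.tsv \
            --out-dir results --window-len 30 --stride 10 --seed 1   # full pipeline
```

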