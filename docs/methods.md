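# Methods

`dynconn` implements a multimodal brain-connectivity analysis chain for
cohorts split into abdominal and non-abdominal obesity groups by the
waist–hip ratio (WHR), together with a synthetic-cohort generator that
plants every quantity the chain is supposed to recover. This note
documents the models, the parameters that matter, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Group definition

Subjects are assigned to the *abdominal* group when WHR strictly
exceeds 0.9 (males) or 0.85 (females), otherwise *non-abdominal*.
Boundary values are non-abdominal. Sex tokens `M/F/male/female` are
accepted in any case.

## Structural connectivity

The structural input per subject is a directed fiber-probability matrix
`F` with entries in [0, 1]: `F[i, j]` is the probability that
probabilistic-tractography streamlines seeded in region `i` reach
region `j`. Tractography itself is upstream of this package; matrices
arrive as headerless TSV. The diagonal is forced to zero on ingestion
(self-connection entries are seeding artifacts). Degree centrality (DC)
on this weighted directed network is

    DC_i = sum_j F[i, j] + sum_j F[j, i]    (out-strength + in-strength)

Asymmetry is preserved; probabilities are summed raw (not
log-transformed).

## Static functional connectivity

Per subject, from a node-by-time matrix sampled every `TR` seconds:

1. Pearson correlation `r_ij` over the full time series.
2. Soft threshold `w_ij = ((r_ij + 1)/2)^beta` with `beta = 6`
   (default). This is the canonical unsigned weighted-network map: it
   avoids a hard edge cutoff, sends r = −1 to 0 and r = 1 to 1, and is
   strictly monotone in r.
3. Fisher r-to-z, `z_ij = atanh(w_ij)`, with the diagonal zeroed first
   (w_ii = 1 would map to infinity and self-edges carry no
   information).
4. Undirected DC = column sums of the z matrix.

The chain is invariant to per-node affine rescaling of the time series
(Pearson invariance) and equivariant under node relabeling.

## Dynamic functional connectivity

### Windowing

A rectangular window of `window_len` time points is convolved with a
Gaussian kernel (SD `taper_sigma` time points, truncated at ±3σ) and
normalized to sum to one; windows advance by `stride`. The number of
windows is `floor((t − window_len)/stride) + 1`. Each window yields a
taper-weighted covariance
`S = Σ_k u_k (x_k − x̄_u)(x_k − x̄_u)ᵀ` with `x̄_u` the weighted mean.

The default `window_len` is derived from the slowest retained
frequency: `round((1/min_freq)/TR)`, which gives 172 TRs (≈111 s) at
TR = 0.645 s and `min_freq` = 0.009 Hz. This default suits real
resting-state data, where the window must cover one full cycle of the
slowest band. When the scientific question is *state* recovery, the
window must instead resolve the state dwell time: a window spanning
several dwell periods averages distinct states into a single
covariance and no clustering can undo that. The state-recovery
experiments therefore use a 16-TR window (stride 6, σ = 1.5) against a
planted mean dwell of 40 — roughly a half-dwell window. This is a
property of sliding-window estimators generally, not of this
implementation.

### Precision estimation

Each windowed covariance is inverted by L1-penalized maximum
likelihood (graphical lasso), maximizing

    log det θ − tr(S θ) − λ ‖θ_offdiag‖₁

The penalty is applied to off-diagonal entries only, so the λ → ∞
limit is the diagonal precision `1/diag(S)`. The solver is
scikit-learn's coordinate-descent graphical lasso (LARS mode for
p ≤ 3, where the coordinate solver can stall near the soft-threshold
kink; LARS is exact there). Ill-conditioned windows are retried with
light diagonal loading (ε·mean(diag)·I, ε up to 1e−2). Solver
tolerances: dual gap 1e−5 for standalone fits; per-window bulk fits
inside a subject use 1e−3 with a 50-iteration cap, since the matrices
feed K-means clustering, which is insensitive to fourth-decimal
precision. A stalled solver (near-zero dual gap at the iteration cap)
is reported via the `converged` flag, not an exception.

One λ is selected per subject by V-fold cross-validation over
*contiguous* blocks of windows (contiguity respects the temporal
dependence of overlapping windows): θ is fit on the average
training-block covariance and scored by the unpenalized log-likelihood
on the held-out block's average covariance; ties prefer the smaller λ.
The same λ is then applied to all of that subject's windows.

Each precision is rescaled to a partial-correlation matrix
`ρ_ij = −θ_ij/√(θ_ii θ_jj)` (unit diagonal), which makes windows
comparable across subjects and is the representation clustered below.

### Brain states

The number of states k is chosen by per-subject silhouette voting:
each subject's vectorized windows (upper triangles) are clustered for
every candidate k, the subject votes for its silhouette-maximizing k,
and the mode over subjects wins. Mode ties fall back to the elbow
criterion (largest second difference of the mean within-cluster
dispersion curve), then to the smaller k.

Group states are K-means clusters (squared Euclidean on vectorized
upper triangles, 10 seeded restarts, 300-iteration cap) of the windows
pooled over subjects, indexed in descending occupancy; each state's
mean matrix is the element-wise mean of its member windows.
Participant-level states are clustered the same way per subject and
matched to group states greedily: in descending order of the variance
each participant cluster explains, assign the still-free group state
with the maximum Pearson correlation of mean matrices (ties to the
lower group-state index). Greedy matching is total — every participant
cluster is assigned even if poorly correlated.

Per-state DC averages a subject's member windows element-wise, then
applies the same soft-threshold + Fisher-z + column-sum path as the
static chain (a deliberate consistency choice; the raw averaged
partial correlations contain negative entries that the unsigned map
handles uniformly). States a subject never visits are absent from that
subject's table and excluded from group tests.

Hub nodes of a state are those whose betweenness centrality (BC),
normalized by the mean BC over nodes, strictly exceeds 1.5. BC uses
edge length 1/weight on the soft-thresholded state matrix; zero-weight
edges are absent (1/0 undefined; a zero probability is no connection),
and co-shortest paths share credit fractionally.

## Group statistics

Node-wise group differences in DC are tested by permutation: observed
statistic = difference in group means; the null reshuffles group
labels (sizes preserved) `n_perm` times (default 5,000); two-sided
add-one p-values `p = (1 + #{|null| ≥ |obs|})/(1 + n_perm)` (never
exactly zero); Benjamini–Hochberg FDR across nodes at α = 0.05
(step-up, `q_i = min_{j≥i} m·p_(j)/j`, reject q < α).

Demographic table checks: Pearson chi-square without continuity
correction for sex, two-sample t from summary statistics for
continuous rows (pooled variance by default; Welch available).

Behavior regressions: OLS of each EDE-Q subscale (restraint, eating,
shape, weight concern) on one or more DC predictors plus age:

    EDEQ = Σ_k β_k DC_k + β_age·age + C

Reported: coefficients, per-coefficient two-sided p, model R², model
F-test p. The BH-FDR family spans regions/networks × the four
subscales jointly; the model F-test p enters the correction by default
(the per-DC-coefficient p is available via `use="coef"` — with a
single DC predictor the two orderings coincide).

## Synthetic cohorts

The generator emulates the statistical structure the chain assumes:

- **States** are sparse SPD precision matrices. A fraction
  `precision_sparsity` of node pairs (default 0.2) receives a planted
  partial correlation of magnitude 0.35–0.55 with random sign;
  positive definiteness is enforced by shrinking the off-diagonal
  until the minimum eigenvalue clears 0.1, then per-node variance
  scales in [0.8, 1.5] are applied (partials unchanged). Supports are
  redrawn per state, which is what makes states distinguishable.
- **Switching** is a Markov chain with geometric dwell: exit
  probability `1/dwell_mean` per step, uniform jump among the other
  states. Mean run length equals `dwell_mean` (default 40).
- **Time series** are zero-mean Gaussian draws from the active state's
  covariance, independent across time points given the state. There is
  no hemodynamic smoothing, drift, or physiological noise — those are
  preprocessing concerns, upstream and out of scope. Passing recovery
  tests therefore shows the estimator chain is correct under its own
  model, not that real fMRI meets that model.
- **Group effect**: in the abdominal group, precision edges touching
  `group_effect_nodes` are scaled by `group_effect_size` (default 1.5;
  edges between two effect nodes scaled once), and the shared base
  fiber matrix (uniform [0, 0.3], zero diagonal) has the corresponding
  rows/columns scaled the same way, clipped to [0, 1]. Because the
  fiber matrix is shared within a group, structural DC carries no
  within-group variance — the planted group contrast is exact.
- **Behavior scores**: each subscale is
  `β·DC* + β_age·age + C + N(0, σ)` with `DC*` the mean structural DC
  over the effect nodes, β = 0.5, β_age = 0.01/year, C = 1,
  σ = 0.5 by default; negative draws are clipped at zero (rare at the
  defaults). Age is uniform on [20, 70]; sexes alternate within each
  group; WHR is drawn from per-sex bands disjoint from the classifier
  thresholds, so group labels round-trip exactly.

Cohorts, time series, fiber matrices and ground truth are written as
plain TSV; a fixed seed reproduces a cohort bit-for-bit.

## Experiment sizes

The verification experiments (test suite and `scripts/acceptance.py`)
use: state recovery on 10 subjects/group, p = 10 nodes, t = 1,200 time
points, 3 states, dwell 40 (20 replicates in the suite, 10 in the
script); permutation calibration on 100-node null tables over 200
replicates at 500 permutations, power on 50 nodes with a 1.5-SD shift
on 5 nodes at n = 40/group; regression recovery at n = 200 subjects
with noise SD 0.1 and a 1,000-replicate null for the type-I rate.
These sizes give tight Monte-Carlo estimates while keeping a full run
in the minutes range on one CPU.

## Known limitations

- The generator's Gaussian, temporally independent states favor the
  graphical-lasso estimator; autocorrelated or non-Gaussian dynamics
  would weaken window-level precision estimates.
- Silhouette voting can under-select k when states overlap heavily or
  windows mix states; the elbow tie-break only arbitrates exact mode
  ties.
- Permutation tests assume exchangeable subjects under the null; no
  covariate adjustment is applied at the permutation stage (age enters
  only the regressions).
- With a single shared fiber matrix per group, structural permutation
  tests on synthetic data are degenerate (zero within-group variance);
  calibration experiments therefore use tables with subject-level
  noise.
- BC is computed on weighted graphs only; a binarized variant is
  deliberately not provided.
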