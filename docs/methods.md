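# Methods

## Problem setting

Two numeric views on one cohort — samples × features, typically expression
levels and methylation beta/M-values — with p, q ≫ n, plus right-censored
survival (time, event) per sample and optional gene-set collections in GMT
format.  The goal is a small set of molecular subtypes derived jointly from
both views, evaluated by how well they separate survival.

## Preprocessing

Features whose missing rate is *strictly above* 5% (configurable) are
discarded; surviving holes are imputed by the feature's observed mean
(median or hard failure selectable).  Only subjects present in both views
and the survival table are retained, in one common sample order.  Columns
are then standardized to mean 0 and unit sample sd (n−1 denominator);
constant columns cannot be scaled and are dropped with a warning rather
than raising — a sparsity penalty would zero them anyway.  Probe-to-gene
summarization and normalization of raw counts are deliberately out of
scope: any numeric matrix is accepted.

## Sparse CCA by alternating elastic net

The objective is the ℓ₁-penalized covariance criterion under unit score
variances (see README).  Because maximizing covariance under
Var(Xw₁) = Var(Yw₂) = 1 equals maximizing correlation, the solver is the
correlation-maximizing alternating scheme: each half-step solves

    min_w ‖t − Aw‖² / (2(n−1)) + ridge‖w‖² + τ‖w‖₁

where t is the partner view's current score, followed by rescaling so the
new score has unit sample variance.  The 1/(2(n−1)) data-fit scale makes
the soft threshold act directly on sample covariances: for a single
standardized column the solution is sign(c)·max(|c|−τ, 0)/(1+2·ridge)
with c the covariance between column and target, so τ is interpretable as
a covariance cutoff.  The step is solved by cyclical coordinate descent
(scikit-learn's elastic net with the penalties remapped onto this scale);
τ = 0 uses an exact linear solve instead.  Each view has its own (τ, ridge)
pair, since the two omics generally require different sparsity.

Numerical choices:

* **Initialization** — w₂ starts at the leading right singular vector of
  the cross-covariance XᵀY/(n−1); deterministic and already in the right
  basin.  A seeded random unit vector is the fallback for degenerate input.
* **Convergence** — stop when the canonical correlation changes by less
  than `tol` (default 1e-6) between sweeps, `max_iter` 200; non-convergence
  flags the component and warns but is not an error.  An all-zero weight
  vector after a step (penalty too large for that view) is an error.
* **Sign convention** — the largest-magnitude entry of w₁ is made positive
  (both weight vectors flip together), so fits are bit-for-bit reproducible.
* **Deflation** — after each component both views are residualized on
  their own score vector and re-standardized (PLS-style), so later
  components are decorrelated from earlier scores.  Internally exhausted
  columns are kept as zero columns so weight vectors retain full length;
  the public `deflate` drops them.  With all penalties zero this scheme
  reproduces the full classical CCA spectrum (checked against the
  generalized-eigenvalue oracle at 1e-6).
* **Aggregation** — per-component scores are z-scored and combined;
  default `both_views` concatenates (u_k, v_k), with `x_only` and
  `mean_of_views` available because the right combination is
  application-dependent.

## Clustering

k-means (k-means++ seeding, 25 restarts by default, Euclidean distance on
the z-scored score columns) with labels canonicalized 1..k by decreasing
cluster size.  Diagnostics for choosing k: the WSS elbow curve (re-run
with more restarts if a local minimum makes WSS non-monotone), mean
silhouette width, and the BSS/WSS ratio.  `select_k` automates the choice
as the silhouette argmax (ties to the smaller k) but always emits the full
diagnostics table so the manual elbow-inspection workflow, or prior
knowledge of subtype counts, can override.

## Survival evaluation

* **Kaplan–Meier** — product-limit estimator with Greenwood standard
  errors; tied events at one time are processed together; censored
  observations shrink the risk set without dropping the curve.  Event
  bookkeeping comes from lifelines' survival table.
* **Log-rank** — the K-sample test (lifelines), df = C−1.
* **Cox fit** — reference-coded subtype indicators fitted by
  Newton–Raphson on the partial likelihood, implemented in-package:
  Efron tie handling by default, Breslow optional (both validated against
  R `survival::coxph` to 1e-6), step-halving on likelihood decrease,
  tolerance 1e-9 on the score norm, at most 50 iterations.  Monotone
  likelihood (a group owning all earliest events) is detected and the
  offending coefficient capped at |β| ≤ 15 with a warning.  Per-group
  coefficients are centered by the size-weighted mean so Σ nᵢβ̂ᵢ = 0
  exactly; pairwise hazard ratios are unaffected by the centering.
* **HRmin / SEP** — computed from the centered coefficients as defined in
  the README.  The bounded SEP form exp(−Σ(nᵢ/n)|β̂ᵢ|) ≤ 1 and its
  reciprocal ≥ 1 are both implemented because both circulate in applied
  work; the reciprocal is the default and every output records which
  convention produced the number.
* **Global Schoenfeld test** — the classic Grambsch–Therneau
  approximation: per-event Schoenfeld residuals are correlated with the
  transformed event times (default: ranks; identity optional) and the
  global χ² with df = C−1 uses the average-information scaling
  d·Uᵀ I⁻¹ U / Σ(g−ḡ)².  This reproduces the classic global statistic
  computed from R's Schoenfeld residuals; note that `survival` ≥ 3.0
  replaced it in `cox.zph` with an exact score test, so numbers differ
  slightly from recent R output by design.  Calibration is verified by
  simulation (type-I error ≈ 0.045 at α = 0.05; power 1.0 against
  crossing hazards at n = 400).

## Hyper-parameter search

`grid_search` evaluates every (τ₁, τ₂, K) on the full chain
fit → aggregate → k-means(k) → Cox, holding k fixed (subtype counts are
usually set by prior knowledge).  The proportional-hazards condition
(GST p > 0.05) is enforced as a hard validity filter before maximizing
HRmin — making the selection rule total rather than a post-hoc check — and
can be switched off.  Ties break by larger SEP, then fewer components,
then lexicographic (τ₁, τ₂), for determinism.  Grid points where a penalty
zeroes a whole view are recorded as `degenerate` and excluded.  Note the
criterion uses survival labels; the tuned model is selected *for* survival
separation and should be read accordingly.

## Differential expression and over-representation

Per subtype, genes are compared subtype-vs-rest with a moderated t-test:
pooled per-gene variances are shrunk toward a scaled-inverse-χ² prior
fitted across genes by the method of moments (no excess dispersion ⇒
complete pooling), t computed on the shrunk variance with inflated df, and
Benjamini–Hochberg control across genes (α = 0.05 default for the up/down
calls).  Over-representation is the hypergeometric upper tail
P(K ≥ k) with the universe fixed to the measured genes intersected with
the GMT universe — enrichment must be judged against what was measurable —
BH-adjusted within each direction.  Canonical-weight interpretation is
provided separately: per-component non-zero gene lists and a ranking by
mean absolute weight across components (sign-flip invariant).

## Synthetic data generator

`gen_paired_omics` draws n samples from C clusters; cluster means sit on a
regular simplex in latent space with pairwise distance `cluster_separation`,
measured in units of the within-cluster standard deviation (within-cluster
covariance I/K, i.e. unit total variance — at K = 1 this is the ordinary
per-coordinate sd).  Each of the K latent factors loads on
`n_nonzero_per_view` features per view, with disjoint supports across
factors and magnitudes uniform on ±[0.5, 1] so supports stay identifiable
at moderate noise; iid Gaussian noise (sd 0.75 by default) is added per
view.  `gen_subtype_survival` draws exponential event times with rate
baseline·exp(log-hazard of the cluster) — the minimal generator satisfying
proportional hazards — with independent exponential censoring calibrated
by root-finding to the requested censored fraction.  A two-group
hazard-crossing generator (rate multiplier exp(±log HR) switching at the
baseline median) exists solely to exercise the Schoenfeld test's power.
`gen_genesets` adds random sets plus one planted set (the expression
support genes in the `recovery` preset).

The presets define the study conditions used throughout the tests:
`recovery` (n = 200, p = 300, q = 400, 3 clusters at separation 4, hazard
ratios 1 : 2 : 4, 15% censoring), `null` (no cluster structure, equal
hazards) and `crossing`.  Simulation sizes elsewhere: 20 random instances
for the classical-CCA equivalence, 10 seeds for support recovery and
end-to-end recovery, 200 replicates at n = 400 for GST calibration.

What the generator does *not* emulate: real marginal distributions
(beta-distributed methylation, count-based expression), feature
correlation beyond the shared factors, batch structure, or informative
censoring.  Passing tests therefore demonstrate correctness of the
algorithms and calibration of the statistics under the stated model — not
that any particular real cohort will yield well-separated subtypes.

## Known limitations

* No covariate-adjusted Cox models, competing risks, or interval censoring.
* No consensus clustering or mixture-model alternatives to k-means.
* The τ penalties are on the covariance scale of standardized data;
  grids must be supplied by the user (no automatic path).
* DE assumes approximately Gaussian expression per gene; counts should be
  transformed upstream.
* Multi-component weights live in deflated coordinate systems; projecting
  *new* samples uses the stored weights per component and is approximate
  beyond the first component.
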