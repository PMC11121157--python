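# scclust

Joint subtyping of paired omics profiles — typically gene expression and
DNA methylation measured on the same patients — by **sparse canonical
correlation analysis (sCCA)** with separate per-view penalties, **k-means
clustering** of the latent canonical scores, and **survival-based
evaluation** of the resulting subtypes (Kaplan–Meier curves, log-rank test,
minimum pairwise hazard ratio, the SEP separation statistic and the global
Schoenfeld proportional-hazards check), followed by per-subtype
differential expression and hypergeometric pathway over-representation.

It is aimed at cancer-genomics analysts who have two high-dimensional views
(p, q ≫ n) on a common cohort with clinical follow-up, and want molecular
subtypes whose survival curves actually separate.

## The model

Given column-standardized views X (n × p) and Y (n × q), sCCA seeks weight
vectors w₁, w₂ solving

```
max  Cov(X w₁, Y w₂) − τ₁‖w₁‖₁ − τ₂‖w₂‖₁
s.t. Var(X w₁) = Var(Y w₂) = 1
```

Each view carries its own ℓ₁ penalty (τ₁, τ₂), since expression and
methylation generally need different sparsity levels.  The solver
alternates two elastic-net regressions (cyclical coordinate descent with
soft-thresholding), regressing each view on the other's score and
rescaling to unit score variance; with τ = 0 it reproduces classical CCA
exactly.  Further components are extracted by deflating each view on its
own score.  The per-component scores u_k = X w₁ᵏ, v_k = Y w₂ᵏ are z-scored,
concatenated and clustered with k-means.

Subtype quality is judged on survival.  For C subtypes with size-weighted
centered Cox log-hazard coefficients β̂ᵢ (Σ nᵢ β̂ᵢ = 0):

* **HRmin** = min over pairs of max(exp(β̂ᵢ−β̂ⱼ), exp(β̂ⱼ−β̂ᵢ)) ≥ 1 — the
  hazard separation of the *worst* pair;
* **SEP** — exp(−Σ (nᵢ/n)|β̂ᵢ|) in its bounded-by-1 form; the package
  reports the reciprocal (≥ 1) by default so larger = better separated,
  and every output labels the convention used;
* the **global Schoenfeld test** (Grambsch–Therneau, ranked event times)
  checks the proportional-hazards assumption; analyses are considered
  valid when its p-value exceeds 0.05.

Hyper-parameters (τ₁, τ₂, number of components) can be tuned by grid
search maximizing HRmin among grid points that keep proportional hazards.

## Worked example

Simulate a cohort with known ground truth (3 subtypes with hazard ratios
1 : 2 : 4, two sparse shared latent factors, one planted gene set), then run
the full pipeline:

```
scclust simulate --preset recovery --out-dir demo/data --seed 0
scclust run --x demo/data/X.tsv --y demo/data/Y.tsv \
            --survival demo/data/survival.tsv --gmt demo/data/sets.gmt \
            --tau1 0.2 --tau2 0.2 --components 2 --k 3 \
            --out-dir demo/run --seed 0
```

`demo/run/summary.json` then contains (abridged):

```json
{
 "correlations": [0.956277, 0.966733],
 "group_sizes": [69, 66, 65],
 "gst_p": 0.4833292648996522,
 "hr_min": 1.5550624237759239,
 "logrank_p": 2.626505681750916e-05,
 "sep": 1.351079018815836,
 "sep_convention": "reciprocal",
 "top_enriched": {"subtype2_down": {"set": "planted_set", "q_value": 4e-08}}
}
```

Reading: the two canonical pairs are strongly correlated across views
(0.96, 0.97); the three recovered subtypes separate in survival (log-rank
p = 2.6 × 10⁻⁵), the worst-separated pair of subtypes still differs by a
hazard ratio of 1.56 (the true worst pair is 2), proportional hazards is
retained (GST p = 0.48 > 0.05), and the planted gene set is the top
over-represented set in every subtype's differential-expression list.
The run directory also holds the canonical weights, latent scores, subtype
labels, per-subtype DE and ORA tables, and a gene ranking by average
absolute canonical weight.

Other entry points: `scclust tune` (HRmin grid search), `scclust cluster`
(with silhouette/elbow/BSS-WSS diagnostics), `scclust survival`,
`scclust ora`, and `--config` for TOML/YAML pipeline configs.  Everything
is importable as a library (`scclust.SparseCCA` is a scikit-learn-style
transformer).

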