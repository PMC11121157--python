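"""Synthetic paired-omics data with known latent, subtype and survival truth.

The generator emulates the structure the pipeline is designed to exploit:
two high-dimensional views (p, q >> n) sharing a small number of sparse
latent factors, latent cluster structure (subtypes separated in factor
space), subtype-dependent exponential survival with independent censoring,
and gene-set databases with one planted enriched set.  Ground truth (latent
factors, loading supports, labels, log-hazards, the planted set) is
returned so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import GeneSetDB

__all__ = [
    "SynthTruth",
    "gen_paired_omics",
    "gen_subtype_survival",
    "gen_crossing_survival",
    "gen_genesets",
    "make_preset",
    "PRESETS",
]


@dataclass
class SynthTruth:
    """Ground truth of one simulated dataset."""

    latent_factors: np.ndarray  # n x K
    loadings_x: np.ndarray  # p x K, sparse
    loadings_y: np.ndarray  # q x K, sparse
    true_labels: np.ndarray  # 1..C per sample
    true_log_hazards: np.ndarray | None = None
    enriched_sets: list[str] = field(default_factory=list)
    seed: int = 0

    def support(self, view: str) -> np.ndarray:
        load = self.loadings_x if view == "x" else self.loadings_y
        return np.abs(load).sum(axis=1) > 0

    def to_json(self, path) -> None:
        payload = {
            "true_labels": self.true_labels.tolist(),
            "true_log_hazards": (
                None
                if self.true_log_hazards is None
                else list(map(float, self.true_log_hazards))
            ),
            "support_x": np.flatnonzero(self.support("x")).tolist(),
            "support_y": np.flatnonzero(self.support("y")).tolist(),
            "enriched_sets": self.enriched_sets,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _cluster_means(n_clusters: int, k_latent: int, separation: float) -> np.ndarray:
    """Centers of a regular simplex with pairwise distance = separation."""
    if n_clusters == 1 or separation == 0:
        return np.zeros((n_clusters, k_latent))
    # regular simplex, embedded isometrically in (n_clusters - 1) dims
    eye = np.eye(n_clusters)
    centered = eye - eye.mean(axis=0)
    u, s, _vt = np.linalg.svd(centered, full_matrices=False)
    coords = u[:, : n_clusters - 1] * s[: n_clusters - 1]
    dist = np.linalg.norm(coords[0] - coords[1])
    coords *= separation / dist
    means = np.zeros((n_clusters, k_latent))
    dims = min(k_latent, n_clusters - 1)
    if k_latent < n_clusters - 1:
        import warnings

        warnings.warn(
            "k_latent < n_clusters - 1: cluster separation is reduced by projection"
        )
    means[:, :dims] = coords[:, :dims]
    return means


def gen_paired_omics(
    n: int = 200,
    p: int = 300,
    q: int = 400,
    k_latent: int = 2,
    n_clusters: int = 3,
    n_nonzero_per_view: int = 10,
    cluster_separation: float = 4.0,
    noise_sd: float = 0.75,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SynthTruth]:
    """Paired views sharing sparse latent factors with clustered means.

    Latent factors are isotropic Gaussian around per-cluster means placed
    on a regular simplex with pairwise distance ``cluster_separation``,
    measured in units of the within-cluster standard deviation (the RMS
    spread, so the within-cluster covariance is I/k_latent and has unit
    total variance).  Each factor loads on
    ``n_nonzero_per_view`` features per view (disjoint supports across
    factors, magnitudes uniform in [0.5, 1] with random signs), plus iid
    Gaussian noise with sd ``noise_sd``.
    """
    if k_latent < 1:
        raise ValueError("k_latent must be >= 1")
    if n_nonzero_per_view * k_latent > min(p, q):
        raise ValueError("infeasible sparsity: too many non-zero loadings")
    rng = np.random.default_rng(seed)
    sizes = np.full(n_clusters, n // n_clusters)
    sizes[: n % n_clusters] += 1
    labels = np.repeat(np.arange(1, n_clusters + 1), sizes)
    labels = rng.permutation(labels)
    means = _cluster_means(n_clusters, k_latent, cluster_separation)
    Z = means[labels - 1] + rng.standard_normal((n, k_latent)) / np.sqrt(k_latent)

    def loadings(dim: int) -> np.ndarray:
        A = np.zeros((dim, k_latent))
        idx = rng.permutation(dim)
        for f in range(k_latent):
            rows = idx[f * n_nonzero_per_view : (f + 1) * n_nonzero_per_view]
            mags = rng.uniform(0.5, 1.0, size=n_nonzero_per_view)
            signs = rng.choice([-1.0, 1.0], size=n_nonzero_per_view)
            A[rows, f] = mags * signs
        return A

    A = loadings(p)
    B = loadings(q)
    X = Z @ A.T + noise_sd * rng.standard_normal((n, p))
    Y = Z @ B.T + noise_sd * rng.standard_normal((n, q))
    samples = [f"S{i + 1:04d}" for i in range(n)]
    xdf = pd.DataFrame(X, index=samples, columns=[f"gene_{j + 1:04d}" for j in range(p)])
    ydf = pd.DataFrame(Y, index=samples, columns=[f"cpg_{j + 1:04d}" for j in range(q)])
    truth = SynthTruth(
        latent_factors=Z,
        loadings_x=A,
        loadings_y=B,
        true_labels=labels,
        seed=seed,
    )
    return xdf, ydf, truth


def _censor_rate_for(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate giving the requested censored fraction.

    With event rate lambda_i and censoring rate c, P(censored) = c/(c+lambda_i);
    solve the sample-average for c by root finding.
    """
    if target <= 0:
        return 0.0
    lo, hi = 1e-12, float(rates.max()) * 1e6

    def f(c):
        return float(np.mean(c / (c + rates))) - target

    return brentq(f, lo, hi)


def gen_subtype_survival(
    true_labels,
    log_hazards,
    baseline_rate: float = 0.1,
    censoring_rate: float = 0.2,
    seed: int = 0,
    sample_ids=None,
) -> pd.DataFrame:
    """Exponential survival with per-subtype hazard multipliers.

    Event times are exponential with rate ``baseline_rate *
    exp(log_hazards[label])``; censoring is an independent exponential
    calibrated so the expected censored fraction equals
    ``censoring_rate``.
    """
    labels = np.asarray(true_labels)
    log_hazards = np.asarray(log_hazards, dtype=float)
    cats = np.unique(labels)
    if len(log_hazards) != len(cats):
        raise ValueError("one log-hazard per cluster required")
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    rng = np.random.default_rng(seed)
    rate_of = {c: baseline_rate * np.exp(lh) for c, lh in zip(cats, log_hazards)}
    rates = np.array([rate_of[c] for c in labels])
    t_event = rng.exponential(1.0 / rates)
    if censoring_rate > 0:
        c_rate = _censor_rate_for(rates, censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(labels))
    else:
        t_cens = np.full(len(labels), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-9)
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(len(labels))]
    return pd.DataFrame({"time": time, "event": event}, index=list(sample_ids))


def gen_crossing_survival(
    labels,
    baseline_rate: float = 0.1,
    log_hr: float = np.log(3.0),
    seed: int = 0,
    sample_ids=None,
) -> pd.DataFrame:
    """Two-group survival with a hazard ratio that reverses sign mid-study.

    Group 1 is exponential at the baseline rate.  Group 2's hazard is
    ``baseline * exp(log_hr)`` before the baseline median time and
    ``baseline * exp(-log_hr)`` after - a deliberate violation of
    proportional hazards used to exercise the Schoenfeld test's power.
    """
    labels = np.asarray(labels)
    cats = np.unique(labels)
    if len(cats) != 2:
        raise ValueError("crossing generator is two-group only")
    rng = np.random.default_rng(seed)
    n = len(labels)
    t0 = np.log(2.0) / baseline_rate
    h1 = baseline_rate * np.exp(log_hr)
    h2 = baseline_rate * np.exp(-log_hr)
    time = np.empty(n)
    u = rng.uniform(size=n)
    cum = -np.log(u)
    g1 = labels == cats[0]
    time[g1] = cum[g1] / baseline_rate
    # piecewise-exponential inverse for group 2
    g2 = ~g1
    early = cum <= h1 * t0
    time[g2 & early] = cum[g2 & early] / h1
    time[g2 & ~early] = t0 + (cum[g2 & ~early] - h1 * t0) / h2
    if sample_ids is None:
        sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    return pd.DataFrame(
        {"time": np.maximum(time, 1e-9), "event": np.ones(n, dtype=int)},
        index=list(sample_ids),
    )


def gen_genesets(
    universe,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (10, 40),
    planted_genes=None,
    seed: int = 0,
) -> GeneSetDB:
    """Random gene sets over a universe, plus one planted set of true genes."""
    universe = list(universe)
    rng = np.random.default_rng(seed)
    lo, hi = set_size_range
    if hi > len(universe):
        raise ValueError("set size exceeds universe")
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"random_set_{i + 1:03d}"] = sorted(members.tolist())
    planted_name = None
    if planted_genes is not None:
        planted_genes = list(planted_genes)
        if not set(planted_genes) <= set(universe):
            raise ValueError("planted genes must lie in the universe")
        planted_name = "planted_set"
        sets[planted_name] = planted_genes
    return GeneSetDB(sets=sets, universe=universe, planted=planted_name)


def make_preset(name: str, seed: int = 0) -> dict:
    """Build one of the named simulation scenarios.

    ``recovery``: 3 separated subtypes (separation 4 sd), hazard ratios
    (1, 2, 4), a planted gene set of the expression-support genes.
    ``null``: no cluster structure, equal hazards.
    ``crossing``: two groups with a hazard reversal (PH violation).
    Returns a dict with X, Y, survival, genesets and truth.
    """
    if name == "recovery":
        x, y, truth = gen_paired_omics(
            n=200, p=300, q=400, k_latent=2, n_clusters=3,
            n_nonzero_per_view=10, cluster_separation=4.0, noise_sd=0.75,
            seed=seed,
        )
        log_hazards = np.log([1.0, 2.0, 4.0])
        surv = gen_subtype_survival(
            truth.true_labels, log_hazards, baseline_rate=0.1,
            censoring_rate=0.15, seed=seed + 1, sample_ids=x.index,
        )
        planted = list(x.columns[truth.support("x")])
        db = gen_genesets(
            list(x.columns), n_sets=50, set_size_range=(10, 40),
            planted_genes=planted, seed=seed + 2,
        )
        truth.true_log_hazards = log_hazards
        truth.enriched_sets = [db.planted]
    elif name == "null":
        x, y, truth = gen_paired_omics(
            n=200, p=300, q=400, k_latent=2, n_clusters=3,
            n_nonzero_per_view=10, cluster_separation=0.0, noise_sd=0.75,
            seed=seed,
        )
        log_hazards = np.zeros(3)
        surv = gen_subtype_survival(
            truth.true_labels, log_hazards, baseline_rate=0.1,
            censoring_rate=0.15, seed=seed + 1, sample_ids=x.index,
        )
        db = gen_genesets(list(x.columns), n_sets=50, seed=seed + 2)
        truth.true_log_hazards = log_hazards
    elif name == "crossing":
        x, y, truth = gen_paired_omics(
            n=200, p=100, q=100, k_latent=1, n_clusters=2,
            n_nonzero_per_view=10, cluster_separation=4.0, noise_sd=0.75,
            seed=seed,
        )
        surv = gen_crossing_survival(
            truth.true_labels, baseline_rate=0.1, seed=seed + 1,
            sample_ids=x.index,
        )
        db = gen_genesets(list(x.columns), n_sets=20, seed=seed + 2)
        truth.true_log_hazards = None
    else:
        raise ValueError(f"unknown preset {name!r}")
    return {"x": x, "y": y, "survival": surv, "genesets": db, "truth": truth}


PRESETS = ("recovery", "null", "crossing")
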