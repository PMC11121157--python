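"""Per-subtype differential expression and gene-set over-representation.

Differential expression is a two-sample (subtype vs rest) moderated t-test:
per-gene pooled variances are shrunk toward a prior fitted across genes by
the method of moments (an empirical-Bayes scheme in the spirit of the
moderated statistics standard in expression analysis), with
Benjamini-Hochberg control across genes.  Over-representation uses the
hypergeometric upper tail against a background universe, BH-adjusted across
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cca import SCCAResult
from .io import GeneSetDB

__all__ = [
    "subtype_de",
    "ora_test",
    "component_gene_lists",
    "rank_genes_by_avg_abs_weight",
]

_D0_CAP = 1e8  # effectively-infinite prior df => complete pooling


def _moment_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of a scaled-inverse-chi-square variance prior.

    Observed gene variances s2 satisfy s2 | sigma2 ~ sigma2 * chi2_d / d.
    Matching the mean and excess variance of s2 across genes yields the
    prior scale s0^2 and degrees of freedom d0; no excess variance means
    complete pooling (d0 -> inf).
    """
    m = float(np.mean(s2))
    v = float(np.var(s2))
    var_sigma = (v - 2.0 * m * m / d) / (1.0 + 2.0 / d)
    if var_sigma <= 0 or m <= 0:
        return m, _D0_CAP
    d0 = 4.0 + 2.0 * m * m / var_sigma
    s0_sq = m * (d0 - 2.0) / d0
    return s0_sq, min(d0, _D0_CAP)


def subtype_de(
    expr: pd.DataFrame, labels, subtype, alpha: float = 0.05
) -> pd.DataFrame:
    """Moderated-t comparison of one subtype against all remaining samples.

    Returns one row per gene with ``mean_diff`` (subtype minus rest),
    ``t_stat``, ``p_value``, BH ``q_value`` and ``direction``
    (up / down / ns at FDR ``alpha``).
    """
    labels = np.asarray(labels)
    in_group = labels == subtype
    n1, n2 = int(in_group.sum()), int((~in_group).sum())
    if n1 < 3 or n2 < 3:
        raise ValueError(
            f"need >= 3 samples in subtype and rest (got {n1} and {n2})"
        )
    a = np.asarray(expr, dtype=float)[in_group]
    b = np.asarray(expr, dtype=float)[~in_group]
    mean_diff = a.mean(axis=0) - b.mean(axis=0)
    d = n1 + n2 - 2
    s2 = ((a - a.mean(axis=0)) ** 2).sum(axis=0) + ((b - b.mean(axis=0)) ** 2).sum(
        axis=0
    )
    s2 = s2 / d
    s0_sq, d0 = _moment_prior(s2, d)
    s2_tilde = (d0 * s0_sq + d * s2) / (d0 + d)
    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    se[se == 0] = np.inf
    t = mean_diff / se
    df_mod = min(d + d0, _D0_CAP)
    p = 2.0 * stats.t.sf(np.abs(t), df_mod)
    _rej, q, _a, _b2 = multipletests(p, method="fdr_bh")
    direction = np.where(
        (q <= alpha) & (mean_diff > 0),
        "up",
        np.where((q <= alpha) & (mean_diff < 0), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "gene_id": list(expr.columns),
            "mean_diff": mean_diff,
            "t_stat": t,
            "p_value": p,
            "q_value": q,
            "direction": direction,
        }
    ).set_index("gene_id")


def ora_test(genes, db: GeneSetDB) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against a database.

    Genes outside the universe are dropped (with a warning).  Per set:
    upper-tail P(K >= k) with population N = |universe|, M = set size in
    universe, n = list size; BH across sets; sorted by p.
    """
    universe = list(dict.fromkeys(db.universe))
    if len(universe) < 10:
        raise ValueError("universe too small (< 10 genes)")
    uset = set(universe)
    genes = list(dict.fromkeys(genes))
    kept = [g for g in genes if g in uset]
    if len(kept) < len(genes):
        warnings.warn(f"{len(genes) - len(kept)} gene(s) outside the universe dropped")
    if not kept:
        raise ValueError("empty gene list after universe intersection")
    N = len(universe)
    n_drawn = len(kept)
    kept_set = set(kept)
    rows = []
    for name, members in db.sets.items():
        in_uni = [g for g in dict.fromkeys(members) if g in uset]
        M = len(in_uni)
        if M == 0:
            continue
        k = len(kept_set.intersection(in_uni))
        p = float(stats.hypergeom.sf(k - 1, N, M, n_drawn))
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": M,
                "list_size": n_drawn,
                "universe_size": N,
                "gene_ratio": k / n_drawn,
                "p_value": min(p, 1.0),
            }
        )
    table = pd.DataFrame(rows)
    _rej, q, _a, _b = multipletests(table["p_value"], method="fdr_bh")
    table["q_value"] = q
    return (
        table.sort_values(["p_value", "set_name"])
        .reset_index(drop=True)
        .set_index("set_name")
    )


def component_gene_lists(result: SCCAResult, view: str = "x") -> list[dict[str, float]]:
    """Non-zero features per canonical component, with signed weights."""
    frame = result.weight_frame(view)
    out = []
    for col in frame.columns:
        w = frame[col]
        nz = w[w != 0]
        out.append({g: float(v) for g, v in nz.items()})
    return out


def rank_genes_by_avg_abs_weight(result: SCCAResult, view: str = "x") -> pd.Series:
    """Features ranked by mean absolute canonical weight across components.

    Ties break by feature-ID order.  Sign flips of whole components do not
    change the ranking.
    """
    frame = result.weight_frame(view)
    mean_abs = frame.abs().mean(axis=1)
    order = sorted(mean_abs.index, key=lambda g: (-mean_abs[g], g))
    return mean_abs.loc[order]


def plot_ora_dotplot(tables: dict, path=None, top: int = 10, ax=None):
    """Dot plot of ORA results: point size = gene ratio, shade = p-value.

    ``tables`` maps a panel label (e.g. ``"subtype1 up"``) to an ORA table.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _fig, ax = plt.subplots(figsize=(7, 5))
    names: list[str] = []
    for t in tables.values():
        for s in t.head(top).index:
            if s not in names:
                names.append(s)
    ypos = {s: i for i, s in enumerate(names)}
    for xi, (label, t) in enumerate(tables.items()):
        sub = t.head(top)
        sizes = 400 * sub["gene_ratio"].to_numpy() + 10
        shades = sub["p_value"].to_numpy()
        ax.scatter(
            [xi] * len(sub),
            [ypos[s] for s in sub.index],
            s=sizes,
            c=shades,
            cmap="Greys_r",
            vmin=0,
            vmax=max(0.05, float(shades.max()) if len(shades) else 1.0),
            edgecolor="k",
        )
    ax.set_xticks(range(len(tables)), list(tables.keys()), rotation=45, ha="right")
    ax.set_yticks(range(len(names)), names, fontsize=7)
    ax.set_xlim(-0.5, len(tables) - 0.5)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
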