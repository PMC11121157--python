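"""Survival-based evaluation of subtype assignments.

Implements the Kaplan-Meier product-limit estimator, the K-sample log-rank
test, a grouped Cox proportional-hazards fit (Newton-Raphson on the partial
likelihood, Efron or Breslow tie handling) and the separation statistics
derived from it:

* pairwise hazard ratios ``exp(beta_i - beta_j)`` between subtypes;
* ``HRmin`` - over all unordered subtype pairs, the smallest of the
  max-oriented ratios, ``exp(min_{i<j} |beta_i - beta_j|) >= 1``: the
  separation of the *worst-separated* pair;
* ``SEP`` - an exponential of the size-weighted mean absolute centered
  coefficient.  The literature formula ``exp(-sum (n_i/n) |beta_i|)`` lies
  in (0, 1]; reported values in practice are usually its reciprocal
  (>= 1), so both conventions are exposed and labelled;
* the global Schoenfeld test (GST) of the proportional-hazards assumption
  (Grambsch-Therneau, default time transform: ranks of event times).

Per-group coefficients are centered by the size-weighted mean so that
``sum n_i beta_i = 0``; pairwise differences are unaffected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import survival_table_from_events
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxGroupFit",
    "km_curve",
    "logrank_test",
    "cox_fit_subtypes",
    "hr_min",
    "sep_statistic",
    "schoenfeld_gst",
]

_BETA_CAP = 15.0  # |beta| bound under monotone likelihood


@dataclass
class KMCurve:
    """Product-limit survival estimate evaluated after each event time."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_se: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "n_events": self.n_events,
                "se": self.greenwood_se,
            }
        )


def km_curve(time, event) -> KMCurve:
    """Kaplan-Meier estimator with Greenwood standard errors.

    Ties at one time are processed together; censored observations shrink
    the risk set without dropping the curve.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty survival input")
    if (time <= 0).any():
        raise ValueError("times must be positive")
    table = survival_table_from_events(time, event)
    observed = table["observed"]
    rows = table[observed > 0]
    d = rows["observed"].to_numpy(dtype=float)
    n_risk = rows["at_risk"].to_numpy(dtype=float)
    surv = np.cumprod(1.0 - d / n_risk)
    # Greenwood: Var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(n_risk > d, d / (n_risk * (n_risk - d)), np.inf)
        var = surv**2 * np.cumsum(inc)
    se = np.sqrt(np.where(np.isfinite(var), var, 0.0))
    return KMCurve(
        event_times=rows.index.to_numpy(dtype=float),
        survival=surv,
        at_risk=n_risk.astype(int),
        n_events=d.astype(int),
        greenwood_se=se,
    )


def logrank_test(time, event, labels) -> tuple[float, int, float]:
    """K-sample log-rank test; returns (chi2, df, p)."""
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(
        np.asarray(time, dtype=float), labels, np.asarray(event, dtype=int)
    )
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# Cox partial likelihood machinery


def _sorted_views(time, event, X):
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order], order


def _tie_groups(time, event):
    """Yield (first_index, death_indices) per distinct event time (ascending)."""
    groups = []
    i = 0
    n = len(time)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        deaths = [k for k in range(i, j) if event[k] == 1]
        if deaths:
            groups.append((i, np.array(deaths)))
        i = j
    return groups


def _partial_likelihood(beta, time, event, X, ties):
    """Log partial likelihood, score vector and information matrix.

    Inputs must be sorted by ascending time.  ``ties`` is ``"efron"`` or
    ``"breslow"``.  The Breslow terms (exact for untied event times) are
    fully vectorized over events; Efron corrections are applied per tied
    group only.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    n, m = X.shape
    eta = np.clip(X @ beta, -500, 500)
    r = np.exp(eta)
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * X)[::-1], axis=0)[::-1]
    xxr = r[:, None, None] * X[:, :, None] * X[:, None, :]
    s2 = np.cumsum(xxr[::-1], axis=0)[::-1]
    first = np.searchsorted(time, time, side="left")  # tie-group start index
    ev = np.flatnonzero(event == 1)
    g0 = s0[first[ev]]
    m1 = s1[first[ev]] / g0[:, None]
    ll = float(eta[ev].sum() - np.log(g0).sum())
    score = X[ev].sum(axis=0) - m1.sum(axis=0)
    info = np.einsum("kij,k->ij", s2[first[ev]], 1.0 / g0) - np.einsum(
        "ki,kj->ij", m1, m1
    )
    if ties == "efron":
        for i0, deaths in _tie_groups(time, event):
            d = len(deaths)
            if d == 1:
                continue
            S0, S1, S2 = s0[i0], s1[i0], s2[i0]
            # replace the d Breslow terms of this group by Efron terms
            xbar = S1 / S0
            ll += d * np.log(S0)
            score += d * xbar
            info -= d * (S2 / S0 - np.outer(xbar, xbar))
            rD = float(r[deaths].sum())
            S1D = (r[deaths, None] * X[deaths]).sum(axis=0)
            S2D = xxr[deaths].sum(axis=0)
            for ell in range(d):
                f = ell / d
                den = S0 - f * rD
                mm = (S1 - f * S1D) / den
                ll -= np.log(den)
                score -= mm
                info += (S2 - f * S2D) / den - np.outer(mm, mm)
    return ll, score, info


def _newton_raphson(time, event, X, ties, tol=1e-9, max_iter=50):
    n, m = X.shape
    beta = np.zeros(m)
    ll, score, info = _partial_likelihood(beta, time, event, X, ties)
    capped = False
    for _ in range(max_iter):
        if np.linalg.norm(score) < tol:
            break
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.solve(info + 1e-8 * np.eye(m), score)
        step = 1.0
        for _half in range(30):
            cand = beta + step * delta
            ll_new, score_new, info_new = _partial_likelihood(
                cand, time, event, X, ties
            )
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if np.abs(beta).max() > _BETA_CAP:
            warnings.warn(
                "monotone partial likelihood detected: coefficient capped at "
                f"|beta| <= {_BETA_CAP}"
            )
            beta = np.clip(beta, -_BETA_CAP, _BETA_CAP)
            ll, score, info = _partial_likelihood(beta, time, event, X, ties)
            capped = True
            break
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return beta, cov, ll, info, capped


@dataclass
class CoxGroupFit:
    """Grouped Cox PH fit with subtype-separation statistics.

    ``beta`` holds per-group log-hazard coefficients centered so that
    ``sum(group_sizes * beta) = 0``.  ``hr_matrix[i, j] = exp(beta_i -
    beta_j)``.  ``sep_printed`` uses the in-(0,1] convention, and
    ``sep_reciprocal`` its inverse (>= 1).
    """

    group_labels: list
    group_sizes: np.ndarray
    beta: np.ndarray
    cov_beta: np.ndarray  # covariance of the C-1 reference-coded coefficients
    loglik: float
    hr_matrix: np.ndarray
    hr_min: float
    sep_printed: float
    sep_reciprocal: float
    logrank_stat: float
    logrank_p: float
    gst_stat: float
    gst_p: float
    ties: str = "efron"
    capped: bool = False
    # internals used by the Schoenfeld machinery
    beta_ref_: np.ndarray = field(default=None, repr=False)
    info_: np.ndarray = field(default=None, repr=False)

    def summary(self, sep_convention: str = "reciprocal") -> dict:
        return {
            "n_groups": len(self.group_labels),
            "group_sizes": [int(s) for s in self.group_sizes],
            "logrank_p": self.logrank_p,
            "hr_min": self.hr_min,
            "sep": sep_statistic(self, sep_convention),
            "sep_convention": sep_convention,
            "gst_p": self.gst_p,
        }


def _group_design(labels):
    labels = np.asarray(labels)
    cats = list(pd.unique(pd.Series(labels).sort_values()))
    m = len(cats) - 1
    X = np.zeros((len(labels), m))
    for j, c in enumerate(cats[1:]):
        X[:, j] = labels == c
    return cats, X


def cox_fit_subtypes(time, event, labels, ties: str = "efron") -> CoxGroupFit:
    """Fit Cox PH on subtype indicators and derive all separation statistics.

    Reference-coded indicator covariates are fitted by Newton-Raphson
    (Efron ties by default), converted to per-group coefficients, and
    centered by the size-weighted mean.  The log-rank test and the global
    Schoenfeld test are computed alongside.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    if event.sum() < 1:
        raise ValueError("no events observed")
    cats, X = _group_design(labels)
    if len(cats) < 2:
        raise ValueError("need at least 2 groups")
    if min((labels == c).sum() for c in cats) == 0:  # pragma: no cover
        raise ValueError("empty group")
    t_s, e_s, X_s, _ = _sorted_views(time, event, X)
    beta_ref, cov, ll, info, capped = _newton_raphson(t_s, e_s, X_s, ties)
    sizes = np.array([(labels == c).sum() for c in cats], dtype=float)
    n = sizes.sum()
    beta_full = np.concatenate([[0.0], beta_ref])
    beta_centered = beta_full - float(sizes @ beta_full) / n
    hr = np.exp(beta_centered[:, None] - beta_centered[None, :])
    lr_stat, _df, lr_p = logrank_test(time, event, labels)
    fit = CoxGroupFit(
        group_labels=cats,
        group_sizes=sizes.astype(int),
        beta=beta_centered,
        cov_beta=cov,
        loglik=ll,
        hr_matrix=hr,
        hr_min=np.nan,
        sep_printed=np.nan,
        sep_reciprocal=np.nan,
        logrank_stat=lr_stat,
        logrank_p=lr_p,
        gst_stat=np.nan,
        gst_p=np.nan,
        ties=ties,
        capped=capped,
        beta_ref_=beta_ref,
        info_=info,
    )
    fit.hr_min = hr_min(fit)
    fit.sep_printed = sep_statistic(fit, "printed")
    fit.sep_reciprocal = sep_statistic(fit, "reciprocal")
    try:
        gst_stat, _gdf, gst_p = schoenfeld_gst(fit, time, event, labels)
        fit.gst_stat, fit.gst_p = gst_stat, gst_p
    except ValueError as exc:
        warnings.warn(f"global Schoenfeld test unavailable: {exc}")
    return fit


def hr_min(fit: CoxGroupFit) -> float:
    """Minimum over subtype pairs of the max-oriented hazard ratio (>= 1)."""
    beta = fit.beta
    C = len(beta)
    diffs = [abs(beta[i] - beta[j]) for i in range(C) for j in range(i + 1, C)]
    return float(np.exp(min(diffs)))


def sep_statistic(fit: CoxGroupFit, convention: str = "reciprocal") -> float:
    """Size-weighted hazard-separation statistic.

    ``printed`` returns ``exp(-sum (n_i/n) |beta_i|)`` in (0, 1];
    ``reciprocal`` (default) its inverse, >= 1.
    """
    w = fit.group_sizes / fit.group_sizes.sum()
    s = float(w @ np.abs(fit.beta))
    if convention == "printed":
        return float(np.exp(-s))
    if convention == "reciprocal":
        return float(np.exp(s))
    raise ValueError(f"unknown SEP convention {convention!r}")


def schoenfeld_gst(
    fit: CoxGroupFit, time, event, labels, time_transform: str = "rank"
) -> tuple[float, int, float]:
    """Global Schoenfeld test of proportional hazards (Grambsch-Therneau).

    Schoenfeld residuals at each event are correlated with the transformed
    event times (default: ranks); the global chi-square has df = C - 1.  A
    small statistic (p above the significance level) supports the
    proportional-hazards assumption.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    cats, X = _group_design(labels)
    m = X.shape[1]
    d_total = int(event.sum())
    if d_total <= m:
        raise ValueError(f"need more events ({d_total}) than df ({m})")
    t_s, e_s, X_s, _ = _sorted_views(time, event, X)
    beta = fit.beta_ref_
    eta = np.clip(X_s @ beta, -500, 500)
    r = np.exp(eta)
    s0 = np.cumsum(r[::-1])[::-1]
    s1 = np.cumsum((r[:, None] * X_s)[::-1], axis=0)[::-1]
    first = np.searchsorted(t_s, t_s, side="left")
    ev = np.flatnonzero(e_s == 1)
    resid = X_s[ev] - s1[first[ev]] / s0[first[ev], None]
    etimes = t_s[ev]
    if time_transform == "rank":
        g = stats.rankdata(etimes)
    elif time_transform == "identity":
        g = etimes.copy()
    else:
        raise ValueError(f"unknown time transform {time_transform!r}")
    g = g - g.mean()
    u = g @ resid  # (m,)
    denom = float(g @ g)
    try:
        inv_info_u = np.linalg.solve(fit.info_, u)
    except np.linalg.LinAlgError:
        inv_info_u = np.linalg.pinv(fit.info_) @ u
    stat = float(d_total * (u @ inv_info_u) / denom)
    p = float(stats.chi2.sf(stat, m))
    return stat, m, p


def plot_km(time, event, labels, path=None, ax=None):
    """Kaplan-Meier step curves per subtype with Greenwood confidence bands
    and the log-rank p-value annotated."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    labels = np.asarray(labels)
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    for lab in np.unique(labels):
        mask = labels == lab
        curve = km_curve(time[mask], event[mask])
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        se = np.concatenate([[0.0], curve.greenwood_se])
        ax.step(t, s, where="post", label=f"subtype {lab}")
        lo = np.clip(s - 1.96 * se, 0, 1)
        hi = np.clip(s + 1.96 * se, 0, 1)
        ax.fill_between(t, lo, hi, step="post", alpha=0.2)
    _stat, _df, p = logrank_test(time, event, labels)
    ax.text(0.62, 0.92, f"log-rank p = {p:.2e}", transform=ax.transAxes)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower left", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
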