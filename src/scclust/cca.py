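"""Sparse canonical correlation analysis by alternating elastic-net regression.

Two data views X (n x p) and Y (n x q), both column-standardized, are
reduced to pairs of canonical weight vectors (w1, w2) maximizing the
correlation of the scores u = X w1 and v = Y w2 under the constraints
Var(u) = Var(v) = 1, with an l1 + l2 (elastic-net) penalty on each weight
vector.  Each view carries its own l1 penalty (tau1, tau2), so the two
views may be sparsified at different levels.  The solver alternates two
penalized regressions:

    w1 <- argmin ||v - X w||^2 / (2 (n-1)) + ridge1 ||w||^2 + tau1 ||w||_1
    w2 <- argmin ||u - Y w||^2 / (2 (n-1)) + ridge2 ||w||^2 + tau2 ||w||_1

rescaling after each step so the score variance is one.  With both
penalties at zero the procedure reduces to classical CCA.  Additional
components are extracted by deflating both views on their own score
vectors and refitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import ElasticNet

__all__ = [
    "SCCAConfig",
    "CanonicalComponent",
    "SCCAResult",
    "SparseCCA",
    "SCCAError",
    "penalized_regression_step",
    "elastic_net_objective",
    "classical_cca",
    "deflate",
    "fit_scca",
    "aggregate_scores",
]


class SCCAError(RuntimeError):
    """Raised when a penalty zeroes an entire view or inputs are degenerate."""


@dataclass
class SCCAConfig:
    """Hyper-parameters of the sparse CCA fit.

    tau1/tau2 are the l1 penalties for the X/Y views (on the covariance
    scale: a feature survives soft-thresholding iff its covariance with the
    partner score exceeds tau); ridge1/ridge2 the corresponding l2 terms.
    """

    tau1: float = 0.0
    tau2: float = 0.0
    ridge1: float = 0.0
    ridge2: float = 0.0
    n_components: int = 1
    max_iter: int = 200
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "ridge1", "ridge2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_components < 1:
            raise ValueError("n_components must be positive")


@dataclass
class CanonicalComponent:
    """One canonical pair: weights, unit-variance scores and their correlation."""

    w1: np.ndarray
    w2: np.ndarray
    u: np.ndarray
    v: np.ndarray
    correlation: float
    n_iter: int
    converged: bool


@dataclass
class SCCAResult:
    components: list[CanonicalComponent]
    feature_ids_x: list[str]
    feature_ids_y: list[str]
    config: SCCAConfig

    @property
    def correlations(self) -> np.ndarray:
        return np.array([c.correlation for c in self.components])

    def weight_frame(self, view: str) -> pd.DataFrame:
        """Weights as a features x components DataFrame for one view."""
        if view == "x":
            w = np.column_stack([c.w1 for c in self.components])
            ids = self.feature_ids_x
        elif view == "y":
            w = np.column_stack([c.w2 for c in self.components])
            ids = self.feature_ids_y
        else:
            raise ValueError("view must be 'x' or 'y'")
        cols = [f"comp{k + 1}" for k in range(len(self.components))]
        return pd.DataFrame(w, index=ids, columns=cols)


def elastic_net_objective(
    design: np.ndarray, target: np.ndarray, w: np.ndarray, tau: float, ridge: float
) -> float:
    """Penalized least-squares objective on the covariance scale (nu = n-1)."""
    nu = design.shape[0] - 1
    resid = target - design @ w
    return (
        float(resid @ resid) / (2 * nu)
        + ridge * float(w @ w)
        + tau * float(np.abs(w).sum())
    )


def penalized_regression_step(
    design: np.ndarray, target: np.ndarray, tau: float, ridge: float = 0.0
) -> np.ndarray:
    """Solve one elastic-net regression of a score vector on a view.

    Minimizes ``||target - design w||^2 / (2 (n-1)) + ridge ||w||^2
    + tau ||w||_1`` by cyclical coordinate descent with soft-thresholding
    (tau > 0) or an exact linear solve (tau = 0).  With standardized
    columns the single-feature solution is
    ``sign(c) max(|c| - tau, 0) / (1 + 2 ridge)`` where c is the sample
    covariance of the feature with the target.  May return an all-zero
    vector when tau dominates every covariance; callers must detect this.
    """
    design = np.asarray(design, dtype=float)
    target = np.asarray(target, dtype=float)
    if not (np.isfinite(design).all() and np.isfinite(target).all()):
        raise ValueError("non-finite values in design or target")
    n, p = design.shape
    nu = n - 1
    if tau == 0.0:
        if ridge == 0.0:
            # min-norm OLS; robust to the rank deficiency deflation introduces
            return np.linalg.lstsq(design, target, rcond=None)[0]
        gram = design.T @ design / nu + 2.0 * ridge * np.eye(p)
        rhs = design.T @ target / nu
        return sla.solve(gram, rhs, assume_a="pos")
    # map (tau, ridge) on the 1/(2 nu) scale onto sklearn's 1/(2 n) objective
    alpha = (tau + 2.0 * ridge) * nu / n
    l1_ratio = tau / (tau + 2.0 * ridge)
    model = ElasticNet(
        alpha=alpha,
        l1_ratio=l1_ratio,
        fit_intercept=False,
        precompute=True,
        max_iter=100_000,
        tol=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter at tiny tol
        model.fit(design, target)
    return np.asarray(model.coef_, dtype=float)


def classical_cca(
    x, y, k: int
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Classical CCA via the whitened cross-covariance SVD (zero-penalty oracle).

    Requires p, q < n and non-singular within-view covariances.  Returns the
    top-k canonical correlations and the corresponding weight pairs.
    """
    X = np.asarray(x, dtype=float)
    Y = np.asarray(y, dtype=float)
    X = X - X.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    n, p = X.shape
    q = Y.shape[1]
    if p >= n or q >= n:
        raise ValueError("classical CCA requires p < n and q < n")
    nu = n - 1
    sxx = X.T @ X / nu
    syy = Y.T @ Y / nu
    sxy = X.T @ Y / nu
    for s, name in ((sxx, "X"), (syy, "Y")):
        if np.linalg.cond(s) > 1e12:
            raise np.linalg.LinAlgError(
                f"singular covariance in view {name}; use ridge > 0"
            )
    isqx = sla.fractional_matrix_power(sxx, -0.5).real
    isqy = sla.fractional_matrix_power(syy, -0.5).real
    u_mat, s, vt = np.linalg.svd(isqx @ sxy @ isqy)
    k = min(k, len(s))
    corrs = np.clip(s[:k], 0.0, 1.0)
    pairs = []
    for i in range(k):
        a = isqx @ u_mat[:, i]
        b = isqy @ vt[i]
        a = a / np.sqrt(a @ sxx @ a)
        b = b / np.sqrt(b @ syy @ b)
        pairs.append((a, b))
    return corrs, pairs


def deflate(view: pd.DataFrame, score: np.ndarray, drop_constant: bool = True):
    """Residualize every column on a score vector and re-standardize.

    Each column is replaced by its residual after least-squares projection
    onto the (centered) score, making the result orthogonal to the score.
    Columns that become constant (they were proportional to the score) are
    dropped when ``drop_constant`` else left as all-zero columns.
    """
    values = np.asarray(view, dtype=float)
    s = np.asarray(score, dtype=float)
    s = s - s.mean()
    ss = float(s @ s)
    if ss <= 0:
        raise ValueError("score has zero variance")
    resid = values - np.outer(s, s @ values / ss)
    resid -= resid.mean(axis=0)
    sd = resid.std(axis=0, ddof=1)
    tolerance = 1e-10 * max(1.0, float(np.abs(values).max()))
    keep = sd > tolerance
    out = np.zeros_like(resid)
    out[:, keep] = resid[:, keep] / sd[keep]
    df = pd.DataFrame(out, index=view.index, columns=view.columns)
    if drop_constant and not keep.all():
        df = df.loc[:, keep]
    return df


class SparseCCA(BaseEstimator, TransformerMixin):
    """Sparse CCA estimator: alternating elastic-net with per-view penalties.

    Parameters
    ----------
    n_components : int
        Number of canonical pairs to extract (by deflation).
    tau1, tau2 : float
        l1 penalties for the X and Y views, on the covariance scale.
    ridge1, ridge2 : float
        l2 penalties per view.
    scale : bool
        Standardize the inputs internally (set False if pre-standardized).
    max_iter, tol : convergence control on the change in canonical
        correlation between alternating sweeps.
    random_state : int
        Seed for the random fallback initialization.

    Attributes
    ----------
    x_weights_, y_weights_ : (p, K) and (q, K) weight matrices.
    x_scores_, y_scores_ : (n, K) unit-variance score matrices.
    correlations_ : (K,) canonical correlations.
    n_iter_, converged_ : per-component diagnostics.
    result_ : :class:`SCCAResult` bundling the above with feature IDs.
    """

    def __init__(
        self,
        n_components: int = 1,
        tau1: float = 0.0,
        tau2: float = 0.0,
        ridge1: float = 0.0,
        ridge2: float = 0.0,
        scale: bool = True,
        max_iter: int = 200,
        tol: float = 1e-6,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.tau1 = tau1
        self.tau2 = tau2
        self.ridge1 = ridge1
        self.ridge2 = ridge2
        self.scale = scale
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_frame(m, prefix: str) -> pd.DataFrame:
        if isinstance(m, pd.DataFrame):
            return m
        m = np.asarray(m, dtype=float)
        return pd.DataFrame(
            m, columns=[f"{prefix}{j}" for j in range(m.shape[1])]
        )

    @staticmethod
    def _standardize(a: np.ndarray) -> np.ndarray:
        a = a - a.mean(axis=0)
        sd = a.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return a / sd

    def _init_w2(self, X: np.ndarray, Y: np.ndarray, rng) -> np.ndarray:
        nu = X.shape[0] - 1
        cross = X.T @ Y / nu
        if np.abs(cross).max() > 0:
            # leading right singular vector of the cross-covariance
            _, _, vt = np.linalg.svd(cross, full_matrices=False)
            w2 = vt[0]
        else:
            w2 = rng.standard_normal(Y.shape[1])
        return w2

    def _fit_component(self, X, Y, rng) -> CanonicalComponent:
        w2 = self._init_w2(X, Y, rng)
        v = Y @ w2
        sd = v.std(ddof=1)
        if sd <= 0:
            w2 = rng.standard_normal(Y.shape[1])
            v = Y @ w2
            sd = v.std(ddof=1)
        w2 = w2 / sd
        v = v / sd
        corr = 0.0
        converged = False
        n_iter = 0
        w1 = np.zeros(X.shape[1])
        u = np.zeros_like(v)
        for n_iter in range(1, self.max_iter + 1):
            w1 = penalized_regression_step(X, v, self.tau1, self.ridge1)
            u = X @ w1
            sd = u.std(ddof=1)
            if sd <= 0:
                raise SCCAError("penalty too large for view 1 (all weights zero)")
            w1 = w1 / sd
            u = u / sd
            w2 = penalized_regression_step(Y, u, self.tau2, self.ridge2)
            v = Y @ w2
            sd = v.std(ddof=1)
            if sd <= 0:
                raise SCCAError("penalty too large for view 2 (all weights zero)")
            w2 = w2 / sd
            v = v / sd
            new_corr = float(np.corrcoef(u, v)[0, 1])
            if abs(new_corr - corr) < self.tol:
                corr = new_corr
                converged = True
                break
            corr = new_corr
        if not converged:
            warnings.warn(
                f"sparse CCA component did not converge in {self.max_iter} iterations"
            )
        # sign convention: largest-|w1| entry positive
        if w1[int(np.argmax(np.abs(w1)))] < 0:
            w1, w2, u, v = -w1, -w2, -u, -v
        return CanonicalComponent(
            w1=w1, w2=w2, u=u, v=v, correlation=corr, n_iter=n_iter, converged=converged
        )

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, Y=None, y=None):
        if Y is None:
            Y = y
        if Y is None:
            raise ValueError("SparseCCA.fit requires two views: fit(X, Y)")
        xf = self._as_frame(X, "x")
        yf = self._as_frame(Y, "y")
        if len(xf) != len(yf):
            raise ValueError("views must share the sample dimension")
        if len(xf) < 4:
            raise ValueError("need at least 4 samples")
        Xd = np.asarray(xf, dtype=float)
        Yd = np.asarray(yf, dtype=float)
        if not (np.isfinite(Xd).all() and np.isfinite(Yd).all()):
            raise ValueError("non-finite values in input views")
        if self.scale:
            Xd = self._standardize(Xd)
            Yd = self._standardize(Yd)
        rng = np.random.default_rng(self.random_state)
        components: list[CanonicalComponent] = []
        for _ in range(self.n_components):
            comp = self._fit_component(Xd, Yd, rng)
            components.append(comp)
            if len(components) < self.n_components:
                # internal deflation keeps full width: exhausted columns are zeroed
                Xd = np.asarray(
                    deflate(pd.DataFrame(Xd), comp.u, drop_constant=False), dtype=float
                )
                Yd = np.asarray(
                    deflate(pd.DataFrame(Yd), comp.v, drop_constant=False), dtype=float
                )
        config = SCCAConfig(
            tau1=self.tau1,
            tau2=self.tau2,
            ridge1=self.ridge1,
            ridge2=self.ridge2,
            n_components=self.n_components,
            max_iter=self.max_iter,
            tol=self.tol,
            seed=self.random_state,
        )
        self.result_ = SCCAResult(
            components=components,
            feature_ids_x=[str(c) for c in xf.columns],
            feature_ids_y=[str(c) for c in yf.columns],
            config=config,
        )
        self.x_weights_ = np.column_stack([c.w1 for c in components])
        self.y_weights_ = np.column_stack([c.w2 for c in components])
        self.x_scores_ = np.column_stack([c.u for c in components])
        self.y_scores_ = np.column_stack([c.v for c in components])
        self.correlations_ = np.array([c.correlation for c in components])
        self.n_iter_ = [c.n_iter for c in components]
        self.converged_ = [c.converged for c in components]
        self._x_mean = np.asarray(xf, dtype=float).mean(axis=0)
        self._x_sd = np.asarray(xf, dtype=float).std(axis=0, ddof=1)
        return self

    def transform(self, X):
        """Project new X-view samples onto the canonical weights.

        Note: multi-component weights live in deflated coordinate systems;
        for the training data prefer the fitted ``x_scores_``.
        """
        Xd = np.asarray(self._as_frame(X, "x"), dtype=float)
        if self.scale:
            sd = np.where(self._x_sd == 0, 1.0, self._x_sd)
            Xd = (Xd - self._x_mean) / sd
        return Xd @ self.x_weights_

    def fit_transform(self, X, Y=None, y=None):
        return self.fit(X, Y=Y, y=y).x_scores_


def fit_scca(x: pd.DataFrame, y: pd.DataFrame, config: SCCAConfig) -> SCCAResult:
    """Fit sparse CCA on sample-aligned, standardized views (thin wrapper)."""
    if list(x.index) != list(y.index):
        raise ValueError("views are not sample-aligned")
    est = SparseCCA(
        n_components=config.n_components,
        tau1=config.tau1,
        tau2=config.tau2,
        ridge1=config.ridge1,
        ridge2=config.ridge2,
        scale=False,
        max_iter=config.max_iter,
        tol=config.tol,
        random_state=config.seed,
    )
    est.fit(x, y)
    return est.result_


def aggregate_scores(
    result: SCCAResult, mode: str = "both_views", sample_ids=None
) -> pd.DataFrame:
    """Combine per-component canonical scores into one clustering input.

    ``both_views`` concatenates (u_k, v_k) for every component (m = 2K);
    ``x_only`` keeps the u_k (m = K); ``mean_of_views`` averages the two
    views per component (m = K).  Every output column is z-scored.
    """
    cols: dict[str, np.ndarray] = {}
    for k, comp in enumerate(result.components, start=1):
        if mode == "both_views":
            cols[f"u{k}"] = comp.u
            cols[f"v{k}"] = comp.v
        elif mode == "x_only":
            cols[f"u{k}"] = comp.u
        elif mode == "mean_of_views":
            cols[f"uv{k}"] = (comp.u + comp.v) / 2.0
        else:
            raise ValueError(f"unknown aggregation mode {mode!r}")
    df = pd.DataFrame(cols)
    sd = df.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(df.columns[sd == 0])
        raise ValueError(f"zero-variance score column(s): {bad}")
    df = (df - df.mean(axis=0)) / sd
    if sample_ids is not None:
        df.index = list(sample_ids)
    return df
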