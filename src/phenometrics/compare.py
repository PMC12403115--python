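"""Cross-metric and cross-trophic comparison layer.

Given a per-tree metrics table (the nine phenological metrics plus herbivory
and coordinates), this module provides:

* Spearman correlation matrices on pairwise-complete observations, with exact
  permutation p-values at very small n;
* Gaussian linear models of caterpillar metrics on tree metrics with a
  sampling-area fixed effect ("cross-trophic" models);
* Beta-likelihood (logit link) regressions of the herbivory fraction on a
  phenology metric, controlling for area and canopy level;
* variance-explained (R^2) deltas for added factors;
* model comparison by expected log pointwise predictive density (ELPD) under
  cross-validation — exhaustive leave-one-out at small n, K-fold otherwise;
* Moran's I residual diagnostics with row-standardized k-nearest-neighbour
  weights and a permutation p-value.

Intervals are percentile bootstrap at the 95% level; "significant" means the
interval excludes zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.spatial import cKDTree
from scipy.special import expit

from .trajfit import _beta_nll_grad

__all__ = [
    "CorrelationEntry",
    "ModelResult",
    "spearman_matrix",
    "variance_explained_delta",
    "fit_cross_trophic_model",
    "fit_herbivory_model",
    "compare_models_elpd",
    "morans_i",
    "LinearComparisonModel",
    "BetaComparisonModel",
]


# ---------------------------------------------------------------------------
# Spearman correlation matrix
# ---------------------------------------------------------------------------

@dataclass
class CorrelationEntry:
    metric_a: str
    metric_b: str
    rho: float
    p: float
    n: int


def _spearman_exact_p(x, y):
    """Two-sided exact permutation p for Spearman's rho at small n."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = np.corrcoef(rx, ry)[0, 1]
    n = len(rx)
    perms = np.array(list(itertools.permutations(range(n))))
    rperm = ry[perms]  # all orderings of one rank vector
    rx_c = rx - rx.mean()
    rp_c = rperm - rperm.mean(axis=1, keepdims=True)
    num = rp_c @ rx_c
    den = np.sqrt((rx_c @ rx_c) * np.sum(rp_c**2, axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(obs) - 1e-12))


def spearman_matrix(metrics: pd.DataFrame, columns: list[str],
                    min_n: int = 4, exact_max_n: int = 9,
                    bh_correct: bool = True) -> pd.DataFrame:
    """Pairwise Spearman correlations over pairwise-complete rows.

    Ties get average ranks.  For n <= ``exact_max_n`` the two-sided p-value
    is by exhaustive permutation; otherwise the t-approximation.  A
    Benjamini-Hochberg column is appended for reference but raw p-values
    drive the default significance stars.
    """
    entries = []
    for a, b in itertools.combinations(columns, 2):
        sub = metrics[[a, b]].dropna()
        n = len(sub)
        if n < min_n:
            entries.append({"metric_a": a, "metric_b": b, "rho": np.nan,
                            "p": np.nan, "n": n})
            continue
        x, y = sub[a].to_numpy(float), sub[b].to_numpy(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            entries.append({"metric_a": a, "metric_b": b, "rho": np.nan,
                            "p": np.nan, "n": n})
            continue
        rho, p_t = stats.spearmanr(x, y)
        p = _spearman_exact_p(x, y) if n <= exact_max_n else float(p_t)
        entries.append({"metric_a": a, "metric_b": b, "rho": float(rho),
                        "p": p, "n": n})
    out = pd.DataFrame(entries)
    if bh_correct and len(out):
        mask = np.isfinite(out["p"].to_numpy(float))
        q = np.full(len(out), np.nan)
        if mask.sum():
            from statsmodels.stats.multitest import multipletests
            q[mask] = multipletests(out.loc[mask, "p"], method="fdr_bh")[1]
        out["p_bh"] = q
    return out


# ---------------------------------------------------------------------------
# Design-matrix building
# ---------------------------------------------------------------------------

def _build_design(df: pd.DataFrame, terms: list[str],
                  references: dict | None = None):
    """Intercept + numeric columns + treatment-coded categoricals."""
    references = references or {}
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    for t in terms:
        s = df[t]
        if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
            levels = sorted(map(str, s.dropna().unique()))
            ref = references.get(t)
            if ref is not None and str(ref) in levels:
                levels.remove(str(ref))
                levels.insert(0, str(ref))
            for lev in levels[1:]:
                cols.append((s.astype(str) == lev).to_numpy(float))
                names.append(f"{t}[{lev}]")
        else:
            cols.append(s.to_numpy(float))
            names.append(t)
    X = np.column_stack(cols)
    return X, names


# ---------------------------------------------------------------------------
# Model results
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    response: str
    predictors: list
    coef: pd.DataFrame  # term, estimate, ci_low, ci_high, significant
    variance_explained: float
    elpd: float
    elpd_pointwise: np.ndarray
    n: int
    row_index: np.ndarray
    moran_i: dict | None = None
    delta_elpd: float | None = None
    family: str = "gaussian"
    notes: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"{self.family.capitalize()} model: {self.response} ~ "
            + " + ".join(map(str, self.predictors)),
            f"n = {self.n}; R2 (conditional) = {self.variance_explained:.3f}; "
            f"elpd = {self.elpd:.2f}"
            + ("" if self.delta_elpd is None else f"; delta_elpd = {self.delta_elpd:.2f}"),
        ]
        for _, r in self.coef.iterrows():
            star = "*" if r["significant"] else " "
            lines.append(
                f"  {r['term']:<22s} {r['estimate']:8.3f} "
                f"({r['ci_low']:.3f}, {r['ci_high']:.3f}){star}"
            )
        if self.moran_i is not None:
            m = self.moran_i
            lines.append(
                f"  Moran's I on residuals: {m['I']:.4f} "
                f"(expected {m['expected']:.4f}, p = {m['p']:.3f})"
            )
        return "\n".join(lines)


def _ols_fit(X, y):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return beta, fitted, y - fitted


def _gaussian_lpd(X_tr, y_tr, X_te, y_te):
    beta, fitted, resid = _ols_fit(X_tr, y_tr)
    sigma2 = max(float(resid @ resid) / len(y_tr), 1e-12)
    mu = X_te @ beta
    return stats.norm.logpdf(y_te, mu, math.sqrt(sigma2))


def _beta_reg_fit(X, y, ridge=1e-8):
    """ML Beta regression (logit link); returns (coefs, logphi)."""
    z = np.log(y / (1.0 - y))
    b0, *_ = np.linalg.lstsq(X, z, rcond=None)
    x0 = np.concatenate([b0, [np.log(10.0)]])
    pen = ridge * np.eye(X.shape[1])
    res = minimize(_beta_nll_grad, x0, args=(X, y, pen), jac=True,
                   method="L-BFGS-B", options={"maxiter": 300, "ftol": 1e-12})
    return res.x[:-1], float(res.x[-1])


def _beta_lpd(X_tr, y_tr, X_te, y_te):
    coef, logphi = _beta_reg_fit(X_tr, y_tr)
    phi = math.exp(min(max(logphi, -6.0), 16.0))
    mu = np.clip(expit(X_te @ coef), 1e-9, 1 - 1e-9)
    return stats.beta.logpdf(y_te, mu * phi, (1 - mu) * phi)


def _cv_pointwise_lpd(X, y, lpd_fn, k_folds=10, loo_max_n=30, random_state=0):
    """Pointwise log predictive density by exhaustive LOO (n <= loo_max_n)
    or shuffled K-fold cross-validation."""
    n = len(y)
    out = np.empty(n)
    if n <= loo_max_n:
        folds = [[i] for i in range(n)]
    else:
        rng = np.random.default_rng(random_state)
        order = rng.permutation(n)
        folds = [order[i::k_folds].tolist() for i in range(k_folds)]
    for te in folds:
        tr = np.setdiff1d(np.arange(n), te)
        out[np.asarray(te)] = lpd_fn(X[tr], y[tr], X[np.asarray(te)], y[np.asarray(te)])
    return out


def _bootstrap_ci(X, y, fit_coefs, n_boot, random_state, level=0.95):
    rng = np.random.default_rng(random_state)
    n, p = X.shape
    draws = np.empty((n_boot, p))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        # guard against resamples that drop a dummy column entirely
        for _ in range(10):
            if np.linalg.matrix_rank(X[idx]) == p:
                break
            idx = rng.integers(0, n, n)
        draws[b] = fit_coefs(X[idx], y[idx])
    alpha = 100 * (1 - level) / 2
    lo = np.percentile(draws, alpha, axis=0)
    hi = np.percentile(draws, 100 - alpha, axis=0)
    return lo, hi


def _conditional_r2(fitted, resid):
    vf, vr = float(np.var(fitted)), float(np.var(resid))
    if vf + vr <= 0:
        return 0.0
    return vf / (vf + vr)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class LinearComparisonModel:
    """Gaussian linear model of one metric on another plus area fixed effects.

    The default cross-trophic specification: caterpillar metric ~ tree metric
    + sampling area, percentile-bootstrap intervals, conditional R^2, ELPD by
    cross-validation, and Moran's I on the residuals when coordinates are
    available.
    """

    def __init__(self, response, predictor, area_col="area",
                 area_reference=None, n_boot=1000, k_folds=10,
                 knn=8, random_state=None):
        self.response = response
        self.predictor = predictor
        self.area_col = area_col
        self.area_reference = area_reference
        self.n_boot = n_boot
        self.k_folds = k_folds
        self.knn = knn
        self.random_state = random_state

    def fit(self, metrics: pd.DataFrame):
        terms = [self.predictor] if self.predictor else []
        need = [self.response] + terms
        df = metrics.copy()
        notes = []
        use_area = False
        if self.area_col and self.area_col in df.columns:
            n_levels = df[self.area_col].dropna().nunique()
            if n_levels >= 2:
                use_area = True
                need.append(self.area_col)
            else:
                warnings.warn("single sampling area: area term dropped")
                notes.append("area term dropped (single level)")
        df = df.dropna(subset=need)
        if len(df) < 10:
            raise ValueError(f"need at least 10 complete rows, got {len(df)}")
        design_terms = terms + ([self.area_col] if use_area else [])
        refs = {self.area_col: self.area_reference} if use_area else {}
        X, names = _build_design(df, design_terms, refs)
        y = df[self.response].to_numpy(float)

        beta, fitted, resid = _ols_fit(X, y)
        seed = np.random.default_rng(self.random_state).integers(2**31 - 1)
        lo, hi = _bootstrap_ci(X, y, lambda Xb, yb: _ols_fit(Xb, yb)[0],
                               self.n_boot, seed)
        lpd = _cv_pointwise_lpd(X, y, _gaussian_lpd, self.k_folds,
                                random_state=seed)
        coef = pd.DataFrame({
            "term": names, "estimate": beta, "ci_low": lo, "ci_high": hi,
        })
        coef["significant"] = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)

        moran = None
        if {"x", "y"}.issubset(df.columns):
            try:
                I, expected, p = morans_i(resid, df[["x", "y"]].to_numpy(float),
                                          k=self.knn, random_state=seed)
                moran = {"I": I, "expected": expected, "p": p}
            except ValueError as exc:
                notes.append(f"Moran's I skipped: {exc}")

        self.coef_ = coef
        self.result_ = ModelResult(
            response=self.response,
            predictors=design_terms or ["1"],
            coef=coef,
            variance_explained=_conditional_r2(fitted, resid),
            elpd=float(lpd.sum()),
            elpd_pointwise=lpd,
            n=len(df),
            row_index=df.index.to_numpy(),
            moran_i=moran,
            family="gaussian",
            notes=notes,
        )
        return self


class BetaComparisonModel:
    """Beta-likelihood (logit link) regression of a bounded fraction.

    Used for herbivory (~ phenology metric + area + canopy level).  The
    canopy term is a shrunken grouping effect in spirit; it enters the design
    as treatment-coded levels and its contribution is included in the
    conditional R^2.
    """

    def __init__(self, response, predictor, area_col="area",
                 canopy_col="canopy_level", area_reference=None,
                 n_boot=400, k_folds=10, knn=8, random_state=None):
        self.response = response
        self.predictor = predictor
        self.area_col = area_col
        self.canopy_col = canopy_col
        self.area_reference = area_reference
        self.n_boot = n_boot
        self.k_folds = k_folds
        self.knn = knn
        self.random_state = random_state

    def fit(self, metrics: pd.DataFrame):
        terms = [self.predictor] if self.predictor else []
        extra = []
        notes = []
        for col in (self.area_col, self.canopy_col):
            if col and col in metrics.columns and metrics[col].dropna().nunique() >= 2:
                extra.append(col)
            elif col:
                notes.append(f"{col} dropped (absent or single level)")
        need = [self.response] + terms + extra
        df = metrics.dropna(subset=need).copy()
        if len(df) < 10:
            raise ValueError(f"need at least 10 complete rows, got {len(df)}")
        y = df[self.response].to_numpy(float)
        if np.any((y < 0) | (y > 1)):
            raise ValueError("herbivory fractions must lie in [0, 1]")
        if np.allclose(y, y[0]):
            raise ValueError("herbivory values all equal: Beta precision undefined")
        if np.any((y <= 0) | (y >= 1)):
            n = len(y)
            y = (y * (n - 1) + 0.5) / n  # open-interval squeeze
            notes.append("boundary squeeze applied to herbivory fractions")

        refs = {self.area_col: self.area_reference}
        X, names = _build_design(df, terms + extra, refs)

        coefs, logphi = _beta_reg_fit(X, y)
        mu = np.clip(expit(X @ coefs), 1e-9, 1 - 1e-9)
        resid = y - mu
        seed = np.random.default_rng(self.random_state).integers(2**31 - 1)
        lo, hi = _bootstrap_ci(X, y, lambda Xb, yb: _beta_reg_fit(Xb, yb)[0],
                               self.n_boot, seed)
        lpd = _cv_pointwise_lpd(X, y, _beta_lpd, self.k_folds, random_state=seed)
        coef = pd.DataFrame({
            "term": names, "estimate": coefs, "ci_low": lo, "ci_high": hi,
        })
        coef["significant"] = (coef["ci_low"] > 0) | (coef["ci_high"] < 0)

        moran = None
        if {"x", "y"}.issubset(df.columns):
            try:
                I, expected, p = morans_i(resid, df[["x", "y"]].to_numpy(float),
                                          k=self.knn, random_state=seed)
                moran = {"I": I, "expected": expected, "p": p}
            except ValueError as exc:
                notes.append(f"Moran's I skipped: {exc}")

        self.coef_ = coef
        self.phi_ = math.exp(min(max(logphi, -6.0), 16.0))
        self.result_ = ModelResult(
            response=self.response,
            predictors=terms + extra or ["1"],
            coef=coef,
            variance_explained=_conditional_r2(mu, resid),
            elpd=float(lpd.sum()),
            elpd_pointwise=lpd,
            n=len(df),
            row_index=df.index.to_numpy(),
            moran_i=moran,
            family="beta",
            notes=notes,
        )
        return self


def fit_cross_trophic_model(metrics: pd.DataFrame, caterpillar_metric: str,
                            tree_metric: str | None, **kwargs) -> ModelResult:
    """Gaussian model of a caterpillar metric on a tree metric + area.

    ``tree_metric=None`` fits the area-only (or intercept-only) sibling used
    as a comparison baseline.
    """
    est = LinearComparisonModel(caterpillar_metric, tree_metric, **kwargs)
    return est.fit(metrics).result_


def fit_herbivory_model(metrics: pd.DataFrame, phenology_metric: str | None,
                        **kwargs) -> ModelResult:
    """Beta regression of the herbivory fraction on a phenology metric,
    controlling for sampling area and canopy level."""
    est = BetaComparisonModel("herbivory", phenology_metric, **kwargs)
    return est.fit(metrics).result_


def variance_explained_delta(metrics: pd.DataFrame, response: str,
                             base_terms: list[str], added_factor: str) -> float:
    """R^2 gain from adding a factor to a base Gaussian model.

    R^2 is var(fitted) / (var(fitted) + var(residual)); both models are fit
    on the rows complete for the full design.
    """
    need = [response] + list(base_terms) + [added_factor]
    df = metrics.dropna(subset=[c for c in need if c in metrics.columns])
    s = df[added_factor]
    n_levels = s.nunique() if s.dtype.kind in "OUSb" else np.unique(s).size
    if n_levels < 2:
        raise ValueError(f"added factor {added_factor!r} has fewer than 2 levels")
    y = df[response].to_numpy(float)

    def r2(terms):
        X, _ = _build_design(df, terms)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design matrix")
        _, fitted, resid = _ols_fit(X, y)
        return _conditional_r2(fitted, resid)

    return r2(list(base_terms) + [added_factor]) - r2(list(base_terms))


def compare_models_elpd(results: list[ModelResult]) -> pd.DataFrame:
    """Delta-ELPD table for models sharing a response over identical rows.

    The best model is pinned at 0; all others are <= 0.
    """
    if len(results) < 2:
        raise ValueError("need at least 2 models to compare")
    base = results[0]
    for r in results[1:]:
        if r.response != base.response:
            raise ValueError("models must share a response")
        if not np.array_equal(np.sort(r.row_index), np.sort(base.row_index)):
            raise ValueError("models must be fit on identical rows")
    elpds = np.array([r.elpd for r in results])
    best = elpds.max()
    rows = []
    for r, e in zip(results, elpds):
        r.delta_elpd = float(e - best)
        rows.append({
            "response": r.response,
            "predictors": " + ".join(map(str, r.predictors)),
            "elpd": float(e),
            "delta_elpd": r.delta_elpd,
        })
    return pd.DataFrame(rows).sort_values("delta_elpd", ascending=False,
                                          ignore_index=True)


def morans_i(values, coords, k: int = 8, permutations: int = 999,
             random_state=None):
    """Moran's I with row-standardized k-nearest-neighbour weights.

    Returns (I, expected, p); the expectation under no spatial structure is
    -1/(n-1) and p is a two-sided permutation probability.  Duplicate
    coordinates are collapsed to one site with the mean value.
    """
    z = np.asarray(values, dtype=float)
    xy = np.asarray(coords, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or xy.shape[0] != z.size:
        raise ValueError("coords must be (n, 2) aligned with values")

    uniq, inv = np.unique(xy, axis=0, return_inverse=True)
    if uniq.shape[0] < xy.shape[0]:
        warnings.warn("duplicate coordinates collapsed to single sites "
                      "(values averaged)")
        agg = np.zeros(uniq.shape[0])
        cnt = np.zeros(uniq.shape[0])
        np.add.at(agg, inv, z)
        np.add.at(cnt, inv, 1.0)
        z, xy = agg / cnt, uniq
    n = z.size
    if n < 10:
        raise ValueError("need at least 10 distinct sites")
    k = min(k, n - 1)

    tree = cKDTree(xy)
    _, idx = tree.query(xy, k=k + 1)
    W = np.zeros((n, n))
    for i in range(n):
        for j in idx[i, 1:]:
            W[i, j] = 1.0
    W /= W.sum(axis=1, keepdims=True)
    s0 = W.sum()

    def stat(v):
        d = v - v.mean()
        return (n / s0) * (d @ W @ d) / (d @ d)

    I = float(stat(z))
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(random_state)
    perms = np.array([stat(rng.permutation(z)) for _ in range(permutations)])
    p = float((1 + np.sum(np.abs(perms - expected) >= abs(I - expected)))
              / (permutations + 1))
    return I, expected, p
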