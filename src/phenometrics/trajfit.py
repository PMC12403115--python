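"""Sigmoidal trajectory fitting and half-date extraction.

Each normalized per-tree series is fitted with a Beta likelihood whose mean
is a logit-linked penalized B-spline of day (a per-tree smooth); series too
short to support the spline fall back to the plain logistic (midpoint, rate,
and a free Beta precision as the third parameter).  The half-date is the day
at which the fitted central curve first crosses y = 0.5 from below, refined
by bisection to 0.01 day; its 95% interval comes from the crossing days of a
bootstrap ensemble of refitted curves (case resampling of visits by default,
with small-sample expanded percentile levels).  The gradient at the
crossing is a centred finite difference of the central curve, so on an exact
logistic with rate k it recovers the analytic midpoint slope k/4.

Boundary handling: the Beta density lives on the open interval, so boundary
observations (exact 0s and 1s, which min-max and cumulative normalization
produce by construction) are squeezed to (y (n-1) + 0.5) / n evaluated at
the endpoints, i.e. 0.5/n and 1 - 0.5/n; interior values already lie on the
Beta support and are left untouched, so exact sigmoid input is recovered
exactly.

Bud-score series may carry an observer label per visit; a ridge-penalized
observer intercept (a shrunken random effect) is then included on the logit
scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma, expit, gammaln, polygamma
from scipy.stats import norm as norm_dist
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator

from ._basis import SplineBasis, linear_basis
from .normalize import NormalizedTrajectory

__all__ = [
    "FittedCurve",
    "HalfDateEstimate",
    "BetaSplineTrajectory",
    "fit_sigmoid",
    "extract_half_date",
    "summarize_ci_widths",
    "shrink_to_species_mean",
]

_EPS = 1e-9


@dataclass
class FittedCurve:
    """A fitted smooth trajectory with an uncertainty ensemble.

    ``values`` and ``ensemble`` are on the reporting scale: proportions in
    (0, 1) for trajectory fits, nonnegative intensities for count fits.
    ``predict`` evaluates the central curve at arbitrary days.
    """

    tree_id: str
    metric: str
    grid: np.ndarray
    values: np.ndarray
    ensemble: np.ndarray  # (B, len(grid)); B may be 0
    scale: str  # "proportion" or "intensity"
    converged: bool
    deviance: float
    predict: object = None  # callable day -> central value
    interval_levels: tuple = (2.5, 97.5)  # ensemble percentiles for the 95% CI
    notes: list = field(default_factory=list)


@dataclass
class HalfDateEstimate:
    tree_id: str
    metric: str
    half_day: float
    ci_low: float
    ci_high: float
    ci_width: float
    gradient_at_half: float
    flag: str  # ok | no_crossing | boundary | undefined
    notes: list = field(default_factory=list)


def _squeeze(y: np.ndarray) -> tuple[np.ndarray, int]:
    """Boundary squeeze: exact 0s and 1s map to the limits of the affine
    transform y' = (y (n-1) + 0.5) / n, i.e. 0.5/n and 1 - 0.5/n; interior
    values, already on the Beta support, are untouched."""
    y = np.clip(np.asarray(y, dtype=float), 0.0, 1.0)
    n = y.size
    lo = 0.5 / n
    out = np.where(y <= 0.0, lo, np.where(y >= 1.0, 1.0 - lo, y))
    return out, n


def _unsqueeze(mu: np.ndarray, n: int) -> np.ndarray:
    return np.clip(mu, _EPS, 1.0 - _EPS)


def _beta_nll_grad(params, X, y, pen):
    """Penalized negative Beta log-likelihood (logit link) and its gradient.

    params = [spline/linear coefficients..., log precision].
    """
    c, logphi = params[:-1], params[-1]
    phi = np.exp(np.clip(logphi, -6.0, 16.0))
    eta = X @ c
    mu = expit(eta)
    mu = np.clip(mu, 1e-12, 1.0 - 1e-12)
    a, b = mu * phi, (1.0 - mu) * phi
    ly, l1y = np.log(y), np.log1p(-y)
    ll = gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1.0) * ly + (b - 1.0) * l1y
    nll = -np.sum(ll) + 0.5 * c @ pen @ c

    dmu = phi * (digamma(b) - digamma(a) + ly - l1y)
    grad_c = -(X.T @ (dmu * mu * (1.0 - mu))) + pen @ c
    dphi = (
        digamma(phi) - mu * digamma(a) - (1.0 - mu) * digamma(b)
        + mu * ly + (1.0 - mu) * l1y
    )
    grad_logphi = -np.sum(dphi) * phi
    return nll, np.concatenate([grad_c, [grad_logphi]])


def _logphi_curvature(params, X):
    """Fisher information for the log-precision parameter."""
    c, logphi = params[:-1], params[-1]
    phi = np.exp(np.clip(logphi, -6.0, 16.0))
    mu = np.clip(expit(X @ c), 1e-12, 1.0 - 1e-12)
    d2 = np.sum(mu**2 * polygamma(1, mu * phi)
                + (1.0 - mu) ** 2 * polygamma(1, (1.0 - mu) * phi)
                - polygamma(1, phi))
    return float(d2 * phi**2)


def _fisher_hessian(params, X, pen):
    c, logphi = params[:-1], params[-1]
    phi = np.exp(np.clip(logphi, -6.0, 16.0))
    mu = np.clip(expit(X @ c), 1e-12, 1.0 - 1e-12)
    w = (phi**2) * (polygamma(1, mu * phi) + polygamma(1, (1.0 - mu) * phi))
    w = w * (mu * (1.0 - mu)) ** 2
    return (X.T * w) @ X + pen


def _logdet_psd(m, tol=1e-10):
    ev = np.linalg.eigvalsh(m)
    ev = ev[ev > tol * max(1.0, ev.max())]
    return float(np.sum(np.log(ev))), ev.size


class BetaSplineTrajectory(BaseEstimator):
    """Beta-likelihood logit-link smooth of a normalized trajectory.

    Parameters
    ----------
    n_basis : int
        B-spline basis size for the penalized smooth; series with fewer
        distinct days than this use the logistic fallback.
    degree : int
        Spline degree (cubic by default).
    lambda_grid : array-like or None
        Grid of roughness-penalty weights; the value maximizing a Laplace
        approximation to the marginal likelihood is kept.  ``None`` uses
        ``10**linspace(-2, 4, 7)``.
    observer_ridge_grid : array-like or None
        Ridge weights tried for the observer intercepts (only when observer
        labels are supplied); ``None`` uses (0.25, 1.0, 4.0).
    ensemble_size : int
        Number of bootstrap refits (B).  0 disables the ensemble (point
        estimates only).
    ensemble_method : {"case", "parametric"}
        "case" (default) resamples visits with replacement and refits — it is
        robust to misspecification of the Beta dispersion and gives honest
        half-date intervals under realistic observation noise; "parametric"
        resamples from the fitted Beta model.
    grid_step : float
        Evaluation-grid resolution in days.
    random_state : int or None
        Seed for the bootstrap resampler.

    Interval percentiles are expanded from 2.5/97.5 using the t-quantile at
    df = n - edf (the classic small-sample bootstrap-percentile adjustment),
    where edf is the effective degrees of freedom of the penalized smooth.

    Attributes (after ``fit``)
    --------------------------
    coef_, phi_, lambda_, converged_, ensemble_coef_, basis_, n_squeeze_,
    edf_, interval_levels_
    """

    def __init__(self, n_basis=8, degree=3, lambda_grid=None,
                 observer_ridge_grid=None, ensemble_size=500,
                 ensemble_method="case", grid_step=0.1, random_state=None):
        self.n_basis = n_basis
        self.degree = degree
        self.lambda_grid = lambda_grid
        self.observer_ridge_grid = observer_ridge_grid
        self.ensemble_size = ensemble_size
        self.ensemble_method = ensemble_method
        self.grid_step = grid_step
        self.random_state = random_state

    # -- internal design construction -----------------------------------

    def _make_design(self, day):
        lo, hi = float(np.min(day)), float(np.max(day))
        n_distinct = np.unique(day).size
        if n_distinct >= max(self.n_basis, self.degree + 2):
            basis = SplineBasis(lo, hi, self.n_basis, self.degree)
            X = basis.design(day)
            pen0 = basis.penalty
            kind = "spline"
        else:
            basis = None
            X = linear_basis(day)
            pen0 = np.zeros((2, 2))
            kind = "logistic"
        return basis, X, pen0, kind, (lo, hi)

    def _observer_design(self, observer):
        levels = sorted(set(map(str, observer)))
        Z = np.zeros((len(observer), len(levels)))
        idx = {l: j for j, l in enumerate(levels)}
        for i, o in enumerate(observer):
            Z[i, idx[str(o)]] = 1.0
        return Z, levels

    def _optimize(self, X, y, pen, x0, maxiter=200, polish=12):
        # log-precision is box-bounded: on (near-)noiseless data the Beta
        # likelihood increases without bound in phi, and the fit should then
        # converge cleanly at the cap rather than fail the line search
        bounds = [(None, None)] * (x0.size - 1) + [(-4.0, 12.0)]
        x0 = x0.copy()
        x0[-1] = np.clip(x0[-1], -4.0, 12.0)
        res = minimize(
            _beta_nll_grad, x0, args=(X, y, pen), jac=True, bounds=bounds,
            method="L-BFGS-B", options={"maxiter": maxiter, "ftol": 1e-11},
        )
        # Fisher-scoring polish: L-BFGS can stall on the steep likelihood at
        # large precision, leaving curve-level bias; alternating Newton steps
        # in the coefficients and in log-precision finish the job cheaply
        x = res.x.copy()
        fun, grad = _beta_nll_grad(x, X, y, pen)
        for _ in range(polish):
            if np.max(np.abs(grad)) < 1e-7 * max(1.0, abs(fun)):
                break
            H = _fisher_hessian(x, X, pen)
            try:
                step_c = np.linalg.solve(H, grad[:-1])
            except np.linalg.LinAlgError:
                break
            step_p = grad[-1] / max(_logphi_curvature(x, X), 1e-8)
            improved = False
            for frac in (1.0, 0.5, 0.25, 0.1):
                cand = x.copy()
                cand[:-1] = x[:-1] - frac * step_c
                cand[-1] = np.clip(x[-1] - frac * step_p, -4.0, 12.0)
                f2, g2 = _beta_nll_grad(cand, X, y, pen)
                if f2 < fun - 1e-12:
                    x, fun, grad = cand, f2, g2
                    improved = True
                    break
            if not improved:
                break
        res.x, res.fun, res.jac = x, fun, grad
        # convergence by Newton decrement (scale-invariant), with the
        # log-precision direction projected out when its cap is active
        try:
            H = _fisher_hessian(x, X, pen)
            nd = float(grad[:-1] @ np.linalg.solve(H, grad[:-1]))
            at_cap = (x[-1] >= 12.0 - 1e-9 and grad[-1] < 0) or (
                x[-1] <= -4.0 + 1e-9 and grad[-1] > 0)
            if not at_cap:
                nd += grad[-1] ** 2 / max(_logphi_curvature(x, X), 1e-8)
            res.success = bool(res.success or nd < 1e-6)
        except np.linalg.LinAlgError:
            pass
        return res

    def _laplace_score(self, res, X, pen):
        """Approximate log marginal likelihood for penalty selection."""
        ld_pen, rank = _logdet_psd(pen)
        H = _fisher_hessian(res.x, X, pen)
        sign, ld_h = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf
        return -res.fun + 0.5 * ld_pen - 0.5 * ld_h

    # -- public API ------------------------------------------------------

    def fit(self, day, y, observer=None):
        day = np.asarray(day, dtype=float)
        yy, n_sq = _squeeze(y)
        if np.unique(day).size < 5:
            raise ValueError("need at least 5 distinct visit days to fit a trajectory")

        basis, Xb, pen0, kind, dom = self._make_design(day)
        lam_grid = (np.asarray(self.lambda_grid, dtype=float)
                    if self.lambda_grid is not None
                    else 10.0 ** np.linspace(-2, 4, 7))
        if kind == "logistic":
            lam_grid = np.array([1.0])  # unpenalized; grid collapses

        Z, levels = (None, [])
        if observer is not None:
            Z, levels = self._observer_design(observer)
        tau_grid = (np.asarray(self.observer_ridge_grid, dtype=float)
                    if self.observer_ridge_grid is not None
                    else np.array([0.25, 1.0, 4.0]))
        if Z is None:
            tau_grid = np.array([np.nan])

        # crude initial coefficients from a ridge fit to the empirical logits
        z = np.log(yy / (1.0 - yy))
        p0 = Xb.shape[1]

        best = None
        for lam in lam_grid:
            for tau in tau_grid:
                if Z is None:
                    X = Xb
                    pen = lam * pen0 + 1e-8 * np.eye(p0)
                else:
                    X = np.hstack([Xb, Z])
                    pen = np.zeros((p0 + Z.shape[1],) * 2)
                    pen[:p0, :p0] = lam * pen0 + 1e-8 * np.eye(p0)
                    pen[p0:, p0:] = tau * np.eye(Z.shape[1])
                c0 = np.linalg.solve(X.T @ X + pen + 1e-6 * np.eye(X.shape[1]), X.T @ z)
                x0 = np.concatenate([c0, [np.log(20.0)]])
                res = self._optimize(X, yy, pen, x0)
                score = self._laplace_score(res, X, pen)
                if best is None or score > best[0]:
                    best = (score, res, X, pen, lam, tau)

        score, res, X, pen, lam, tau = best
        self.kind_ = kind
        self.basis_ = basis
        self.domain_ = dom
        self.design_ = X
        self.penalty_ = pen
        self.coef_ = res.x[:-1].copy()
        self.logphi_ = float(res.x[-1])
        self.phi_ = float(np.exp(np.clip(self.logphi_, -6.0, 16.0)))
        self.lambda_ = float(lam)
        self.observer_ridge_ = float(tau) if Z is not None else None
        self.observer_levels_ = levels
        self.n_spline_coef_ = p0
        self.converged_ = bool(res.success or np.max(np.abs(res.jac)) < 1e-3)
        self.deviance_ = 2.0 * float(res.fun - 0.5 * res.x[:-1] @ pen @ res.x[:-1])
        self.n_squeeze_ = n_sq
        self.day_ = day
        self.y_squeezed_ = yy

        # effective degrees of freedom of the smooth -> expanded interval
        # percentiles (t-quantile at df = n - edf)
        try:
            H = _fisher_hessian(res.x, X, pen)
            H0 = _fisher_hessian(res.x, X, np.zeros_like(pen))
            self.edf_ = float(np.trace(np.linalg.solve(H, H0)))
        except np.linalg.LinAlgError:
            self.edf_ = float(X.shape[1])
        df = max(day.size - self.edf_, 3.0)
        zstar = float(t_dist.ppf(0.975, df))
        self.interval_levels_ = (100.0 * norm_dist.cdf(-zstar),
                                 100.0 * norm_dist.cdf(zstar))

        # bootstrap ensemble, refit with the selected penalty and warm-started
        # at the central solution
        B = int(self.ensemble_size)
        self.ensemble_coef_ = np.empty((0, res.x.size))
        if B > 0:
            rng = np.random.default_rng(self.random_state)
            x0 = res.x
            coefs = np.empty((B, res.x.size))
            if self.ensemble_method == "parametric":
                mu_hat = np.clip(expit(X @ self.coef_), 1e-9, 1.0 - 1e-9)
                draws = rng.beta(mu_hat * self.phi_, (1.0 - mu_hat) * self.phi_,
                                 size=(B, mu_hat.size))
                draws = np.clip(draws, 1e-9, 1.0 - 1e-9)
                for b in range(B):
                    rb = self._optimize(X, draws[b], pen, x0, maxiter=60, polish=4)
                    coefs[b] = rb.x
            elif self.ensemble_method == "case":
                n = day.size
                for b in range(B):
                    idx = rng.integers(0, n, n)
                    rb = self._optimize(X[idx], yy[idx], pen, x0,
                                        maxiter=60, polish=4)
                    coefs[b] = rb.x
            else:
                raise ValueError(
                    f"unknown ensemble_method {self.ensemble_method!r}")
            self.ensemble_coef_ = coefs
        return self

    def _design_at(self, day):
        day = np.asarray(day, dtype=float)
        if self.kind_ == "spline":
            Xn = self.basis_.design(day)
        else:
            Xn = linear_basis(day)
        return Xn

    def predict(self, day):
        """Central fitted proportion (original scale) at the given days."""
        Xn = self._design_at(day)
        mu = expit(Xn @ self.coef_[: self.n_spline_coef_])
        return _unsqueeze(mu, self.n_squeeze_)

    def to_curve(self, tree_id: str = "", metric: str = "") -> FittedCurve:
        lo, hi = self.domain_
        n_pts = int(np.floor((hi - lo) / self.grid_step + 1e-9)) + 1
        grid = lo + self.grid_step * np.arange(n_pts)
        Xg = self._design_at(grid)[:, : self.n_spline_coef_]
        central = _unsqueeze(expit(Xg @ self.coef_[: self.n_spline_coef_]),
                             self.n_squeeze_)
        if self.ensemble_coef_.shape[0]:
            ens = _unsqueeze(
                expit(self.ensemble_coef_[:, : self.n_spline_coef_] @ Xg.T),
                self.n_squeeze_,
            )
        else:
            ens = np.empty((0, grid.size))
        return FittedCurve(
            tree_id=tree_id, metric=metric, grid=grid, values=central,
            ensemble=ens, scale="proportion", converged=self.converged_,
            deviance=self.deviance_, predict=self.predict,
            interval_levels=self.interval_levels_,
        )


def fit_sigmoid(traj: NormalizedTrajectory, settings: dict | None = None,
                **kwargs) -> FittedCurve:
    """Fit a sigmoidal curve to one normalized trajectory.

    ``settings``/keyword arguments are passed to
    :class:`BetaSplineTrajectory`.  Undefined trajectories are refused.
    """
    if not traj.ok:
        raise ValueError(
            f"trajectory {traj.tree_id}/{traj.metric} is flagged "
            f"{traj.flag}: {'; '.join(map(str, traj.notes))}"
        )
    opts = dict(settings or {})
    opts.update(kwargs)
    est = BetaSplineTrajectory(**opts)
    est.fit(traj.days, traj.y, observer=traj.observer_id)
    return est.to_curve(traj.tree_id, traj.metric)


def _crossings_on_grid(grid, rows):
    """First upward 0.5-crossing per ensemble row, by linear interpolation."""
    out = np.full(rows.shape[0], np.nan)
    below = rows < 0.5
    for i in range(rows.shape[0]):
        idx = np.nonzero(below[i, :-1] & ~below[i, 1:])[0]
        if idx.size:
            j = idx[0]
            y0, y1 = rows[i, j], rows[i, j + 1]
            out[i] = grid[j] + (0.5 - y0) / (y1 - y0) * (grid[j + 1] - grid[j])
    return out


def extract_half_date(curve: FittedCurve) -> HalfDateEstimate:
    """Day at which the central curve first passes through y = 0.5.

    Bisection refines the crossing to 0.01 day on the continuous fitted
    curve; the 95% interval is the (possibly expanded) percentile interval of
    crossing days over the uncertainty ensemble; the gradient is a centred
    finite difference of the central curve at the crossing.
    """
    if curve.scale != "proportion":
        raise ValueError("half-dates are defined for proportion-scale curves only")
    tid, met = curve.tree_id, curve.metric
    if not curve.converged:
        return HalfDateEstimate(tid, met, np.nan, np.nan, np.nan, np.nan,
                                np.nan, "undefined", ["fit did not converge"])
    g, v = curve.grid, curve.values
    notes = []
    if v[0] >= 0.5:
        return HalfDateEstimate(tid, met, np.nan, np.nan, np.nan, np.nan, np.nan,
                                "boundary", ["curve already above 0.5 at season start"])
    up = np.nonzero((v[:-1] < 0.5) & (v[1:] >= 0.5))[0]
    if up.size == 0:
        return HalfDateEstimate(tid, met, np.nan, np.nan, np.nan, np.nan, np.nan,
                                "no_crossing", ["central curve never reaches 0.5"])
    if up.size > 1:
        notes.append(f"multiple crossings ({up.size}); first reported")
    j = up[0]
    flag = "ok"
    if j == 0 or j >= g.size - 2:
        flag = "boundary"

    lo, hi = g[j], g[j + 1]
    f = curve.predict
    if f is not None:
        while hi - lo > 0.01:
            mid = 0.5 * (lo + hi)
            if float(f(np.array([mid]))[0]) < 0.5:
                lo = mid
            else:
                hi = mid
    half = 0.5 * (lo + hi)

    if f is not None:
        h = 0.05
        a = float(f(np.array([half - h]))[0])
        b = float(f(np.array([half + h]))[0])
        grad = (b - a) / (2.0 * h)
    else:
        grad = float((v[j + 1] - v[j]) / (g[j + 1] - g[j]))
    if grad <= 0:
        flag = "undefined"
        notes.append("nonpositive gradient at crossing")

    ci_low = ci_high = np.nan
    if curve.ensemble.shape[0]:
        cross = _crossings_on_grid(g, curve.ensemble)
        good = cross[np.isfinite(cross)]
        if good.size < curve.ensemble.shape[0]:
            notes.append(
                f"{curve.ensemble.shape[0] - good.size} ensemble curves had no crossing"
            )
        if good.size >= 20:
            ci_low, ci_high = np.percentile(good, list(curve.interval_levels))
            if not (ci_low <= half <= ci_high):
                ci_low, ci_high = min(ci_low, half), max(ci_high, half)
        else:
            notes.append("ensemble too degenerate for an interval")
    return HalfDateEstimate(tid, met, half, float(ci_low), float(ci_high),
                            float(ci_high - ci_low), grad, flag, notes)


def summarize_ci_widths(estimates, grouping=("species", "metric")) -> pd.DataFrame:
    """Mean and SD of half-date interval widths per group.

    ``estimates`` is a DataFrame with at least ``ci_width``, ``flag`` and the
    grouping columns.  Groups with no ok-flagged estimates are reported with
    missing values, not zeros.
    """
    df = pd.DataFrame(estimates)
    grouping = list(grouping)
    out = []
    for keys, sub in df.groupby(grouping, dropna=False):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ok = sub[(sub["flag"] == "ok") & np.isfinite(sub["ci_width"])]
        row = dict(zip(grouping, keys))
        row["n_ok"] = len(ok)
        row["mean_ci_width"] = float(ok["ci_width"].mean()) if len(ok) else np.nan
        row["sd_ci_width"] = (
            float(ok["ci_width"].std(ddof=1)) if len(ok) >= 2 else np.nan
        )
        out.append(row)
    return pd.DataFrame(out)


def shrink_to_species_mean(curves: list[FittedCurve], weight: float) -> list[FittedCurve]:
    """Shrink per-tree curves toward their group's mean curve (logit scale).

    An approximation to factor-smooth pooling: with weight w, each curve's
    logit is replaced by (1-w)*own + w*group mean, evaluated on a common day
    grid (the intersection of the curves' domains).
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("shrinkage weight must lie in [0, 1]")
    if weight == 0.0 or len(curves) < 2:
        return curves
    lo = max(c.grid[0] for c in curves)
    hi = min(c.grid[-1] for c in curves)
    if hi <= lo:
        warnings.warn("curve domains do not overlap; shrinkage skipped")
        return curves
    step = float(curves[0].grid[1] - curves[0].grid[0])
    grid = np.arange(lo, hi + step / 2, step)

    def logit(p):
        p = np.clip(p, _EPS, 1 - _EPS)
        return np.log(p / (1 - p))

    mats = [logit(np.interp(grid, c.grid, c.values)) for c in curves]
    mean_logit = np.mean(mats, axis=0)
    out = []
    for c, m in zip(curves, mats):
        new_vals = expit((1 - weight) * m + weight * mean_logit)
        ens = c.ensemble
        if ens.shape[0]:
            ens_i = np.vstack([logit(np.interp(grid, c.grid, row)) for row in ens])
            ens = expit((1 - weight) * ens_i + weight * mean_logit)
        out.append(FittedCurve(
            c.tree_id, c.metric, grid, new_vals, ens, c.scale, c.converged,
            c.deviance, predict=None, notes=c.notes + [f"shrunk w={weight}"],
        ))
    return out
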