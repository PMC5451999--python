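"""Daily variogram modelling and ordinary kriging of ensemble residuals.

After the bagged additive model removes the mean structure, the daily
residuals ε(s, t) still carry spatial autocorrelation.  Each day is treated
independently: an empirical semivariogram is computed from that day's
station residuals, a parametric variogram family

    γ(d, t) = c0(t) + c(t) · g(d / a0(t)),   γ(0) = 0,

is fitted — by profiled Gaussian REML on the residual values (default) or
by weighted least squares on the binned empirical variogram (families:
spherical, circular, exponential, Gaussian, linear) — the family may be
chosen by leave-one-station-out cross-validated kriging, and ordinary
kriging with the unbiasedness constraint Σλ = 1 interpolates the residual
to target locations.  The kriged residual is added to the ensemble mean
on the log scale before back-transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = ["EmpiricalVariogram", "VariogramModel", "GridSpec", "FAMILIES",
           "variogram_value", "empirical_variogram", "fit_variogram",
           "fit_variogram_ml",
           "select_family_loocv", "krige", "loo_krige", "daily_variograms",
           "daily_surfaces", "block_mean", "surface_for_day_of_year",
           "KrigingError"]

FAMILIES = ("spherical", "circular", "exponential", "gaussian", "linear")
MIN_STATIONS_FOR_KRIGING = 10


class KrigingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Variogram families
# ---------------------------------------------------------------------------

def variogram_value(family: str, d, c0: float, c: float, a: float):
    """γ(d) for the named family; γ(0) = 0 exactly (the nugget is a
    discontinuity at the origin)."""
    d = np.asarray(d, dtype=float)
    h = d / max(a, 1e-300)
    if family == "exponential":
        struct = 1.0 - np.exp(-h)
    elif family == "gaussian":
        struct = 1.0 - np.exp(-h ** 2)
    elif family == "spherical":
        hc = np.minimum(h, 1.0)
        struct = 1.5 * hc - 0.5 * hc ** 3
    elif family == "circular":
        hc = np.minimum(h, 1.0)
        struct = (2.0 / np.pi) * (hc * np.sqrt(np.maximum(1 - hc ** 2, 0.0))
                                  + np.arcsin(hc))
    elif family == "linear":
        struct = h                      # unbounded; a is a reference lag
    else:
        raise ValueError(f"unknown variogram family {family!r}")
    out = np.where(d > 0, c0 + c * struct, 0.0)
    return out if out.ndim else float(out)


def effective_range(family: str, a: float) -> float:
    """Distance at which correlation has essentially vanished (95%)."""
    return {"exponential": 3.0 * a, "gaussian": float(np.sqrt(3.0)) * a,
            "spherical": a, "circular": a, "linear": np.inf}[family]


@dataclass
class EmpiricalVariogram:
    day: int
    lags: np.ndarray          # bin centres, metres
    gamma: np.ndarray         # semivariance per bin
    counts: np.ndarray        # station pairs per bin
    max_lag: float
    n_stations: int


@dataclass
class VariogramModel:
    family: str
    nugget: float             # c0 ≥ 0
    partial_sill: float       # c ≥ 0
    a0: float                 # range parameter > 0
    day: int = 0
    wsse: float = float("nan")
    loocv_rmse: float = float("nan")

    def __call__(self, d):
        return variogram_value(self.family, d, self.nugget,
                               self.partial_sill, self.a0)

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def effective_range(self) -> float:
        return effective_range(self.family, self.a0)


# ---------------------------------------------------------------------------
# Empirical variogram
# ---------------------------------------------------------------------------

def empirical_variogram(coords: np.ndarray, values: np.ndarray, day: int = 0,
                        n_bins: int = 12, max_lag: float | None = None,
                        min_pairs: int = 5) -> EmpiricalVariogram:
    """Binned method-of-moments semivariogram of one day's residuals.

    γ̂(bin) = ½ · mean over pairs in the bin of (ε_i − ε_j)², plotted at the
    mean pair distance of the bin.  ``max_lag`` defaults to a third of the
    maximum inter-station distance (the conventional geostatistical
    cutoff); bins with fewer than ``min_pairs`` pairs are dropped.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    coords, values = coords[ok], values[ok]
    n = len(values)
    if n < MIN_STATIONS_FOR_KRIGING:
        raise KrigingError(f"only {n} stations with residuals (< "
                           f"{MIN_STATIONS_FOR_KRIGING}); day flagged no-kriging")
    d = pdist(coords)
    if max_lag is None:
        max_lag = float(d.max()) / 3.0
    sq = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if np.allclose(values, values[0]):
        warnings.warn(f"day {day}: residuals are constant; zero variogram")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges) - 1
    lags, gam, cnt = [], [], []
    for b in range(n_bins):
        sel = which == b
        m = int(sel.sum())
        if m >= min_pairs:
            lags.append(float(d[sel].mean()))
            gam.append(float(sq[sel].mean()))
            cnt.append(m)
    return EmpiricalVariogram(day=day, lags=np.array(lags),
                              gamma=np.array(gam), counts=np.array(cnt),
                              max_lag=float(max_lag), n_stations=n)


# ---------------------------------------------------------------------------
# Parametric fit
# ---------------------------------------------------------------------------

def fit_variogram(emp: EmpiricalVariogram, family: str = "exponential",
                  min_bins: int = 4, weights: str = "npairs_dist2"
                  ) -> VariogramModel:
    """Weighted least-squares fit of one family to the empirical variogram.

    Default weights N_j/h_j² (pairs over squared lag, the common
    geostatistical default) emphasise the short lags that identify the
    range; ``weights`` may also be "npairs" (pair counts) or "cressie".
    Multi-start trust-region optimisation over (c0, c, a0) with
    non-negativity bounds and deterministic starts; falls back to a
    pure-nugget model if every start fails.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if emp.lags.size < min_bins:
        raise KrigingError(f"only {emp.lags.size} variogram bins (< {min_bins})")
    g, lags = emp.gamma, emp.lags
    npairs = emp.counts.astype(float)
    if weights == "npairs":
        w = np.sqrt(npairs)
    elif weights == "npairs_dist2":
        w = np.sqrt(npairs) / lags
    elif weights == "cressie":
        w = np.sqrt(npairs) / np.maximum(g, 1e-12 * max(g.max(), 1e-300))
    else:
        raise ValueError(f"unknown weighting scheme {weights!r}")
    if np.allclose(g, 0.0):
        return VariogramModel(family=family, nugget=0.0, partial_sill=0.0,
                              a0=emp.max_lag / 3.0, day=emp.day, wsse=0.0)

    gmax = float(g.max())
    c0_start = max(float(g.min()), 1e-8 * gmax)
    c_start = max(gmax - c0_start, 1e-8 * gmax)
    a_starts = [emp.max_lag / 3.0, emp.max_lag / 10.0, emp.max_lag]

    if family == "linear":
        # γ = c0 + slope·d: weighted linear regression, slope ≥ 0
        X = np.column_stack([np.ones_like(lags), lags]) * w[:, None]
        coef, *_ = np.linalg.lstsq(X, g * w, rcond=None)
        c0f, slope = max(coef[0], 0.0), max(coef[1], 0.0)
        a_ref = emp.max_lag
        model = VariogramModel(family, c0f, slope * a_ref, a_ref, day=emp.day)
        model.wsse = float(np.sum((w * (model(lags) - g)) ** 2))
        return model

    def resid(theta):
        return w * (variogram_value(family, lags, *theta) - g)

    best = None
    for a_s in a_starts:
        try:
            sol = least_squares(resid, x0=[c0_start, c_start, a_s],
                                bounds=([0, 0, 1e-6 * emp.max_lag],
                                        [np.inf, np.inf, 100 * emp.max_lag]),
                                method="trf", max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.all(np.isfinite(best.x)):
        warnings.warn(f"variogram fit failed for day {emp.day}; "
                      "falling back to pure nugget")
        return VariogramModel(family, float(np.average(g, weights=w ** 2)),
                              0.0, emp.max_lag / 3.0, day=emp.day)
    c0f, cf, af = best.x
    model = VariogramModel(family, float(c0f), float(cf), float(af),
                           day=emp.day, wsse=float(2 * best.cost))
    return _prefer_nugget_if_insignificant(model, g, lags, w, emp)


def _prefer_nugget_if_insignificant(model: VariogramModel, g, lags, w, emp,
                                    alpha: float = 0.05) -> VariogramModel:
    """Guard against spurious spatial structure.

    A 3-parameter variogram can absorb sampling noise of the empirical
    semivariances (especially in sparse short-lag bins) into an apparent
    partial sill.  The structured fit is kept only when it improves the
    weighted SSE over the 1-parameter pure-nugget model by more than an
    approximate F-test at level ``alpha``; otherwise the day is treated as
    spatially unstructured (all variance in the nugget).
    """
    k = lags.size
    if k <= 3 or model.partial_sill == 0.0:
        return model
    c0_flat = float(np.sum(w ** 2 * g) / np.sum(w ** 2))
    wsse0 = float(np.sum((w * (c0_flat - g)) ** 2))
    wsse1 = model.wsse
    if wsse1 <= 0:
        return model
    fstat = ((wsse0 - wsse1) / 2.0) / (wsse1 / (k - 3))
    from scipy.stats import f as f_dist
    if fstat < f_dist.ppf(1.0 - alpha, 2, k - 3):
        return VariogramModel(model.family, c0_flat, 0.0, emp.max_lag / 3.0,
                              day=emp.day, wsse=wsse0)
    return model


# ---------------------------------------------------------------------------
# Likelihood-based fitting from field values
# ---------------------------------------------------------------------------

def _correlation(family: str, d: np.ndarray, a: float) -> np.ndarray:
    """Stationary correlation function ρ(d) = 1 − γ_struct(d)/c."""
    return 1.0 - variogram_value(family, d, 0.0, 1.0, a)


def fit_variogram_ml(coords: np.ndarray, values: np.ndarray,
                     family: str = "exponential", day: int = 0,
                     reml: bool = True) -> VariogramModel:
    """Gaussian (restricted) maximum-likelihood fit of a variogram model
    directly to one day's field values.

    Far more efficient than curve-fitting the binned empirical variogram,
    especially for the range parameter.  The likelihood is profiled: the
    constant mean and the overall variance scale are solved analytically,
    leaving a 2-D optimisation over (nugget/partial-sill ratio, range),
    multi-started deterministically.  The linear family has no stationary
    covariance and is not supported here.
    """
    if family == "linear":
        raise ValueError("linear variogram has no stationary covariance; "
                         "use the least-squares fit")
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = ~np.isnan(values)
    coords, values = coords[ok], values[ok]
    n = len(values)
    if n < MIN_STATIONS_FOR_KRIGING:
        raise KrigingError(f"only {n} stations with residuals (< "
                           f"{MIN_STATIONS_FOR_KRIGING})")
    if np.allclose(values, values[0]):
        warnings.warn(f"day {day}: residuals are constant; zero variogram")
        return VariogramModel(family, 0.0, 0.0, 1.0, day=day)

    D = squareform(pdist(coords))
    dmax = float(D.max())
    one = np.ones(n)
    eye = np.eye(n)
    p = 1        # constant-mean degrees of freedom

    def nll(theta: np.ndarray) -> float:
        delta, a = np.exp(theta)
        K0 = _correlation(family, D, a) + (delta + 1e-8) * eye
        try:
            L = np.linalg.cholesky(K0)
        except np.linalg.LinAlgError:
            return 1e10
        one_l = np.linalg.solve(L, one)
        y_l = np.linalg.solve(L, values)
        q = float(one_l @ one_l)
        mu = float(one_l @ y_l) / q
        r = y_l - mu * one_l
        dof = n - p if reml else n
        chat = float(r @ r) / dof
        out = 0.5 * dof * np.log(max(chat, 1e-300)) \
            + float(np.log(np.diag(L)).sum())
        if reml:
            out += 0.5 * np.log(q)
        return out

    from scipy.optimize import minimize
    best = None
    for a_s in (dmax / 30.0, dmax / 10.0, dmax / 3.0):
        for d_s in (0.02, 0.2):
            sol = minimize(nll, np.log([d_s, a_s]), method="Nelder-Mead",
                           options=dict(maxiter=250, xatol=1e-3, fatol=1e-5))
            if best is None or sol.fun < best.fun:
                best = sol
    # likelihood-ratio guard against spurious structure: compare with the
    # iid (pure nugget) model, reached exactly in the a → 0 limit
    nll_nugget = nll(np.log([1.0, dmax * 1e-12]))
    from scipy.stats import chi2
    if 2.0 * (nll_nugget - best.fun) < chi2.ppf(0.95, 2):
        return VariogramModel(family, float(np.var(values, ddof=1)), 0.0,
                              dmax / 3.0, day=day)
    delta, a = np.exp(best.x)
    # recover the profiled variance scale
    K0 = _correlation(family, D, a) + (delta + 1e-8) * eye
    L = np.linalg.cholesky(K0)
    one_l = np.linalg.solve(L, one)
    y_l = np.linalg.solve(L, values)
    mu = float(one_l @ y_l) / float(one_l @ one_l)
    r = y_l - mu * one_l
    c = float(r @ r) / (n - p if reml else n)
    return VariogramModel(family, float(delta * c), float(c), float(a),
                          day=day)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def _dedupe(coords: np.ndarray, values: np.ndarray):
    """Average values at (numerically) duplicated station coordinates."""
    key = np.round(coords, 6)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True,
                               return_counts=True)
    if counts.max() == 1:
        return coords, values
    m = counts.size
    cc = np.zeros((m, 2))
    vv = np.zeros(m)
    np.add.at(cc, inv, coords)
    np.add.at(vv, inv, values)
    return cc / counts[:, None], vv / counts


def _kriging_matrix(coords: np.ndarray, vgm: VariogramModel) -> np.ndarray:
    n = len(coords)
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = vgm(squareform(pdist(coords)))
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    return A


def krige(coords: np.ndarray, values: np.ndarray, vgm: VariogramModel,
          targets: np.ndarray, return_weights: bool = False):
    """Ordinary kriging of one day's residuals to target locations.

    Solves the augmented (n+1)×(n+1) system per target; returns
    (estimates, kriging variances) and optionally the weight matrix.
    Duplicate station coordinates are averaged before solving.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    targets = np.atleast_2d(np.asarray(targets, dtype=float))
    ok = ~np.isnan(values)
    coords, values = coords[ok], values[ok]
    coords, values = _dedupe(coords, values)
    n = len(values)
    if n < 2:
        raise KrigingError("need at least 2 distinct stations to krige")

    A = _kriging_matrix(coords, vgm)
    B = np.empty((n + 1, len(targets)))
    B[:n] = vgm(cdist(coords, targets))
    B[n] = 1.0
    try:
        sol = np.linalg.solve(A, B)
    except np.linalg.LinAlgError as e:
        raise KrigingError(f"singular kriging system: {e}") from e
    lam, mu = sol[:n], sol[n]
    est = lam.T @ values
    var = np.maximum(np.einsum("it,it->t", lam, B[:n]) + mu, 0.0)
    if return_weights:
        return est, var, lam.T
    return est, var


def loo_krige(coords: np.ndarray, values: np.ndarray,
              vgm: VariogramModel) -> np.ndarray:
    """Leave-one-station-out kriging estimate at every station (NaN values
    are excluded from every neighbourhood and returned as NaN).

    The full variogram matrix is built once; each held-out station then
    solves its own reduced augmented system.
    """
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    out = np.full(len(values), np.nan)
    ok = np.where(~np.isnan(values))[0]
    if ok.size < 3:
        return out
    G = vgm(squareform(pdist(coords[ok])))
    m = ok.size
    for pos in range(m):
        rest = np.concatenate([np.arange(pos), np.arange(pos + 1, m)])
        A = np.empty((m, m))
        A[:m - 1, :m - 1] = G[np.ix_(rest, rest)]
        A[:m - 1, m - 1] = 1.0
        A[m - 1, :m - 1] = 1.0
        A[m - 1, m - 1] = 0.0
        b = np.empty(m)
        b[:m - 1] = G[rest, pos]
        b[m - 1] = 1.0
        try:
            sol = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        out[ok[pos]] = sol[:m - 1] @ values[ok[rest]]
    return out


def select_family_loocv(coords: np.ndarray, values: np.ndarray, day: int = 0,
                        families=FAMILIES, n_bins: int = 12,
                        max_lag: float | None = None,
                        min_pairs: int = 5,
                        method: str = "reml") -> VariogramModel:
    """Fit every candidate family and keep the one whose leave-one-station-
    out kriging RMSE is smallest.

    Pointwise LOOCV errors of the bounded families usually differ by less
    than their own sampling noise, so a winner is only declared over the
    exponential family (the default for these residual fields) when it
    improves the paired squared error by more than one standard error;
    otherwise the comparison is treated as a tie and exponential is kept.
    Falls back to pure nugget if every fit fails.
    """
    emp = empirical_variogram(coords, values, day=day, n_bins=n_bins,
                              max_lag=max_lag, min_pairs=min_pairs)
    vals = np.asarray(values, dtype=float)
    ok = ~np.isnan(vals)
    results: dict[str, tuple[VariogramModel, np.ndarray]] = {}
    for fam in families:
        try:
            if method == "reml" and fam != "linear":
                model = fit_variogram_ml(coords, values, family=fam, day=day)
            else:
                model = fit_variogram(emp, family=fam)
            pred = loo_krige(coords, values, model)
            sq = (pred[ok] - vals[ok]) ** 2
            model.loocv_rmse = float(np.sqrt(np.nanmean(sq)))
        except (KrigingError, np.linalg.LinAlgError):
            continue
        if np.isfinite(model.loocv_rmse):
            results[fam] = (model, sq)
    if not results:
        warnings.warn(f"day {day}: all variogram candidates failed; pure nugget")
        return VariogramModel("exponential", float(np.nanvar(vals)), 0.0,
                              1.0, day=day)
    best_fam = min(results, key=lambda f: results[f][0].loocv_rmse)
    if best_fam != "exponential" and "exponential" in results:
        # paired comparison of squared LOO errors, Bonferroni-corrected for
        # the number of competitor families: a competitor replaces the
        # exponential default only if it wins significantly, not by noise
        from scipy.stats import norm
        diff = results["exponential"][1] - results[best_fam][1]
        diff = diff[~np.isnan(diff)]
        se = diff.std(ddof=1) / np.sqrt(diff.size) if diff.size > 1 else 0.0
        n_comp = max(len(results) - 1, 1)
        zcrit = norm.ppf(1.0 - 0.05 / n_comp)
        if diff.mean() <= zcrit * se:
            best_fam = "exponential"
    return results[best_fam][0]


# ---------------------------------------------------------------------------
# Daily surfaces, parameter series, block means
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Regular prediction grid in projected metres."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float
    cell: float

    def __post_init__(self):
        if self.xmax <= self.xmin or self.ymax <= self.ymin or self.cell <= 0:
            raise ValueError("degenerate grid specification")

    @property
    def xs(self) -> np.ndarray:
        return np.arange(self.xmin + self.cell / 2, self.xmax, self.cell)

    @property
    def ys(self) -> np.ndarray:
        return np.arange(self.ymin + self.cell / 2, self.ymax, self.cell)

    def points(self) -> np.ndarray:
        xx, yy = np.meshgrid(self.xs, self.ys)
        return np.column_stack([xx.ravel(), yy.ravel()])

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.ys), len(self.xs))


def daily_variograms(residuals: np.ndarray, coords: np.ndarray,
                     days: np.ndarray, family: str = "exponential",
                     select_family: bool = False, n_bins: int = 12,
                     min_pairs: int = 5, method: str = "reml"
                     ) -> tuple[pd.DataFrame, dict]:
    """Fit one variogram per day of a station × day residual matrix.

    ``method="reml"`` (default) fits each day's parameters by restricted
    maximum likelihood on the residual values; ``method="wls"`` uses the
    weighted least-squares fit of the binned empirical variogram.  Returns
    the per-day parameter table (a range / partial-sill / nugget time
    series) and a dict day → fitted :class:`VariogramModel`.  Days with
    fewer than 10 reporting stations are flagged ``kriged = False``.
    """
    rows, models = [], {}
    for j, day in enumerate(days):
        vals = residuals[:, j]
        try:
            if select_family:
                model = select_family_loocv(coords, vals, day=int(day),
                                            n_bins=n_bins, min_pairs=min_pairs,
                                            method=method)
            elif method == "reml" and family != "linear":
                model = fit_variogram_ml(coords, vals, family=family,
                                         day=int(day))
            else:
                emp = empirical_variogram(coords, vals, day=int(day),
                                          n_bins=n_bins, min_pairs=min_pairs)
                model = fit_variogram(emp, family=family)
            models[int(day)] = model
            rows.append((int(day), model.family, model.nugget,
                         model.partial_sill, model.a0, model.effective_range,
                         model.loocv_rmse, True))
        except KrigingError:
            rows.append((int(day), family, np.nan, np.nan, np.nan, np.nan,
                         np.nan, False))
    table = pd.DataFrame(rows, columns=["day", "family", "nugget",
                                        "partial_sill", "a0",
                                        "effective_range", "loocv_rmse",
                                        "kriged"])
    return table, models


def daily_surfaces(residuals: np.ndarray, coords: np.ndarray,
                   days: np.ndarray, grid: GridSpec,
                   family: str = "exponential", select_family: bool = False,
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Kriged residual grid for every day plus the parameter time series.

    Days flagged no-kriging produce all-zero surfaces (the residual term of
    the final prediction is then 0 there).
    """
    table, models = daily_variograms(residuals, coords, days, family=family,
                                     select_family=select_family)
    pts = grid.points()
    ny, nx = grid.shape
    stack = np.zeros((len(days), ny, nx))
    for j, day in enumerate(days):
        model = models.get(int(day))
        if model is None:
            continue
        est, _ = krige(coords, residuals[:, j], model, pts)
        stack[j] = est.reshape(ny, nx)
    return stack, table


def block_mean(surface: np.ndarray, grid: GridSpec, polygon,
               refine: int = 1) -> float:
    """Discretised block estimate: the average of the (bilinearly
    interpolated) point surface over the polygon.

    ``polygon`` is a shapely polygon in projected metres; ``refine``
    subdivides each grid cell edge for a finer discretisation.
    """
    step = grid.cell / refine
    xs = np.arange(grid.xmin + step / 2, grid.xmax, step)
    ys = np.arange(grid.ymin + step / 2, grid.ymax, step)
    xx, yy = np.meshgrid(xs, ys)
    try:
        from shapely import contains_xy
        inside = contains_xy(polygon, xx, yy)
    except ImportError:
        from shapely.geometry import Point
        inside = np.array([[polygon.contains(Point(x, y)) for x in xs]
                           for y in ys])
    if not inside.any():
        raise ValueError("polygon does not intersect the grid")
    interp = RegularGridInterpolator((grid.ys, grid.xs), surface,
                                     bounds_error=False, fill_value=None)
    vals = interp(np.column_stack([yy[inside], xx[inside]]))
    return float(vals.mean())


def surface_for_day_of_year(stack: np.ndarray, days: np.ndarray,
                            target_doy: int) -> tuple[np.ndarray, bool]:
    """Residual surface for a day-of-year, for transfer to other years.

    Assumes the daily variograms change little between years; returns the
    stored surface for the matching day-of-year and an extrapolation flag
    (True — the surface comes from the modelled year, not the target one).
    """
    days = np.asarray(days)
    j = int(np.argmin(np.abs(days - target_doy)))
    return stack[j], True
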