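"""Temporal basis functions from the station × day panel.

Daily particulate levels over a region share a dominant seasonal shape
(high in winter, low in summer).  The first right singular vectors of the
station-centred log panel capture that shared temporal structure; smoothed
with a cubic smoothing spline they become the seasonal predictors f1(t),
f2(t) of the additive model.  Missing daily means are first completed by an
iterative truncated-SVD matrix-completion scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MeasurementPanel

__all__ = ["TemporalBasis", "svd_impute", "extract_basis", "smooth_basis",
           "SmoothingSpline", "ImputationWarning"]


class ImputationWarning(UserWarning):
    pass


@dataclass
class TemporalBasis:
    """Raw and smoothed temporal basis functions indexed by day.

    ``raw[:, k]`` is the k-th unit-norm right singular vector of the
    station-centred log panel; ``smooth[:, k]`` its cubic-smoothing-spline
    fit (populated by :func:`smooth_basis`).  ``variance_fraction[k]`` is
    the share of (centred) variance the component explains.
    """

    days: np.ndarray
    raw: np.ndarray
    singular_values: np.ndarray
    variance_fraction: np.ndarray
    smooth: np.ndarray | None = None
    smoothing_df: float | None = None

    @property
    def n_basis(self) -> int:
        return self.raw.shape[1]

    def functions(self) -> np.ndarray:
        """Per-day predictor values: smoothed if available, else raw."""
        return self.smooth if self.smooth is not None else self.raw

    def to_frame(self) -> pd.DataFrame:
        cols = {"day": self.days}
        for k in range(self.n_basis):
            cols[f"b{k + 1}"] = self.raw[:, k]
        if self.smooth is not None:
            for k in range(self.n_basis):
                cols[f"f{k + 1}"] = self.smooth[:, k]
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# SVD-based matrix completion
# ---------------------------------------------------------------------------

def svd_impute(panel: MeasurementPanel, rank: int = 2, tol: float = 1e-6,
               max_iter: int = 500) -> MeasurementPanel:
    """Complete missing entries by iterative truncated-SVD reconstruction.

    Missing cells start at their station/day mean estimate; each iteration
    replaces them with the rank-``rank`` SVD reconstruction of the current
    matrix, until the relative change in imputed values falls below ``tol``.
    Observed entries are never altered.
    """
    values = panel.values
    mask = np.isnan(values)
    if not mask.any():
        return panel

    frac = mask.mean()
    if frac >= 0.5:
        raise ValueError(f"missing fraction {frac:.0%} ≥ 50%; refusing to impute")
    if rank > min(values.shape):
        raise ValueError("rank exceeds matrix dimensions")

    empty_rows = mask.all(axis=1)
    empty_cols = mask.all(axis=0)
    if empty_rows.any():
        raise ValueError(
            f"station {panel.stations[int(np.argmax(empty_rows))].id} has no data")
    if empty_cols.any():
        raise ValueError(
            f"day {panel.days[int(np.argmax(empty_cols))]} has no data")

    filled = values.copy()
    row_mean = np.nanmean(values, axis=1, keepdims=True)
    col_mean = np.nanmean(values, axis=0, keepdims=True)
    grand = np.nanmean(values)
    init = np.broadcast_to(row_mean + col_mean - grand, values.shape)
    filled[mask] = init[mask]

    converged = False
    for _ in range(max_iter):
        u, s, vt = np.linalg.svd(filled, full_matrices=False)
        recon = (u[:, :rank] * s[:rank]) @ vt[:rank]
        new_imp = recon[mask]
        denom = np.linalg.norm(filled[mask])
        change = np.linalg.norm(new_imp - filled[mask]) / max(denom, 1e-300)
        filled[mask] = new_imp
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn("SVD imputation did not converge; returning last iterate",
                      ImputationWarning)

    out = panel.copy_with(values=filled)
    out.imputed_mask = mask  # type: ignore[attr-defined]
    out.converged = converged  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Basis extraction
# ---------------------------------------------------------------------------

def extract_basis(panel: MeasurementPanel, n_basis: int = 2,
                  winter_day: int = 15) -> TemporalBasis:
    """First ``n_basis`` right singular vectors of the station-centred panel.

    Each station's own mean is removed first, so the leading components
    describe the temporal shape shared across the network rather than
    between-site level differences.  Signs are fixed so that each component
    is positive in mid-winter (``winter_day``), making the winter-high
    seasonal trend the positive direction.
    """
    values = panel.values
    if np.isnan(values).any():
        raise ValueError("panel has missing entries; run svd_impute first")
    if n_basis < 1 or n_basis > 2:
        raise ValueError("n_basis must be 1 or 2")
    centred = values - values.mean(axis=1, keepdims=True)
    if np.allclose(centred, 0.0):
        raise ValueError("panel is constant per station; no temporal basis exists")

    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    total = float((s ** 2).sum())
    raw = vt[:n_basis].T.copy()
    j_winter = int(np.argmin(np.abs(panel.days - winter_day)))
    for k in range(n_basis):
        if raw[j_winter, k] < 0:
            raw[:, k] = -raw[:, k]
    return TemporalBasis(days=panel.days.copy(), raw=raw,
                         singular_values=s[:n_basis].copy(),
                         variance_fraction=(s[:n_basis] ** 2) / total)


# ---------------------------------------------------------------------------
# Cubic smoothing spline (natural spline penalty, df-parameterised)
# ---------------------------------------------------------------------------

class SmoothingSpline:
    """Natural cubic smoothing spline at fixed knots, tuned by effective df.

    Solves min_f Σ (y_i − f(t_i))² + λ ∫ f″² with the classical
    band-matrix construction of the roughness penalty; λ is chosen by
    root-finding so that trace of the smoother matrix equals ``df``.
    df → n recovers interpolation, df → 2 the least-squares straight line.
    """

    def __init__(self, t: np.ndarray):
        t = np.asarray(t, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("knots must be strictly increasing")
        n = t.size
        if n < 4:
            raise ValueError("need at least 4 knots")
        h = np.diff(t)
        # penalty K = Q R^{-1} Q^T with Q (n × n-2), R (n-2 × n-2) tridiagonal
        Q = np.zeros((n, n - 2))
        R = np.zeros((n - 2, n - 2))
        for j in range(n - 2):
            Q[j, j] = 1.0 / h[j]
            Q[j + 1, j] = -1.0 / h[j] - 1.0 / h[j + 1]
            Q[j + 2, j] = 1.0 / h[j + 1]
            R[j, j] = (h[j] + h[j + 1]) / 3.0
            if j + 1 < n - 2:
                R[j, j + 1] = R[j + 1, j] = h[j + 1] / 6.0
        K = Q @ np.linalg.solve(R, Q.T)
        # eigendecomposition gives edf(λ) = Σ 1/(1+λ d_i) cheaply
        d, U = np.linalg.eigh((K + K.T) / 2.0)
        self.t = t
        self._d = np.clip(d, 0.0, None)
        self._U = U

    def edf(self, lam: float) -> float:
        return float(np.sum(1.0 / (1.0 + lam * self._d)))

    def lambda_for_df(self, df: float) -> float:
        n = self.t.size
        if not 2.0 < df <= n:
            raise ValueError(f"smoothing df must be in (2, {n}], got {df}")
        if self.edf(0.0) <= df:
            return 0.0
        lo, hi = 0.0, 1.0
        while self.edf(hi) > df:
            hi *= 10.0
            if hi > 1e18:
                break
        for _ in range(200):
            mid = (lo + hi) / 2.0
            if self.edf(mid) > df:
                lo = mid
            else:
                hi = mid
        return (lo + hi) / 2.0

    def fit(self, y: np.ndarray, df: float) -> np.ndarray:
        """Smoothed values at the knots for the target effective df."""
        lam = self.lambda_for_df(df)
        shrink = 1.0 / (1.0 + lam * self._d)
        return self._U @ (shrink * (self._U.T @ np.asarray(y, dtype=float)))


def smooth_basis(basis: TemporalBasis, smoothing_df: float = 12.0) -> TemporalBasis:
    """Fit cubic smoothing splines to each raw basis vector.

    ``smoothing_df`` is the effective degrees of freedom of the smoother
    (must lie in (2, T]); around 12 keeps the two seasonal cycles while
    suppressing day-to-day noise.
    """
    spline = SmoothingSpline(basis.days.astype(float))
    smooth = np.column_stack([spline.fit(basis.raw[:, k], smoothing_df)
                              for k in range(basis.n_basis)])
    return TemporalBasis(days=basis.days, raw=basis.raw,
                         singular_values=basis.singular_values,
                         variance_fraction=basis.variance_fraction,
                         smooth=smooth, smoothing_df=smoothing_df)
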