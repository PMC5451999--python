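"""Covariate screening and backward-stepwise selection.

Two-stage variable selection for the additive model: first a variance
inflation factor (VIF) screen against multicollinearity, then backward
stepwise elimination under AIC, dropping one term at a time until no single
removal lowers the criterion.  AIC comes from the same additive fitter used
by the ensemble, so selection and fitting are consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gam_ensemble import Term, fit_additive

__all__ = ["SelectionReport", "compute_vif", "vif_screen",
           "backward_stepwise_aic", "correlation_screen"]


@dataclass
class SelectionReport:
    vif: pd.Series | None
    trace: pd.DataFrame
    selected: list[Term]

    @property
    def selected_names(self) -> list[str]:
        return [t.name for t in self.selected]

    def to_frame(self) -> pd.DataFrame:
        return self.trace


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 − R²_j), regressing column j on the others (with
    intercept).  Perfect collinearity yields ``inf`` rather than an error."""
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("need at least 2 candidate columns")
    if n < p + 1:
        raise ValueError("need more rows than columns")
    if np.isnan(X).any():
        raise ValueError("design contains missing values")
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        sse = float(np.sum((y - others @ coef) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            out[name] = np.inf        # constant column
            continue
        r2 = 1.0 - sse / sst
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def vif_screen(design: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[list[str], pd.Series]:
    """Iteratively drop the highest-VIF column until all fall below
    ``threshold``; returns (kept column names, final VIFs)."""
    cols = list(design.columns)
    while len(cols) >= 2:
        vif = compute_vif(design[cols])
        worst = vif.idxmax()
        if vif[worst] < threshold:
            return cols, vif
        cols.remove(worst)
    return cols, pd.Series(1.0, index=cols, name="VIF")


def correlation_screen(design: pd.DataFrame, response: pd.Series) -> pd.Series:
    """Pearson correlation of each candidate with the response — a quick
    relevance check for dropping unrelated site descriptors."""
    return design.apply(lambda c: c.corr(response)).rename("corr")


def backward_stepwise_aic(data: pd.DataFrame, response: str, terms,
                          vif: pd.Series | None = None) -> SelectionReport:
    """Backward stepwise elimination of additive terms under AIC.

    At each step the single term whose removal most lowers AIC is dropped;
    the procedure stops when no removal strictly lowers AIC.  Among equal
    improvements the later-listed term is dropped, keeping the
    earlier-listed one.  An empty final set is permitted (with a warning)
    when even the last term hurts the criterion.
    """
    current = list(terms)
    if not current:
        raise ValueError("empty candidate term set")
    aic_now = _aic(data, response, current)
    steps = [("<start>", np.nan, aic_now)]
    while current:
        best_aic, best_j = aic_now, None
        for j in range(len(current)):
            reduced = current[:j] + current[j + 1:]
            cand = _aic(data, response, reduced) if reduced else _null_aic(data, response)
            if cand <= best_aic:       # <=: ties drop the later-listed term
                best_aic, best_j = cand, j
        if best_j is None or best_aic >= aic_now:
            break
        dropped = current.pop(best_j)
        steps.append((dropped.name, aic_now, best_aic))
        aic_now = best_aic
    if not current:
        warnings.warn("backward selection removed every candidate term")
    trace = pd.DataFrame(steps, columns=["removed", "aic_before", "aic_after"])
    return SelectionReport(vif=vif, trace=trace, selected=current)


def _aic(data: pd.DataFrame, response: str, terms) -> float:
    fit = fit_additive(data, response, terms)
    if not np.isfinite(fit.aic):
        raise RuntimeError(f"non-finite AIC for terms {[t.name for t in terms]}")
    return fit.aic


def _null_aic(data: pd.DataFrame, response: str) -> float:
    y = data[response].to_numpy(dtype=float)
    n = y.size
    sse = float(np.sum((y - y.mean()) ** 2))
    return n * np.log(max(sse, 1e-300) / n) + 2.0 * 2
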