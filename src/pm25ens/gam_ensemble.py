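"""Non-linear additive modelling of log concentrations, with bagging.

The mean model is

    y(s,t) = μ(s,t) + ε(s,t),  y ~ N(μ, σ²)
    μ(s,t) = f1(t) + f2(t) + Σ_i s(x_i(s,t)) + Σ_k s(p_k(s))

on the natural-log concentration scale: the smoothed temporal basis
functions enter linearly, every other covariate through a smooth term.
Smooths are cubic regression splines with knots at training quantiles; the
flexibility of each term is bounded by its degrees of freedom, capped at 10
to prevent overfitting.  A wind vector may enter as one bivariate
(tensor-product) smooth of its eastward/northward components.

Bagging draws B bootstrap resamples of the rows, fits one additive model on
each, and scores each member on its out-of-bag (OOB) rows.  The ensemble
prediction is the R²-weighted mean

    μ_f = Σ_i w_i μ_i,   w_i = (R²_i)² / Σ_j (R²_j)²,

and the uncertainty is the weighted ensemble standard deviation

    σ_f = sqrt( Σ_i w_i (μ_i − μ_f)² / ( (M−1)/M · Σ_i w_i ) ),

with M the number of members carrying nonzero weight (σ_f := 0 when M ≤ 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

__all__ = ["Term", "s", "lin", "te", "AdditiveModelFit", "EnsembleModel",
           "EnsemblePrediction", "fit_additive", "bagging_fit",
           "ensemble_weights", "ensemble_predict", "oob_predict",
           "expected_unique_fraction", "term_variance_report", "FitError"]

MAX_TERM_DF = 10


class FitError(RuntimeError):
    """Raised when an additive fit cannot be computed (e.g. rank deficiency)."""


@dataclass(frozen=True)
class Term:
    """One additive term: 'linear', 'spline' (univariate smooth) or
    'tensor' (bivariate smooth of two columns, e.g. a wind vector)."""

    kind: str
    cols: tuple[str, ...]
    df: int = 6

    def __post_init__(self):
        if self.kind not in ("linear", "spline", "tensor"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "tensor" and len(self.cols) != 2:
            raise ValueError("tensor term needs exactly 2 columns")
        if self.kind != "tensor" and len(self.cols) != 1:
            raise ValueError(f"{self.kind} term needs exactly 1 column")

    @property
    def name(self) -> str:
        inner = ",".join(self.cols)
        return {"linear": inner, "spline": f"s({inner})",
                "tensor": f"te({inner})"}[self.kind]


def s(col: str, df: int = 6) -> Term:
    """Univariate cubic-spline smooth with the given degrees of freedom."""
    return Term("spline", (col,), df)


def lin(col: str) -> Term:
    return Term("linear", (col,), 1)


def te(col1: str, col2: str) -> Term:
    """Bivariate tensor-product smooth (quadratic marginals, 8 df)."""
    return Term("tensor", (col1, col2), 8)


# ---------------------------------------------------------------------------
# Basis construction
# ---------------------------------------------------------------------------

def _bspline_design(x: np.ndarray, knots: np.ndarray, degree: int) -> np.ndarray:
    xc = np.clip(x, knots[degree], knots[-degree - 1])
    return BSpline.design_matrix(xc, knots, degree).toarray()


def _knot_vector(x: np.ndarray, n_basis: int, degree: int) -> np.ndarray:
    """Clamped knot vector with interior knots at training quantiles."""
    n_interior = n_basis - degree - 1
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise FitError("constant covariate cannot carry a smooth term")
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(x, qs)
        interior = np.clip(interior, lo + 1e-12 * (hi - lo), hi - 1e-12 * (hi - lo))
    else:
        interior = np.array([])
    return np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])


class _TermEncoder:
    """Maps a term to centred design columns; remembers knots/means so that
    prediction uses the training-time basis."""

    def __init__(self, term: Term):
        self.term = term

    def fit(self, data: pd.DataFrame) -> np.ndarray:
        t = self.term
        df_eff = min(t.df, MAX_TERM_DF)
        if t.kind == "linear":
            cols = data[t.cols[0]].to_numpy(dtype=float)[:, None]
        elif t.kind == "spline":
            x = data[t.cols[0]].to_numpy(dtype=float)
            if df_eff < 3:
                cols = x[:, None]
            else:
                # df_eff + 1 basis functions sum to one; drop the first so the
                # term is identifiable next to the global intercept
                self.knots = _knot_vector(x, df_eff + 1, 3)
                cols = _bspline_design(x, self.knots, 3)[:, 1:]
        else:  # tensor: 3×3 quadratic marginal product basis, drop first
            x1 = data[t.cols[0]].to_numpy(dtype=float)
            x2 = data[t.cols[1]].to_numpy(dtype=float)
            self.knots = (_knot_vector(x1, 3, 2), _knot_vector(x2, 3, 2))
            b1 = _bspline_design(x1, self.knots[0], 2)
            b2 = _bspline_design(x2, self.knots[1], 2)
            cols = np.einsum("ni,nj->nij", b1, b2).reshape(len(x1), -1)[:, 1:]
        self.ranges = {c: (float(data[c].min()), float(data[c].max()))
                       for c in t.cols}
        self.means = cols.mean(axis=0)
        return cols - self.means

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        t = self.term
        if t.kind == "linear" or (t.kind == "spline" and not hasattr(self, "knots")):
            cols = data[t.cols[0]].to_numpy(dtype=float)[:, None]
        elif t.kind == "spline":
            cols = _bspline_design(data[t.cols[0]].to_numpy(dtype=float),
                                   self.knots, 3)[:, 1:]
        else:
            b1 = _bspline_design(data[t.cols[0]].to_numpy(dtype=float),
                                 self.knots[0], 2)
            b2 = _bspline_design(data[t.cols[1]].to_numpy(dtype=float),
                                 self.knots[1], 2)
            cols = np.einsum("ni,nj->nij", b1, b2).reshape(len(b1), -1)[:, 1:]
        return cols - self.means

    def extrapolating(self, data: pd.DataFrame) -> np.ndarray:
        flags = np.zeros(len(data), dtype=bool)
        for c, (lo, hi) in self.ranges.items():
            x = data[c].to_numpy(dtype=float)
            flags |= (x < lo) | (x > hi)
        return flags


# ---------------------------------------------------------------------------
# Single additive fit
# ---------------------------------------------------------------------------

@dataclass
class AdditiveModelFit:
    """A fitted additive model on the log scale."""

    terms: tuple[Term, ...]
    response: str
    coef: np.ndarray
    encoders: list[_TermEncoder]
    slices: list[slice]
    r2: float
    sigma2: float
    edf: float
    aic: float
    n: int
    oob_index: np.ndarray | None = None
    oob_r2: float | None = None

    def design(self, data: pd.DataFrame) -> np.ndarray:
        blocks = [np.ones((len(data), 1))]
        blocks += [enc.transform(data) for enc in self.encoders]
        return np.hstack(blocks)

    def predict(self, data: pd.DataFrame, return_flags: bool = False):
        missing = [c for t in self.terms for c in t.cols if c not in data.columns]
        if missing:
            raise KeyError(f"missing covariate columns: {sorted(set(missing))}")
        pred = self.design(data) @ self.coef
        if return_flags:
            flags = np.zeros(len(data), dtype=bool)
            for enc in self.encoders:
                flags |= enc.extrapolating(data)
            return pred, flags
        return pred

    def term_contribution(self, data: pd.DataFrame, term_name: str) -> np.ndarray:
        """Centred partial contribution of one term (for effect plots)."""
        for k, t in enumerate(self.terms):
            if t.name == term_name:
                cols = self.encoders[k].transform(data)
                return cols @ self.coef[self.slices[k]]
        raise KeyError(term_name)


def fit_additive(data: pd.DataFrame, response: str, terms,
                 max_df: int = MAX_TERM_DF) -> AdditiveModelFit:
    """Least-squares fit of the additive regression-spline model.

    ``terms`` is a sequence of :class:`Term`; each smooth's df is capped at
    ``max_df``.  Raises :class:`FitError` on a rank-deficient design.
    """
    terms = tuple(Term(t.kind, t.cols, min(t.df, max_df)) for t in terms)
    if not terms:
        raise FitError("empty term list")
    y = data[response].to_numpy(dtype=float)
    n = y.size

    encoders, blocks, slices = [], [np.ones((n, 1))], []
    pos = 1
    for t in terms:
        enc = _TermEncoder(t)
        cols = enc.fit(data)
        encoders.append(enc)
        blocks.append(cols)
        slices.append(slice(pos, pos + cols.shape[1]))
        pos += cols.shape[1]
    X = np.hstack(blocks)
    p = X.shape[1]
    if n <= p:
        raise FitError(f"{n} rows cannot support {p} coefficients")

    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        raise FitError(f"rank-deficient design (rank {rank} < {p} columns); "
                       "check for collinear or constant covariates")
    fitted = X @ coef
    sse = float(np.sum((y - fitted) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 0.0 if sst == 0 else 1.0 - sse / sst
    aic = n * np.log(max(sse, 1e-300) / n) + 2.0 * (p + 1)
    return AdditiveModelFit(terms=terms, response=response, coef=coef,
                            encoders=encoders, slices=slices, r2=r2,
                            sigma2=sse / max(n - p, 1), edf=float(p),
                            aic=float(aic), n=n)


def term_variance_report(data: pd.DataFrame, response: str, terms) -> pd.DataFrame:
    """Variance explained per predictor, univariately and by drop-one loss
    in the multivariate model (a variance-decomposition table)."""
    terms = list(terms)
    full = fit_additive(data, response, terms)
    rows = []
    for t in terms:
        uni = fit_additive(data, response, [t]).r2
        rest = [u for u in terms if u is not t]
        drop = full.r2 - fit_additive(data, response, rest).r2 if rest else full.r2
        rows.append((t.name, uni, max(drop, 0.0)))
    return pd.DataFrame(rows, columns=["term", "univariate_r2",
                                       "multivariate_delta_r2"])


# ---------------------------------------------------------------------------
# Bagging
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    members: list[AdditiveModelFit]
    weights: np.ndarray
    seed: int
    n_rows: int
    use_pm10: bool = False
    use_residual_kriging: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def B(self) -> int:
        return len(self.members)

    @property
    def oob_r2(self) -> np.ndarray:
        return np.array([m.oob_r2 for m in self.members], dtype=float)


@dataclass
class EnsemblePrediction:
    mean: np.ndarray       # μ_f(s,t), log scale
    sd: np.ndarray         # σ_f(s,t)
    n_effective: int       # M, number of nonzero weights

    def interval95(self):
        return self.mean - 1.96 * self.sd, self.mean + 1.96 * self.sd


def expected_unique_fraction(n: int) -> float:
    """Expected fraction of distinct rows in a size-n bootstrap resample,
    1 − (1 − 1/n)ⁿ → 1 − e⁻¹ ≈ 0.632; the complement is the OOB share."""
    return 1.0 - (1.0 - 1.0 / n) ** n


def ensemble_weights(r2_list) -> np.ndarray:
    """Weights proportional to the square of each member's R²."""
    r2 = np.asarray(r2_list, dtype=float)
    if np.any((r2 < 0) | (r2 > 1)):
        raise ValueError("each R² must lie in [0, 1]")
    sq = r2 ** 2
    total = sq.sum()
    if total == 0:
        warnings.warn("all member R² are zero; falling back to uniform weights")
        return np.full(r2.size, 1.0 / r2.size)
    return sq / total


def bagging_fit(data: pd.DataFrame, response: str, terms, B: int = 1000,
                seed: int = 0, weight_on: str = "oob",
                max_redraws: int = 10) -> EnsembleModel:
    """Fit B additive models on bootstrap resamples of the rows.

    Each resample has the size of the original data (expected unique share
    ≈ 63.2%); each member's R² is computed on its out-of-bag rows
    (``weight_on="train"`` switches to training R²).  Degenerate resamples
    (rank-deficient designs) are redrawn up to ``max_redraws`` times.
    """
    if B < 1:
        raise ValueError("B must be ≥ 1")
    rng = np.random.default_rng(seed)
    n = len(data)
    data = data.reset_index(drop=True)
    members: list[AdditiveModelFit] = []
    for _ in range(B):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            try:
                fit = fit_additive(data.iloc[idx], response, terms)
                break
            except FitError:
                if attempt == max_redraws:
                    raise
        fit.oob_index = oob
        if oob.size >= 2:
            obs = data[response].to_numpy(dtype=float)[oob]
            pred = fit.predict(data.iloc[oob])
            sst = float(np.sum((obs - obs.mean()) ** 2))
            fit.oob_r2 = max(0.0, 1.0 - float(np.sum((obs - pred) ** 2)) / sst) \
                if sst > 0 else 0.0
        else:
            fit.oob_r2 = fit.r2
        members.append(fit)
    scores = [m.oob_r2 if weight_on == "oob" else m.r2 for m in members]
    weights = ensemble_weights(np.clip(scores, 0.0, 1.0))
    return EnsembleModel(members=members, weights=weights, seed=seed, n_rows=n)


def _weighted_sd(preds: np.ndarray, weights: np.ndarray,
                 mean: np.ndarray) -> np.ndarray:
    """Ensemble SD: sqrt( Σ w (μ_i−μ_f)² / ((M−1)/M Σ w) ), 0 when M ≤ 1."""
    nz = weights > 0
    M = int(nz.sum())
    if M <= 1:
        return np.zeros(mean.shape)
    num = np.einsum("i,ij->j", weights, (preds - mean[None, :]) ** 2)
    denom = (M - 1) / M * weights.sum()
    return np.sqrt(np.maximum(num / denom, 0.0))


def ensemble_predict(model: EnsembleModel, data: pd.DataFrame,
                     return_flags: bool = False):
    """Weighted-mean prediction with ensemble-SD uncertainty (log scale)."""
    preds = np.empty((model.B, len(data)))
    flags = np.zeros(len(data), dtype=bool)
    for i, m in enumerate(model.members):
        if return_flags:
            preds[i], fl = m.predict(data, return_flags=True)
            flags |= fl
        else:
            preds[i] = m.predict(data)
    mean = model.weights @ preds
    sd = _weighted_sd(preds, model.weights, mean)
    out = EnsemblePrediction(mean=mean, sd=sd,
                             n_effective=int((model.weights > 0).sum()))
    return (out, flags) if return_flags else out


def oob_predict(model: EnsembleModel, data: pd.DataFrame) -> np.ndarray:
    """Out-of-bag ensemble prediction for the training rows.

    Row j is predicted only by members whose bootstrap sample excluded j,
    with weights renormalised over those members — the bagging analogue of
    a 63.2/36.8% cross-validation.  Rows no member left out (rare for
    moderate B) fall back to the full weighted mean.
    """
    n = len(data)
    if n != model.n_rows:
        raise ValueError("oob_predict expects the original training rows")
    preds = np.vstack([m.predict(data) for m in model.members])
    wmask = np.zeros((model.B, n))
    for i, m in enumerate(model.members):
        wmask[i, m.oob_index] = model.weights[i]
    wsum = wmask.sum(axis=0)
    out = np.empty(n)
    covered = wsum > 0
    out[covered] = (wmask[:, covered] * preds[:, covered]).sum(axis=0) / wsum[covered]
    if not covered.all():
        full = model.weights @ preds
        out[~covered] = full[~covered]
    return out
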