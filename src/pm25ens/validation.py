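"""Model scenarios, cross-validation and performance metrics.

Six scenarios span the design axes of the method: single additive model
vs. bagged ensemble, with vs. without the co-located PM₁₀ predictor, and
with vs. without daily residual kriging:

    1  single GAM, no PM₁₀, no kriging      4  bagging, no PM₁₀, kriging
    2  single GAM, PM₁₀, no kriging         5  bagging, PM₁₀, no kriging
    3  bagging, no PM₁₀, no kriging         6  bagging, PM₁₀, kriging

Single-model scenarios are scored by repeated k-fold cross-validation
(10 × 10-fold by default); bagging scenarios by out-of-bag aggregation,
which plays the role of a 63.2/36.8% split validation.  Metrics (R² =
1 − SSE/SST and RMSE) are computed on the original concentration scale
after back-transform.  Kriging scenarios evaluate the residual term
honestly: the kriged residual at a station uses only the other stations'
residuals for that day (leave-one-station-out).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import CovariateTable, MeasurementPanel, back_transform, log_transform
from .gam_ensemble import (Term, bagging_fit, ensemble_predict, fit_additive,
                           lin, oob_predict, s, te)
from .residual_kriging import (MIN_STATIONS_FOR_KRIGING, daily_variograms,
                               loo_krige)
from .temporal_basis import extract_basis, smooth_basis, svd_impute

__all__ = ["ScenarioConfig", "MetricReport", "ModelingDataset", "metrics",
           "assemble_dataset", "default_terms", "kfold_cv", "run_scenario",
           "run_all_scenarios", "diagnostic_plots", "SCENARIO_TABLE"]

SCENARIO_TABLE = {
    1: ("single_gam", False, False),
    2: ("single_gam", True, False),
    3: ("bagging", False, False),
    4: ("bagging", False, True),
    5: ("bagging", True, False),
    6: ("bagging", True, True),
}


@dataclass(frozen=True)
class ScenarioConfig:
    id: int
    engine: str                    # "single_gam" | "bagging"
    use_pm10: bool
    use_residual_kriging: bool

    @classmethod
    def from_id(cls, scenario_id: int) -> "ScenarioConfig":
        if scenario_id not in SCENARIO_TABLE:
            raise ValueError(f"scenario id must be 1..6, got {scenario_id}")
        engine, pm10, krige_flag = SCENARIO_TABLE[scenario_id]
        return cls(scenario_id, engine, pm10, krige_flag)

    @property
    def description(self) -> str:
        eng = "GAM" if self.engine == "single_gam" else "bagging"
        pm = "with" if self.use_pm10 else "without"
        kg = "with" if self.use_residual_kriging else "without"
        return f"{eng}, {pm} PM10, {kg} residual kriging"


@dataclass
class MetricReport:
    scenario_id: int
    r2: float                       # held-out R², concentration scale
    rmse: float                     # μg/m³
    train_r2: float = float("nan")
    per_fold: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {"model": self.scenario_id, "r2": self.train_r2,
                "cv_r2": self.r2, "cv_rmse": self.rmse}


def metrics(observed, predicted) -> tuple[float, float]:
    """(R², RMSE) with R² = 1 − Σ(o−p)²/Σ(o−ō)².  Pairs with a missing
    member are dropped; a constant observed vector yields R² = NaN."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError("observed and predicted must have equal length")
    ok = ~(np.isnan(o) | np.isnan(p))
    o, p = o[ok], p[ok]
    if o.size < 2:
        raise ValueError("need at least 2 non-missing pairs")
    rmse = float(np.sqrt(np.mean((o - p) ** 2)))
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        return float("nan"), rmse
    return 1.0 - float(np.sum((o - p) ** 2)) / sst, rmse


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

@dataclass
class ModelingDataset:
    """Long modelling frame plus the station/day geometry needed for
    kriging and for mapping rows back into the station × day matrix."""

    frame: pd.DataFrame
    coords: np.ndarray
    station_ids: list[str]
    days: np.ndarray
    station_index: np.ndarray      # row → station position
    day_index: np.ndarray          # row → day position
    terms: list[Term]              # without the PM10 term
    pm10_term: Term
    basis: object = None


def default_terms(covariates: CovariateTable, df: int = 6) -> list[Term]:
    """Additive terms: the smoothed basis functions enter linearly, wind as
    one bivariate smooth of its components, everything else univariately."""
    terms: list[Term] = [lin("f1"), lin("f2")]
    st_cols = list(covariates.spatiotemporal.columns)
    if "wind_e" in st_cols and "wind_n" in st_cols:
        terms.append(te("wind_e", "wind_n"))
        st_cols = [c for c in st_cols if c not in ("wind_e", "wind_n")]
    terms += [s(c, df) for c in st_cols]
    terms += [s(c, df) for c in covariates.spatial.columns]
    return terms


def assemble_dataset(panel_pm25: MeasurementPanel,
                     panel_pm10: MeasurementPanel | None,
                     covariates: CovariateTable,
                     smoothing_df: float = 12.0,
                     impute_rank: int = 2) -> ModelingDataset:
    """Impute, extract/smooth the temporal basis, and build the modelling
    frame of observed PM₂.₅ rows joined with all predictors."""
    covariates.validate_against(panel_pm25)
    log25 = log_transform(panel_pm25)
    log25_full = svd_impute(log25, rank=impute_rank)
    basis = smooth_basis(extract_basis(log25_full), smoothing_df=smoothing_df)
    f = basis.functions()

    log10_full = None
    if panel_pm10 is not None:
        log10_full = svd_impute(log_transform(panel_pm10), rank=impute_rank)

    ids = panel_pm25.station_ids
    n_s, n_d = panel_pm25.n_stations, panel_pm25.n_days
    obs = ~np.isnan(panel_pm25.values)
    si, dj = np.nonzero(obs)

    frame = pd.DataFrame({
        "station_id": np.asarray(ids, dtype=object)[si],
        "day": panel_pm25.days[dj],
        "x": panel_pm25.coords[si, 0],
        "y": panel_pm25.coords[si, 1],
        "pm25": panel_pm25.values[si, dj],
        "log_pm25": log25.values[si, dj],
        "f1": f[dj, 0],
        "f2": f[dj, 1],
    })
    if log10_full is not None:
        frame["log_pm10"] = log10_full.values[si, dj]

    st = covariates.spatiotemporal
    key = pd.MultiIndex.from_arrays([frame["station_id"], frame["day"]])
    for c in st.columns:
        frame[c] = st[c].reindex(key).to_numpy()
    for c in covariates.spatial.columns:
        frame[c] = covariates.spatial[c].reindex(frame["station_id"]).to_numpy()
    if frame.drop(columns=["station_id"]).isna().any().any():
        bad = frame.columns[frame.isna().any()].tolist()
        raise ValueError(f"missing covariate values after join: {bad}")

    return ModelingDataset(frame=frame, coords=panel_pm25.coords,
                           station_ids=ids, days=panel_pm25.days,
                           station_index=si, day_index=dj,
                           terms=default_terms(covariates),
                           pm10_term=s("log_pm10", 10), basis=basis)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def kfold_cv(frame: pd.DataFrame, response: str, terms, k: int = 10,
             repeats: int = 10, seed: int = 0,
             stratify_by_station: bool = False) -> MetricReport:
    """Repeated k-fold cross-validation of one additive model.

    Fold assignment is by record (the pooled-CV convention); with
    ``stratify_by_station`` whole stations are held out instead, a sterner
    spatial test.  Metrics are computed on back-transformed concentrations,
    pooled over folds; per-repeat R² values are kept in ``per_fold``.
    """
    n = len(frame)
    if k < 2:
        raise ValueError("k must be ≥ 2")
    if k > n:
        raise ValueError(f"k = {k} exceeds {n} records")
    rng = np.random.default_rng(seed)
    frame = frame.reset_index(drop=True)
    obs_conc = back_transform(frame[response].to_numpy())
    per_repeat, pooled_pred = [], np.empty(n)
    for _ in range(repeats):
        if stratify_by_station:
            stations = frame["station_id"].unique()
            fold_of_station = dict(zip(stations,
                                       rng.permutation(len(stations)) % k))
            folds = frame["station_id"].map(fold_of_station).to_numpy()
        else:
            folds = rng.permutation(n) % k
        for j in range(k):
            test = folds == j
            fit = fit_additive(frame.loc[~test], response, terms)
            pooled_pred[test] = fit.predict(frame.loc[test])
        r2_rep, _ = metrics(obs_conc, back_transform(pooled_pred))
        per_repeat.append(r2_rep)
    r2, rmse = metrics(obs_conc, back_transform(pooled_pred))
    return MetricReport(scenario_id=0, r2=float(np.mean(per_repeat)),
                        rmse=rmse, per_fold=per_repeat)


# ---------------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------------

def _residual_matrix(ds: ModelingDataset, resid_rows: np.ndarray) -> np.ndarray:
    mat = np.full((len(ds.station_ids), len(ds.days)), np.nan)
    mat[ds.station_index, ds.day_index] = resid_rows
    return mat


def run_scenario(config: ScenarioConfig, ds: ModelingDataset, B: int = 25,
                 seed: int = 0, cv_repeats: int = 10, k: int = 10,
                 variogram_family: str = "exponential") -> MetricReport:
    """Train and validate one scenario; returns held-out metrics on the
    concentration scale (μg/m³)."""
    terms = list(ds.terms)
    if config.use_pm10:
        if "log_pm10" not in ds.frame.columns:
            raise ValueError("scenario requires PM10 but the dataset has none")
        terms = [ds.pm10_term] + terms
    frame = ds.frame
    obs_conc = frame["pm25"].to_numpy()

    if config.engine == "single_gam":
        fit = fit_additive(frame, "log_pm25", terms)
        cv = kfold_cv(frame, "log_pm25", terms, k=k, repeats=cv_repeats,
                      seed=seed)
        return MetricReport(scenario_id=config.id, r2=cv.r2, rmse=cv.rmse,
                            train_r2=fit.r2, per_fold=cv.per_fold,
                            extras={"fit": fit})

    model = bagging_fit(frame, "log_pm25", terms, B=B, seed=seed)
    model.use_pm10 = config.use_pm10
    model.use_residual_kriging = config.use_residual_kriging
    mu_oob = oob_predict(model, frame)
    pred_log = mu_oob.copy()
    extras: dict = {"ensemble": model}

    if config.use_residual_kriging:
        resid = _residual_matrix(ds, frame["log_pm25"].to_numpy() - mu_oob)
        if len(ds.station_ids) < MIN_STATIONS_FOR_KRIGING:
            warnings.warn("residual kriging requested with fewer than "
                          f"{MIN_STATIONS_FOR_KRIGING} stations; "
                          "falling back to no kriging", stacklevel=2)
        else:
            table, models = daily_variograms(resid, ds.coords, ds.days,
                                             family=variogram_family)
            eps = np.zeros_like(resid)
            for j, day in enumerate(ds.days):
                vgm = models.get(int(day))
                if vgm is None:
                    continue
                est = loo_krige(ds.coords, resid[:, j], vgm)
                eps[:, j] = np.where(np.isnan(est), 0.0, est)
            pred_log = mu_oob + eps[ds.station_index, ds.day_index]
            extras["variogram_table"] = table
            extras["kriged_residual"] = eps

    r2_log, _ = metrics(frame["log_pm25"].to_numpy(), pred_log)
    r2, rmse = metrics(obs_conc, back_transform(pred_log))
    extras["r2_log"] = r2_log
    train_pred = ensemble_predict(model, frame)
    train_r2, _ = metrics(obs_conc, back_transform(train_pred.mean))
    return MetricReport(scenario_id=config.id, r2=r2, rmse=rmse,
                        train_r2=train_r2, extras=extras)


def diagnostic_plots(observed, predicted, path, title: str = "") -> None:
    """Predicted-vs-observed scatter and residual plot, saved to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    ok = ~(np.isnan(o) | np.isnan(p))
    o, p = o[ok], p[ok]
    r2, rmse = metrics(o, p)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(o, p, s=4, alpha=0.3)
    lim = [0, max(o.max(), p.max()) * 1.02]
    ax1.plot(lim, lim, "k--", lw=1)
    ax1.set_xlabel("observed (μg/m³)")
    ax1.set_ylabel("predicted (μg/m³)")
    ax1.set_title(f"{title} R²={r2:.2f} RMSE={rmse:.1f}")
    ax2.scatter(p, o - p, s=4, alpha=0.3)
    ax2.axhline(0.0, color="k", lw=1)
    ax2.set_xlabel("predicted (μg/m³)")
    ax2.set_ylabel("residual (μg/m³)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_all_scenarios(ds: ModelingDataset, B: int = 25, seed: int = 0,
                      cv_repeats: int = 10, scenario_ids=range(1, 7)
                      ) -> pd.DataFrame:
    """Comparison table across the six scenarios."""
    rows = []
    for sid in scenario_ids:
        rep = run_scenario(ScenarioConfig.from_id(sid), ds, B=B, seed=seed,
                           cv_repeats=cv_repeats)
        row = rep.to_row()
        row["description"] = ScenarioConfig.from_id(sid).description
        rows.append(row)
    return pd.DataFrame(rows)[["model", "description", "r2", "cv_r2",
                               "cv_rmse"]]
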