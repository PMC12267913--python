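"""Statistical layer over the per-cell table.

Reproduces the analysis design applied to the 1-ha cell records: one-way
ANOVA across forest types with Tukey HSD pairwise comparisons, univariate
regressions with a forest-type interaction, multiple OLS regressions on
standardized predictors, and a spatially buffered leave-one-out
cross-validation whose exclusion radius is the range of a spherical
semivariogram fitted to the model residuals. Volume losses are made
absolute and log(x + 1)-transformed before fitting to tame their right
skew.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
import statsmodels.api as sm

__all__ = [
    "RegressionResult",
    "SpatialCVResult",
    "LOSS_LOG_OFFSET",
    "prepare_response",
    "anova_by_type",
    "fit_univariate",
    "fit_multiple",
    "empirical_semivariogram",
    "residual_range",
    "spatial_loo_cv",
]

LOSS_LOG_OFFSET = 1.0  # m^3 ha^-1 yr^-1 added before the log of losses


@dataclass
class RegressionResult:
    formula: str
    coefficients: pd.DataFrame  # index term, columns coef / se
    r2: float
    n: int
    residuals: Optional[np.ndarray] = None
    per_type: Optional[pd.DataFrame] = None  # slope / intercept per forest type
    pooled_r: Optional[float] = None
    rank_deficient: bool = False


@dataclass
class SpatialCVResult:
    autocorrelation_range: float
    predictions: pd.DataFrame  # observed / predicted per evaluated cell
    spatial_r2: float
    n_skipped: int = 0


def prepare_response(records: pd.DataFrame, response: str) -> np.ndarray:
    """Response vector with the loss transform applied where it belongs.

    Loss responses (columns whose name contains ``losses``) are converted
    to absolute values and log(x + 1)-transformed; everything else passes
    through unchanged.
    """
    y = records[response].to_numpy(dtype=float)
    if "losses" in response:
        y = np.log(np.abs(y) + LOSS_LOG_OFFSET)
    return y


def anova_by_type(
    records: pd.DataFrame,
    response: str,
    type_column: str = "forest_type",
) -> dict:
    """One-way ANOVA of a response across forest types plus Tukey HSD.

    Returns ``{"F": ..., "p": ..., "groups": table, "pairwise": table}``.
    """
    y = prepare_response(records, response)
    g = records[type_column].to_numpy()
    groups = [y[g == t] for t in pd.unique(g)]
    if len(groups) < 2 or any(len(v) < 2 for v in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 records each")
    F, p = stats.f_oneway(*groups)
    tukey = pairwise_tukeyhsd(y, g)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    summary = (
        pd.DataFrame({"value": y, "group": g})
        .groupby("group")["value"]
        .agg(["mean", "std", "count"])
    )
    return {"F": float(F), "p": float(p), "groups": summary, "pairwise": pairwise}


def fit_univariate(
    records: pd.DataFrame,
    response: str,
    predictor: str,
    type_column: str = "forest_type",
) -> RegressionResult:
    """Linear model with type-specific intercepts and slopes, plus pooled fit.

    Fits ``y ~ x * C(type)`` over the types with at least 3 records (others
    get no slope); also reports the pooled single-slope fit and the pooled
    Pearson correlation.
    """
    y = prepare_response(records, response)
    x = records[predictor].to_numpy(dtype=float)
    g = records[type_column].to_numpy()
    ok = np.isfinite(y) & np.isfinite(x)
    y, x, g = y[ok], x[ok], g[ok]

    per_type_rows = []
    fit_types = []
    for t in pd.unique(g):
        sel = g == t
        if sel.sum() >= 3:
            fit_types.append(t)
    sel_fit = np.isin(g, fit_types)
    design_parts = []
    terms = []
    for t in fit_types:
        ind = (g[sel_fit] == t).astype(float)
        design_parts += [ind, ind * x[sel_fit]]
        terms += [f"intercept[{t}]", f"slope[{t}]"]
    X = np.column_stack(design_parts)
    model = sm.OLS(y[sel_fit], X).fit()
    for i, t in enumerate(fit_types):
        per_type_rows.append(
            {
                "forest_type": t,
                "intercept": model.params[2 * i],
                "slope": model.params[2 * i + 1],
                "slope_se": model.bse[2 * i + 1],
                "n": int((g == t).sum()),
            }
        )
    per_type = pd.DataFrame(per_type_rows).set_index("forest_type")

    pooled = sm.OLS(y, sm.add_constant(x)).fit()
    pooled_r = float(stats.pearsonr(x, y)[0]) if len(y) > 2 else np.nan
    coefs = pd.DataFrame({"coef": model.params, "se": model.bse}, index=terms)
    coefs.loc["pooled_slope"] = [pooled.params[1], pooled.bse[1]]
    return RegressionResult(
        formula=f"{response} ~ {predictor} * {type_column}",
        coefficients=coefs,
        r2=float(model.rsquared),
        n=int(sel_fit.sum()),
        residuals=np.asarray(model.resid),
        per_type=per_type,
        pooled_r=pooled_r,
    )


def fit_multiple(
    records: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
) -> RegressionResult:
    """OLS of a response on standardized predictors.

    Coefficients are on the z-score scale of each predictor; the naive
    in-sample R^2 is reported (the honest predictive number comes from
    :func:`spatial_loo_cv`). No effect-size comparison between correlated
    predictors is offered.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    y = prepare_response(records, response)
    X = records[list(predictors)].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(X).all(axis=1)
    y, X = y[ok], X[ok]
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = sm.add_constant((X - mu) / sd)
    model = sm.OLS(y, Z).fit()
    rank_def = np.linalg.matrix_rank(Z) < Z.shape[1]
    coefs = pd.DataFrame(
        {"coef": model.params, "se": model.bse},
        index=["intercept"] + list(predictors),
    )
    return RegressionResult(
        formula=f"{response} ~ " + " + ".join(predictors),
        coefficients=coefs,
        r2=float(model.rsquared),
        n=len(y),
        residuals=np.asarray(model.resid),
        rank_deficient=bool(rank_def),
    )


def empirical_semivariogram(
    coords: np.ndarray,
    values: np.ndarray,
    bin_width: float,
    max_lag: Optional[float] = None,
) -> pd.DataFrame:
    """Matheron classical semivariogram on regular-grid point data."""
    coords = np.asarray(coords, dtype=float)
    values = np.asarray(values, dtype=float)
    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
    sq = 0.5 * (values[:, None] - values[None, :]) ** 2
    iu = np.triu_indices(len(values), k=1)
    d, sq = d[iu], sq[iu]
    if max_lag is None:
        max_lag = d.max() / 2
    sel = d <= max_lag
    d, sq = d[sel], sq[sel]
    bins = np.arange(0, max_lag + bin_width, bin_width)
    idx = np.digitize(d, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        m = idx == b
        if m.any():
            rows.append(
                {
                    "lag": 0.5 * (bins[b] + bins[b + 1]),
                    "gamma": float(sq[m].mean()),
                    "n_pairs": int(m.sum()),
                }
            )
    return pd.DataFrame(rows)


def _spherical(h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    h = np.asarray(h, dtype=float)
    g = np.where(
        h >= rng,
        nugget + psill,
        nugget + psill * (1.5 * h / max(rng, 1e-12) - 0.5 * (h / max(rng, 1e-12)) ** 3),
    )
    return np.where(h == 0, 0.0, g)


def residual_range(
    records: pd.DataFrame,
    model: RegressionResult,
    bin_width: float = 100.0,
    x_column: str = "x",
    y_column: str = "y",
) -> float:
    """Autocorrelation range (m) of model residuals.

    Fits a spherical model (nugget + partial sill + range) to the Matheron
    semivariogram of the residuals by unweighted least squares; bin width
    defaults to the cell size and the maximum lag is half the landscape
    diameter. Residuals with no spatial structure (flat variogram, or a
    vanishing partial sill) report a range of 0.
    """
    if model.residuals is None or len(model.residuals) < 30:
        raise ValueError("need >= 30 records with residuals")
    coords = records[[x_column, y_column]].to_numpy(dtype=float)
    resid = np.asarray(model.residuals, dtype=float)
    if len(coords) != len(resid):
        # model may have dropped non-finite rows; align on the fitted subset
        raise ValueError("records and residuals length mismatch")
    var = resid.var()
    if var < 1e-15:
        return 0.0
    vario = empirical_semivariogram(coords, resid, bin_width)
    lags = vario["lag"].to_numpy()
    gam = vario["gamma"].to_numpy()
    max_lag = lags.max()

    def loss(theta: np.ndarray) -> np.ndarray:
        return _spherical(lags, *theta) - gam

    # multi-start over candidate ranges: the spherical objective has
    # nugget-absorbing local minima that a single start can fall into
    best = None
    for r0 in (max_lag / 6, max_lag / 3, 2 * max_lag / 3, max_lag):
        fit = optimize.least_squares(
            loss,
            x0=[0.0, var, r0],
            bounds=([0, 0, bin_width / 10], [np.inf, np.inf, 2 * max_lag]),
        )
        if best is None or fit.cost < best.cost:
            best = fit
    nugget, psill, rng = best.x
    total = nugget + psill
    if total <= 0 or psill < 1e-3 * total:
        return 0.0
    return float(min(rng, max_lag))


def spatial_loo_cv(
    records: pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    buffer_range: float,
    x_column: str = "x",
    y_column: str = "y",
) -> SpatialCVResult:
    """Leave-one-out cross-validation with a spatial exclusion buffer.

    For each cell, the model is refit on all cells whose centroid lies
    strictly farther than ``buffer_range`` from the held-out cell, and the
    held-out value is predicted. ``buffer_range = 0`` degenerates to
    ordinary leave-one-out. Cells whose buffer leaves fewer than p + 2
    training cells are skipped (and counted). Spatial R^2 =
    1 - SSE / SST over the evaluated cells.
    """
    if buffer_range < 0:
        raise ValueError("buffer_range must be >= 0")
    y = prepare_response(records, response)
    X = sm.add_constant(records[list(predictors)].to_numpy(dtype=float), has_constant="add")
    coords = records[[x_column, y_column]].to_numpy(dtype=float)
    n, p = X.shape
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    thresh2 = buffer_range**2
    preds = np.full(n, np.nan)
    skipped = 0
    for i in range(n):
        train = d2[i] > thresh2
        if train.sum() < p + 1:
            skipped += 1
            continue
        beta, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
        preds[i] = X[i] @ beta
    ok = np.isfinite(preds)
    if ok.sum() < 2:
        raise ValueError("too few evaluable cells for spatial CV")
    sse = float(((y[ok] - preds[ok]) ** 2).sum())
    sst = float(((y[ok] - y[ok].mean()) ** 2).sum())
    table = pd.DataFrame({"observed": y[ok], "predicted": preds[ok]})
    return SpatialCVResult(
        autocorrelation_range=float(buffer_range),
        predictions=table,
        spatial_r2=1.0 - sse / sst,
        n_skipped=skipped,
    )
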