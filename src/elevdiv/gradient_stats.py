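"""Regression machinery for elevational diversity gradients.

Implements the species-area relationship (SAR) in the three classical
forms — linear (S ~ A), semilogarithmic (S ~ log A) and curvilinear
(log S ~ log A, the power law S = cA^z) — plus quadratic fits for null-model
comparison, AICc model selection with Akaike weights, a global SAR exponent
z pooled across gradients, power-law area correction of richness curves,
topographic-heterogeneity models, and a latitudinal model set with natural
model averaging.

Conventions
-----------
* Log transforms use base 10 (slopes of log-log fits are base-invariant, so
  z is unaffected).
* AICc counts the Gaussian error variance as an estimated parameter
  (``k = n_regressors + 1``), the small-sample convention of the ecological
  model-selection literature; ``AICc = AIC + 2k(k+1)/(n-k-1)``.
* AICc values of models with differently transformed responses (linear vs.
  log-log) are compared directly, as is customary in the SAR literature;
  strictly the likelihoods are not commensurable across response scales, so
  an optional Jacobian correction (``jacobian=True``) maps log-response
  likelihoods back to the raw-richness scale.  It is off by default.
* Adjusted r-squared is reported alongside r-squared and can be negative for
  uninformative fits; it is the headline statistic for SAR/TRI model tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .ranges import RichnessProfile

logger = logging.getLogger("elevdiv")

__all__ = [
    "FORMS",
    "RegressionFit",
    "ModelSet",
    "GlobalZ",
    "AveragedEstimates",
    "fit_form",
    "compare_models",
    "global_z",
    "area_correct",
    "tri_models",
    "sar_models",
    "latitude_models",
]

FORMS = ("linear", "semilog", "curvilinear", "quadratic")

LOG_X_FORMS = {"semilog", "curvilinear"}
LOG_Y_FORMS = {"curvilinear"}


@dataclass(frozen=True)
class RegressionFit:
    """One ordinary-least-squares fit on a stated transform of (x, y)."""

    form: str
    params: dict[str, float]
    bse: dict[str, float]
    n: int
    k: int  # estimated parameters incl. intercept and error variance
    r2: float
    adj_r2: float
    F: float
    df: tuple[int, int]
    p_value: float
    aicc: float
    label: str = ""
    excluded: int = 0  # rows dropped (non-positive under a log transform)

    @property
    def slope(self) -> float:
        """Coefficient of the (first-order) predictor."""
        for name, v in self.params.items():
            if name != "intercept" and not name.endswith("^2"):
                return v
        raise KeyError("fit has no slope parameter")

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted response on the original y scale."""
        x = np.asarray(x, dtype=float)
        xt = np.log10(x) if self.form in LOG_X_FORMS else x
        yhat = self.params["intercept"] + self.slope * xt
        if self.form == "quadratic":
            yhat = yhat + self.params["x^2"] * x**2
        if self.form in LOG_Y_FORMS:
            yhat = 10.0**yhat
        return yhat


@dataclass(frozen=True)
class ModelSet:
    """A collection of fits to the same response, compared by AICc."""

    fits: tuple[RegressionFit, ...]
    delta_aicc: tuple[float, ...]
    akaike_weight: tuple[float, ...]

    @property
    def best(self) -> RegressionFit:
        return self.fits[int(np.argmin(self.delta_aicc))]

    def __getitem__(self, form: str) -> RegressionFit:
        for f in self.fits:
            if f.form == form or f.label == form:
                return f
        raise KeyError(form)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fit, d, w in zip(self.fits, self.delta_aicc, self.akaike_weight):
            rows.append(
                {
                    "form": fit.label or fit.form,
                    "n": fit.n,
                    "k": fit.k,
                    "F": fit.F,
                    "df1": fit.df[0],
                    "df2": fit.df[1],
                    "p": fit.p_value,
                    "r2": fit.r2,
                    "adj_r2": fit.adj_r2,
                    "AICc": fit.aicc,
                    "delta": d,
                    "weight": w,
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class GlobalZ:
    """Pooled SAR exponent across gradients with significant power-law SARs."""

    z: float
    ci_low: float
    ci_high: float
    contributing: tuple[str, ...]


@dataclass(frozen=True)
class AveragedEstimates:
    """Natural model-averaged coefficients over an AICc-weighted model set."""

    estimates: dict[str, float]
    weights: dict[str, float] = field(default_factory=dict)


def _aicc_from_llf(llf: float, n: int, k: int) -> float:
    aic = 2 * k - 2 * llf
    if n - k - 1 <= 0:
        return float("inf")
    return aic + 2 * k * (k + 1) / (n - k - 1)


def _ols_fit(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    form: str,
    label: str,
    n_excluded: int = 0,
    llf_offset: float = 0.0,
) -> RegressionFit:
    res = sm.OLS(y, X).fit()
    n = len(y)
    k = X.shape[1] + 1  # + error variance
    degenerate = np.ptp(y) == 0  # zero-variance response: define r2 = 0
    if degenerate or np.isnan(res.fvalue):
        F, p, df = 0.0, float("nan"), (max(X.shape[1] - 1, 0), n - X.shape[1])
    else:
        F = float(res.fvalue)
        p = float(res.f_pvalue)
        df = (int(res.df_model), int(res.df_resid))
    return RegressionFit(
        form=form,
        params=dict(zip(names, map(float, res.params))),
        bse=dict(zip(names, map(float, res.bse))),
        n=n,
        k=k,
        r2=0.0 if degenerate else float(res.rsquared),
        adj_r2=0.0 if degenerate else float(res.rsquared_adj),
        F=F,
        df=df,
        p_value=p,
        aicc=_aicc_from_llf(float(res.llf) + llf_offset, n, k),
        label=label or form,
        excluded=n_excluded,
    )


def fit_form(
    x: np.ndarray,
    y: np.ndarray,
    form: str,
    *,
    on_nonpositive: str = "drop",
    jacobian: bool = False,
    label: str = "",
) -> RegressionFit:
    """OLS fit of y on x under one of the standard SAR transforms.

    Parameters
    ----------
    form
        ``linear`` (y ~ x), ``semilog`` (y ~ log10 x), ``curvilinear``
        (log10 y ~ log10 x; the power law) or ``quadratic`` (y ~ x + x^2).
    on_nonpositive
        ``drop`` removes rows with non-positive values under a log
        transform (logged); ``error`` raises.
    jacobian
        Apply the change-of-variables correction to the log-likelihood of
        log-response fits so AICc is on the raw-response scale.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    if form in LOG_X_FORMS:
        keep &= x > 0
    if form in LOG_Y_FORMS:
        keep &= y > 0
    n_excluded = int(len(x) - keep.sum())
    if n_excluded:
        if on_nonpositive == "error":
            raise ValueError(
                f"{form} fit: {n_excluded} rows non-finite or non-positive under log"
            )
        logger.info("%s fit: dropped %d rows (non-finite/non-positive)", form, n_excluded)
    x, y = x[keep], y[keep]
    if len(x) < 4:
        raise ValueError(f"{form} fit needs at least 4 usable observations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError(f"{form} fit: constant predictor")

    xt = np.log10(x) if form in LOG_X_FORMS else x
    yt = np.log10(y) if form in LOG_Y_FORMS else y
    if form == "quadratic":
        X = np.column_stack([np.ones_like(x), x, x**2])
        names = ["intercept", "x", "x^2"]
    else:
        X = np.column_stack([np.ones_like(xt), xt])
        names = ["intercept", "x"]
    llf_offset = 0.0
    if jacobian and form in LOG_Y_FORMS:
        llf_offset = -float(np.sum(np.log(y * np.log(10.0))))
    return _ols_fit(X, yt, names, form, label, n_excluded, llf_offset)


def compare_models(fits: Sequence[RegressionFit]) -> ModelSet:
    """Rank fits by AICc: delta-AICc and Akaike weights.

    ``w_i = exp(-delta_i / 2) / sum_j exp(-delta_j / 2)``.
    """
    if not fits:
        raise ValueError("no fits to compare")
    aicc = np.array([f.aicc for f in fits])
    best = aicc.min()
    if np.isneginf(best):  # perfect fit(s): all weight on them
        delta = np.where(np.isneginf(aicc), 0.0, np.inf)
    else:
        delta = aicc - best
    with np.errstate(over="ignore"):
        raw = np.exp(-delta / 2)
    if raw.sum() == 0:  # underflow: weight collapses onto the best model(s)
        raw = (delta == 0).astype(float)
    w = raw / raw.sum()
    return ModelSet(tuple(fits), tuple(map(float, delta)), tuple(map(float, w)))


def sar_models(
    richness: RichnessProfile | np.ndarray,
    area: np.ndarray,
    *,
    jacobian: bool = False,
) -> ModelSet:
    """Species-area model set: linear, semilog and curvilinear fits + AICc."""
    y = richness.counts if isinstance(richness, RichnessProfile) else np.asarray(richness)
    fits = [
        fit_form(area, y, form, jacobian=jacobian)
        for form in ("linear", "semilog", "curvilinear")
    ]
    return compare_models(fits)


def global_z(
    fits: Mapping[str, RegressionFit],
    alpha: float = 0.05,
) -> GlobalZ:
    """Global SAR exponent: mean curvilinear (log-log) slope across gradients
    with significant power-law SARs, with a t-based 95% CI.
    """
    contrib = {
        name: f
        for name, f in fits.items()
        if f.form == "curvilinear" and np.isfinite(f.p_value) and f.p_value < alpha
    }
    if len(contrib) < 2:
        raise ValueError(
            f"global z needs >= 2 gradients with significant curvilinear SARs "
            f"(got {len(contrib)}); use the per-gradient z instead"
        )
    slopes = np.array([f.slope for f in contrib.values()])
    m = float(slopes.mean())
    df = len(slopes) - 1
    se = slopes.std(ddof=1) / np.sqrt(len(slopes))
    tcrit = scipy.stats.t.ppf(1 - (1 - 0.95) / 2, df)
    return GlobalZ(m, m - tcrit * se, m + tcrit * se, tuple(contrib))


def area_correct(
    richness: RichnessProfile | np.ndarray,
    area: np.ndarray,
    z: float,
) -> np.ndarray:
    """Deflate a richness curve for unequal band areas via S = cA^z.

    ``corrected[i] = counts[i] / area[i]^z``, rescaled so the corrected
    curve's maximum equals the empirical maximum (shape-preserving; makes
    the correction invariant to a constant rescaling of all areas).
    """
    counts = (
        richness.counts if isinstance(richness, RichnessProfile) else np.asarray(richness)
    ).astype(float)
    area = np.asarray(area, dtype=float)
    if ((area <= 0) & (counts > 0)).any():
        raise ValueError("zero or negative band area with nonzero richness")
    corrected = np.zeros_like(counts)
    pos = area > 0
    corrected[pos] = counts[pos] / area[pos] ** z
    if corrected.max() > 0:
        corrected *= counts.max() / corrected.max()
    return corrected


def tri_models(
    richness: RichnessProfile | np.ndarray,
    tri: np.ndarray,
    area: np.ndarray | None = None,
    *,
    jacobian: bool = False,
) -> ModelSet:
    """Topographic-heterogeneity model set (linear/semilog/curvilinear + AICc).

    The predictor is the per-band mean TRI, or TRI / sqrt(area) when band
    areas are supplied (deflating ruggedness for band size).  Bands with
    missing TRI are dropped pairwise.
    """
    y = (
        richness.counts if isinstance(richness, RichnessProfile) else np.asarray(richness)
    ).astype(float)
    tri = np.asarray(tri, dtype=float)
    if area is not None:
        area = np.asarray(area, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            pred = np.where(area > 0, tri / np.sqrt(area), np.nan)
    else:
        pred = tri
    keep = np.isfinite(pred) & np.isfinite(y)
    if keep.sum() < 4:
        raise ValueError(f"TRI models need >= 4 usable bands, got {int(keep.sum())}")
    fits = [
        fit_form(pred[keep], y[keep], form, jacobian=jacobian)
        for form in ("linear", "semilog", "curvilinear")
    ]
    return compare_models(fits)


# ---------------------------------------------------------------------------
# Latitudinal model set with natural model averaging

_LAT_MODELS: dict[str, tuple[str, ...]] = {
    "latitude": ("latitude",),
    "latitude+elevation": ("latitude", "elevation"),
    "latitude+tri": ("latitude", "tri"),
    "intercept-only": (),
}


def latitude_models(
    table: pd.DataFrame,
    *,
    signed_latitude: bool = False,
) -> tuple[ModelSet, AveragedEstimates]:
    """Latitudinal regression set over mountain ranges + model averaging.

    ``table`` holds one row per mountain range with columns ``richness``,
    ``mid_latitude`` (decimal degrees), ``mean_tri`` (m) and
    ``mid_elevation`` (m).  Four models are fitted: richness ~ latitude,
    ~ latitude + elevation, ~ latitude + TRI, and intercept-only, compared
    by AICc.  Latitude enters as absolute degrees from the equator unless
    ``signed_latitude``.

    Coefficients are model-averaged naturally: a parameter is averaged only
    over the models that contain it, with those models' Akaike weights
    renormalized.
    """
    required = {"richness", "mid_latitude", "mean_tri", "mid_elevation"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"latitude table missing columns: {sorted(missing)}")
    if len(table) < 5:
        raise ValueError(f"latitude models need >= 5 mountain ranges, got {len(table)}")
    y = table["richness"].to_numpy(dtype=float)
    predictors = {
        "latitude": (
            table["mid_latitude"].to_numpy(dtype=float)
            if signed_latitude
            else np.abs(table["mid_latitude"].to_numpy(dtype=float))
        ),
        "tri": table["mean_tri"].to_numpy(dtype=float),
        "elevation": table["mid_elevation"].to_numpy(dtype=float),
    }

    fits = []
    for label, terms in _LAT_MODELS.items():
        X = np.column_stack([np.ones(len(y))] + [predictors[t] for t in terms])
        names = ["intercept", *terms]
        if np.linalg.matrix_rank(X) < X.shape[1]:
            warnings.warn(f"model {label!r}: collinear predictors")
        fits.append(_ols_fit(X, y, names, form="linear", label=label))
    mset = compare_models(fits)

    estimates: dict[str, float] = {}
    for param in ("intercept", "latitude", "tri", "elevation"):
        idx = [i for i, f in enumerate(mset.fits) if param in f.params]
        if not idx:
            continue
        # renormalize within the containing subset via delta differences —
        # numerically stable even when all subset weights underflowed to 0
        d = np.array([mset.delta_aicc[i] for i in idx])
        with np.errstate(over="ignore", invalid="ignore"):
            w = np.exp(-(d - d.min()) / 2)
        w[~np.isfinite(w)] = 0.0
        if w.sum() == 0:
            w = (d == d.min()).astype(float)
        w = w / w.sum()
        est = np.array([mset.fits[i].params[param] for i in idx])
        estimates[param] = float(np.sum(w * est))
    weights = {f.label: w for f, w in zip(mset.fits, mset.akaike_weight)}
    return mset, AveragedEstimates(estimates, weights)
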