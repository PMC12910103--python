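"""Acoustic-to-CTD matching and GAMs of mean Sv against environmental drivers.

The driver models regress layer-mean volume backscattering strength on
hydrography with identity link and Gaussian errors:

    Sv18 = Temp + s(Chla) + s(O2) + Sal + s(PAR) + Location + e
    Sv38 = Temp + s(Chla) + s(O2) + Sal + PAR    + Location + e

where s() are penalized cubic B-spline smooths (basis dimension 10,
smoothing parameter by generalized cross-validation) and Location is a
three-level region factor.  Predictors are z-scored before fitting; the
response stays in dB.  Candidate models are compared by AIC.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam
from statsmodels.stats.diagnostic import het_breuschpagan

from .io import CTDStation, ValidationError
from .preprocess import IntegrationGrid, db_to_linear, haversine_nmi, linear_to_db
from .dvm import classify_diel, solar_altitude

logger = logging.getLogger("sslseascape")

PREDICTORS = ["temperature", "salinity", "oxygen", "chlorophyll_a", "par"]

# term structure per response frequency
MODEL_TERMS = {
    "sv18": {"linear": ["temperature", "salinity"], "smooth": ["chlorophyll_a", "oxygen", "par"]},
    "sv38": {"linear": ["temperature", "salinity", "par"], "smooth": ["chlorophyll_a", "oxygen"]},
}


def match_acoustic_to_ctd(
    grids: dict[int, IntegrationGrid],
    stations: list[CTDStation],
    radius_nmi: float = 0.1,
    threshold_db: float = -70.0,
) -> pd.DataFrame:
    """Aggregate SSL backscatter around each CTD station and sample its profiles.

    For each station, integration columns within ``radius_nmi`` (great
    circle) are pooled; the per-frequency Sv is the linear-domain mean over
    the above-threshold cells of those columns, and each environmental
    predictor is the station profile's mean over the depth span of those
    cells.  Stations with no matched column or no above-threshold cell are
    skipped with a log message; if nothing matches at all an error reports
    the closest approach.
    """
    g_ref = next(iter(grids.values()))
    rows = []
    min_dist = np.inf
    for st in stations:
        dist = haversine_nmi(st.latitude, st.longitude, g_ref.cell_lat, g_ref.cell_lon)
        min_dist = min(min_dist, float(np.min(dist)))
        cols = np.nonzero(dist <= radius_nmi)[0]
        if len(cols) == 0:
            logger.info("match_acoustic_to_ctd: station %s has no column within %.3f nmi", st.station_id, radius_nmi)
            continue
        row: dict = {"station_id": st.station_id, "location": st.station_id.split("-")[0]}
        span_min, span_max = np.inf, -np.inf
        ok = True
        for freq, g in grids.items():
            sub = g.cell_sv[:, cols]
            use = np.isfinite(sub) & (sub >= threshold_db)
            if not use.any():
                ok = False
                break
            row[f"sv{freq}"] = float(linear_to_db(np.mean(db_to_linear(sub[use]))))
            zsel = g.depth_bins[np.nonzero(use.any(axis=1))[0]]
            span_min = min(span_min, float(zsel.min()))
            span_max = max(span_max, float(zsel.max()))
        if not ok:
            logger.info("match_acoustic_to_ctd: station %s has no above-threshold cell", st.station_id)
            continue
        zgrid = np.linspace(span_min, span_max, 50)
        for name in PREDICTORS:
            row[name] = float(np.mean(np.interp(zgrid, st.depth_axis, st.profile(name))))
        if st.turbidity is not None:
            row["turbidity"] = float(np.mean(np.interp(zgrid, st.depth_axis, st.turbidity)))
        alt = solar_altitude(st.time, st.latitude, st.longitude)
        row["diel"] = classify_diel(alt)
        rows.append(row)
    if not rows:
        raise ValidationError(
            f"no CTD station matched any acoustic column (closest approach {min_dist:.3f} nmi)"
        )
    return pd.DataFrame(rows)


def screen_collinearity(
    records: pd.DataFrame, r_flag: float = 0.8, columns: list[str] | None = None
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pairwise Pearson correlations among predictors; |r| >= r_flag is flagged.

    Flagging is advisory: which flagged variables are excluded is a config
    decision (by default turbidity, a physical proxy collinear with
    chlorophyll-a, is dropped while temperature-oxygen is retained).
    Constant columns yield NaN correlations and are flagged as undefined.
    """
    cols = columns or [c for c in records.columns if c in PREDICTORS + ["turbidity"]]
    if len(records) < 3:
        raise ValidationError("need at least 3 records")
    sub = records[cols].astype(float)
    corr = sub.corr(method="pearson")
    flags = []
    for i, a in enumerate(cols):
        if sub[a].std() == 0:
            flags.append((a, a, np.nan))
        for b in cols[i + 1:]:
            r = corr.loc[a, b]
            if np.isnan(r) or abs(r) >= r_flag:
                flags.append((a, b, float(r)))
    return corr, flags


@dataclass
class GAMResult:
    """Fitted driver model: per-term tests, fit statistics, diagnostics inputs."""

    response: str
    terms: pd.DataFrame  # name, kind, estimate (linear only), p_value
    deviance_explained: float  # percent
    aic: float
    fitted: np.ndarray
    residuals: np.ndarray
    alpha: np.ndarray  # smoothing parameters actually used
    _smoother: BSplines = field(repr=False, default=None)
    _params: np.ndarray = field(repr=False, default=None)
    _k_linear: int = field(repr=False, default=0)
    _standardizers: dict = field(repr=False, default=None)

    def smooth_curve(self, name: str, x: np.ndarray) -> np.ndarray:
        """Fitted partial effect of a smooth term on the original predictor scale."""
        idx = self._smooth_names.index(name)
        mu, sd = self._standardizers[name]
        xz = (np.asarray(x, dtype=float) - mu) / sd
        smoother = self._smoother.smoothers[idx]
        basis = smoother.transform(xz)
        mask = self._smoother.mask[idx]
        coefs = self._params[self._k_linear:][mask]
        return basis @ coefs

    _smooth_names: list = field(default_factory=list, repr=False)


def _zscore_frame(records: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, dict]:
    standardizers = {}
    out = pd.DataFrame(index=records.index)
    for c in cols:
        v = records[c].astype(float)
        mu, sd = float(v.mean()), float(v.std(ddof=0))
        if sd == 0:
            raise ValidationError(f"predictor {c!r} is constant")
        out[c] = (v - mu) / sd
        standardizers[c] = (mu, sd)
    return out, standardizers


def fit_gam(
    records: pd.DataFrame,
    response: str = "sv18",
    linear_terms: list[str] | None = None,
    smooth_terms: list[str] | None = None,
    spline_df: int = 10,
    select_smoothing: bool = True,
) -> GAMResult:
    """Fit the Sv driver GAM (identity link, Gaussian errors) for one frequency.

    Continuous predictors are z-scored; ``location`` enters as treatment-coded
    dummies.  Smooths are cubic B-splines of basis dimension ``spline_df``
    with the penalty weight chosen by generalized cross-validation
    (``select_smoothing=False`` keeps a fixed mild penalty).  Per-term
    p-values are Wald tests on the coefficient (blocks).
    """
    spec = MODEL_TERMS.get(response, {})
    linear_terms = list(linear_terms if linear_terms is not None else spec.get("linear", []))
    smooth_terms = list(smooth_terms if smooth_terms is not None else spec.get("smooth", []))
    n = len(records)
    n_terms = len(linear_terms) + len(smooth_terms) + (1 if "location" in records.columns else 0)
    if n < 10 * max(n_terms, 1):
        logger.warning("fit_gam: only %d records for %d terms (rule of thumb wants %d)", n, n_terms, 10 * n_terms)

    y = records[response].to_numpy(dtype=float)
    zframe, standardizers = _zscore_frame(records, linear_terms + smooth_terms)

    exog = pd.DataFrame({"const": np.ones(n)}, index=records.index)
    for c in linear_terms:
        exog[c] = zframe[c]
    loc_levels: list[str] = []
    if "location" in records.columns:
        dummies = pd.get_dummies(records["location"].astype(str), prefix="location", drop_first=True, dtype=float)
        loc_levels = list(dummies.columns)
        exog = pd.concat([exog, dummies], axis=1)

    x_smooth = zframe[smooth_terms].to_numpy() if smooth_terms else None
    smoother = None
    if smooth_terms:
        smoother = BSplines(
            x_smooth,
            df=[spline_df] * len(smooth_terms),
            degree=[3] * len(smooth_terms),
            include_intercept=False,
            variable_names=smooth_terms,
        )
    exog_arr = exog.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(exog_arr)
    if rank < exog_arr.shape[1]:
        raise ValidationError(f"rank-deficient design among terms {list(exog.columns)}")

    alpha = np.ones(len(smooth_terms)) if smooth_terms else None
    model = GLMGam(y, exog=exog_arr, smoother=smoother, alpha=alpha)
    if smooth_terms and select_smoothing:
        try:
            if not hasattr(model, "scale"):  # select_penweight expects the attribute pre-set
                model.scale = None
            alpha = np.asarray(model.select_penweight(criterion="gcv", method="minimize")[0], dtype=float)
            model = GLMGam(y, exog=exog_arr, smoother=smoother, alpha=alpha)
        except Exception as exc:  # numerical failure: keep the mild default penalty
            logger.warning("fit_gam: GCV penalty selection failed (%s); using default alpha", exc)
    res = model.fit()

    k_lin = exog_arr.shape[1]
    rows = []
    pvalues = res.pvalues
    for idx, name in enumerate(exog.columns):
        if name == "const":
            continue
        kind = "factor" if name.startswith("location_") else "linear"
        rows.append({"term": name, "kind": kind, "estimate": float(res.params[idx]), "p_value": float(pvalues[idx])})
    with warnings.catch_warnings():
        # penalized smooth blocks give reduced-rank constraint covariances by design
        warnings.simplefilter("ignore")
        if loc_levels:
            # joint Wald test for the location factor
            R = np.zeros((len(loc_levels), len(res.params)))
            for r, name in enumerate(loc_levels):
                R[r, list(exog.columns).index(name)] = 1.0
            wt = res.wald_test(R, scalar=True)
            rows.append({"term": "location", "kind": "factor_joint", "estimate": np.nan, "p_value": float(wt.pvalue)})
        if smooth_terms:
            for i, name in enumerate(smooth_terms):
                mask = smoother.mask[i]
                idxs = k_lin + np.nonzero(mask)[0]
                R = np.zeros((len(idxs), len(res.params)))
                for r, c in enumerate(idxs):
                    R[r, c] = 1.0
                wt = res.wald_test(R, scalar=True)
                rows.append({"term": name, "kind": "smooth", "estimate": np.nan, "p_value": float(wt.pvalue)})

    fitted = np.asarray(res.fittedvalues, dtype=float)
    resid = y - fitted
    null_dev = float(np.sum((y - y.mean()) ** 2))
    dev = float(np.sum(resid**2))
    dev_expl = float(np.clip(100.0 * (1.0 - dev / null_dev), 0.0, 100.0)) if null_dev > 0 else np.nan

    result = GAMResult(
        response=response,
        terms=pd.DataFrame(rows),
        deviance_explained=dev_expl,
        aic=float(res.aic),
        fitted=fitted,
        residuals=resid,
        alpha=np.asarray(alpha) if alpha is not None else np.array([]),
        _smoother=smoother,
        _params=np.asarray(res.params),
        _k_linear=k_lin,
        _standardizers=standardizers,
    )
    result._smooth_names = smooth_terms
    return result


def diagnostics(result: GAMResult) -> dict:
    """Residual checks: Shapiro-Wilk normality and Breusch-Pagan heteroscedasticity."""
    resid = result.residuals
    out: dict = {}
    if np.allclose(resid, 0):
        out["degenerate"] = True
        out["shapiro_p"] = np.nan
        out["breusch_pagan_p"] = np.nan
        logger.warning("diagnostics: residuals are identically zero")
        return out
    out["degenerate"] = False
    if len(resid) < 8:
        logger.warning("diagnostics: too few residuals for reliable tests")
    sw = stats.shapiro(resid if len(resid) <= 5000 else resid[:5000])
    out["shapiro_w"] = float(sw.statistic)
    out["shapiro_p"] = float(sw.pvalue)
    exog = np.column_stack([np.ones_like(result.fitted), result.fitted])
    lm, lm_p, _, _ = het_breuschpagan(resid, exog)
    out["breusch_pagan_lm"] = float(lm)
    out["breusch_pagan_p"] = float(lm_p)
    out["resid_vs_fitted_slope"] = float(np.polyfit(result.fitted, resid, 1)[0]) if np.std(result.fitted) > 0 else np.nan
    return out
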