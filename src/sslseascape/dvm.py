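"""Diel classification, day/night vertical profiles, weighted mean depth.

Day and night are defined astronomically: a ping (or integration column) is
*day* when the sun stands more than +18 degrees above the horizon, *night*
below -18 degrees, and *transition* in between (astronomical twilight), the
crepuscular window during which migrating scatterers are in transit and are
excluded from diel contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError
from .preprocess import IntegrationGrid, db_to_linear, linear_to_db

DAY = "day"
NIGHT = "night"
TRANSITION = "transition"


def solar_altitude(time, lat, lon) -> np.ndarray | float:
    """Geometric solar altitude in degrees above the horizon.

    NOAA low-accuracy ephemeris (fractional-year formulation): equation of
    time and declination from a truncated Fourier series in the fractional
    year, then the altitude from the hour angle.  Accuracy is a few tenths of
    a degree, ample against an 18-degree twilight threshold; atmospheric
    refraction is ignored.

    Parameters
    ----------
    time : datetime64, scalar or array
        UTC instant(s).
    lat, lon : float or array
        Decimal degrees; longitude positive eastward.
    """
    t = np.asarray(time, dtype="datetime64[ns]")
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    lat = np.broadcast_to(np.asarray(lat, dtype=float), t.shape)
    lon = np.broadcast_to(np.asarray(lon, dtype=float), t.shape)

    ts = pd.DatetimeIndex(t)
    doy = ts.dayofyear.to_numpy()
    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0 + ts.second.to_numpy() / 3600.0 \
        + ts.microsecond.to_numpy() / 3.6e9
    n_days = np.where(np.asarray(ts.is_leap_year), 366.0, 365.0)

    gamma = 2.0 * np.pi / n_days * (doy - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (
        0.000075
        + 0.001868 * np.cos(gamma)
        - 0.032077 * np.sin(gamma)
        - 0.014615 * np.cos(2 * gamma)
        - 0.040849 * np.sin(2 * gamma)
    )
    decl = (
        0.006918
        - 0.399912 * np.cos(gamma)
        + 0.070257 * np.sin(gamma)
        - 0.006758 * np.cos(2 * gamma)
        + 0.000907 * np.sin(2 * gamma)
        - 0.002697 * np.cos(3 * gamma)
        + 0.00148 * np.sin(3 * gamma)
    )
    time_offset = eqtime + 4.0 * lon  # minutes
    tst = hours * 60.0 + time_offset  # true solar time, minutes
    ha = np.deg2rad(tst / 4.0 - 180.0)  # hour angle

    lat_r = np.deg2rad(lat)
    sin_alt = np.sin(lat_r) * np.sin(decl) + np.cos(lat_r) * np.cos(decl) * np.cos(ha)
    alt = np.rad2deg(np.arcsin(np.clip(sin_alt, -1.0, 1.0)))
    return float(alt[0]) if scalar else alt


def classify_diel(altitude, threshold: float = 18.0) -> np.ndarray | str:
    """Map solar altitude(s) to {day, night, transition}.

    Strict inequalities: an altitude of exactly +-threshold is *transition*.
    """
    alt = np.asarray(altitude, dtype=float)
    scalar = alt.ndim == 0
    alt = np.atleast_1d(alt)
    out = np.full(alt.shape, TRANSITION, dtype=object)
    out[alt > threshold] = DAY
    out[alt < -threshold] = NIGHT
    return str(out[0]) if scalar else out


def column_diel_labels(g: IntegrationGrid, threshold: float = 18.0) -> np.ndarray:
    """Diel label per integration column, from the column's mean time and position."""
    alt = solar_altitude(g.cell_time, g.cell_lat, g.cell_lon)
    return classify_diel(alt, threshold)


@dataclass
class VerticalProfile:
    """Day and night mean Sv per 1 m depth bin plus their difference."""

    depth_bins: np.ndarray  # bin-centre depths, m
    mean_sv_day: np.ndarray  # dB
    mean_sv_night: np.ndarray  # dB
    delta: np.ndarray  # dB, night minus day
    n_day: np.ndarray
    n_night: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "depth_m": self.depth_bins,
                "mean_sv_day_db": self.mean_sv_day,
                "mean_sv_night_db": self.mean_sv_night,
                "delta_night_day_db": self.delta,
                "n_day": self.n_day,
                "n_night": self.n_night,
            }
        )


def mean_profiles(g: IntegrationGrid, labels: np.ndarray, domain: str = "linear") -> VerticalProfile:
    """Per-depth-bin day and night mean Sv and their night-minus-day difference.

    Transition columns are excluded.  Means are taken in the linear intensity
    domain by default (energy averaging); ``domain='db'`` averages dB values
    directly for comparison.
    """
    labels = np.asarray(labels)
    day_cols = labels == DAY
    night_cols = labels == NIGHT
    if not day_cols.any() or not night_cols.any():
        raise ValidationError("need at least one day and one night column")

    def _bin_mean(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = g.cell_sv[:, cols]
        n = np.isfinite(sub).sum(axis=1)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-missing bins yield NaN
            if domain == "linear":
                mean = linear_to_db(np.nanmean(db_to_linear(sub), axis=1))
            elif domain == "db":
                mean = np.nanmean(sub, axis=1)
            else:
                raise ValueError("domain must be 'linear' or 'db'")
        mean = np.where(n > 0, mean, np.nan)
        return mean, n

    mday, nday = _bin_mean(day_cols)
    mnight, nnight = _bin_mean(night_cols)
    return VerticalProfile(
        depth_bins=g.depth_bins.copy(),
        mean_sv_day=mday,
        mean_sv_night=mnight,
        delta=mnight - mday,
        n_day=nday,
        n_night=nnight,
    )


@dataclass
class WMDSeries:
    """Backscatter-weighted mean depth per integration column."""

    wmd: np.ndarray  # m, NaN where a column is empty
    time: np.ndarray  # datetime64 per column
    lat: np.ndarray
    lon: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "lat": self.lat, "lon": self.lon, "wmd_m": self.wmd})


def compute_wmd(g: IntegrationGrid, threshold_db: float | None = None) -> WMDSeries:
    """Weighted mean depth per column: sum(z_i s_i)/sum(s_i) with s_i linear Sv.

    A proxy for the depth of greatest acoustic density.  All non-missing
    cells enter by default; pass ``threshold_db`` to restrict to cells at or
    above an extraction threshold.  Columns with no usable cell yield NaN.
    """
    sv = g.cell_sv
    use = np.isfinite(sv)
    if threshold_db is not None:
        use = use & (sv >= threshold_db)
    lin = np.where(use, db_to_linear(np.where(use, sv, 0.0)), 0.0)
    wsum = lin.sum(axis=0)
    zsum = (g.depth_bins[:, None] * lin).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        wmd = np.where(wsum > 0, zsum / wsum, np.nan)
    return WMDSeries(wmd=wmd, time=g.cell_time.copy(), lat=g.cell_lat.copy(), lon=g.cell_lon.copy())


def cross_frequency_validation(
    wmd18: WMDSeries,
    wmd38: WMDSeries,
    labels: np.ndarray,
    time_tolerance_s: float = 1.0,
) -> dict:
    """Pearson correlation of paired 18/38 kHz WMDs and per-frequency DVM amplitude.

    The series must share a common column timebase (within ``time_tolerance_s``).
    DVM amplitude is mean night WMD minus mean day WMD for each frequency.
    """
    if len(wmd18.wmd) != len(wmd38.wmd):
        raise ValidationError("WMD series have different lengths")
    dt = np.abs((wmd18.time - wmd38.time).astype("timedelta64[ns]").astype(np.int64)) / 1e9
    if np.any(dt > time_tolerance_s):
        raise ValidationError("WMD series timebases differ beyond tolerance")
    ok = np.isfinite(wmd18.wmd) & np.isfinite(wmd38.wmd)
    x, y = wmd18.wmd[ok], wmd38.wmd[ok]
    if len(x) < 3:
        raise ValidationError("need at least 3 paired WMDs")
    result: dict = {}
    if np.std(x) == 0 or np.std(y) == 0:
        result["pearson_r"] = np.nan
        result["zero_variance"] = True
    else:
        result["pearson_r"] = float(stats.pearsonr(x, y).statistic)
        result["zero_variance"] = False
    labels = np.asarray(labels)
    for name, series in (("18", wmd18), (("38"), wmd38)):
        day = series.wmd[(labels == DAY) & np.isfinite(series.wmd)]
        night = series.wmd[(labels == NIGHT) & np.isfinite(series.wmd)]
        amp = float(np.mean(night) - np.mean(day)) if len(day) and len(night) else np.nan
        result[f"amplitude_day_night_{name}"] = amp
    return result
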