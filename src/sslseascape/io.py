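"""Data model and file formats for echograms, CTD stations, layer tables and config.

Depth convention used throughout the package: metres below the sea surface,
positive downward.  A depth axis stores *bin centres* on a uniform grid; the
bin covering centre ``z`` is the half-open interval ``[z - dz/2, z + dz/2)``.
Missing backscatter samples are encoded as NaN and excluded from every mean.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

logger = logging.getLogger("sslseascape")

MISSING = np.nan

LAYER_TABLE_COLUMNS = [
    "layer_id",
    "frequency_khz",
    "date",
    "min_depth_m",
    "max_depth_m",
    "width_m",
    "length_m",
    "mean_sv_db",
    "diel",
]


class FormatError(ValueError):
    """A required column or field is absent or malformed."""


class ValidationError(ValueError):
    """Data violate a structural invariant (shapes, ranges, monotonicity)."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional")
    return arr


@dataclass
class Echogram:
    """A depth x ping matrix of volume backscattering strength Sv (dB re 1 m-1).

    Parameters
    ----------
    frequency_khz : float
        Echosounder frequency.
    depth_axis : array of float
        Bin-centre depths in metres, strictly increasing, uniform step.
    ping_times : array of datetime64
        UTC instants, non-decreasing, one per ping.
    latitude, longitude : array of float
        Per-ping position in decimal degrees.
    sv : 2-D array of float
        Sv in dB, shape ``(len(depth_axis), len(ping_times))``; NaN marks
        missing samples.
    """

    frequency_khz: float
    depth_axis: np.ndarray
    ping_times: np.ndarray
    latitude: np.ndarray
    longitude: np.ndarray
    sv: np.ndarray

    def __post_init__(self) -> None:
        self.depth_axis = _as_float_array(self.depth_axis, "depth_axis")
        self.ping_times = np.asarray(self.ping_times, dtype="datetime64[ns]")
        self.latitude = _as_float_array(self.latitude, "latitude")
        self.longitude = _as_float_array(self.longitude, "longitude")
        self.sv = np.asarray(self.sv, dtype=float)
        self.validate()

    # ---- invariants -------------------------------------------------
    def validate(self) -> None:
        nz, nping = len(self.depth_axis), len(self.ping_times)
        if self.sv.shape != (nz, nping):
            raise ValidationError(
                f"sv shape {self.sv.shape} != (n_depth={nz}, n_ping={nping})"
            )
        steps = np.diff(self.depth_axis)
        if nz > 1:
            if not np.all(steps > 0):
                raise ValidationError("depth_axis must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ValidationError("depth_axis must have a uniform step")
        if self.depth_axis[0] < 0:
            raise ValidationError("depth_axis[0] must be >= 0 (metres below surface)")
        if np.any(np.diff(self.ping_times).astype("timedelta64[ns]").astype(np.int64) < 0):
            raise ValidationError("ping_times must be non-decreasing")
        if len(self.latitude) != nping or len(self.longitude) != nping:
            raise ValidationError("positions must have one entry per ping")
        if np.any(np.abs(self.latitude) > 90) or np.any(np.abs(self.longitude) > 180):
            raise ValidationError("positions outside [-90,90]x[-180,180]")
        finite_or_nan = np.isfinite(self.sv) | np.isnan(self.sv)
        if not np.all(finite_or_nan):
            raise ValidationError("non-missing sv must be finite")

    @property
    def depth_step(self) -> float:
        if len(self.depth_axis) > 1:
            return float(self.depth_axis[1] - self.depth_axis[0])
        return 1.0

    @property
    def n_pings(self) -> int:
        return len(self.ping_times)


@dataclass
class CTDStation:
    """One CTD cast: position/time plus vertical profiles of five variables."""

    station_id: str
    latitude: float
    longitude: float
    time: np.datetime64
    depth_axis: np.ndarray
    temperature: np.ndarray  # degC
    salinity: np.ndarray  # PSU
    oxygen: np.ndarray  # umol kg-1
    chlorophyll_a: np.ndarray  # ug m-3
    par: np.ndarray  # umol m-2 s-1
    turbidity: np.ndarray | None = None  # arbitrary units, optional

    def __post_init__(self) -> None:
        self.depth_axis = _as_float_array(self.depth_axis, "depth_axis")
        for name in ("temperature", "salinity", "oxygen", "chlorophyll_a", "par"):
            arr = _as_float_array(getattr(self, name), name)
            setattr(self, name, arr)
            if len(arr) != len(self.depth_axis):
                raise ValidationError(f"{name} length != depth_axis length")
        if self.turbidity is not None:
            self.turbidity = _as_float_array(self.turbidity, "turbidity")
            if len(self.turbidity) != len(self.depth_axis):
                raise ValidationError("turbidity length != depth_axis length")
        self.time = np.datetime64(self.time, "ns")
        if np.any(self.oxygen < 0):
            raise ValidationError("oxygen must be >= 0")
        if np.any((self.salinity <= 0) | (self.salinity >= 45)):
            raise ValidationError("salinity must be in (0, 45) PSU")
        if np.any(self.par < 0):
            raise ValidationError("par must be >= 0")

    def profile(self, variable: str) -> np.ndarray:
        return getattr(self, variable)


_CONFIG_FIELDS: dict[str, type] = {}


@dataclass
class PipelineConfig:
    """Resolved pipeline parameters; defaults are the study's processing constants."""

    threshold_db: float = -70.0
    surface_offset_m: float = 10.0
    integration_distance_nmi: float = 0.1
    depth_bin_m: float = 1.0
    diel_altitude_deg: float = 18.0
    k_range: tuple[int, int] = (2, 8)
    rng_seed: int = 0
    cluster_unit: str = "per_day"  # or "per_layer"
    min_cells: int = 5
    jaccard_threshold: float = 0.25
    n_init: int = 20
    ctd_match_radius_nmi: float = 0.1
    collinearity_r: float = 0.8
    exclude_predictors: tuple[str, ...] = ("turbidity",)

    def __post_init__(self) -> None:
        if not self.threshold_db < 0:
            raise ValidationError("threshold_db must be < 0 dB")
        if self.surface_offset_m < 0:
            raise ValidationError("surface_offset_m must be >= 0")
        self.k_range = tuple(int(k) for k in self.k_range)
        if len(self.k_range) != 2 or self.k_range[0] < 2 or self.k_range[1] < self.k_range[0]:
            raise ValidationError("k_range must be (min>=2, max>=min)")
        if self.cluster_unit not in ("per_day", "per_layer"):
            raise ValidationError("cluster_unit must be per_day or per_layer")
        self.exclude_predictors = tuple(self.exclude_predictors)


_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file, apply defaults and validate.

    Unknown keys raise :class:`FormatError` to guard against typos; the fully
    resolved configuration is echoed to the package logger.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a mapping of key: value")
    # one level of nesting is allowed and flattened (sections are cosmetic)
    flat: dict = {}
    for key, value in raw.items():
        if isinstance(value, dict):
            for sub, subval in value.items():
                flat[sub] = subval
        else:
            flat[key] = value
    unknown = set(flat) - set(_CONFIG_FIELDS)
    if unknown:
        raise FormatError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    for key, value in flat.items():
        fld = _CONFIG_FIELDS[key]
        try:
            if key == "k_range":
                value = tuple(int(v) for v in value)
            elif key == "exclude_predictors":
                value = tuple(str(v) for v in value)
            elif fld.type in ("float",):
                value = float(value)
            elif fld.type in ("int",):
                value = int(value)
            elif fld.type in ("str",):
                value = str(value)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"config key {key!r}: cannot coerce {value!r}") from exc
        if fld.type == "float" and not isinstance(value, (int, float)):
            raise FormatError(f"config key {key!r}: expected a number, got {value!r}")
        kwargs[key] = value
    cfg = PipelineConfig(**kwargs)
    logger.info("resolved config: %s", dataclasses.asdict(cfg))
    return cfg


# ---------------------------------------------------------------------------
# Echogram I/O
# ---------------------------------------------------------------------------

_LONG_CSV_COLUMNS = ["ping_time", "lat", "lon", "depth_m", "sv_db"]


def read_echogram(path: str | Path, dialect: str = "long_csv", frequency_khz: float = 38.0) -> Echogram:
    """Read an echogram from a long-format CSV or a gridded netCDF container."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_csv":
        return _read_long_csv(path, frequency_khz)
    if dialect == "gridded_netcdf":
        return _read_gridded(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long_csv(path: Path, frequency_khz: float) -> Echogram:
    df = pd.read_csv(path)
    for col in _LONG_CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    df["ping_time"] = pd.to_datetime(df["ping_time"], utc=True).dt.tz_localize(None)
    pivot = df.pivot_table(index="depth_m", columns="ping_time", values="sv_db", aggfunc="mean")
    depth_axis = pivot.index.to_numpy(dtype=float)
    ping_times = pivot.columns.to_numpy(dtype="datetime64[ns]")
    pos = df.groupby("ping_time")[["lat", "lon"]].mean().reindex(pd.Index(ping_times, name="ping_time"))
    n_missing = int(pivot.isna().to_numpy().sum())
    if n_missing:
        logger.info("read_echogram: %d missing sv samples flagged", n_missing)
    return Echogram(
        frequency_khz=frequency_khz,
        depth_axis=depth_axis,
        ping_times=ping_times,
        latitude=pos["lat"].to_numpy(),
        longitude=pos["lon"].to_numpy(),
        sv=pivot.to_numpy(dtype=float),
    )


def _read_gridded(path: Path) -> Echogram:
    with xr.open_dataset(path, engine="scipy") as ds:
        return Echogram(
            frequency_khz=float(ds.attrs.get("frequency_khz", 38.0)),
            depth_axis=ds["depth"].values.astype(float),
            ping_times=ds["time"].values.astype("datetime64[ns]"),
            latitude=ds["lat"].values.astype(float),
            longitude=ds["lon"].values.astype(float),
            sv=ds["sv"].values.astype(float),
        )


def write_echogram(e: Echogram, path: str | Path, dialect: str = "long_csv") -> None:
    """Write an echogram; ``long_csv`` is the canonical interchange format."""
    path = Path(path)
    if dialect == "long_csv":
        nz, nping = e.sv.shape
        times = np.repeat(pd.Series(e.ping_times).dt.strftime("%Y-%m-%dT%H:%M:%S.%f").to_numpy()[None, :], nz, axis=0)
        df = pd.DataFrame(
            {
                "ping_time": times.ravel(),
                "lat": np.repeat(e.latitude[None, :], nz, axis=0).ravel(),
                "lon": np.repeat(e.longitude[None, :], nz, axis=0).ravel(),
                "depth_m": np.repeat(e.depth_axis[:, None], nping, axis=1).ravel(),
                "sv_db": e.sv.ravel(),
            }
        )
        df.to_csv(path, index=False)
    elif dialect == "gridded_netcdf":
        ds = xr.Dataset(
            {"sv": (("depth", "time"), e.sv)},
            coords={
                "depth": e.depth_axis,
                "time": e.ping_times,
                "lat": ("time", e.latitude),
                "lon": ("time", e.longitude),
            },
            attrs={"frequency_khz": e.frequency_khz},
        )
        ds.to_netcdf(path, engine="scipy")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# CTD I/O (long CSV: one row per station x depth)
# ---------------------------------------------------------------------------

_CTD_COLUMNS = [
    "station_id", "lat", "lon", "time", "depth_m",
    "temperature", "salinity", "oxygen", "chlorophyll_a", "par",
]


def write_ctd(stations: Sequence[CTDStation], path: str | Path) -> None:
    rows = []
    for st in stations:
        for i, z in enumerate(st.depth_axis):
            row = {
                "station_id": st.station_id,
                "lat": st.latitude,
                "lon": st.longitude,
                "time": pd.Timestamp(st.time).strftime("%Y-%m-%dT%H:%M:%S"),
                "depth_m": z,
                "temperature": st.temperature[i],
                "salinity": st.salinity[i],
                "oxygen": st.oxygen[i],
                "chlorophyll_a": st.chlorophyll_a[i],
                "par": st.par[i],
            }
            if st.turbidity is not None:
                row["turbidity"] = st.turbidity[i]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_ctd(path: str | Path) -> list[CTDStation]:
    df = pd.read_csv(path)
    for col in _CTD_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    stations = []
    for sid, g in df.groupby("station_id", sort=False):
        g = g.sort_values("depth_m")
        stations.append(
            CTDStation(
                station_id=str(sid),
                latitude=float(g["lat"].iloc[0]),
                longitude=float(g["lon"].iloc[0]),
                time=np.datetime64(pd.to_datetime(g["time"].iloc[0])),
                depth_axis=g["depth_m"].to_numpy(),
                temperature=g["temperature"].to_numpy(),
                salinity=g["salinity"].to_numpy(),
                oxygen=g["oxygen"].to_numpy(),
                chlorophyll_a=g["chlorophyll_a"].to_numpy(),
                par=g["par"].to_numpy(),
                turbidity=g["turbidity"].to_numpy() if "turbidity" in g.columns else None,
            )
        )
    return stations


# ---------------------------------------------------------------------------
# Layer tables
# ---------------------------------------------------------------------------


def write_layers(layers: Sequence, path: str | Path) -> None:
    """Write one row per extracted scattering layer (header-only CSV if empty)."""
    rows = [
        {
            "layer_id": ly.layer_id,
            "frequency_khz": ly.frequency_khz,
            "date": str(ly.date),
            "min_depth_m": ly.min_depth,
            "max_depth_m": ly.max_depth,
            "width_m": ly.width,
            "length_m": ly.length,
            "mean_sv_db": ly.mean_sv,
            "diel": ly.diel,
        }
        for ly in layers
    ]
    pd.DataFrame(rows, columns=LAYER_TABLE_COLUMNS).to_csv(path, index=False)


def read_layer_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in LAYER_TABLE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing required column {col!r}")
    return df
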