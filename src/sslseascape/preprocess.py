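"""Surface-offset exclusion, echo-integration and thresholding.

Volume backscattering strength Sv is logarithmic (dB re 1 m-1); all averaging
is done on the linear intensity sv = 10**(Sv/10), because acoustic intensities
add, and converted back to dB afterwards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Echogram, ValidationError

logger = logging.getLogger("sslseascape")

NMI_M = 1852.0
EARTH_RADIUS_M = 6_371_000.0


def db_to_linear(sv_db):
    """dB -> linear intensity: 10**(Sv/10)."""
    return np.power(10.0, np.asarray(sv_db, dtype=float) / 10.0)


def linear_to_db(sv_linear):
    """Linear intensity -> dB: 10 log10(sv)."""
    arr = np.asarray(sv_linear, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 10.0 * np.log10(arr)


def haversine_nmi(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in nautical miles (spherical Earth, R = 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.deg2rad(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return d / NMI_M


def apply_surface_offset(e: Echogram, offset_m: float = 10.0) -> Echogram:
    """Drop all samples shallower than ``offset_m`` (near-surface bubble zone)."""
    if offset_m <= 0:
        return e
    if offset_m >= e.depth_axis[-1] + e.depth_step / 2:
        raise ValidationError(f"surface offset {offset_m} m >= maximum depth")
    keep = e.depth_axis >= offset_m
    return Echogram(
        frequency_khz=e.frequency_khz,
        depth_axis=e.depth_axis[keep],
        ping_times=e.ping_times,
        latitude=e.latitude,
        longitude=e.longitude,
        sv=e.sv[keep, :],
    )


@dataclass
class IntegrationGrid:
    """Echo-integrated cells: linear-mean Sv per (depth bin x along-track block).

    ``cell_sv`` is the dB of the arithmetic mean of the linear sv of the
    member samples; ``n_samples`` counts the non-missing samples per cell.
    ``depth_bins`` are bin-centre depths of ``depth_bin_m``-wide bins.
    """

    frequency_khz: float
    cell_sv: np.ndarray  # (n_bins, n_cols) dB, NaN where empty
    depth_bins: np.ndarray  # bin centres, m
    depth_bin_m: float
    cell_distance_nmi: float  # along-track width of one column
    cell_start_nmi: np.ndarray  # cumulative track distance at column start
    cell_time: np.ndarray  # mean UTC per column
    cell_lat: np.ndarray
    cell_lon: np.ndarray
    n_samples: np.ndarray  # (n_bins, n_cols)

    @property
    def depth_edges(self) -> np.ndarray:
        return np.concatenate([self.depth_bins - self.depth_bin_m / 2, [self.depth_bins[-1] + self.depth_bin_m / 2]])

    @property
    def n_cols(self) -> int:
        return self.cell_sv.shape[1]


def echo_integrate(e: Echogram, distance_nmi: float = 0.1, depth_bin_m: float = 1.0) -> IntegrationGrid:
    """Echo-integrate an echogram into (``distance_nmi`` x ``depth_bin_m``) cells.

    Pings are partitioned into contiguous along-track blocks of the requested
    extent using great-circle distance between successive pings; within each
    block x depth bin the cell value is the dB of the mean linear sv over
    non-missing samples.  Columns are ordered by track distance.
    """
    seg = haversine_nmi(e.latitude[:-1], e.longitude[:-1], e.latitude[1:], e.longitude[1:])
    cumdist = np.concatenate([[0.0], np.cumsum(np.atleast_1d(seg))]) if e.n_pings > 1 else np.zeros(1)
    total = cumdist[-1]
    if total <= 1e-9:
        logger.warning("echo_integrate: zero along-track extent (stationary ship); single column")
        col_idx = np.zeros(e.n_pings, dtype=int)
        uniq = np.zeros(1, dtype=int)
        n_cols = 1
    else:
        blocks = np.minimum((cumdist / distance_nmi).astype(int), int(np.floor((total - 1e-12) / distance_nmi)))
        # sparse ping spacing can leave block ids with no ping; keep only populated blocks
        uniq, col_idx = np.unique(blocks, return_inverse=True)
        n_cols = len(uniq)

    # depth bins: half-open [z, z+dz) bins indexed by floor(depth/dz)
    bin_idx = np.floor(e.depth_axis / depth_bin_m).astype(int)
    b0, b1 = bin_idx.min(), bin_idx.max()
    n_bins = b1 - b0 + 1
    depth_bins = (np.arange(b0, b1 + 1) + 0.5) * depth_bin_m

    lin = db_to_linear(e.sv)
    miss = ~np.isfinite(e.sv)
    lin = np.where(miss, 0.0, lin)
    counts = (~miss).astype(np.int64)

    # aggregate with two grouped sums (depth rows, then ping columns)
    row_group = bin_idx - b0
    lin_rows = np.zeros((n_bins, e.n_pings))
    cnt_rows = np.zeros((n_bins, e.n_pings), dtype=np.int64)
    np.add.at(lin_rows, row_group, lin)
    np.add.at(cnt_rows, row_group, counts)

    lin_cells = np.zeros((n_bins, n_cols))
    cnt_cells = np.zeros((n_bins, n_cols), dtype=np.int64)
    np.add.at(lin_cells.T, col_idx, lin_rows.T)
    np.add.at(cnt_cells.T, col_idx, cnt_rows.T)

    with np.errstate(invalid="ignore", divide="ignore"):
        cell_sv = linear_to_db(np.where(cnt_cells > 0, lin_cells / np.maximum(cnt_cells, 1), np.nan))

    t_int = e.ping_times.astype("datetime64[ns]").astype(np.int64).astype(float)
    col_counts = np.bincount(col_idx, minlength=n_cols).astype(float)
    cell_time = (np.bincount(col_idx, weights=t_int, minlength=n_cols) / col_counts).astype(np.int64).astype(
        "datetime64[ns]"
    )
    cell_lat = np.bincount(col_idx, weights=e.latitude, minlength=n_cols) / col_counts
    cell_lon = np.bincount(col_idx, weights=e.longitude, minlength=n_cols) / col_counts
    cell_start = uniq * distance_nmi

    return IntegrationGrid(
        frequency_khz=e.frequency_khz,
        cell_sv=cell_sv,
        depth_bins=depth_bins,
        depth_bin_m=depth_bin_m,
        cell_distance_nmi=distance_nmi,
        cell_start_nmi=cell_start,
        cell_time=cell_time,
        cell_lat=cell_lat,
        cell_lon=cell_lon,
        n_samples=cnt_cells,
    )


def threshold_mask(g: IntegrationGrid, threshold_db: float = -70.0) -> np.ndarray:
    """Boolean extraction mask: True iff a cell is non-missing and >= threshold.

    The comparison is inclusive, so a cell at exactly the threshold is kept.
    """
    with np.errstate(invalid="ignore"):
        return np.isfinite(g.cell_sv) & (g.cell_sv >= threshold_db)


def grid_to_frame(g: IntegrationGrid) -> pd.DataFrame:
    """Long-format export of an integration grid (one row per cell)."""
    n_bins, n_cols = g.cell_sv.shape
    return pd.DataFrame(
        {
            "depth_m": np.repeat(g.depth_bins, n_cols),
            "column": np.tile(np.arange(n_cols), n_bins),
            "time": np.tile(g.cell_time, n_bins),
            "lat": np.tile(g.cell_lat, n_bins),
            "lon": np.tile(g.cell_lon, n_bins),
            "sv_db": g.cell_sv.ravel(),
            "n_samples": g.n_samples.ravel(),
        }
    )
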