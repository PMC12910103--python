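"""Segmentation of sound scattering layers and their descriptors.

Layers are connected components (4-connectivity) of the thresholded
integration grid — the grid-resolution equivalent of filled isocontours at
the extraction threshold.  Components smaller than ``min_cells`` cells are
discarded as speckle (count logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dvm import column_diel_labels
from .io import ValidationError
from .preprocess import NMI_M, IntegrationGrid, db_to_linear, linear_to_db

logger = logging.getLogger("sslseascape")

FOUR_CONNECTIVITY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)
EIGHT_CONNECTIVITY = np.ones((3, 3), dtype=int)

# a survey "day" runs dawn to dawn: columns before this UTC hour belong to the
# previous date, so one diel cycle (and its post-midnight night half) shares a date
DAY_START_HOUR = 6


@dataclass
class SSLayer:
    """One extracted scattering layer with its descriptors.

    Depths come from bin edges: ``min_depth`` is the top edge of the
    shallowest member bin, ``max_depth`` the bottom edge of the deepest, so
    ``width = max_depth - min_depth`` and a single-cell layer has width equal
    to one depth bin.  ``mean_sv`` is the linear-domain mean over member
    cells.  ``diel`` summarises the member columns' diel classes (``mixed``
    when both day and night columns contribute).
    """

    layer_id: str
    frequency_khz: float
    member_cells: frozenset  # of (depth_bin_index, column_index)
    min_depth: float
    max_depth: float
    width: float
    length: float  # m along track
    mean_sv: float
    date: str  # ISO date of the majority of member columns
    diel: str
    lat: float = np.nan  # mean position of member columns
    lon: float = np.nan

    @property
    def n_cells(self) -> int:
        return len(self.member_cells)

    @property
    def columns(self) -> np.ndarray:
        return np.unique([c for _, c in self.member_cells])


def compute_descriptors(cells, g: IntegrationGrid) -> dict:
    """Descriptor record for a set of (bin, column) member cells."""
    cells = list(cells)
    if not cells:
        raise ValidationError("empty cell set")
    bins = np.array([b for b, _ in cells])
    cols = np.array([c for _, c in cells])
    edges = g.depth_edges
    min_depth = float(edges[bins.min()])
    max_depth = float(edges[bins.max() + 1])
    ucols = np.unique(cols)
    length = float((ucols.max() - ucols.min() + 1) * g.cell_distance_nmi * NMI_M)
    mean_sv = float(linear_to_db(np.mean(db_to_linear(g.cell_sv[bins, cols]))))

    shifted = pd.DatetimeIndex(g.cell_time[ucols]) - pd.Timedelta(hours=DAY_START_HOUR)
    date = str(pd.Series(shifted.normalize()).mode().iloc[0].date())
    return {
        "min_depth": min_depth,
        "max_depth": max_depth,
        "width": max_depth - min_depth,
        "length": length,
        "mean_sv": mean_sv,
        "date": date,
        "lat": float(np.mean(g.cell_lat[ucols])),
        "lon": float(np.mean(g.cell_lon[ucols])),
    }


def _diel_summary(member_cols: np.ndarray, labels: np.ndarray) -> str:
    present = set(labels[member_cols])
    if {"day", "night"} <= present:
        return "mixed"
    if "day" in present:
        return "day"
    if "night" in present:
        return "night"
    return "transition"


def extract_layers(
    mask: np.ndarray,
    g: IntegrationGrid,
    min_cells: int = 5,
    connectivity: int = 4,
    diel_threshold_deg: float = 18.0,
) -> list[SSLayer]:
    """Segment the boolean extraction mask into scattering layers.

    Connected components of True cells (4-connectivity by default) with at
    least ``min_cells`` cells become layers; smaller components are discarded
    with a logged count.  Layers are ordered by (date, min_depth).
    """
    if mask.shape != g.cell_sv.shape:
        raise ValidationError("mask dimensions must equal the grid")
    structure = FOUR_CONNECTIVITY if connectivity == 4 else EIGHT_CONNECTIVITY
    labeled, n_comp = ndimage.label(mask, structure=structure)
    if n_comp == 0:
        return []
    diel_labels = column_diel_labels(g, diel_threshold_deg)
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n_comp + 1))
    discarded = int(np.sum(sizes < min_cells))
    if discarded:
        logger.info("extract_layers: discarded %d sub-min_cells component(s)", discarded)
    layers = []
    objects = ndimage.find_objects(labeled)
    for comp, sl in enumerate(objects, start=1):
        if sizes[comp - 1] < min_cells:
            continue
        sub = labeled[sl] == comp
        bins, cols = np.nonzero(sub)
        bins = bins + sl[0].start
        cols = cols + sl[1].start
        cells = frozenset(zip(bins.tolist(), cols.tolist()))
        desc = compute_descriptors(cells, g)
        layers.append(
            SSLayer(
                layer_id="",
                frequency_khz=g.frequency_khz,
                member_cells=cells,
                diel=_diel_summary(np.unique(cols), diel_labels),
                **desc,
            )
        )
    layers.sort(key=lambda ly: (ly.date, ly.min_depth))
    for i, ly in enumerate(layers, start=1):
        ly.layer_id = f"{int(round(g.frequency_khz))}k-{i:03d}"
    return layers


def split_at_diel_boundaries(
    layers: list[SSLayer], g: IntegrationGrid, diel_threshold_deg: float = 18.0
) -> list[SSLayer]:
    """Split layers spanning day and night at the diel boundaries.

    Profile analyses use day/night-pure segments; clustering keeps the
    unsplit layers.  Each segment is re-extracted as the connected components
    of the layer's cells restricted to one diel class.
    """
    labels = column_diel_labels(g, diel_threshold_deg)
    out: list[SSLayer] = []
    for ly in layers:
        if ly.diel != "mixed":
            out.append(ly)
            continue
        for phase in ("day", "night", "transition"):
            keep_cols = set(np.nonzero(labels == phase)[0].tolist())
            cells = [c for c in ly.member_cells if c[1] in keep_cols]
            if not cells:
                continue
            sub_mask = np.zeros_like(g.cell_sv, dtype=bool)
            idx = tuple(np.array(cells).T)
            sub_mask[idx] = True
            out.extend(extract_layers(sub_mask, g, min_cells=1, diel_threshold_deg=diel_threshold_deg))
    for i, ly in enumerate(sorted(out, key=lambda ly: (ly.date, ly.min_depth)), start=1):
        ly.layer_id = f"{int(round(g.frequency_khz))}k-s{i:03d}"
    return out


def _cells_by_time_depth(ly: SSLayer) -> frozenset:
    return ly.member_cells  # grids verified on a common (bin, column) frame


def match_frequencies(
    layers18: list[SSLayer],
    layers38: list[SSLayer],
    g18: IntegrationGrid,
    g38: IntegrationGrid,
    jaccard_threshold: float = 0.25,
    time_tolerance_s: float = 1.0,
) -> tuple[list[tuple[int, int, float]], list[int], list[int]]:
    """Match layers across frequencies by member-cell overlap in (time, depth).

    The two grids must share a ping/column timebase within
    ``time_tolerance_s``; cells are then comparable by (bin, column) index.
    Pairs with Jaccard overlap >= the threshold are formed greedily in order
    of descending overlap; each layer joins at most one pair.

    Returns ``(pairs, unmatched18, unmatched38)`` where each pair is
    ``(index18, index38, jaccard)``.
    """
    n = min(g18.n_cols, g38.n_cols)
    if g18.n_cols != g38.n_cols:
        raise ValidationError("grids have different column counts")
    dt = np.abs((g18.cell_time - g38.cell_time).astype("timedelta64[ns]").astype(np.int64)) / 1e9
    if np.any(dt > time_tolerance_s):
        raise ValidationError("grid timebases are disjoint beyond tolerance")
    candidates = []
    for i, l18 in enumerate(layers18):
        for j, l38 in enumerate(layers38):
            inter = len(l18.member_cells & l38.member_cells)
            if inter == 0:
                continue
            union = len(l18.member_cells | l38.member_cells)
            jac = inter / union
            if jac >= jaccard_threshold:
                candidates.append((jac, i, j))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    pairs = []
    used18: set[int] = set()
    used38: set[int] = set()
    for jac, i, j in candidates:
        if i in used18 or j in used38:
            continue
        pairs.append((i, j, jac))
        used18.add(i)
        used38.add(j)
    unmatched18 = [i for i in range(len(layers18)) if i not in used18]
    unmatched38 = [j for j in range(len(layers38)) if j not in used38]
    return pairs, unmatched18, unmatched38
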