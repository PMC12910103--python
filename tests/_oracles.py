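"""Independent reference implementations used only to check the package.

Each oracle is deliberately written by a different route than the code under
test: recursive flood fill instead of scipy labelling, the O(n^2) silhouette
definition instead of scikit-learn, the Michalsky ephemeris instead of the
NOAA series, the spherical law of cosines instead of haversine, and direct
summation formulas for WMD and Pearson.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd


def flood_fill_components(mask: np.ndarray) -> list[set]:
    """4-connected components of a boolean grid by explicit stack flood fill."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    nrow, ncol = mask.shape
    for r0 in range(nrow):
        for c0 in range(ncol):
            if not mask[r0, c0] or seen[r0, c0]:
                continue
            comp = set()
            stack = [(r0, c0)]
            seen[r0, c0] = True
            while stack:
                r, c = stack.pop()
                comp.add((r, c))
                for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nrow and 0 <= cc < ncol and mask[rr, cc] and not seen[rr, cc]:
                        seen[rr, cc] = True
                        stack.append((rr, cc))
            comps.append(comp)
    return comps


def silhouette_direct(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width from the O(n^2) pairwise-distance definition."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(X)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    sil = []
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        if not own.any():
            sil.append(0.0)
            continue
        a = dist[i, own].mean()
        b = min(dist[i, labels == lab].mean() for lab in np.unique(labels) if lab != labels[i])
        sil.append((b - a) / max(a, b))
    return float(np.mean(sil))


def michalsky_altitude(time, lat_deg: float, lon_deg: float) -> float:
    """Solar altitude (deg) by the Michalsky (Astronomical Almanac) algorithm."""
    t = pd.Timestamp(time)
    jd = t.to_julian_date()
    n = jd - 2451545.0
    mnlong = (280.460 + 0.9856474 * n) % 360.0
    mnanom = math.radians((357.528 + 0.9856003 * n) % 360.0)
    eclong = math.radians(
        (mnlong + 1.915 * math.sin(mnanom) + 0.020 * math.sin(2 * mnanom)) % 360.0
    )
    oblqec = math.radians(23.439 - 0.0000004 * n)
    num = math.cos(oblqec) * math.sin(eclong)
    den = math.cos(eclong)
    ra = math.atan2(num, den) % (2 * math.pi)
    dec = math.asin(math.sin(oblqec) * math.sin(eclong))
    hour_ut = t.hour + t.minute / 60.0 + t.second / 3600.0 + t.microsecond / 3.6e9
    gmst = (6.697375 + 0.0657098242 * n + hour_ut) % 24.0
    lmst = math.radians(((gmst + lon_deg / 15.0) % 24.0) * 15.0)
    ha = lmst - ra
    if ha < -math.pi:
        ha += 2 * math.pi
    if ha > math.pi:
        ha -= 2 * math.pi
    lat = math.radians(lat_deg)
    el = math.asin(math.sin(dec) * math.sin(lat) + math.cos(dec) * math.cos(lat) * math.cos(ha))
    return math.degrees(el)


def spherical_law_of_cosines_nmi(lat1, lon1, lat2, lon2, radius_m: float = 6_371_000.0) -> float:
    """Great-circle distance via the spherical law of cosines."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dl = math.radians(lon2 - lon1)
    arg = math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl)
    return radius_m * math.acos(min(1.0, max(-1.0, arg))) / 1852.0


def wmd_direct(sv_db: np.ndarray, depths: np.ndarray) -> float:
    """Weighted mean depth by an explicit loop over non-missing cells."""
    num = den = 0.0
    for z, sv in zip(depths, sv_db):
        if np.isfinite(sv):
            s = 10.0 ** (sv / 10.0)
            num += z * s
            den += s
    return num / den if den > 0 else float("nan")


def pearson_direct(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r from the raw covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))
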