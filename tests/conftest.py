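from __future__ import annotations

import numpy as np
import pytest

from sslseascape import dvm as sdvm
from sslseascape import preprocess as sprep
from sslseascape import synthetic as ssyn


@pytest.fixture(scope="session")
def at_day_grid():
    """AT daytime scene (local late morning at 25 W), integrated to 0.1 nmi x 1 m."""
    e = ssyn.generate_echogram(
        ssyn.AT, start="2021-12-15T13:00:00", duration_h=2.0, ping_interval_s=5.0, seed=11
    )
    e = sprep.apply_surface_offset(e, 10.0)
    return sprep.echo_integrate(e)


@pytest.fixture(scope="session")
def at_full_day():
    """One full simulated day in the AT at both frequencies (same scene)."""
    grids = {}
    for f in (18, 38):
        e = ssyn.generate_echogram(
            ssyn.AT, frequency_khz=f, start="2021-12-15T06:00:00", duration_h=24.0,
            ping_interval_s=20.0, seed=21,
        )
        e = sprep.apply_surface_offset(e, 10.0)
        grids[f] = sprep.echo_integrate(e)
    return grids


@pytest.fixture(scope="session")
def at_day_labels(at_full_day):
    return sdvm.column_diel_labels(at_full_day[38])


@pytest.fixture()
def toy_grid():
    """Tiny hand-built integration grid (5 bins x 6 columns, 1 m x 0.1 nmi)."""
    sv = np.full((5, 6), -85.0)
    times = np.datetime64("2021-12-15T12:00:00") + np.arange(6) * np.timedelta64(60, "s")
    return sprep.IntegrationGrid(
        frequency_khz=38.0,
        cell_sv=sv,
        depth_bins=np.arange(5) + 0.5,
        depth_bin_m=1.0,
        cell_distance_nmi=0.1,
        cell_start_nmi=np.arange(6) * 0.1,
        cell_time=times,
        cell_lat=np.full(6, 18.0),
        cell_lon=-25.0 - np.arange(6) * 0.001,
        n_samples=np.ones((5, 6), dtype=int),
    )
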