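import numpy as np
import pandas as pd
import pytest

from sslseascape import gam as sg
from sslseascape import preprocess as sp
from sslseascape import synthetic as ssyn
from sslseascape.io import ValidationError

from _oracles import spherical_law_of_cosines_nmi


def _records(n=500, seed=0, response=None, noise=0.1):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({c: rng.normal(size=n) for c in sg.PREDICTORS})
    df["location"] = rng.choice(["AT", "SA", "PA"], size=n)
    if response == "signal":
        df["sv18"] = 2.0 * df["temperature"] + np.sin(np.pi * df["oxygen"]) + rng.normal(0, noise, n)
    else:
        df["sv18"] = rng.normal(size=n)
    df["sv38"] = rng.normal(size=n)
    return df


class TestMatching:
    def _grid_and_station(self, station_offset_nmi):
        e = ssyn.generate_echogram(ssyn.AT, start="2021-12-15T13:00:00", duration_h=0.5,
                                   ping_interval_s=10.0, seed=2)
        g = sp.echo_integrate(sp.apply_surface_offset(e, 10.0))
        lat = float(g.cell_lat[0])
        lon = float(g.cell_lon[0]) + station_offset_nmi / (60.0 * np.cos(np.deg2rad(lat)))
        st = ssyn.generate_ctd(ssyn.AT, 1, seed=3, positions=[(lat, lon)],
                               times=[g.cell_time[0]])[0]
        return g, st

    def test_station_on_track_is_matched(self):
        g, st = self._grid_and_station(0.0)
        recs = sg.match_acoustic_to_ctd({38: g}, [st])
        assert len(recs) == 1
        assert recs.iloc[0]["location"] == "AT"
        assert np.isfinite(recs.iloc[0]["sv38"])

    def test_station_beyond_radius_is_unmatched(self):
        g, st = self._grid_and_station(5.0)
        with pytest.raises(ValidationError, match="closest approach"):
            sg.match_acoustic_to_ctd({38: g}, [st], radius_nmi=0.1)

    def test_haversine_vs_law_of_cosines_at_station_scales(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            lat, lon = rng.uniform(5, 30), rng.uniform(-90, -20)
            dlat, dlon = rng.uniform(-0.05, 0.05, 2)
            a = float(sp.haversine_nmi(lat, lon, lat + dlat, lon + dlon))
            b = spherical_law_of_cosines_nmi(lat, lon, lat + dlat, lon + dlon)
            assert abs(a - b) * 1852.0 < 1.0


class TestCollinearity:
    def test_duplicated_column_flagged(self):
        df = _records(50, seed=1)
        df["turbidity"] = df["chlorophyll_a"]
        corr, flags = sg.screen_collinearity(df)
        assert corr.loc["turbidity", "chlorophyll_a"] == pytest.approx(1.0)
        assert any({a, b} == {"turbidity", "chlorophyll_a"} for a, b, _ in flags)

    def test_independent_columns_unflagged(self):
        df = _records(1000, seed=2)
        corr, flags = sg.screen_collinearity(df)
        off_diag = corr.to_numpy()[~np.eye(len(corr), dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.1)
        assert flags == []

    def test_correlated_proxy_flagged_at_080(self):
        rng = np.random.default_rng(3)
        df = _records(800, seed=3)
        df["turbidity"] = 0.85 * df["chlorophyll_a"] + np.sqrt(1 - 0.85**2) * rng.normal(size=800)
        _, flags = sg.screen_collinearity(df, r_flag=0.8)
        assert any({a, b} == {"turbidity", "chlorophyll_a"} for a, b, _ in flags)


class TestFit:
    def test_pure_noise_explains_little(self):
        res = sg.fit_gam(_records(500, seed=5), "sv18")
        assert res.deviance_explained < 5.0

    def test_generate_and_recover(self):
        df = _records(500, seed=6, response="signal")
        res = sg.fit_gam(df, "sv18")
        coef = res.terms.set_index("term").loc["temperature", "estimate"]
        assert coef == pytest.approx(2.0, abs=0.1)
        xg = np.linspace(-2, 2, 200)
        curve = res.smooth_curve("oxygen", xg)
        truth = np.sin(np.pi * xg)
        rmse = np.sqrt(np.mean((curve - curve.mean() - (truth - truth.mean())) ** 2))
        assert rmse < 0.15

    def test_term_structure_follows_frequency(self):
        df = _records(300, seed=7)
        res18 = sg.fit_gam(df, "sv18")
        res38 = sg.fit_gam(df, "sv38")
        kinds18 = dict(zip(res18.terms["term"], res18.terms["kind"]))
        assert kinds18["temperature"] == "linear" and kinds18["salinity"] == "linear"
        assert kinds18["chlorophyll_a"] == "smooth" and kinds18["oxygen"] == "smooth"
        assert kinds18["par"] == "smooth" and kinds18["location"] == "factor_joint"
        kinds38 = dict(zip(res38.terms["term"], res38.terms["kind"]))
        assert kinds38["par"] == "linear"  # PAR enters linearly at 38 kHz
        assert kinds38["chlorophyll_a"] == "smooth" and kinds38["oxygen"] == "smooth"

    def test_added_term_never_reduces_deviance_explained(self):
        df = _records(400, seed=8, response="signal")
        small = sg.fit_gam(df, "sv18", linear_terms=["temperature"], smooth_terms=["oxygen"],
                           select_smoothing=False)
        big = sg.fit_gam(df, "sv18", linear_terms=["temperature", "salinity"],
                         smooth_terms=["oxygen"], select_smoothing=False)
        assert big.deviance_explained >= small.deviance_explained - 1e-9

    def test_refit_is_bit_identical(self):
        df = _records(300, seed=9, response="signal")
        a = sg.fit_gam(df, "sv18")
        b = sg.fit_gam(df, "sv18")
        assert a.aic == b.aic and a.deviance_explained == b.deviance_explained
        pd.testing.assert_frame_equal(a.terms, b.terms)

    def test_rank_deficiency_is_named(self):
        df = _records(200, seed=10)
        df["salinity"] = df["temperature"]
        with pytest.raises(ValidationError, match="rank-deficient"):
            sg.fit_gam(df, "sv18", linear_terms=["temperature", "salinity"], smooth_terms=[])

    def test_excluding_turbidity_like_predictor(self):
        # the advisory exclusion drops a configured predictor from model terms
        df = _records(300, seed=11)
        res = sg.fit_gam(df, "sv18", smooth_terms=[t for t in ["chlorophyll_a", "oxygen", "par"]
                                                   if t != "par"])
        assert "par" not in set(res.terms["term"])


class TestDiagnostics:
    def test_normality_calibration_on_gaussian_residuals(self):
        # Shapiro-Wilk should accept true Gaussian residuals in >= 90% of runs
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            resid = rng.normal(0, 1, 200)
            fitted = rng.normal(0, 1, 200)
            res = sg.GAMResult("sv18", pd.DataFrame(), 50.0, 0.0, fitted, resid, np.array([]))
            if sg.diagnostics(res)["shapiro_p"] > 0.05:
                hits += 1
        assert hits >= 90

    def test_heteroscedasticity_flagged(self):
        rng = np.random.default_rng(1)
        fitted = rng.uniform(1, 5, 400)
        resid = rng.normal(0, 1, 400) * fitted
        res = sg.GAMResult("sv18", pd.DataFrame(), 50.0, 0.0, fitted, resid, np.array([]))
        assert sg.diagnostics(res)["breusch_pagan_p"] < 0.05

    def test_zero_residuals_degenerate(self):
        res = sg.GAMResult("sv18", pd.DataFrame(), 100.0, 0.0, np.ones(20), np.zeros(20), np.array([]))
        out = sg.diagnostics(res)
        assert out["degenerate"] is True


def test_deviance_matches_r_mgcv_on_shared_data(tmp_path):
    """Cross-check against an independent GAM implementation (mgcv via Rscript)."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the independent GAM cross-check")
    df = _records(300, seed=20, response="signal")
    csv = tmp_path / "records.csv"
    df.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        """
        suppressMessages(library(mgcv))
        d <- read.csv(commandArgs(trailingOnly=TRUE)[1])
        for (v in c("temperature","salinity","oxygen","chlorophyll_a","par"))
            d[[v]] <- as.numeric(scale(d[[v]]))
        m <- gam(sv18 ~ temperature + s(chlorophyll_a, k=10) + s(oxygen, k=10) +
                 salinity + s(par, k=10) + factor(location), data=d, method="GCV.Cp")
        cat(summary(m)$dev.expl * 100)
        """
    )
    out = subprocess.run(["Rscript", str(script), str(csv)], capture_output=True, text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    mgcv_dev = float(out.stdout.strip().split()[-1])
    res = sg.fit_gam(df, "sv18")
    assert res.deviance_explained == pytest.approx(mgcv_dev, abs=2.0)
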