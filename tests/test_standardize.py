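"""Area assignment, trip aggregation, delta model fitting, index recovery."""

import numpy as np
import pandas as pd
import pytest

import cpuerecon as cr
from cpuerecon.standardize import _fit_component


class TestAssignArea:
    def test_latitude_cutoff(self):
        df = pd.DataFrame({"lat": [25.0, 23.0, 24.3]})
        out = cr.assign_area(df)
        assert list(out) == ["north", "south", "north"]

    def test_port_fallback(self):
        df = pd.DataFrame({"lat": [None, None], "port": ["Suao", "Tungkang"]})
        out = cr.assign_area(df)
        assert list(out) == ["north", "south"]

    def test_neither_field_rejected(self):
        with pytest.raises(ValueError):
            cr.assign_area(pd.DataFrame({"x": [1]}))


class TestAggregateTrips:
    def _trips(self):
        return pd.DataFrame({
            "trip_id": ["T1", "T2"],
            "year": [2010, 2010], "month": [5, 4],
            "area": ["south", "south"], "vessel_class": ["CT2", "CT2"],
            "fishing_days": [5.0, 4.0],
        })

    def test_sums_events_per_trip(self):
        events = pd.DataFrame({"trip_id": ["T1"] * 3, "n_fish": [1, 1, 1]})
        out = cr.aggregate_trips(events, self._trips())
        assert out["catch_n"].iloc[0] == 3
        assert out["cpue"].iloc[0] == pytest.approx(0.6)

    def test_off_season_trip_excluded(self):
        out = cr.aggregate_trips(pd.DataFrame({"trip_id": [], "n_fish": []}),
                                 self._trips())
        assert list(out["trip_id"]) == ["T1"]
        assert out.attrs["n_excluded"] == 1

    def test_orphan_events_reported(self):
        events = pd.DataFrame({"trip_id": ["T9"], "n_fish": [1]})
        out = cr.aggregate_trips(events, self._trips())
        assert len(out.attrs["orphans"]) == 1


class TestDeltaFit:
    def test_noise_free_pcm_reproduces_effects(self):
        """With no zeros and no lognormal error the PCM year contrasts equal
        the generating log effect ratios exactly."""
        cfg = cr.SimConfig(seed=51, n_trips=3000, p_zero=0.0, pcm_logsd=0.0)
        rec, truth = cr.gen_cpue(cfg)
        fit = cr.DeltaLognormalModel(
            rec,
            cr.ModelSpec("ZPM", ("year", "month")),
            cr.ModelSpec("PCM", ("year", "month", "vessel_class", "area")),
        ).fit()
        years = fit.years
        mus = fit.lsmeans_year("PCM")["mean"].to_numpy()
        log_true = np.log([truth["year_effects"][y] for y in years])
        np.testing.assert_allclose(np.diff(mus), np.diff(log_true), atol=1e-6)
        assert (fit.lsmeans_year("ZPM")["mean"] > 0.99).all()

    def test_single_year_rejected(self):
        cfg = cr.SimConfig(seed=5, n_trips=200, year_effects={2001: 1.0, 2002: 1.0})
        rec, _ = cr.gen_cpue(cfg)
        rec = rec[rec["year"] == 2001]
        with pytest.raises(ValueError, match="year"):
            cr.DeltaLognormalModel(rec)

    def test_year_without_positives_named(self):
        cfg = cr.SimConfig(seed=5, n_trips=400, year_effects={2001: 1.0, 2002: 1.0})
        rec, _ = cr.gen_cpue(cfg)
        rec.loc[rec["year"] == 2002, "cpue"] = 0.0
        with pytest.raises(ValueError, match="2002"):
            cr.DeltaLognormalModel(rec)

    def test_index_recovery(self, cpue_data):
        """Relative index correlates r >= 0.9 with the true year effects and
        yearly positive probability is recovered within 0.05."""
        cfg, rec, truth = cpue_data
        fit = cr.DeltaLognormalModel(
            rec, cr.ModelSpec("ZPM", ("year", "month")),
            cr.ModelSpec("PCM", ("year", "month"))).fit()
        idx = fit.index()
        te = np.array([truth["year_effects"][y] for y in idx["year"]])
        r = np.corrcoef(idx["relative_index"], te / te.mean())[0, 1]
        assert r >= 0.9
        pp = np.array([truth["p_pos"][int(y)] for y in idx["year"]])
        assert np.abs(idx["p_pos"].to_numpy() - pp).max() <= 0.05

    def test_index_invariant_to_effort_rescaling(self, cpue_data):
        _, rec, _ = cpue_data
        zs = cr.ModelSpec("ZPM", ("year", "month"))
        ps = cr.ModelSpec("PCM", ("year", "month"))
        base = cr.DeltaLognormalModel(rec, zs, ps).fit().index()
        scaled_rec = rec.copy()
        scaled_rec["fishing_days"] *= 3.0
        scaled_rec["cpue"] = scaled_rec["cpue"] / 3.0
        scaled = cr.DeltaLognormalModel(scaled_rec, zs, ps).fit().index()
        np.testing.assert_allclose(scaled["index"], base["index"] / 3.0, rtol=1e-6)
        np.testing.assert_allclose(scaled["relative_index"], base["relative_index"],
                                   rtol=1e-6)
        assert scaled["relative_index"].mean() == pytest.approx(1.0)


class TestLSMeans:
    def test_weighted_months_contract(self):
        """Two months in a 3:1 observation ratio enter the year LSmean with
        0.75/0.25 weights."""
        rows = []
        rng = np.random.default_rng(9)
        for year in (2001, 2002):
            for month, n in ((5, 300), (6, 100)):
                for _ in range(n):
                    rows.append({
                        "year": year, "month": month, "vessel_class": "CT2",
                        "area": "south", "fishing_days": 5.0,
                        "cpue": float(np.exp(rng.normal(0.1 * year % 7 + 0.2 * month, 0.3))),
                    })
        rec = pd.DataFrame(rows)
        fit = cr.DeltaLognormalModel(
            rec, cr.ModelSpec("ZPM", ("year", "month")),
            cr.ModelSpec("PCM", ("year", "month"))).fit()
        ls = fit.lsmeans_year("PCM")
        for i, year in enumerate((2001, 2002)):
            cells = []
            for month in (5, 6):
                cell = pd.DataFrame({"year": [year], "month": [month]})
                cells.append(fit.pcm.predict_eta(cell)[0])
            expected = 0.75 * cells[0] + 0.25 * cells[1]
            assert ls["mean"].iloc[i] == pytest.approx(expected, abs=1e-10)


class TestBiasCorrectedIndex:
    def test_unit_case(self):
        out = cr.bias_corrected_index([1.0], [0.0], [0.0])
        assert out["index"].iloc[0] == pytest.approx(1.0)

    def test_lognormal_correction(self):
        out = cr.bias_corrected_index([1.0], [0.0], [2.0])
        assert out["index"].iloc[0] == pytest.approx(np.e)

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            cr.bias_corrected_index([1.0], [0.0], [-1.0])

    def test_doubled_year_effect_doubles_index(self):
        years = {2001: 1.0, 2002: 2.0}
        cfg = cr.SimConfig(seed=61, n_trips=6000, year_effects=years,
                           p_zero=0.2, pcm_logsd=0.4)
        rec, _ = cr.gen_cpue(cfg)
        fit = cr.DeltaLognormalModel(
            rec, cr.ModelSpec("ZPM", ("year",)), cr.ModelSpec("PCM", ("year",))).fit()
        idx = fit.index()
        ratio = idx["index"].iloc[1] / idx["index"].iloc[0]
        assert ratio == pytest.approx(2.0, rel=0.1)


class TestStepwise:
    def test_class_free_generator_drops_class(self, cpue_data):
        _, rec, _ = cpue_data
        spec = cr.stepwise_select(rec, "PCM", "AIC")
        assert "vessel_class" not in spec.fixed_terms
        assert spec.aic <= _fit_component(
            rec, cr.ModelSpec("PCM", ("year", "month", "vessel_class"))).aic

    def test_interaction_retained_when_real(self):
        cfg = cr.SimConfig(seed=71, n_trips=6000, ym_effect_logsd=0.5)
        rec, _ = cr.gen_cpue(cfg)
        spec = cr.stepwise_select(rec, "PCM", "AIC")
        assert "year:month" in spec.random_terms

    def test_selected_not_worse_than_full(self, cpue_data):
        _, rec, _ = cpue_data
        for component in ("ZPM", "PCM"):
            spec = cr.stepwise_select(rec, component, "AIC")
            full = _fit_component(
                rec, cr.ModelSpec(component, ("year", "month", "vessel_class")))
            assert spec.aic <= full.aic + 1e-9

    def test_bad_criterion_rejected(self, cpue_data):
        _, rec, _ = cpue_data
        with pytest.raises(ValueError):
            cr.stepwise_select(rec, "PCM", "DIC")


class TestResidualDiagnostics:
    def test_normal_residuals_pass(self, cpue_data):
        _, rec, _ = cpue_data
        fit = cr.DeltaLognormalModel(
            rec, cr.ModelSpec("ZPM", ("year", "month")),
            cr.ModelSpec("PCM", ("year", "month"))).fit()
        diag = fit.residual_diagnostics()
        assert not diag["degenerate"]
        assert diag["ks"].p_value > 0.10
        assert diag["qq_slope"] == pytest.approx(1.0, abs=0.1)

    def test_heavy_tails_detected(self):
        """Injecting t(2) errors into positive catches trips the KS check
        more often than the nominal rate."""
        rng = np.random.default_rng(10)
        rejections = 0
        for trial in range(10):
            cfg = cr.SimConfig(seed=500 + trial, n_trips=2000, pcm_logsd=0.0,
                               p_zero=0.2)
            rec, _ = cr.gen_cpue(cfg)
            pos = rec["cpue"] > 0
            rec.loc[pos, "cpue"] *= np.exp(rng.standard_t(2, size=int(pos.sum())))
            fit = cr.DeltaLognormalModel(
                rec, cr.ModelSpec("ZPM", ("year",)),
                cr.ModelSpec("PCM", ("year", "month"))).fit()
            if fit.residual_diagnostics()["ks"].p_value < 0.05:
                rejections += 1
        assert rejections >= 3  # nominal would be ~0.5 of 10

    def test_degenerate_residuals_flagged(self):
        cfg = cr.SimConfig(seed=81, n_trips=500, p_zero=0.0, pcm_logsd=0.0)
        rec, _ = cr.gen_cpue(cfg)
        fit = cr.DeltaLognormalModel(
            rec, cr.ModelSpec("ZPM", ("year",)),
            cr.ModelSpec("PCM", ("year", "month", "vessel_class", "area"))).fit()
        assert fit.residual_diagnostics()["degenerate"]
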