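"""Power-law decay fits, facility-pair averaging, windows and monthly series."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix

from distdecay.decay import (
    decay_fit_from_pairs,
    facility_annual_mean,
    facility_pair_table,
    fit_log_log,
    monthly_decay_series,
    pairs_to_matrix,
    sliding_window_decay,
    taxon_volume_fit,
)
from distdecay.model import DataModelError
from distdecay.synth import generate_powerlaw_pairs

from conftest import make_design


def ols_normal_equations(x, y):
    """Closed-form OLS oracle evaluated in extended precision."""
    lx = np.log10(np.asarray(x, dtype=np.longdouble))
    ly = np.log10(np.asarray(y, dtype=np.longdouble))
    n = len(lx)
    sx, sy = lx.sum(), ly.sum()
    sxx, sxy = (lx * lx).sum(), (lx * ly).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return float(slope), float(intercept)


class TestFitLogLog:
    def test_noiseless_power_law_recovered_exactly(self):
        x = np.array([12.0, 40.0, 150.0, 420.0])
        y = 0.3 * x**0.12
        fit = fit_log_log(x, y)
        assert fit.slope == pytest.approx(0.12, abs=1e-12)
        assert fit.pearson_rho == pytest.approx(1.0)

    def test_hand_points(self):
        fit = fit_log_log([10, 100, 1000], [0.05, 0.1, 0.2])
        assert fit.slope == pytest.approx(0.301030, abs=1e-6)
        assert fit.intercept == pytest.approx(-1.602060, abs=1e-6)

    def test_matches_normal_equation_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(3, 40))
            x = 10 ** rng.uniform(0, 3, n)
            y = 10 ** rng.uniform(-2, 0, n)
            if np.ptp(np.log10(x)) == 0 or np.ptp(np.log10(y)) == 0:
                continue
            fit = fit_log_log(x, y)
            slope, intercept = ols_normal_equations(x, y)
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_nonpositive_pairs_excluded(self):
        fit = fit_log_log([10, 100, 1000, 0.0], [0.05, 0.1, 0.2, 0.5])
        assert fit.n_pairs == 3

    def test_degenerate_inputs(self):
        with pytest.raises(DataModelError):
            fit_log_log([10, 100], [0.1, 0.2])
        with pytest.raises(DataModelError):
            fit_log_log([10, 10, 10], [0.1, 0.2, 0.3])
        flat = fit_log_log([10, 100, 1000], [0.2, 0.2, 0.2])
        assert flat.slope == 0.0 and flat.pearson_rho == 0.0 and flat.p_value == 1.0


class TestFacilityAnnualMean:
    def _ds(self, values, ids):
        return DistanceMatrix(values, ids=ids)

    def test_singleton_pair_mean(self):
        ds = self._ds([[0, 0.4], [0.4, 0]], ["a1", "b1"])
        d = make_design({"a1": ("A", "A1", 0), "b1": ("B", "B1", 0)},
                        {"A": {"latitude": 45, "longitude": -93},
                         "B": {"latitude": 44, "longitude": -94}})
        pairs = facility_annual_mean(ds, d)
        assert len(pairs) == 1
        assert pairs.iloc[0]["ds_mean"] == pytest.approx(0.4)

    def test_parallel_bioreactors_averaged(self):
        # facility B vs two bioreactors of facility C: mean of 0.4 and 0.6
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 0.4
        m[0, 2] = m[2, 0] = 0.6
        m[1, 2] = m[2, 1] = 0.2
        ds = self._ds(m, ["b", "c1", "c2"])
        d = make_design(
            {"b": ("B", "B1", 0), "c1": ("C", "C1", 0), "c2": ("C", "C2", 0)},
            {"B": {"latitude": 45, "longitude": -93},
             "C": {"latitude": 44, "longitude": -94}})
        pairs = facility_annual_mean(ds, d)
        assert pairs.iloc[0]["ds_mean"] == pytest.approx(0.5)
        assert pairs.iloc[0]["n_sample_pairs"] == 2

    def test_month_matched_drops_disjoint_months(self):
        ds = self._ds([[0, 0.4], [0.4, 0]], ["a1", "b1"])
        d = make_design({"a1": ("A", "A1", 0), "b1": ("B", "B1", 3)},
                        {"A": {"latitude": 45, "longitude": -93},
                         "B": {"latitude": 44, "longitude": -94}})
        assert len(facility_annual_mean(ds, d, month_matched=True)) == 0
        assert len(facility_annual_mean(ds, d, month_matched=False)) == 1

    def test_beta_invariant_to_facility_relabeling(self, small_study):
        from distdecay.metrics import beta_dissimilarity, geographic_distance_km
        table, design, _ = small_study
        ds = beta_dissimilarity(table, "braycurtis")
        geo = geographic_distance_km(design)
        pairs = facility_pair_table(facility_annual_mean(ds, design), geo)
        beta = decay_fit_from_pairs(pairs).slope

        relabel = {f: f"Z{f}" for f in design.facility_ids}
        samples = design.samples.copy()
        samples["facility"] = samples["facility"].map(relabel)
        facilities = design.facilities.rename(index=relabel)
        from distdecay.model import StudyDesign
        design2 = StudyDesign(samples, facilities)
        geo2 = geographic_distance_km(design2)
        pairs2 = facility_pair_table(facility_annual_mean(ds, design2), geo2)
        assert decay_fit_from_pairs(pairs2).slope == pytest.approx(beta, abs=1e-12)

    def test_pairs_to_matrix_round_trip(self):
        pairs = pd.DataFrame({
            "facility_i": ["A", "A", "B"], "facility_j": ["B", "C", "C"],
            "ds_mean": [0.1, 0.2, 0.3]})
        m = pairs_to_matrix(pairs)
        assert m["A", "C"] == 0.2 and m["B", "C"] == 0.3


class TestTaxonVolume:
    def _setup(self, volumes, richness):
        facs = {f: {"latitude": 45.0, "longitude": -93.0, "flow_rate": v}
                for f, v in volumes.items()}
        samples = {f"{f}s": (f, f"{f}1", 0) for f in volumes}
        d = make_design(samples, facs)
        alpha = pd.DataFrame({"richness": richness, "shannon": 1.0},
                             index=list(samples))
        return alpha, d

    def test_noiseless_exponent_recovered(self):
        v = {"A": 1.0, "B": 10.0, "C": 100.0, "D": 1000.0}
        alpha, d = self._setup(v, [100 * x**0.03 for x in v.values()])
        fit = taxon_volume_fit(alpha, d)
        assert fit.slope == pytest.approx(0.03, abs=1e-10)

    def test_flat_richness_zero_exponent(self):
        v = {"A": 1.0, "B": 10.0, "C": 100.0}
        alpha, d = self._setup(v, [50, 50, 50])
        fit = taxon_volume_fit(alpha, d)
        assert fit.slope == 0.0 and fit.p_value == 1.0

    def test_missing_flow_rate_excluded(self):
        v = {"A": 1.0, "B": 10.0, "C": 100.0, "D": np.nan}
        alpha, d = self._setup(v, [10, 20, 40, 99])
        assert taxon_volume_fit(alpha, d).n_pairs == 3


class TestSlidingWindow:
    def test_schedule_matches_ladder(self):
        pairs = generate_powerlaw_pairs(0.12, -0.55, 0.05, 190, seed=3)
        windows = sliding_window_decay(pairs)
        first_18 = [(w.lo_km, w.hi_km) for w in windows[:18]]
        assert first_18 == [(10.0 + 10 * i, 210.0 + 10 * i) for i in range(18)]

    def test_single_window_equals_global_fit(self):
        rng = np.random.default_rng(4)
        d = rng.uniform(50, 100, 30)
        ds = 0.3 * d**0.1 * 10 ** rng.normal(0, 0.02, 30)
        pairs = pd.DataFrame({"d_km": d, "ds_mean": ds})
        windows = sliding_window_decay(pairs, width_km=200, start_km=10)
        global_fit = fit_log_log(d, ds)
        assert windows[0].fit.slope == pytest.approx(global_fit.slope)

    def test_planted_slope_gradient_is_monotone(self):
        # three distance strata with increasing planted slopes
        rng = np.random.default_rng(9)
        frames = []
        for lo, hi, beta in [(10, 150, 0.05), (150, 290, 0.25), (290, 430, 0.6)]:
            d = rng.uniform(lo, hi, 80)
            c = -0.4 - beta * np.log10(lo)
            frames.append(pd.DataFrame({
                "d_km": d,
                "ds_mean": 10 ** (c + beta * np.log10(d)
                                  + rng.normal(0, 0.01, 80))}))
        pairs = pd.concat(frames, ignore_index=True)
        windows = sliding_window_decay(pairs, width_km=140, step_km=140,
                                       start_km=10, min_pairs=10)
        slopes = [w.fit.slope for w in windows[:3]]
        assert slopes == sorted(slopes)

    def test_min_pairs_guard(self):
        pairs = pd.DataFrame({"d_km": [20.0, 30.0], "ds_mean": [0.2, 0.3]})
        with pytest.raises(DataModelError):
            sliding_window_decay(pairs, min_pairs=10)


class TestMonthlySeries:
    def test_noiseless_monthly_beta_exact(self):
        facs = {f: {"latitude": 45 + i * 0.5, "longitude": -93.0}
                for i, f in enumerate("ABCD")}
        samples = {f"{f}m{m}": (f, f"{f}1", m) for f in "ABCD" for m in (0, 1)}
        d = make_design(samples, facs)
        from distdecay.metrics import geographic_distance_km
        geo = geographic_distance_km(d)
        ids = list(samples)
        m = np.zeros((len(ids), len(ids)))
        for i, si in enumerate(ids):
            for j, sj in enumerate(ids):
                if i < j:
                    fi, fj = samples[si][0], samples[sj][0]
                    if fi == fj:
                        continue
                    val = 0.3 * geo[fi, fj] ** 0.2
                    m[i, j] = m[j, i] = val
        ds = DistanceMatrix(m, ids=ids)
        series = monthly_decay_series(ds, d, geo)
        assert len(series) == 2
        np.testing.assert_allclose(series["beta"], 0.2, atol=1e-10)
        assert series["significant"].all()

    def test_insufficient_month_reported(self):
        facs = {f: {"latitude": 45 + i, "longitude": -93.0}
                for i, f in enumerate("AB")}
        samples = {"a": ("A", "A1", 0), "b": ("B", "B1", 0)}
        d = make_design(samples, facs)
        from distdecay.metrics import geographic_distance_km
        ds = DistanceMatrix([[0, 0.5], [0.5, 0]], ids=["a", "b"])
        series = monthly_decay_series(ds, d, geographic_distance_km(d))
        assert not series.iloc[0]["sufficient"]
        assert np.isnan(series.iloc[0]["beta"])

    def test_recovers_planted_beta_each_month(self, default_study):
        """On the full synthetic design every monthly β̂ sits near planted 0.12."""
        from distdecay.metrics import beta_dissimilarity, geographic_distance_km
        table, design, _ = default_study
        ds = beta_dissimilarity(table, "braycurtis")
        geo = geographic_distance_km(design)
        series = monthly_decay_series(ds, design, geo)
        assert len(series) == 12 and series["sufficient"].all()
        assert np.all(np.abs(series["beta"] - 0.12) <= 0.25 * 0.12 + 0.02)
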