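import numpy as np
import pandas as pd
import pytest

from targetmet.msio import CompoundEntry, PeakTable, PipelineConfig, SampleMeta
from targetmet.normqc import (
    apply_factors,
    dilution_linearity,
    is_factors,
    pooled_cv,
    qc_filter,
    th_relative_abundance,
    total_signal_normalize,
)
from targetmet.simulate import ScenarioConfig, simulate_study


def _table(areas: dict, samples, compounds):
    df = pd.DataFrame(areas, index=[s.sample_id for s in samples])
    return PeakTable(df, samples=samples, compounds=compounds)


def _two_sample_meta():
    return [SampleMeta("s1", "a", "study", 1.0, 1, 5.0),
            SampleMeta("s2", "b", "study", 1.0, 2, 5.0)]


class TestIsFactors:
    def test_identical_is_gives_unit_factors(self):
        samples = _two_sample_meta()
        compounds = [CompoundEntry("is_1", target_mz=100.0, rt=1.0,
                                   is_internal_standard=True)]
        table = _table({"is_1": [400.0, 400.0]}, samples, compounds)
        f = is_factors(table)
        np.testing.assert_allclose(f.factors.to_numpy(), [1.0, 1.0])

    def test_doubled_sample_gets_double_factor(self):
        samples = _two_sample_meta()
        compounds = [
            CompoundEntry("is_1", target_mz=100.0, rt=1.0,
                          is_internal_standard=True),
            CompoundEntry("is_2", target_mz=200.0, rt=1.0,
                          is_internal_standard=True),
        ]
        table = _table({"is_1": [100.0, 200.0], "is_2": [50.0, 100.0]},
                       samples, compounds)
        f = is_factors(table).factors
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_hand_computed_mean_centered_means(self):
        # IS1 (100, 200), IS2 (10, 30): means 150, 20;
        # ratios (2/3, 4/3) and (1/2, 3/2); f = (0.58333, 1.41667)
        samples = _two_sample_meta()
        compounds = [
            CompoundEntry("is_1", target_mz=100.0, rt=1.0,
                          is_internal_standard=True),
            CompoundEntry("is_2", target_mz=200.0, rt=1.0,
                          is_internal_standard=True),
        ]
        table = _table({"is_1": [100.0, 200.0], "is_2": [10.0, 30.0]},
                       samples, compounds)
        f = is_factors(table).factors
        np.testing.assert_allclose(f.to_numpy(), [0.583333333, 1.416666667],
                                   rtol=1e-9)

    def test_is_with_missing_dropped_with_warning(self):
        samples = _two_sample_meta()
        compounds = [
            CompoundEntry("is_1", target_mz=100.0, rt=1.0,
                          is_internal_standard=True),
            CompoundEntry("is_2", target_mz=200.0, rt=1.0,
                          is_internal_standard=True),
        ]
        table = _table({"is_1": [100.0, 100.0], "is_2": [10.0, np.nan]},
                       samples, compounds)
        with pytest.warns(UserWarning, match="is_2"):
            f = is_factors(table)
        assert f.is_used == ["is_1"]

    def test_zero_usable_is_errors(self):
        samples = _two_sample_meta()
        compounds = [CompoundEntry("m", target_mz=100.0, rt=1.0)]
        table = _table({"m": [1.0, 2.0]}, samples, compounds)
        with pytest.raises(ValueError, match="internal-standard"):
            is_factors(table)


class TestPooledCv:
    def _pool_table(self, values):
        samples = [SampleMeta(f"p{i}", "pool", "pool", 1.0, i, 5.0)
                   for i in range(len(values))]
        compounds = [CompoundEntry("c", target_mz=100.0, rt=1.0)]
        return _table({"c": values}, samples, compounds)

    def test_constant_pools_zero_cv(self):
        cv = pooled_cv(self._pool_table([100.0, 100.0, 100.0]))
        assert cv["c"] == 0.0

    def test_hand_sd_over_mean(self):
        # sd(90, 110) = 14.142, mean = 100 -> 14.14%
        cv = pooled_cv(self._pool_table([90.0, 110.0]))
        assert cv["c"] == pytest.approx(14.1421356, rel=1e-6)

    def test_single_value_undefined(self):
        cv = pooled_cv(self._pool_table([100.0, np.nan]))
        assert np.isnan(cv["c"])

    def test_no_pools_errors(self):
        samples = _two_sample_meta()
        compounds = [CompoundEntry("c", target_mz=100.0, rt=1.0)]
        table = _table({"c": [1.0, 2.0]}, samples, compounds)
        with pytest.raises(ValueError, match="pool"):
            pooled_cv(table)


def _dilution_table(areas):
    samples = [
        SampleMeta("p1", "pool", "pool", 1.0, 1, 5.0),
        SampleMeta("d3", "pool", "pool_dilution", 1 / 3, 2, 5.0),
        SampleMeta("d10", "pool", "pool_dilution", 1 / 10, 3, 5.0),
    ]
    compounds = [CompoundEntry("c", target_mz=100.0, rt=1.0)]
    return _table({"c": areas}, samples, compounds)


class TestDilutionLinearity:
    def test_exactly_proportional(self):
        rsq = dilution_linearity(_dilution_table([900.0, 300.0, 90.0]))
        assert rsq["c"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_response_undefined(self):
        rsq = dilution_linearity(_dilution_table([500.0, 500.0, 500.0]))
        assert np.isnan(rsq["c"])

    def test_independent_ols_oracle(self):
        # brute-force OLS recomputed here, independent of the implementation
        x = np.array([1.0, 1 / 3, 1 / 10])
        y = np.array([1000.0, 350.0, 120.0])
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        expected = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        rsq = dilution_linearity(_dilution_table(list(y)))
        assert rsq["c"] == pytest.approx(expected, rel=1e-12)
        assert rsq["c"] == pytest.approx(0.9999949, abs=1e-6)

    def test_fewer_than_three_levels_errors(self):
        samples = [
            SampleMeta("p1", "pool", "pool", 1.0, 1, 5.0),
            SampleMeta("d3", "pool", "pool_dilution", 1 / 3, 2, 5.0),
        ]
        compounds = [CompoundEntry("c", target_mz=100.0, rt=1.0)]
        table = _table({"c": [900.0, 300.0]}, samples, compounds)
        with pytest.raises(ValueError, match="3 distinct"):
            dilution_linearity(table)


class TestQcFilter:
    def _table_with(self, ids):
        samples = _two_sample_meta()
        compounds = [CompoundEntry(c, target_mz=100.0 + i, rt=1.0)
                     for i, c in enumerate(ids)]
        areas = {c: [1.0, 2.0] for c in ids}
        return _table(areas, samples, compounds)

    def test_boundary_strictness(self):
        table = self._table_with(["kept", "cv_at_cutoff", "rsq_at_cutoff"])
        cv = pd.Series({"kept": 29.9, "cv_at_cutoff": 30.0,
                        "rsq_at_cutoff": 10.0})
        rsq = pd.Series({"kept": 0.951, "cv_at_cutoff": 0.99,
                         "rsq_at_cutoff": 0.95})
        kept, report = qc_filter(table, cv, rsq)
        assert kept.compound_ids == ["kept"]
        assert not report.passed["cv_at_cutoff"]
        assert not report.passed["rsq_at_cutoff"]

    def test_uncomputable_metric_fails(self):
        table = self._table_with(["a", "b"])
        cv = pd.Series({"a": np.nan, "b": 5.0})
        rsq = pd.Series({"a": 0.99, "b": np.nan})
        kept, report = qc_filter(table, cv, rsq)
        assert kept.compound_ids == []
        assert "not computable" in report.reason["a"]

    def test_is_compounds_retained_but_flagged(self):
        samples = _two_sample_meta()
        compounds = [
            CompoundEntry("m", target_mz=100.0, rt=1.0),
            CompoundEntry("is_1", target_mz=200.0, rt=1.0,
                          is_internal_standard=True),
        ]
        table = _table({"m": [1.0, 2.0], "is_1": [3.0, 4.0]},
                       samples, compounds)
        cv = pd.Series({"m": 50.0, "is_1": 50.0})
        rsq = pd.Series({"m": 0.5, "is_1": 0.5})
        kept, report = qc_filter(table, cv, rsq)
        assert kept.compound_ids == ["is_1"]
        assert report.n_kept == 0
        assert "internal standard" in report.reason["is_1"]

    def test_idempotent_and_matches_brute_force(self):
        rng = np.random.default_rng(9)
        ids = [f"c{i}" for i in range(20)]
        table = self._table_with(ids)
        cv = pd.Series(rng.uniform(0, 60, 20), index=ids)
        rsq = pd.Series(rng.uniform(0.8, 1.0, 20), index=ids)
        config = PipelineConfig()
        kept, report = qc_filter(table, cv, rsq, config)
        brute = [c for c in ids
                 if cv[c] < config.cv_cutoff and rsq[c] > config.rsq_cutoff]
        assert kept.compound_ids == brute
        kept2, _ = qc_filter(kept, cv[kept.compound_ids],
                             rsq[kept.compound_ids], config)
        assert kept2.compound_ids == kept.compound_ids


class TestTotalSignalNormalize:
    def _three_sample_table(self, rows):
        samples = [SampleMeta(f"s{i}", "g", "study", 1.0, i, 5.0)
                   for i in range(len(rows))]
        compounds = [CompoundEntry("c1", target_mz=100.0, rt=1.0),
                     CompoundEntry("c2", target_mz=200.0, rt=1.0)]
        df = pd.DataFrame(rows, index=[s.sample_id for s in samples],
                          columns=["c1", "c2"])
        return PeakTable(df, samples=samples, compounds=compounds)

    def test_doubled_sample_equalized(self):
        table = self._three_sample_table([[10.0, 20.0], [20.0, 40.0]])
        out = total_signal_normalize(table)
        np.testing.assert_allclose(out.areas.loc["s0"].to_numpy(),
                                   out.areas.loc["s1"].to_numpy())

    def test_single_sample_unchanged(self):
        table = self._three_sample_table([[10.0, 20.0]])
        out = total_signal_normalize(table)
        np.testing.assert_allclose(out.areas.to_numpy(),
                                   table.areas.to_numpy())

    def test_hand_scale_factors(self):
        # totals (100, 200, 400), mean 233.33 -> scales (2.333, 1.167, 0.583)
        table = self._three_sample_table(
            [[60.0, 40.0], [120.0, 80.0], [240.0, 160.0]])
        out = total_signal_normalize(table)
        scales = out.areas["c1"] / table.areas["c1"]
        np.testing.assert_allclose(
            scales.to_numpy(), [7 / 3, 7 / 6, 7 / 12], rtol=1e-12)

    def test_zero_total_sample_flagged(self):
        samples = [SampleMeta("s0", "g", "study", 1.0, 0, 5.0),
                   SampleMeta("bl", "blank", "blank", 1.0, 1, 5.0)]
        compounds = [CompoundEntry("c1", target_mz=100.0, rt=1.0)]
        df = pd.DataFrame({"c1": [10.0, 0.0]}, index=["s0", "bl"])
        table = PeakTable(df, samples=samples, compounds=compounds)
        with pytest.warns(UserWarning, match="zero total"):
            out = total_signal_normalize(table)
        assert out.areas.loc["bl", "c1"] == 0.0


class TestThRelativeAbundance:
    def _pair_table(self, analyte, ref, volumes=(5.0, 5.0)):
        samples = [SampleMeta(f"s{i}", "g", "study", 1.0, i, volumes[i])
                   for i in range(len(analyte))]
        compounds = [
            CompoundEntry("T3", target_mz=651.7973, rt=9.0, is_pair="T3_IS"),
            CompoundEntry("T3_IS", target_mz=657.8174, rt=9.0,
                          is_internal_standard=True),
        ]
        df = pd.DataFrame({"T3": analyte, "T3_IS": ref},
                          index=[s.sample_id for s in samples])
        return PeakTable(df, samples=samples, compounds=compounds)

    def test_simple_ratio(self):
        out = th_relative_abundance(self._pair_table([500.0, 250.0],
                                                     [1000.0, 1000.0]))
        np.testing.assert_allclose(out["T3"].to_numpy(), [0.5, 0.25])

    def test_missing_is_flagged_not_zero(self):
        with pytest.warns(UserWarning, match="T3_IS"):
            out = th_relative_abundance(
                self._pair_table([500.0, 250.0], [1000.0, np.nan]))
        assert np.isnan(out.loc["s1", "T3"])

    def test_zero_area_treated_as_missing(self):
        out = th_relative_abundance(
            self._pair_table([0.0, 250.0], [1000.0, 1000.0]))
        assert np.isnan(out.loc["s0", "T3"])

    def test_matrix_factor_cancels(self):
        base = self._pair_table([500.0, 500.0], [1000.0, 1000.0])
        distorted = base.with_areas(base.areas.mul(
            pd.Series({"s0": 1.5, "s1": 0.7}), axis=0))
        pd.testing.assert_frame_equal(th_relative_abundance(base),
                                      th_relative_abundance(distorted))

    def test_unequal_volumes_error(self):
        table = self._pair_table([1.0, 1.0], [2.0, 2.0], volumes=(5.0, 10.0))
        with pytest.raises(ValueError, match="volume"):
            th_relative_abundance(table)


@pytest.fixture(scope="module")
def clean_study():
    config = ScenarioConfig(n_metabolites=12, n_is=4, noise_cv=0.0,
                            matrix_sd=0.3, missing_rate=0.0)
    return simulate_study(config, seed=23)


class TestNoiseFreeRecovery:
    """Simulator-backed invariants: exact factor recovery without noise."""

    def test_factors_proportional_to_matrix(self, clean_study):
        table, truth = clean_study
        f = is_factors(table).factors
        m = pd.Series(truth.matrix_factors)[f.index]
        ratio = (f / m).to_numpy()
        assert np.nanmax(np.abs(ratio / ratio[0] - 1)) < 1e-10

    def test_normalized_equals_predistortion(self, clean_study):
        table, truth = clean_study
        normalized = apply_factors(table, is_factors(table))
        study_ids = table.samples_of_type("study")
        sub = normalized.areas.loc[study_ids, "met_001"]
        groups = {s.sample_id: s.group for s in table.samples}
        expected = pd.Series({
            sid: truth.true_conc(groups[sid], "met_001") for sid in study_ids
        })
        # equal up to the global mean matrix factor
        ratio = (sub / expected).to_numpy()
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-10)

    def test_th_ratio_invariant_to_matrix(self, clean_study):
        table, truth = clean_study
        out = th_relative_abundance(table)
        study_ids = table.samples_of_type("study")
        groups = {s.sample_id: s.group for s in table.samples}
        for sid in study_ids:
            expected = truth.true_conc(groups[sid], "T3") / \
                truth.is_spikes["T3_IS"]
            assert out.loc[sid, "T3"] == pytest.approx(expected, rel=1e-12)
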