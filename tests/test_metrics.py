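"""Precision metrics: RSD, robust RSD, D-ratio, detection rate, cleaning."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboqc.metrics import (
    CRITERIA_PROFILES,
    CleaningCriteria,
    MAD_TO_SD,
    clean,
    compute_feature_stats,
    d_ratio,
    detection_rate,
    dilution_linearity,
    robust_rsd,
    rsd,
)
from metaboqc.simulate import simulate_study, truth_rsd


class TestRsd:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([10, 10, 10], 0.0),
            ([8, 10, 12], 20.0),  # mean 10, sample SD 2
        ],
    )
    def test_hand_computed(self, values, expected):
        assert rsd(values) == pytest.approx(expected)

    def test_undefined_cases(self):
        assert math.isnan(rsd([5]))
        assert math.isnan(rsd([-1, 1]))  # zero mean
        assert math.isnan(rsd([np.nan, 3.0]))  # one usable value

    def test_missing_excluded(self):
        assert rsd([8, np.nan, 10, 12]) == pytest.approx(20.0)


class TestRobustRsd:
    def test_hand_computed(self):
        # median 10, MAD 1 -> 100 * 1.4826 * 1 / 10
        assert robust_rsd([9, 10, 11]) == pytest.approx(100 * MAD_TO_SD / 10, rel=1e-12)
        assert robust_rsd([9, 10, 11]) == pytest.approx(14.826, abs=5e-3)

    def test_outlier_resistant(self):
        # MAD of deviations {0,0,0,990} is 0
        assert robust_rsd([10, 10, 10, 1000]) == 0.0

    def test_undefined_on_zero_median(self):
        assert math.isnan(robust_rsd([-5, 0, 5]))

    def test_gaussian_convergence(self):
        # 1.4826 calibrates MAD to the Gaussian SD: at sigma/mu = 10%
        # the robust RSD converges to the plain RSD
        rng = np.random.default_rng(12345)
        x = rng.normal(100.0, 10.0, 200_000)
        assert robust_rsd(x) == pytest.approx(10.0, abs=0.15)
        assert robust_rsd(x) == pytest.approx(rsd(x), abs=0.2)


class TestDRatio:
    def test_perfect_measurement_is_zero(self):
        assert d_ratio([100, 100, 100, 100, 100], [80, 90, 100, 110, 120]) == 0.0

    def test_no_biological_information_is_100(self):
        assert d_ratio([8, 10, 12], [8, 10, 12]) == 100.0

    def test_half_dispersion(self):
        qc = [8, 10, 12]          # SD 2
        samples = [6, 10, 14]     # SD 4
        assert d_ratio(qc, samples) == pytest.approx(50.0)

    def test_robust_variant_uses_raw_mads(self):
        qc = [9, 10, 11]      # MAD 1
        bio = [6, 10, 14]     # MAD 4
        assert d_ratio(qc, bio, robust=True) == pytest.approx(25.0)

    def test_undefined_cases(self):
        assert math.isnan(d_ratio([1, 2, 3], [5, 5, 5]))  # no biological variance
        assert math.isnan(d_ratio([5], [1, 2, 3]))


class TestDetectionRate:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1.0] * 8 + [np.nan] * 2, 80.0),
            ([np.nan] * 4, 0.0),
            ([1.0, 2.0, 3.0], 100.0),
            ([0.0, 1.0], 50.0),  # measured zero is not a detection
        ],
    )
    def test_rates(self, values, expected):
        assert detection_rate(values) == expected

    def test_zero_expected_is_error(self):
        with pytest.raises(ValueError):
            detection_rate([])


class TestComputeFeatureStats:
    def test_recovers_simulated_precision(self):
        from metaboqc.core_matrix import drop_conditioning
        from metaboqc.runorder import RunOrderSpec

        study = simulate_study(
            40, 25, 1, drift_spec="none", sigma_technical=0.05,
            batch_shift_sd=0.0,
            run_order_spec=RunOrderSpec(qc_interval=2), seed=42,
        )
        m = drop_conditioning(study.matrix)
        n_qc = int(m.type_mask({"pooled_qc"}).sum())
        assert n_qc >= 20
        stats = compute_feature_stats(m)
        # sampling error of an RSD estimate ~ RSD / sqrt(2 (n-1));
        # with 25 features an occasional 3-sigma excursion is expected
        within = 0
        for j, s in enumerate(stats):
            expected = truth_rsd(study.truth, j)
            tol = 3 * expected / math.sqrt(2 * (n_qc - 1))
            within += abs(s.rsd - expected) <= tol
        assert within >= 0.95 * len(stats)

    def test_feature_absent_from_qcs(self, matrix_builder):
        m = matrix_builder(
            [
                ("pooled_qc", [np.nan, 10.0]),
                ("pooled_qc", [np.nan, 11.0]),
                ("biological", [5.0, 9.0]),
                ("biological", [6.0, 12.0]),
            ]
        )
        stats = compute_feature_stats(m)
        assert math.isnan(stats[0].rsd)
        assert stats[0].detection_rate == 0.0
        assert "insufficient_qc" in stats[0].flags
        assert not math.isnan(stats[1].rsd)

    def test_requires_conditioning_removed(self, matrix_builder):
        m = matrix_builder(
            [
                ("conditioning_qc", [1.0]),
                ("pooled_qc", [1.0]),
                ("pooled_qc", [1.0]),
                ("biological", [1.0]),
                ("biological", [2.0]),
            ]
        )
        with pytest.raises(ValueError, match="conditioning"):
            compute_feature_stats(m)

    def test_log10_close_to_natural_for_low_noise(self):
        # locally linear regime: both CVs small, so the log transform
        # preserves the (scale-free) robust D-ratio
        study = simulate_study(30, 15, 1, drift_spec="none",
                               sigma_technical=0.02, sigma_biological=0.08,
                               batch_shift_sd=0.0, seed=7)
        from metaboqc.core_matrix import drop_conditioning

        m = drop_conditioning(study.matrix)
        nat = compute_feature_stats(m)
        logd = compute_feature_stats(m, transform="log10")
        for a, b in zip(nat, logd):
            if math.isnan(a.robust_d_ratio) or math.isnan(b.robust_d_ratio):
                continue
            # D-ratio is scale-free; for small CVs the log transform is
            # locally linear so the two estimates agree closely
            assert b.robust_d_ratio == pytest.approx(a.robust_d_ratio, rel=0.10)


class TestClean:
    def _stats(self, **kw):
        from metaboqc.metrics import QCFeatureStats

        defaults = dict(detection_rate=100.0, rsd=10.0, d_ratio=20.0,
                        robust_rsd=10.0, robust_d_ratio=20.0)
        defaults.update(kw)
        return QCFeatureStats(feature_id=kw.get("feature_id", "F1"), **{
            k: v for k, v in defaults.items() if k != "feature_id"
        })

    def test_default_thresholds(self):
        assert CRITERIA_PROFILES["strict"].max_rsd == 20.0
        assert CRITERIA_PROFILES["lenient"].max_rsd == 30.0
        c = CleaningCriteria()
        assert c.min_detection_rate == 70.0
        assert c.max_d_ratio == 50.0

    def test_engineered_fixture_counts(self, matrix_builder):
        # 10 features; 4 engineered to breach exactly one criterion each
        from metaboqc.metrics import QCFeatureStats

        stats = [
            self._stats(feature_id=f"F{i}") for i in range(1, 7)
        ] + [
            self._stats(feature_id="F7", detection_rate=50.0),
            self._stats(feature_id="F8", rsd=25.0),
            self._stats(feature_id="F9", d_ratio=60.0),
            self._stats(feature_id="F10", rsd=math.nan),
        ]
        m = matrix_builder(
            [("pooled_qc", [1.0] * 10), ("biological", [1.0] * 10)],
            feature_ids=[f"F{i}" for i in range(1, 11)],
        )
        cleaned, report = clean(m, stats, "strict")
        assert cleaned.n_features == 6
        assert report["retained"].sum() == 6
        assert not report.loc["F10", "pass_rsd"]

    @pytest.mark.parametrize(
        "field,value",
        [("detection_rate", 70.0), ("rsd", 20.0), ("d_ratio", 50.0)],
    )
    def test_boundary_values_removed(self, matrix_builder, field, value):
        # strict inequalities: a feature exactly at a threshold fails it
        stats = [self._stats(feature_id="F1", **{field: value})]
        m = matrix_builder([("pooled_qc", [1.0]), ("biological", [1.0])])
        cleaned, report = clean(m, stats, CleaningCriteria())
        assert cleaned.n_features == 0

    @given(
        dr=st.floats(1.0, 100.0),
        max_rsd=st.floats(1.0, 100.0),
        max_d=st.floats(1.0, 100.0),
        looser=st.floats(0.0, 50.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_criteria(self, dr, max_rsd, max_d, looser):
        # loosening thresholds never drops a previously retained feature
        s = self._stats(feature_id="F1", detection_rate=80.0, rsd=15.0, d_ratio=30.0)

        def retained(crit):
            return (
                s.detection_rate > crit.min_detection_rate
                and s.rsd < crit.max_rsd
                and s.d_ratio < crit.max_d_ratio
            )

        tight = CleaningCriteria(
            min_detection_rate=dr, max_rsd=max_rsd, max_d_ratio=max_d
        )
        loose = CleaningCriteria(
            min_detection_rate=max(dr - looser, 1.0),
            max_rsd=min(max_rsd + looser, 100.0),
            max_d_ratio=min(max_d + looser, 100.0),
        )
        if retained(tight):
            assert retained(loose)


class TestDilutionLinearity:
    def _dilution_matrix(self, responses, matrix_builder):
        rows = []
        dilutions = {}
        factors = [0.25, 0.5, 0.75, 1.0]
        for i, f in enumerate(factors):
            rows.append(("dilution_qc", [resp(f) for resp in responses]))
            dilutions[i] = f
        return rows, dilutions

    def test_perfect_and_anti_and_flat(self, matrix_builder):
        responses = [
            lambda f: 100 * f,          # perfectly linear
            lambda f: -50 * f + 100,    # perfectly anticorrelated
            lambda f: 42.0,             # constant
        ]
        rows, dilutions = self._dilution_matrix(responses, matrix_builder)
        m = matrix_builder(rows, dilutions=dilutions)
        table = dilution_linearity(m)
        assert table.iloc[0]["correlation"] == pytest.approx(1.0)
        assert not table.iloc[0]["flagged"]
        assert table.iloc[1]["correlation"] == pytest.approx(-1.0)
        assert table.iloc[1]["flagged"]
        assert math.isnan(table.iloc[2]["correlation"])
        assert table.iloc[2]["flagged"]
        assert "nonlinear_dilution" in m.features[1].flags
        assert "nonlinear_dilution" not in m.features[0].flags

    def test_too_few_points_is_error(self, matrix_builder):
        m = matrix_builder(
            [("dilution_qc", [1.0]), ("dilution_qc", [2.0])],
            dilutions={0: 0.5, 1: 1.0},
        )
        with pytest.raises(ValueError, match="3"):
            dilution_linearity(m)
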