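"""Drift-model fitting, Eq-style subtraction, and batch alignment."""

import numpy as np
import pytest

from metaboqc.core_matrix import SampleType, drop_conditioning
from metaboqc.correct import (
    CorrectionConfig,
    ExtrapolationError,
    apply_correction,
    correct_batches,
    correct_matrix,
    default_smoothing_grid,
    fit_drift,
)
from metaboqc.metrics import rsd
from metaboqc.simulate import simulate_study


class TestFitDrift:
    def test_linear_exact_recovery(self):
        t = np.arange(1.0, 11.0)
        y = 3.0 + 0.5 * t
        model = fit_drift(t, y, method="linear")
        assert np.allclose(model.predict(t), y, atol=1e-9)
        assert model.cv_error == pytest.approx(0.0, abs=1e-9)

    def test_constant_qcs_give_identity_correction(self):
        t = np.arange(1.0, 13.0)
        y = np.full(12, 100.0)
        model = fit_drift(t, y, method="cubic_spline")
        z = apply_correction(t, y, model)
        assert np.allclose(z, 100.0, atol=1e-6)

    def test_cv_selects_interior_smoothing_on_noisy_sine(self):
        rng = np.random.default_rng(0)
        t = np.linspace(1, 60, 16)
        y = 1000 + 150 * np.sin(t / 12) + rng.normal(0, 10, 16)
        model = fit_drift(t, y, method="cubic_spline")
        errs = dict(model.cv_curve)
        grid = default_smoothing_grid("cubic_spline", 16)
        assert model.cv_error < errs[float(grid[0])]
        assert model.cv_error < errs[float(grid[-1])]

    def test_too_few_qcs_names_minimum(self):
        with pytest.raises(ValueError, match="8"):
            fit_drift(np.arange(1.0, 6.0), np.ones(5), method="cubic_spline")
        with pytest.raises(ValueError, match="2"):
            fit_drift(np.array([1.0]), np.array([5.0]), method="linear")

    def test_non_monotone_t_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            fit_drift([1.0, 3.0, 2.0], [1.0, 2.0, 3.0], method="linear")

    def test_holdout_third_keeps_test_qcs_blind(self):
        rng = np.random.default_rng(3)
        t = np.arange(1.0, 16.0)
        y = 500 + 2 * t + rng.normal(0, 5, 15)
        model = fit_drift(t, y, method="cubic_spline", cv_scheme="holdout_third", seed=1)
        assert len(model.holdout_idx) == pytest.approx(13 / 3, abs=1)
        assert model.n_qc_used == 15 - len(model.holdout_idx)
        # ends are never in the hold-out
        assert 0 not in model.holdout_idx and 14 not in model.holdout_idx

    @pytest.mark.parametrize("method", ["loess", "bracketed_linear"])
    def test_alternative_methods_fit_smooth_trend(self, method):
        t = np.linspace(1, 40, 12)
        y = 100 + 0.8 * t
        model = fit_drift(t, y, method=method)
        assert np.allclose(model.predict(t), y, rtol=0.05)


class TestApplyCorrection:
    def test_no_drift_model_is_identity(self):
        t = np.arange(1.0, 11.0)
        y = np.full(10, 50.0)
        model = fit_drift(t, y, method="linear")
        bio_y = np.array([30.0, 80.0, np.nan])
        z = apply_correction([2.0, 5.0, 7.0], bio_y, model)
        assert z[0] == pytest.approx(30.0)
        assert z[1] == pytest.approx(80.0)
        assert np.isnan(z[2])

    def test_linear_drift_cancels_exactly(self):
        # Eq-style algebraic cancellation: y = 100 + 0.5 t corrects to
        # the QC mean everywhere, post-correction RSD exactly 0
        t = np.arange(1.0, 13.0)
        y = 100 + 0.5 * t
        model = fit_drift(t, y, method="linear")
        z = apply_correction(t, y, model)
        assert np.allclose(z, y.mean(), atol=1e-9)
        assert rsd(z) == pytest.approx(0.0, abs=1e-9)

    def test_additive_contract_for_distant_samples(self):
        t = np.arange(1.0, 13.0)
        y_qc = 100 + 2.0 * t
        model = fit_drift(t, y_qc, method="linear")
        # a biological sample far above the QC mean is shifted by the
        # same fitted f(t) as its neighbours
        z_hi = apply_correction([6.0], [1000.0], model)
        z_lo = apply_correction([6.0], [100.0], model)
        assert (z_hi - z_lo)[0] == pytest.approx(900.0, abs=1e-9)

    def test_extrapolation_rejected_with_positions(self):
        t = np.arange(5.0, 15.0)
        model = fit_drift(t, np.ones(10), method="linear")
        with pytest.raises(ExtrapolationError, match=r"\[2\]"):
            apply_correction([2.0], [1.0], model)


class TestCorrectBatches:
    def test_two_batches_align_to_grand_mean(self, matrix_builder):
        rows = (
            [("pooled_qc", [100.0]), ("pooled_qc", [100.0]),
             ("biological", [90.0]), ("biological", [115.0])]
        )
        rows = [(t, v, 1) for t, v in rows] + [
            ("pooled_qc", [120.0], 2), ("pooled_qc", [120.0], 2),
            ("biological", [130.0], 2), ("biological", [105.0], 2),
        ]
        m = matrix_builder(rows)
        out = correct_batches(m)
        qc = out.type_mask({SampleType.POOLED_QC})
        batches = out.batches
        for b in (1, 2):
            assert out.intensities[qc & (batches == b), 0].mean() == pytest.approx(110.0)
        # biological rows shifted by the same offsets
        assert out.intensities[2, 0] == pytest.approx(100.0)
        assert out.intensities[6, 0] == pytest.approx(120.0)

    def test_single_batch_identity(self, matrix_builder):
        m = matrix_builder([("pooled_qc", [5.0]), ("biological", [7.0])])
        out = correct_batches(m)
        assert np.array_equal(out.intensities, m.intensities)

    def test_equal_batch_means_identity(self, matrix_builder):
        rows = []
        for b in (1, 2, 3):
            rows += [("pooled_qc", [50.0], b), ("pooled_qc", [50.0], b),
                     ("biological", [60.0], b)]
        m = matrix_builder(rows)
        out = correct_batches(m)
        assert np.allclose(out.intensities, m.intensities)

    def test_batch_without_qc_values_flagged(self, matrix_builder):
        rows = [
            ("pooled_qc", [100.0, 100.0], 1), ("biological", [90.0, 90.0], 1),
            ("pooled_qc", [np.nan, 120.0], 2), ("biological", [95.0, 95.0], 2),
        ]
        m = matrix_builder(rows)
        out = correct_batches(m)
        assert "uncorrectable_batch" in out.features[0].flags
        # feature 1 unshifted in batch 2
        assert out.intensities[3, 0] == pytest.approx(95.0)
        # feature 2 aligned normally
        assert "uncorrectable_batch" not in out.features[1].flags


class TestCorrectMatrix:
    def test_drift_correction_improves_qc_precision(self, drifted_study):
        m = drop_conditioning(drifted_study.matrix)
        corrected, report = correct_matrix(m, CorrectionConfig(method="cubic_spline"))
        fs = report.feature_summary
        assert np.nanmedian(fs["rsd_post"]) < np.nanmedian(fs["rsd_pre"])
        assert (fs["rsd_post"] < fs["rsd_pre"]).mean() >= 0.95

    def test_no_drift_study_is_near_identity(self, quiet_study):
        m = drop_conditioning(quiet_study.matrix)
        corrected, _ = correct_matrix(m, CorrectionConfig(method="linear"))
        mask = m.type_mask(
            {SampleType.BIOLOGICAL, SampleType.POOLED_QC}
        )
        before = m.intensities[mask, :]
        after = corrected.intensities[mask, :]
        rel = np.abs(after - before) / before
        assert np.nanmedian(rel) < 0.01

    def test_spline_request_with_few_qcs_falls_back_to_linear(self):
        study = simulate_study(15, 8, 1, drift_spec="linear", seed=6)
        m = drop_conditioning(study.matrix)
        n_qc = int(m.type_mask({SampleType.POOLED_QC}).sum())
        assert n_qc < 8
        _, report = correct_matrix(m, CorrectionConfig(method="cubic_spline"))
        assert (report.models["method"] == "linear").all()
        assert report.models["fallback_applied"].all()

    def test_qc_mean_preserved_within_batch(self, drifted_study):
        m = drop_conditioning(drifted_study.matrix)
        corrected, _ = correct_matrix(m, CorrectionConfig(method="cubic_spline"))
        qc = m.type_mask({SampleType.POOLED_QC})
        for j in range(m.n_features):
            pre = m.intensities[qc, j]
            post = corrected.intensities[qc, j]
            ok = np.isfinite(pre)
            assert post[ok].mean() == pytest.approx(pre[ok].mean(), rel=1e-6)

    def test_multibatch_alignment_equalises_qc_means(self):
        study = simulate_study(60, 10, 3, drift_spec="linear",
                               batch_shift_sd=0.15, seed=8)
        m = drop_conditioning(study.matrix)
        corrected, _ = correct_matrix(m, CorrectionConfig(method="linear"))
        qc = corrected.type_mask({SampleType.POOLED_QC})
        batches = corrected.batches
        for j in range(corrected.n_features):
            means = []
            for b in sorted(set(batches)):
                vals = corrected.intensities[qc & (batches == b), j]
                means.append(np.nanmean(vals))
            assert np.ptp(means) <= 1e-9 * abs(np.mean(means))

    def test_blinded_holdout_rsd_matches_training_rsd(self):
        # CV-constrained smoothing must not make the reported precision
        # unrealistically good: QC RSD on a blinded 1/3 hold-out stays
        # close to the RSD on the training QCs
        rng = np.random.default_rng(12)
        t = np.linspace(1, 80, 16)
        train_rsds, hold_rsds = [], []
        for rep in range(40):
            drift = rng.uniform(50, 200) * np.sin(t / rng.uniform(15, 30))
            mean = rng.uniform(800, 1200)
            y = mean + drift + rng.normal(0, 0.05 * mean, t.size)
            model = fit_drift(t, y, method="cubic_spline",
                              cv_scheme="holdout_third", seed=rep)
            hold = np.array(model.holdout_idx, dtype=int)
            train = np.setdiff1d(np.arange(t.size), hold)
            z = apply_correction(t, y, model)
            train_rsds.append(rsd(z[train]))
            hold_rsds.append(rsd(z[hold]))
        med_train = np.median(train_rsds)
        med_hold = np.median(hold_rsds)
        assert med_hold == pytest.approx(med_train, rel=0.20)

    def test_error_without_pooled_qcs(self, matrix_builder):
        m = matrix_builder([("biological", [1.0]), ("biological", [2.0])])
        with pytest.raises(ValueError, match="pooled QC"):
            correct_matrix(m)

    def test_fit_accuracy_improves_with_more_qcs(self):
        # recovery of a known smooth drift (evaluated on a dense grid)
        # improves as the QC trajectory densifies
        dense = np.linspace(1, 100, 200)
        truth_dense = 1000 + 20 * np.sin(dense / 20)
        errors = []
        for n_qc in (8, 16, 32):
            rng = np.random.default_rng(42)
            t = np.linspace(1, 100, n_qc)
            f_true = 20 * np.sin(t / 20)
            maes = []
            for rep in range(20):
                y = 1000 + f_true + rng.normal(0, 5, n_qc)
                model = fit_drift(t, y, method="cubic_spline")
                maes.append(np.mean(np.abs(model.predict(dense) - truth_dense)))
            errors.append(np.mean(maes))
        assert errors[1] < errors[0]
        assert errors[2] < errors[0]
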