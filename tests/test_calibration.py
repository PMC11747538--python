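"""Two-stage calibration: fitting, application, clipping, recovery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from sleepcal import (
    BiasGrid,
    CalibrationModel,
    CohortConfig,
    PairedNight,
    RatingsMatrix,
    SleepMetrics,
    apply_calibration,
    apply_duration_calibration,
    apply_tst_calibration,
    default_calibration,
    fit_calibration,
    fit_duration_calibration,
    fit_tst_calibration,
    generate_cohort,
    icc_single,
)
from sleepcal.io import model_from_json, model_to_json
from sleepcal.metrics import derive_cohort_metrics, paired_truth_metrics

BED = pd.Timestamp("2024-01-01 23:00:00")


def metrics(tib, onset_latency, duration, tst, offset_latency=None):
    if offset_latency is None:
        offset_latency = tib - onset_latency - duration
    return SleepMetrics(
        tib=tib,
        sleep_onset=BED + pd.Timedelta(hours=onset_latency),
        sleep_offset=BED + pd.Timedelta(hours=onset_latency + duration),
        onset_latency=onset_latency,
        offset_latency=offset_latency,
        duration=duration,
        tst=tst,
    )


def zero_noise_cohort(seed=3, **overrides):
    cfg = CohortConfig(
        seed=seed,
        noise_sd_latency=0.0,
        noise_sd_tst=0.0,
        offset_latency_mean_test=0.0,
        offset_latency_mean_ref=0.0,
        **overrides,
    )
    return generate_cohort(cfg)


class TestDefaultModel:
    def test_constants(self):
        m = default_calibration()
        assert (m.dur_latency_coef, m.dur_intercept) == (0.59, 0.26)
        assert (m.tst_slope, m.tst_intercept) == (0.73, 2.15)
        assert m.provenance == "default"

    def test_serialization_round_trip(self, tmp_path):
        m = default_calibration()
        path = tmp_path / "model.json"
        model_to_json(m, path)
        assert model_from_json(path) == m

    def test_fitted_coef_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            CalibrationModel(dur_latency_coef=1.2, provenance="fitted")


class TestApply:
    def test_duration_equation(self):
        m = default_calibration()
        assert apply_duration_calibration(m, metrics(8.0, 1.0, 6.0, 5.0)) == pytest.approx(6.85)

    def test_duration_clips_to_tib(self):
        m = default_calibration()
        # unclipped 0.59*2 + 7.5 + 0.26 = 8.94 > TIB
        assert apply_duration_calibration(m, metrics(8.0, 2.0, 7.5, 6.0, 0.0)) == pytest.approx(8.0)

    def test_zero_model_is_identity_on_duration(self):
        m = CalibrationModel(dur_latency_coef=0.0, dur_intercept=0.0)
        assert apply_duration_calibration(m, metrics(8.0, 1.5, 6.0, 5.0)) == pytest.approx(6.0)

    def test_tst_equation(self):
        m = default_calibration()
        assert apply_tst_calibration(m, metrics(8.0, 1.0, 6.9, 5.0), 6.85) == pytest.approx(5.80)

    def test_tst_clips_to_calibrated_duration(self):
        m = default_calibration()
        # unclipped 0.73*7 + 2.15 = 7.26 > D'
        assert apply_tst_calibration(m, metrics(9.0, 1.0, 7.5, 7.0), 6.0) == pytest.approx(6.0)

    def test_identity_tst_model(self):
        m = CalibrationModel(tst_slope=1.0, tst_intercept=0.0)
        assert apply_tst_calibration(m, metrics(8.0, 1.0, 6.0, 4.5), 6.0) == pytest.approx(4.5)


class TestFitRecovery:
    def test_zero_noise_exact_recovery_from_latent_truth(self):
        paired = paired_truth_metrics(zero_noise_cohort())
        m = fit_calibration(paired)
        assert m.dur_latency_coef == pytest.approx(0.59, abs=1e-8)
        assert m.dur_intercept == pytest.approx(0.26, abs=1e-8)
        assert m.tst_slope == pytest.approx(0.73, abs=1e-8)
        assert m.tst_intercept == pytest.approx(2.15, abs=1e-8)
        assert m.fit_diagnostics["bias_term_h"] == 0.0

    def test_zero_noise_grid_selection_matches_exhaustive_oracle(self):
        paired = paired_truth_metrics(zero_noise_cohort(seed=9))
        grid = BiasGrid()
        m = fit_duration_calibration(paired, grid)
        alpha = m.fit_diagnostics["latency_ols_slope"]
        beta = m.fit_diagnostics["latency_ols_intercept"]
        S = np.array([p.metrics_test.onset_latency for p in paired])
        D = np.array([p.metrics_test.duration for p in paired])
        TIB = np.array([p.metrics_test.tib for p in paired])
        D_ref = np.array([p.metrics_ref.duration for p in paired])
        d_star = D + (1 - alpha) * S - beta
        best = max(
            grid.candidates_hours(),
            key=lambda b: (
                icc_single(
                    RatingsMatrix(np.column_stack([np.minimum(d_star + b, TIB), D_ref])),
                    "absolute",
                ).estimate,
                -abs(b),
            ),
        )
        assert m.fit_diagnostics["bias_term_h"] == pytest.approx(best, abs=1e-12)
        resid = np.minimum(d_star + best, TIB) - D_ref
        assert np.abs(resid).max() < 1e-8

    def test_identical_devices_need_no_correction(self):
        cfg = dict(
            latency_slope_a=1.0,
            latency_intercept_b=0.0,
            tst_slope=1.0,
            tst_intercept=0.0,
            waso_rate=0.0,
            latency_shift=0.2,
            true_latency_mean=0.45,
        )
        paired = paired_truth_metrics(zero_noise_cohort(seed=4, **cfg))
        m = fit_calibration(paired)
        assert m.dur_latency_coef == pytest.approx(0.0, abs=1e-6)
        assert abs(m.dur_intercept) <= 5 / 60 + 1e-9
        assert m.tst_slope == pytest.approx(1.0, abs=1e-6)
        assert m.tst_intercept == pytest.approx(0.0, abs=1e-6)
        cal = np.asarray(apply_calibration(m, paired))
        dur = np.array([p.metrics_test.duration for p in paired])
        assert np.allclose(cal[:, 0], dur, atol=5 / 60 + 1e-9)

    def test_low_noise_recovery_from_epoch_data(self):
        cfg = CohortConfig(
            seed=2,
            noise_sd_latency=0.01,
            noise_sd_tst=0.01,
            offset_latency_mean_test=0.0,
            offset_latency_mean_ref=0.0,
        )
        paired, _ = derive_cohort_metrics(generate_cohort(cfg))
        m = fit_calibration(paired)
        assert m.dur_latency_coef == pytest.approx(0.59, abs=0.05)
        assert m.dur_intercept == pytest.approx(0.26, abs=0.08)
        assert m.tst_slope == pytest.approx(0.73, abs=0.05)
        assert m.tst_intercept == pytest.approx(2.15, abs=0.15)

    def test_recovery_sharpens_with_cohort_size(self):
        """Fitted coefficients approach generator truth as n grows."""
        errs = {}
        for n, nights in ((64, (5, 21)), (640, (50, 210))):
            cfg = CohortConfig(
                seed=8,
                nights_low=nights[0],
                nights_high=nights[1],
                total_nights=n,
                noise_sd_latency=0.05,
                noise_sd_tst=0.05,
                offset_latency_mean_test=0.0,
                offset_latency_mean_ref=0.0,
            )
            paired = paired_truth_metrics(generate_cohort(cfg))
            m = fit_calibration(paired)
            errs[n] = abs(m.tst_slope - 0.73) + abs(m.dur_latency_coef - 0.59)
        assert errs[640] < max(errs[64], 0.02)

    def test_degenerate_latency_variance_rejected(self):
        rows = [
            PairedNight("p1", f"n{i}", metrics(8.0, 1.0, 6.0, 5.0 + 0.1 * i),
                        metrics(8.0, 0.2, 7.0, 6.0 + 0.1 * i))
            for i in range(5)
        ]
        with pytest.raises(ValueError):
            fit_duration_calibration(rows)

    def test_too_few_nights_rejected(self, default_paired):
        with pytest.raises(ValueError):
            fit_calibration(default_paired[:2])


class TestClippingInvariants:
    def test_clipping_holds_on_fuzzed_cohorts(self):
        rng = np.random.default_rng(0)
        n_nights = 0
        seed = 0
        while n_nights < 1000:
            cfg = CohortConfig(
                seed=seed,
                tib_mean=float(rng.uniform(5.8, 8.0)),
                noise_sd_latency=float(rng.uniform(0.0, 0.3)),
                noise_sd_tst=float(rng.uniform(0.0, 0.6)),
                waso_rate=float(rng.uniform(0.0, 4.0)),
                true_latency_mean=float(rng.uniform(0.7, 1.3)),
            )
            paired, _ = derive_cohort_metrics(generate_cohort(cfg))
            model = fit_calibration(paired) if seed % 2 else default_calibration()
            for p, (d_cal, t_cal) in zip(paired, apply_calibration(model, paired)):
                assert d_cal <= p.metrics_test.tib + 1e-12
                assert 0.0 <= t_cal <= d_cal + 1e-12
            n_nights += len(paired)
            seed += 1
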