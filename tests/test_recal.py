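import numpy as np
import pytest

from msirecal.io import PeakSpectrum
from msirecal.recal import (
    PixelRecalModel,
    PixelReferenceSet,
    apply_model,
    filter_common_error,
    fit_orbitrap_model,
    fit_tof_model,
    recalibrate_dataset,
)


def refset(theo, pred):
    return PixelReferenceSet(0, np.asarray(theo, float), np.asarray(pred, float))


class TestCommonErrorFilter:
    def test_discordant_reference_removed(self):
        theo = np.array([300.0, 400.0, 500.0, 600.0])
        errs = np.array([5.0, 5.2, 4.9, -20.0])
        pred = theo * (1 + errs * 1e-6)
        out = filter_common_error(refset(theo, pred), band_ppm=2.5)
        assert len(out) == 3
        assert 600.0 not in out.theoretical

    def test_all_equal_errors_retained(self):
        theo = np.array([300.0, 400.0, 500.0])
        pred = theo * (1 + 5e-6)
        out = filter_common_error(refset(theo, pred), band_ppm=2.5)
        assert len(out) == 3

    def test_bimodal_errors_keep_exactly_one_mode(self):
        theo = np.arange(300.0, 500.0, 10.0)  # 20 refs
        errs = np.array([5.0] * 10 + [-5.0] * 10)
        pred = theo * (1 + errs * 1e-6)
        out = filter_common_error(refset(theo, pred), band_ppm=2.5)
        kept_errs = np.round(out.errors_ppm, 3)
        assert len(out) == 10
        assert len(np.unique(np.sign(kept_errs))) == 1
        # deterministic: repeated runs keep the same mode
        out2 = filter_common_error(refset(theo, pred), band_ppm=2.5)
        np.testing.assert_array_equal(out.theoretical, out2.theoretical)

    def test_fallback_when_filter_too_aggressive(self):
        theo = np.array([300.0, 400.0])
        pred = theo * (1 + np.array([50.0, -50.0]) * 1e-6)
        with pytest.warns(UserWarning, match="unfiltered"):
            out = filter_common_error(refset(theo, pred), band_ppm=1.0)
        assert len(out) == 2


class TestOrbitrapModel:
    def test_identity_recovered(self):
        theo = np.linspace(255.0, 885.0, 10)
        model = fit_orbitrap_model(refset(theo, theo))
        assert model.coefficients[0] == pytest.approx(0.0, abs=1e-9)
        assert model.coefficients[1] == pytest.approx(1.0, abs=1e-12)

    def test_planted_shift_inverted(self):
        theo = np.linspace(255.0, 885.0, 10)
        pred = theo * (1 + 5e-6)
        model = fit_orbitrap_model(refset(theo, pred))
        recal, _ = model.predict(pred)
        resid_ppm = (recal - theo) / theo * 1e6
        assert np.abs(resid_ppm).max() < 0.01

    def test_two_references_interpolate_exactly(self):
        theo = np.array([300.0, 600.0])
        pred = theo + np.array([0.002, -0.001])
        model = fit_orbitrap_model(refset(theo, pred))
        recal, _ = model.predict(pred)
        np.testing.assert_allclose(recal, theo, atol=1e-9)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_orbitrap_model(refset([300.0, 400.0], [500.0, 500.0]))


class TestTofModel:
    def test_bic_selects_quadratic_generator(self, rng):
        theo_base = np.linspace(255.0, 885.0, 50)
        s_hat = np.sqrt(theo_base)
        hits = 0
        for _ in range(100):
            # sqrt-domain quadratic map plus ppm-scale noise
            s_star = 2e-3 + (1 - 1e-5) * s_hat + 3e-5 * s_hat**2
            s_star = s_star + rng.normal(0, 3.5e-5, s_star.size)
            model = fit_tof_model(refset(s_star**2, s_hat**2))
            hits += model.degree == 2
        assert hits >= 90

    def test_exact_linear_data_selects_degree_one(self):
        # exact linear relation in the sqrt domain: every degree fits to
        # machine precision, so the BIC complexity penalty decides
        pred = np.linspace(255.0, 885.0, 12)
        s_star = 0.001 + 1.00001 * np.sqrt(pred)
        model = fit_tof_model(refset(s_star**2, pred))
        assert model.degree == 1

    def test_identity_recovered(self):
        theo = np.linspace(255.0, 885.0, 8)
        model = fit_tof_model(refset(theo, theo))
        recal, ok = model.predict(theo)
        np.testing.assert_allclose(recal, theo, rtol=1e-9)
        assert ok.all()

    def test_degree_capped_by_sample_size(self):
        theo = np.linspace(255.0, 885.0, 4)
        model = fit_tof_model(refset(theo, theo * (1 + 1e-6)))
        assert model.degree <= 2  # n - 2 with n = 4


class TestApplyModel:
    def test_identity_model_is_identity(self):
        model = PixelRecalModel(0, "orbitrap", np.array([0.0, 1.0]), 1)
        spec = PeakSpectrum(0, 1, 1, [300.0, 400.0], [1.0, 2.0])
        out = apply_model(model, spec)
        np.testing.assert_array_equal(out.masses, spec.masses)
        np.testing.assert_array_equal(out.intensities, spec.intensities)

    def test_five_ppm_slope_arithmetic(self):
        model = PixelRecalModel(0, "orbitrap", np.array([0.0, 1 + 5e-6]), 1)
        out, _ = model.predict(np.array([600.0]))
        assert out[0] == pytest.approx(600.0030, abs=1e-9)

    def test_empty_spectrum_passthrough(self):
        model = PixelRecalModel(0, "orbitrap", np.array([0.0, 1.0]), 1)
        out = apply_model(model, PeakSpectrum(0, 1, 1, np.empty(0), np.empty(0)))
        assert len(out) == 0

    def test_negative_sqrt_prediction_left_uncorrected(self):
        # strongly negative intercept drives low masses negative in sqrt domain
        model = PixelRecalModel(0, "tof", np.array([-100.0, 1.0]), 1)
        out, ok = model.predict(np.array([100.0, 1e6]))
        assert not ok[0] and out[0] == 100.0

    def test_peak_count_and_intensities_conserved(self, rng):
        model = PixelRecalModel(0, "orbitrap", np.array([0.001, 1 - 2e-6]), 1)
        mz = np.sort(rng.uniform(200, 900, 50))
        inten = rng.uniform(0, 10, 50).astype(np.float32)
        out = apply_model(model, PeakSpectrum(0, 1, 1, mz, inten))
        assert len(out) == 50
        assert sorted(out.intensities.tolist()) == sorted(inten.tolist())


class TestEndToEnd:
    def test_orbitrap_sine_drift_corrected(self, orbitrap_small):
        from msirecal.simulate import score_recalibration

        cfg, ds, roi, truth, result = orbitrap_small
        score = score_recalibration(truth, result.recalibrated, result.models)
        assert score["before"]["median"] > 3.0
        assert score["after"]["median"] < 0.5

    def test_heteroskedasticity_reduced(self, orbitrap_small):
        # before: a ppm-scale drift makes Da-domain residuals grow with mass;
        # after recalibration the residual-vs-mass slope collapses
        cfg, ds, roi, truth, result = orbitrap_small
        det = truth.detected
        ions = truth.ion_mz
        models = {m.pixel_index: m for m in result.models}
        mass_all, before_da, after_da = [], [], []
        for p in range(truth.n_pixels):
            mdl = models.get(p)
            if mdl is None:
                continue
            k = np.nonzero(det[p])[0]
            pred, _ = mdl.predict(truth.prenoise[p, k])
            mass_all.extend(ions[k])
            before_da.extend(np.abs(truth.prenoise[p, k] - ions[k]))
            after_da.extend(np.abs(pred - ions[k]))
        slope_before = np.polyfit(mass_all, before_da, 1)[0]
        slope_after = np.polyfit(mass_all, after_da, 1)[0]
        assert abs(slope_after) < abs(slope_before) / 5

    def test_forced_linear_tof_close_to_bic_choice(self):
        from msirecal.pipeline import PipelineConfig, run_pipeline
        from msirecal.simulate import SimulationConfig, score_recalibration, simulate_dataset

        cfg = SimulationConfig(
            n_rows=20, n_cols=20, analyzer="tof", drift_kind="sqrt_quadratic",
            amplitude_ppm=60.0, noise_sigma_ppm=3.0, seed=6,
        )
        ds, roi, truth = simulate_dataset(cfg)
        pc = PipelineConfig(analyzer="tof", seed=6)
        res = run_pipeline(ds, roi, cfg.reference_mz, pc)
        recal_lin, models_lin = recalibrate_dataset(ds, roi, res.trends, "tof", max_degree=1)
        med_bic = score_recalibration(truth, res.recalibrated, res.models)["after"]["median"]
        med_lin = score_recalibration(truth, recal_lin, models_lin)["after"]["median"]
        assert abs(med_lin - med_bic) < 2.0

    def test_no_trends_refused(self, orbitrap_small):
        cfg, ds, roi, truth, result = orbitrap_small
        with pytest.raises(ValueError, match="no accepted"):
            recalibrate_dataset(ds, roi, [], "orbitrap")
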