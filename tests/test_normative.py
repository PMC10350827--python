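import json
import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from neonorm import normative as nm
from neonorm import synthetic as syn


def demo_frame(sex, pma, ga, ids=None):
    sex = np.atleast_1d(sex)
    pma = np.atleast_1d(pma).astype(float)
    ga = np.atleast_1d(ga).astype(float)
    idx = ids if ids is not None else [f"d{i}" for i in range(len(sex))]
    return pd.DataFrame({"sex": sex, "pma_scan": pma, "ga_birth": ga,
                         "age_from_birth": pma - ga},
                        index=pd.Index(idx, name="subject_id"))


class TestFit:
    def test_near_constant_target_recovered(self, control_cohort):
        """A (numerically) constant measure predicts ~ c across the range."""
        demo, _ = control_cohort
        c = 7.0
        rng = np.random.default_rng(0)
        y = c + 1e-7 * rng.normal(size=len(demo))
        model = nm.fit_normative(demo, y, "const", seed=0, n_restarts=1)
        mean, _ = model.predict(demo)
        assert np.all(np.abs(mean - c) < 1e-3 * abs(c) + 1e-6)

    def test_exactly_constant_target_rejected(self, control_cohort):
        demo, _ = control_cohort
        with pytest.raises(nm.FitError, match="zero variance"):
            nm.fit_normative(demo, np.full(len(demo), 3.0), "const")

    def test_too_few_controls_rejected(self):
        demo = demo_frame(["female"] * 5, [40.0] * 5, [39.0] * 5)
        with pytest.raises(nm.FitError, match="at least 30"):
            nm.fit_normative(demo, np.arange(5.0), "m")

    def test_missing_covariate_rejected(self, control_cohort):
        demo, segs = control_cohort
        broken = demo.copy()
        broken.loc[broken.index[0], "pma_scan"] = np.nan
        with pytest.raises(nm.FitError, match="covariates"):
            nm.fit_normative(broken, segs["cerebellum"], "cerebellum")

    def test_single_point_closed_form(self):
        """Frozen-kernel 1-point posterior equals the textbook conditional.

        With a centred prior and one observation, the posterior mean is the
        observation itself and the posterior SD follows the 1x1 conditional
        sd^2 = k(x*,x*) - k(x*,x)^2 / (k(x,x) + jitter).
        """
        sig2, ls, noise = 2.0, 1.5, 0.3
        kernel = ConstantKernel(sig2, "fixed") * RBF([ls, ls, ls], "fixed") \
            + WhiteKernel(noise, "fixed")
        demo_tr = demo_frame("female", 40.0, 39.0)
        y = np.array([5.0])
        model = nm.fit_normative(demo_tr, y, "toy", optimize=False,
                                 min_controls=1, kernel=kernel)
        # standardized distance is 0 for all dims (single point -> sd=1 guard)
        demo_te = demo_frame("female", 40.0, 39.0, ids=["t"])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mean, sd = model.predict(demo_te)
        k_xx = sig2 + noise + 1e-8
        k_sx = sig2  # same point, RBF = 1, no white term across points
        k_ss = sig2 + noise
        var = k_ss - k_sx ** 2 / k_xx
        assert mean[0] == pytest.approx(5.0, abs=1e-9)
        assert sd[0] == pytest.approx(np.sqrt(var), rel=1e-6)

    def test_recovers_generator_mean_function(self, control_cohort, cerebellum_model):
        """Predictive mean tracks the generator's noiseless growth curve."""
        demo, _ = control_cohort
        g = syn.DEFAULT_GROWTH["cerebellum"]
        grid = demo_frame(["female"] * 8 + ["male"] * 8,
                          np.tile(np.linspace(34, 45, 8), 2),
                          np.tile(np.linspace(34, 45, 8), 2) - 2.0)
        mean, _ = cerebellum_model.predict(grid)
        male = (grid["sex"] == "male").to_numpy(float)
        truth = g.mean(grid["pma_scan"].to_numpy(), male)
        sigma_med = np.median(g.cv * truth)
        assert np.mean(np.abs(mean - truth)) < 0.5 * sigma_med

    def test_deterministic_given_seed(self, control_cohort):
        demo, segs = control_cohort
        a = nm.fit_normative(demo, segs["thalamus"], "thalamus", seed=3, n_restarts=2)
        b = nm.fit_normative(demo, segs["thalamus"], "thalamus", seed=3, n_restarts=2)
        assert np.array_equal(a._gp.kernel_.theta, b._gp.kernel_.theta)
        mean_a, sd_a = a.predict(demo)
        mean_b, sd_b = b.predict(demo)
        assert np.array_equal(mean_a, mean_b) and np.array_equal(sd_a, sd_b)


class TestPredict:
    def test_unfitted_model_errors(self):
        with pytest.raises(nm.NotFittedError):
            nm.NormativeModel("x").predict(demo_frame("female", 40.0, 39.0))

    def test_interpolates_noise_free_data(self):
        """With noise pinned ~0 and a kernel containing the target, the
        posterior passes through the data."""
        from sklearn.gaussian_process.kernels import DotProduct
        pma = np.linspace(35, 44, 12)
        demo = demo_frame(["female"] * 12, pma, pma - 1.5)
        y = 10.0 + 0.8 * pma
        kernel = ConstantKernel(1.0, "fixed") * DotProduct(1.0, "fixed") \
            + WhiteKernel(1e-12, "fixed")
        model = nm.fit_normative(demo, y, "toy", optimize=False, min_controls=1,
                                 kernel=kernel)
        mean, _ = model.predict(demo)
        np.testing.assert_allclose(mean, y, rtol=1e-6)

    def test_out_of_range_warns_but_predicts(self, cerebellum_model):
        far = demo_frame("male", 49.5, 30.0, ids=["far"])
        with pytest.warns(UserWarning, match="outside the training range"):
            mean, sd = cerebellum_model.predict(far)
        assert np.isfinite(mean).all() and (sd > 0).all()

    def test_zero_sex_effect_generator(self):
        """With no simulated sex effect, predictions barely depend on sex."""
        growth = syn._default_growth()
        growth["cerebellum"] = syn.GrowthParams(48.0, 0.35, 40.0, sex_offset=0.0)
        demo, segs = syn.generate_controls(
            syn.CohortSpec(n=120, seed=21, growth=growth))
        model = nm.fit_normative(demo, segs["cerebellum"], "cerebellum",
                                 seed=0, n_restarts=2)
        pair = demo_frame(["female", "male"], [40.0, 40.0], [39.0, 39.0])
        mean, sd = model.predict(pair)
        assert abs(mean[0] - mean[1]) < 0.1 * sd.mean()

    def test_sd_grows_toward_range_edge(self):
        """Posterior SD at the covariate-range centre <= SD at the edge for an
        RBF fit on a symmetric design."""
        pma = np.linspace(36, 44, 30)
        demo = demo_frame(["female"] * 30, pma, pma - 2.0)
        rng = np.random.default_rng(2)
        y = 3.0 * (pma - 30.0) + rng.normal(0, 1.0, 30)
        kernel = ConstantKernel(25.0, "fixed") * RBF([1.0] * 3, "fixed") \
            + WhiteKernel(1.0, "fixed")
        model = nm.fit_normative(demo, y, "toy", optimize=False, min_controls=1,
                                 kernel=kernel)
        probe = demo_frame(["female"] * 2, [40.0, 44.0], [38.0, 42.0])
        _, sd = model.predict(probe)
        assert sd[0] <= sd[1]


class TestZscore:
    @pytest.mark.parametrize("offset_sd, z_expected, extreme", [
        (0.0, 0.0, False),
        (2.61, 2.61, True),
        (-2.61, -2.61, True),
        (-1.0, -1.0, False),
        (2.59, 2.59, False),
    ])
    def test_zscore_definition_and_extreme_rule(self, cerebellum_model,
                                                offset_sd, z_expected, extreme):
        demo = demo_frame("female", 40.0, 38.0, ids=["p"])
        mean, sd = cerebellum_model.predict(demo)
        scores = nm.zscore(cerebellum_model, demo, mean + offset_sd * sd)
        assert scores["z"].iloc[0] == pytest.approx(z_expected, abs=1e-9)
        assert bool(scores["extreme"].iloc[0]) is extreme

    def test_extreme_boundary_is_inclusive(self, cerebellum_model):
        """A z-score exactly at the threshold is flagged extreme."""
        demo = demo_frame(["female", "male"], [40.0, 41.0], [38.0, 39.0])
        mean, sd = cerebellum_model.predict(demo)
        scores = nm.zscore(cerebellum_model, demo, mean + 2.6 * sd)
        z = scores["z"].to_numpy()
        at_threshold = nm.zscore(cerebellum_model, demo, mean + 2.6 * sd,
                                 threshold=float(np.abs(z).max()))
        assert at_threshold["extreme"].any()  # |z| == threshold counts
        above = nm.zscore(cerebellum_model, demo, mean + 2.6 * sd,
                          threshold=float(np.abs(z).max()) * (1 + 1e-9))
        assert not above["extreme"].all()

    def test_affine_equivariance(self, control_cohort, heldout_cohort):
        """Scaling the measure by a > 0 scales mean/SD and leaves z fixed."""
        demo, segs = control_cohort
        demo_h, segs_h = heldout_cohort
        a = 2.0
        base = nm.fit_normative(demo, segs["brainstem"], "brainstem",
                                seed=5, n_restarts=2)
        scaled = nm.fit_normative(demo, a * segs["brainstem"], "brainstem",
                                  seed=5, n_restarts=2)
        m0, s0 = base.predict(demo_h)
        m1, s1 = scaled.predict(demo_h)
        np.testing.assert_allclose(m1, a * m0, rtol=1e-6)
        np.testing.assert_allclose(s1, a * s0, rtol=1e-6)
        z0 = nm.zscore(base, demo_h, segs_h["brainstem"])["z"]
        z1 = nm.zscore(scaled, demo_h, a * segs_h["brainstem"])["z"]
        np.testing.assert_allclose(z1, z0, atol=1e-6)


class TestCalibration:
    def test_heldout_controls_are_standard_normal(self, cerebellum_model,
                                                  heldout_cohort):
        demo, segs = heldout_cohort
        rep = nm.calibration_report(cerebellum_model, demo, segs["cerebellum"])
        assert -0.15 < rep["mean_z"] < 0.15
        assert 0.85 < rep["sd_z"] < 1.15
        assert rep["fraction_extreme"] < 0.03

    def test_training_set_rejected_as_heldout(self, cerebellum_model,
                                              control_cohort):
        demo, segs = control_cohort
        with pytest.raises(ValueError, match="overlap"):
            nm.calibration_report(cerebellum_model, demo, segs["cerebellum"])

    def test_empty_heldout_rejected(self, cerebellum_model):
        empty = demo_frame([], [], [])
        with pytest.raises(ValueError, match="empty"):
            nm.calibration_report(cerebellum_model, empty, [])

    def test_noise_free_identity(self):
        """Scoring the training targets of a noise-free interpolator gives
        z ~ 0 (observed equals predicted)."""
        from sklearn.gaussian_process.kernels import DotProduct
        pma = np.linspace(35, 44, 10)
        demo = demo_frame(["male"] * 10, pma, pma - 2.0)
        y = 2.0 + 0.5 * pma
        kernel = ConstantKernel(1.0, "fixed") * DotProduct(1.0, "fixed") \
            + WhiteKernel(1e-8, "fixed")
        model = nm.fit_normative(demo, y, "toy", optimize=False, min_controls=1,
                                 kernel=kernel)
        scores = nm.zscore(model, demo, y)
        assert np.all(np.abs(scores["z"]) < 1e-3)


class TestRecovery:
    @pytest.mark.parametrize("delta", [-2.0, -1.0, 1.0, 2.0])
    def test_injected_shift_recovered_in_median_z(self, control_cohort,
                                                  cerebellum_model, delta):
        """Median z of n=25 atypical subjects with a delta*sigma shift lands
        within +-0.5 of delta."""
        spec = syn.CohortSpec(n=25, seed=int(40 + delta * 10) % 2**16,
                              group="atypical")
        dev = syn.DeviationSpec(mean_shift={"cerebellum": delta})
        demo_a, segs_a, _ = syn.generate_atypical(
            spec, dev, {"cerebellum": cerebellum_model})
        z = nm.zscore(cerebellum_model, demo_a, segs_a["cerebellum"])["z"]
        assert abs(np.median(z) - delta) < 0.5


def test_json_round_trip(cerebellum_model, heldout_cohort):
    demo, segs = heldout_cohort
    clone = nm.NormativeModel.from_json(cerebellum_model.to_json())
    m0, s0 = cerebellum_model.predict(demo)
    m1, s1 = clone.predict(demo)
    np.testing.assert_array_equal(m0, m1)
    np.testing.assert_array_equal(s0, s1)
    state = json.loads(cerebellum_model.to_json())
    assert state["measure_name"] == "cerebellum"
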