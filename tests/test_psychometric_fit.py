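"""Maximum-likelihood psychometric fitting and bootstrap inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import rollvection as rv
from rollvection.psychometric_fit import FitConfig, _extract

from conftest import make_observer, trials_frame


def phi_quadrature(z):
    val, _ = quad(lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi), -12, z)
    return val


def grid_fit(v, y, mu_lo=-10.0, mu_hi=10.0, config=FitConfig()):
    """Brute-force (mu, sigma) grid-search oracle, coarse-to-fine."""
    lo_s, hi_s = config.sigma_bounds

    def nll_grid(mus, sigmas):
        z = (v[None, None, :] - mus[:, None, None]) / sigmas[None, :, None]
        from scipy.special import ndtr

        p = np.clip(ndtr(z), config.eps, 1 - config.eps)
        return -(y * np.log(p) + (1 - y) * np.log1p(-p)).sum(axis=-1)

    mus = np.arange(mu_lo, mu_hi + 1e-9, 0.05)
    sigmas = np.geomspace(lo_s, hi_s, 240)
    nll = nll_grid(mus, sigmas)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    mu_c, sg_c = mus[i], sigmas[j]
    mus = np.arange(mu_c - 0.1, mu_c + 0.1 + 1e-9, 0.005)
    sigmas = np.clip(np.linspace(sg_c * 0.7, sg_c * 1.4, 200), lo_s, hi_s)
    nll = nll_grid(mus, sigmas)
    i, j = np.unravel_index(np.argmin(nll), nll.shape)
    return float(mus[i]), float(sigmas[j])


class TestNegloglik:
    def test_single_trial_at_pse_is_log_two(self):
        trials = trials_frame([0.0], ["CW"])
        assert rv.negloglik(0.0, 1.0, trials) == pytest.approx(np.log(2.0), abs=1e-9)

    def test_four_symmetric_correct_trials(self):
        # all four responses have probability Phi(1); oracle by quadrature
        trials = trials_frame([-1, -1, 1, 1], ["CCW", "CCW", "CW", "CW"])
        expected = 4 * (-np.log(phi_quadrature(1.0)))
        assert rv.negloglik(0.0, 1.0, trials) == pytest.approx(expected, abs=1e-6)

    def test_additivity_under_duplication(self):
        trials = trials_frame([-1, 0.5, 1.2], ["CCW", "CW", "CW"])
        base = rv.negloglik(0.1, 0.9, trials)
        dup = trials_frame([-1, 0.5, 1.2, 1.2], ["CCW", "CW", "CW", "CW"])
        extra = rv.negloglik(0.1, 0.9, trials_frame([1.2], ["CW"]))
        assert rv.negloglik(0.1, 0.9, dup) == pytest.approx(base + extra, abs=1e-9)

    def test_nonpositive_sigma_raises(self):
        with pytest.raises(ValueError):
            rv.negloglik(0.0, 0.0, trials_frame([0.0], ["CW"]))

    def test_empty_input_raises(self):
        import pandas as pd

        with pytest.raises(ValueError):
            rv.negloglik(0.0, 1.0, trials_frame([], []))


class TestFitCdf:
    def test_matches_grid_oracle_on_simulated_sets(self, rng):
        obs = make_observer(mu_cw=0.3, sigma=1.1)
        for n in (40, 80, 100):
            v = rng.uniform(-4, 4, n)
            y = (rng.random(n) < [rv.p_clockwise(obs, x, (8.0, "CW")) for x in v]).astype(float)
            fit = rv.fit_cdf((v, y))
            mu_g, sg_g = grid_fit(v, y)
            assert fit.pse == pytest.approx(mu_g, abs=0.015)
            assert fit.threshold == pytest.approx(sg_g, rel=0.05, abs=0.02)

    def test_perfect_separation_pins_sigma_and_flags(self):
        v = np.array([0.0, 0.5, 1.0, 3.0, 3.5, 4.0])
        y = np.array([0, 0, 0, 1, 1, 1], dtype=float)
        fit = rv.fit_cdf((v, y))
        assert fit.degenerate
        assert fit.threshold == pytest.approx(0.05)  # sigma floor
        assert fit.pse == pytest.approx(2.0, abs=0.5)

    def test_one_category_returns_unconverged_not_exception(self):
        fit = rv.fit_cdf((np.array([1.0, 2.0, 3.0]), np.array([1.0, 1.0, 1.0])))
        assert not fit.converged and fit.degenerate

    def test_mirrored_data_negates_pse(self, rng):
        obs = make_observer(mu_cw=0.7, sigma=1.0)
        v = rng.uniform(-4, 4, 60)
        y = (rng.random(60) < [rv.p_clockwise(obs, x, (8.0, "CW")) for x in v]).astype(float)
        fit = rv.fit_cdf((v, y))
        mirrored = rv.fit_cdf((-v, 1 - y))
        assert mirrored.pse == pytest.approx(-fit.pse, abs=1e-3)
        assert mirrored.threshold == pytest.approx(fit.threshold, rel=1e-3)

    @settings(derandomize=True, max_examples=15, deadline=None)
    @given(shift=st.floats(min_value=-3, max_value=3, allow_nan=False))
    def test_translation_equivariance(self, shift):
        rng = np.random.default_rng(99)
        obs = make_observer(mu_cw=0.2, sigma=1.2)
        v = rng.uniform(-4, 4, 60)
        y = (rng.random(60) < [rv.p_clockwise(obs, x, (8.0, "CW")) for x in v]).astype(float)
        base = rv.fit_cdf((v, y))
        moved = rv.fit_cdf((v + shift, y))
        assert moved.pse == pytest.approx(base.pse + shift, abs=2e-3)
        assert moved.threshold == pytest.approx(base.threshold, rel=2e-3)

    def test_recovers_study_scale_pse_from_staircase_levels(self, rng):
        # generative truth at the study's printed 8-s clockwise PSE
        obs = make_observer(mu_cw=0.55, sigma=1.5)
        levels = np.tile(np.array([-8, -6, -4, -2, -1, 0, 0.55, 1, 2, 4]), 100)
        y = (
            rng.random(levels.size)
            < [rv.p_clockwise(obs, x, (8.0, "CW")) for x in levels]
        ).astype(float)
        fit = rv.fit_cdf((levels, y))
        assert fit.pse == pytest.approx(0.55, abs=0.15)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rv.fit_cdf((np.array([]), np.array([])))


class TestBootstrapFit:
    def test_resample_count_and_reproducibility(self, design_8s):
        obs = make_observer(mu_cw=0.5, mu_ccw=-0.5, sigma=1.0)
        block = rv.run_block(obs, design_8s, seed=4)
        cw = block[block["vfm_direction"] == "CW"]
        a = rv.bootstrap_fit(cw, n_resamples=300, seed=10)
        b = rv.bootstrap_fit(cw, n_resamples=300, seed=10)
        assert len(a.resample_pse) == 300
        np.testing.assert_array_equal(a.resample_pse, b.resample_pse)
        assert a.ci95_pse == tuple(np.percentile(a.resample_pse, [2.5, 97.5]))

    def test_sign_coherent_ci_for_separated_effect(self):
        v = np.concatenate([np.linspace(-4, -0.5, 15), np.linspace(0.5, 4, 15)])
        y = (v > 0).astype(float)
        fr = rv.bootstrap_fit((v, y), n_resamples=400, seed=0)
        assert fr.ci95_pse[0] > -0.6  # excludes large negative values

    def test_degenerate_resamples_retained(self, design_8s):
        obs = make_observer(mu_cw=0.0, mu_ccw=0.0, sigma=0.7)
        block = rv.run_block(obs, design_8s, seed=11)
        fr = rv.bootstrap_fit(block[block["vfm_direction"] == "CW"], n_resamples=400, seed=1)
        assert len(fr.resample_pse) == 400  # nothing dropped
        assert fr.n_degenerate_resamples >= 0
        assert np.isfinite(fr.resample_pse).all()

    def test_low_precision_flag(self):
        v = np.tile([-2.0, -1.0, 1.0, 2.0], 10)
        y = np.tile([0.0, 0.0, 1.0, 1.0], 10)
        assert rv.bootstrap_fit((v, y), n_resamples=50, seed=0).low_precision
        assert not rv.bootstrap_fit((v, y), n_resamples=400, seed=0).low_precision

    def test_doubling_trials_shrinks_median_ci_width(self):
        # monotone information: more staircase trials -> tighter intervals
        widths = {}
        for n_per in (18, 36):
            design = rv.BlockDesign(vfm_duration=8.0, trials_per_staircase=n_per)
            w = []
            for s in range(30):
                obs = make_observer(mu_cw=0.4, mu_ccw=0.4, sigma=1.0)
                block = rv.run_block(obs, design, seed=700 + s)
                fr = rv.bootstrap_fit(
                    block[block["vfm_direction"] == "CW"], n_resamples=300, seed=s
                )
                w.append(fr.ci95_pse[1] - fr.ci95_pse[0])
            widths[n_per] = np.median(w)
        assert widths[36] < widths[18]


class TestConditionDifference:
    def _fit(self, seed, mu=0.5, design=None):
        design = design or rv.BlockDesign(vfm_duration=8.0)
        obs = make_observer(mu_cw=mu, mu_ccw=mu, sigma=1.0)
        block = rv.run_block(obs, design, seed=seed)
        return rv.bootstrap_fit(block[block["vfm_direction"] == "CW"], n_resamples=400, seed=seed)

    def test_identical_fits_give_p_one(self):
        fr = self._fit(1)
        test = rv.condition_difference(fr, fr)
        assert test.delta_pse == 0.0
        assert test.p_value == 1.0
        assert not test.significant

    def test_no_overlap_gives_floor_p(self):
        import dataclasses

        a = self._fit(2)
        b = dataclasses.replace(a, pse=a.pse - 10.0, resample_pse=a.resample_pse - 10.0)
        test = rv.condition_difference(a, b)
        assert test.p_value == pytest.approx(2.0 / 400)
        assert test.significant

    def test_mismatched_resample_counts_raise(self):
        a = self._fit(3)
        import dataclasses

        b = dataclasses.replace(a, resample_pse=a.resample_pse[:100])
        with pytest.raises(ValueError):
            rv.condition_difference(a, b)

    def test_unpaired_variant_agrees_on_separated_case(self):
        import dataclasses

        a = self._fit(4)
        b = dataclasses.replace(a, resample_pse=a.resample_pse - 10.0)
        assert rv.condition_difference(a, b, paired=False).significant

    def test_delta_matches_point_estimates(self):
        a, b = self._fit(5), self._fit(6)
        assert rv.condition_difference(a, b).delta_pse == pytest.approx(a.pse - b.pse)


class TestCombinedShift:
    @pytest.mark.parametrize(
        "cw,ccw,expected",
        [
            (0.55, -0.49, 0.52),  # the study's 8-s pair: half of 1.04
            (-0.12, -0.21, 0.045),  # the study's 1-s pair: half of 0.09
            (0.7, 0.7, 0.0),
        ],
    )
    def test_arithmetic(self, cw, ccw, expected):
        assert rv.combined_shift(cw, ccw) == pytest.approx(expected, abs=1e-12)


class TestExtract:
    def test_accepts_frames_and_arrays(self):
        frame = trials_frame([0.5, -0.5], ["CW", "CCW"])
        v1, y1 = _extract(frame)
        v2, y2 = _extract(([0.5, -0.5], ["CW", "CCW"]))
        np.testing.assert_array_equal(v1, v2)
        np.testing.assert_array_equal(y1, y2)

    def test_rejects_nonbinary_frame(self):
        frame = trials_frame([0.5, -0.5], ["CW", "CCW"])
        frame.loc[1, "response"] = "none"
        with pytest.raises(ValueError):
            _extract(frame)
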