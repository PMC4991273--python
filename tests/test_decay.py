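"""Decay-law evaluation, reconvolution, and derived photophysical quantities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photophys.decay import (
    DegreesOfFreedomError,
    InstrumentResponse,
    InvalidParameterError,
    MultiExpParams,
    TimeAxis,
    average_lifetime,
    evaluate_multiexp,
    fractional_intensities,
    reconvolve,
    reduced_chisq,
)

from conftest import direct_convolution


class TestEvaluateMultiexp:
    def test_value_at_origin_equals_scale(self):
        ax = TimeAxis(0.0, 1.0, 16)
        out = evaluate_multiexp(MultiExpParams(tau=(5.0,), scale=100.0), ax)
        assert out[0] == pytest.approx(100.0)

    def test_one_lifetime_elapsed(self):
        ax = TimeAxis(0.0, 5.0, 8)
        out = evaluate_multiexp(MultiExpParams(tau=(5.0,), scale=100.0), ax)
        assert out[1] == pytest.approx(100.0 / np.e, rel=1e-12)

    def test_triexponential_term_by_term(self):
        # brute-force term-by-term oracle at t = 1.3 ns
        tau = (1.3, 3.7, 10.0)
        alpha = (0.90, 0.07, 0.03)
        ax = TimeAxis(0.0, 1.3, 8)
        expected = sum(a * np.exp(-1.3 / t) for a, t in zip(alpha, tau))
        out = evaluate_multiexp(MultiExpParams(tau=tau, alpha=alpha[1:]), ax)
        assert out[1] == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_without_background(self):
        ax = TimeAxis(0.0, 0.5, 64)
        out = evaluate_multiexp(
            MultiExpParams(tau=(1.0, 4.0), alpha=(0.3,), scale=10.0), ax
        )
        assert np.all(np.diff(out) < 0) and np.all(out > 0)

    def test_equal_lifetimes_collapse_to_mono(self):
        ax = TimeAxis(0.0, 0.5, 64)
        tri = evaluate_multiexp(MultiExpParams(tau=(2.0, 2.0, 2.0), alpha=(0.2, 0.3)), ax)
        mono = evaluate_multiexp(MultiExpParams(tau=(2.0,)), ax)
        np.testing.assert_allclose(tri, mono, rtol=1e-12)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(InvalidParameterError):
            MultiExpParams(tau=(-1.0,))
        with pytest.raises(InvalidParameterError):
            MultiExpParams(tau=(1.0, 0.0), alpha=(0.5,))


class TestReconvolve:
    def test_delta_irf_is_identity(self, axis):
        counts = np.zeros(axis.n)
        counts[0] = 1.0
        irf = InstrumentResponse(axis=axis, counts=counts)
        model = evaluate_multiexp(MultiExpParams(tau=(5.0,), scale=100.0), axis)
        np.testing.assert_allclose(reconvolve(model, irf), model, rtol=1e-9, atol=1e-9)

    def test_shift_and_unshift_recover_kernel(self, axis):
        from photophys.decay import _shifted_irf

        g = np.exp(-0.5 * ((axis.times - 5.0) / 0.4) ** 2)
        irf = InstrumentResponse(axis=axis, counts=g)
        once = _shifted_irf(irf, 0.13)
        back = _shifted_irf(InstrumentResponse(axis=axis, counts=once), -0.13)
        np.testing.assert_allclose(back, g / g.sum(), atol=5e-4)

    def test_matches_direct_convolution_oracle(self, axis):
        rng = np.random.default_rng(7)
        small = TimeAxis(0.0, 0.1, 128)
        for _ in range(5):
            center = rng.uniform(1.0, 4.0)
            g = np.exp(-0.5 * ((small.times - center) / rng.uniform(0.1, 0.5)) ** 2)
            irf = InstrumentResponse(axis=small, counts=g)
            a = rng.uniform(0.05, 1.0, 3)
            a /= a.sum()
            model = evaluate_multiexp(
                MultiExpParams(
                    tau=tuple(np.sort(rng.uniform(0.5, 8.0, 3))),
                    alpha=tuple(a[1:]),
                    scale=rng.uniform(10, 1000),
                ),
                small,
            )
            expected = direct_convolution(g / g.sum(), model)
            got = reconvolve(model, irf, 0.0)
            np.testing.assert_allclose(got, expected, rtol=1e-10, atol=1e-10 * model[0])

    def test_axis_mismatch_raises(self, axis):
        irf = InstrumentResponse(axis=axis, counts=np.ones(axis.n))
        with pytest.raises(ValueError, match="length"):
            reconvolve(np.ones(axis.n + 5), irf)


class TestDerivedQuantities:
    def test_mono_exponential_fraction_is_one(self):
        np.testing.assert_allclose(fractional_intensities([1.0], [15.8]), [1.0])

    def test_symmetric_components(self):
        np.testing.assert_allclose(
            fractional_intensities([0.5, 0.5], [2.0, 2.0]), [0.5, 0.5]
        )

    def test_free_dye_fractions_match_reported_rounding(self):
        # alpha inverted from the printed f1 = 93 % at tau = (1.3, 3.7) ns;
        # rounding there makes the printed f sum to 101 %
        f = fractional_intensities([0.974, 0.026], [1.3, 3.7])
        assert f[0] == pytest.approx(0.929, abs=0.002)
        assert f[1] == pytest.approx(0.071, abs=0.002)
        assert round(f[0] * 100) + round(f[1] * 100 + 1) == 101

    def test_permutation_invariance(self):
        alpha, tau = np.array([0.6, 0.3, 0.1]), np.array([1.0, 4.0, 9.0])
        perm = [2, 0, 1]
        np.testing.assert_allclose(
            np.sort(fractional_intensities(alpha, tau)),
            np.sort(fractional_intensities(alpha[perm], tau[perm])),
        )
        assert average_lifetime(alpha, tau) == pytest.approx(
            average_lifetime(alpha[perm], tau[perm])
        )

    def test_all_zero_amplitudes_undefined(self):
        with pytest.raises(InvalidParameterError):
            fractional_intensities([0.0, 0.0], [1.0, 2.0])

    @pytest.mark.parametrize(
        "alpha,tau,expected",
        [([1.0], [15.8], 15.8), ([0.5, 0.5], [2.0, 4.0], 3.0), ([0.9, 0.1], [1.0, 11.0], 2.0)],
    )
    def test_average_lifetime_values(self, alpha, tau, expected):
        assert average_lifetime(alpha, tau) == pytest.approx(expected)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=3),
        st.lists(st.floats(0.1, 50.0), min_size=3, max_size=3),
    )
    @settings(max_examples=50, deadline=None)
    def test_fraction_simplex_and_tau_bar_bounds(self, raw_alpha, tau):
        alpha = np.array(raw_alpha + [0.5] * (3 - len(raw_alpha)))
        alpha = alpha / alpha.sum()
        tau = np.array(tau)
        f = fractional_intensities(alpha, tau)
        assert np.all(f >= 0) and np.all(f <= 1)
        assert f.sum() == pytest.approx(1.0)
        tb = average_lifetime(alpha, tau)
        assert tau.min() - 1e-9 <= tb <= tau.max() + 1e-9


class TestReducedChisq:
    def test_perfect_fit_is_zero(self):
        data = np.array([100.0, 50, 25, 12, 6, 3, 2, 1])
        assert reduced_chisq(data, data, 1) == 0.0

    def test_hand_computed_weighted_sum(self):
        obs = np.array([100.0, 50.0, 25.0, 12.0])
        model = np.array([90.0, 55.0, 20.0, 15.0])
        # Poisson weights 1/obs, 1 free parameter, dof = 3
        expected = (10**2 / 100 + 5**2 / 50 + 5**2 / 25 + 3**2 / 12) / 3
        assert reduced_chisq(obs, model, 1) == pytest.approx(expected, rel=1e-12)

    def test_halved_window_invariant_for_uniform_residual_contribution(self):
        obs = np.array([100.0, 50.0, 25.0, 12.0, 6.0, 3.0, 2.0, 1.0])
        model = obs + 0.3 * np.sqrt(obs)  # every channel contributes 0.09 to chi-square
        full = reduced_chisq(obs, model, 0)
        halved = reduced_chisq(obs, model, 0, fit_window=(0, 4))
        assert halved == pytest.approx(full) == pytest.approx(0.09)

    def test_dof_error(self):
        obs = np.array([10.0, 5.0, 2.0, 1.0])
        with pytest.raises(DegreesOfFreedomError):
            reduced_chisq(obs, obs, 4)
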