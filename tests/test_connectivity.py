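import numpy as np
import pytest
from scipy.special import iv

from zerolag.connectivity import (aec, build_matrices, mean_phase_delay,
                                  orth_aec, plv, wpli_from_imag_segments,
                                  wrap_angle)
from zerolag.spectral import RegionTimeSeries, analytic_signal, welch_csd
from zerolag.connectivity import (coherence_matrix, imag_coherency_matrix,
                                  wpli_matrix, plv_matrix, aec_matrix,
                                  orth_aec_matrix, phase_delay_matrix)

FS = 250.0
T = np.arange(0, 20, 1 / FS)


def lagged_pair(phi, f=10.0):
    return np.vstack([np.cos(2 * np.pi * f * T),
                      np.cos(2 * np.pi * f * T - phi)])


class TestMeanPhaseDelay:
    def test_constant_offset(self):
        n = 1000
        tau, r = mean_phase_delay(np.full(n, 0.7), np.full(n, 0.2))
        assert tau == pytest.approx(0.5)
        assert r == pytest.approx(1.0)

    def test_symmetric_offsets_cancel(self):
        tau, _ = mean_phase_delay(np.array([0.1, -0.1]), np.zeros(2))
        assert tau == pytest.approx(0.0, abs=1e-12)

    def test_antipodal_offsets_give_pi(self):
        tau, _ = mean_phase_delay(np.array([np.pi - 0.1, -(np.pi - 0.1)]),
                                  np.zeros(2))
        assert abs(tau) == pytest.approx(np.pi)

    def test_zero_resultant_is_flagged(self):
        tau, r = mean_phase_delay(np.array([0.0, np.pi / 2, np.pi, -np.pi / 2]),
                                  np.zeros(4))
        assert np.isnan(tau) and r < 1e-12

    def test_antisymmetry_up_to_wrap(self, rng):
        a = rng.uniform(-np.pi, np.pi, 500)
        b = rng.uniform(-np.pi, np.pi, 500)
        t1, _ = mean_phase_delay(a, b)
        t2, _ = mean_phase_delay(b, a)
        assert wrap_angle(t1 + t2) == pytest.approx(0.0, abs=1e-10)


class TestPlv:
    def test_constant_lag_gives_one(self):
        assert plv(np.linspace(0, 50, 999), np.linspace(0, 50, 999) - 1.2) \
            == pytest.approx(1.0)

    def test_uniform_phases_near_rayleigh_level(self, rng):
        # Rayleigh statistic: E[PLV] ~ sqrt(pi / (4 N)) for uniform phases
        n = 5000
        vals = [plv(rng.uniform(-np.pi, np.pi, n),
                    rng.uniform(-np.pi, np.pi, n)) for _ in range(20)]
        expected = np.sqrt(np.pi / (4 * n))
        assert np.mean(vals) == pytest.approx(expected, rel=0.25)

    def test_von_mises_matches_bessel_ratio(self, rng):
        # closed form: mean resultant of von Mises(kappa) is I1(k)/I0(k)
        dtheta = rng.vonmises(0.0, 2.0, 200_000)
        assert plv(dtheta, np.zeros_like(dtheta)) == pytest.approx(
            iv(1, 2.0) / iv(0, 2.0), abs=0.01)

    def test_plv_equals_resultant_of_mean_phase_delay(self, rng):
        a = rng.uniform(-np.pi, np.pi, 1000)
        b = rng.uniform(-np.pi, np.pi, 1000)
        _, r = mean_phase_delay(a, b)
        assert plv(a, b) == pytest.approx(r, abs=1e-14)


class TestSpectralEstimators:
    def test_self_coherence_one_imag_zero(self):
        x = np.cos(2 * np.pi * 10 * T)
        csd = welch_csd(RegionTimeSeries(np.vstack([x, x]), FS, band="alpha"))
        with pytest.warns(UserWarning):
            coh = coherence_matrix(csd, "alpha").weights
            img = imag_coherency_matrix(csd, "alpha").weights
        assert coh[0, 1] == pytest.approx(1.0, abs=1e-9)
        assert img[0, 1] == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("phi", np.arange(0.1, 3.01, 0.29))
    def test_attenuation_law_imgcoh_over_coherence_is_sin_phi(self, phi):
        # analytic oracle: for a noiseless narrowband pair at constant lag
        # phi, ImgCoh/Coh = |sin phi|
        csd = welch_csd(RegionTimeSeries(lagged_pair(phi), FS, band="alpha"))
        with pytest.warns(UserWarning):
            coh = coherence_matrix(csd, "alpha").weights[0, 1]
            img = imag_coherency_matrix(csd, "alpha").weights[0, 1]
        assert img / coh == pytest.approx(abs(np.sin(phi)), rel=0.01)

    def test_independent_noise_coherence_near_bias_floor(self, rng):
        data = rng.standard_normal((2, 5000))
        csd = welch_csd(RegionTimeSeries(data, FS))
        coh = coherence_matrix(csd, "alpha").weights[0, 1]
        # 19 Welch segments -> bias floor around 1/sqrt(19) ~ 0.23
        assert coh < 0.4


class TestWpli:
    def test_consistent_sign_gives_one(self):
        assert wpli_from_imag_segments([0.3, 0.3]) == pytest.approx(1.0)

    def test_mixed_sign_arithmetic(self):
        assert wpli_from_imag_segments([0.3, -0.1]) == pytest.approx(0.5)

    def test_pure_zero_lag_defined_as_zero(self):
        assert wpli_from_imag_segments([0.0, 0.0]) == 0.0

    def test_zero_lag_common_signal_inflates_plv_not_wpli(self, rng):
        # adding a shared zero-lag component leaves the imaginary
        # cross-spectrum centred on zero while coherence/PLV rise
        noise = rng.standard_normal((2, 5000))
        common = rng.standard_normal(5000)
        data = noise + 2.0 * common
        ts = RegionTimeSeries(data, FS)
        csd = welch_csd(ts)
        w = wpli_matrix(csd, "alpha").weights[0, 1]
        c = coherence_matrix(csd, "alpha").weights[0, 1]
        p = plv_matrix(analytic_signal(ts)).weights[0, 1]
        assert c > 0.6 and p > 0.4
        assert w < 0.3


class TestAec:
    def test_identical_envelopes(self, rng):
        e = rng.uniform(0.1, 2.0, 1000)
        assert aec(e, e) == pytest.approx(1.0)

    def test_negative_affine_relation_gives_magnitude_one(self, rng):
        e = rng.uniform(0.1, 2.0, 1000)
        assert aec(e, -3.0 * e + 10.0) == pytest.approx(1.0)

    def test_independent_envelopes_near_zero(self, rng):
        vals = [aec(rng.uniform(0, 1, 5000), rng.uniform(0, 1, 5000))
                for _ in range(10)]
        assert np.mean(vals) < 0.05

    def test_flat_envelope_is_flagged(self):
        with pytest.warns(UserWarning, match="zero-variance"):
            assert np.isnan(aec(np.ones(100), np.arange(100.0)))


class TestOrthAec:
    def test_collinear_signals_return_zero(self):
        x = np.cos(2 * np.pi * 10 * T)
        with pytest.warns(UserWarning, match="collinear"):
            assert orth_aec(x, 0.5 * x, FS) == 0.0

    def test_shared_amplitude_modulation_survives_orthogonalisation(self, rng):
        # two sources at quadrature carriers sharing one slow modulator:
        # genuine amplitude coupling that orthogonalisation must keep
        slow = np.convolve(rng.standard_normal(len(T)),
                           np.ones(250) / 250, mode="same")
        mod = np.exp(slow / max(slow.std(), 1e-12))   # strongly varying, > 0
        x = mod * np.cos(2 * np.pi * 10 * T)
        y = mod * np.cos(2 * np.pi * 10 * T - np.pi / 2)
        # null level for independent 20-s signals is ~0.02; genuine shared
        # modulation must stand clearly above it
        assert orth_aec(x, y, FS) > 0.2

    def test_leakage_mixture_suppressed_relative_to_aec(self, rng):
        # one true source leaking into both channels at zero lag
        from zerolag.spectral import bandpass_filter
        src = bandpass_filter(RegionTimeSeries(
            rng.standard_normal((3, len(T))), FS), "alpha").data
        x = src[0] + 0.1 * src[1]
        y = 0.8 * src[0] + 0.1 * src[2]
        env = analytic_signal(RegionTimeSeries(np.vstack([x, y]), FS))
        plain = aec(env.envelope[0], env.envelope[1])
        orth = orth_aec(x, y, FS)
        assert orth < 0.5 * plain


class TestBuildMatrices:
    def test_shapes_symmetry_ranges(self, rng):
        epoch = RegionTimeSeries(rng.standard_normal((4, 5000)), FS)
        out, tau = build_matrices(epoch, "alpha")
        assert set(out) == {"coherence", "img_coh", "plv", "wpli", "aec",
                            "orth_aec"}
        for m, mat in out.items():
            w = mat.weights
            assert w.shape == (4, 4)
            np.testing.assert_allclose(w, w.T, atol=1e-12)
            assert np.all(np.diag(w) == 0)
            assert np.nanmin(w) >= 0 and np.nanmax(w) <= 1
        assert tau.tau.shape == (4, 4)
        assert np.all(np.abs(tau.tau[~np.isnan(tau.tau)]) <= np.pi)

    def test_region_permutation_equivariance(self, rng):
        data = rng.standard_normal((4, 5000))
        perm = [2, 0, 3, 1]
        out1, _ = build_matrices(RegionTimeSeries(data, FS), "alpha")
        out2, _ = build_matrices(RegionTimeSeries(data[perm], FS), "alpha")
        for m in out1:
            np.testing.assert_allclose(
                out1[m].weights[np.ix_(perm, perm)], out2[m].weights,
                atol=1e-10)

    def test_repeatability(self, rng):
        epoch = RegionTimeSeries(rng.standard_normal((3, 5000)), FS)
        out1, t1 = build_matrices(epoch, "theta")
        out2, t2 = build_matrices(epoch, "theta")
        for m in out1:
            np.testing.assert_array_equal(out1[m].weights, out2[m].weights)
        np.testing.assert_array_equal(t1.tau, t2.tau)

    def test_global_amplitude_rescaling_invariance(self, rng):
        # all six estimators are scale-free
        data = rng.standard_normal((3, 5000))
        out1, _ = build_matrices(RegionTimeSeries(data, FS), "alpha")
        out2, _ = build_matrices(RegionTimeSeries(37.5 * data, FS), "alpha")
        for m in out1:
            np.testing.assert_allclose(out1[m].weights, out2[m].weights,
                                       atol=1e-9)
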