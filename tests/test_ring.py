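import numpy as np
import pytest

import balv1 as b
from balv1.ring import (
    BalancedStateError,
    DEFAULT_N_MAX,
    cosine_profile,
    profile_from_function,
)


class TestProfiles:
    def test_cosine_profile_modes(self):
        c = cosine_profile(0.44)
        assert c[0] == 1.0 and c[1] == 0.22 and np.all(c[2:] == 0)

    def test_quadrature_matches_closed_form(self):
        c_num = profile_from_function(lambda t: 1 + 0.44 * np.cos(2 * np.pi * t))
        assert abs(c_num[1] - 0.22) < 1e-10
        assert np.all(np.abs(c_num[2:]) < 1e-10)

    def test_unnormalized_profile_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            profile_from_function(lambda t: 2.0 + 0 * t)
        with pytest.raises(ValueError, match="nonnegative"):
            profile_from_function(lambda t: np.cos(2 * np.pi * t))

    def test_negative_modulation_rejected(self):
        with pytest.raises(ValueError):
            cosine_profile(1.5)


class TestFourierInteractions:
    def test_flat_profile_no_modulated_modes(self):
        j = b.fourier_interactions(b.RingSpec())
        for key in j:
            assert np.all(j[key][1:] == 0.0)
            assert j[key][0] > 0

    def test_reconnected_first_mode(self):
        # J_EE(1) = G_EE eps_cE / 2 = 32 * 0.22 = 7.04
        spec = b.RingSpec.reconnected(0.44, 0.22)
        j = b.fourier_interactions(spec)
        assert j[("E", "E")][1] == pytest.approx(7.04)
        assert j[("I", "E")][1] == pytest.approx(96 * 0.22)
        assert j[("E", "I")][1] == pytest.approx(96 * 0.11)


class TestBalancedRates:
    def test_mean_rate_ratio(self):
        # (|G_II| - |G_EI|) / (|G_IE| - |G_EE|) = 32/64 = 0.5 at equal drive
        sol = b.balanced_rates(b.RingSpec.reconnected(0.3, 0.3))
        assert sol.nu_e[0] / sol.nu_i[0] == pytest.approx(0.5)

    def test_higher_modes_vanish(self):
        sol = b.balanced_rates(b.RingSpec.reconnected(0.44, 0.22))
        assert np.all(sol.nu_e[2:] == 0.0)
        assert np.all(sol.nu_i[2:] == 0.0)
        assert sol.nu_e[1] != 0.0

    def test_unmodulated_drive_flat_rates(self):
        sol = b.balanced_rates(b.RingSpec.reconnected(0.44, 0.22, rho=0.0))
        assert sol.nu_e[1] == 0.0
        assert np.allclose(sol.rates_e, sol.rates_e[0])

    def test_salt_and_pepper_mode_divergence(self):
        with pytest.raises(BalancedStateError, match="singular"):
            b.balanced_rates(b.RingSpec())  # flat profiles, modulated drive

    def test_feasibility_violation_named(self):
        with pytest.raises(BalancedStateError, match="J_EI"):
            b.balanced_rates(b.RingSpec.reconnected(0.1, 0.1, g_ei=200.0))

    def test_matches_dense_discretized_solve(self):
        """Mode-wise balance solution vs a dense linear solve of the
        discretized convolution system on a 512-point ring, to 1e-8."""
        n = 512
        spec = b.RingSpec.reconnected(0.44, 0.22)
        theta = np.arange(n) / n
        d = theta[None, :] - theta[:, None]
        c_e = 1 + 0.44 * np.cos(2 * np.pi * d)
        c_i = 1 + 0.22 * np.cos(2 * np.pi * d)
        i_ext = 1 + 2 * spec.rho * np.cos(2 * np.pi * theta)
        # block system: J_AE*nu_E - J_AI*nu_I + I_A = 0, circular convolution
        j_ee = spec.g_ee * c_e / n
        j_ei = spec.g_ei * c_i / n
        j_ie = spec.g_ie * c_e / n
        j_ii = spec.g_ii * c_i / n
        a = np.block([[j_ee, -j_ei], [j_ie, -j_ii]])
        rhs = -np.concatenate([i_ext, i_ext])
        # cosine profiles make the operator low-rank (modes 0, +-1 only);
        # the minimum-norm solution zeroes the undetermined higher modes,
        # matching the balanced-state convention
        nu = np.linalg.lstsq(a, rhs, rcond=None)[0]
        sol = b.balanced_rates(spec, n_grid=n)
        modes_dense_e = np.fft.fft(nu[:n])[: DEFAULT_N_MAX + 1].real / n
        modes_dense_i = np.fft.fft(nu[n:])[: DEFAULT_N_MAX + 1].real / n
        assert np.max(np.abs(modes_dense_e - sol.nu_e)) < 1e-8
        assert np.max(np.abs(modes_dense_i - sol.nu_i)) < 1e-8


class TestSelectivityPrediction:
    def test_closed_form_value(self):
        sel = b.selectivity_prediction(b.RingSpec.reconnected(0.44, 0.22))
        assert sel["E"] == pytest.approx(2 * 0.06 / 0.44)
        assert sel["I"] == pytest.approx(2 * 0.06 / 0.22)

    def test_doubling_eps_halves_prediction(self):
        s1 = b.selectivity_prediction(b.RingSpec.reconnected(0.2, 0.2))
        s2 = b.selectivity_prediction(b.RingSpec.reconnected(0.4, 0.4))
        assert s1["E"] / s2["E"] == pytest.approx(2.0)

    def test_independent_of_coupling_magnitudes(self):
        s1 = b.selectivity_prediction(b.RingSpec.reconnected(0.3, 0.25))
        s2 = b.selectivity_prediction(
            b.RingSpec.reconnected(0.3, 0.25, g_ee=64.0, g_ei=192.0, g_ie=192.0, g_ii=256.0)
        )
        assert s1 == s2

    def test_consistent_with_balanced_modes(self):
        spec = b.RingSpec.reconnected(0.44, 0.22)
        sol = b.balanced_rates(spec)
        sel = b.selectivity_prediction(spec)
        assert sol.nu_e[1] / sol.nu_e[0] == pytest.approx(sel["E"], abs=1e-12)

    def test_identity_recovers_two_rho(self):
        for eps in (0.11, 0.22, 0.44, 0.9):
            sel = b.selectivity_prediction(b.RingSpec.reconnected(eps, eps))
            assert abs(sel["E"] * eps - 2 * 0.06) < 1e-12

    def test_flat_profile_signalled(self):
        with pytest.raises(BalancedStateError, match="unmodulated"):
            b.selectivity_prediction(b.RingSpec())


class TestStability:
    def test_flat_profiles_stable_and_feasible(self):
        rep = b.stability_report(b.RingSpec())
        assert rep.feasible  # 1 > 96/128 > 32/96
        assert rep.stable
        assert np.all(rep.trace_ok) and np.all(rep.det_ok)

    def test_published_boundary(self):
        # |G_EE/G_II| = 1/4 -> eps_cI_min = 0.44/4 = 0.11
        rep = b.stability_report(b.RingSpec.reconnected(0.44, 0.22), eps_ce=0.44)
        assert rep.eps_ci_min == pytest.approx(0.11, abs=1e-9)

    def test_unstable_combination(self):
        rep = b.stability_report(b.RingSpec.reconnected(0.44, 0.03))
        assert not rep.trace_ok[1]
        assert not rep.stable

    def test_stable_combination(self):
        rep = b.stability_report(b.RingSpec.reconnected(0.44, 0.22))
        assert rep.stable

    def test_boundary_matches_eigenvalue_scan(self):
        """The bisected boundary must agree with the sign change of the
        leading eigenvalue of the mode-1 interaction matrix to 1e-10."""
        from scipy.optimize import brentq

        spec = b.RingSpec.reconnected(0.44, 0.22)
        rep = b.stability_report(spec, eps_ce=0.44, tol=1e-13)

        def lead_real(eps_ci):
            a = np.array(
                [
                    [spec.g_ee * 0.44 / 2, -spec.g_ei * eps_ci / 2],
                    [spec.g_ie * 0.44 / 2, -spec.g_ii * eps_ci / 2],
                ]
            )
            return np.max(np.linalg.eigvals(a).real)

        boundary = brentq(lead_real, 1e-6, 1.0, xtol=1e-14)
        assert abs(rep.eps_ci_min - boundary) < 1e-10

    def test_predictions_scale_invariant_in_g(self):
        base = b.RingSpec.reconnected(0.44, 0.22)
        scaled = b.RingSpec.reconnected(
            0.44, 0.22, g_ee=96.0, g_ei=288.0, g_ie=288.0, g_ii=384.0
        )
        s_base, s_scaled = b.balanced_rates(base), b.balanced_rates(scaled)
        ratio = s_base.nu_e[0] / s_base.nu_i[0]
        assert s_scaled.nu_e[0] / s_scaled.nu_i[0] == pytest.approx(ratio)
        # absolute rates scale down with the couplings
        assert s_scaled.nu_e[0] == pytest.approx(s_base.nu_e[0] / 3)


class TestSTDPTheory:
    def test_unselective_population(self):
        th = b.stdp_theory(3.0, 3.0, 0.0, 0.0, alpha=0.204, j0=1.0, j1=0.1)
        assert th.dj1 == 0.0
        assert th.dj0 > 0
        assert th.d_selectivity > 0  # pure mean growth raises selectivity

    def test_quadratic_selectivity_dependence(self):
        # the more selective population builds ~4.5x more functional
        # connectivity: (0.57 / 0.27)^2
        hi = b.stdp_theory(3.0, 3.0, 0.57, 0.57, alpha=0.204)
        lo = b.stdp_theory(3.0, 3.0, 0.27, 0.27, alpha=0.204)
        assert hi.dj1 / lo.dj1 == pytest.approx((0.57 / 0.27) ** 2)
        assert hi.dj1 / lo.dj1 == pytest.approx(4.46, abs=0.01)

    def test_sign_flip_with_alpha(self):
        pos = b.stdp_theory(3.0, 3.0, 0.3, 0.3, alpha=0.204)
        neg = b.stdp_theory(3.0, 3.0, 0.3, 0.3, alpha=-0.204)
        assert neg.dj0 == -pos.dj0 and neg.dj1 == -pos.dj1
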