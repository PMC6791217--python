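"""Spectra, characteristic coefficients and stability certificates."""

import numpy as np
import pytest
from scipy.optimize import brentq

from oncodelay.model import (
    ModelParameters,
    TransmissionTerm,
    basic_reproduction_number,
    beta_total,
    equilibria,
    with_target_r0,
)
from oncodelay.scenarios import TABLE_RATES, FixtureSpec, preset, random_fixture
from oncodelay.stability import (
    characteristic_value,
    dfe_delay_robustness,
    dfe_spectrum_tau0,
    endemic_char_coefficients,
    endemic_delay_condition,
    endemic_tau0_stability,
    jacobian,
)


def coefficient_form(params, lam):
    """Characteristic value rebuilt from the extracted coefficients."""
    c = endemic_char_coefficients(params)
    S = sum(t.beta * np.exp(-lam * t.tau) for t in params.transmission)
    return lam**3 + c.A * lam**2 + c.B_tilde * lam + c.C + S * (c.D * lam + c.E)


class TestDFESpectrum:
    def test_first_eigenvalue_is_minus_growth_rate(self, fig3):
        spec = dfe_spectrum_tau0(fig3.params)
        assert spec.lambda1 == pytest.approx(-0.206, rel=1e-12)
        assert spec.lambda3 < 0.0

    def test_threshold_eigenvalue_vanishes_at_unit_r0(self):
        p = with_target_r0(preset("fig5").params, 1.0)
        spec = dfe_spectrum_tau0(p)
        assert abs(spec.lambda3) < 1e-9

    def test_supthreshold_eigenvalue_positive(self, fig5):
        assert dfe_spectrum_tau0(fig5.params).lambda3 > 0.0

    @pytest.mark.parametrize("name", ["fig3", "fig5"])
    def test_matches_numeric_jacobian_eigenvalues(self, name):
        p = preset(name).params
        J = jacobian(p, equilibria(p).E1, beta_total(p)).real
        eigs = np.sort(np.linalg.eigvals(J).real)
        spec = dfe_spectrum_tau0(p)
        closed = np.sort([spec.lambda1, spec.lambda2, spec.lambda3])
        assert np.allclose(eigs, closed, atol=1e-9)

    def test_sign_change_located_at_unit_r0_by_bisection(self):
        base = preset("fig5").params

        def lambda3_of_b(b):
            return dfe_spectrum_tau0(
                ModelParameters(
                    b=b, transmission=base.transmission, **TABLE_RATES
                )
            ).lambda3

        b_crossing = brentq(lambda3_of_b, 0.5, 3.0, xtol=1e-14)
        from oncodelay.model import burst_size_for_r0

        b_unit = burst_size_for_r0(base, 1.0)
        assert b_crossing == pytest.approx(b_unit, rel=1e-9)


class TestDFEDelayRobustness:
    def test_single_term_has_no_cross_sum(self):
        p = ModelParameters(
            b=0.5, transmission=(TransmissionTerm(1.1e-4, 2.0),), **TABLE_RATES
        )
        cert = dfe_delay_robustness(p)
        assert cert.a2_min == 0.0
        assert cert.issued

    def test_subthreshold_certificate_issued(self, fig3):
        cert = dfe_delay_robustness(fig3.params)
        r0 = basic_reproduction_number(fig3.params)
        g = beta_total(fig3.params) * fig3.params.K + fig3.params.gamma
        assert cert.a3 == pytest.approx(
            fig3.params.delta**2 * g**2 * (1 - r0**2), rel=1e-12
        )
        assert cert.a3 > 0.0 and cert.issued

    def test_supthreshold_certificate_withheld(self, fig5):
        cert = dfe_delay_robustness(fig5.params)
        assert cert.a3 < 0.0 and not cert.issued

    def test_empty_grid_rejected(self, fig3):
        with pytest.raises(ValueError):
            dfe_delay_robustness(fig3.params, omega_grid=[])


class TestLemmaIdentity:
    def test_square_of_sum_expansion(self, rng):
        """(sum a_i)^2 = sum a_i^2 + 2 sum_{i<j} a_i a_j, numerically."""
        for _ in range(100):
            n = rng.integers(2, 9)
            a = rng.normal(size=n) * 10.0 ** rng.integers(-3, 4)
            lhs = a.sum() ** 2
            rhs = (a**2).sum() + 2.0 * sum(
                a[i] * a[j] for i in range(n) for j in range(i + 1, n)
            )
            # tolerance relative to the term scale: the two sides cancel
            # identically, so the residual is pure floating-point noise
            scale = np.abs(a).sum() ** 2
            assert abs(lhs - rhs) <= 1e-12 * scale


class TestEndemicCoefficients:
    def test_single_delay_scenario_values(self, fig5):
        c = endemic_char_coefficients(fig5.params)
        assert c.A == pytest.approx(0.516204, abs=1e-5)
        assert c.D == pytest.approx(824.698, abs=1e-2)
        assert c.E == pytest.approx(1.145798, abs=1e-5)
        assert c.C + c.beta0 * c.E == pytest.approx(-1.0095e-5, rel=1e-3)
        assert c.K3 == pytest.approx(-1.3027e-8, rel=1e-3)

    @pytest.mark.parametrize("name", ["fig4", "fig5"])
    def test_closed_form_coefficient_expressions(self, name):
        """A, C, D, E match their closed forms in the equilibrium values."""
        p = preset(name).params
        xs, ys, vs = equilibria(p).Estar
        r, K, rho, delta, b, gamma = p.r, p.K, p.rho, p.delta, p.b, p.gamma
        beta = beta_total(p)
        c = endemic_char_coefficients(p)
        assert c.A == pytest.approx(
            beta * xs + gamma + delta + (r / K) * xs, rel=1e-10
        )
        assert c.C == pytest.approx(
            (r / K) * xs * delta * (beta * xs + gamma)
            - delta * beta**2 * xs * vs,
            rel=1e-9,
        )
        assert c.D == pytest.approx(
            (r / K + rho) * xs * vs - b * delta * xs, rel=1e-10
        )
        assert c.E == pytest.approx(
            ((r / K + rho) * gamma + beta * delta * b) * xs * vs
            - (r / K) * b * delta * xs**2,
            rel=1e-10,
        )

    def test_coefficient_form_equals_determinant_oracle(self, rng):
        """Both characteristic-function routes agree at random complex lambda."""
        fixtures = [preset("fig4").params, preset("fig5").params] + [
            random_fixture(FixtureSpec(seed=s, target_r0_range=(1.2, 2.5))).params
            for s in range(5)
        ]
        for p in fixtures:
            for _ in range(20):
                lam = complex(rng.normal(), rng.normal())
                a = coefficient_form(p, lam)
                b = characteristic_value(p, "Estar", lam)
                assert abs(a - b) <= 1e-9 * max(1.0, abs(a))

    def test_absent_endemic_rejected(self, fig3):
        with pytest.raises(ValueError):
            endemic_char_coefficients(fig3.params)


class TestRouthHurwitz:
    def test_multi_delay_endemic_scenario_stable(self, fig4):
        report = endemic_tau0_stability(fig4.params)
        assert report.verdict == "stable"
        assert report.H2 > 0.0

    def test_leading_and_constant_coefficients_positive_above_threshold(self):
        for seed in range(10):
            p = random_fixture(
                FixtureSpec(seed=seed, target_r0_range=(1.05, 3.0))
            ).params
            report = endemic_tau0_stability(p)
            assert report.b1 > 0.0
            assert report.b3 > 0.0

    @pytest.mark.parametrize("name", ["fig4", "fig5"])
    def test_cubic_roots_match_zero_delay_jacobian_eigenvalues(self, name):
        p = preset(name).params
        report = endemic_tau0_stability(p)
        roots = np.roots([1.0, report.b1, report.b2, report.b3])
        J = jacobian(p, equilibria(p).Estar, beta_total(p)).real
        eigs = np.linalg.eigvals(J)
        assert np.allclose(
            np.sort_complex(roots), np.sort_complex(eigs), atol=1e-8
        )


class TestEndemicDelayCondition:
    def test_single_delay_reduces_to_constants(self, fig5):
        c = endemic_char_coefficients(fig5.params)
        omega = np.linspace(0.01, 2.0, 50)
        cert = endemic_delay_condition(fig5.params, omega_grid=omega)
        assert cert.K1 == pytest.approx(c.K1, rel=1e-12)
        assert cert.K2_min == pytest.approx(c.K2, rel=1e-12)
        assert cert.K3_min == pytest.approx(c.K3, rel=1e-12)

    def test_hopf_capable_scenario_not_certified(self, fig5):
        cert = endemic_delay_condition(fig5.params)
        assert cert.K3_min < 0.0 and not cert.issued

    def test_multi_delay_scenario_certified(self, fig4):
        cert = endemic_delay_condition(fig4.params)
        assert cert.tau0_verdict == "stable"
        assert cert.issued  # all crossing coefficients stay positive


class TestCharacteristicValue:
    def test_minus_growth_rate_is_always_a_dfe_root(self, fig3, fig5):
        for sc in (fig3, fig5):
            val = characteristic_value(sc.params, "E1", -sc.params.r)
            assert abs(val) < 1e-9

    def test_zero_is_not_a_dfe_root_away_from_threshold(self, fig3, fig5):
        for sc in (fig3, fig5):
            assert abs(characteristic_value(sc.params, "E1", 0.0)) > 1e-6
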