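"""Forward-model math: equations of state, isotherms, inversions, areas."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tensiofit import (
    IsothermParams,
    R,
    RegionAnchor,
    area_per_molecule,
    format_area,
    frumkin_concentration,
    frumkin_tension,
    gibbs_gamma_inf,
    langmuir_tension,
    modified_frumkin_concentration,
    modified_frumkin_tension,
    modified_langmuir_tension,
    solve_coverage,
    solve_coverage_anchored,
)

GAMMA0 = 72.0
T = 298.15


class TestAreaPerMolecule:
    @pytest.mark.parametrize(
        "gamma_inf_umol, expected",
        [
            (1.16, 143.15),  # lipopeptide saturation density
            (1.00, 166.06),  # closed form 1e20/(1e-6 * N_A)
        ],
    )
    def test_values(self, gamma_inf_umol, expected):
        assert area_per_molecule(gamma_inf_umol * 1e-6) == pytest.approx(expected, abs=0.01)

    def test_sdbs_value_rounds_to_45(self):
        assert format_area(area_per_molecule(3.67e-6)) == "45"

    @pytest.mark.parametrize(
        "gamma_inf_umol, printed",
        [(2.70, "61.5"), (1.16, "143"), (3.33, "50"), (0.97, "171")],
    )
    def test_report_rounding(self, gamma_inf_umol, printed):
        assert format_area(area_per_molecule(gamma_inf_umol * 1e-6)) == printed

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            area_per_molecule(0.0)


class TestGibbsGammaInf:
    def test_hand_value(self):
        assert gibbs_gamma_inf(-2.404, 1, T) * 1e6 == pytest.approx(0.97, abs=0.005)

    def test_identity_construction(self):
        slope = -R * T * 1e-6 * 1e3  # slope that encodes exactly 1 umol/m^2
        assert gibbs_gamma_inf(slope, 1, T) == pytest.approx(1e-6, rel=1e-12)

    def test_prefactor_halves_estimate(self):
        assert gibbs_gamma_inf(-2.404, 2, T) == pytest.approx(
            gibbs_gamma_inf(-2.404, 1, T) / 2, rel=1e-12
        )

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="decrease"):
            gibbs_gamma_inf(0.5, 1, T)


class TestLangmuirTension:
    def test_zero_concentration_gives_solvent_tension(self):
        p = IsothermParams(3.33e-6, K=2.0)
        assert langmuir_tension(p, 0.0, GAMMA0, T) == GAMMA0

    def test_unit_log_drop(self):
        # KC = e - 1 makes ln(1 + KC) = 1, so the drop is exactly RT*Gamma_inf
        p = IsothermParams(3.33e-6, K=1.0)
        got = langmuir_tension(p, np.e - 1.0, GAMMA0, T)
        assert got == pytest.approx(72.0 - 8.254, abs=0.001)

    def test_vanishing_adsorption(self):
        p = IsothermParams(1e-15, K=2.0)
        assert langmuir_tension(p, 100.0, GAMMA0, T) == pytest.approx(GAMMA0, abs=1e-6)

    def test_strictly_decreasing(self):
        p = IsothermParams(2.84e-6, K=5.0)
        c = np.linspace(0, 10, 50)
        g = langmuir_tension(p, c, GAMMA0, T)
        assert np.all(np.diff(g) < 0)


class TestFrumkinForward:
    def test_zero_coverage_gives_solvent_tension(self):
        p = IsothermParams(1.16e-6, K=10.0, beta=2.8)
        assert frumkin_tension(p, 0.0, GAMMA0, T) == GAMMA0
        assert frumkin_concentration(p, 0.0) == 0.0

    def test_half_coverage_attractive(self):
        p = IsothermParams(1.16e-6, K=10.0, beta=2.8)
        got = frumkin_tension(p, 0.5 * p.gamma_inf, GAMMA0, T)
        assert got == pytest.approx(71.01, abs=0.01)

    def test_half_coverage_beta_zero_equals_langmuir_at_half_saturation(self):
        p = IsothermParams(1.16e-6, K=10.0, beta=0.0)
        got = frumkin_tension(p, 0.5 * p.gamma_inf, GAMMA0, T)
        assert got == pytest.approx(70.01, abs=0.01)
        assert got == pytest.approx(langmuir_tension(p, 1.0 / p.K, GAMMA0, T), rel=1e-12)

    def test_half_coverage_concentration(self):
        p0 = IsothermParams(1.16e-6, K=10.0, beta=0.0)
        assert frumkin_concentration(p0, 0.5 * p0.gamma_inf) == pytest.approx(1 / p0.K, rel=1e-12)
        p = IsothermParams(1.16e-6, K=10.0, beta=2.8)
        assert frumkin_concentration(p, 0.5 * p.gamma_inf) == pytest.approx(
            np.exp(-1.4) / p.K, rel=1e-12
        )

    def test_saturated_coverage_rejected(self):
        p = IsothermParams(1.16e-6, K=10.0, beta=2.8)
        with pytest.raises(ValueError):
            frumkin_tension(p, p.gamma_inf, GAMMA0, T)
        with pytest.raises(ValueError):
            frumkin_concentration(p, 1.01 * p.gamma_inf)

    def test_beta_at_monotone_bound_rejected(self):
        with pytest.raises(ValueError, match="non-monotone"):
            IsothermParams(1e-6, K=1.0, beta=4.0)


class TestSolveCoverage:
    def test_zero_and_half_saturation(self):
        p = IsothermParams(1.16e-6, K=10.0, beta=0.0)
        assert solve_coverage(p, 0.0) == 0.0
        assert solve_coverage(p, 1.0 / p.K) == pytest.approx(p.gamma_inf / 2, rel=1e-10)

    def test_inverts_attractive_case(self):
        p = IsothermParams(1.16e-6, K=10.0, beta=2.8)
        c = frumkin_concentration(p, 0.5 * p.gamma_inf)
        assert solve_coverage(p, c) / p.gamma_inf == pytest.approx(0.5, abs=1e-8)

    def test_negative_concentration_rejected(self):
        p = IsothermParams(1.16e-6, K=10.0, beta=0.0)
        with pytest.raises(ValueError):
            solve_coverage(p, -1.0)

    @pytest.mark.parametrize("beta", [-2.1, -0.8, 0.0, 2.8])
    def test_round_trip_identity(self, beta):
        p = IsothermParams(2.0e-6, K=5.0, beta=beta)
        theta = np.linspace(0.01, 0.99, 25)
        c = frumkin_concentration(p, theta * p.gamma_inf)
        back = frumkin_concentration(p, solve_coverage(p, c))
        np.testing.assert_allclose(back, c, rtol=1e-8)

    @given(
        beta=st.floats(-9.0, 3.9),
        log_kc=st.floats(-6.0, 6.0),
        gamma_inf=st.floats(0.5e-6, 5e-6),
    )
    def test_round_trip_property(self, beta, log_kc, gamma_inf):
        p = IsothermParams(gamma_inf, K=7.0, beta=beta)
        c = np.exp(log_kc) / p.K
        cov = solve_coverage(p, c)
        assert 0 <= cov < p.gamma_inf
        assert frumkin_concentration(p, cov) == pytest.approx(c, rel=1e-8)


class TestBetaZeroCollapse:
    def test_frumkin_reproduces_langmuir(self):
        p = IsothermParams(2.84e-6, K=5.0, beta=0.0)
        c = np.geomspace(1e-3, 10.0, 40) / p.K
        cov = solve_coverage(p, c)
        frum = frumkin_tension(p, cov, GAMMA0, T)
        lang = langmuir_tension(p, c, GAMMA0, T)
        np.testing.assert_allclose(frum, lang, rtol=1e-9)


class TestGibbsLimit:
    def test_langmuir_slope_approaches_gibbs_plateau(self):
        # at KC >> 1 the gamma-lnC slope tends to -n R T Gamma_inf
        p = IsothermParams(2.0e-6, K=1.0)
        c = 1e3 / p.K
        h = 1e-5
        slope = (
            langmuir_tension(p, c * np.exp(h), GAMMA0, T)
            - langmuir_tension(p, c * np.exp(-h), GAMMA0, T)
        ) / (2 * h)
        assert slope == pytest.approx(-R * T * p.gamma_inf * 1e3, rel=0.01)


class TestAnchoredModels:
    def _setup(self, beta=2.8):
        p = IsothermParams(1.16e-6, K=10.0, beta=beta)
        anchor = RegionAnchor(0.5, 50.0, 0.6 * p.gamma_inf)
        return p, anchor

    def test_anchor_identity(self):
        p, anchor = self._setup()
        cov12 = anchor.coverage_12
        assert modified_frumkin_tension(p, cov12, anchor, T) == pytest.approx(50.0, rel=1e-14)
        assert modified_frumkin_concentration(p, cov12, anchor) == pytest.approx(0.5, rel=1e-14)
        assert modified_langmuir_tension(p, anchor.c_12, anchor, T) == pytest.approx(50.0, rel=1e-14)

    def test_hand_value_tension(self):
        p, anchor = self._setup()
        got = modified_frumkin_tension(p, 0.9 * p.gamma_inf, anchor, T)
        assert got == pytest.approx(47.83, abs=0.01)

    def test_hand_value_concentration_beta_zero(self):
        p, anchor = self._setup(beta=0.0)
        got = modified_frumkin_concentration(p, 0.9 * p.gamma_inf, anchor)
        assert got == pytest.approx(0.5 + 7.5 / p.K, rel=1e-12)

    def test_coverage_below_anchor_rejected(self):
        p, anchor = self._setup()
        with pytest.raises(ValueError, match="anchor"):
            modified_frumkin_tension(p, 0.3 * p.gamma_inf, anchor, T)
        with pytest.raises(ValueError, match="anchor"):
            modified_frumkin_concentration(p, 0.3 * p.gamma_inf, anchor)

    @pytest.mark.parametrize("beta", [-2.1, 0.0, 2.8])
    def test_reduction_to_plain_model_when_anchor_on_curve(self, beta):
        # anchored equations equal the plain ones when the anchor satisfies them
        p = IsothermParams(1.16e-6, K=10.0, beta=beta)
        cov12 = 0.4 * p.gamma_inf
        anchor = RegionAnchor(
            frumkin_concentration(p, cov12),
            frumkin_tension(p, cov12, GAMMA0, T),
            cov12,
        )
        cov = np.linspace(0.4, 0.98, 30) * p.gamma_inf
        np.testing.assert_allclose(
            modified_frumkin_tension(p, cov, anchor, T),
            frumkin_tension(p, cov, GAMMA0, T),
            rtol=1e-12,
        )
        np.testing.assert_allclose(
            modified_frumkin_concentration(p, cov, anchor),
            frumkin_concentration(p, cov),
            rtol=1e-12,
        )

    def test_anchored_solver_round_trip(self):
        p, anchor = self._setup()
        cov = np.linspace(0.6, 0.99, 20) * p.gamma_inf
        c = modified_frumkin_concentration(p, cov, anchor)
        back = solve_coverage_anchored(p, c, anchor)
        np.testing.assert_allclose(back, cov, rtol=1e-8)

    def test_modified_langmuir_reduces_to_plain_at_small_anchor(self):
        p = IsothermParams(2.0e-6, K=10.0)
        anchor = RegionAnchor(1e-12, GAMMA0)
        c = np.geomspace(0.01, 5.0, 20)
        np.testing.assert_allclose(
            modified_langmuir_tension(p, c, anchor, T),
            langmuir_tension(p, c, GAMMA0, T),
            rtol=1e-9,
        )


class TestMonotonicity:
    @pytest.mark.parametrize("beta", [-5.0, -0.8, 0.0, 2.8, 3.9])
    def test_tension_strictly_decreasing_in_concentration(self, beta):
        p = IsothermParams(2.0e-6, K=5.0, beta=beta)
        c = np.geomspace(1e-4, 1e3, 60) / p.K
        cov = solve_coverage(p, c)
        g = frumkin_tension(p, cov, GAMMA0, T)
        assert np.all(np.diff(g) < 0)
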