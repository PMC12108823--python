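"""Forward-model unit and property tests.

Frozen expected values were computed with an independent term-by-term
evaluation script written before the package (scratch oracle); they are
asserted here to full float precision.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dielspec import (
    EPS_0,
    ColeColeParams,
    DielectricSpectrum,
    FrequencyGrid,
    ImprovedColeColeParams,
    ModelEvaluationError,
    effective_conductivity,
    evaluate_cole_cole,
    evaluate_improved,
)

# oracle values: single-pole model with/without the linear term
ORACLE_IMPROVED_VT30_433MHZ = (52.02673579409861, 1.7899709628868434)
ORACLE_IMPROVED_VT80_915MHZ = (35.800676418860455, 1.6468457154733427)
ORACLE_COLE_VT30_433MHZ = (61.98420220521067, 1.7899709628868434)
ORACLE_SIGMA_VT30_433MHZ = 0.043118384452447596


def _grid(*freqs):
    return FrequencyGrid(np.asarray(freqs, dtype=float))


class TestFrequencyGrid:
    def test_default_grid(self):
        g = FrequencyGrid.default()
        assert len(g) == 101
        assert g.freqs_hz[0] == 1.0e8 and g.freqs_hz[-1] == 1.0e9
        assert np.all(np.diff(g.freqs_hz) > 0)

    def test_rejects_non_increasing(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _grid(2e8, 2e8, 3e8)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError, match="> 0"):
            _grid(0.0, 1e8)

    def test_out_of_band_warns_not_errors(self):
        with pytest.warns(UserWarning, match="outside"):
            g = _grid(1e6, 1e8)
        assert len(g) == 2

    def test_omega(self):
        g = _grid(433e6)
        assert g.omega[0] == 2 * np.pi * 433e6


class TestSpectrumInvariants:
    def test_length_mismatch(self, default_grid):
        with pytest.raises(ValueError, match="grid length"):
            DielectricSpectrum(default_grid, np.ones(5), np.ones(5))

    def test_negative_loss_rejected(self):
        g = _grid(2e8, 3e8)
        with pytest.raises(ValueError, match="non-negative"):
            DielectricSpectrum(g, np.ones(2), np.array([0.1, -0.1]))


class TestParamInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"eps_inf": 0.0},
            {"delta_eps": -1.0},
            {"tau_s": 0.0},
            {"alpha": 1.0},
            {"alpha": -0.1},
            {"sigma_s": -1e-3},
        ],
    )
    def test_cole_cole_rejects(self, kwargs):
        base = dict(eps_inf=3.0, delta_eps=50.0, tau_s=6e-12, alpha=0.0, sigma_s=0.02)
        base.update(kwargs)
        with pytest.raises(ValueError):
            ColeColeParams(**base)

    def test_a_coef_magnitude_bounded(self):
        base = ColeColeParams(3.0, 50.0, 6e-12, 0.0, 0.02)
        with pytest.raises(ValueError, match="a_coef"):
            ImprovedColeColeParams(base, 1e-5)

    def test_tau_ps(self):
        p = ColeColeParams(3.0, 50.0, 6.04e-12, 0.0, 0.02)
        assert p.tau_ps == pytest.approx(6.04)


class TestColeCole:
    def test_no_dispersion_no_conduction(self):
        p = ColeColeParams(4.2, 0.0, 1e-12, 0.3, 0.0)
        s = evaluate_cole_cole(p, _grid(5e8))
        assert s.eps_real[0] == pytest.approx(4.2, rel=1e-15)
        assert s.eps_loss[0] == 0.0

    def test_debye_at_unit_omega_tau(self):
        f = 5e8
        tau = 1.0 / (2 * np.pi * f)
        p = ColeColeParams(3.0, 40.0, tau, 0.0, 0.0)
        s = evaluate_cole_cole(p, _grid(f))
        # 1/(1+j) = (1-j)/2
        assert s.eps_real[0] == pytest.approx(3.0 + 20.0, rel=1e-14)
        assert s.eps_loss[0] == pytest.approx(20.0, rel=1e-14)

    def test_oracle_vt30_433mhz(self, lung_table):
        s = evaluate_cole_cole(lung_table[30].base, _grid(433e6))
        assert s.eps_real[0] == pytest.approx(ORACLE_COLE_VT30_433MHZ[0], rel=1e-14)
        assert s.eps_loss[0] == pytest.approx(ORACLE_COLE_VT30_433MHZ[1], rel=1e-14)


class TestImproved:
    def test_zero_a_reduces_to_cole_cole(self, lung_table, default_grid):
        base = lung_table[30].base
        improved = ImprovedColeColeParams(base, 0.0)
        s1 = evaluate_improved(improved, default_grid)
        s0 = evaluate_cole_cole(base, default_grid)
        np.testing.assert_array_equal(s1.eps_real, s0.eps_real)
        np.testing.assert_array_equal(s1.eps_loss, s0.eps_loss)

    def test_linear_term_only(self):
        p = ImprovedColeColeParams.from_values(3.0, 0.0, 1e-12, 0.0, 0.0, 2e-9)
        g = _grid(2e8, 5e8, 9e8)
        s = evaluate_improved(p, g)
        np.testing.assert_allclose(s.eps_real, 3.0 + 2e-9 * g.omega, rtol=1e-15)
        np.testing.assert_array_equal(s.eps_loss, np.zeros(3))

    def test_oracle_vt80_915mhz(self, lung_table):
        s = evaluate_improved(lung_table[80], _grid(915e6))
        assert s.eps_real[0] == pytest.approx(ORACLE_IMPROVED_VT80_915MHZ[0], rel=1e-14)
        assert s.eps_loss[0] == pytest.approx(ORACLE_IMPROVED_VT80_915MHZ[1], rel=1e-14)

    def test_oracle_vt30_433mhz(self, lung_table):
        s = evaluate_improved(lung_table[30], _grid(433e6))
        assert s.eps_real[0] == pytest.approx(ORACLE_IMPROVED_VT30_433MHZ[0], rel=1e-14)
        assert s.eps_loss[0] == pytest.approx(ORACLE_IMPROVED_VT30_433MHZ[1], rel=1e-14)

    def test_unphysical_real_part_raises(self, default_grid):
        # strongly negative linear coefficient drives eps_real below zero
        p = ImprovedColeColeParams.from_values(3.0, 10.0, 6e-12, 0.0, 0.01, -1e-7)
        with pytest.raises(ModelEvaluationError, match="non-positive real"):
            evaluate_improved(p, default_grid)


params_strategy = st.builds(
    ColeColeParams,
    eps_inf=st.floats(1.5, 5.0),
    delta_eps=st.floats(0.0, 200.0),
    tau_s=st.floats(0.1e-12, 100e-12),
    alpha=st.floats(0.0, 0.5),
    sigma_s=st.floats(0.0, 1.0),
)


class TestReductionProperties:
    @settings(max_examples=50, deadline=None)
    @given(params=params_strategy, a=st.floats(-5e-9, 5e-9))
    def test_improved_a_zero_identity(self, params, a):
        g = FrequencyGrid.default(21)
        s_cc = evaluate_cole_cole(params, g)
        s_imp = evaluate_improved(ImprovedColeColeParams(params, 0.0), g)
        np.testing.assert_array_equal(s_imp.eps_real, s_cc.eps_real)
        np.testing.assert_array_equal(s_imp.eps_loss, s_cc.eps_loss)

    @settings(max_examples=50, deadline=None)
    @given(params=params_strategy)
    def test_alpha_zero_matches_closed_form_debye(self, params):
        p = ColeColeParams(params.eps_inf, params.delta_eps, params.tau_s, 0.0, params.sigma_s)
        g = FrequencyGrid.default(21)
        w = g.omega
        wt = w * p.tau_s
        real = p.eps_inf + p.delta_eps / (1 + wt**2)
        loss = p.delta_eps * wt / (1 + wt**2) + p.sigma_s / (w * EPS_0)
        s = evaluate_cole_cole(p, g)
        np.testing.assert_allclose(s.eps_real, real, rtol=1e-12)
        np.testing.assert_allclose(s.eps_loss, loss, rtol=1e-12)


class TestEffectiveConductivity:
    def test_round_trip_constant_sigma(self, default_grid):
        sigma = 0.02
        loss = sigma / (default_grid.omega * EPS_0)
        s = DielectricSpectrum(default_grid, np.full(101, 50.0), loss)
        np.testing.assert_allclose(effective_conductivity(s), sigma, rtol=1e-12)

    def test_zero_loss(self, default_grid):
        s = DielectricSpectrum(default_grid, np.full(101, 50.0), np.zeros(101))
        np.testing.assert_array_equal(effective_conductivity(s), np.zeros(101))

    def test_oracle_composition_vt30(self, lung_table):
        s = evaluate_improved(lung_table[30], _grid(433e6))
        assert effective_conductivity(s)[0] == pytest.approx(
            ORACLE_SIGMA_VT30_433MHZ, rel=1e-14
        )


class TestPhysicalTrends:
    def test_conduction_dominated_loss_decreases_with_frequency(self, default_grid):
        # with no relaxation the loss is sigma/(omega eps0), strictly decreasing
        p = ColeColeParams(3.0, 0.0, 1e-12, 0.0, 0.1)
        s = evaluate_cole_cole(p, default_grid)
        assert np.all(np.diff(s.eps_loss) < 0)

    def test_conductivity_433mhz_strictly_decreasing_in_vt(self, lung_table):
        # the packaged table gives a strictly decreasing conductivity at 433 MHz;
        # note eps_real and the 915 MHz conductivity are NOT strictly monotone
        # for the printed parameter rows (the 50 and 70 mL rows break the order)
        g = _grid(433e6)
        sig = [
            effective_conductivity(evaluate_improved(lung_table[vt], g))[0]
            for vt in sorted(lung_table.entries)
        ]
        assert np.all(np.diff(sig) < 0)

    def test_endpoint_trend_30_vs_80(self, lung_table):
        # both quantities decrease between the extreme tidal volumes at both
        # ISM frequencies
        for f in (433e6, 915e6):
            g = _grid(f)
            lo = evaluate_improved(lung_table[30], g)
            hi = evaluate_improved(lung_table[80], g)
            assert lo.eps_real[0] > hi.eps_real[0]
            assert effective_conductivity(lo)[0] > effective_conductivity(hi)[0]
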