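"""Static model ingredients: grid, sigmoids, kernels, delays, alpha profile."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nfdbs.model import (
    ActivationParams,
    KernelParams,
    build_alpha,
    build_delays,
    build_grid,
    build_kernels,
    mm_to_normalized,
    sigmoid,
    sigmoid_slope,
    velocity_to_normalized,
)


class TestGrid:
    def test_nominal_partition(self):
        g = build_grid(60)
        assert g.n_stn == g.n_gpe == 10
        assert list(g.stn_indices) == list(range(10))
        assert list(g.gpe_indices) == list(range(50, 60))
        assert g.silent_indices.size == 40
        assert g.dr == pytest.approx(1 / 60)
        # mean STN position = 1/12 normalized = 1.25 mm on the 15 mm domain
        assert g.stn_center == pytest.approx(1 / 12)
        assert g.stn_center * g.scale_mm == pytest.approx(1.25)

    def test_smallest_grid(self):
        g = build_grid(6)
        assert g.n_stn == g.n_gpe == 1
        assert g.stn_positions[0] == pytest.approx(1 / 12)
        assert g.gpe_positions[0] == pytest.approx(11 / 12)
        assert g.silent_indices.size == 4

    def test_positions_uniform_interior(self):
        g = build_grid(36)
        assert np.all(g.positions > 0) and np.all(g.positions < 1)
        assert np.allclose(np.diff(g.positions), g.dr)

    @pytest.mark.parametrize("m", [0, 5, 7, 61, -6])
    def test_rejects_bad_node_count(self, m):
        with pytest.raises(ValueError, match="multiple of 6"):
            build_grid(m)

    def test_refinement_preserves_mm_geometry(self):
        """Doubling m moves population spans and centers by less than a cell."""
        g1, g2 = build_grid(60), build_grid(120)
        cell_mm = g1.dr * g1.scale_mm
        for a, b in [(g1.stn_positions, g2.stn_positions), (g1.gpe_positions, g2.gpe_positions)]:
            assert abs(a.mean() - b.mean()) * g1.scale_mm < cell_mm
            assert abs(a.min() - b.min()) * g1.scale_mm < cell_mm
            assert abs(a.max() - b.max()) * g1.scale_mm < cell_mm


class TestSigmoid:
    STN = ActivationParams(300.0, 17.0)
    GPE = ActivationParams(400.0, 75.0)

    def test_baseline_at_zero(self):
        assert sigmoid(0.0, self.STN) == pytest.approx(17.0)
        assert sigmoid(0.0, self.GPE) == pytest.approx(75.0)

    def test_saturation_limits(self):
        assert sigmoid(1e6, self.STN) == pytest.approx(300.0)
        assert sigmoid(-1e6, self.STN) == pytest.approx(0.0, abs=1e-12)

    def test_value_at_nominal_cortical_drive(self):
        # S1(337.5) = 300*17 / (17 + 283 e^{-4.5}), high-precision scalar
        expected = 300 * 17 / (17 + 283 * np.exp(-4.5))
        assert expected == pytest.approx(253.18, abs=0.01)
        assert sigmoid(337.5, self.STN) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("p", [STN, GPE])
    def test_max_slope_is_unity(self, p):
        """The 4/m exponent normalizes the maximum gain to exactly 1."""
        x = np.linspace(-3 * p.max_rate, 3 * p.max_rate, 200001)
        num = sigmoid_slope(x, p)
        assert abs(num.max() - 1.0) < 1e-6

    @given(
        m=st.floats(10.0, 1000.0),
        frac=st.floats(0.01, 0.99),
    )
    @settings(max_examples=50, deadline=None)
    def test_max_slope_unity_for_any_params(self, m, frac):
        p = ActivationParams(m, frac * m)
        x_star = (m / 4) * np.log((m - p.base_rate) / p.base_rate)
        assert sigmoid_slope(x_star, p) == pytest.approx(1.0, abs=1e-9)
        # strictly increasing and bounded
        xs = np.linspace(x_star - m, x_star + m, 101)
        vals = sigmoid(xs, p)
        assert np.all(np.diff(vals) > 0)
        assert np.all((vals > 0) & (vals < m))


class TestKernels:
    def test_invariants(self, nominal_model):
        ks = nominal_model.kernels
        assert np.all(ks.W11 == 0.0)
        assert np.all(ks.W12 <= 0.0)
        assert np.all(ks.W21 >= 0.0)
        assert np.all(ks.W22 <= 0.0)
        assert np.all(np.diag(ks.W22) == 0.0)

    def test_w22_toeplitz_symmetry(self, nominal_model):
        """GPe lateral weights depend only on the inter-node distance."""
        W = nominal_model.kernels.W22
        for off in range(1, W.shape[0]):
            d = np.diagonal(W, off)
            assert np.allclose(d, d[0])
            assert np.allclose(d, np.diagonal(W, -off))

    def test_topographic_alignment_peak(self):
        """Homologous STN/GPe positions couple at full amplitude K."""
        g = build_grid(60)
        ks = build_kernels(g, KernelParams(), quadrature="plain")
        assert np.allclose(np.diag(ks.W12), -30.0)
        assert np.allclose(np.diag(ks.W21), 38.0)
        # off-diagonal couplings are strictly weaker
        assert np.all(np.abs(ks.W12) <= 30.0 + 1e-12)

    def test_measure_quadrature_scaling(self):
        g = build_grid(60)
        plain = build_kernels(g, KernelParams(), quadrature="plain")
        meas = build_kernels(g, KernelParams(), quadrature="measure")
        assert np.allclose(meas.W12, plain.W12 * g.dr)
        assert meas.measure == pytest.approx(g.dr)


class TestAlpha:
    def test_full_photosensitization(self):
        g = build_grid(60)
        a = build_alpha(g)
        assert a.values.shape == (10,)
        assert np.all(a.values > 0)
        # peak at the node(s) nearest the 1.25 mm STN center, amplitude ~1
        assert a.values.max() > 0.99
        assert int(np.argmax(a.values)) in (4, 5)
        # edges attenuated by light absorption but nonzero
        assert 0 < a.values[0] < a.values.max()

    def test_degeneracy_count_and_reproducibility(self):
        g = build_grid(60)
        a1 = build_alpha(g, degeneracy=0.5, seed=7)
        a2 = build_alpha(g, degeneracy=0.5, seed=7)
        a3 = build_alpha(g, degeneracy=0.5, seed=8)
        assert a1.n_zeroed == 5
        assert np.array_equal(a1.values, a2.values)
        assert not np.array_equal(a1.values, a3.values)

    @pytest.mark.parametrize("degeneracy,expected", [(0.0, 0), (0.25, 2), (0.5, 5), (1.0, 10)])
    def test_zeroed_counts(self, degeneracy, expected):
        g = build_grid(60)
        assert build_alpha(g, degeneracy=degeneracy, seed=0).n_zeroed == expected

    def test_full_degeneracy_disables_actuation(self):
        g = build_grid(60)
        assert np.all(build_alpha(g, degeneracy=1.0, seed=0).values == 0.0)

    def test_rejects_bad_degeneracy(self):
        with pytest.raises(ValueError):
            build_alpha(build_grid(60), degeneracy=1.5)


class TestDelays:
    def test_hand_computed_extremes(self):
        g = build_grid(60)
        dt_ = build_delays(g, c1=0.166, c2=0.09, dt=1.0)
        # farthest pair: node 0 (r=0.00833) to node 59 (r=0.99167)
        assert dt_.steps_from_stn[59, 0] == round(0.983333 / 0.166)  # == 6
        assert dt_.steps_from_gpe[0, 59] == 11  # round(10.93)
        assert dt_.max_steps == 11
        assert np.all(np.diag(dt_.steps_from_stn) == 0)

    def test_monotone_in_distance_and_velocity(self):
        g = build_grid(60)
        slow = build_delays(g, c1=0.1, c2=0.05, dt=1.0)
        fast = build_delays(g, c1=0.2, c2=0.1, dt=1.0)
        row = slow.steps_from_stn[0]  # distances increase with index from node 0
        assert np.all(np.diff(row) >= 0)
        assert np.all(fast.steps_from_stn <= slow.steps_from_stn)
        assert np.all(fast.steps_from_gpe <= slow.steps_from_gpe)

    def test_rejects_nonpositive_velocity(self):
        with pytest.raises(ValueError):
            build_delays(build_grid(6), c1=0.0, c2=0.1, dt=1.0)


class TestUnitConversions:
    def test_velocities_match_nominal_table(self):
        assert velocity_to_normalized(2.5) == pytest.approx(0.1667, abs=5e-4)
        assert velocity_to_normalized(1.4) == pytest.approx(0.0933, abs=5e-4)

    def test_full_domain_length(self):
        assert mm_to_normalized(15.0) == pytest.approx(1.0)
        assert mm_to_normalized(1.25) == pytest.approx(1 / 12)

    def test_rejects_bad_scale(self):
        with pytest.raises(ValueError):
            mm_to_normalized(1.0, scale_mm=0.0)
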