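import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from osteosim.kinetics import (
    BMUHistory,
    BMUParams,
    Layer,
    LayerStack,
    MineralizationLaw,
    activation_frequency,
    apply_turnover,
    focal_balance,
    formation_rate,
    layer_mineral,
    net_rate,
    origination_rate,
    resorption_rate,
    stack_summary,
)


class TestActivation:
    def test_no_inhibition_at_zero_stimulus(self):
        assert activation_frequency(0.0, 1.0, 5e-3) == pytest.approx(5e-3)

    def test_half_at_reference(self):
        assert activation_frequency(2.0, 2.0, 5e-3) == pytest.approx(2.5e-3)

    def test_full_inhibition_limit(self):
        assert activation_frequency(1e12, 1.0, 5e-3) == pytest.approx(0.0, abs=1e-14)

    def test_decreasing_in_stimulus(self):
        z = np.linspace(0, 5, 50)
        f = activation_frequency(z, 1.0, 5e-3)
        assert np.all(np.diff(f) < 0)

    def test_requires_positive_reference(self):
        with pytest.raises(ValueError):
            activation_frequency(1.0, 0.0, 5e-3)

    @pytest.mark.parametrize(
        "f_or, s_v, expected", [(0.0, 4.0, 0.0), (5e-3, 0.0, 0.0), (5e-3, 4.0, 0.02)]
    )
    def test_origination_rate(self, f_or, s_v, expected):
        assert origination_rate(f_or, s_v) == pytest.approx(expected)


class TestFocalBalance:
    def test_dead_zone_is_balanced(self, bmu):
        assert focal_balance(0.0, 1.0, bmu) == 1.0
        assert focal_balance(bmu.w, 1.0, bmu) == 1.0
        assert focal_balance(-bmu.w, 1.0, bmu) == 1.0

    def test_saturation_values(self, bmu):
        assert focal_balance(1.0, 1.0, bmu) == pytest.approx(1.15)
        assert focal_balance(-1.0, 1.0, bmu) == pytest.approx(0.85)

    def test_kappa_scales_linearly(self, bmu):
        # the whole curve shifts down multiplicatively with κ
        assert focal_balance(0.0, 0.903, bmu) == pytest.approx(0.903)
        for x in (-1.0, -2e-3, 0.0, 2e-3, 1.0):
            assert focal_balance(x, 0.7, bmu) == pytest.approx(
                0.7 * focal_balance(x, 1.0, bmu)
            )

    @given(st.floats(-0.01, 0.01))
    def test_continuity(self, x):
        bmu = BMUParams()
        eps = 1e-9
        left, right = focal_balance(x - eps, 1.0, bmu), focal_balance(x + eps, 1.0, bmu)
        assert abs(left - right) < 1e-5

    @given(st.lists(st.floats(-0.02, 0.02), min_size=2, max_size=10))
    def test_non_decreasing(self, xs):
        bmu = BMUParams()
        xs = sorted(xs)
        vals = [focal_balance(x, 1.0, bmu) for x in xs]
        assert all(b - a >= -1e-12 for a, b in zip(vals, vals[1:]))


class TestRates:
    """Formation/resorption from a constant history equal A·v·(T_R+T_I+T_F)·c.

    With a constant origination rate c, the active-BMU density is
    c·(T_R+T_I+T_F) everywhere, so both windowed averages return
    A_BMU·v_BMU·c·(T_R+T_I+T_F), scaled by f_bb for formation.
    """

    def test_zero_history(self, bmu):
        h = BMUHistory.equilibrium(0.0, bmu)
        assert formation_rate(h, bmu) == 0.0
        assert resorption_rate(h, bmu) == 0.0

    def test_constant_history_steady_state(self, bmu):
        c = 1.7e-3
        h = BMUHistory.equilibrium(c, bmu)
        expected = bmu.A_BMU * bmu.v_BMU * bmu.lifespan * c
        assert resorption_rate(h, bmu) == pytest.approx(expected, rel=1e-12)
        assert formation_rate(h, bmu) == pytest.approx(expected, rel=1e-12)
        assert net_rate(formation_rate(h, bmu), resorption_rate(h, bmu)) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_formation_linear_in_fbb(self, bmu):
        c = 1.7e-3
        h = BMUHistory.equilibrium(c, bmu)
        for _ in range(2 * bmu.lifespan):  # flush with f_bb = 0.9
            h.push(c, 0.9)
        expected = 0.9 * bmu.A_BMU * bmu.v_BMU * bmu.lifespan * c
        assert formation_rate(h, bmu) == pytest.approx(expected, rel=1e-10)
        assert resorption_rate(h, bmu) == pytest.approx(expected / 0.9, rel=1e-10)

    def test_pulse_leaves_resorption_window(self, bmu):
        """An activation pulse stops driving resorption once it is older
        than the BMU lifespan plus the resorption window."""
        h = BMUHistory.equilibrium(0.0, bmu)
        h.push(1.0, 1.0)
        assert resorption_rate(h, bmu) > 0.0
        for _ in range(bmu.lifespan + bmu.T_R):
            h.push(0.0, 1.0)
        assert resorption_rate(h, bmu) == pytest.approx(0.0, abs=1e-15)

    def test_warmup_required(self, bmu):
        h = BMUHistory(bmu)
        h.push(1e-3, 1.0)
        with pytest.raises(ValueError, match="warm-up"):
            formation_rate(h, bmu)

    def test_net_rate(self):
        assert net_rate(1.0, 1.0) == 0.0
        assert net_rate(0.9, 1.0) == pytest.approx(-0.1)
        assert net_rate(0.5, 0.0) == 0.5
        with pytest.raises(ValueError):
            net_rate(-0.1, 0.0)

    def test_incremental_sums_match_naive_resummation(self, bmu, rng):
        """Sliding-window rates agree with brute-force re-summation over
        500 random steps (independent oracle for the ring-buffer algebra)."""
        W = bmu.lifespan
        h = BMUHistory.equilibrium(2e-3, bmu)
        ndot_log = [2e-3] * (2 * W)
        fbb_log = [1.0] * (2 * W)
        scale = bmu.A_BMU * bmu.v_BMU
        for _ in range(500):
            nd = float(rng.uniform(0, 5e-3))
            fb = float(rng.uniform(0.5, 1.15))
            h.push(nd, fb)
            ndot_log.append(nd)
            fbb_log.append(fb)
            # naive: active density at day τ is the sum of the previous
            # lifespan of originations, windows summed directly
            nact = lambda i: sum(ndot_log[i - W + 1 : i + 1])
            t = len(ndot_log)
            vr = scale / bmu.T_R * sum(nact(i) for i in range(t - bmu.T_R, t))
            vf = scale / bmu.T_F * sum(
                nact(i) * fbb_log[i] for i in range(t - W, t - bmu.T_R - bmu.T_I)
            )
            assert resorption_rate(h, bmu) == pytest.approx(vr, abs=1e-10)
            assert formation_rate(h, bmu) == pytest.approx(vf, abs=1e-10)


class TestMineralization:
    def test_endpoints(self, law):
        assert layer_mineral(0.0, law) == pytest.approx(law.alpha_0)
        assert layer_mineral(1e9, law) == pytest.approx(law.alpha_max)

    def test_one_time_constant(self, law):
        expected = law.alpha_max - (law.alpha_max - law.alpha_0) / np.e
        assert layer_mineral(law.tau_days, law) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(0, 1e5), st.floats(1, 1e4))
    def test_non_decreasing(self, age, dt):
        law = MineralizationLaw()
        assert layer_mineral(age + dt, law) >= layer_mineral(age, law)

    def test_validation(self):
        with pytest.raises(ValueError):
            MineralizationLaw(alpha_0=0.8, alpha_max=0.7)
        with pytest.raises(ValueError):
            layer_mineral(-1.0, MineralizationLaw())


class TestLayerStack:
    def test_conservation_balanced(self):
        stack = LayerStack([Layer(0.5, 1000.0)])
        apply_turnover(stack, 1e-3, 1e-3, dt=1.0)
        assert stack.total_vb == pytest.approx(0.5, abs=1e-15)

    def test_pure_aging(self):
        stack = LayerStack([Layer(0.4, 100.0), Layer(0.1, 10.0)])
        apply_turnover(stack, 0.0, 0.0, dt=2.5)
        assert [l.age for l in stack.layers] == [102.5, 12.5]
        assert stack.total_vb == pytest.approx(0.5)

    def test_lifo_digging_consumes_young_layers_first(self):
        """Resorption larger than the two youngest layers digs partially
        into the third, leaving deeper layers untouched (brute-force case)."""
        stack = LayerStack(
            [Layer(0.30, 5000.0), Layer(0.02, 400.0), Layer(0.01, 200.0), Layer(0.01, 100.0)],
            coalesce_gap_days=30.0,
        )
        apply_turnover(stack, 0.0, 0.025, dt=1.0)
        # 0.01 + 0.01 removed fully, 0.005 taken from the 0.02 layer
        assert len(stack) == 2
        assert stack.layers[-1].thickness_vb == pytest.approx(0.015, abs=1e-15)
        assert stack.layers[-1].age == pytest.approx(401.0)
        assert stack.layers[0].thickness_vb == pytest.approx(0.30)

    def test_over_resorption_clamps_with_warning(self):
        stack = LayerStack([Layer(0.01, 100.0)])
        with pytest.warns(RuntimeWarning, match="degenerate"):
            stack.resorb(0.02)
        assert stack.total_vb == 0.0

    def test_coalescing_merges_close_ages(self):
        stack = LayerStack([Layer(0.1, 20.0)], coalesce_gap_days=30.0)
        stack.push(0.1, age=0.0)
        assert len(stack) == 1
        assert stack.layers[0].age == pytest.approx(10.0)  # thickness-weighted
        stack.push(0.1, age=0.0)  # merged age 10 - 0 < 30 still merges
        assert len(stack) == 1

    @given(
        st.lists(
            st.tuples(st.floats(0, 2e-3), st.floats(0, 2e-3)), min_size=1, max_size=200
        )
    )
    def test_volume_bookkeeping_property(self, rates):
        """total_vb tracks the integral of (v̇_f − v̇_r)·dt to 1e-10."""
        stack = LayerStack([Layer(0.5, 10000.0)])
        expected = 0.5
        for vf, vr in rates:
            vr = min(vr, stack.total_vb)  # stay clear of the degenerate clamp
            apply_turnover(stack, vf, vr, dt=1.0)
            expected += vf - vr
        assert stack.total_vb == pytest.approx(expected, abs=1e-10)


class TestStackSummary:
    def test_single_layer(self, law, constants):
        stack = LayerStack([Layer(0.6, 1500.0)])
        v_b, v_m, alpha = stack_summary(stack, law, constants)
        assert v_b == pytest.approx(0.6)
        assert alpha == pytest.approx(layer_mineral(1500.0, law))

    def test_two_equal_layers_average(self, law, constants):
        stack = LayerStack([Layer(0.2, 2000.0), Layer(0.2, 100.0)])
        _, _, alpha = stack_summary(stack, law, constants)
        expected = (layer_mineral(2000.0, law) + layer_mineral(100.0, law)) / 2
        assert alpha == pytest.approx(expected, rel=1e-12)

    def test_empty_stack_is_zero(self, law, constants):
        assert stack_summary(LayerStack([]), law, constants) == (0.0, 0.0, 0.0)

    def test_mineral_mass_consistent(self, law, constants):
        """v_m is aggregated per layer, so total mineral volume is the sum
        of the layers' own mineral volumes."""
        from osteosim.tissue import mineral_fraction_from_ash

        stack = LayerStack([Layer(0.3, 3000.0), Layer(0.1, 50.0)])
        v_b, v_m, _ = stack_summary(stack, law, constants)
        per_layer = sum(
            l.thickness_vb * mineral_fraction_from_ash(layer_mineral(l.age, law), constants)
            for l in stack.layers
        )
        assert v_m * v_b == pytest.approx(per_layer, rel=1e-12)


def test_params_validation():
    with pytest.raises(ValueError):
        BMUParams(T_R=0)
    with pytest.raises(ValueError):
        BMUParams(f_bb_min=1.05)
    assert BMUParams().lifespan == 106
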