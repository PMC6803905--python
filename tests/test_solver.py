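"""Finite-volume solver: oracle equivalence, conservation, interface
partitioning, linearity and grid convergence."""

import numpy as np
import pytest

import migrastack as ms
from migrastack.core import Layer
from migrastack.solver import short_time_rate, time_to_fraction


class TestNullAndConservation:
    def test_zero_initial_concentration_stays_zero(self, desorption_assembly):
        asm = desorption_assembly.replace_layer(1, initial_concentration=0.0)
        res = ms.solve_step(asm, 1.0)
        assert np.all(res.kinetics.layer_amounts == 0.0)
        assert np.all(res.kinetics.fluid_amount == 0.0)

    def test_closed_system_mass_constant_over_fo_100(self):
        sc = ms.fixture("S1", solute="sB")
        res = ms.solve_step(sc.assembly, 100.0)
        assert ms.mass_balance(res.kinetics) < 1e-6
        assert res.kinetics.total()[0] == pytest.approx(1.0, abs=1e-12)

    def test_mass_balance_residual_shrinks_with_refinement(self):
        sc = ms.fixture("S1", solute="sA")
        residuals = [
            ms.mass_balance(ms.solve_step(sc.assembly, 10.0,
                                          grid=ms.GridSpec(nodes_per_layer=n)).kinetics)
            for n in (10, 20)
        ]
        assert all(r < 1e-6 for r in residuals)


class TestCrankOracle:
    def test_plane_sheet_series_within_one_percent(self, desorption_assembly, crank):
        fos = np.array([0.01, 0.1, 1.0])
        res = ms.solve_step(desorption_assembly, 1.0,
                            grid=ms.GridSpec(nodes_per_layer=80), t_eval=fos)
        kin = res.kinetics
        for fo in fos:
            sim = kin.fluid_amount[kin.times == fo][0]
            assert sim == pytest.approx(crank(fo), rel=0.01)

    def test_early_time_square_root_law(self, desorption_assembly):
        # uptake ∝ √t on Fo ∈ [1e-4, 1e-2] with negligible film resistance
        fos = np.geomspace(1e-4, 1e-2, 9)
        res = ms.solve_step(desorption_assembly, 1e-2,
                            grid=ms.GridSpec(nodes_per_layer=200), t_eval=fos)
        kin = res.kinetics
        y = kin.fluid_amount[1:]
        slope = np.polyfit(np.log(fos), np.log(y), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.02)

    def test_grid_convergence_below_half_percent(self, desorption_assembly):
        fos = np.array([0.01, 0.1, 1.0])
        out = []
        for n in (40, 80):
            kin = ms.solve_step(desorption_assembly, 1.0,
                                grid=ms.GridSpec(nodes_per_layer=n), t_eval=fos).kinetics
            out.append(kin.fluid_amount[np.isin(kin.times, fos)])
        assert np.max(np.abs(out[1] / out[0] - 1.0)) < 0.005


class TestInterfacePartitioning:
    def test_steady_state_concentration_jump_is_k_ratio(self):
        # closed bilayer with k2/k1 = 4 equilibrates at C1/C2 = 4
        l1 = Layer(material="A", thickness=1.0, henry_k=1.0, diffusivity=1.0,
                   initial_concentration=1.0)
        l2 = Layer(material="B", thickness=1.0, henry_k=4.0, diffusivity=1.0)
        asm = ms.build_assembly([l1, l2])
        res = ms.solve_step(asm, 50.0)
        st = res.final_state
        c1 = st.concentrations[0][-1]
        c2 = st.concentrations[1][0]
        assert c1 / c2 == pytest.approx(4.0, rel=1e-6)

    def test_periodic_wrap_reaches_uniform_activity(self):
        # set-off configuration: the far face feeds the near face directly
        l1 = Layer(material="A", thickness=1.0, henry_k=1.0, diffusivity=1.0,
                   initial_concentration=1.0)
        l2 = Layer(material="B", thickness=0.5, henry_k=2.0, diffusivity=1.0)
        asm = ms.Assembly(layers=(l1, l2), boundary_near="periodic", boundary_far="periodic")
        res = ms.solve_step(asm, 50.0)
        st = res.final_state
        acts = np.concatenate([st.concentrations[0] * 1.0, st.concentrations[1] * 2.0])
        assert np.ptp(acts) / acts.mean() < 1e-6
        assert ms.mass_balance(res.kinetics) < 1e-6

    def test_periodic_transfers_faster_than_impervious(self):
        # with set-off, layer B loads from both faces of A
        l1 = Layer(material="A", thickness=1.0, henry_k=1.0, diffusivity=1.0,
                   initial_concentration=1.0)
        l2 = Layer(material="B", thickness=1.0, henry_k=1.0, diffusivity=1.0)
        t_eval = np.array([0.05])
        per = ms.Assembly(layers=(l1, l2), boundary_near="periodic", boundary_far="periodic")
        imp = ms.build_assembly([l1, l2])
        up_per = ms.solve_step(per, 0.05, t_eval=t_eval).kinetics.layer_amounts[1, -1]
        up_imp = ms.solve_step(imp, 0.05, t_eval=t_eval).kinetics.layer_amounts[1, -1]
        assert up_per > 1.5 * up_imp


class TestSuperposition:
    def test_joint_equals_sum_of_single_source_runs(self):
        joint = ms.fixture("S1", solute="sB").assembly
        # split the same solute between both layers
        joint = joint.replace_layer(2, initial_concentration=0.5)
        src1 = joint.replace_layer(2, initial_concentration=0.0)
        src2 = joint.replace_layer(1, initial_concentration=0.0)
        t = np.geomspace(1e-3, 10.0, 20)
        g = ms.GridSpec(rtol=1e-10, atol_factor=1e-15)
        kin_joint = ms.solve_step(joint, 10.0, t_eval=t, grid=g).kinetics
        kin_1 = ms.solve_step(src1, 10.0, t_eval=t, grid=g).kinetics
        kin_2 = ms.solve_step(src2, 10.0, t_eval=t, grid=g).kinetics
        summed = ms.superpose(kin_1, kin_2)
        np.testing.assert_allclose(
            summed.layer_amounts * summed.base,
            kin_joint.layer_amounts * kin_joint.base,
            rtol=1e-8, atol=1e-12,
        )

    def test_identity_with_zero_run_and_homogeneity(self):
        asm = ms.fixture("S1", solute="sB").assembly
        t = np.geomspace(1e-2, 5.0, 10)
        kin = ms.solve_step(asm, 5.0, t_eval=t).kinetics
        zero = ms.solve_step(asm.replace_layer(1, initial_concentration=0.0), 5.0,
                             t_eval=t).kinetics
        assert zero.base == pytest.approx(0.0)
        combined = ms.superpose(kin, zero)
        np.testing.assert_allclose(combined.layer_amounts, kin.layer_amounts, rtol=0, atol=0)
        # scaling the source scales the kinetics linearly
        kin2 = ms.solve_step(asm.replace_layer(1, initial_concentration=2.0), 5.0,
                             t_eval=t).kinetics
        np.testing.assert_allclose(kin2.layer_amounts * kin2.base,
                                   2.0 * kin.layer_amounts * kin.base, rtol=1e-9)

    def test_mismatched_grids_rejected(self):
        asm = ms.fixture("S1", solute="sB").assembly
        k1 = ms.solve_step(asm, 1.0, t_eval=np.array([0.5, 1.0])).kinetics
        k2 = ms.solve_step(asm, 1.0, t_eval=np.array([0.4, 1.0])).kinetics
        with pytest.raises(ValueError):
            ms.superpose(k1, k2)


class TestShortTimeScreening:
    def test_zero_volatility_gives_zero_rate(self):
        assert short_time_rate(1.0, 0.0 * 1.0, 1.0, 1e8, 1e8) == 0.0

    def test_rate_linear_in_source_henry(self):
        r1 = short_time_rate(1.0, 1.0, 1.0, 1e8, 1e8)
        r2 = short_time_rate(1.0, 2.0, 1.0, 1e8, 1e8)
        assert r2 == pytest.approx(2 * r1)

    def test_screening_estimate_vs_transient_solver(self):
        """Gas-film estimate matches the full solution deep in the
        short-time regime and stays a conservative upper bound after."""
        sc = ms.fixture("S2", solute="sB")
        rate = short_time_rate(1.0, 1.0, 1.0, 1e8, 1e8)
        fos = np.array([1e-3, 2e-3, 5e-3, 1e-2])
        kin = ms.solve_step(sc.assembly, 1e-2,
                            grid=ms.GridSpec(nodes_per_layer=40), t_eval=fos).kinetics
        source = kin.fraction_in((1,))
        loss = 1.0 - source[1:] / source[0]
        assert loss[0] == pytest.approx(rate * fos[0], rel=0.10)
        assert np.all(loss <= rate * fos * (1 + 1e-9))


class TestTimeToFraction:
    def test_log_interpolated_crossing(self):
        t = np.array([0.0, 1.0, 10.0, 100.0])
        y = np.array([0.0, 0.2, 0.5, 1.0])
        teq = time_to_fraction(t, y, 1.0, 0.5)
        assert teq == pytest.approx(10.0)
        assert time_to_fraction(t, y, 1.0, 0.99) == pytest.approx(
            np.exp(np.log(10) + 0.98 * np.log(10)), rel=1e-9
        )

    def test_unreached_returns_inf(self):
        assert time_to_fraction(np.array([0.0, 1.0]), np.array([0.0, 0.1]), 1.0) == np.inf


class TestFailureModes:
    def test_strictly_increasing_output_times_required(self, desorption_assembly):
        with pytest.raises(ValueError):
            ms.solve_step(desorption_assembly, 1.0, t_eval=np.array([0.5, 0.5]))

    def test_min_three_nodes(self):
        with pytest.raises(ValueError):
            ms.GridSpec(nodes_per_layer=2).nodes_for(ms.fixture("S1").assembly)
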