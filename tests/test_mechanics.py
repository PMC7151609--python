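"""Biot poroelasticity: moduli, coupling oracle, consolidation, relaxation."""

import numpy as np
import pytest
from oracles import monolithic_step, terzaghi_series

from lobulesim.lattice import build_unit_cell
from lobulesim.mechanics import (
    BiotParams,
    CouplingConvergenceError,
    PoroelasticModel,
    iterative_coupling_step,
    run_fibrosis_scenarios,
    run_stress_relaxation,
    shear_modulus,
)
from lobulesim.properties import FlowProperties, InvalidParameterError


class TestModuli:
    def test_liver_shear_modulus(self):
        assert shear_modulus(5.0e3, 0.35) == pytest.approx(1.8519e3, rel=1e-4)

    def test_limits(self):
        assert shear_modulus(6.0e3, 0.0) == pytest.approx(3.0e3)
        assert shear_modulus(6.0e3, 0.49999) == pytest.approx(2.0e3, rel=1e-4)

    def test_rejects_invalid(self):
        with pytest.raises(InvalidParameterError):
            shear_modulus(5.0e3, 0.5)
        with pytest.raises(InvalidParameterError):
            shear_modulus(-1.0, 0.3)
        with pytest.raises(InvalidParameterError):
            BiotParams(skempton=0.0)

    def test_incompressible_constituents_have_zero_storage(self):
        assert BiotParams(biot_alpha=1.0, skempton=1.0).inverse_biot_modulus == 0.0
        assert BiotParams(biot_alpha=1.0, skempton=0.5).inverse_biot_modulus > 0.0


@pytest.fixture(scope="module")
def cell():
    return build_unit_cell(FlowProperties())


@pytest.fixture(scope="module")
def small_model(cell):
    return PoroelasticModel(cell, (2, 2, 2), BiotParams(), mode="lobule")


class TestIterativeCoupling:
    def test_zero_load_zero_state(self, small_model):
        state, _ = small_model.step(small_model.initial_state(), 0.01, 0.0)
        assert np.all(state.displacement == 0.0)
        assert np.all(state.pressure == 0.0)

    def test_decoupled_alpha_zero_converges_in_one_iteration(self, cell):
        model = PoroelasticModel(cell, (2, 2, 2), BiotParams(biot_alpha=0.0))
        _, iters = model.step(model.initial_state(), 0.01, 1.0)
        assert iters == 1

    def test_matches_monolithic_solve(self, small_model):
        state = small_model.initial_state()
        load = 0.05 * 2 * 30.0 * 0.5
        new, _ = iterative_coupling_step(small_model, state, 0.005, load, tol=1e-11, max_iters=500)
        u, p = monolithic_step(small_model, state, 0.005, load)
        assert np.max(np.abs(p - new.pressure)) / np.max(np.abs(p)) < 1e-6
        assert np.max(np.abs(u - new.displacement)) / np.max(np.abs(u)) < 1e-6

    def test_tightening_tolerance_never_worsens_oracle_agreement(self, small_model):
        state = small_model.initial_state()
        load = 1.0
        u_ref, p_ref = monolithic_step(small_model, state, 0.005, load)
        diffs = []
        for tol in (1e-4, 1e-6, 1e-8, 1e-10):
            new, _ = small_model.step(state, 0.005, load, tol=tol, max_iters=1000)
            diffs.append(np.max(np.abs(new.pressure - p_ref)))
        assert all(b <= a + 1e-12 for a, b in zip(diffs, diffs[1:]))

    def test_nonconvergence_raises_with_residuals(self, small_model):
        with pytest.raises(CouplingConvergenceError) as err:
            small_model.step(small_model.initial_state(), 0.005, 1.0, tol=1e-14, max_iters=2)
        assert err.value.iterations == 2
        assert err.value.residual_pressure > 0.0

    def test_momentum_balance_residual_at_accepted_step(self, small_model):
        state, _ = small_model.step(small_model.initial_state(), 0.01, 1.5, tol=1e-10)
        f = small_model.params.biot_alpha * (small_model.D.T @ small_model.mean_pressure(state.pressure))
        r = (small_model.K @ state.displacement - f)[small_model.free]
        scale = np.max(np.abs(small_model.K @ state.displacement))
        assert np.max(np.abs(r)) / scale < 1e-9


class TestSkemptonLimit:
    def test_sealed_undrained_pressure_equals_mean_stress(self, cell):
        model = PoroelasticModel(cell, (4, 4, 4), BiotParams(), mode="sealed")
        state, _ = model.step(model.initial_state(), 1e-4, 0.05 * 4 * 30.0 * 0.01, max_iters=500)
        s = model.summary(state)
        assert -s["avg_pressure"] / s["mean_total_stress"] == pytest.approx(1.0, rel=0.01)


class TestTerzaghiConsolidation:
    def test_column_pressure_history_matches_series(self):
        props = FlowProperties(tissue_permeability=8.8e-3)
        cell = build_unit_cell(props)
        params = BiotParams()
        n = 16
        model = PoroelasticModel(
            cell, (1, 1, n), params, mode="column", single_compartment=True, load_control=True
        )
        H = n * cell.pitch
        c_v = (model.k_eff[0] / params.fluid_viscosity) / (
            params.biot_alpha**2 / params.confined_modulus
        )
        sigma0, ramp = 100.0, 0.02
        state = model.initial_state()
        for i in range(10):
            state, _ = model.step(state, ramp / 10, sigma0 * (i + 1) / 10)
        times, num = [], []
        dt = 0.01
        while state.time < 10.0:
            state, _ = model.step(state, dt, sigma0)
            times.append(state.time)
            num.append(state.pressure.copy())
            dt = min(dt * 1.1, 0.04)
        z = (np.arange(n) + 0.5) * cell.pitch
        xi = (H - z) / H
        ana = np.array([terzaghi_series(xi, t, c_v, H, sigma0, ramp=ramp) for t in times])
        num = np.array(num)
        err = np.linalg.norm(num - ana) / np.linalg.norm(ana)
        assert err < 0.02

    def test_high_permeability_limit_is_drained(self, cell):
        props = FlowProperties(tissue_permeability=1e3)
        fast = build_unit_cell(props)
        model = PoroelasticModel(fast, (1, 1, 8), BiotParams(), mode="column", single_compartment=True)
        state, _ = model.step(model.initial_state(), 0.05, 0.05 * 8 * 30.0, max_iters=500)
        # fully drained: negligible pressure against the confined-stress scale
        stress_scale = BiotParams().confined_modulus * 0.05
        assert np.max(np.abs(state.pressure)) < 1e-3 * stress_scale


@pytest.fixture(scope="module")
def run(cell):
    return run_stress_relaxation(cell, dims=(4, 4, 4), hold=5.0)


class TestStressRelaxation:
    def test_protocol_strain_rate(self):
        assert 0.05 / 0.1 == pytest.approx(0.5)

    def test_peak_pressure_at_ramp_end_then_monotone_decay(self, run):
        hist, _, _ = run
        ramp_end = hist[hist["time"] <= 0.1 + 1e-9]["avg_pressure"].idxmax()
        assert hist["time"].iloc[ramp_end] == pytest.approx(0.1)
        assert hist["avg_pressure"].max() == hist["avg_pressure"].iloc[ramp_end]
        hold = hist[hist["time"] > 0.1 + 1e-9]["avg_pressure"].to_numpy()
        assert np.all(np.diff(hold) <= 1e-9)

    def test_expelled_fluid_monotone_and_balances_content_change(self, run):
        hist, state, model = run
        assert np.all(np.diff(hist["expelled_volume"]) >= -1e-9)
        # mass balance: expelled fluid = -(change of fluid content)
        content = float(model.invM_vol @ state.pressure) + model.params.biot_alpha * float(
            model.cell_volume * state.eps_v.sum()
        )
        assert state.expelled_volume == pytest.approx(-content, rel=0.01)

    def test_distinct_compartment_pressures(self, run):
        hist, _, _ = run
        peak = hist.iloc[hist["avg_pressure"].idxmax()]
        # the sinusoid network drains orders of magnitude faster than tissue
        assert peak["avg_pressure_sinusoid"] < 0.01 * peak["avg_pressure_tissue"]


class TestFibrosisScenarios:
    def test_unit_factors_collapse_to_identical_cases(self, cell):
        table = run_fibrosis_scenarios(
            cell, (3, 3, 3), stiffness_factor=1.0, permeability_factor=1.0, hold=0.5
        )
        assert table["peak_loading_stress"].nunique() == 1
        assert table["peak_avg_pressure"].nunique() == 1

    def test_stiffness_and_permeability_orderings(self, cell):
        table = run_fibrosis_scenarios(cell, (4, 4, 4), hold=1.0).set_index("scenario")
        stress = table["peak_loading_stress"]
        assert stress["fibrotic"] >= stress["stiff_only"] > stress["normal"]
        assert table["peak_avg_pressure"]["fibrotic"] >= table["peak_avg_pressure"]["stiff_only"]
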