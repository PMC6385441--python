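import numpy as np
import pytest
from scipy.integrate import solve_ivp

from yeastiron.ode_models import build_system
from yeastiron.params import Condition
from yeastiron.rate_laws import o2_matrix_steady
from yeastiron.steady_state import attractor_probe, solve_steady, steady_residuals


class TestC1SteadyValues:
    def test_wt_iron_starved_cell_iron(self, wt):
        # printed simulated whole-cell iron 60 uM at N=1
        res = solve_steady(build_system("C1", Condition("WT", 1.0), wt))
        assert res.converged
        assert res.state["Fe_cell"] == pytest.approx(58.7, abs=0.5)

    def test_mutant_mid_iron_cell_iron(self, dd):
        # printed simulated whole-cell iron 2300 uM at N=11
        res = solve_steady(build_system("C1", Condition("DD", 11.0), dd))
        assert res.state["Fe_cell"] == pytest.approx(2.29e3, rel=0.01)


class TestConvergenceContract:
    def test_converged_flag_and_residual(self, c9_steady):
        res = c9_steady("WT", 41.0)
        assert res.converged
        assert res.max_relative_residual <= 1e-9

    def test_rates_reproducible_from_state(self, c9_steady):
        res = c9_steady("WT", 41.0)
        again = res.system.rates(res.state.to_array())
        assert again == res.rates

    def test_nonconvergence_flagged_not_raised(self, wt):
        res = solve_steady(build_system("C9", Condition("WT", 41.0), wt), t_max=0.5)
        assert not res.converged

    def test_bad_tolerance_rejected(self, wt):
        with pytest.raises(ValueError):
            solve_steady(build_system("C1", Condition("WT", 1.0), wt), tol=0.0)


class TestSteadyResiduals:
    def test_all_balances_tight_at_convergence(self, c9_steady):
        for strain, N in (("WT", 41.0), ("DD", 41.0), ("DD", 1.0)):
            res = c9_steady(strain, N)
            resid = steady_residuals(res)
            y = res.state.components
            for name, v in resid.items():
                scale = max(abs(res.rates.R_cyt), 1.0)
                assert abs(v) / scale <= 1e-6, (strain, N, name)

    def test_perturbed_state_breaks_isc_balance(self, c9_steady):
        res = c9_steady("WT", 41.0)
        y = res.state.to_array()
        y[3] *= 1.10  # +10% FS
        perturbed = res.__class__(
            condition=res.condition,
            state=res.system.state(y),
            rates=res.system.rates(y),
            residuals=res.system.rhs(0.0, y),
            converged=False,
            t_final=res.t_final,
            system=res.system,
        )
        resid = steady_residuals(perturbed)
        assert abs(resid["isu"]) > 1.0  # R_isu - alpha*FS no longer balances

    def test_residuals_are_the_component_equations(self, c9_steady):
        """Algebraic identity: the cytosolic budget line equals the labile-pool
        equation and the production=dilution lines equal their component
        equations, so budget residuals are sums of rhs entries."""
        res = c9_steady("DD", 11.0)
        y = res.state.to_array() * 1.07  # off steady state on purpose
        sys9 = res.system
        fake = res.__class__(
            condition=res.condition, state=sys9.state(y), rates=sys9.rates(y),
            residuals=sys9.rhs(0.0, y), converged=False, t_final=0.0, system=sys9,
        )
        resid = steady_residuals(fake)
        dy = sys9.rhs(0.0, y)
        g = sys9.geometry
        assert resid["cytosol"] == pytest.approx(dy[0], rel=1e-12)
        assert resid["cia"] == pytest.approx(dy[1], rel=1e-12)
        assert resid["mito_import"] == pytest.approx(g.mit_over_cyt * dy[2], rel=1e-12)
        assert resid["vac_import"] == pytest.approx(g.vac_over_cyt * dy[5], rel=1e-12)

    def test_wrong_tier_rejected(self, wt):
        res = solve_steady(build_system("C1", Condition("WT", 1.0), wt))
        with pytest.raises(ValueError):
            steady_residuals(res)


class TestOxygenClosedForm:
    def test_integrated_o2_matches_closed_form(self, c9_steady):
        """The long-time [O2] must satisfy the algebraic rearrangement of the
        oxygen balance to 1e-6 relative; the oracle is the integration itself."""
        for strain, N in (("WT", 41.0), ("DD", 1.0), ("DD", 41.0)):
            res = c9_steady(strain, N)
            c = res.state.components
            closed = o2_matrix_steady(c["FM"], c["FS"], res.rates.alpha, res.system.params)
            assert c["O2"] == pytest.approx(closed, rel=1e-6)


class TestAttractors:
    def test_wt_replete_conditions_have_one_attractor(self, wt):
        system = build_system("C9", Condition("WT", 41.0), wt)
        probes = attractor_probe(system, scales=(0.1, 1.0, 10.0))
        ref = probes[1].state.to_array()
        for pr in probes:
            y = pr.state.to_array()
            assert np.all(np.abs(y - ref) <= 1e-4 * np.maximum(np.abs(ref), 1.0))

    def test_iron_starved_mutant_is_bistable(self, dd):
        """The starved deletion strain supports two stable branches: the
        nanoparticle-dominated (diseased) branch reached from the canonical
        10 uM start, and a healthy high-ISC branch reached from larger
        inocula — the model's vicious-cycle switch seen from the state space."""
        system = build_system("C9", Condition("DD", 1.0), dd)
        diseased, healthy = attractor_probe(system, scales=(1.0, 10.0))
        assert diseased.state["MP"] > 4.0 * healthy.state["MP"]
        assert diseased.state["O2"] > 10.0 * healthy.state["O2"]
        assert healthy.state["FS"] > 100.0 * diseased.state["FS"]
        # both are genuine steady states of the same equations
        for res in (diseased, healthy):
            assert res.converged and res.max_relative_residual <= 1e-9


class TestTrajectoryCollapse:
    def test_fine_trajectory_satisfies_collapsed_equations(self, wt, geometry):
        """At every stored time point of a C9 trajectory, the compartment sums
        must obey the three-pool equations with the induced rates (the fine
        system 'collapses' exactly, not just at steady state)."""
        system = build_system("C9", Condition("WT", 41.0), wt, geometry)
        sol = solve_ivp(system.rhs, (0.0, 30.0), system.initial_state(),
                        method="LSODA", rtol=1e-10, atol=1e-12,
                        t_eval=np.linspace(0.0, 30.0, 40))
        a = system.alpha
        for k in range(sol.y.shape[1]):
            y = sol.y[:, k]
            dy = system.rhs(0.0, y)
            r = system.rates(y)
            fe_cyt, dfe_cyt = y[0] + y[1], dy[0] + dy[1]
            fe_mit, dfe_mit = y[2:5].sum(), dy[2:5].sum()
            fe_vac, dfe_vac = y[5:8].sum(), dy[5:8].sum()
            scale = max(abs(r.R_cyt), 1.0)
            assert abs(dfe_cyt - (r.R_cyt - r.R_mit - r.R_vac - a * fe_cyt)) <= 1e-8 * scale
            assert abs(dfe_mit - (r.R_mit / geometry.mit_over_cyt - a * fe_mit)) <= 1e-8 * scale
            assert abs(dfe_vac - (r.R_vac / geometry.vac_over_cyt - a * fe_vac)) <= 1e-8 * scale
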