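"""TI engine: planning, windows, quadrature, gating and Kd conversion."""

import numpy as np
import pytest

from mirrorbind import alchemy, toyfactory
from mirrorbind.alchemy import (
    AlchemyError,
    LambdaSchedule,
    StabilityGate,
    WindowProtocol,
    WindowStats,
    default_schedules,
    gauss_legendre_schedule,
    integrate,
    kd_fold_change,
    plan,
    run_stage,
    run_window,
    stability_gate,
    trapezoid_schedule,
)
from mirrorbind.ffmodel import AlchemicalState
from mirrorbind.sampler import SamplerConfig, Trajectory


def _traj(frames):
    cfg = SamplerConfig(n_steps=1, snapshot_stride=1, move_scale=0.1)
    return Trajectory(frames=[np.asarray(f, float) for f in frames],
                      energies=[0.0] * len(frames), acceptance_rate=1.0, config=cfg)


class TestPlan:
    def test_standard_54_legs(self):
        legs = plan("D27DPP", default_schedules(n=9))
        assert len(legs) == 54
        assert len({leg.seed for leg in legs}) == 54  # reproducible, distinct

    def test_single_leg(self):
        sched = default_schedules(n=1)
        legs = plan("x", sched, environments=("complex",))
        assert len(legs) == 3  # one window per stage
        one = [l for l in legs if l.stage == "vdw"]
        assert len(one) == 1

    def test_product_counts(self):
        legs = plan("x", default_schedules(n=5))
        assert len(legs) == 30

    def test_missing_stage_errors(self):
        sched = {"vdw": gauss_legendre_schedule("vdw")}
        with pytest.raises(AlchemyError, match="missing stage"):
            plan("x", sched)

    def test_seeds_are_stable(self):
        a = plan("x", default_schedules(), master_seed=5)
        b = plan("x", default_schedules(), master_seed=5)
        assert [l.seed for l in a] == [l.seed for l in b]
        c = plan("x", default_schedules(), master_seed=6)
        assert [l.seed for l in a] != [l.seed for l in c]


class TestSchedules:
    def test_gauss_weights_sum_to_one(self):
        s = gauss_legendre_schedule("vdw", 9)
        assert sum(s.weights) == pytest.approx(1.0, abs=1e-12)
        assert all(0 < x < 1 for x in s.abscissas)

    def test_trapezoid_weights_sum_to_one(self):
        s = trapezoid_schedule("vdw", 9)
        assert sum(s.weights) == pytest.approx(1.0, abs=1e-12)

    def test_bad_lambdas_rejected(self):
        with pytest.raises(AlchemyError):
            LambdaSchedule(stage="vdw", abscissas=(0.0, 0.5), weights=(0.5, 0.5))


class TestStabilityGate:
    def test_rigid_trajectory_passes(self):
        frames = [np.zeros((4, 3)) + [[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]]] * 5
        v = stability_gate(_traj(frames), _traj(frames), StabilityGate(4.0))
        assert v.passed and v.max_rmsd < 1e-9

    def test_excursion_fails(self):
        base = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        # one frame displaces a single atom by a large non-rigid amount
        burst = base.copy()
        burst[0] += [20.0, 0, 0]
        frames = [base] * 6 + [burst] + [base] * 5
        v = stability_gate(_traj(frames), _traj([base] * 5), StabilityGate(4.0))
        assert not v.passed
        assert v.max_rmsd > 4.0

    def test_boundary_is_strict(self):
        v = alchemy.GateVerdict(passed=not (4.0 > 4.0), max_rmsd=4.0, threshold=4.0)
        assert v.passed

    def test_empty_trajectory_errors(self):
        with pytest.raises(AlchemyError):
            stability_gate(_traj([]), _traj([]), StabilityGate())


class TestRunWindow:
    def test_null_transformation_zero_derivative(self, ff):
        # A == B: no vanishing or appearing atoms -> dU/dlambda identically 0
        asys, _ = toyfactory.make_charge_flip_toy(q_a=0.3, q_b=0.3)
        proto = WindowProtocol(minimize_iters=0, equil_steps=50, prod_steps=200,
                               stride=2, move_scale=0.2)
        for lam in (0.25, 0.75):
            # identical charges still traverse distinct dual-topology atoms;
            # a genuinely null topology has empty mutating sets:
            import mirrorbind.ffmodel as fm
            topo = fm.AlchemicalTopology(system=asys.topo.system,
                                         vanishing=frozenset(), appearing=frozenset())
            nsys = alchemy.AlchemicalSystem(topo=topo, coords=asys.coords,
                                            movable=asys.movable)
            stats = run_window(nsys, AlchemicalState("decharge", lam), proto, seed=1)
            assert stats.mean_dudl == 0.0

    def test_frozen_pair_linear_charging_analytic(self, ff):
        # frozen geometry: decharging a +0.5 bead 3.2 A from a -1 host
        asys, _ = toyfactory.make_charge_flip_toy(q_a=0.5, q_b=-0.5,
                                                  host_charge=-1.0, r0=3.2)
        proto = WindowProtocol(frozen=True, prod_steps=100, stride=10,
                               equil_steps=0, minimize_iters=0)
        stats = run_window(asys, AlchemicalState("decharge", 0.5), proto, seed=0)
        expect = -ff.coulomb_constant * 0.5 * (-1.0) / 3.2
        assert stats.mean_dudl == pytest.approx(expect, abs=1e-9)
        assert stats.stderr == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_identical(self):
        asys, _ = toyfactory.make_charge_flip_toy()
        proto = WindowProtocol(minimize_iters=5, equil_steps=50, prod_steps=200,
                               stride=2, move_scale=0.2)
        a = run_window(asys, AlchemicalState("vdw", 0.5), proto, seed=9)
        b = run_window(asys, AlchemicalState("vdw", 0.5), proto, seed=9)
        assert (a.mean_dudl, a.stderr, a.n_samples) == (b.mean_dudl, b.stderr, b.n_samples)


class TestIntegrate:
    def test_constant_integrand(self):
        sched = gauss_legendre_schedule("vdw", 9)
        stats = [WindowStats(mean_dudl=3.7, stderr=0.0, n_samples=10)] * 9
        dg, err = integrate(stats, sched)
        assert dg == pytest.approx(3.7, abs=1e-12)
        assert err == 0.0

    def test_linear_integrand_exact(self):
        sched = gauss_legendre_schedule("vdw", 9)
        stats = [WindowStats(mean_dudl=2.0 * lam - 1.0, stderr=0.0, n_samples=1)
                 for lam in sched.abscissas]
        dg, _ = integrate(stats, sched)
        assert dg == pytest.approx(0.0, abs=1e-12)  # integral of 2x-1 over (0,1)

    def test_error_propagation_arithmetic(self):
        sched = gauss_legendre_schedule("vdw", 3)
        stats = [WindowStats(mean_dudl=0.0, stderr=s, n_samples=1) for s in (0.1, 0.2, 0.3)]
        _, err = integrate(stats, sched)
        w = np.array(sched.weights)
        assert err == pytest.approx(np.sqrt(np.sum(w**2 * np.array([0.1, 0.2, 0.3]) ** 2)))

    def test_length_mismatch_errors(self):
        sched = gauss_legendre_schedule("vdw", 9)
        with pytest.raises(AlchemyError):
            integrate([WindowStats(0.0, 0.0, 1)] * 5, sched)

    def test_harmonic_spring_free_energy(self):
        # k: 1 -> 2 kcal/mol/A^2 at 300 K: dG = (kT/2) ln 2 = 0.2066 kcal/mol
        hs = toyfactory.HarmonicMorphSystem(1.0, 2.0, ndim=1)
        sched = gauss_legendre_schedule("vdw", 9)
        proto = WindowProtocol(minimize_iters=0, equil_steps=500, prod_steps=6000,
                               stride=5, move_scale=0.6)
        dg, err, _ = run_stage(hs, sched, proto, master_seed=4)
        exact = toyfactory.exact_dG(toyfactory.OracleSystem(
            "harmonic_spring", {"k_A": 1.0, "k_B": 2.0, "ndim": 1}))
        assert dg == pytest.approx(exact, abs=max(3 * err, 0.01))

    def test_reversed_direction_consistency(self):
        fwd = toyfactory.HarmonicMorphSystem(1.0, 2.0, ndim=1)
        rev = toyfactory.HarmonicMorphSystem(2.0, 1.0, ndim=1)
        sched = gauss_legendre_schedule("vdw", 9)
        proto = WindowProtocol(minimize_iters=0, equil_steps=300, prod_steps=4000,
                               stride=5, move_scale=0.6)
        dg_f, err_f, _ = run_stage(fwd, sched, proto, master_seed=1)
        dg_r, err_r, _ = run_stage(rev, sched, proto, master_seed=2)
        sigma = np.hypot(err_f, err_r)
        assert dg_f == pytest.approx(-dg_r, abs=max(3 * sigma, 0.01))


class TestDdgBinding:
    def test_identity_mutation_zero(self):
        cx, _ = toyfactory.make_charge_flip_toy(q_a=0.4, q_b=0.4, environment="complex")
        fr, _ = toyfactory.make_charge_flip_toy(q_a=0.4, q_b=0.4, environment="free")
        proto = WindowProtocol(minimize_iters=10, equil_steps=200, prod_steps=800,
                               stride=4, move_scale=0.3)
        res = alchemy.ddG_binding("identity", cx, fr,
                                  schedules=default_schedules(n=5),
                                  protocol=proto, master_seed=3)
        assert abs(res.ddG_bind) <= max(2 * res.ddG_err, 0.02)

    def test_gate_failure_short_circuits(self):
        cx, _ = toyfactory.make_charge_flip_toy(environment="complex")
        fr, _ = toyfactory.make_charge_flip_toy(environment="free")
        verdict = alchemy.GateVerdict(passed=False, max_rmsd=6.0, threshold=4.0)
        res = alchemy.ddG_binding("bad", cx, fr, gate_verdict=verdict)
        assert res.rejected
        assert np.isnan(res.dG_mut_complex)

    def test_ddg_consistency_with_components(self):
        r = alchemy.TIResult(mutation="x", dG_stage={}, dG_mut_complex=-3.2,
                             dG_mut_free=-1.1, err_complex=0.1, err_free=0.2)
        assert r.ddG_bind == pytest.approx(-2.1, abs=1e-12)
        assert r.ddG_err == pytest.approx(np.hypot(0.1, 0.2), abs=1e-12)


class TestKdFoldChange:
    def test_zero_ddg_is_unity(self):
        assert kd_fold_change(0.0) == 1.0

    def test_published_magnitude(self):
        # -7.18 kcal/mol at 300 K is about a 1.7e5-fold Kd improvement
        fold = kd_fold_change(-7.18, T=300.0)
        assert fold == pytest.approx(np.exp(7.18 / 0.59616), rel=1e-6)
        assert 1e5 < fold < 2e5

    def test_inverse_identity(self):
        rt = alchemy.GAS_CONSTANT_KCAL * 300.0
        assert kd_fold_change(-rt * np.log(10.0)) == pytest.approx(10.0, rel=1e-12)

    def test_bad_temperature(self):
        with pytest.raises(AlchemyError):
            kd_fold_change(1.0, T=0.0)
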