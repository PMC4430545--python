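import numpy as np
import pytest

from adaptivepull import (
    KB,
    PMFCurve,
    PotentialSpec,
    StagePlan,
    SystemState,
    System,
    assemble_pmf,
    jackknife_delta_f,
    je_select,
    make_potential,
    reference_pmf,
    run_fr_asmd,
    run_naive_asmd,
    run_smd,
)
from adaptivepull.errors import ConfigurationError

from conftest import make_1d_system, make_params, make_steering


class TestStagePlan:
    def test_default_is_ten_two_angstrom_segments(self):
        plan = StagePlan()
        assert len(plan.segments) == 10
        assert plan.lam_start == 13.0 and plan.lam_end == 33.0
        widths = [b - a for a, b in plan.segments]
        np.testing.assert_allclose(widths, 2.0)
        assert plan.t_relax == 100.0

    def test_non_contiguous_rejected(self):
        with pytest.raises(ConfigurationError, match="contiguity"):
            StagePlan(segments=((0.0, 1.0), (1.5, 2.0)))

    def test_zero_tps_rejected(self):
        with pytest.raises(ConfigurationError, match="tps"):
            StagePlan(segments=((0.0, 1.0),), tps=0)

    def test_stage_grid_hits_endpoints_exactly(self):
        plan = StagePlan(segments=((0.3, 1.7),), record_spacing=0.1)
        g = plan.stage_grid(0)
        assert g[0] == 0.3 and g[-1] == 1.7


class TestRunSMD:
    def test_harmonic_closed_form_within_3se(self, harmonic):
        steer = make_steering(k=1.0, velocity=20.0)  # 0.02 A/ps, 100 ps pull
        plan = StagePlan(segments=((0.0, 2.0),), tps=100, t_relax=0.0)
        res = run_smd(make_1d_system(harmonic), steer, plan, make_params(), master_seed=42)
        dF, se = jackknife_delta_f(res.ensemble)
        assert abs(dF - 1.0) < 3 * se

    def test_deterministic_limit_f_equals_w(self, harmonic):
        # deterministic dynamics (zero bath coupling): all work traces are
        # bit-identical and the estimator degenerates to F = W
        steer = make_steering(k=1.0, velocity=100.0)
        plan = StagePlan(segments=((0.0, 2.0),), tps=5, t_relax=0.0)
        res = run_smd(make_1d_system(harmonic), steer, plan, make_params(gamma=0.0), 7)
        W = res.ensemble.works
        np.testing.assert_array_equal(W, np.tile(W[0], (5, 1)))
        np.testing.assert_allclose(res.pmf.F, W[0], atol=1e-12)

    def test_single_trajectory_pmf_is_its_work(self, harmonic):
        steer = make_steering(k=1.0, velocity=100.0)
        plan = StagePlan(segments=((0.0, 2.0),), tps=1, t_relax=0.0)
        res = run_smd(make_1d_system(harmonic), steer, plan, make_params(), 3)
        np.testing.assert_allclose(res.pmf.F, res.ensemble.works[0], atol=1e-12)


class TestNaiveASMD:
    def test_degenerate_staging_identical_to_smd(self, harmonic):
        steer = make_steering(k=1.0, velocity=100.0)
        plan = StagePlan(segments=((0.0, 2.0),), tps=10, t_relax=0.0)
        sys_ = make_1d_system(harmonic)
        res_smd = run_smd(sys_, steer, plan, make_params(), master_seed=11)
        results, pmf = run_naive_asmd(sys_, steer, plan, make_params(), master_seed=11)
        np.testing.assert_array_equal(res_smd.ensemble.works, results[0].ensemble.works)
        np.testing.assert_array_equal(res_smd.pmf.F, pmf.F)
        assert res_smd.selected == results[0].selected

    def test_double_well_matches_quadrature(self, tilted_double_well):
        steer = make_steering(k=15.0, lam_start=-2.0, lam_end=2.0, velocity=50.0)
        plan = StagePlan(
            segments=tuple(StagePlan.default_segments(-2.0, 2.0, 10)), tps=60, t_relax=0.0
        )
        params = make_params(dt=0.005)
        results, pmf = run_naive_asmd(
            make_1d_system(tilted_double_well, x0=-2.0), steer, plan, params, master_seed=5
        )
        ref = reference_pmf(tilted_double_well, 15.0, pmf.lambdas, params.temperature)
        assert np.max(np.abs(pmf.F - ref.F)) < 0.5 * KB * params.temperature

    def test_selected_index_matches_bruteforce(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(segments=tuple(StagePlan.default_segments(-1, 1, 4)), tps=12, t_relax=0.0)
        results, _ = run_naive_asmd(
            make_1d_system(double_well, x0=-1.0), steer, plan, make_params(), 19
        )
        for res in results:
            w = res.ensemble.end_works
            f_end = res.record["F_end"]
            brute = min(range(len(w)), key=lambda i: abs(w[i] - f_end))
            assert res.selected == brute
            assert res.selected == je_select(w, f_end)

    def test_contraction_start_states_identical(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(segments=tuple(StagePlan.default_segments(-1, 1, 2)), tps=8, t_relax=0.0)
        results, _ = run_naive_asmd(
            make_1d_system(double_well, x0=-1.0), steer, plan, make_params(), 23
        )
        # stage works have spread, yet stage 1 restarted from one state:
        assert np.std(results[0].ensemble.end_works) > 0
        sel = results[0].selected
        start = results[0].final_states[sel].positions
        # re-run stage 1 start is encoded in the first xi sample: all works 0 at start
        assert np.all(results[1].ensemble.works[:, 0] == 0.0)
        assert np.isfinite(start).all()

    def test_seed_determinism_full_run(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(segments=tuple(StagePlan.default_segments(-1, 1, 3)), tps=6, t_relax=0.0)
        out = []
        for _ in range(2):
            results, pmf = run_naive_asmd(
                make_1d_system(double_well, x0=-1.0), steer, plan, make_params(), 31
            )
            out.append((pmf.F.copy(), [r.ensemble.works.copy() for r in results]))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        for w0, w1 in zip(out[0][1], out[1][1]):
            np.testing.assert_array_equal(w0, w1)


class TestFRASMD:
    def test_relaxation_zero_work_exact(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(segments=tuple(StagePlan.default_segments(-1, 1, 4)), tps=6, t_relax=2.0)
        results, _ = run_fr_asmd(
            make_1d_system(double_well, x0=-1.0), steer, plan, make_params(), 13
        )
        for res in results[:-1]:
            assert res.record["relax_work"] == 0.0

    def test_zero_relax_continuous_streams_identical_to_smd(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        params = make_params()
        sys_ = make_1d_system(double_well, x0=-1.0)
        plan_multi = StagePlan(
            segments=tuple(StagePlan.default_segments(-1, 1, 4)), tps=7, t_relax=0.0
        )
        plan_one = StagePlan(segments=((-1.0, 1.0),), tps=7, t_relax=0.0)
        results, pmf_fr = run_fr_asmd(
            sys_, steer, plan_multi, params, 17, continuous_streams=True
        )
        res_smd = run_smd(sys_, steer, plan_one, params, 17)
        # concatenated stage-relative works reproduce the single-pull works
        Wcat = results[0].ensemble.works
        for res in results[1:]:
            Wcat = np.hstack([Wcat, Wcat[:, -1:] + res.ensemble.works[:, 1:]])
        np.testing.assert_allclose(Wcat, res_smd.ensemble.works, atol=1e-12)
        np.testing.assert_allclose(pmf_fr.F, res_smd.pmf.F, atol=1e-10)

    def test_harmonic_closed_form_within_3se(self, harmonic):
        steer = make_steering(k=1.0, velocity=20.0)
        plan = StagePlan(
            segments=tuple(StagePlan.default_segments(0.0, 2.0, 2)), tps=100, t_relax=2.0
        )
        results, pmf = run_fr_asmd(make_1d_system(harmonic), steer, plan, make_params(), 29)
        # endpoint SE from the cumulative works
        Wend = results[0].ensemble.end_works + results[1].ensemble.end_works
        from adaptivepull import WorkEnsemble

        ens = WorkEnsemble(np.array([0.0, 2.0]), np.column_stack([np.zeros(100), Wend]), 300.0)
        dF, se = jackknife_delta_f(ens)
        assert abs(pmf.delta_F - 1.0) < 3 * se + 1e-9 or abs(dF - 1.0) < 3 * se

    def test_hold_spring_relax_mode_zero_work(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(segments=tuple(StagePlan.default_segments(-1, 1, 2)), tps=4, t_relax=1.0)
        results, _ = run_fr_asmd(
            make_1d_system(double_well, x0=-1.0), steer, plan, make_params(), 3,
            relax_mode="hold_spring",
        )
        assert results[0].record["relax_work"] == 0.0

    def test_no_contraction_trajectories_continue(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(segments=tuple(StagePlan.default_segments(-1, 1, 2)), tps=5, t_relax=0.0)
        results, _ = run_fr_asmd(
            make_1d_system(double_well, x0=-1.0), steer, plan, make_params(), 37
        )
        assert results[0].selected is None
        # distinct final states per trajectory (no collapse to one structure)
        finals = np.array([s.positions[0] for s in results[0].final_states])
        assert np.unique(finals).size == finals.size


class TestAssemblePMF:
    def test_single_stage_identity(self, harmonic):
        steer = make_steering(k=1.0, velocity=100.0)
        plan = StagePlan(segments=((0.0, 2.0),), tps=4, t_relax=0.0)
        res = run_smd(make_1d_system(harmonic), steer, plan, make_params(), 1)
        glob = assemble_pmf([res])
        np.testing.assert_array_equal(glob.F, res.pmf.F - res.pmf.F[0])

    def test_two_stage_additivity_and_continuity(self):
        grid1 = np.linspace(0.0, 1.0, 5)
        grid2 = np.linspace(1.0, 2.0, 5)
        from adaptivepull.asmd import StageResult
        from adaptivepull import WorkEnsemble

        def fake(stage, grid, f_end):
            F = np.linspace(0.0, f_end, grid.size)
            W = F[None, :].copy()
            return StageResult(stage, WorkEnsemble(grid, W, 300.0), PMFCurve(grid, F), [])

        glob = assemble_pmf([fake(0, grid1, 2.0), fake(1, grid2, 3.0)])
        assert glob.F[-1] == pytest.approx(5.0, abs=1e-12)
        # continuity at the join is exact
        i = np.searchsorted(glob.lambdas, 1.0)
        assert glob.lambdas[i] == 1.0
        assert np.all(np.diff(glob.lambdas) > 0)

    def test_non_contiguous_stages_rejected(self):
        from adaptivepull.asmd import StageResult
        from adaptivepull import WorkEnsemble

        def fake(stage, grid):
            W = np.zeros((1, grid.size))
            return StageResult(stage, WorkEnsemble(grid, W, 300.0), PMFCurve(grid, W[0]), [])

        with pytest.raises(ConfigurationError, match="contiguous"):
            assemble_pmf([fake(0, np.linspace(0, 1, 3)), fake(1, np.linspace(2, 3, 3))])

    def test_ten_stage_fr_assembly_equals_single_je(self, double_well):
        # algebraic identity: with carried works and no contraction the
        # assembled profile equals one exponential average over cumulative works
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(
            segments=tuple(StagePlan.default_segments(-1, 1, 10)), tps=9, t_relax=0.0
        )
        params = make_params()
        results, pmf = run_fr_asmd(
            make_1d_system(double_well, x0=-1.0), steer, plan, params, 41,
            continuous_streams=True,
        )
        Wcat = results[0].ensemble.works
        grid = results[0].ensemble.lambda_grid
        for res in results[1:]:
            Wcat = np.hstack([Wcat, Wcat[:, -1:] + res.ensemble.works[:, 1:]])
            grid = np.concatenate([grid, res.ensemble.lambda_grid[1:]])
        from adaptivepull import WorkEnsemble, jarzynski_pmf

        single = jarzynski_pmf(WorkEnsemble(grid, Wcat, params.temperature))
        np.testing.assert_allclose(pmf.F, single.F, atol=1e-10)

    def test_global_pmf_boundary_continuity_exact(self, double_well):
        steer = make_steering(k=5.0, lam_start=-1.0, lam_end=1.0, velocity=200.0)
        plan = StagePlan(segments=tuple(StagePlan.default_segments(-1, 1, 4)), tps=5, t_relax=0.0)
        _, pmf = run_naive_asmd(make_1d_system(double_well, x0=-1.0), steer, plan, make_params(), 2)
        # grid strictly increasing => each boundary appears once; the curve is
        # single-valued there by construction
        assert np.all(np.diff(pmf.lambdas) > 0)
        assert pmf.F[0] == 0.0
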