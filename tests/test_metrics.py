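"""Interpretation metrics: similarity, entropy, ideal steps, memory probe."""

from collections import deque

import numpy as np
import pytest

from planxai import (PolicyValueNet, entropy, ideal_steps, memory_probe,
                     organ_attribution, reward_vectors, run_episode,
                     similarity)
from planxai.agent import apply_action, build_action_space
from planxai.ig import AttributionRecord
from planxai import metrics as mm
from planxai.metrics import (MAX_ENTROPY, PlanAnalysis, cohort_report,
                             probe_separation, tpp_space_summary)
from planxai.network import N_ACTIONS
from planxai.phantom import TPPVector


def record_with_dvh(ig_dvh):
    return AttributionRecord(action=0, ig_dvh=np.asarray(ig_dvh, float),
                             ig_c=np.zeros(32), ig_h=np.zeros(32),
                             baseline_output=0.0, actual_output=0.0,
                             path_steps=2)


class TestOrganAttribution:
    def test_all_ones(self):
        assert np.array_equal(organ_attribution(record_with_dvh(np.ones(300))),
                              [100.0, 100.0, 100.0])

    def test_rectum_only(self):
        a = np.zeros(300)
        a[200:] = 0.5
        assert np.array_equal(organ_attribution(record_with_dvh(a)),
                              [0.0, 0.0, 50.0])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=300)
        got = organ_attribution(record_with_dvh(a))
        want = [sum(a[k] for k in range(100)),
                sum(a[k] for k in range(100, 200)),
                sum(a[k] for k in range(200, 300))]
        assert np.allclose(got, want, atol=1e-9)


class TestSimilarity:
    def test_perfect_alignment_is_one(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 18, 3)) + 2
        p = rng.dirichlet(np.ones(18), size=3)
        assert similarity(p, A, A) == pytest.approx(1.0)

    def test_perfect_antialignment_is_minus_one(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(3, 18, 3)) + 2
        p = rng.dirichlet(np.ones(18), size=3)
        assert similarity(p, A, -A) == pytest.approx(-1.0)

    def test_matches_double_loop_oracle(self):
        """Hand-built 3-step, 18-action table versus a spreadsheet-style
        naive double loop, to 1e-12."""
        rng = np.random.default_rng(13)
        N = 3
        p = rng.dirichlet(np.ones(18), size=N)
        A = rng.normal(size=(N, 18, 3))
        R = rng.normal(size=(N, 18, 3))
        A[1, 4] = 0.0  # exercise the zero-vector convention
        total = 0.0
        for i in range(N):
            for j in range(18):
                na = np.linalg.norm(A[i, j])
                nr = np.linalg.norm(R[i, j])
                c = 0.0 if na == 0 or nr == 0 \
                    else float(A[i, j] @ R[i, j] / (na * nr))
                total += p[i, j] * c
        assert similarity(p, A, R) == pytest.approx(total / N, abs=1e-12)

    def test_bounded_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        p = rng.dirichlet(np.ones(18), size=5)
        A = rng.normal(size=(5, 18, 3))
        R = rng.normal(size=(5, 18, 3))
        s = similarity(p, A, R)
        assert -1.0 <= s <= 1.0
        perm = rng.permutation(5)
        assert similarity(p[perm], A[perm], R[perm]) == pytest.approx(s)


class TestEntropy:
    def test_uniform_rows_give_ln_18(self):
        p = np.full((4, 18), 1.0 / 18.0)
        assert entropy(p) == pytest.approx(np.log(18.0), abs=1e-12)
        assert entropy(p) == pytest.approx(2.8904, abs=1e-4)

    def test_one_hot_rows_give_zero(self):
        p = np.zeros((3, 18))
        p[:, 5] = 1.0
        assert entropy(p) == 0.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.full(18, 0.3), size=6)
        total = 0.0
        for i in range(6):
            for j in range(18):
                if p[i, j] > 0:
                    total -= p[i, j] * np.log(p[i, j])
        assert entropy(p) == pytest.approx(total / 6, abs=1e-12)

    def test_bounds_and_invalid_rows(self):
        rng = np.random.default_rng(4)
        p = rng.dirichlet(np.ones(18), size=8)
        assert 0.0 <= entropy(p) <= MAX_ENTROPY
        with pytest.raises(ValueError):
            entropy(p * 0.8)


def bfs_min_steps(initial, final, actions):
    """Shortest path on the TPP action lattice with clipping."""
    start = tuple(np.round(initial.values, 9))
    goal = tuple(np.round(final.values, 9))
    seen = {start}
    queue = deque([(start, 0)])
    while queue:
        state, d = queue.popleft()
        if state == goal:
            return d
        tpps = initial.with_values(np.array(state))
        for act in actions:
            nxt = tuple(np.round(apply_action(tpps, act).values, 9))
            if nxt not in seen:
                seen.add(nxt)
                queue.append((nxt, d + 1))
    raise AssertionError("goal unreachable")


class TestIdealSteps:
    def test_zero_when_unchanged(self):
        t = TPPVector.default()
        assert ideal_steps(t, t) == 0

    def test_single_parameter_five_steps(self):
        t = TPPVector.default()
        moved = t.with_values(t.values + np.array([5 * 0.15] + [0.0] * 8))
        assert ideal_steps(t, moved) == 5

    def test_off_lattice_rejected(self):
        t = TPPVector.default()
        bad = t.with_values(t.values + np.array([0.07] + [0.0] * 8))
        with pytest.raises(ValueError):
            ideal_steps(t, bad)

    def test_matches_bfs_oracle(self):
        """100 random lattice targets: the monotonic-adjustment count
        equals the BFS shortest-path length over the 18-action graph."""
        rng = np.random.default_rng(21)
        initial = TPPVector.default()
        actions = build_action_space(initial)
        for _ in range(100):
            # sparse targets keep the breadth-first search tractable
            shift = np.zeros(9, dtype=int)
            which = rng.choice(9, size=2, replace=False)
            shift[which] = rng.integers(-2, 3, size=2)
            vals = np.clip(initial.values + shift * initial.delta,
                           initial.lo, initial.hi)
            final = initial.with_values(vals)
            got = ideal_steps(initial, final)
            assert got == bfs_min_steps(initial, final, actions)


class TestMemoryProbe:
    def test_eighty_vectors_each(self, default_net):
        C, H, labels = memory_probe(default_net, repeats=10)
        assert C.shape == (80, 32)
        assert H.shape == (80, 32)
        assert len(labels) == 80
        assert len(set(labels)) == 8

    def test_deterministic(self, default_net):
        C1, H1, _ = memory_probe(default_net)
        C2, H2, _ = memory_probe(default_net)
        assert np.array_equal(C1, C2)
        assert np.array_equal(H1, H2)

    def test_vectors_unit_normalized(self, default_net):
        C, H, _ = memory_probe(default_net)
        norms = np.linalg.norm(C, axis=1)
        assert np.allclose(norms[norms > 0], 1.0)

    def test_scenarios_separate_in_memory_space(self, default_net):
        """Even an untrained recurrent net maps distinct violation
        scenarios to distinct memory trajectories; within-scenario cosine
        distance must undercut between-scenario distance."""
        C, H, labels = memory_probe(default_net)
        for V in (C, H):
            d = probe_separation(V, labels)
            assert d["within"] < d["between"]


class TestRewardVectors:
    def test_clipped_action_gives_zero_vector(self, small_case, criteria,
                                              default_net):
        t = TPPVector.default()
        at_hi = t.with_values(np.concatenate([[t.hi[0]], t.values[1:]]))
        trace = run_episode(small_case, default_net, initial_tpps=at_hi,
                            max_steps=1, mode="greedy")
        R = reward_vectors(trace.steps[0], small_case, criteria, mode=2)
        assert np.array_equal(R[0], np.zeros(3))  # increase lam_PTV clipped

    def test_mode2_sign_convention(self):
        """A violation reduction 0.30 -> 0.10 contributes +0.20."""
        before = np.array([0.0, 0.0, 0.30])
        after = np.array([0.0, 0.0, 0.10])
        assert (before - after)[2] == pytest.approx(0.20)

    def test_matches_cold_start_oracle(self, criteria, default_net):
        """Warm-started counterfactual rewards versus an independent
        cold-start re-optimization, on a toy case whose crossfire coupling
        keeps every penalty active, making the optimum unique."""
        from planxai import optimize_fluence
        from planxai.dvh import plan_dvhs, score_plan
        from planxai.phantom import OptimizerConfig, PhantomCase
        M = np.array([[1.0, 0.3], [0.3, 1.0], [0.6, 0.6],
                      [0.5, 0.8], [0.8, 0.5]])
        case = PhantomCase(
            case_id="toy52", grid_shape=(1, 5),
            structure_masks={"PTV": np.array([0, 1]),
                             "BLA": np.array([2, 3]),
                             "REC": np.array([4])},
            dose_matrix=M, prescription_dose=10.0, seed=0)
        tpps0 = TPPVector(np.array([2.0, 1.0, 1.0, 1.0, 0.55, 0.55,
                                    0.05, 0.05, 0.05]))
        tight = OptimizerConfig(max_outer=40, max_inner=400, rel_tol=1e-12)
        trace = run_episode(case, default_net, initial_tpps=tpps0,
                            max_steps=1, mode="greedy", opt_config=tight)
        step = trace.steps[0]
        R = reward_vectors(step, case, criteria, mode=2, opt_config=tight)
        actions = build_action_space(step.tpps_before)
        before = score_plan(
            plan_dvhs(case, optimize_fluence(case, step.tpps_before,
                                             config=tight)), criteria)
        for j in range(18):
            tpps_j = apply_action(step.tpps_before, actions[j])
            plan_j = optimize_fluence(case, tpps_j, config=tight)
            after = score_plan(plan_dvhs(case, plan_j), criteria)
            want = before.violations_vector - after.violations_vector
            assert np.allclose(R[j], want, atol=1e-6), j

    def test_invalid_mode_rejected(self, small_case, criteria, default_net):
        trace = run_episode(small_case, default_net, max_steps=1,
                            mode="greedy")
        with pytest.raises(ValueError):
            reward_vectors(trace.steps[0], small_case, criteria, mode=3)


def plan(ckpt, sim2, steps, full=True, ent=0.5):
    return PlanAnalysis(case_id="c", checkpoint=ckpt, initial_score=5.0,
                        final_score=9.0 if full else 7.0, n_steps=steps,
                        full_score=full, ideal_steps=max(steps - 2, 0),
                        entropy=ent, similarity_mode1=sim2 / 2,
                        similarity_mode2=sim2)


class TestCohortReport:
    def test_perfect_at_step_zero(self):
        a = PlanAnalysis("c", "k", 9.0, 9.0, 0, True, 0, float("nan"),
                         float("nan"), float("nan"))
        rep = cohort_report([a])
        assert rep.summaries[0].final_score_mean == 9.0
        assert rep.summaries[0].steps_mean == 0.0

    def test_two_point_correlation_minus_one(self):
        analyses = [plan("a", 0.1, 20), plan("b", 0.5, 10)]
        rep = cohort_report(analyses)
        assert rep.pearson_r == pytest.approx(-1.0)

    def test_totals_reconstructible(self):
        analyses = [plan("a", 0.1, 20), plan("a", 0.3, 10, full=False),
                    plan("b", 0.5, 10)]
        rep = cohort_report(analyses)
        a = next(s for s in rep.summaries if s.checkpoint == "a")
        assert a.n_plans == 2
        assert a.n_full_score == 1
        assert a.steps_mean == 20.0  # full-score plans only

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            cohort_report([])


class TestTPPSpace:
    def test_multiplicities_sum_to_full_score_plans(self, small_case,
                                                    default_net):
        traces = [run_episode(small_case, default_net, max_steps=2,
                              mode="stochastic", seed=s) for s in range(3)]
        # mark outcomes against an impossible bar so none are full score
        summary = tpp_space_summary(traces, max_points=9.0)
        n_full = sum(t.final_score >= 9.0 for t in traces)
        for counter in summary.final_values:
            assert sum(counter.values()) == n_full


class TestMixedModelHook:
    def test_mixed_model_hook_runs(self):
        """The optional statsmodels hook fits a per-case random-intercept
        model of planning steps by checkpoint."""
        import pandas as pd
        rng = np.random.default_rng(0)
        rows = []
        for ck, base in (("early", 22), ("late", 13)):
            for case in range(6):
                for _ in range(3):
                    rows.append({"checkpoint": ck, "case_id": f"c{case}",
                                 "n_steps": base + case
                                 + rng.integers(-2, 3)})
        fit = mm.planning_steps_mixed_model(pd.DataFrame(rows))
        assert "C(checkpoint)" in fit.summary().as_text()


class TestReportExport:
    def test_csv_and_json_written(self, tmp_path):
        analyses = [plan("a", 0.1, 20), plan("a", 0.3, 12),
                    plan("b", 0.5, 10)]
        report = cohort_report(analyses)
        mm.write_report(analyses, report, tmp_path / "report")
        import pandas as pd, json
        plans = pd.read_csv(tmp_path / "report" / "plans.csv")
        assert len(plans) == 3
        assert {"case_id", "checkpoint", "n_steps",
                "similarity_mode2"} <= set(plans.columns)
        ckpts = pd.read_csv(tmp_path / "report" / "checkpoints.csv")
        assert len(ckpts) == 2
        payload = json.loads((tmp_path / "report" / "summary.json").read_text())
        assert payload["pearson_r"] == pytest.approx(report.pearson_r)
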