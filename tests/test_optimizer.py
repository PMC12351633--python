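import itertools

import numpy as np
import pytest

from tesgroup.cohort import CohortSpec, generate_cohort
from tesgroup.geometry import icosphere
from tesgroup.model import LeadField, Montage, SubjectModel, TargetMap
from tesgroup.objective import nerni
from tesgroup.optimize import (
    OptimizationConfig,
    _GroupQuadratic,
    _solve_qp,
    check_constraints,
    ga_optimize,
    optimize_group_loo,
    solve_currents,
)


def _grid_best_2d(Q, b, imax=2.0, itot=4.0, step=0.001):
    """Brute-force maximum of 2 b.I - I.Q.I over the 2-electrode polytope."""
    g = np.arange(-imax, imax + step / 2, step)
    G1, G2 = np.meshgrid(g, g, indexing="ij")
    ref = -(G1 + G2)
    anodal = np.maximum(G1, 0) + np.maximum(G2, 0) + np.maximum(ref, 0)
    feas = (np.abs(ref) <= imax) & (anodal <= itot)
    obj = 2 * (b[0] * G1 + b[1] * G2) - (
        Q[0, 0] * G1**2 + 2 * Q[0, 1] * G1 * G2 + Q[1, 1] * G2**2
    )
    return float(obj[feas].max())


def _random_quad(rng, n_nodes=20, n_elec=2):
    K = rng.normal(0, 0.1, (n_nodes, n_elec))
    t = rng.normal(0, 0.2, n_nodes)
    w = rng.uniform(0.5, 2.0, n_nodes)
    wt = w * t
    D = wt @ wt
    M = w[:, None] * K
    return M.T @ M / D, M.T @ wt / D


class TestSolveCurrents:
    def test_clipped_one_electrode_toy(self):
        # w=1, target 0.25 V/m, K=0.1 V/m per mA: unconstrained I=2.5 clips to 2.0
        surf = icosphere(1, 78.0)
        n = surf.n_nodes
        K = np.zeros((n, 1))
        K[0, 0] = 0.1
        en = np.zeros(n)
        en[0] = 0.25
        w = np.zeros(n)
        w[0] = 1.0
        sub = SubjectModel("t", surf, LeadField(K, ("F3",)), TargetMap(en, w))
        sol = solve_currents(["F3"], sub)
        assert sol.currents["F3"] == pytest.approx(2.0, abs=1e-8)

    def test_zero_leadfield_gives_zero_currents(self):
        surf = icosphere(1, 78.0)
        n = surf.n_nodes
        en = np.zeros(n)
        en[0] = 0.25
        w = np.ones(n)
        sub = SubjectModel(
            "z", surf, LeadField(np.zeros((n, 2)), ("F3", "Fz")), TargetMap(en, w)
        )
        sol = solve_currents(["F3", "Fz"], sub)
        assert sol.objective == pytest.approx(0.0, abs=1e-12)
        assert all(abs(c) < 1e-9 for c in sol.currents.values())

    def test_matches_grid_search_on_random_leadfields(self, rng):
        cfg = OptimizationConfig()
        for _ in range(10):
            Q, b = _random_quad(rng)
            _, val = _solve_qp(Q, b, cfg)
            assert val == pytest.approx(_grid_best_2d(Q, b), abs=1e-4)

    def test_solution_respects_all_bounds(self, cohort6):
        # full-set solve: current bounds apply but no cardinality cap
        cfg = OptimizationConfig()
        labels = list(cohort6[0].leadfield.electrode_labels)
        sol = solve_currents(labels, cohort6, cfg)
        check_constraints(
            sol.montage, OptimizationConfig(max_electrodes=len(labels))
        )

    def test_objective_matches_group_nerni(self, cohort6):
        from tesgroup.objective import nerni_group

        sol = solve_currents(["F3", "AF3", "FC1", "T8"], cohort6)
        assert nerni_group(sol.montage, cohort6) == pytest.approx(sol.objective, abs=1e-9)

    def test_empty_subset_is_an_error(self, subject):
        with pytest.raises(ValueError, match="empty"):
            solve_currents([], subject)


class TestGaOptimize:
    def test_few_candidates_degenerates_to_full_solve(self, subject):
        cfg = OptimizationConfig(ga_population=20, seed=3)
        cands = subject.leadfield.electrode_labels[:6]
        res = ga_optimize(subject, candidates=cands, config=cfg)
        full = solve_currents(list(cands), subject, cfg)
        assert res.objective == pytest.approx(full.objective, abs=1e-12)
        assert res.generations_run == 0

    def test_deterministic_for_fixed_seed(self, subject):
        cfg = OptimizationConfig(ga_population=40, max_electrodes=3, seed=9)
        cands = subject.leadfield.electrode_labels[:12]
        r1 = ga_optimize(subject, candidates=cands, config=cfg)
        r2 = ga_optimize(subject, candidates=cands, config=cfg)
        assert r1.montage.currents == r2.montage.currents
        assert r1.history == r2.history

    def test_attains_exhaustive_optimum_on_small_instance(self, subject):
        cands = subject.leadfield.electrode_labels[:10]
        cfg = OptimizationConfig(max_electrodes=3, seed=1)  # default population
        quad = _GroupQuadratic([subject], cands)
        best = -np.inf
        for combo in itertools.combinations(range(10), 3):
            idx = np.asarray(combo)
            _, v = _solve_qp(quad.Q[np.ix_(idx, idx)], quad.b[idx], cfg)
            best = max(best, v)
        res = ga_optimize(subject, candidates=cands, config=cfg)
        assert res.objective == pytest.approx(best, abs=1e-9)

    def test_history_is_non_decreasing(self, subject):
        cfg = OptimizationConfig(ga_population=40, max_electrodes=4, seed=17)
        res = ga_optimize(subject, config=cfg)
        assert all(b >= a for a, b in zip(res.history, res.history[1:]))

    def test_objective_grows_with_electrode_budget(self, subject):
        cands = subject.leadfield.electrode_labels[:8]
        cfg = lambda k: OptimizationConfig(max_electrodes=k, seed=5)
        quad = _GroupQuadratic([subject], cands)

        def exhaustive(k):
            best = -np.inf
            for combo in itertools.combinations(range(8), k):
                idx = np.asarray(combo)
                _, v = _solve_qp(quad.Q[np.ix_(idx, idx)], quad.b[idx], cfg(k))
                best = max(best, v)
            return best

        assert exhaustive(3) >= exhaustive(2) - 1e-12
        assert exhaustive(4) >= exhaustive(3) - 1e-12

    def test_single_candidate_set_is_an_error(self, subject):
        with pytest.raises(ValueError, match="at least 2"):
            ga_optimize(subject, candidates=("F3",))


@pytest.fixture(scope="module")
def twin_cohort():
    return generate_cohort(
        CohortSpec(
            n_subjects=2,
            seed=4,
            radius_jitter=0.0,
            surface_subdivisions=2,
            compute_features=False,
        )
    )


class TestGroupLoo:
    def test_identical_twins_get_each_others_personalized_montage(self, twin_cohort):
        cfg = OptimizationConfig(ga_population=30, max_electrodes=3, seed=2)
        loo = optimize_group_loo(twin_cohort, config=cfg)
        pers = {s.subject_id: ga_optimize(s, config=cfg) for s in twin_cohort}
        for held, r in loo.items():
            other = next(s for s in twin_cohort if s.subject_id != held)
            assert r.result.montage.currents == pers[other.subject_id].montage.currents

    def test_zero_jitter_heldout_equals_ingroup(self, twin_cohort):
        cfg = OptimizationConfig(ga_population=30, max_electrodes=3, seed=2)
        for r in optimize_group_loo(twin_cohort, config=cfg).values():
            assert r.held_out_nerni == pytest.approx(r.result.objective, abs=1e-9)

    def test_needs_two_subjects(self, subject):
        with pytest.raises(ValueError, match="at least 2"):
            optimize_group_loo([subject])


class TestConstraintChecker:
    def test_accepts_balanced_montage(self):
        check_constraints(Montage({"F3": 1.5, "Fp1": -1.5}))

    @pytest.mark.parametrize(
        "currents",
        [
            {"F3": 2.5},  # per-electrode bound
            {"F3": 2.0, "Fz": 1.9},  # implicit reference exceeds 2 mA
            {"F3": 2.0, "Fz": 2.0, "C3": 1.5, "C4": -2.0, "T7": -2.0, "T8": -1.5},
        ],
    )
    def test_rejects_violations(self, currents):
        with pytest.raises(ValueError):
            check_constraints(Montage(currents))

    def test_rejects_too_many_active_electrodes(self, subject):
        labels = subject.leadfield.electrode_labels[:18]
        half = len(labels) // 2
        currents = {lab: 0.2 for lab in labels[:half]}
        currents.update({lab: -0.2 for lab in labels[half:]})
        with pytest.raises(ValueError, match="active electrodes"):
            check_constraints(Montage(currents))
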