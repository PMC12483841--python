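"""Minimum-set solver: oracle equivalence, boundary accounting, contracts."""

import numpy as np
import pytest

from sageplan.minset import (
    ProblemSpec,
    Target,
    boundary_term,
    calibrate_boundary_penalty,
    capture_report,
    formulate,
    solve,
)
from sageplan.units import build_units


def _line_units(n, cell=30.0):
    el = np.zeros((1, n), bool)
    el[0, :n] = True
    return build_units(el, cell)


def _spec(cost, features, targets, **kw):
    cost = np.asarray(cost, dtype=float)
    units = kw.pop("units", None) or _line_units(cost.size)
    return ProblemSpec(units=units, cost=cost,
                       features={k: np.asarray(v, dtype=float) for k, v in features.items()},
                       targets=targets, **kw)


def _random_instance(rng):
    """Small random instance on a 4x4 grid with 2-3 features."""
    while True:
        el = rng.random((4, 4)) < 0.6
        if 3 <= el.sum() <= 12:
            break
    units = build_units(el, 30.0)
    n = units.n_units
    cost = rng.uniform(0.5, 3.0, n)
    nfeat = rng.integers(2, 4)
    features = {f"f{j}": rng.uniform(0.0, 1.0, n) for j in range(nfeat)}
    targets = {k: Target("relative", float(rng.uniform(0.1, 0.5))) for k in features}
    b = float(rng.choice([0.0, 0.1, 1.0]))
    return ProblemSpec(units=units, cost=cost, features=features, targets=targets,
                       boundary_penalty=b, gap=0.0)


class TestEnumerationExamples:
    def test_cheapest_covering_unit_selected(self):
        # need >= 0.2 * 20 = 4; unit 1 (cost 1, f = 5) suffices
        spec = _spec([3.0, 1.0, 2.0], {"f": [10.0, 5.0, 5.0]},
                     {"f": Target("relative", 0.2)}, gap=0.0)
        for backend in ("milp", "exhaustive"):
            sol = solve(spec, backend)
            assert sol.objective == pytest.approx(1.0)
        exact = solve(spec, "exhaustive")
        np.testing.assert_array_equal(exact.selected, [False, True, False])

    def test_locked_in_always_selected(self):
        spec = _spec([5.0, 1.0], {"f": [0.0, 10.0]},
                     {"f": Target("relative", 0.2)},
                     locked_in=np.array([0]), gap=0.0)
        for backend in ("milp", "exhaustive", "greedy"):
            sol = solve(spec, backend)
            assert sol.selected[0]

    def test_zero_total_feature_relative_target_is_vacuous(self):
        spec = _spec([1.0, 1.0], {"f": [0.0, 0.0]}, {"f": Target("relative", 0.2)},
                     gap=0.0)
        with pytest.warns(UserWarning, match="vacuous"):
            sol = solve(spec, "exhaustive")
        assert sol.status != "infeasible"
        assert sol.n_selected == 0

    def test_infeasible_names_violated_features(self):
        spec = _spec([1.0], {"good": [5.0], "bad": [1.0]},
                     {"good": Target("absolute", 1.0), "bad": Target("absolute", 2.0)},
                     gap=0.0)
        for backend in ("milp", "exhaustive", "greedy"):
            sol = solve(spec, backend)
            assert sol.status == "infeasible"
            assert sol.violated == ["bad"]

    def test_zero_target_is_vacuous_constraint(self):
        spec = _spec([1.0, 2.0], {"f": [1.0, 1.0]}, {"f": Target("relative", 0.0)},
                     gap=0.0)
        assert solve(spec, "exhaustive").n_selected == 0


class TestBoundaryAccounting:
    def test_no_penalty_reduces_to_cost(self):
        spec = _spec([2.0, 3.0], {"f": [1.0, 1.0]}, {"f": Target("relative", 1.0)},
                     boundary_penalty=0.0, gap=0.0)
        form = formulate(spec)
        assert form.n_pairs == 0
        np.testing.assert_array_equal(form.obj, [2.0, 3.0])

    def test_domino_hand_accounting(self):
        # both cells of a 1x2 block selected, cell 30 m, edge factor 0.5:
        # exposed boundary is all study edge (6 sides x 30 m) at factor 0.5
        units = _line_units(2)
        sel = np.array([True, True])
        assert boundary_term(sel, units, edge_factor=0.5) == pytest.approx(90.0)
        # one selected cell: 3 study sides at 0.5 + the full shared edge
        assert boundary_term(np.array([True, False]), units, 0.5) == pytest.approx(75.0)

    def test_boundary_term_matches_formulation_objective(self):
        rng = np.random.default_rng(12)
        spec = _random_instance(rng)
        sol = solve(spec, "exhaustive")
        recomputed = (spec.cost[sol.selected].sum()
                      + spec.boundary_penalty
                      * boundary_term(sol.selected, spec.units, spec.edge_factor))
        assert sol.objective == pytest.approx(recomputed, abs=1e-12)

    def test_penalty_encourages_clumping(self):
        # two equally priced ways to meet the target: scattered or contiguous
        units = _line_units(4)
        features = {"f": np.array([1.0, 0.0, 1.0, 1.0])}
        cost = np.ones(4)
        spec = ProblemSpec(units=units, cost=cost, features=features,
                           targets={"f": Target("relative", 2.0 / 3.0)},
                           boundary_penalty=0.01, gap=0.0)
        sol = solve(spec, "exhaustive")
        # contiguous pair {2, 3} beats {0, 2} or {0, 3} on boundary
        np.testing.assert_array_equal(sol.selected, [False, False, True, True])


class TestOracleEquivalence:
    def test_milp_matches_exhaustive_on_random_instances(self):
        rng = np.random.default_rng(2024)
        n_checked = 0
        for _ in range(40):
            spec = _random_instance(rng)
            exact = solve(spec, "exhaustive")
            approx = solve(spec, "milp")
            assert (exact.status == "infeasible") == (approx.status == "infeasible")
            if exact.status == "infeasible":
                continue
            assert approx.objective == pytest.approx(exact.objective, abs=1e-9)
            t = spec.absolute_targets()
            for k, req in t.items():
                assert spec.features[k][approx.selected].sum() >= req - 1e-9
                assert spec.features[k][exact.selected].sum() >= req - 1e-9
            n_checked += 1
        assert n_checked >= 30

    def test_greedy_never_beats_exact(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            spec = _random_instance(rng)
            exact = solve(spec, "exhaustive")
            greedy = solve(spec, "greedy")
            if exact.status == "infeasible":
                assert greedy.status == "infeasible"
                continue
            assert greedy.objective >= exact.objective - 1e-9

    def test_objective_monotone_in_target(self):
        rng = np.random.default_rng(77)
        units = _line_units(6)
        cost = rng.uniform(1, 2, 6)
        f = rng.uniform(0, 1, 6)
        prev = 0.0
        for tval in (0.1, 0.3, 0.5, 0.7, 0.9):
            spec = ProblemSpec(units=units, cost=cost, features={"f": f},
                               targets={"f": Target("relative", tval)}, gap=0.0)
            obj = solve(spec, "exhaustive").objective
            assert obj >= prev - 1e-12
            prev = obj

    def test_uniform_cost_matches_minimum_cardinality_cover(self):
        rng = np.random.default_rng(5)
        units = _line_units(8)
        features = {"a": rng.uniform(0, 1, 8), "b": rng.uniform(0, 1, 8)}
        targets = {k: Target("relative", 0.4) for k in features}
        spec = ProblemSpec(units=units, cost=np.ones(8), features=features,
                           targets=targets, gap=0.0)
        sol = solve(spec, "exhaustive")
        # brute-force minimum cardinality over all subsets
        best = None
        import itertools
        for r in range(9):
            for combo in itertools.combinations(range(8), r):
                sel = np.zeros(8, bool); sel[list(combo)] = True
                if all(features[k][sel].sum() >= 0.4 * features[k].sum() - 1e-12
                       for k in features):
                    best = r
                    break
            if best is not None:
                break
        assert sol.n_selected == best


class TestCaptureAndCalibration:
    def test_capture_full_and_empty(self):
        spec = _spec([1.0, 1.0], {"f": [2.0, 3.0]}, {"f": Target("relative", 1.0)},
                     gap=0.0)
        sol = solve(spec, "exhaustive")
        assert capture_report(sol, spec.features)["f"] == pytest.approx(1.0)
        empty = solve(_spec([1.0, 1.0], {"f": [2.0, 3.0]},
                            {"f": Target("relative", 0.0)}, gap=0.0), "exhaustive")
        assert capture_report(empty, spec.features)["f"] == 0.0

    def test_degenerate_candidate_sweep(self):
        spec = _spec([1.0, 2.0], {"f": [1.0, 1.0]}, {"f": Target("relative", 0.5)},
                     gap=0.0)
        b, report = calibrate_boundary_penalty(spec, [0.0], np.inf, backend="exhaustive")
        assert b == 0.0 and len(report) == 1

    def test_unbounded_tolerance_returns_max_candidate(self):
        spec = _spec([1.0, 2.0, 1.0], {"f": [1.0, 1.0, 1.0]},
                     {"f": Target("relative", 0.5)}, gap=0.0)
        b, _ = calibrate_boundary_penalty(spec, [0.0, 0.01, 0.1], np.inf,
                                          backend="exhaustive")
        assert b == 0.1

    def test_exposed_boundary_nonincreasing_in_penalty(self):
        # two clumps of value; stronger penalties never fragment more
        units = _line_units(6)
        f = np.array([1.0, 1.0, 0.0, 0.0, 1.0, 1.0])
        spec = ProblemSpec(units=units, cost=np.ones(6), features={"f": f},
                           targets={"f": Target("relative", 0.5)}, gap=0.0)
        _, report = calibrate_boundary_penalty(spec, [0.0, 0.005, 0.05, 0.5],
                                               np.inf, backend="exhaustive")
        bnd = report["exposed_boundary"].to_numpy()
        assert np.all(np.diff(bnd) <= 1e-9)
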