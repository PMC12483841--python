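"""Problem catalog, uncertainty sweep and reporting."""

import dataclasses

import numpy as np
import pytest
import yaml
from shapely.geometry import box

from sageplan.catalog import (
    DEFAULT_SWEEP_WEIGHTS,
    PreparedLandscape,
    default_catalog,
    overlap_report,
    run_catalog_problem,
    scd_chain,
    single_species_entry,
    summarize_solution,
    umbrella_matrix,
    uncertainty_sweep,
)
from sageplan.geodata import PolygonLayer
from sageplan.minset import ProblemSpec, Solution, Target, solve
from sageplan.synth import BundleConfig, SpeciesSpec, generate_bundle
from sageplan.units import build_units


class TestCatalogDefaults:
    def test_catalog_matches_frozen_config(self):
        """Drift guard: the in-code defaults equal the shipped config file."""
        from importlib.resources import files
        frozen = yaml.safe_load(
            (files("sageplan") / "data" / "catalog_defaults.yaml").read_text())
        cat = default_catalog()
        assert set(cat) == set(frozen["problems"])
        for pid, expect in frozen["problems"].items():
            entry = cat[pid]
            for key, val in expect.items():
                assert getattr(entry, key) == val, f"{pid}.{key}"
            assert entry.relative_target == frozen["global"]["relative_target"]
            assert entry.gap == frozen["global"]["gap"]
            assert entry.edge_factor == frozen["global"]["edge_factor"]

    def test_single_species_variant_zeroes_other_targets(self, small_prep):
        entry = single_species_entry(default_catalog()["1a"], "obligate_songbird")
        res = run_catalog_problem(entry, small_prep)
        assert res.solution.status != "infeasible"
        assert res.captures["obligate_songbird"] >= 0.2 - 1e-6
        # protection single-species runs drop the nominal penalty
        assert entry.boundary_penalty == 0.0


class TestCatalogRuns:
    def test_all_species_targets_met(self, small_prep):
        res = run_catalog_problem(default_catalog()["1a"], small_prep)
        assert res.solution.status != "infeasible"
        for k, prop in res.captures.items():
            assert prop >= 0.2 - 1e-6, k

    def test_intact_locked_into_restoration_solution(self, small_prep):
        res = run_catalog_problem(default_catalog()["2a"], small_prep)
        units = res.units
        in_intact = small_prep.intact[units.cells[:, 0], units.cells[:, 1]]
        assert res.solution.selected[in_intact].all()

    def test_selection_concentrates_where_features_do(self):
        """When one region holds all the feature value, selection goes there."""
        bundle = generate_bundle(21, BundleConfig(shape=(30, 30), n_leks=4))
        ncol = 30
        for name, g in bundle.features.items():
            vals = g.values.copy()
            vals[:, ncol // 2:] = 1e-6   # right half nearly worthless
            bundle.features[name] = g.copy(values=vals)
        prep = PreparedLandscape(bundle)
        res = run_catalog_problem(default_catalog()["1a"], prep)
        sel_cols = res.units.cells[res.solution.selected][:, 1]
        assert (sel_cols < ncol // 2).mean() > 0.9

    def test_empty_pool_reported_infeasible(self, small_bundle):
        bundle = dataclasses.replace(
            small_bundle,
            future_cover=small_bundle.future_cover.copy(
                values=np.minimum(small_bundle.future_cover.values, 12.0)))
        prep = PreparedLandscape(bundle)
        entry = dataclasses.replace(default_catalog()["1d"],
                                    future_cover_threshold=15.0)
        with pytest.warns(UserWarning, match="empty planning-unit pool"):
            res = run_catalog_problem(entry, prep)
        assert res.solution.status == "infeasible"
        assert res.units.n_units == 0


class TestUncertaintySweep:
    def test_default_schedule_is_nine_iterations(self, small_prep):
        res = uncertainty_sweep(default_catalog()["2b"], small_prep)
        assert len(DEFAULT_SWEEP_WEIGHTS) == 9
        assert res.sensitivity.n_iterations == 9
        assert len(res.solutions) == 9

    def test_zero_cv_gives_identical_low_sensitivity_solutions(self, small_bundle):
        zero = lambda g: g.copy(values=np.zeros_like(g.values))
        bundle = dataclasses.replace(
            small_bundle,
            soil_moisture_cv=zero(small_bundle.soil_moisture_cv),
            lek_abundance_cv=zero(small_bundle.lek_abundance_cv),
            feature_cv={k: zero(g) for k, g in small_bundle.feature_cv.items()})
        prep = PreparedLandscape(bundle)
        res = uncertainty_sweep(default_catalog()["2b"], prep)
        first = res.solutions[0].selected
        for sol in res.solutions[1:]:
            np.testing.assert_array_equal(sol.selected, first)
        classes = res.sensitivity.classes()
        assert np.all(classes[first] == "low")
        assert np.all(res.sensitivity.counts[first] == 9)

    def test_selections_meet_frozen_targets_on_original_features(self, small_prep):
        res = uncertainty_sweep(default_catalog()["2b"], small_prep)
        # rebuild the original (unpenalized) feature vectors
        from sageplan.catalog import _assemble_spec
        _, spec0 = _assemble_spec(default_catalog()["2b"], small_prep)
        for sol, ok in zip(res.solutions, res.feasible):
            if not ok:
                continue
            for k, t in res.frozen_targets.items():
                assert spec0.features[k][sol.selected].sum() >= t - 1e-6

    def test_counts_invariant_to_weight_order(self, small_prep):
        a = uncertainty_sweep(default_catalog()["2b"], small_prep,
                              weights=(0.0, 0.4, 0.8))
        b = uncertainty_sweep(default_catalog()["2b"], small_prep,
                              weights=(0.8, 0.0, 0.4))
        np.testing.assert_array_equal(a.sensitivity.counts, b.sensitivity.counts)

    def test_sensitivity_class_partition(self):
        from sageplan.catalog import SensitivityMap
        counts = np.array([0, 1, 3, 4, 6, 7, 9])
        m = SensitivityMap(counts=counts, n_iterations=9, n_feasible=9)
        assert list(m.classes()) == ["never", "high", "high", "medium",
                                     "medium", "low", "low"]
        assert sum(m.class_counts().values()) == counts.size

    def test_sweep_rejects_boundary_penalty(self, small_prep):
        entry = dataclasses.replace(default_catalog()["2b"], boundary_penalty=0.1)
        with pytest.raises(ValueError, match="boundary"):
            uncertainty_sweep(entry, small_prep)


class TestSummaries:
    def _toy_solution(self, n_sel, n=120):
        sel = np.zeros(n, bool)
        sel[:n_sel] = True
        return Solution(selected=sel, objective=0.0, cost_component=0.0,
                        boundary_component=0.0, captured={}, status="optimal")

    def test_area_in_hectares(self):
        sol = self._toy_solution(100)
        _, area = summarize_solution(sol, {}, cell_size=30.0)
        assert area == pytest.approx(9.0)

    def test_order_statistics(self):
        sol = self._toy_solution(5)
        layers = {"v": np.array([1.0, 2.0, 3.0, 4.0, 5.0] + [99.0] * 115)}
        df, _ = summarize_solution(sol, layers, 30.0)
        row = df.loc["v"]
        assert (row["median"], row["q1"], row["q3"], row["min"], row["max"]) \
            == (3.0, 2.0, 4.0, 1.0, 5.0)

    def test_empty_selection_sentinel(self):
        df, area = summarize_solution(self._toy_solution(0), {"v": np.ones(120)}, 30.0)
        assert df.empty and area == 0.0

    def test_summary_captures_match_capture_report(self, small_prep):
        from sageplan.minset import capture_report
        res = run_catalog_problem(default_catalog()["1b"], small_prep)
        again = capture_report(res.solution, res.spec.features)
        assert res.captures == again


class TestOverlapReport:
    def _sol(self, units, sel):
        return Solution(selected=sel, objective=0.0, cost_component=0.0,
                        boundary_component=0.0, captured={}, status="optimal")

    def test_full_and_zero_cover(self, grid33):
        units = build_units(np.ones((3, 3), bool), 30.0)
        sel = np.ones(9, bool)
        whole = PolygonLayer(ids=["w"], polygons=[box(-1, -1, 91, 901)])
        away = PolygonLayer(ids=["a"], polygons=[box(1e5, 1e5, 2e5, 2e5)])
        assert overlap_report(self._sol(units, sel), units, whole, grid33) == 100.0
        assert overlap_report(self._sol(units, sel), units, away, grid33) == 0.0

    def test_half_plane_on_symmetric_selection(self):
        from sageplan.geodata import RasterGrid
        template = RasterGrid(np.zeros((4, 4)), 30.0, (0.0, 120.0))
        units = build_units(np.ones((4, 4), bool), 30.0)
        sel = np.ones(16, bool)
        left = PolygonLayer(ids=["l"], polygons=[box(0, 0, 60, 120)])
        assert overlap_report(self._sol(units, sel), units, left, template) \
            == pytest.approx(50.0)


class TestUmbrellaAndChains:
    def test_diagonal_meets_target(self, small_prep):
        mat = umbrella_matrix(small_prep)
        for sp in mat.columns:
            assert mat.loc[sp, sp] >= 0.2 - 1e-6

    def test_generalist_solution_covers_specialist(self):
        """A species whose high-value core is another's whole habitat
        protects that other species when targeted alone."""
        specs = (SpeciesSpec("generalist", "increasing", "density", True),
                 SpeciesSpec("specialist", "increasing", "probability", True))
        bundle = generate_bundle(31, BundleConfig(shape=(30, 30), n_leks=4,
                                                  species=specs))
        gen = np.full((30, 30), 1e-9)
        spc = np.zeros((30, 30))
        gen[5:25, 5:25] = 1.0      # broad habitat
        gen[10:16, 10:16] = 10.0   # high-value core...
        spc[10:16, 10:16] = 1.0    # ...which is the specialist's whole range
        bundle.features["generalist"] = bundle.features["generalist"].copy(values=gen)
        bundle.features["specialist"] = bundle.features["specialist"].copy(values=spc)
        prep = PreparedLandscape(bundle)
        mat = umbrella_matrix(prep)
        assert mat.loc["generalist", "specialist"] >= 0.2

    def test_right_skewed_feature_needs_fewer_units(self):
        """Equal totals, opposite skew, uniform cost: the right-skewed
        (density-like) feature meets its 20% target with fewer units because
        its top values far exceed the mean."""
        rng = np.random.default_rng(99)
        n = 200
        right = rng.lognormal(0.0, 1.2, n)
        left = right.max() + right.min() - right  # mirrored: left-skewed
        left *= right.sum() / left.sum()          # equalize totals
        units = build_units(np.ones((1, n), bool), 30.0)
        counts = {}
        for name, f in (("right", right), ("left", left)):
            spec = ProblemSpec(units=units, cost=np.ones(n), features={"f": f},
                               targets={"f": Target("relative", 0.2)}, gap=0.0)
            counts[name] = solve(spec, "milp").n_selected
        assert counts["right"] < counts["left"]

    def test_scd_chain_nesting_and_masks(self, small_prep):
        chain = scd_chain(small_prep)
        sel3a = {tuple(c) for c in chain["3a"].units.cells[chain["3a"].solution.selected]}
        for pid in ("3b", "3c"):
            res = chain[pid]
            assert res.solution.status != "infeasible"
            sel = {tuple(c) for c in res.units.cells[res.solution.selected]}
            pool = {tuple(c) for c in res.units.cells}
            # 3a's sites, where present in the pool, are locked in
            assert (sel3a & pool) <= sel
        # all selections stay inside the conservation-area mask or 3a's sites
        cmask = small_prep.conservation_mask
        for pid in ("3a", "3b", "3c"):
            cells = chain[pid].units.cells[chain[pid].solution.selected]
            inside = cmask[cells[:, 0], cells[:, 1]]
            outside = {tuple(c) for c in cells[~inside]}
            assert outside <= sel3a
        # connectivity-loss costs are shifted to >= 1
        assert chain["3c"].spec.cost.min() >= 1.0
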