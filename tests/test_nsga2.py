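"""Non-dominated sorting, crowding, the evolutionary loop and ideal-point pick."""

import numpy as np
import pytest

import pgropt
from pgropt.exceptions import DegenerateScaleError, EvaluationError
from pgropt.nsga2 import (
    GAConfig,
    Individual,
    ObjectiveSpec,
    crowding_distance,
    dominates,
    evolve,
    fast_nondominated_sort,
    ideal_point_select,
    scale_objectives,
)


def spec_maxmaxmin(bounds=((0.0, 1.0),) * 2, evaluate=None):
    return ObjectiveSpec(
        evaluate=evaluate or (lambda X: X),
        directions=("max", "max", "min"),
        bounds=list(bounds),
    )


def min_spec(n_obj, n_genes=2, evaluate=None):
    return ObjectiveSpec(
        evaluate=evaluate or (lambda X: X),
        directions=("min",) * n_obj,
        bounds=[(0.0, 1.0)] * n_genes,
    )


class TestDominates:
    def test_better_everywhere(self):
        s = spec_maxmaxmin()
        assert dominates((7, 4, 0.1), (6, 3, 0.2), s)
        assert not dominates((6, 3, 0.2), (7, 4, 0.1), s)

    def test_equal_points_do_not_dominate(self):
        s = spec_maxmaxmin()
        assert not dominates((7, 4, 0.1), (7, 4, 0.1), s)

    def test_trade_off_is_incomparable(self):
        s = spec_maxmaxmin()
        assert not dominates((7, 3, 0.1), (6, 4, 0.2), s)
        assert not dominates((6, 4, 0.2), (7, 3, 0.1), s)


def peel_oracle(F, spec):
    """Brute-force O(N^2 * fronts) peeling: repeatedly strip the maximal
    non-dominated set.  Independent of the production sort."""
    remaining = list(range(F.shape[0]))
    ranks = np.full(F.shape[0], -1)
    r = 0
    while remaining:
        front = [
            i for i in remaining
            if not any(dominates(F[j], F[i], spec) for j in remaining if j != i)
        ]
        for i in front:
            ranks[i] = r
        remaining = [i for i in remaining if i not in front]
        r += 1
    return ranks


class TestNondominatedSort:
    def test_agrees_with_peeling_oracle_on_random_populations(self):
        rng = np.random.default_rng(0)
        for trial in range(200):
            n = int(rng.integers(2, 41))
            k = int(rng.integers(2, 5))
            dirs = tuple(rng.choice(["min", "max"], size=k))
            spec = ObjectiveSpec(
                evaluate=lambda X: X, directions=dirs,
                bounds=[(0.0, 1.0)], names=(),
            )
            # duplicates included on purpose
            F = rng.integers(0, 5, size=(n, k)).astype(float)
            _, ranks = fast_nondominated_sort(F, spec)
            assert np.array_equal(ranks, peel_oracle(F, spec)), f"trial {trial}"

    def test_single_champion_front(self):
        s = min_spec(2)
        F = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 1.0], [1.0, 2.0]])
        fronts, ranks = fast_nondominated_sort(F, s)
        assert list(fronts[0]) == [0]
        assert ranks[0] == 0

    def test_antichain_is_one_front(self):
        s = min_spec(2)
        F = np.array([[0.0, 3.0], [1.0, 2.0], [2.0, 1.0], [3.0, 0.0]])
        fronts, ranks = fast_nondominated_sort(F, s)
        assert len(fronts) == 1 and np.all(ranks == 0)


class TestCrowdingDistance:
    def test_three_collinear_equally_spaced(self):
        s = min_spec(2)
        F = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        d = crowding_distance(F, s)
        assert d[0] == np.inf and d[2] == np.inf
        # middle point: per objective gap (2-0)/range(2) = 1, two objectives
        assert d[1] == pytest.approx(2.0)

    def test_pairs_are_infinite(self):
        s = min_spec(2)
        assert np.all(np.isinf(crowding_distance(np.array([[0.0, 1], [1, 0]]), s)))

    def test_duplicated_vectors_have_zero_interior_distance(self):
        s = min_spec(2)
        F = np.array([[0.0, 0.0], [1.0, 1.0], [1.0, 1.0], [1.0, 1.0], [2.0, 2.0]])
        d = crowding_distance(F, s)
        assert np.count_nonzero(d[1:4] == 0.0) >= 1


def hv_2d(F, ref):
    """Exact 2-objective hypervolume (minimization) — independent oracle."""
    pts = F[np.all(F <= ref, axis=1)]
    if pts.size == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0])]
    hv, y_best = 0.0, ref[1]
    for x, y in pts:
        if y < y_best:
            hv += (ref[0] - x) * (y_best - y)
            y_best = y
    return hv


class TestEvolve:
    def constructed_spec(self, a=0.3, b=0.7):
        def f(X):
            return np.column_stack([
                -((X[:, 0] - a) ** 2),
                -((X[:, 1] - b) ** 2),
                (X[:, 0] + X[:, 1] - a - b) ** 2,
            ])
        return ObjectiveSpec(
            evaluate=f, directions=("max", "max", "min"),
            bounds=[(0.0, 1.0), (0.0, 1.0)],
        ), (a, b)

    def test_recovers_analytic_optimum(self):
        spec, (a, b) = self.constructed_spec()
        res = evolve(spec, GAConfig(population=40, generations=200, seed=1))
        best = min(
            res.front,
            key=lambda ind: -ind.objectives[0] - ind.objectives[1] + ind.objectives[2],
        )
        assert np.allclose(best.genes, [a, b], atol=1e-2)

    def test_no_variation_keeps_initial_genes(self):
        spec, _ = self.constructed_spec()
        cfg = GAConfig(population=12, generations=10, crossover_rate=0.0,
                       mutation_rate=0.0, seed=4)
        rng = np.random.default_rng(4)
        lo = np.array([0.0, 0.0]); hi = np.array([1.0, 1.0])
        initial = {tuple(g) for g in rng.uniform(lo, hi, size=(12, 2))}
        res = evolve(spec, cfg)
        assert all(tuple(ind.genes) in initial for ind in res.population)

    def test_genes_stay_in_bounds_every_generation(self):
        spec, _ = self.constructed_spec()
        seen = []

        def cb(gen, genes, F, fronts):
            seen.append((genes.min(), genes.max()))

        evolve(spec, GAConfig(population=16, generations=60, seed=2,
                              mutation_rate=0.2), callback=cb)
        assert len(seen) == 60
        assert all(lo >= 0.0 and hi <= 1.0 for lo, hi in seen)

    def test_front_hypervolume_nondecreasing_under_elitism(self):
        # 2-objective trade-off: minimize (x^2 + y^2, (x-1)^2 + (y-1)^2)
        def f(X):
            return np.column_stack([
                X[:, 0] ** 2 + X[:, 1] ** 2,
                (X[:, 0] - 1) ** 2 + (X[:, 1] - 1) ** 2,
            ])
        spec = ObjectiveSpec(
            evaluate=f, directions=("min", "min"),
            bounds=[(0.0, 1.0), (0.0, 1.0)],
        )
        ref = np.array([3.0, 3.0])
        hvs = []
        archive = []

        def cb(gen, genes, F, fronts):
            # crowding truncation may churn the population's own front, so the
            # elitism property is checked on the archive of all points seen
            archive.extend(F[fronts[0]])
            if gen % 50 == 0:
                A = np.vstack(archive)
                keep = ~np.array([
                    np.any(np.all(A <= A[i], axis=1) & np.any(A < A[i], axis=1))
                    for i in range(A.shape[0])
                ])
                hvs.append(hv_2d(A[keep], ref))

        evolve(spec, GAConfig(population=20, generations=300, seed=7), callback=cb)
        assert len(hvs) == 6
        assert all(b >= a - 1e-12 for a, b in zip(hvs, hvs[1:]))
        # and the population front itself should sit near the archive optimum
        assert hvs[-1] > 8.0

    def test_per_objective_best_never_worsens(self):
        spec, _ = self.constructed_spec()
        res = evolve(spec, GAConfig(population=20, generations=100, seed=3))
        log = res.log
        assert np.all(np.diff(log["best_0"]) >= -1e-12)   # maximized
        assert np.all(np.diff(log["best_1"]) >= -1e-12)   # maximized
        assert np.all(np.diff(log["best_2"]) <= 1e-12)    # minimized

    def test_deterministic_for_fixed_seed(self):
        spec, _ = self.constructed_spec()
        cfg = GAConfig(population=16, generations=40, seed=9)
        r1, r2 = evolve(spec, cfg), evolve(spec, cfg)
        g1 = np.vstack([i.genes for i in r1.population])
        g2 = np.vstack([i.genes for i in r2.population])
        assert np.array_equal(g1, g2)

    def test_non_finite_evaluator_is_reported(self):
        spec = ObjectiveSpec(
            evaluate=lambda X: np.full((X.shape[0], 2), np.nan),
            directions=("min", "min"), bounds=[(0.0, 1.0)],
        )
        with pytest.raises(EvaluationError, match="non-finite"):
            evolve(spec, GAConfig(population=4, generations=1, seed=0))


class TestScaleObjectives:
    def test_endpoints_map_to_unit_interval(self, wallflower):
        lo = [wallflower.output_range(n)[0] for n in wallflower.output_names]
        hi = [wallflower.output_range(n)[1] for n in wallflower.output_names]
        assert np.allclose(scale_objectives(np.array([hi]), wallflower), 1.0)
        assert np.allclose(scale_objectives(np.array([lo]), wallflower), 0.0)

    def test_observed_midpoint(self, wallflower):
        got = scale_objectives(np.array([[3.25, 0.0, 0.0]]), wallflower)[0, 0]
        assert got == pytest.approx(0.5)   # SN range is [0, 6.5]

    def test_extrapolation_beyond_one_is_allowed(self, wallflower):
        got = scale_objectives(np.array([[7.12, 0.0, 0.0]]), wallflower)[0, 0]
        assert got == pytest.approx(7.12 / 6.5)
        assert got > 1.0

    def test_degenerate_range_rejected(self, wallflower):
        recs = [
            pgropt.TreatmentRecord(ba=float(i), kin=0, naa=0, ga3=0,
                                   sn=1.0, sl=float(i), cw=0.1)
            for i in range(3)
        ]
        t = pgropt.ExperimentTable(records=recs)
        with pytest.raises(DegenerateScaleError, match="SN"):
            scale_objectives(np.array([[1.0, 1.0, 0.1]]), t)


class TestIdealPointSelect:
    def make_ind(self, objs, genes=(1.0, 1.0, 0.05, 0.1)):
        return Individual(
            genes=np.asarray(genes, float), objectives=np.asarray(objs, float)
        )

    def test_fixture_ideal_point_in_original_units(self, wallflower):
        sol = ideal_point_select([self.make_ind([5, 3, 0.1])], wallflower)
        assert sol.ideal_point == (6.50, 3.99, 0.00)

    def test_coincident_member_selected_with_zero_distance(self, wallflower):
        front = [
            self.make_ind([5.0, 3.0, 0.10]),
            self.make_ind([6.50, 3.99, 0.00]),
        ]
        sol = ideal_point_select(front, wallflower)
        assert sol.individual is front[1]
        assert sol.distance == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_two_member_front(self, wallflower):
        # scaled deviations: a = (0.3, 0, 0); b = (0, 0.5, 0)
        a = self.make_ind([6.5 - 0.3 * 6.5, 3.99, 0.0])
        b = self.make_ind([6.5, 3.99 - 0.5 * 3.99, 0.0])
        sol = ideal_point_select([a, b], wallflower)
        assert sol.individual is a
        assert sol.distance == pytest.approx(0.3)

    def test_tie_breaks_toward_smaller_callus(self, wallflower):
        # equal distance: one trades SN deviation, the other CW deviation
        a = self.make_ind([6.5 - 0.2 * 6.5, 3.99, 0.0])
        b = self.make_ind([6.5, 3.99, 0.2 * 0.3])
        sol = ideal_point_select([a, b], wallflower)
        assert sol.individual is a   # same E; a has the smaller CW
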