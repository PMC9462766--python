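"""Real-coded NSGA-II over trained response surrogates, plus ideal-point selection.

The medium-design problem: find dose vectors (BA, Kin, NAA, GA3) inside the
observed factor box that maximize predicted shoot number and shoot length
while minimizing predicted callus weight.  The optimizer is the canonical
elitist NSGA-II: fast non-dominated sorting, crowding distance, binary
tournament selection, simulated binary crossover (SBX) and polynomial
mutation, with (mu + lambda) environmental selection.

A single recommended medium is picked from the final Pareto front as the
member closest (Euclidean distance on 0-1 scaled objectives) to the ideal
point assembled from the observed data: maximum observed SN and SL, minimum
observed CW.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data import ExperimentTable
from .exceptions import DegenerateScaleError, EvaluationError

__all__ = [
    "ObjectiveSpec",
    "GAConfig",
    "Individual",
    "IdealPointSolution",
    "EvolutionResult",
    "dominates",
    "fast_nondominated_sort",
    "crowding_distance",
    "evolve",
    "scale_objectives",
    "ideal_point_select",
    "optimize_media",
]

#: growth responses and their optimization directions
DEFAULT_DIRECTIONS = ("max", "max", "min")


@dataclass
class ObjectiveSpec:
    """Objectives, directions and the box the optimizer searches in."""

    evaluate: Callable[[np.ndarray], np.ndarray]   # (N, n_genes) -> (N, n_obj)
    directions: tuple[str, ...]
    bounds: list[tuple[float, float]]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"bounds require lower < upper, got ({lo}, {hi})")
        for d in self.directions:
            if d not in ("min", "max"):
                raise ValueError(f"direction must be 'min' or 'max', got {d!r}")

    @property
    def signs(self) -> np.ndarray:
        """+1 for minimized objectives, -1 for maximized (minimization-native)."""
        return np.array([1.0 if d == "min" else -1.0 for d in self.directions])

    @classmethod
    def from_models(
        cls,
        models: dict,
        table: ExperimentTable,
        bounds: Sequence[tuple[float, float]] | None = None,
    ) -> "ObjectiveSpec":
        """Surrogate-backed spec: maximize SN and SL, minimize CW."""
        names = tuple(table.output_names)
        mods = [models[n] for n in names]

        def _eval(X: np.ndarray) -> np.ndarray:
            return np.column_stack([m.predict(X) for m in mods])

        return cls(
            evaluate=_eval,
            directions=DEFAULT_DIRECTIONS,
            bounds=list(bounds) if bounds is not None else table.input_bounds(),
            names=names,
        )


@dataclass
class GAConfig:
    """NSGA-II settings; defaults follow the study protocol (50 x 800, 0.8/0.01)."""

    population: int = 50
    generations: int = 800
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    eta_c: float = 15.0
    eta_m: float = 20.0
    seed: int = 0
    mutation_mode: str = "per-gene"    # or "per-individual"

    def __post_init__(self) -> None:
        if self.population < 4 or self.population % 2:
            raise ValueError("population must be even and >= 4")
        for r in (self.crossover_rate, self.mutation_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.mutation_mode not in ("per-gene", "per-individual"):
            raise ValueError(f"unknown mutation_mode {self.mutation_mode!r}")


@dataclass
class Individual:
    """One candidate medium with its predicted responses and NSGA-II bookkeeping."""

    genes: np.ndarray
    objectives: np.ndarray
    rank: int = 0
    crowding: float = 0.0


@dataclass
class IdealPointSolution:
    """The recommended medium: front member nearest the ideal point."""

    individual: Individual
    distance: float                    # E, on 0-1 scaled objectives
    ideal_point: tuple[float, ...]     # original units (max SN, max SL, min CW)


@dataclass
class EvolutionResult:
    population: list[Individual]
    front: list[Individual]            # rank-0 members of the final population
    log: pd.DataFrame                  # per-generation progress


# ---------------------------------------------------------------------------
# dominance machinery

def dominates(a: np.ndarray, b: np.ndarray, spec: ObjectiveSpec) -> bool:
    """True iff a is no worse than b everywhere and strictly better somewhere."""
    fa = np.asarray(a, float) * spec.signs
    fb = np.asarray(b, float) * spec.signs
    return bool(np.all(fa <= fb) and np.any(fa < fb))


def fast_nondominated_sort(
    F: np.ndarray, spec: ObjectiveSpec
) -> tuple[list[np.ndarray], np.ndarray]:
    """Deb's fast non-dominated sort.

    ``F`` is the (N, n_obj) objective matrix on the natural scale; returns the
    ordered fronts (index arrays) and a rank per individual (0 = first front).
    """
    F = np.atleast_2d(np.asarray(F, float)) * spec.signs
    n = F.shape[0]
    if n == 0:
        raise ValueError("population is empty")
    # pairwise dominance: dom[i, j] True if i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    fronts: list[np.ndarray] = []
    current = np.nonzero(n_dominators == 0)[0]
    r = 0
    remaining = n
    while current.size:
        ranks[current] = r
        fronts.append(current)
        remaining -= current.size
        n_dominators = n_dominators - dom[current].sum(axis=0)
        n_dominators[ranks >= 0] = -1
        current = np.nonzero(n_dominators == 0)[0]
        r += 1
    assert remaining == 0
    return fronts, ranks


def crowding_distance(F: np.ndarray, spec: ObjectiveSpec) -> np.ndarray:
    """Crowding distance of one front (natural-scale objectives).

    Boundary members of each objective sort get infinity; interior members
    accumulate normalized neighbor gaps.  Fronts of size <= 2 are all infinite.
    """
    F = np.atleast_2d(np.asarray(F, float)) * spec.signs
    n, k = F.shape
    if n == 0:
        raise ValueError("front is empty")
    if n <= 2:
        return np.full(n, np.inf)
    d = np.zeros(n)
    for j in range(k):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


# ---------------------------------------------------------------------------
# variation operators (bounded SBX + polynomial mutation)

def _sbx_pair(
    p1: np.ndarray, p2: np.ndarray, lo: np.ndarray, hi: np.ndarray,
    eta: float, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    c1, c2 = p1.copy(), p2.copy()
    for i in range(p1.size):
        if rng.random() > 0.5 or abs(p1[i] - p2[i]) < 1e-14:
            continue
        y1, y2 = sorted((p1[i], p2[i]))
        u = rng.random()
        for child, y_near in ((0, y1), (1, y2)):
            if child == 0:
                beta = 1.0 + 2.0 * (y1 - lo[i]) / (y2 - y1)
            else:
                beta = 1.0 + 2.0 * (hi[i] - y2) / (y2 - y1)
            a = 2.0 - beta ** -(eta + 1.0)
            if u <= 1.0 / a:
                bq = (u * a) ** (1.0 / (eta + 1.0))
            else:
                bq = (1.0 / (2.0 - u * a)) ** (1.0 / (eta + 1.0))
            if child == 0:
                val = 0.5 * ((y1 + y2) - bq * (y2 - y1))
                c1[i] = min(max(val, lo[i]), hi[i])
            else:
                val = 0.5 * ((y1 + y2) + bq * (y2 - y1))
                c2[i] = min(max(val, lo[i]), hi[i])
        if rng.random() < 0.5:
            c1[i], c2[i] = c2[i], c1[i]
    return c1, c2


def _poly_mutate(
    x: np.ndarray, lo: np.ndarray, hi: np.ndarray, rate: float, eta: float,
    rng: np.random.Generator, mode: str,
) -> np.ndarray:
    y = x.copy()
    if mode == "per-individual":
        if rng.random() >= rate:
            return y
        which = [int(rng.integers(x.size))]
    else:
        which = [i for i in range(x.size) if rng.random() < rate]
    for i in which:
        span = hi[i] - lo[i]
        u = rng.random()
        d1 = (y[i] - lo[i]) / span
        d2 = (hi[i] - y[i]) / span
        if u < 0.5:
            dq = (2.0 * u + (1.0 - 2.0 * u) * (1.0 - d1) ** (eta + 1.0)) ** (
                1.0 / (eta + 1.0)
            ) - 1.0
        else:
            dq = 1.0 - (
                2.0 * (1.0 - u) + 2.0 * (u - 0.5) * (1.0 - d2) ** (eta + 1.0)
            ) ** (1.0 / (eta + 1.0))
        y[i] = min(max(y[i] + dq * span, lo[i]), hi[i])
    return y


# ---------------------------------------------------------------------------
# the evolutionary loop

def _evaluate_population(spec: ObjectiveSpec, genes: np.ndarray) -> np.ndarray:
    F = np.atleast_2d(np.asarray(spec.evaluate(genes), float))
    bad = ~np.all(np.isfinite(F), axis=1)
    if bad.any():
        i = int(np.nonzero(bad)[0][0])
        raise EvaluationError(
            f"surrogate returned non-finite objectives for genes {genes[i].tolist()}"
        )
    return F


def _rank_and_crowd(
    F: np.ndarray, spec: ObjectiveSpec
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    fronts, ranks = fast_nondominated_sort(F, spec)
    crowd = np.zeros(F.shape[0])
    for fr in fronts:
        crowd[fr] = crowding_distance(F[fr], spec)
    return fronts, ranks, crowd


def _tournament(
    ranks: np.ndarray, crowd: np.ndarray, rng: np.random.Generator
) -> int:
    i, j = rng.integers(ranks.size, size=2)
    if ranks[i] < ranks[j]:
        return int(i)
    if ranks[j] < ranks[i]:
        return int(j)
    if crowd[i] > crowd[j]:
        return int(i)
    if crowd[j] > crowd[i]:
        return int(j)
    return int(i)


def evolve(
    spec: ObjectiveSpec, config: GAConfig, callback: Callable | None = None
) -> EvolutionResult:
    """Run the (mu + lambda) NSGA-II loop; deterministic for a fixed seed.

    ``callback(gen, genes, objectives, fronts)`` is invoked after each
    generation's environmental selection (used for diagnostics and tests).
    """
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in spec.bounds])
    hi = np.array([b[1] for b in spec.bounds])
    n_genes = lo.size
    N = config.population

    genes = rng.uniform(lo, hi, size=(N, n_genes))
    F = _evaluate_population(spec, genes)
    fronts, ranks, crowd = _rank_and_crowd(F, spec)

    signs = spec.signs
    log_rows = []
    for gen in range(1, config.generations + 1):
        # offspring via tournament + SBX + polynomial mutation
        children = np.empty_like(genes)
        for p in range(0, N, 2):
            i = _tournament(ranks, crowd, rng)
            j = _tournament(ranks, crowd, rng)
            if rng.random() < config.crossover_rate:
                c1, c2 = _sbx_pair(genes[i], genes[j], lo, hi, config.eta_c, rng)
            else:
                c1, c2 = genes[i].copy(), genes[j].copy()
            children[p] = _poly_mutate(
                c1, lo, hi, config.mutation_rate, config.eta_m, rng,
                config.mutation_mode,
            )
            children[p + 1] = _poly_mutate(
                c2, lo, hi, config.mutation_rate, config.eta_m, rng,
                config.mutation_mode,
            )
        np.clip(children, lo, hi, out=children)
        F_child = _evaluate_population(spec, children)

        # elitist environmental selection on parents + offspring
        all_genes = np.vstack([genes, children])
        all_F = np.vstack([F, F_child])
        all_fronts, _, all_crowd = _rank_and_crowd(all_F, spec)
        chosen: list[int] = []
        for fr in all_fronts:
            if len(chosen) + fr.size <= N:
                chosen.extend(int(i) for i in fr)
            else:
                room = N - len(chosen)
                # descending crowding, stable input order on ties
                order = np.argsort(-all_crowd[fr], kind="stable")
                chosen.extend(int(i) for i in fr[order[:room]])
                break
        idx = np.array(chosen)
        genes, F = all_genes[idx], all_F[idx]
        fronts, ranks, crowd = _rank_and_crowd(F, spec)

        Fm = F * signs
        best = Fm.min(axis=0) * signs
        log_rows.append(
            {"generation": gen, "front0_size": int(fronts[0].size),
             **{f"best_{k}": float(best[k]) for k in range(F.shape[1])}}
        )
        if callback is not None:
            callback(gen, genes, F, fronts)

    population = [
        Individual(genes=genes[i].copy(), objectives=F[i].copy(),
                   rank=int(ranks[i]), crowding=float(crowd[i]))
        for i in range(N)
    ]
    front = [population[int(i)] for i in fronts[0]]
    return EvolutionResult(
        population=population, front=front, log=pd.DataFrame(log_rows)
    )


# ---------------------------------------------------------------------------
# ideal-point selection

def scale_objectives(values: np.ndarray, table: ExperimentTable) -> np.ndarray:
    """Scale objective triples by the observed per-output min/max to [0, 1].

    Surrogate predictions outside the observed range are NOT clipped, so
    scaled values may leave [0, 1] when the optimizer extrapolates.
    """
    V = np.atleast_2d(np.asarray(values, float))
    lows, spans = [], []
    for name in table.output_names:
        lo, hi = table.output_range(name)
        if hi <= lo:
            raise DegenerateScaleError(
                f"observed range of {name!r} is degenerate ({lo}, {hi})"
            )
        lows.append(lo)
        spans.append(hi - lo)
    return (V - np.array(lows)) / np.array(spans)


def ideal_point_select(
    front: Sequence[Individual], table: ExperimentTable
) -> IdealPointSolution:
    """Pick the front member minimizing distance E to the observed ideal point.

    The ideal point takes the best observed value of each objective — maximum
    SN, maximum SL, minimum CW — and E is the Euclidean distance on 0-1
    scaled objectives.  Ties break toward smaller predicted CW, then
    lexicographically smaller genes.
    """
    if not front:
        raise ValueError("front is empty")
    sn_lo, sn_hi = table.output_range("SN")
    sl_lo, sl_hi = table.output_range("SL")
    cw_lo, cw_hi = table.output_range("CW")
    ideal_orig = (sn_hi, sl_hi, cw_lo)
    ideal_scaled = scale_objectives(np.array([ideal_orig]), table)[0]
    F = np.vstack([ind.objectives for ind in front])
    S = scale_objectives(F, table)
    E = np.sqrt(((S - ideal_scaled) ** 2).sum(axis=1))
    keys = [
        (E[i], F[i, 2], tuple(front[i].genes)) for i in range(len(front))
    ]
    best = min(range(len(front)), key=lambda i: keys[i])
    return IdealPointSolution(
        individual=front[best], distance=float(E[best]), ideal_point=ideal_orig
    )


def front_frame(front: Sequence[Individual], table: ExperimentTable) -> pd.DataFrame:
    rows = []
    for ind in front:
        row = {n: g for n, g in zip(table.input_names, ind.genes)}
        row.update(
            {"pred_" + n: o for n, o in zip(table.output_names, ind.objectives)}
        )
        row["rank"] = ind.rank
        row["crowding"] = ind.crowding
        rows.append(row)
    return pd.DataFrame(rows)


def optimize_media(
    models: dict,
    table: ExperimentTable,
    config: GAConfig,
    bounds: Sequence[tuple[float, float]] | None = None,
) -> tuple[IdealPointSolution, pd.DataFrame, EvolutionResult]:
    """End-to-end medium design: evolve on the surrogates, then pick the
    ideal-point member of the final front.  Returns the recommendation, the
    front as a table (doses + predictions + rank + crowding), and the raw
    evolution result."""
    spec = ObjectiveSpec.from_models(models, table, bounds=bounds)
    result = evolve(spec, config)
    solution = ideal_point_select(result.front, table)
    return solution, front_frame(result.front, table), result
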