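"""Synthetic factorial dose-response datasets with known ground truth.

Emulates the structure of the wallflower experiment: a full factorial over
the four PGR dose grids, smooth unimodal response surfaces with a
cytokinin-cytokinin interaction, and replicate noise at the magnitude of
the real table's standard errors.  Because the generating surfaces are
known, optimum recovery and importance-ranking recovery can be scored
exactly — something the real dataset can never offer.

Surface family (per output, doses normalized to [0, 1] by their grid maxima):

    u(z) = b . z + sum_i q_i z_i^2 + sum_(i<j) c_ij z_i z_j - offset
    y(z) = clip_0( ceiling * tanh(u) )

The saturating tanh link caps responses the way shoot counts plateau, and
negative quadratic / interaction terms produce the decline at high cytokinin
doses seen in real media experiments (an interior optimum).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data import ExperimentTable, TreatmentRecord
from .nsga2 import IdealPointSolution

__all__ = [
    "ResponseSurface",
    "SurfaceSpec",
    "GroundTruth",
    "RecoveryScore",
    "generate",
    "replicate_expand",
    "score_recovery",
]

#: the experiment's dose grids, mg/L
DEFAULT_LEVELS = (
    (0.0, 0.5, 1.0, 2.0),   # BA
    (0.0, 0.5, 1.0, 2.0),   # Kin
    (0.0, 0.1),             # NAA
    (0.0, 0.2),             # GA3
)


@dataclass
class ResponseSurface:
    """Parameters of one saturating quadratic-with-interactions surface."""

    linear: tuple[float, ...]
    quad: tuple[float, ...]
    interactions: dict[tuple[int, int], float]
    ceiling: float
    offset: float = 0.0
    noise_sd: float = 0.0        # per-observation (single replicate) SD

    def latent(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, float))
        u = Z @ np.asarray(self.linear) + (Z ** 2) @ np.asarray(self.quad)
        for (i, j), c in self.interactions.items():
            u = u + c * Z[:, i] * Z[:, j]
        return u - self.offset

    def mean(self, Z: np.ndarray) -> np.ndarray:
        return np.clip(self.ceiling * np.tanh(self.latent(Z)), 0.0, None)


@dataclass
class SurfaceSpec:
    """Full description of a synthetic experiment.

    Defaults are calibrated to the wallflower table: the same factor grids,
    response ceilings giving SN ~ 0-6.5, SL ~ 0-4, CW ~ 0-0.3, and noise SDs
    equal to the median observed SE times sqrt(4 replicates).
    """

    levels: tuple[tuple[float, ...], ...] = DEFAULT_LEVELS
    surfaces: dict[str, ResponseSurface] = field(default_factory=dict)
    n_reps: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.surfaces:
            self.surfaces = _default_surfaces()
        if len(self.levels) != 4:
            raise ValueError("need four dose grids")
        for lv in self.levels:
            if len(lv) < 2 or sorted(lv) != list(lv) or lv[0] < 0:
                raise ValueError(f"bad level grid {lv}")

    @property
    def scale(self) -> np.ndarray:
        return np.array([lv[-1] for lv in self.levels])

    def bounds(self) -> list[tuple[float, float]]:
        return [(lv[0], lv[-1]) for lv in self.levels]

    def true_response(self, X: np.ndarray, output: str) -> np.ndarray:
        """Noiseless surface value at raw doses X (N, 4), original units."""
        Z = np.atleast_2d(np.asarray(X, float)) / self.scale
        return self.surfaces[output].mean(Z)


def _default_surfaces() -> dict[str, ResponseSurface]:
    # Linear weights encode the planted importance order per output
    # (SN, CW: BA > Kin > NAA > GA3; SL: BA > Kin > GA3 > NAA).  Quadratic
    # terms are strong enough that the multi-objective optimum is sharply
    # identified in every dose — a flat optimum would make recovery scoring
    # meaningless no matter how good the optimizer is.
    return {
        "SN": ResponseSurface(
            linear=(1.5, 1.3, 0.25, 0.2), quad=(-1.2, -0.9, 0.0, 0.0),
            interactions={(0, 1): -0.3}, ceiling=7.0, noise_sd=0.33,
        ),
        "SL": ResponseSurface(
            linear=(1.4, 1.2, 0.18, 0.28), quad=(-0.8, -0.6, 0.0, 0.0),
            interactions={(0, 1): -0.25}, ceiling=4.0, noise_sd=0.012,
        ),
        "CW": ResponseSurface(
            linear=(0.75, 0.6, 0.06, 0.02), quad=(0.0, 0.0, 0.0, 0.0),
            interactions={}, ceiling=0.36, offset=0.45, noise_sd=0.005,
        ),
    }


@dataclass
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    spec: SurfaceSpec
    optimum_genes: np.ndarray          # ideal-point optimum of the true surfaces
    optimum_responses: tuple[float, float, float]
    optimum_distance: float            # E at the optimum, scaled objectives
    importance_order: dict[str, list[str]]   # per output, most important first
    true_means: np.ndarray             # (64, 3) noiseless cell means


def _true_ideal_point_optimum(
    spec: SurfaceSpec, cell_means: np.ndarray, n_grid: tuple[int, ...] = (41, 41, 21, 21)
) -> tuple[np.ndarray, tuple[float, float, float], float]:
    """Dense grid search for the dose vector whose TRUE responses minimize the
    scaled ideal-point distance; the ground-truth analog of the pipeline's
    selection step (scaling and ideal point from the noiseless cell means)."""
    lo = np.array([lv[0] for lv in spec.levels])
    hi = np.array([lv[-1] for lv in spec.levels])
    axes = [np.linspace(lo[i], hi[i], n_grid[i]) for i in range(4)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
    F = np.column_stack([spec.true_response(G, o) for o in ("SN", "SL", "CW")])
    mins, maxs = cell_means.min(axis=0), cell_means.max(axis=0)
    span = np.where(maxs > mins, maxs - mins, 1.0)
    S = (F - mins) / span
    ideal = (np.array([maxs[0], maxs[1], mins[2]]) - mins) / span
    E = np.sqrt(((S - ideal) ** 2).sum(axis=1))
    k = int(np.argmin(E))
    return G[k], tuple(float(v) for v in F[k]), float(E[k])


def generate(spec: SurfaceSpec) -> tuple[ExperimentTable, GroundTruth]:
    """Full-factorial synthetic table plus its ground truth.

    Each cell's observed value is the surface mean plus Gaussian noise with
    SD = noise_sd / sqrt(n_reps) (the SE of a replicate mean), clipped at
    zero.  Deterministic for a fixed spec seed.
    """
    rng = np.random.default_rng(spec.seed)
    cells = np.array(list(itertools.product(*spec.levels)), dtype=float)
    outputs = ("SN", "SL", "CW")
    true_means = np.column_stack([spec.true_response(cells, o) for o in outputs])
    records = []
    for row in range(cells.shape[0]):
        obs, ses = [], []
        for j, o in enumerate(outputs):
            se = spec.surfaces[o].noise_sd / np.sqrt(spec.n_reps)
            val = true_means[row, j] + (rng.normal(0.0, se) if se > 0 else 0.0)
            obs.append(max(val, 0.0))
            ses.append(se)
        records.append(
            TreatmentRecord(
                ba=cells[row, 0], kin=cells[row, 1],
                naa=cells[row, 2], ga3=cells[row, 3],
                sn=obs[0], sl=obs[1], cw=obs[2],
                se_sn=ses[0], se_sl=ses[1], se_cw=ses[2],
                n_reps=spec.n_reps,
            )
        )
    table = ExperimentTable(records=records)
    opt_genes, opt_resp, opt_E = _true_ideal_point_optimum(spec, true_means)
    # planted importance = main-effect strength of the TRUE surface on the
    # factorial grid (SD of per-level conditional means); with curvature in
    # play this, not the raw linear coefficient, is what ablation measures
    importance = {}
    names = ("BA", "Kin", "NAA", "GA3")
    for j, o in enumerate(outputs):
        effects = []
        for i in range(4):
            level_means = [
                true_means[np.isclose(cells[:, i], lv), j].mean()
                for lv in spec.levels[i]
            ]
            effects.append(float(np.std(level_means)))
        importance[o] = [
            name for _, name in sorted(zip(effects, names), key=lambda t: -t[0])
        ]
    truth = GroundTruth(
        spec=spec, optimum_genes=opt_genes, optimum_responses=opt_resp,
        optimum_distance=opt_E, importance_order=importance,
        true_means=true_means,
    )
    return table, truth


def replicate_expand(table: ExperimentTable, seed: int = 0) -> ExperimentTable:
    """Emit pseudo-replicate rows from cell means and their SEs.

    Each cell yields n_reps draws of mean + Normal(0, SE * sqrt(n_reps))
    (the per-observation SD implied by the SE of the mean), clipped at zero.
    """
    rng = np.random.default_rng(seed)
    records = []
    for r in table.records:
        if r.se_sn is None or r.se_sl is None or r.se_cw is None or r.n_reps is None:
            raise ValueError("replicate expansion needs SE and replicate counts")
        sds = np.array([r.se_sn, r.se_sl, r.se_cw]) * np.sqrt(r.n_reps)
        for _ in range(r.n_reps):
            draw = np.array(r.outputs) + np.where(
                sds > 0, rng.normal(0.0, np.where(sds > 0, sds, 1.0)), 0.0
            )
            draw = np.clip(draw, 0.0, None)
            records.append(
                TreatmentRecord(
                    ba=r.ba, kin=r.kin, naa=r.naa, ga3=r.ga3,
                    sn=float(draw[0]), sl=float(draw[1]), cw=float(draw[2]),
                    n_reps=1,
                )
            )
    return ExperimentTable(records=records, allow_duplicates=True)


@dataclass
class RecoveryScore:
    """How close a recommendation landed to the planted optimum."""

    per_gene_error: np.ndarray      # |gene - optimum| / bound width, per dose
    aggregate: float                # mean of per-gene errors
    response_gap: np.ndarray        # predicted minus true response at the genes


def score_recovery(
    recommendation: IdealPointSolution, spec: SurfaceSpec
) -> RecoveryScore:
    """Normalized gene distance to the planted optimum plus the prediction gap."""
    _, truth = generate(spec)
    genes = np.asarray(recommendation.individual.genes, float)
    lo = np.array([b[0] for b in spec.bounds()])
    hi = np.array([b[1] for b in spec.bounds()])
    per_gene = np.abs(genes - truth.optimum_genes) / (hi - lo)
    true_at = np.array(
        [spec.true_response(genes[None, :], o)[0] for o in ("SN", "SL", "CW")]
    )
    gap = np.asarray(recommendation.individual.objectives, float) - true_at
    return RecoveryScore(
        per_gene_error=per_gene, aggregate=float(per_gene.mean()), response_gap=gap
    )
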