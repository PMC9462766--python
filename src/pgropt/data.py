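"""Factorial treatment tables: I/O, [-1, 1] scaling, splitting, PCA outlier screen.

The experimental unit is one cell of a designed factorial: four plant-growth-
regulator doses (BA, Kin, NAA, GA3, all mg/L) and three measured responses
(shoot number SN, shoot length SL in cm, callus weight CW in g), optionally
with per-cell standard errors and replicate counts.  The packaged wallflower
dataset is a full 4 x 4 x 2 x 2 factorial of treatment means (64 cells).
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .exceptions import (
    ConfigError,
    DegenerateScaleError,
    InvalidSplitError,
    TableParseError,
)

logger = logging.getLogger(__name__)

INPUT_NAMES = ("BA", "Kin", "NAA", "GA3")
OUTPUT_NAMES = ("SN", "SL", "CW")
SE_NAMES = ("SE_SN", "SE_SL", "SE_CW")

#: regex for "mean ± SE" cells (tolerates stray internal spaces in the SE part)
_PM_RE = re.compile(r"^\s*([-\d.eE]+)\s*(?:±|\+/-)\s*([\d.eE ]+)\s*$")


@dataclass
class TreatmentRecord:
    """One factorial cell: four PGR doses and three mean responses.

    Doses are mg/L; ``sn`` is shoots per explant, ``sl`` is cm, ``cw`` is g.
    Standard errors and the replicate count are optional metadata carried
    through from the source table.
    """

    ba: float
    kin: float
    naa: float
    ga3: float
    sn: float
    sl: float
    cw: float
    se_sn: float | None = None
    se_sl: float | None = None
    se_cw: float | None = None
    n_reps: int | None = None

    def __post_init__(self) -> None:
        for name in ("ba", "kin", "naa", "ga3", "sn", "sl", "cw"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("se_sn", "se_sl", "se_cw"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @property
    def inputs(self) -> tuple[float, float, float, float]:
        return (self.ba, self.kin, self.naa, self.ga3)

    @property
    def outputs(self) -> tuple[float, float, float]:
        return (self.sn, self.sl, self.cw)


@dataclass
class ExperimentTable:
    """Ordered collection of treatment records with fixed column labels."""

    records: list[TreatmentRecord]
    input_names: tuple[str, ...] = INPUT_NAMES
    output_names: tuple[str, ...] = OUTPUT_NAMES
    #: replicate-level tables repeat dose combinations; mean-level tables do not
    allow_duplicates: bool = False

    def __post_init__(self) -> None:
        if self.allow_duplicates:
            return
        seen = set()
        for r in self.records:
            if r.inputs in seen:
                raise ValueError(f"duplicate input combination {r.inputs}")
            seen.add(r.inputs)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def X(self) -> np.ndarray:
        """(N, 4) dose matrix in table order."""
        return np.array([r.inputs for r in self.records], dtype=float)

    @property
    def Y(self) -> np.ndarray:
        """(N, 3) response matrix in table order."""
        return np.array([r.outputs for r in self.records], dtype=float)

    def output_column(self, name: str) -> np.ndarray:
        return self.Y[:, self.output_names.index(name)]

    def output_range(self, name: str) -> tuple[float, float]:
        col = self.output_column(name)
        return float(col.min()), float(col.max())

    def input_bounds(self) -> list[tuple[float, float]]:
        """Observed (min, max) per dose column — the optimizer's default box."""
        X = self.X
        return [(float(X[:, i].min()), float(X[:, i].max())) for i in range(X.shape[1])]

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {n: [] for n in self.input_names + self.output_names}
        have_se = any(r.se_sn is not None for r in self.records)
        have_reps = any(r.n_reps is not None for r in self.records)
        if have_se:
            cols.update({n: [] for n in SE_NAMES})
        if have_reps:
            cols["NREP"] = []
        for r in self.records:
            for n, v in zip(self.input_names, r.inputs):
                cols[n].append(v)
            for n, v in zip(self.output_names, r.outputs):
                cols[n].append(v)
            if have_se:
                for n, v in zip(SE_NAMES, (r.se_sn, r.se_sl, r.se_cw)):
                    cols[n].append(np.nan if v is None else v)
            if have_reps:
                cols["NREP"].append(np.nan if r.n_reps is None else r.n_reps)
        return pd.DataFrame(cols)

    def save(self, path: str | Path) -> None:
        """Write CSV preserving full float precision (round-trips exactly)."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def _parse_cell(value, column: str, row: int) -> tuple[float, float | None]:
    """Parse a numeric or 'mean ± SE' cell; returns (mean, se_or_None)."""
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value), None
    text = str(value).strip()
    m = _PM_RE.match(text)
    if m:
        try:
            return float(m.group(1)), float(m.group(2).replace(" ", ""))
        except ValueError:
            raise TableParseError(
                f"row {row}: cannot parse cell {value!r} in column {column!r}"
            ) from None
    try:
        return float(text), None
    except ValueError:
        raise TableParseError(
            f"row {row}: non-numeric cell {value!r} in column {column!r}"
        ) from None


def load_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> ExperimentTable:
    """Load a factorial treatment table from CSV.

    The file must resolve the four dose columns and three response columns;
    ``dialect`` maps canonical names (``"BA"``, ..., ``"CW"``, ``"SE_SN"``,
    ``"NREP"``) to the file's actual headers.  Response cells may be plain
    numbers or ``"mean ± SE"`` strings; the SE lands in the matching SE field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"input table not found: {path}")
    try:
        df = pd.read_csv(path, dtype=object)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TableParseError(f"cannot read {path}: {exc}") from exc
    if df.empty and df.columns.empty:
        raise TableParseError(f"{path}: empty file, no table")

    rename = dict(dialect) if dialect else {}
    canon_cols: dict[str, str] = {}
    lower_map = {c.lower(): c for c in df.columns}
    for canon in INPUT_NAMES + OUTPUT_NAMES + SE_NAMES + ("NREP",):
        actual = rename.get(canon, canon)
        if actual in df.columns:
            canon_cols[canon] = actual
        elif actual.lower() in lower_map:
            canon_cols[canon] = lower_map[actual.lower()]
    missing = [c for c in INPUT_NAMES + OUTPUT_NAMES if c not in canon_cols]
    if missing:
        raise ConfigError(f"{path}: missing required column(s) {missing}")
    if df.empty:
        raise TableParseError(f"{path}: table has a header but no rows")

    records: list[TreatmentRecord] = []
    for i, row in df.iterrows():
        vals: dict[str, float] = {}
        ses: dict[str, float | None] = {}
        for canon in INPUT_NAMES:
            v, _ = _parse_cell(row[canon_cols[canon]], canon, i)
            vals[canon] = v
        for canon in OUTPUT_NAMES:
            v, se = _parse_cell(row[canon_cols[canon]], canon, i)
            vals[canon] = v
            ses["SE_" + canon] = se
        for canon in SE_NAMES:
            if canon in canon_cols and not pd.isna(row[canon_cols[canon]]):
                v, _ = _parse_cell(row[canon_cols[canon]], canon, i)
                ses[canon] = v
        nrep = None
        if "NREP" in canon_cols and not pd.isna(row[canon_cols["NREP"]]):
            nrep = int(float(row[canon_cols["NREP"]]))
        try:
            records.append(
                TreatmentRecord(
                    ba=vals["BA"], kin=vals["Kin"], naa=vals["NAA"], ga3=vals["GA3"],
                    sn=vals["SN"], sl=vals["SL"], cw=vals["CW"],
                    se_sn=ses.get("SE_SN"), se_sl=ses.get("SE_SL"),
                    se_cw=ses.get("SE_CW"), n_reps=nrep,
                )
            )
        except ValueError as exc:
            raise TableParseError(f"row {i}: {exc}") from exc
    return ExperimentTable(records=records)


def load_wallflower() -> ExperimentTable:
    """The packaged 64-cell wallflower factorial (treatment means ± SE)."""
    with resources.as_file(
        resources.files("pgropt").joinpath("data/wallflower_table1.csv")
    ) as p:
        return load_table(p)


@dataclass
class RangeScaler:
    """Per-column affine map of observed [min, max] onto [-1, 1].

    The same transform MATLAB calls ``mapminmax``: x' = 2(x-min)/(max-min) - 1.
    ``transform`` and ``inverse`` are exact inverses up to float rounding.
    """

    mins: np.ndarray
    maxs: np.ndarray
    columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.mins = np.asarray(self.mins, dtype=float)
        self.maxs = np.asarray(self.maxs, dtype=float)
        if np.any(self.maxs <= self.mins):
            bad = [
                self.columns[i] if self.columns else i
                for i in np.nonzero(self.maxs <= self.mins)[0]
            ]
            raise DegenerateScaleError(
                f"column(s) {bad} have zero range; cannot map to [-1, 1]"
            )

    @property
    def spans(self) -> np.ndarray:
        return self.maxs - self.mins

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return 2.0 * (X - self.mins) / self.spans - 1.0

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        Xs = np.asarray(Xs, dtype=float)
        return (Xs + 1.0) / 2.0 * self.spans + self.mins

    def to_dict(self) -> dict:
        return {
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "columns": list(self.columns),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RangeScaler":
        return cls(
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
            columns=tuple(d.get("columns", ())),
        )


def fit_scaler(table: ExperimentTable, columns: Sequence[str]) -> RangeScaler:
    """Fit a RangeScaler on the named input/output columns of ``table``."""
    df = table.to_frame()
    for c in columns:
        if c not in df.columns:
            raise ConfigError(f"unknown column {c!r}")
    sub = df[list(columns)].to_numpy(dtype=float)
    return RangeScaler(
        mins=sub.min(axis=0), maxs=sub.max(axis=0), columns=tuple(columns)
    )


@dataclass(frozen=True)
class SplitIndex:
    """Disjoint train/test index sets covering all records."""

    train: tuple[int, ...]
    test: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train) & set(self.test):
            raise ValueError("train and test indices overlap")


def split(table: ExperimentTable, fraction: float = 0.8, seed: int = 0) -> SplitIndex:
    """Random train/test split; the test partition gets ceil((1-fraction) * N).

    Deterministic for a fixed seed.  For the 64-cell wallflower table at the
    default fraction this gives 51 training and 13 testing cells.
    """
    n = len(table)
    if n == 0:
        raise InvalidSplitError("cannot split an empty table")
    if not 0.0 < fraction < 1.0:
        raise InvalidSplitError(f"fraction must be in (0, 1), got {fraction}")
    n_train = n - math.ceil((1.0 - fraction) * n)
    if n_train == 0 or n_train == n:
        raise InvalidSplitError(
            f"fraction {fraction} leaves an empty partition for {n} records"
        )
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndex(
        train=tuple(int(i) for i in perm[:n_train]),
        test=tuple(int(i) for i in perm[n_train:]),
        seed=seed,
    )


def pca_outlier_screen(
    table: ExperimentTable, alpha: float = 0.05, bonferroni: bool = True
) -> np.ndarray:
    """Flag multivariate outliers by Hotelling T² in PCA score space.

    Correlation-matrix PCA on the 7 numeric columns (doses + responses);
    scores on the components explaining >= 95% of variance are tested against
    the Hotelling T² critical value at family-wise significance ``alpha``
    (Bonferroni over the N records by default — a raw per-record level would
    flag ~alpha*N points of any clean sample by chance, defeating a screen).
    Screening only: flags are returned, records are never removed.
    Degenerate inputs (no variance) yield no flags and a logged warning.
    """
    n = len(table)
    if n < 3:
        raise ValueError("outlier screen needs at least 3 records")
    M = np.column_stack([table.X, table.Y])
    sd = M.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        logger.warning("all columns constant; outlier screen skipped")
        return np.zeros(n, dtype=bool)
    Z = (M[:, keep] - M[:, keep].mean(axis=0)) / sd[keep]
    pca = PCA()
    scores = pca.fit_transform(Z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, 0.95) + 1)
    lam = pca.explained_variance_[:k]
    pos = lam > 1e-12
    if not pos.any():
        logger.warning("degenerate covariance; outlier screen skipped")
        return np.zeros(n, dtype=bool)
    t2 = np.sum(scores[:, :k][:, pos] ** 2 / lam[pos], axis=1)
    k_eff = int(pos.sum())
    if n <= k_eff:
        logger.warning("too few records for %d components; screen skipped", k_eff)
        return np.zeros(n, dtype=bool)
    level = alpha / n if bonferroni else alpha
    crit = (
        k_eff * (n - 1) / (n - k_eff) * stats.f.ppf(1.0 - level, k_eff, n - k_eff)
    )
    return t2 > crit
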