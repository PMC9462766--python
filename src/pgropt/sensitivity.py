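"""Input-importance ranking by Variable Sensitivity Error / Ratio (VSE, VSR).

VSE asks how well a trained surrogate performs when one input is "not
available"; VSR divides that by the full-model error, so an inert input
scores exactly 1 and larger ratios mark more important inputs.  By default
"not available" is operationalized as mean-substitution: the column is
replaced by its training mean and the model is NOT retrained, which is fast
and deterministic.  A retraining policy (drop the column, refit) is
available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExperimentTable, SplitIndex
from .exceptions import UndefinedMetricError
from .mlp import MLPModel, TrainingConfig, train

__all__ = ["SensitivityReport", "variable_sensitivity_error", "vsr_table"]

POLICIES = ("mean-substitution", "retrain")


def _rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    r = np.asarray(y, float).ravel() - np.asarray(yhat, float).ravel()
    return float(np.sqrt(r @ r / r.size))


@dataclass
class SensitivityReport:
    """Per-(input, output) VSE/VSR with importance ranks (1 = most important)."""

    frame: pd.DataFrame             # columns: output, input, VSE, VSR, rank
    baseline: dict[str, float]      # full-model RMSE per output
    policy: str

    def __post_init__(self) -> None:
        for _, grp in self.frame.groupby("output"):
            ranks = sorted(grp["rank"])
            if ranks != list(range(1, len(grp) + 1)):
                raise ValueError("ranks are not a permutation of 1..n_inputs")
            ordered = grp.sort_values("rank")
            if not ordered["VSR"].is_monotonic_decreasing:
                raise ValueError("rank order does not match descending VSR")

    def rank_order(self, output: str) -> list[str]:
        grp = self.frame[self.frame["output"] == output]
        return list(grp.sort_values("rank")["input"])


def variable_sensitivity_error(
    model: MLPModel,
    X: np.ndarray,
    y: np.ndarray,
    which: int,
    policy: str = "mean-substitution",
    fill_value: float | None = None,
    train_data: tuple[np.ndarray, np.ndarray] | None = None,
    config: TrainingConfig | None = None,
) -> float:
    """Model RMSE (original units) with input column ``which`` ablated.

    Mean-substitution replaces the column with ``fill_value`` (default: its
    mean over ``X``, i.e. the training mean when X is the training set).
    The retrain policy refits a model without the column on ``train_data``
    and scores it on (X, y).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if not 0 <= which < X.shape[1]:
        raise IndexError(f"input index {which} out of range for {X.shape[1]} inputs")
    if policy == "mean-substitution":
        Xa = X.copy()
        Xa[:, which] = X[:, which].mean() if fill_value is None else fill_value
        return _rmse(y, model.predict(Xa))
    if policy == "retrain":
        if train_data is None or config is None:
            raise ValueError("retrain policy needs train_data and a config")
        Xt, yt = train_data
        keep = [i for i in range(X.shape[1]) if i != which]
        xs, ys_ = model.input_scaler, model.target_scaler
        Xts = xs.transform(np.atleast_2d(Xt))[:, keep]
        yts = ys_.transform(np.asarray(yt, float).reshape(-1, 1)).ravel()
        sub, _ = train(Xts, yts, config)
        yhat_s = sub.predict_scaled(xs.transform(X)[:, keep])
        yhat = ys_.inverse(yhat_s[:, None]).ravel()
        return _rmse(y, yhat)
    raise ValueError(f"unknown ablation policy {policy!r}")


def vsr_table(
    models: dict[str, MLPModel],
    table: ExperimentTable,
    policy: str = "mean-substitution",
    split_index: SplitIndex | None = None,
    config: TrainingConfig | None = None,
) -> SensitivityReport:
    """VSE/VSR of every input for every response model, with ranks.

    Errors are computed on the full table (train + test) in original units.
    When a split is supplied, mean-substitution uses training-set column
    means; otherwise full-table means.  A zero baseline RMSE (perfect model)
    makes the ratio undefined and raises.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown ablation policy {policy!r}")
    X = table.X
    fill_rows = list(split_index.train) if split_index is not None else None
    rows = []
    baseline: dict[str, float] = {}
    for out in table.output_names:
        model = models[out]
        y = table.output_column(out)
        base = _rmse(y, model.predict(X))
        if base == 0.0:
            raise UndefinedMetricError(
                f"baseline RMSE for {out!r} is zero; VSR undefined"
            )
        baseline[out] = base
        for i, inp in enumerate(table.input_names):
            kwargs = {}
            if policy == "mean-substitution" and fill_rows is not None:
                kwargs["fill_value"] = float(X[fill_rows, i].mean())
            if policy == "retrain":
                tr = fill_rows if fill_rows is not None else list(range(len(table)))
                kwargs["train_data"] = (X[tr], y[tr])
                kwargs["config"] = config or TrainingConfig(
                    n_hidden=model.n_hidden, seed=model.meta.get("seed", 0)
                )
            vse = variable_sensitivity_error(model, X, y, i, policy=policy, **kwargs)
            rows.append({"output": out, "input": inp, "VSE": vse, "VSR": vse / base})
    frame = pd.DataFrame(rows)
    frame["rank"] = 0
    for out in table.output_names:
        mask = frame["output"] == out
        # stable sort: ties keep input-column order
        order = np.argsort(-frame.loc[mask, "VSR"].to_numpy(), kind="stable")
        ranks = np.empty(order.size, dtype=int)
        ranks[order] = np.arange(1, order.size + 1)
        frame.loc[mask, "rank"] = ranks
    return SensitivityReport(frame=frame, baseline=baseline, policy=policy)
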