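"""Single-output three-layer perceptrons with Bayesian-regularized training.

The surrogate for each growth response is a 4-input, m-hidden, 1-output
perceptron with hyperbolic-tangent (tansig) hidden units and a linear
(purelin) output:

    yhat = w0 + sum_j v_j * tanh(sum_i W_ji x_i + b_j)

Training minimizes the regularized objective

    F = beta * E_D + alpha * E_W,      E_D = sum of squared errors,
                                       E_W = sum of squared weights,

by Levenberg-Marquardt steps, re-estimating alpha and beta each epoch from
the Gauss-Newton evidence approximation (Foresee & Hagan / MacKay):

    H = 2*beta*J'J + 2*alpha*I
    gamma = P - 2*alpha*tr(H^-1)          (effective number of parameters)
    alpha <- gamma / (2*E_W),  beta <- (K - gamma) / (2*E_D)

All training happens on the [-1, 1] scaled domain; models carry their input
and target scalers so predictions can be made in original units.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ExperimentTable, RangeScaler, SplitIndex, fit_scaler, split
from .exceptions import (
    DegenerateScaleError,
    TrainingDivergenceError,
    UndefinedMetricError,
)

__all__ = [
    "MLPModel",
    "TrainingConfig",
    "FitReport",
    "forward",
    "training_error",
    "train",
    "evaluate",
    "select_hidden_size",
    "fit_all_outputs",
]


# ---------------------------------------------------------------------------
# model container and forward pass

@dataclass
class MLPModel:
    """Weights, biases and transfer identities of one trained perceptron."""

    hidden_weights: np.ndarray   # (m, n)
    hidden_biases: np.ndarray    # (m,)
    output_weights: np.ndarray   # (m,)
    output_bias: float
    input_scaler: RangeScaler | None = None
    target_scaler: RangeScaler | None = None
    hidden_transfer: str = "tansig"
    output_transfer: str = "purelin"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hidden_weights = np.atleast_2d(np.asarray(self.hidden_weights, float))
        self.hidden_biases = np.asarray(self.hidden_biases, float).ravel()
        self.output_weights = np.asarray(self.output_weights, float).ravel()
        self.output_bias = float(self.output_bias)
        m, n = self.hidden_weights.shape
        if self.hidden_biases.shape != (m,) or self.output_weights.shape != (m,):
            raise ValueError("inconsistent layer dimensions")
        for arr in (self.hidden_weights, self.hidden_biases, self.output_weights):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite weights")

    @property
    def n_inputs(self) -> int:
        return self.hidden_weights.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.hidden_weights.shape[0]

    def predict_scaled(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[1] != self.n_inputs:
            raise ValueError(
                f"expected {self.n_inputs} input columns, got {X.shape[1]}"
            )
        H = np.tanh(X @ self.hidden_weights.T + self.hidden_biases)
        return H @ self.output_weights + self.output_bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict in original units (scale in, inverse-scale out)."""
        if self.input_scaler is None or self.target_scaler is None:
            raise ValueError("model has no scalers; use predict_scaled")
        Xs = self.input_scaler.transform(np.atleast_2d(np.asarray(X, float)))
        ys = self.predict_scaled(Xs)
        return self.target_scaler.inverse(ys[:, None]).ravel()

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "hidden_weights": self.hidden_weights.tolist(),
            "hidden_biases": self.hidden_biases.tolist(),
            "output_weights": self.output_weights.tolist(),
            "output_bias": self.output_bias,
            "hidden_transfer": self.hidden_transfer,
            "output_transfer": self.output_transfer,
            "input_scaler": None if self.input_scaler is None else self.input_scaler.to_dict(),
            "target_scaler": None if self.target_scaler is None else self.target_scaler.to_dict(),
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPModel":
        return cls(
            hidden_weights=np.asarray(d["hidden_weights"], float),
            hidden_biases=np.asarray(d["hidden_biases"], float),
            output_weights=np.asarray(d["output_weights"], float),
            output_bias=d["output_bias"],
            hidden_transfer=d.get("hidden_transfer", "tansig"),
            output_transfer=d.get("output_transfer", "purelin"),
            input_scaler=RangeScaler.from_dict(d["input_scaler"]) if d.get("input_scaler") else None,
            target_scaler=RangeScaler.from_dict(d["target_scaler"]) if d.get("target_scaler") else None,
            meta=d.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "MLPModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def forward(model: MLPModel, x: np.ndarray, scaled: bool = True) -> np.ndarray:
    """Evaluate the network; original units when ``scaled`` is False."""
    x = np.atleast_2d(np.asarray(x, float))
    return model.predict_scaled(x) if scaled else model.predict(x)


def training_error(model: MLPModel, X: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error E = (1/K) sum (y_k - yhat_k)^2 on the scaled domain."""
    y = np.asarray(y, float).ravel()
    if y.size == 0:
        raise ValueError("training_error needs at least one observation")
    r = model.predict_scaled(X) - y
    return float(r @ r / y.size)


# ---------------------------------------------------------------------------
# parameter vector plumbing (shared by the trainer and gradient tests)

def pack_params(model: MLPModel) -> np.ndarray:
    return np.concatenate([
        model.hidden_weights.ravel(),
        model.hidden_biases,
        model.output_weights,
        [model.output_bias],
    ])


def unpack_params(p: np.ndarray, n_in: int, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    W = p[: m * n_in].reshape(m, n_in)
    b = p[m * n_in: m * n_in + m]
    v = p[m * n_in + m: m * n_in + 2 * m]
    w0 = float(p[-1])
    return W, b, v, w0


def _net_forward(p: np.ndarray, X: np.ndarray, n_in: int, m: int) -> tuple[np.ndarray, np.ndarray]:
    W, b, v, w0 = unpack_params(p, n_in, m)
    H = np.tanh(X @ W.T + b)
    return H @ v + w0, H


def _jacobian(p: np.ndarray, X: np.ndarray, H: np.ndarray, n_in: int, m: int) -> np.ndarray:
    """d yhat_k / d p  (K x P), analytic."""
    _, _, v, _ = unpack_params(p, n_in, m)
    D = (1.0 - H ** 2) * v          # (K, m): v_j * sech^2(a_j)
    JW = D[:, :, None] * X[:, None, :]   # (K, m, n)
    return np.concatenate(
        [JW.reshape(X.shape[0], m * n_in), D, H, np.ones((X.shape[0], 1))], axis=1
    )


def objective_and_gradient(
    p: np.ndarray, X: np.ndarray, y: np.ndarray, alpha: float, beta: float,
    n_in: int, m: int,
) -> tuple[float, np.ndarray]:
    """F = beta*E_D + alpha*E_W and its analytic gradient (for tests too)."""
    yhat, H = _net_forward(p, X, n_in, m)
    r = yhat - y
    F = beta * float(r @ r) + alpha * float(p @ p)
    J = _jacobian(p, X, H, n_in, m)
    g = 2.0 * (beta * (J.T @ r) + alpha * p)
    return F, g


# ---------------------------------------------------------------------------
# training

@dataclass
class TrainingConfig:
    """Knobs of the Bayesian-regularized Levenberg-Marquardt trainer."""

    n_hidden: int = 8
    max_epochs: int = 1000
    tol_error: float = 1e-10      # stop when E = E_D/K drops below this
    tol_grad: float = 1e-7        # stop when max |dF/dw| drops below this
    seed: int = 0
    regularization: str = "bayesian"   # or "fixed-decay"
    alpha0: float = 0.01          # initial weight-penalty coefficient
    beta0: float = 1.0            # initial error-precision coefficient
    init_scale: float = 0.5       # uniform init half-width

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.tol_error <= 0 or self.tol_grad <= 0:
            raise ValueError("tolerances must be positive")
        if self.regularization not in ("bayesian", "fixed-decay"):
            raise ValueError(f"unknown regularization {self.regularization!r}")


@dataclass
class FitReport:
    """Goodness-of-fit of one response model on both partitions."""

    output: str
    r2_train: float
    r2_test: float
    rmse_train: float
    rmse_test: float
    mbe_train: float
    mbe_test: float
    n_hidden: int
    epochs: int
    alpha: float
    beta: float
    gamma: float


_MU0, _MU_INC, _MU_DEC, _MU_MAX = 0.005, 10.0, 0.1, 1e10


def train(
    X: np.ndarray,
    y: np.ndarray,
    config: TrainingConfig,
) -> tuple[MLPModel, dict]:
    """Train one perceptron on scaled (X, y) pairs.

    Returns the model and a convergence trace with per-epoch F, E_D, E_W,
    alpha, beta, gamma.  Deterministic for a fixed config seed.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    K, n_in = X.shape
    m = config.n_hidden
    if K != y.size:
        raise ValueError("X and y disagree on the number of observations")
    if K < m + 2:
        warnings.warn(
            f"only {K} observations for {m} hidden units: underdetermined fit",
            stacklevel=2,
        )
    P = m * n_in + 2 * m + 1
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(-config.init_scale, config.init_scale, size=P)

    alpha, beta = config.alpha0, config.beta0
    bayes = config.regularization == "bayesian"
    mu = _MU0
    trace: dict[str, list] = {k: [] for k in ("F", "E_D", "E_W", "alpha", "beta", "gamma")}
    gamma = float(P)
    epoch = 0

    yhat, H = _net_forward(p, X, n_in, m)
    r = yhat - y
    E_D, E_W = float(r @ r), float(p @ p)
    F = beta * E_D + alpha * E_W

    for epoch in range(1, config.max_epochs + 1):
        if not np.isfinite(F):
            raise TrainingDivergenceError(
                f"objective became non-finite at epoch {epoch}", epoch=epoch
            )
        J = _jacobian(p, X, H, n_in, m)
        g = 2.0 * (beta * (J.T @ r) + alpha * p)
        if np.max(np.abs(g)) < config.tol_grad:
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= _MU_MAX:
            A = 2.0 * beta * JtJ + (2.0 * alpha + mu) * np.eye(P)
            try:
                delta = np.linalg.solve(A, -g)
            except np.linalg.LinAlgError:
                mu *= _MU_INC
                continue
            p_new = p + delta
            yhat_new, H_new = _net_forward(p_new, X, n_in, m)
            r_new = yhat_new - y
            E_D_new, E_W_new = float(r_new @ r_new), float(p_new @ p_new)
            F_new = beta * E_D_new + alpha * E_W_new
            if np.isfinite(F_new) and F_new < F:
                p, H, r = p_new, H_new, r_new
                E_D, E_W, F = E_D_new, E_W_new, F_new
                mu = max(mu * _MU_DEC, 1e-20)
                accepted = True
                break
            mu *= _MU_INC
        if not accepted:
            break

        if bayes:
            # evidence re-estimation at the accepted point (current-epoch J)
            Hess = 2.0 * beta * JtJ + 2.0 * alpha * np.eye(P)
            try:
                tr_inv = float(np.trace(np.linalg.inv(Hess)))
            except np.linalg.LinAlgError:
                tr_inv = 0.0
            gamma = P - 2.0 * alpha * tr_inv
            gamma = float(np.clip(gamma, 1e-6, P))
            alpha = gamma / max(2.0 * E_W, 1e-30)
            beta = max(K - gamma, 1e-6) / max(2.0 * E_D, 1e-30)
            F = beta * E_D + alpha * E_W

        for k, v_ in (("F", F), ("E_D", E_D), ("E_W", E_W),
                      ("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            trace[k].append(v_)
        if E_D / K < config.tol_error:
            break

    W, b, v, w0 = unpack_params(p, n_in, m)
    model = MLPModel(
        hidden_weights=W, hidden_biases=b, output_weights=v, output_bias=w0,
        meta={
            "epochs": epoch, "alpha": alpha, "beta": beta, "gamma": gamma,
            "seed": config.seed, "regularization": config.regularization,
        },
    )
    return model, trace


# ---------------------------------------------------------------------------
# evaluation

def _metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float | None, float, float]:
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    n = y.size
    if n < 1:
        raise ValueError("metrics need at least one observation")
    resid = y - yhat
    rmse = float(np.sqrt(resid @ resid / n))
    mbe = float(resid.mean())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return None, rmse, mbe
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return r2, rmse, mbe


def evaluate(
    model: MLPModel, X: np.ndarray, y: np.ndarray, scaled: bool = False
) -> dict:
    """R², RMSE, MBE of ``model`` on (X, y).

    By default inputs/targets are in original units; ``scaled=True`` evaluates
    directly on the [-1, 1] domain.  A zero-variance target makes R²
    undefined; the raised error still carries RMSE and MBE.
    """
    yhat = model.predict_scaled(X) if scaled else model.predict(X)
    r2, rmse, mbe = _metrics(y, yhat)
    if r2 is None:
        err = UndefinedMetricError("R² undefined: target has zero variance")
        err.rmse, err.mbe = rmse, mbe
        raise err
    return {"r2": r2, "rmse": rmse, "mbe": mbe}


# ---------------------------------------------------------------------------
# model selection and the three-response fit

def _prepare_scaled(
    table: ExperimentTable, output: str
) -> tuple[np.ndarray, np.ndarray, RangeScaler, RangeScaler]:
    x_scaler = fit_scaler(table, table.input_names)
    y_scaler = fit_scaler(table, (output,))
    Xs = x_scaler.transform(table.X)
    ys = y_scaler.transform(table.output_column(output)[:, None]).ravel()
    return Xs, ys, x_scaler, y_scaler


def _fit_one(
    table: ExperimentTable, output: str, config: TrainingConfig, idx: SplitIndex
) -> tuple[MLPModel, FitReport]:
    Xs, ys, x_scaler, y_scaler = _prepare_scaled(table, output)
    tr, te = list(idx.train), list(idx.test)
    model, _ = train(Xs[tr], ys[tr], config)
    model.input_scaler = x_scaler
    model.target_scaler = y_scaler
    X, y = table.X, table.output_column(output)
    m_tr = evaluate(model, X[tr], y[tr])
    m_te = evaluate(model, X[te], y[te])
    report = FitReport(
        output=output,
        r2_train=m_tr["r2"], r2_test=m_te["r2"],
        rmse_train=m_tr["rmse"], rmse_test=m_te["rmse"],
        mbe_train=m_tr["mbe"], mbe_test=m_te["mbe"],
        n_hidden=config.n_hidden, epochs=model.meta["epochs"],
        alpha=model.meta["alpha"], beta=model.meta["beta"],
        gamma=model.meta["gamma"],
    )
    return model, report


def select_hidden_size(
    table: ExperimentTable,
    grid: Sequence[int] = tuple(range(1, 13)),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    outputs: Sequence[str] | None = None,
    fraction: float = 0.8,
    config: TrainingConfig | None = None,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Trial-and-error hidden-size search: median test RMSE over seeds.

    For each output, every grid size is trained once per seed (the seed fixes
    both the split and the initialization) and the size with the smallest
    median test RMSE wins; ties go to the smaller network.
    """
    if not grid:
        raise ValueError("hidden-size grid is empty")
    outputs = tuple(outputs or table.output_names)
    base = config or TrainingConfig()
    rows = []
    chosen: dict[str, int] = {}
    for out in outputs:
        medians = {}
        for m in grid:
            rmses = []
            for s in seeds:
                cfg = TrainingConfig(
                    n_hidden=m, max_epochs=base.max_epochs,
                    tol_error=base.tol_error, tol_grad=base.tol_grad,
                    seed=s, regularization=base.regularization,
                    alpha0=base.alpha0, beta0=base.beta0,
                )
                idx = split(table, fraction, seed=s)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    _, rep = _fit_one(table, out, cfg, idx)
                rmses.append(rep.rmse_test)
            med = float(np.median(rmses))
            medians[m] = med
            rows.append({"output": out, "n_hidden": m, "median_test_rmse": med})
        best = min(sorted(medians), key=lambda k: (medians[k], k))
        chosen[out] = int(best)
    return chosen, pd.DataFrame(rows)


def fit_all_outputs(
    table: ExperimentTable,
    config: TrainingConfig,
    split_index: SplitIndex,
    hidden_sizes: dict[str, int] | None = None,
) -> tuple[dict[str, MLPModel], dict[str, FitReport | UndefinedMetricError]]:
    """Fit one independent single-output model per response column.

    ``hidden_sizes`` overrides the config's hidden-layer width per output
    (the product of a trial-and-error search).  Returns the three models plus
    per-output fit reports.  An output whose target variance vanishes on a
    partition yields an UndefinedMetricError entry for that output only; the
    other responses are still fitted.
    """
    n = len(table)
    covered = sorted(set(split_index.train) | set(split_index.test))
    if covered != list(range(n)):
        raise ValueError("split does not cover the table")
    models: dict[str, MLPModel] = {}
    reports: dict[str, FitReport | UndefinedMetricError] = {}
    for out in table.output_names:
        cfg = config
        if hidden_sizes and out in hidden_sizes:
            cfg = dataclasses.replace(config, n_hidden=hidden_sizes[out])
        try:
            model, report = _fit_one(table, out, cfg, split_index)
        except UndefinedMetricError as err:
            reports[out] = err
            continue
        except DegenerateScaleError:
            err = UndefinedMetricError(
                f"R² undefined: output {out!r} is constant"
            )
            reports[out] = err
            continue
        models[out] = model
        reports[out] = report
    return models, reports


def reports_frame(reports: dict[str, FitReport]) -> pd.DataFrame:
    """Assemble fit reports in the familiar metric x (output, partition) grid."""
    cols = {}
    for out, rep in reports.items():
        if not isinstance(rep, FitReport):
            continue
        cols[(out, "Training")] = [rep.r2_train, rep.rmse_train, rep.mbe_train]
        cols[(out, "Testing")] = [rep.r2_test, rep.rmse_test, rep.mbe_test]
    return pd.DataFrame(cols, index=["R2", "RMSE", "MBE"])
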