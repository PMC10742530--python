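"""Train/test splitting, regression metrics and model comparison.

Metrics follow the standard definitions: coefficient of determination R^2,
root-mean-square error, mean absolute error and the residual predictive
deviation RPD = SD(observed) / RMSE.  Interpretation bands: RPD > 2.5 marks
an "accurate and reliable" model, R^2 > 0.82 a practically usable one and
R^2 > 0.9 an excellent one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = ["SplitSpec", "Metrics", "make_split", "compute_metrics",
           "interpretation_flags"]


@dataclass
class SplitSpec:
    """A random train/test partition (defaults: 154 train / 50 test)."""

    n_total: int
    n_train: int = 154
    n_test: int = 50
    seed: int = 0
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None


@dataclass
class Metrics:
    """Regression quality measures; ``rpd_from_r2`` is the 1/sqrt(1-R^2)
    variant, equivalent to SD/RMSE only in expectation."""

    r2: float
    rmse: float
    mae: float
    rpd: float
    rpd_from_r2: float

    def as_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "mae": self.mae,
                "rpd": self.rpd, "rpd_from_r2": self.rpd_from_r2}


def make_split(n_total: int, spec: SplitSpec | None = None) -> SplitSpec:
    """Uniform random partition without replacement; seeded."""
    spec = spec if spec is not None else SplitSpec(n_total=n_total)
    if spec.n_train < 1 or spec.n_test < 1:
        raise InvalidArgumentError("n_train and n_test must be >= 1")
    if spec.n_train + spec.n_test > n_total:
        raise InvalidArgumentError(
            f"n_train + n_test = {spec.n_train + spec.n_test} exceeds n_total {n_total}"
        )
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n_total)
    train = np.sort(perm[: spec.n_train])
    test = np.sort(perm[spec.n_train : spec.n_train + spec.n_test])
    return SplitSpec(n_total=n_total, n_train=spec.n_train, n_test=spec.n_test,
                     seed=spec.seed, train_indices=train, test_indices=test)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """R^2, RMSE, MAE and both RPD variants for a prediction vector."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise InvalidArgumentError("y_true and y_pred lengths differ")
    if y_true.size < 2:
        raise InvalidArgumentError("need at least two observations")
    if np.all(y_true == y_true[0]):
        raise InvalidArgumentError("R^2 undefined for constant y_true")
    resid = y_true - y_pred
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - sse / sst
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    sd = float(np.std(y_true, ddof=1))
    rpd = sd / rmse if rmse > 0 else float("inf")
    rpd_r2 = 1.0 / np.sqrt(1.0 - r2) if r2 < 1.0 else float("inf")
    return Metrics(r2=r2, rmse=rmse, mae=mae, rpd=rpd, rpd_from_r2=float(rpd_r2))


def interpretation_flags(m: Metrics) -> dict:
    """Quality bands used to read a model's test metrics."""
    return {
        "accurate_and_reliable": bool(m.rpd > 2.5),
        "practical": bool(m.r2 > 0.82),
        "excellent": bool(m.r2 > 0.9),
    }
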