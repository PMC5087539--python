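"""Accuracy metrics: confusion matrices, kappa, relative error, TAE/RTAE.

Covers the three validation layers of the pipeline: building detection
(2-class confusion matrix with producer/user accuracy and kappa), height
retrieval (absolute-error bins, see :mod:`dasypop.shadow`), and population
estimation (per-unit relative error, total absolute error and its
census-normalised form RTAE, which runs from 0 for a perfect model to 2
for a completely misplaced one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix2",
    "accuracy_summary",
    "relative_error",
    "tae",
    "rtae",
    "re_distribution",
    "read_unit_table",
    "unit_table_summary",
]


@dataclass(frozen=True)
class ConfusionMatrix2:
    """2-class counts; rows = predicted (building, non-building), cols = actual."""

    building_building: int
    building_nonbuilding: int
    nonbuilding_building: int
    nonbuilding_nonbuilding: int

    def __post_init__(self) -> None:
        if min(self.building_building, self.building_nonbuilding,
               self.nonbuilding_building, self.nonbuilding_nonbuilding) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [[self.building_building, self.building_nonbuilding],
             [self.nonbuilding_building, self.nonbuilding_nonbuilding]],
            dtype=np.float64,
        )

    @property
    def total(self) -> float:
        return float(self.matrix.sum())

    @classmethod
    def from_predictions(cls, predicted: np.ndarray, actual: np.ndarray) -> "ConfusionMatrix2":
        p = np.asarray(predicted, dtype=bool)
        a = np.asarray(actual, dtype=bool)
        return cls(
            int((p & a).sum()), int((p & ~a).sum()),
            int((~p & a).sum()), int((~p & ~a).sum()),
        )


def accuracy_summary(cm: ConfusionMatrix2) -> dict:
    """Overall, producer and user accuracies, kappa, and per-class kappa.

    Kappa uses the standard marginal-product expected agreement.  Per-class
    kappa is the conditional kappa on each class's actual (column) margin,
    κ_i = (p_ii − p_i+·p_+i) / (p_+i − p_i+·p_+i).
    """
    m = cm.matrix
    total = m.sum()
    if total <= 0:
        raise ValueError("empty confusion matrix")
    p = m / total
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = float(np.trace(p))
    p_e = float((row * col).sum())
    if np.isclose(p_e, 1.0):
        raise ValueError("degenerate margins: kappa undefined (expected agreement = 1)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    producer = np.diag(p) / col
    user = np.diag(p) / row
    per_class = (np.diag(p) - row * col) / (col - row * col)
    return {
        "overall_accuracy": p_o,
        "producer_accuracy": {"building": float(producer[0]), "nonbuilding": float(producer[1])},
        "user_accuracy": {"building": float(user[0]), "nonbuilding": float(user[1])},
        "kappa": float(kappa),
        "kappa_per_class": {"building": float(per_class[0]), "nonbuilding": float(per_class[1])},
    }


def relative_error(p_model: float, p_stat: float) -> float:
    """Signed relative error in percent: (model − statistic)/statistic × 100."""
    if p_stat == 0:
        raise ValueError("relative error undefined for zero statistical population")
    return (p_model - p_stat) / p_stat * 100.0


def tae(p_model: np.ndarray, p_stat: np.ndarray) -> float:
    """Total absolute error Σ|P_i − P_j|."""
    return float(np.abs(np.asarray(p_model, dtype=np.float64)
                        - np.asarray(p_stat, dtype=np.float64)).sum())


def rtae(p_model: np.ndarray, p_stat: np.ndarray) -> float:
    """Relative total absolute error Σ|P_i − P_j| / ΣP_j (0 perfect, 2 worst)."""
    stat = np.asarray(p_stat, dtype=np.float64)
    if stat.sum() <= 0:
        raise ValueError("total statistical population must be positive")
    return tae(p_model, p_stat) / float(stat.sum())


def re_distribution(res_pct: np.ndarray, thresholds_pct: tuple[float, ...] = (10.0, 30.0)) -> dict:
    """Counts of units with |RE| below each threshold, plus the mean |RE|."""
    abs_re = np.abs(np.asarray(res_pct, dtype=np.float64))
    return {
        "counts_below": {float(t): int((abs_re < t).sum()) for t in thresholds_pct},
        "mean_abs_re": float(abs_re.mean()),
        "n": int(len(abs_re)),
    }


def read_unit_table(path) -> pd.DataFrame:
    """Read a per-unit population CSV (unit, census_population, model_population)."""
    df = pd.read_csv(path)
    required = {"unit", "census_population", "model_population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"unit table missing columns: {sorted(missing)}")
    return df


def unit_table_summary(df: pd.DataFrame) -> dict:
    """RE per unit, mean |RE|, TAE/RTAE and threshold counts of a unit table.

    Rows with zero statistical population are excluded with a warning.
    """
    df = df.copy()
    zero = df["census_population"] == 0
    if zero.any():
        warnings.warn(f"excluding {int(zero.sum())} unit(s) with zero census population")
        df = df[~zero]
    stat = df["census_population"].to_numpy(dtype=np.float64)
    model = df["model_population"].to_numpy(dtype=np.float64)
    res = (model - stat) / stat * 100.0
    dist = re_distribution(res)
    return {
        "re_pct": res,
        "mean_abs_re": dist["mean_abs_re"],
        "counts_below": dist["counts_below"],
        "tae": tae(model, stat),
        "rtae": rtae(model, stat),
        "model_total": float(model.sum()),
        "statistic_total": float(stat.sum()),
        "n_units": int(len(df)),
    }
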