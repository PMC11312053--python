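"""Evaluation metrics for virtual screening.

Beyond the usual confusion-matrix quantities, early-recognition metrics are
central here: a screening model is judged by how many actives it places at
the very top of a ranked library.

* **BEDROC_α** (Boltzmann-enhanced discrimination of ROC): the exponentially
  rank-weighted "robust initial enhancement" (RIE), min–max normalized to
  [0, 1]. α controls how early the weight concentrates; α = 80.5 puts ~80%
  of the weight on the first 2% of the ranking.
* **HR_f% / EF_f%**: the hit rate among the top f% of the ranking, and its
  ratio to the library-wide active prevalence (enrichment factor).

A rank-averaging utility supports comparing methods across datasets whose
class ratios differ too much for raw metric values to be comparable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MetricConfig", "MetricReport", "confusion_metrics", "bedroc",
    "bedroc_random_expectation", "hit_rate_and_ef", "rank_average",
]


@dataclass(frozen=True)
class MetricConfig:
    bedroc_alpha: float = 80.5
    hr_fractions: tuple[float, ...] = (0.01, 0.05)
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.bedroc_alpha <= 0:
            raise ValueError("bedroc_alpha must be positive")
        if list(self.hr_fractions) != sorted(self.hr_fractions):
            raise ValueError("hr_fractions must be sorted ascending")
        if any(not (0 < f <= 1) for f in self.hr_fractions):
            raise ValueError("hr_fractions must lie in (0, 1]")


@dataclass
class MetricReport:
    """Confusion counts plus derived and early-recognition metrics.

    Ratios with zero denominators are NaN (with a warning at computation
    time), never silently 0.
    """

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    sen: float = float("nan")
    spe: float = float("nan")
    acc: float = float("nan")
    f1: float = float("nan")
    bedroc: float = float("nan")
    hr: dict[float, float] = field(default_factory=dict)
    ef: dict[float, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"counts": {"tp": self.tp, "fp": self.fp,
                           "tn": self.tn, "fn": self.fn},
                "sen": self.sen, "spe": self.spe, "acc": self.acc,
                "f1": self.f1, "bedroc": self.bedroc,
                "hr": {str(k): v for k, v in self.hr.items()},
                "ef": {str(k): v for k, v in self.ef.items()}}


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      RuntimeWarning, stacklevel=3)
        return float("nan")
    return num / den


def confusion_metrics(truth, predicted) -> MetricReport:
    """Sensitivity, specificity, accuracy and F1 from binary labels."""
    truth = np.asarray(truth, dtype=int)
    predicted = np.asarray(predicted, dtype=int)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted must have equal length")
    if truth.size == 0:
        raise ValueError("empty inputs")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fp = int(np.sum((truth == 0) & (predicted == 1)))
    tn = int(np.sum((truth == 0) & (predicted == 0)))
    fn = int(np.sum((truth == 1) & (predicted == 0)))
    return MetricReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sen=_ratio(tp, tp + fn, "sensitivity"),
        spe=_ratio(tn, tn + fp, "specificity"),
        acc=(tp + tn) / truth.size,
        f1=_ratio(2 * tp, 2 * tp + fp + fn, "F1"),
    )


def _ranks_of_actives(scores, truth) -> tuple[np.ndarray, int]:
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=int)
    if scores.shape != truth.shape:
        raise ValueError("scores and truth must have equal length")
    if len(np.unique(scores)) < scores.size:
        warnings.warn("tied scores broken by stable input order",
                      RuntimeWarning, stacklevel=3)
    order = np.argsort(-scores, kind="stable")
    ranks = np.nonzero(truth[order] == 1)[0] + 1  # 1-based ranks of actives
    return ranks, scores.size


def bedroc(scores, truth, alpha: float = 80.5) -> float:
    """BEDROC_α of a ranking (higher score = earlier rank).

    Computed as the exponentially weighted RIE of the active ranks,
    normalized so that ranking all actives first gives 1 and all last
    gives 0. Requires at least one active and one inactive.
    """
    ranks, n = _ranks_of_actives(scores, truth)
    n_act = ranks.size
    if n_act == 0 or n_act == n:
        raise ValueError("BEDROC needs at least one active and one inactive")
    ra = n_act / n
    rie = (np.exp(-alpha * ranks / n).sum() / n_act) / (
        (1.0 / n) * (1 - math.exp(-alpha)) / (math.exp(alpha / n) - 1))
    return float(
        rie * ra * math.sinh(alpha / 2)
        / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
        + 1.0 / (1 - math.exp(alpha * (1 - ra)))
    )


def bedroc_random_expectation(n: int, n_actives: int, alpha: float = 80.5) -> float:
    """Analytic expectation of BEDROC under a uniformly random ranking
    (RIE = 1 plugged into the normalization)."""
    ra = n_actives / n
    return (ra * math.sinh(alpha / 2)
            / (math.cosh(alpha / 2) - math.cosh(alpha / 2 - alpha * ra))
            + 1.0 / (1 - math.exp(alpha * (1 - ra))))


def hit_rate_and_ef(scores, truth, fraction: float) -> tuple[float, float]:
    """Hit rate and enrichment factor in the top ``fraction`` of the ranking.

    The top set holds ``ceil(fraction * n)`` compounds (stable sort; ties at
    the boundary resolved by input order with a warning). EF is the hit rate
    divided by the library-wide active prevalence, so EF at fraction 1 is
    identically 1. With zero actives EF is NaN.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    ranks, n = _ranks_of_actives(scores, truth)
    top = math.ceil(fraction * n)
    hits = int(np.sum(ranks <= top))
    hr = hits / top
    n_act = ranks.size
    if n_act == 0:
        warnings.warn("no actives: enrichment factor undefined (NaN)",
                      RuntimeWarning, stacklevel=2)
        return hr, float("nan")
    return hr, hr / (n_act / n)


def rank_average(table: pd.DataFrame) -> pd.Series:
    """Average per-dataset ranks of methods (rows = datasets, columns =
    methods; higher metric = better = higher rank number, ties get the
    midrank). Missing cells are dropped pairwise with a warning.
    """
    if table.shape[1] < 2:
        raise ValueError("rank averaging needs at least two methods")
    if table.isna().any().any():
        warnings.warn("missing dataset x method cells dropped pairwise",
                      RuntimeWarning, stacklevel=2)
    ranks = table.rank(axis=1, method="average", ascending=True)
    return ranks.mean(axis=0, skipna=True)
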