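"""Training strategies for activity classifiers under scarce negative data.

All strategies share one base learner — a soft-margin SVM with an RBF
kernel whose decision values are Platt-calibrated to probabilities — and
differ only in how they exploit the four data pools (positives P, true
negatives N, putative negatives, unlabeled U):

``baseline``
    P vs N only.
``tao``
    P vs N plus cluster-derived putative negatives (all at weight 1).
``pn_weighted``
    P vs N plus the unlabeled pool treated as negatives at a reduced
    sample weight (default 0.5), reflecting their lower credibility.
``pu_iterative``
    Start from P vs N; repeatedly score the unlabeled pool and absorb
    compounds predicted negative into N until a fixed point.
``pu_bagging``
    Ensemble of SVMs, each trained on all of P vs a fresh random bag of U.
``napu_bagging``
    Negative-augmented PU-bagging: each bag's non-positive portion mixes
    true negatives and unlabeled compounds at a fixed N:U ratio (default
    0.4:4.5, i.e. P:N:U = 1:0.4:4.5 at bag size |P|), merged into a single
    negative class. This keeps the high recall of PU-bagging while the
    "strong" negatives rein in the false-positive rate.

Ensemble predictions are the mean of member probabilities; a compound is a
hit when its probability strictly exceeds the decision threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .augment import PUPools
from .featurize import FingerprintConfig, FingerprintMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "BaseLearnerConfig", "BagConfig", "EnsembleModel", "PredictionResult",
    "fit_base", "tune_base", "fit_baseline", "fit_tao", "fit_pn_weighted",
    "fit_pu_iterative", "sample_bag", "fit_pu_bagging", "fit_napu_bagging",
    "predict", "napu_default_bag_config", "save_model", "load_model",
    "DEFAULT_THRESHOLD", "SCREENING_THRESHOLD",
]

DEFAULT_THRESHOLD = 0.5
SCREENING_THRESHOLD = 0.75

#: final P:N:U bag composition — at bag size |P|, draw N and U at 0.4:4.5
NAPU_RATIO_N = 0.4
NAPU_RATIO_U = 4.5


@dataclass(frozen=True)
class BaseLearnerConfig:
    """c-SVC base learner with RBF kernel.

    ``gamma="scale"`` is 1 / (n_features * Var(X)), the usual heuristic
    for binary fingerprints. ``calibrate_probabilities`` wraps the SVM in
    Platt sigmoid calibration fitted by internal cross-validation.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | str = "scale"
    calibrate_probabilities: bool = True
    calibration_folds: int = 5

    def __post_init__(self) -> None:
        if self.kernel != "rbf":
            raise ValueError("only the RBF kernel is supported")
        if self.C <= 0:
            raise ValueError("C must be positive")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ValueError("explicit gamma must be positive")

    def to_dict(self) -> dict:
        return {"kernel": self.kernel, "C": self.C, "gamma": self.gamma,
                "calibrate_probabilities": self.calibrate_probabilities,
                "calibration_folds": self.calibration_folds}


@dataclass(frozen=True)
class BagConfig:
    """Bag composition for the bagging strategies.

    The non-positive portion of each bag has ``round(bag_multiplier * |P|)``
    compounds, of which a fraction ``n_fraction`` is drawn from the true
    negatives and ``u_fraction`` from the unlabeled pool (the two must sum
    to 1). ``n_fraction = 0`` is plain PU-bagging.
    """

    n_bags: int = 100
    bag_multiplier: float = 1.0
    n_fraction: float = 0.0
    u_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bags < 1:
            raise ValueError("n_bags must be positive")
        if self.bag_multiplier <= 0:
            raise ValueError("bag_multiplier must be positive")
        if not (0 <= self.n_fraction <= 1 and 0 <= self.u_fraction <= 1):
            raise ValueError("n_fraction and u_fraction must lie in [0, 1]")
        if abs(self.n_fraction + self.u_fraction - 1.0) > 1e-9:
            raise ValueError("n_fraction + u_fraction must equal 1")

    def to_dict(self) -> dict:
        return {"n_bags": self.n_bags, "bag_multiplier": self.bag_multiplier,
                "n_fraction": self.n_fraction, "u_fraction": self.u_fraction,
                "seed": self.seed}


def napu_default_bag_config(seed: int = 0, n_bags: int = 100,
                            bag_multiplier: float = 1.0) -> BagConfig:
    """The final negative-augmented configuration: bag size |P| with the
    non-positive portion drawn at N:U = 0.4:4.5."""
    total = NAPU_RATIO_N + NAPU_RATIO_U
    return BagConfig(n_bags=n_bags, bag_multiplier=bag_multiplier,
                     n_fraction=NAPU_RATIO_N / total,
                     u_fraction=NAPU_RATIO_U / total, seed=seed)


@dataclass
class EnsembleModel:
    """Fitted base classifiers plus mean-probability aggregation."""

    members: list
    aggregation: str = "mean_probability"
    threshold: float = DEFAULT_THRESHOLD
    feature_config: FingerprintConfig | None = None
    strategy: str = ""
    bags: list[tuple[tuple[str, ...], tuple[str, ...]]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        if self.aggregation != "mean_probability":
            raise ValueError("only mean_probability aggregation is supported")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Mean probability-of-active over ensemble members."""
        probs = np.stack([_member_proba(m, X) for m in self.members])
        return probs.mean(axis=0)


@dataclass
class PredictionResult:
    """Per-compound probability of activity and hit calls."""

    ids: list[str]
    probability: np.ndarray
    is_hit: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.probability = np.asarray(self.probability, dtype=float)
        self.is_hit = np.asarray(self.is_hit, dtype=bool)
        if not (len(self.ids) == len(self.probability) == len(self.is_hit)):
            raise ValueError("ids, probability and is_hit must align")

    def hits(self) -> list[str]:
        return [i for i, h in zip(self.ids, self.is_hit) if h]


# ---------------------------------------------------------------------------
# base learner


def _svc(cfg: BaseLearnerConfig, random_state: int | None = None) -> SVC:
    return SVC(kernel=cfg.kernel, C=cfg.C, gamma=cfg.gamma,
               random_state=random_state)


def fit_base(X: np.ndarray, y: np.ndarray,
             weights: np.ndarray | None = None,
             cfg: BaseLearnerConfig | None = None,
             random_state: int | None = None):
    """Fit one base classifier on rows ``X`` with binary labels ``y``.

    Returns a fitted estimator exposing ``predict`` and (when calibrated)
    ``predict_proba``; uncalibrated models fall back to a logistic map of
    the SVM decision value. Deterministic for fixed inputs and config.
    """
    cfg = cfg or BaseLearnerConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        missing = ({0, 1} - set(classes.tolist())) or {"second class"}
        raise ValueError(f"single-class training set: missing class {missing}")
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if np.any(weights <= 0):
            raise ValueError("sample weights must be positive")
    if cfg.calibrate_probabilities:
        folds = min(cfg.calibration_folds, int(counts.min()))
        if folds < 2:
            raise ValueError("probability calibration needs >= 2 samples per "
                             "class; disable calibrate_probabilities for toys")
        clf = CalibratedClassifierCV(_svc(cfg, random_state), method="sigmoid",
                                     cv=folds, ensemble=False)
    else:
        clf = _svc(cfg, random_state)
    clf.fit(X, y, sample_weight=weights)
    return clf


def tune_base(X: np.ndarray, y: np.ndarray,
              cfg: BaseLearnerConfig | None = None,
              cv: int = 5) -> BaseLearnerConfig:
    """Optional per-target hyperparameter grid search (F1-maximizing)."""
    cfg = cfg or BaseLearnerConfig()
    grid = {"C": np.logspace(-1, 2, 4),
            "gamma": [2.0 ** e for e in range(-12, -3)]}
    search = GridSearchCV(_svc(cfg), grid, scoring="f1", cv=cv)
    search.fit(np.asarray(X, dtype=np.float64), np.asarray(y, dtype=int))
    return replace(cfg, C=float(search.best_params_["C"]),
                   gamma=float(search.best_params_["gamma"]))


def _member_proba(clf, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if hasattr(clf, "predict_proba"):
        proba = clf.predict_proba(X)
        col = int(np.where(clf.classes_ == 1)[0][0])
        return proba[:, col]
    d = clf.decision_function(X)
    return 1.0 / (1.0 + np.exp(-d))


# ---------------------------------------------------------------------------
# pool plumbing


def _rows(pools_ids: Sequence[str], fps: FingerprintMatrix) -> np.ndarray:
    return fps.bits[fps.positions(pools_ids)].astype(np.float64)


def _pn_arrays(pools: PUPools, fps: FingerprintMatrix,
               extra_negatives: Sequence[str] = ()) -> tuple[np.ndarray, np.ndarray]:
    pos = sorted(pools.positives)
    neg = sorted(pools.true_negatives) + list(extra_negatives)
    X = np.vstack([_rows(pos, fps), _rows(neg, fps)])
    y = np.concatenate([np.ones(len(pos), dtype=int),
                        np.zeros(len(neg), dtype=int)])
    return X, y


def _single_member_model(clf, fps: FingerprintMatrix, strategy: str,
                         threshold: float) -> EnsembleModel:
    return EnsembleModel([clf], threshold=threshold,
                         feature_config=fps.config, strategy=strategy)


# ---------------------------------------------------------------------------
# non-bagging strategies


def fit_baseline(pools: PUPools, fps: FingerprintMatrix,
                 cfg: BaseLearnerConfig | None = None,
                 threshold: float = DEFAULT_THRESHOLD) -> EnsembleModel:
    """Supervised reference model: positives vs true negatives only."""
    if not pools.positives or not pools.true_negatives:
        raise ValueError("baseline needs non-empty positives and true negatives")
    X, y = _pn_arrays(pools, fps)
    return _single_member_model(fit_base(X, y, cfg=cfg), fps, "baseline", threshold)


def fit_tao(pools: PUPools, fps: FingerprintMatrix,
            cfg: BaseLearnerConfig | None = None,
            threshold: float = DEFAULT_THRESHOLD) -> EnsembleModel:
    """Cluster-based putative-negative augmentation: positives vs the union
    of true and putative negatives, all at weight 1."""
    if not pools.putative_negatives:
        raise ValueError("putative-negative strategy needs a non-empty "
                         "putative_negatives pool")
    X, y = _pn_arrays(pools, fps, sorted(pools.putative_negatives))
    return _single_member_model(fit_base(X, y, cfg=cfg), fps, "tao", threshold)


def fit_pn_weighted(pools: PUPools, fps: FingerprintMatrix,
                    cfg: BaseLearnerConfig | None = None,
                    augment_weight: float = 0.5,
                    threshold: float = DEFAULT_THRESHOLD) -> EnsembleModel:
    """Unlabeled compounds join the negative class at a reduced sample
    weight (< 1), encoding their lower credibility as negatives."""
    if not pools.unlabeled:
        raise ValueError("PN-weighted strategy needs a non-empty unlabeled pool")
    if not (0 < augment_weight < 1):
        raise ValueError("augment_weight must lie strictly between 0 and 1")
    X, y = _pn_arrays(pools, fps, sorted(pools.unlabeled))
    n_core = len(pools.positives) + len(pools.true_negatives)
    w = np.ones(len(y))
    w[n_core:] = augment_weight
    return _single_member_model(fit_base(X, y, weights=w, cfg=cfg), fps,
                                "pn_weighted", threshold)


def fit_pu_iterative(pools: PUPools, fps: FingerprintMatrix,
                     cfg: BaseLearnerConfig | None = None,
                     max_rounds: int = 20,
                     threshold: float = DEFAULT_THRESHOLD) -> EnsembleModel:
    """Iteratively absorb unlabeled compounds predicted negative.

    Round 0 trains on P vs N. Each subsequent round scores the remaining
    unlabeled pool, moves everything predicted negative into the negative
    class, and refits; the loop stops when a round absorbs nothing (or
    ``max_rounds`` is reached). Intermediate rounds skip probability
    calibration (only the class call matters); the returned model is
    refit with the configured calibration.
    """
    if not pools.unlabeled:
        raise ValueError("PU-iterative strategy needs a non-empty unlabeled pool")
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    cfg = cfg or BaseLearnerConfig()
    fast_cfg = replace(cfg, calibrate_probabilities=False)
    absorbed: list[str] = []
    remaining = sorted(pools.unlabeled)
    rounds_run = 0
    for round_no in range(1, max_rounds + 1):
        rounds_run = round_no
        X, y = _pn_arrays(pools, fps, absorbed)
        clf = fit_base(X, y, cfg=fast_cfg)
        pred = clf.predict(_rows(remaining, fps))
        newly = [cid for cid, p in zip(remaining, pred) if p == 0]
        logger.info("PU-iterative round %d: absorbed %d of %d unlabeled",
                    round_no, len(newly), len(remaining))
        if not newly:
            break
        absorbed.extend(newly)
        remaining = [cid for cid in remaining if cid not in set(newly)]
        if not remaining:
            break
    X, y = _pn_arrays(pools, fps, absorbed)
    model = _single_member_model(fit_base(X, y, cfg=cfg), fps,
                                 "pu_iterative", threshold)
    model.absorbed_ids = absorbed  # exposed for inspection
    model.n_rounds = rounds_run
    return model


# ---------------------------------------------------------------------------
# bagging strategies


def _bag_rng(cfg: BagConfig, bag_index: int) -> np.random.Generator:
    return np.random.default_rng([abs(cfg.seed) % (2 ** 31), bag_index])


def sample_bag(pools: PUPools, cfg: BagConfig,
               bag_index: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Draw one bag: (all positives, sampled non-positive portion).

    The non-positive portion has ``round(bag_multiplier * |P|)`` compounds:
    ``round(size * n_fraction)`` true negatives and the remainder unlabeled,
    drawn without replacement when the pool is large enough (otherwise with
    replacement, logged). Deterministic given (seed, bag_index).
    """
    pos = tuple(sorted(pools.positives))
    if not pos:
        raise ValueError("bagging needs a non-empty positive pool")
    size = int(round(cfg.bag_multiplier * len(pos)))
    n_n = int(round(size * cfg.n_fraction))
    n_u = size - n_n
    if n_u > 0 and not pools.unlabeled:
        raise ValueError("u_fraction > 0 requires a non-empty unlabeled pool")
    if n_n > 0 and not pools.true_negatives:
        raise ValueError("n_fraction > 0 requires a non-empty true-negative pool")
    rng = _bag_rng(cfg, bag_index)
    nonpos: list[str] = []
    for pool, want, name in ((sorted(pools.true_negatives), n_n, "true-negative"),
                             (sorted(pools.unlabeled), n_u, "unlabeled")):
        if want == 0:
            continue
        replacement = want > len(pool)
        if replacement:
            logger.info("bag %d: drawing %d from %d %s compounds with "
                        "replacement", bag_index, want, len(pool), name)
        idx = rng.choice(len(pool), size=want, replace=replacement)
        nonpos.extend(pool[i] for i in idx)
    if not nonpos:
        raise ValueError("bag would contain no negative-class samples; "
                         "increase bag_multiplier or pool sizes")
    return pos, tuple(nonpos)


def _fit_bagging(pools: PUPools, fps: FingerprintMatrix,
                 base_cfg: BaseLearnerConfig | None, bag_cfg: BagConfig,
                 strategy: str, threshold: float) -> EnsembleModel:
    members, bags = [], []
    pos_rows_cache: np.ndarray | None = None
    for b in range(bag_cfg.n_bags):
        pos, nonpos = sample_bag(pools, bag_cfg, b)
        if pos_rows_cache is None:
            pos_rows_cache = _rows(pos, fps)
        # With-replacement draws (small pools) are collapsed to unique
        # compounds with multiplicity weights: the SVM objective is
        # identical, but probability calibration no longer sees the same
        # compound on both sides of a CV split.
        uniq, counts = np.unique(nonpos, return_counts=True)
        X = np.vstack([pos_rows_cache, _rows(list(uniq), fps)])
        y = np.concatenate([np.ones(len(pos), dtype=int),
                            np.zeros(len(uniq), dtype=int)])
        w = np.concatenate([np.ones(len(pos)), counts.astype(float)])
        member_seed = int(_bag_rng(bag_cfg, b).integers(2 ** 31))
        members.append(fit_base(X, y, weights=w, cfg=base_cfg,
                                random_state=member_seed))
        bags.append((pos, nonpos))
    model = EnsembleModel(members, threshold=threshold,
                          feature_config=fps.config, strategy=strategy, bags=bags)
    return model


def fit_pu_bagging(pools: PUPools, fps: FingerprintMatrix,
                   base_cfg: BaseLearnerConfig | None = None,
                   bag_cfg: BagConfig | None = None,
                   threshold: float = DEFAULT_THRESHOLD) -> EnsembleModel:
    """Bagging ensemble of positives vs random unlabeled bags (1:1 by
    default). Requires ``n_fraction == 0``."""
    bag_cfg = bag_cfg or BagConfig()
    if bag_cfg.n_fraction != 0:
        raise ValueError("PU-bagging draws only unlabeled compounds; "
                         "use fit_napu_bagging for n_fraction > 0")
    return _fit_bagging(pools, fps, base_cfg, bag_cfg, "pu_bagging", threshold)


def fit_napu_bagging(pools: PUPools, fps: FingerprintMatrix,
                     base_cfg: BaseLearnerConfig | None = None,
                     bag_cfg: BagConfig | None = None,
                     threshold: float = DEFAULT_THRESHOLD) -> EnsembleModel:
    """Negative-augmented PU-bagging: each bag mixes true negatives and
    unlabeled compounds (merged as one negative class) at ``n_fraction``.

    With ``n_fraction = 0`` this reduces exactly to PU-bagging (identical
    bags and members under shared seeds).
    """
    bag_cfg = bag_cfg or napu_default_bag_config()
    if bag_cfg.n_fraction > 0 and not pools.true_negatives:
        raise ValueError("n_fraction > 0 requires true negatives")
    return _fit_bagging(pools, fps, base_cfg, bag_cfg, "napu_bagging", threshold)


# ---------------------------------------------------------------------------
# prediction and persistence


def predict(model: EnsembleModel, fps: FingerprintMatrix,
            threshold: float | None = None) -> PredictionResult:
    """Score compounds with the ensemble; a compound is a hit when its mean
    probability strictly exceeds the threshold."""
    if model.feature_config is not None and fps.n_bits != _model_width(model):
        raise ValueError(f"fingerprint width {fps.n_bits} does not match "
                         f"model width {_model_width(model)}")
    threshold = model.threshold if threshold is None else threshold
    proba = model.predict_proba(fps.bits.astype(np.float64))
    return PredictionResult(list(fps.ids), proba, proba > threshold, threshold)


def _model_width(model: EnsembleModel) -> int:
    return model.feature_config.n_bits


def save_model(model: EnsembleModel, directory: str | Path) -> None:
    """Persist an ensemble as a directory: JSON manifest + joblib members."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "strategy": model.strategy,
        "aggregation": model.aggregation,
        "threshold": model.threshold,
        "n_members": len(model.members),
        "feature_config": (model.feature_config.to_dict()
                           if model.feature_config else None),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))
    joblib.dump(model.members, directory / "members.joblib")


def load_model(directory: str | Path) -> EnsembleModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    members = joblib.load(directory / "members.joblib")
    feature_config = (FingerprintConfig.from_dict(manifest["feature_config"])
                      if manifest["feature_config"] else None)
    return EnsembleModel(members, aggregation=manifest["aggregation"],
                         threshold=manifest["threshold"],
                         feature_config=feature_config,
                         strategy=manifest.get("strategy", ""))
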