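"""Synthetic fingerprint datasets with the structure PU screening assumes.

The generator emulates a clustered chemical space as binary bit patterns.
Each cluster has a sparse random prototype; a compound is its cluster's
prototype with independent bit flips. A minority of clusters are *active
chemotypes* whose members are actives; the rest are generic, inactive
chemical space. On top sit the data pathologies that positive-unlabeled
augmentation strategies are designed for:

* **activity cliffs** — active chemotypes carry a *near-miss shell*: the
  core prototype with a small set of dedicated "cliff bits" toggled,
  representing the specific structural change that abolishes activity.
  Shell compounds are inactive yet far closer to the actives than generic
  space is.
* **scarce, biased true negatives** — confirmed inactives are few, are a
  mix of near-miss shell compounds and generic compounds, and cover only a
  subset of the active chemotypes (assays probe the series someone chose
  to make).
* **broad unlabeled pool with contamination** — the unlabeled set spans
  generic space, and a fraction of it consists of hidden actives drawn
  from the active chemotypes.
* **distribution shift at evaluation** — held-out compounds are noisier
  than training compounds, and held-out actives drift part-way toward the
  cliff (cliff-straddling analogues), so a model's boundary tightness
  around the active chemotypes is what the held-out metrics probe.

Hidden ground-truth labels are kept on the dataset object only for
evaluation; training code consumes the pools and fingerprints alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import PUPools
from .featurize import FingerprintConfig, FingerprintKind, FingerprintMatrix
from .learners import PredictionResult
from .metrics import MetricReport, confusion_metrics

__all__ = ["SynthConfig", "SynthDataset", "generate", "evaluate_against_truth"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Defaults model one screening target with plentiful actives, an order
    of magnitude fewer confirmed inactives, and a large unlabeled pool
    with 10% hidden actives — the imbalance pattern of public bioactivity
    data.
    """

    n_bits: int = 256
    n_clusters: int = 20
    n_pos: int = 200
    n_true_neg: int = 40
    n_unlabeled: int = 2000
    #: fraction of the unlabeled pool that is hidden actives
    contamination: float = 0.1
    bit_flip_noise: float = 0.05
    #: fraction of clusters carrying both classes (active cores + near-miss
    #: shells); capped at active_cluster_fraction
    activity_cliff_rate: float = 0.4
    seed: int = 0
    # --- auxiliary pools and held-out evaluation data -------------------
    n_putative: int = 400
    n_test_pos: int = 100
    n_test_neg: int = 400
    prototype_density: float = 0.05
    active_cluster_fraction: float = 0.4
    #: width of the activity cliff: dedicated bits toggled in shell compounds
    n_cliff_bits: int = 16
    #: fraction of active chemotypes whose shells appear among the true
    #: negatives (assay coverage; lower it to model partially explored
    #: chemotype space)
    observed_chemotype_fraction: float = 1.0
    #: near-miss (shell) share of true negatives / held-out negatives
    near_miss_fraction_negatives: float = 0.6
    near_miss_fraction_test: float = 1.0
    #: near-miss share of the (non-contaminated) unlabeled pool: a
    #: representative-per-cluster unlabeled set contains a few compounds
    #: from near-miss clusters
    near_miss_fraction_unlabeled: float = 0.0
    #: held-out actives toggle each cliff bit with probability drawn
    #: uniformly from [0, 2 * test_cliff_drift] (cliff-straddling analogues
    #: at heterogeneous depths)
    test_cliff_drift: float = 0.5
    #: held-out noise relative to training noise (set above 1 to model the
    #: extra distribution shift of external validation sets)
    test_noise_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("need at least two clusters")
        for name in ("n_pos", "n_true_neg", "n_unlabeled"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.contamination < 0.5):
            raise ValueError("contamination must lie in [0, 0.5)")
        if not (0 <= self.bit_flip_noise < 1):
            raise ValueError("bit_flip_noise must lie in [0, 1)")
        if not (0 <= self.activity_cliff_rate < 1):
            raise ValueError("activity_cliff_rate must lie in [0, 1)")
        if self.n_cliff_bits >= self.n_bits:
            raise ValueError("n_cliff_bits must be below n_bits")

    @classmethod
    def noiseless(cls, seed: int = 0, **overrides) -> "SynthConfig":
        """Clean control condition: no bit-flip noise, no contamination, no
        activity cliffs and no held-out distribution shift. True negatives
        are plentiful enough to cover every inactive chemotype, so every
        training strategy has the information to separate this perfectly.
        """
        defaults = dict(bit_flip_noise=0.0, contamination=0.0,
                        activity_cliff_rate=0.0, test_cliff_drift=0.0,
                        test_noise_factor=1.0, near_miss_fraction_test=0.0,
                        near_miss_fraction_negatives=0.0,
                        near_miss_fraction_unlabeled=0.0, n_true_neg=120,
                        seed=seed)
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SynthDataset:
    """Generated corpus: fingerprints, training pools, held-out test ids,
    and hidden ground truth (evaluation only)."""

    fps: FingerprintMatrix
    pools: PUPools
    hidden_labels: dict[str, int]
    test_positive_ids: list[str] = field(default_factory=list)
    test_negative_ids: list[str] = field(default_factory=list)
    config: SynthConfig | None = None

    @property
    def test_ids(self) -> list[str]:
        return self.test_positive_ids + self.test_negative_ids

    def test_matrix(self) -> FingerprintMatrix:
        return self.fps.subset(self.test_ids)

    def test_truth(self) -> np.ndarray:
        return np.array([self.hidden_labels[i] for i in self.test_ids], dtype=int)


def generate(cfg: SynthConfig | None = None) -> SynthDataset:
    """Draw a synthetic dataset. Deterministic given ``cfg.seed``."""
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)

    n_active = max(1, round(cfg.active_cluster_fraction * cfg.n_clusters))
    n_active = min(n_active, cfg.n_clusters - 1)
    active = np.arange(n_active)
    generic = np.arange(n_active, cfg.n_clusters)
    n_cliff = min(round(cfg.activity_cliff_rate * cfg.n_clusters), n_active)
    cliffed = active[:n_cliff]  # chemotypes carrying a near-miss shell

    prototypes = (rng.random((cfg.n_clusters, cfg.n_bits))
                  < cfg.prototype_density).astype(np.uint8)
    cliff_bits = {int(c): rng.choice(cfg.n_bits, size=cfg.n_cliff_bits,
                                     replace=False) for c in cliffed}
    n_obs = max(1, round(cfg.observed_chemotype_fraction * max(n_cliff, 1)))
    observed = (cliffed[rng.choice(n_cliff, size=n_obs, replace=False)]
                if n_cliff else np.array([], dtype=int))

    ids: list[str] = []
    rows: list[np.ndarray] = []
    hidden: dict[str, int] = {}

    def emit(prefix: str, label: int, vec: np.ndarray) -> str:
        cid = f"{prefix}-{len(ids):05d}"
        ids.append(cid)
        hidden[cid] = label
        rows.append(vec)
        return cid

    def noisy(pattern: np.ndarray, noise: float) -> np.ndarray:
        flips = rng.random(cfg.n_bits) < noise
        return np.where(flips, 1 - pattern, pattern).astype(np.uint8)

    def core(c: int, noise: float, drift: float = 0.0) -> np.ndarray:
        p = prototypes[c].copy()
        if drift > 0 and c in cliff_bits:
            mask = rng.random(cfg.n_cliff_bits) < drift
            p[cliff_bits[c][mask]] ^= 1
        return noisy(p, noise)

    def shell(c: int, noise: float) -> np.ndarray:
        p = prototypes[c].copy()
        p[cliff_bits[c]] ^= 1
        return noisy(p, noise)

    def inactive(near_miss_frac: float, shell_source: np.ndarray,
                 noise: float) -> np.ndarray:
        if len(shell_source) and rng.random() < near_miss_frac:
            return shell(int(rng.choice(shell_source)), noise)
        return noisy(prototypes[int(rng.choice(generic))], noise)

    nz = cfg.bit_flip_noise
    pos = [emit("pos", 1, core(int(rng.choice(active)), nz))
           for _ in range(cfg.n_pos)]
    neg = [emit("neg", 0, inactive(cfg.near_miss_fraction_negatives,
                                   observed, nz))
           for _ in range(cfg.n_true_neg)]
    put = [emit("put", 0, noisy(prototypes[int(rng.choice(generic))], nz))
           for _ in range(cfg.n_putative)]

    # Hidden actives in the unlabeled pool are structurally ordinary
    # members of the active chemotypes.
    n_contam = round(cfg.contamination * cfg.n_unlabeled)
    unl = [emit("unl", 1, core(int(rng.choice(active)), nz))
           for _ in range(n_contam)]
    unl += [emit("unl", 0, inactive(cfg.near_miss_fraction_unlabeled,
                                    cliffed, nz))
            for _ in range(cfg.n_unlabeled - n_contam)]
    tnz = nz * cfg.test_noise_factor
    test_pos = [emit("tpos", 1, core(int(rng.choice(active)), tnz,
                                     drift=min(1.0, rng.uniform(
                                         0, 2 * cfg.test_cliff_drift))))
                for _ in range(cfg.n_test_pos)]
    test_neg = [emit("tneg", 0, inactive(cfg.near_miss_fraction_test,
                                         cliffed, tnz))
                for _ in range(cfg.n_test_neg)]

    fps = FingerprintMatrix(
        ids, np.vstack(rows),
        FingerprintConfig(kind=FingerprintKind.OTHER, n_bits=cfg.n_bits))
    pools = PUPools(frozenset(pos), frozenset(neg), frozenset(put),
                    frozenset(unl))
    return SynthDataset(fps, pools, hidden, test_pos, test_neg, cfg)


def evaluate_against_truth(result: PredictionResult,
                           data: SynthDataset) -> MetricReport:
    """Confusion metrics of a prediction against the hidden ground truth."""
    missing = [i for i in result.ids if i not in data.hidden_labels]
    if missing:
        raise ValueError(f"ids absent from the synthetic corpus: {missing[:5]}")
    truth = np.array([data.hidden_labels[i] for i in result.ids], dtype=int)
    return confusion_metrics(truth, result.is_hit.astype(int))
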