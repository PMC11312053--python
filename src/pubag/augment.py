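"""Chemistry-space data pools for semi-supervised augmentation.

A large compound library is partitioned by k-means clustering of its
fingerprints. Two auxiliary training pools are then derived per target:

* **putative negatives** — one randomly drawn member of every cluster that
  contains no known active. The cluster-level absence of actives is the
  (fallible) evidence of inactivity.
* **unlabeled** — one representative member of *every* cluster, used by
  positive-unlabeled learners. Unlike putative negatives, this pool may
  legitimately contain actives.

Both pools are capped (default 50,000) by uniform subsampling to keep SVM
training tractable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from sklearn.cluster import KMeans

from .chem_io import LabeledDataset, canonical_smiles
from .featurize import FingerprintMatrix

logger = logging.getLogger(__name__)

DEFAULT_POOL_CAP = 50_000


@dataclass
class ClusterAssignment:
    """k-means cluster labels over a fingerprinted library."""

    ids: list[str]
    cluster_id: np.ndarray  # per-compound cluster index in [0, k)
    k: int
    seed: int
    distance_to_centroid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cluster_id = np.asarray(self.cluster_id, dtype=np.intp)
        if len(self.ids) != self.cluster_id.shape[0]:
            raise ValueError("ids and cluster_id must align")
        if self.cluster_id.size and self.cluster_id.max() >= self.k:
            raise ValueError("cluster_id out of range")

    def members(self, cluster: int) -> list[str]:
        return [cid for cid, c in zip(self.ids, self.cluster_id) if c == cluster]

    def cluster_of(self) -> dict[str, int]:
        return dict(zip(self.ids, self.cluster_id.tolist()))


@dataclass
class PUPools:
    """Disjoint positive / true-negative / putative-negative / unlabeled
    id sets over one featurized corpus."""

    positives: frozenset[str]
    true_negatives: frozenset[str]
    putative_negatives: frozenset[str] = frozenset()
    unlabeled: frozenset[str] = frozenset()
    cap: int = DEFAULT_POOL_CAP

    def __post_init__(self) -> None:
        self.positives = frozenset(self.positives)
        self.true_negatives = frozenset(self.true_negatives)
        self.putative_negatives = frozenset(self.putative_negatives)
        self.unlabeled = frozenset(self.unlabeled)
        sets = [self.positives, self.true_negatives,
                self.putative_negatives, self.unlabeled]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError("pool id sets must be pairwise disjoint")
        if len(self.putative_negatives) > self.cap or len(self.unlabeled) > self.cap:
            raise ValueError(f"putative/unlabeled pools exceed cap {self.cap}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "positives": sorted(self.positives),
            "true_negatives": sorted(self.true_negatives),
            "putative_negatives": sorted(self.putative_negatives),
            "unlabeled": sorted(self.unlabeled),
            "cap": self.cap,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PUPools":
        d = json.loads(Path(path).read_text())
        return cls(frozenset(d["positives"]), frozenset(d["true_negatives"]),
                   frozenset(d["putative_negatives"]), frozenset(d["unlabeled"]),
                   cap=d.get("cap", DEFAULT_POOL_CAP))


def default_k(n_compounds: int) -> int:
    """Desk-scale cluster count: one cluster per ~150 compounds, at least 10."""
    return min(n_compounds, max(10, n_compounds // 150))


def cluster_library(fps: FingerprintMatrix, k: int, seed: int) -> ClusterAssignment:
    """k-means clustering of the binary fingerprint matrix (treated as
    real-valued). Deterministic given the seed."""
    n = len(fps)
    if k > n:
        raise ValueError(f"k={k} exceeds number of compounds ({n})")
    if k < 1:
        raise ValueError("k must be positive")
    X = fps.bits.astype(np.float64)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    dists = np.linalg.norm(X - km.cluster_centers_[labels], axis=1)
    return ClusterAssignment(list(fps.ids), labels, k=k, seed=seed,
                             distance_to_centroid=dists)


def _subsample(ids: list[str], cap: int, rng: np.random.Generator) -> list[str]:
    if len(ids) <= cap:
        return ids
    idx = rng.choice(len(ids), size=cap, replace=False)
    return [ids[i] for i in sorted(idx)]


def build_putative_negatives(clusters: ClusterAssignment,
                             known_actives: Iterable[str],
                             seed: int,
                             cap: int = DEFAULT_POOL_CAP) -> frozenset[str]:
    """One random member per cluster containing no known active, capped.

    Returns an empty set (with a warning) when every cluster holds an
    active. Deterministic given the seed.
    """
    known_actives = set(known_actives)
    unknown = known_actives - set(clusters.ids)
    if unknown:
        raise ValueError(f"known actives not present in clustering: {sorted(unknown)}")
    active_clusters = {c for cid, c in zip(clusters.ids, clusters.cluster_id)
                       if cid in known_actives}
    rng = np.random.default_rng(seed)
    picks: list[str] = []
    by_cluster: dict[int, list[str]] = {}
    for cid, c in zip(clusters.ids, clusters.cluster_id.tolist()):
        by_cluster.setdefault(c, []).append(cid)
    for c in sorted(by_cluster):
        if c in active_clusters:
            continue
        members = sorted(by_cluster[c])
        picks.append(members[rng.integers(len(members))])
    if not picks:
        logger.warning("no active-free clusters: putative-negative set is empty")
        return frozenset()
    return frozenset(_subsample(picks, cap, rng))


def build_unlabeled(clusters: ClusterAssignment,
                    seed: int,
                    cap: int = DEFAULT_POOL_CAP) -> frozenset[str]:
    """One representative per cluster (member nearest its centroid, ties
    broken by lowest id), capped by uniform subsampling."""
    if not clusters.ids:
        return frozenset()
    if clusters.distance_to_centroid is None:
        # No geometry available: fall back to lowest id per cluster.
        dists = np.zeros(len(clusters.ids))
    else:
        dists = clusters.distance_to_centroid
    best: dict[int, tuple[float, str]] = {}
    for cid, c, d in zip(clusters.ids, clusters.cluster_id.tolist(), dists):
        key = (float(d), cid)
        if c not in best or key < best[c]:
            best[c] = key
    picks = [best[c][1] for c in sorted(best)]
    rng = np.random.default_rng(seed)
    return frozenset(_subsample(picks, cap, rng))


def assemble_pools(labeled: LabeledDataset,
                   putative: Iterable[str],
                   unlabeled: Iterable[str],
                   library_smiles: Mapping[str, str] | None = None,
                   cap: int = DEFAULT_POOL_CAP) -> PUPools:
    """Combine labeled data with augmentation pools, enforcing disjointness.

    Any putative/unlabeled id that collides with a labeled compound — by id,
    or by canonical structure when ``library_smiles`` provides id->SMILES for
    the pools — is removed (and logged). Putative ids are also removed from
    the unlabeled pool so the four sets partition cleanly.
    """
    positives = set(labeled.positives)
    negatives = set(labeled.negatives)
    labeled_ids = positives | negatives
    labeled_structures = {canonical_smiles(r.smiles) for r in labeled.records}
    labeled_structures.discard(None)

    def clash(cid: str) -> bool:
        if cid in labeled_ids:
            return True
        if library_smiles is not None and cid in library_smiles:
            return canonical_smiles(library_smiles[cid]) in labeled_structures
        return False

    putative = set(putative)
    unlabeled = set(unlabeled)
    removed_p = {i for i in putative if clash(i)}
    removed_u = {i for i in unlabeled if clash(i)}
    if removed_p or removed_u:
        logger.info("removed %d putative and %d unlabeled ids overlapping "
                    "labeled compounds", len(removed_p), len(removed_u))
    putative -= removed_p
    unlabeled -= removed_u
    overlap = putative & unlabeled
    if overlap:
        logger.info("removed %d unlabeled ids already used as putative "
                    "negatives", len(overlap))
        unlabeled -= overlap
    return PUPools(frozenset(positives), frozenset(negatives),
                   frozenset(putative), frozenset(unlabeled), cap=cap)
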