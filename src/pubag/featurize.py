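"""Molecular fingerprints and Tanimoto similarity.

Molecules are represented as fixed-length binary bit vectors. The default
representation is ECFP4 (extended-connectivity, Morgan radius 2, hashed to
2048 bits), the standard choice for ligand-based virtual screening. An
881-bit hashed substructure fingerprint is provided as an alternative, and
precomputed matrices of any other representation can be wrapped in a
:class:`FingerprintMatrix` directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem_io import CompoundRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FingerprintKind",
    "FingerprintConfig",
    "FingerprintMatrix",
    "fingerprint",
    "tanimoto",
    "bulk_tanimoto",
    "max_similarity_to_set",
]


class FingerprintKind(str, Enum):
    """Supported fingerprint families."""

    ECFP4 = "ecfp4"
    SUBSTRUCTURE_KEYS_881 = "substructure_keys_881"
    OTHER = "other"


@dataclass(frozen=True)
class FingerprintConfig:
    """Configuration of a binary fingerprint.

    Parameters
    ----------
    kind
        Fingerprint family. ``OTHER`` marks externally computed matrices;
        :func:`fingerprint` refuses it.
    n_bits
        Bit-vector width. For hashed kinds (ECFP4) this must be a power of
        two between 256 and 8192; the substructure-key kind is fixed at 881.
    radius
        Circular-environment radius for ECFP-style fingerprints (2 for ECFP4).
    """

    kind: FingerprintKind = FingerprintKind.ECFP4
    n_bits: int = 2048
    radius: int = 2

    def __post_init__(self) -> None:
        kind = FingerprintKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is FingerprintKind.ECFP4:
            if not (256 <= self.n_bits <= 8192 and (self.n_bits & (self.n_bits - 1)) == 0):
                raise ValueError(
                    f"n_bits for hashed fingerprints must be a power of two in "
                    f"[256, 8192], got {self.n_bits}"
                )
            if self.radius < 1:
                raise ValueError(f"radius must be >= 1, got {self.radius}")
        elif kind is FingerprintKind.SUBSTRUCTURE_KEYS_881:
            if self.n_bits != 881:
                raise ValueError("substructure-key fingerprints are fixed at 881 bits")

    def to_dict(self) -> dict:
        return {"kind": self.kind.value, "n_bits": self.n_bits, "radius": self.radius}

    @classmethod
    def from_dict(cls, d: dict) -> "FingerprintConfig":
        return cls(kind=FingerprintKind(d["kind"]), n_bits=int(d["n_bits"]),
                   radius=int(d.get("radius", 2)))


@dataclass
class FingerprintMatrix:
    """Binary fingerprint rows aligned to an ordered list of compound ids."""

    ids: list[str]
    bits: np.ndarray  # shape (len(ids), n_bits), dtype uint8, entries in {0, 1}
    config: FingerprintConfig
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.ids):
            raise ValueError("bits must be a 2-D matrix with one row per id")
        if self.bits.size and self.bits.max() > 1:
            raise ValueError("fingerprint entries must be binary")
        self._index = {cid: i for i, cid in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("compound ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_bits(self) -> int:
        return self.bits.shape[1]

    def row(self, compound_id: str) -> np.ndarray:
        return self.bits[self._index[compound_id]]

    def positions(self, ids: Iterable[str]) -> np.ndarray:
        return np.array([self._index[i] for i in ids], dtype=np.intp)

    def subset(self, ids: Sequence[str]) -> "FingerprintMatrix":
        ids = list(ids)
        return FingerprintMatrix(ids, self.bits[self.positions(ids)], self.config)

    # -- caching -----------------------------------------------------------

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.mtx`` (sparse bits), ``<prefix>.ids.txt`` and
        ``<prefix>.config.json``."""
        prefix = Path(prefix)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")),
                         scipy.sparse.csr_matrix(self.bits))
        prefix.with_suffix(".ids.txt").write_text("\n".join(self.ids) + "\n")
        prefix.with_suffix(".config.json").write_text(json.dumps(self.config.to_dict()))

    @classmethod
    def load(cls, prefix: str | Path) -> "FingerprintMatrix":
        prefix = Path(prefix)
        bits = np.asarray(
            scipy.io.mmread(str(prefix.with_suffix(".mtx"))).todense(), dtype=np.uint8
        )
        ids = prefix.with_suffix(".ids.txt").read_text().splitlines()
        config = FingerprintConfig.from_dict(
            json.loads(prefix.with_suffix(".config.json").read_text())
        )
        return cls(ids, bits, config)


def _fingerprint_mol(mol: Chem.Mol, cfg: FingerprintConfig) -> np.ndarray:
    if cfg.kind is FingerprintKind.ECFP4:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=cfg.radius,
                                                        fpSize=cfg.n_bits)
        fp = gen.GetFingerprint(mol)
    else:  # SUBSTRUCTURE_KEYS_881: hashed substructure (pattern) keys
        fp = Chem.PatternFingerprint(mol, fpSize=881)
    arr = np.zeros(cfg.n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def fingerprint(records: Sequence[CompoundRecord],
                cfg: FingerprintConfig | None = None) -> FingerprintMatrix:
    """Featurize compounds into a :class:`FingerprintMatrix`.

    Deterministic: the same records and config always produce the identical
    matrix. Raises ``ValueError`` listing the offending ids if any SMILES
    fails to parse, and for ``FingerprintKind.OTHER`` (precomputed matrices
    are constructed directly, not through this function).
    """
    cfg = cfg or FingerprintConfig()
    if cfg.kind is FingerprintKind.OTHER:
        raise ValueError("FingerprintKind.OTHER wraps precomputed matrices; "
                         "construct FingerprintMatrix directly")
    bad: list[str] = []
    rows: list[np.ndarray] = []
    ids: list[str] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            bad.append(rec.id)
            continue
        ids.append(rec.id)
        rows.append(_fingerprint_mol(mol, cfg))
    if bad:
        raise ValueError(f"invalid SMILES for ids: {bad}")
    bits = np.vstack(rows) if rows else np.zeros((0, cfg.n_bits), dtype=np.uint8)
    return FingerprintMatrix(ids, bits, cfg)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a∧b| / |a∨b| of two binary vectors.

    Two all-zero vectors are defined as identical (similarity 1.0); an
    all-zero vector against a non-empty one scores 0.0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    union = int(np.sum(a | b))
    if union == 0:
        return 1.0
    return int(np.sum(a & b)) / union


def bulk_tanimoto(query: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Tanimoto of one query vector against every row of ``reference``."""
    q = np.asarray(query, dtype=np.int64)
    ref = np.asarray(reference, dtype=np.int64)
    if ref.ndim != 2 or ref.shape[1] != q.shape[0]:
        raise ValueError("reference width does not match query length")
    inter = ref @ q
    union = ref.sum(axis=1) + q.sum() - inter
    out = np.ones(ref.shape[0], dtype=float)  # empty/empty convention
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


def max_similarity_to_set(query: np.ndarray, reference: FingerprintMatrix) -> float:
    """Maximal Tanimoto similarity of ``query`` over all reference compounds.

    This is the usual novelty measure: a low value means the query is
    structurally distant from every known reference compound.
    """
    if len(reference) == 0:
        raise ValueError("reference fingerprint set is empty")
    return float(bulk_tanimoto(query, reference.bits).max())
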