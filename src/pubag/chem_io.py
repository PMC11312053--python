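"""Reading compound libraries and bioactivity tables; binary activity labels.

Bioactivity is expressed as pChEMBL values: the negative base-10 logarithm
of a half-maximal response measurement (IC50, Ki, EC50, ...), so higher
means more potent. Continuous values are converted to binary classification
labels with a two-cutoff scheme: compounds above the positive cutoff are
actives, compounds below the negative cutoff are inactives, and the band in
between is excluded to keep assay noise away from the decision boundary.
Typical cutoffs are 7.5/6.5 for kinases and 7/6 for GPCRs.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# RDKit is extremely chatty about unparseable SMILES; we log rejections ourselves.
RDLogger.DisableLog("rdApp.error")

POSITIVE = "POSITIVE"
NEGATIVE = "NEGATIVE"

#: provenance tags for negative-class examples
TRUE = "TRUE"
PUTATIVE = "PUTATIVE"
UNLABELED_AS_NEGATIVE = "UNLABELED_AS_NEGATIVE"

KINASE_CUTOFFS = (7.5, 6.5)
GPCR_CUTOFFS = (7.0, 6.0)


@dataclass
class CompoundRecord:
    """A compound: opaque id, SMILES, and optional pChEMBL activity."""

    id: str
    smiles: str
    pchembl: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be non-empty")
        if self.pchembl is not None and self.pchembl < 0:
            raise ValueError(f"pChEMBL must be non-negative, got {self.pchembl}")


@dataclass(frozen=True)
class LabelingConfig:
    """Two-cutoff binarization of pChEMBL values (strict inequalities)."""

    positive_cutoff: float = 7.5
    negative_cutoff: float = 6.5

    def __post_init__(self) -> None:
        if not self.negative_cutoff < self.positive_cutoff:
            raise ValueError("negative_cutoff must be below positive_cutoff")


@dataclass
class LabeledDataset:
    """Binary-labeled compounds with per-record provenance.

    ``labels`` holds POSITIVE/NEGATIVE aligned 1:1 with ``records``;
    ``provenance`` records whether a negative is experimentally confirmed
    (TRUE), cluster-derived (PUTATIVE), or unlabeled-treated-as-negative.
    """

    records: list[CompoundRecord]
    labels: list[str]
    provenance: list[str] = field(default_factory=list)
    excluded_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.provenance:
            self.provenance = [TRUE] * len(self.records)
        if not (len(self.records) == len(self.labels) == len(self.provenance)):
            raise ValueError("records, labels and provenance must align 1:1")

    def ids_with_label(self, label: str) -> list[str]:
        return [r.id for r, l in zip(self.records, self.labels) if l == label]

    @property
    def positives(self) -> list[str]:
        return self.ids_with_label(POSITIVE)

    @property
    def negatives(self) -> list[str]:
        return self.ids_with_label(NEGATIVE)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "smiles", "pchembl", "label", "provenance"])
            for rec, lab, prov in zip(self.records, self.labels, self.provenance):
                w.writerow([rec.id, rec.smiles,
                            "" if rec.pchembl is None else rec.pchembl, lab, prov])

    @classmethod
    def from_csv(cls, path: str | Path) -> "LabeledDataset":
        records, labels, prov = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                records.append(CompoundRecord(
                    row["id"], row["smiles"],
                    float(row["pchembl"]) if row["pchembl"] else None))
                labels.append(row["label"])
                prov.append(row["provenance"])
        return cls(records, labels, prov)


def canonical_smiles(smiles: str) -> str | None:
    """Canonical SMILES, or None if the input does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


DEFAULT_COLUMN_MAP = {"id": "id", "smiles": "smiles", "pchembl": "pchembl"}


def read_bioactivity_csv(path: str | Path,
                         column_map: dict[str, str] | None = None
                         ) -> list[CompoundRecord]:
    """Read a ChEMBL-export-style bioactivity CSV.

    ``column_map`` maps the roles ``id``/``smiles``/``pchembl`` to the actual
    column names in the file. SMILES are canonicalized at read time, so
    duplicate detection is structure-based; duplicated compounds keep the
    first id seen, with conflicting pChEMBL measurements merged by median.
    Unparseable SMILES are dropped and counted.
    """
    colmap = dict(DEFAULT_COLUMN_MAP, **(column_map or {}))
    df = pd.read_csv(path)
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise KeyError(f"bioactivity CSV {path} lacks mapped columns: {missing}")
    if df.empty:
        logger.warning("bioactivity CSV %s is empty", path)
        return []

    n_invalid = 0
    by_structure: dict[str, dict] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        raw_smiles = str(row[colmap["smiles"]])
        can = canonical_smiles(raw_smiles)
        if can is None:
            n_invalid += 1
            logger.info("dropping unparseable SMILES %r (id %s)",
                        raw_smiles, row[colmap["id"]])
            continue
        pchembl = row[colmap["pchembl"]]
        pchembl = None if pd.isna(pchembl) else float(pchembl)
        entry = by_structure.get(can)
        if entry is None:
            by_structure[can] = {"id": str(row[colmap["id"]]), "values": []}
            order.append(can)
            entry = by_structure[can]
        elif str(row[colmap["id"]]) != entry["id"]:
            logger.info("duplicate structure %s: keeping first id %s, "
                        "dropping %s", can, entry["id"], row[colmap["id"]])
        if pchembl is not None:
            entry["values"].append(pchembl)
    if n_invalid:
        logger.warning("%s: dropped %d rows with unparseable SMILES", path, n_invalid)

    records = []
    for can in order:
        entry = by_structure[can]
        values = entry["values"]
        if len(set(values)) > 1:
            logger.info("id %s: merging %d pChEMBL measurements by median",
                        entry["id"], len(values))
        records.append(CompoundRecord(entry["id"], can,
                                      median(values) if values else None))
    return records


def label_bioactivity(records: Sequence[CompoundRecord],
                      cfg: LabelingConfig) -> LabeledDataset:
    """Binarize pChEMBL values with the two-cutoff scheme.

    Strictly above the positive cutoff -> POSITIVE; strictly below the
    negative cutoff -> NEGATIVE; anything in the closed in-between band
    (cutoff values included) is excluded and reported via
    ``LabeledDataset.excluded_ids``.
    """
    missing = [r.id for r in records if r.pchembl is None]
    if missing:
        raise ValueError(f"records without pChEMBL value: {missing}")
    out_records, labels, excluded = [], [], []
    for rec in records:
        if rec.pchembl > cfg.positive_cutoff:
            out_records.append(rec)
            labels.append(POSITIVE)
        elif rec.pchembl < cfg.negative_cutoff:
            out_records.append(rec)
            labels.append(NEGATIVE)
        else:
            excluded.append(rec.id)
    if excluded:
        logger.info("excluded %d compounds in the [%.2f, %.2f] ambiguity band",
                    len(excluded), cfg.negative_cutoff, cfg.positive_cutoff)
    return LabeledDataset(out_records, labels, [TRUE] * len(out_records),
                          excluded_ids=excluded)


def _read_smi(path: Path) -> list[CompoundRecord]:
    records, n_invalid = [], 0
    stem = path.name
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            cid = parts[1].strip() if len(parts) > 1 else f"{stem}:{i}"
            can = canonical_smiles(smiles)
            if can is None:
                n_invalid += 1
                continue
            records.append(CompoundRecord(cid, can))
    if n_invalid:
        logger.warning("%s: skipped %d invalid SMILES lines", path, n_invalid)
    return records


def _read_sdf(path: Path) -> list[CompoundRecord]:
    records, n_invalid = [], 0
    opener = gzip.open if path.name.endswith(".gz") else open
    with opener(path, "rb") as fh:
        supplier = Chem.ForwardSDMolSupplier(fh)
        for i, mol in enumerate(supplier):
            if mol is None:
                n_invalid += 1
                continue
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            cid = name.strip() or f"{path.name}:{i}"
            records.append(CompoundRecord(cid, Chem.MolToSmiles(mol)))
    if n_invalid:
        logger.warning("%s: skipped %d unreadable SDF entries", path, n_invalid)
    if not records:
        logger.warning("%s: no molecules read", path)
    return records


def read_library(path: str | Path) -> list[CompoundRecord]:
    """Read a screening/augmentation library (.smi, .smiles, .sdf, .sdf.gz).

    Returned records carry no pChEMBL value. Entries that fail to parse are
    skipped and counted; SDF molecules without a title get a synthesized
    ``<filename>:<index>`` id.
    """
    path = Path(path)
    name = path.name.lower()
    if name.endswith((".smi", ".smiles")):
        return _read_smi(path)
    if name.endswith((".sdf", ".sdf.gz")):
        return _read_sdf(path)
    raise ValueError(f"unrecognized library extension: {path.name} "
                     "(expected .smi, .smiles, .sdf or .sdf.gz)")
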