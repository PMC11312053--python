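"""Multitarget virtual screening: score, intersect, filter, report novelty.

A screening deck is scored by one ensemble per target; compounds whose
probability strictly exceeds the hit threshold (default 0.75) for *every*
target are multitarget hits. Hits are then filtered for drug-likeness
(Lipinski's rule of five in its at-most-one-violation form, and the Ghose
ranges as a hard pass) and optionally against named SMARTS alert catalogs
(PAINS-style reactive/promiscuous substructures). Finally, each surviving
hit's structural novelty is reported as its maximal Tanimoto similarity to
the known actives of each target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski

from .chem_io import CompoundRecord
from .featurize import FingerprintMatrix, fingerprint, max_similarity_to_set
from .learners import (EnsembleModel, PredictionResult, SCREENING_THRESHOLD,
                       load_model, predict)

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig", "MultiTargetHit", "ScreenResult", "FilterVerdict",
    "druglikeness_filter", "screen_deck", "novelty_report",
    "load_smarts_catalog", "DEMO_ALERTS",
]

#: tiny built-in demonstration alert catalog (real screens should load
#: full PAINS/Dundee/BMS catalogs from SMARTS files)
DEMO_ALERTS: dict[str, str] = {
    "nitro_aromatic": "c[N+](=O)[O-]",
    "acyl_halide": "C(=O)[Cl,Br,I]",
    "1,2-dicarbonyl": "C(=O)C(=O)",
}


def load_smarts_catalog(path: str | Path) -> dict[str, str]:
    """Read a catalog file of ``SMARTS<whitespace>name`` lines."""
    catalog: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        name = parts[1].strip() if len(parts) > 1 else f"alert_{i}"
        catalog[name] = parts[0]
    return catalog


@dataclass(frozen=True)
class ScreenConfig:
    """Targets (name -> fitted ensemble or saved-model directory), hit
    threshold, and filter switches."""

    targets: tuple[tuple[str, EnsembleModel | str], ...]
    hit_threshold: float = SCREENING_THRESHOLD
    lipinski: bool = True
    ghose: bool = True
    alert_catalogs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one target is required")
        if not (0 < self.hit_threshold < 1):
            raise ValueError("hit_threshold must lie in (0, 1)")


@dataclass
class FilterVerdict:
    """Per-compound drug-likeness verdict with reasons for failures."""

    id: str
    passed: bool
    flags: dict[str, bool]
    reasons: list[str] = field(default_factory=list)


@dataclass
class MultiTargetHit:
    id: str
    smiles: str
    probability: dict[str, float]
    max_tanimoto: dict[str, float] = field(default_factory=dict)
    passed_filters: bool = True
    filter_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class ScreenResult:
    per_target: dict[str, PredictionResult]
    hits: list[MultiTargetHit]
    n_intersection_prefilter: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for h in self.hits:
            row = {"id": h.id, "smiles": h.smiles}
            row.update({f"prob_{t}": p for t, p in h.probability.items()})
            row.update({f"max_tanimoto_{t}": v for t, v in h.max_tanimoto.items()})
            row.update({f"pass_{k}": v for k, v in h.filter_flags.items()})
            row["passed_filters"] = h.passed_filters
            rows.append(row)
        return pd.DataFrame(rows)


def _lipinski(mol: Chem.Mol) -> tuple[bool, list[str]]:
    violations = []
    if Descriptors.MolWt(mol) > 500:
        violations.append("MW > 500")
    if Crippen.MolLogP(mol) > 5:
        violations.append("logP > 5")
    if Lipinski.NumHDonors(mol) > 5:
        violations.append("H-bond donors > 5")
    if Lipinski.NumHAcceptors(mol) > 10:
        violations.append("H-bond acceptors > 10")
    # the customary reading: a compound may break at most one of the four
    return len(violations) <= 1, violations


def _ghose(mol: Chem.Mol) -> tuple[bool, list[str]]:
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    n_atoms = Chem.AddHs(mol).GetNumAtoms()
    mr = Crippen.MolMR(mol)
    violations = []
    if not 160 <= mw <= 480:
        violations.append(f"MW {mw:.1f} outside [160, 480]")
    if not -0.4 <= logp <= 5.6:
        violations.append(f"logP {logp:.2f} outside [-0.4, 5.6]")
    if not 20 <= n_atoms <= 70:
        violations.append(f"atom count {n_atoms} outside [20, 70]")
    if not 40 <= mr <= 130:
        violations.append(f"molar refractivity {mr:.1f} outside [40, 130]")
    return not violations, violations


def druglikeness_filter(records: Sequence[CompoundRecord],
                        lipinski: bool = True,
                        ghose: bool = True,
                        alert_catalogs: Sequence[str] = (),
                        catalogs: Mapping[str, Mapping[str, str]] | None = None,
                        ) -> list[FilterVerdict]:
    """Medicinal-chemistry filters with per-record pass/fail and reasons.

    ``alert_catalogs`` names entries of ``catalogs`` (a mapping of catalog
    name -> {alert name -> SMARTS}); the built-in ``demo`` catalog is always
    available. A compound fails a catalog if any of its SMARTS matches.
    """
    catalogs = dict(catalogs or {})
    catalogs.setdefault("demo", DEMO_ALERTS)
    unknown = [c for c in alert_catalogs if c not in catalogs]
    if unknown:
        raise KeyError(f"unknown alert catalog(s): {unknown}")
    compiled = {
        name: [(aname, Chem.MolFromSmarts(s))
               for aname, s in catalogs[name].items()]
        for name in alert_catalogs
    }
    verdicts = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles)
        if mol is None:
            verdicts.append(FilterVerdict(rec.id, False, {},
                                          ["unparseable SMILES"]))
            continue
        flags: dict[str, bool] = {}
        reasons: list[str] = []
        if lipinski:
            ok, viol = _lipinski(mol)
            flags["lipinski"] = ok
            if not ok:
                reasons.append("Lipinski: " + "; ".join(viol))
        if ghose:
            ok, viol = _ghose(mol)
            flags["ghose"] = ok
            if not ok:
                reasons.append("Ghose: " + "; ".join(viol))
        for cname, patterns in compiled.items():
            matched = [aname for aname, patt in patterns
                       if patt is not None and mol.HasSubstructMatch(patt)]
            flags[cname] = not matched
            if matched:
                reasons.append(f"{cname} alerts: {', '.join(matched)}")
        verdicts.append(FilterVerdict(rec.id, all(flags.values()), flags, reasons))
    return verdicts


def _resolve_models(cfg: ScreenConfig) -> list[tuple[str, EnsembleModel]]:
    models = []
    for name, model in cfg.targets:
        if not isinstance(model, EnsembleModel):
            model = load_model(model)
        models.append((name, model))
    widths = {m.feature_config.n_bits for _, m in models
              if m.feature_config is not None}
    kinds = {m.feature_config.kind for _, m in models
             if m.feature_config is not None}
    if len(widths) > 1 or len(kinds) > 1:
        raise ValueError("all target models must share one fingerprint config")
    return models


def screen_deck(deck: Sequence[CompoundRecord] | FingerprintMatrix,
                cfg: ScreenConfig,
                catalogs: Mapping[str, Mapping[str, str]] | None = None,
                ) -> ScreenResult:
    """Score a deck against every target and intersect the hit lists.

    ``deck`` may be compound records (fingerprinted here with the models'
    shared config) or an already-featurized matrix. Filters are applied to
    the intersection; the pre-filter intersection size is retained so both
    counts are reported.
    """
    models = _resolve_models(cfg)
    if isinstance(deck, FingerprintMatrix):
        fps = deck
        smiles = {}
    else:
        feature_cfg = models[0][1].feature_config
        fps = fingerprint(deck, feature_cfg)
        smiles = {r.id: r.smiles for r in deck}
    if len(fps) == 0:
        return ScreenResult({name: PredictionResult([], [], [], cfg.hit_threshold)
                             for name, _ in models}, [], 0)

    per_target = {name: predict(model, fps, threshold=cfg.hit_threshold)
                  for name, model in models}
    hit_sets = [set(res.hits()) for res in per_target.values()]
    intersection = sorted(set.intersection(*hit_sets))
    logger.info("per-target hit counts %s; intersection %d",
                {n: len(r.hits()) for n, r in per_target.items()},
                len(intersection))

    records = [CompoundRecord(i, smiles.get(i, "")) for i in intersection]
    if smiles and (cfg.lipinski or cfg.ghose or cfg.alert_catalogs):
        verdicts = {v.id: v for v in druglikeness_filter(
            records, lipinski=cfg.lipinski, ghose=cfg.ghose,
            alert_catalogs=cfg.alert_catalogs, catalogs=catalogs)}
    else:
        verdicts = {}

    hits = []
    for cid in intersection:
        idx = {name: res.ids.index(cid) for name, res in per_target.items()}
        verdict = verdicts.get(cid)
        hits.append(MultiTargetHit(
            id=cid,
            smiles=smiles.get(cid, ""),
            probability={name: float(res.probability[idx[name]])
                         for name, res in per_target.items()},
            passed_filters=verdict.passed if verdict else True,
            filter_flags=verdict.flags if verdict else {},
        ))
    kept = [h for h in hits if h.passed_filters]
    logger.info("filters kept %d of %d intersecting hits", len(kept), len(hits))
    return ScreenResult(per_target, kept, n_intersection_prefilter=len(hits))


def novelty_report(hits: Sequence[MultiTargetHit],
                   known_actives: Mapping[str, FingerprintMatrix],
                   deck_fps: FingerprintMatrix | None = None,
                   ) -> pd.DataFrame:
    """Maximal Tanimoto similarity of each hit to each target's known
    actives (one row per hit, one column per target). Low values indicate
    structurally novel chemotypes."""
    for name, ref in known_actives.items():
        if len(ref) == 0:
            raise ValueError(f"known-active set for target {name!r} is empty")
    rows = {}
    for hit in hits:
        if deck_fps is not None:
            query = deck_fps.row(hit.id)
        else:
            ref0 = next(iter(known_actives.values()))
            query = fingerprint([CompoundRecord(hit.id, hit.smiles)],
                                ref0.config).bits[0]
        row = {}
        for name, ref in known_actives.items():
            sim = max_similarity_to_set(query, ref)
            row[name] = sim
            hit.max_tanimoto[name] = sim
        rows[hit.id] = row
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=list(known_actives))
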