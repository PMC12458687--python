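"""Proteome-wide screening of predicted structure models.

Workflow: trim annotated signal peptides, drop models under 100 residues
or with mean pLDDT under 70, detect pockets on every surviving model,
score each pocket with the trained classifier, and report the best pocket
probability as the protein score.  Proteins scoring at or above the
threshold (default 0.5) are hits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from lipocket.classifier import TrainedModel
from lipocket.descriptors import DEFAULT_SCALES, compute_descriptors
from lipocket.pocket_detection import detect_pockets
from lipocket.structure_io import StructureModel, mean_plddt, trim_n_terminal

__all__ = [
    "ProteinPrediction",
    "filter_proteome",
    "score_protein",
    "rank_hits",
    "scan_proteome",
]

MIN_LENGTH_DEFAULT = 100
MIN_PLDDT_DEFAULT = 70.0
HIT_THRESHOLD_DEFAULT = 0.5

STATUSES = ("scored", "filtered_length", "filtered_plddt", "no_pockets",
            "detection_error")


@dataclass(frozen=True)
class ProteinPrediction:
    protein_id: str
    n_residues: int
    mean_plddt: float | None
    n_pockets: int
    best_pocket_id: int | None
    score: float | None
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if (self.score is not None) != (self.status == "scored"):
            raise ValueError("score present iff status == 'scored'")


def filter_proteome(
    models: Iterable[StructureModel],
    min_len: int = MIN_LENGTH_DEFAULT,
    min_plddt: float = MIN_PLDDT_DEFAULT,
) -> tuple[list[StructureModel], dict]:
    """Remove short and low-confidence models ("less than" is strict:
    a 100-residue model and a mean pLDDT of exactly 70 are kept).

    Returns the kept models and a report tallying removals by reason.
    """
    kept: list[StructureModel] = []
    report = {"input": 0, "kept": 0,
              "filtered_length": 0, "filtered_plddt": 0}
    for model in models:
        report["input"] += 1
        if model.n_residues < min_len:
            report["filtered_length"] += 1
            continue
        if mean_plddt(model) < min_plddt:
            report["filtered_plddt"] += 1
            continue
        kept.append(model)
        report["kept"] += 1
    return kept, report


def score_protein(
    structure: StructureModel,
    model: TrainedModel,
    detection_config: Mapping | None = None,
    descriptor_config: Mapping | None = None,
    seed: int = 0,
) -> tuple[ProteinPrediction, pd.DataFrame]:
    """Detect, describe, and score every pocket of one model.

    The protein score is the maximum pocket probability; its pocket id is
    reported as ``best_pocket_id``.  A model with no detected pockets gets
    status ``no_pockets``; detection failures are recorded in the status,
    never raised, so a proteome scan survives individual bad models.
    Returns the prediction and the per-pocket score table.
    """
    det_cfg = dict(detection_config or {})
    desc_cfg = dict(descriptor_config or {})
    desc_cfg.setdefault("scales", DEFAULT_SCALES)
    desc_cfg.setdefault("mc_samples", 20_000)
    try:
        pockets = detect_pockets(structure, **det_cfg)
    except Exception:
        return (ProteinPrediction(
            protein_id=structure.source_id, n_residues=structure.n_residues,
            mean_plddt=_safe_plddt(structure), n_pockets=0,
            best_pocket_id=None, score=None, status="detection_error"),
            pd.DataFrame())
    if not pockets:
        return (ProteinPrediction(
            protein_id=structure.source_id, n_residues=structure.n_residues,
            mean_plddt=_safe_plddt(structure), n_pockets=0,
            best_pocket_id=None, score=None, status="no_pockets"),
            pd.DataFrame())

    rows = []
    for pocket in pockets:
        vec = compute_descriptors(
            pocket, structure, seed=seed + pocket.pocket_id, **desc_cfg)
        prob = model.predict_proba(vec.as_array()[None, :])[0]
        rows.append({"pocket_id": pocket.pocket_id, "score": float(prob),
                     **vec.as_dict()})
    pocket_table = pd.DataFrame(rows)
    best = pocket_table.loc[pocket_table["score"].idxmax()]
    return (ProteinPrediction(
        protein_id=structure.source_id, n_residues=structure.n_residues,
        mean_plddt=_safe_plddt(structure), n_pockets=len(pockets),
        best_pocket_id=int(best["pocket_id"]), score=float(best["score"]),
        status="scored"),
        pocket_table)


def _safe_plddt(structure: StructureModel) -> float | None:
    if structure.model_kind != "predicted":
        return None
    try:
        return mean_plddt(structure)
    except Exception:
        return None


def rank_hits(
    predictions: Sequence[ProteinPrediction],
    threshold: float = HIT_THRESHOLD_DEFAULT,
) -> tuple[pd.DataFrame, dict]:
    """Rank scored proteins and summarize the hit rate.

    Hits score at or above ``threshold`` (inclusive).  The summary's
    ``hit_pct`` is the percentage of scored proteins that are hits,
    rounded to one decimal (round-half-even).
    """
    rows = [{
        "protein_id": p.protein_id, "score": p.score,
        "best_pocket_id": p.best_pocket_id, "n_pockets": p.n_pockets,
        "n_residues": p.n_residues, "mean_plddt": p.mean_plddt,
        "status": p.status,
    } for p in predictions]
    df = pd.DataFrame(rows, columns=[
        "protein_id", "score", "best_pocket_id", "n_pockets",
        "n_residues", "mean_plddt", "status"])
    scored = df[df["status"] == "scored"].sort_values(
        ["score", "protein_id"], ascending=[False, True]).reset_index(drop=True)
    scored["hit"] = scored["score"] >= threshold
    n_scored = len(scored)
    n_hits = int(scored["hit"].sum())
    summary = {
        "n_input": len(df),
        "n_scored": n_scored,
        "n_hits": n_hits,
        "hit_pct": round(100.0 * n_hits / n_scored, 1) if n_scored else 0.0,
        "threshold": threshold,
    }
    unscored = df[df["status"] != "scored"]
    ranked = pd.concat([scored, unscored], ignore_index=True)
    return ranked, summary


def scan_proteome(
    models: Iterable[StructureModel],
    model: TrainedModel,
    signal_peptides: Mapping[str, int] | None = None,
    min_len: int = MIN_LENGTH_DEFAULT,
    min_plddt: float = MIN_PLDDT_DEFAULT,
    threshold: float = HIT_THRESHOLD_DEFAULT,
    detection_config: Mapping | None = None,
    descriptor_config: Mapping | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
    keep_pockets: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """End-to-end scan: trim, filter, score, rank.

    Signal peptides are trimmed before length filtering.  Per-protein
    results are order-independent: scanning any subset in any order gives
    identical rows.  With ``out_dir`` the ranked TSV and summary JSON are
    written; ``keep_pockets`` additionally saves per-pocket descriptor
    tables.
    """
    signal_peptides = signal_peptides or {}
    trimmed = []
    for m in models:
        cut = signal_peptides.get(m.source_id, 0)
        trimmed.append(trim_n_terminal(m, cut) if cut else m)

    kept, filter_report = filter_proteome(trimmed, min_len, min_plddt)
    filtered_ids = {m.source_id for m in kept}

    predictions: list[ProteinPrediction] = []
    pocket_tables: dict[str, pd.DataFrame] = {}
    for m in trimmed:
        if m.source_id not in filtered_ids:
            status = ("filtered_length" if m.n_residues < min_len
                      else "filtered_plddt")
            predictions.append(ProteinPrediction(
                protein_id=m.source_id, n_residues=m.n_residues,
                mean_plddt=_safe_plddt(m), n_pockets=0,
                best_pocket_id=None, score=None, status=status))
            continue
        pred, ptable = score_protein(
            m, model, detection_config, descriptor_config, seed=seed)
        predictions.append(pred)
        if keep_pockets and len(ptable):
            pocket_tables[m.source_id] = ptable

    ranked, summary = rank_hits(
        [p for p in predictions], threshold=threshold)
    summary["filter_report"] = filter_report

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ranked.to_csv(out_dir / "ranked.tsv", sep="\t", index=False)
        (out_dir / "summary.json").write_text(
            json.dumps(summary, indent=2) + "\n")
        if keep_pockets:
            pdir = out_dir / "pockets"
            pdir.mkdir(exist_ok=True)
            for pid, ptable in pocket_tables.items():
                ptable.to_csv(pdir / f"{pid}.tsv", sep="\t", index=False)
    return ranked, summary
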