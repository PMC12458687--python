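"""Dataset assembly: labeling pockets against bound ligands, balancing the
pseudo-pocket majority class, and stratified train/test splitting.

Labels:
  LBP  -- pocket matched to a lipid-class ligand (CLR, MYR, PLM, STE, OLA)
  nLBP -- pocket matched to a non-lipid ligand (ADN, B12, BGC, COA)
  HEME -- pocket matched to HEM (kept in the schema, excluded from default
          training)
  PP   -- pseudo pocket: a detected pocket that overlaps no ligand; the
          dominant negative class
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from lipocket.descriptors import DESCRIPTOR_NAMES, PocketDescriptorVector
from lipocket.pocket_detection import Pocket
from lipocket.structure_io import LigandInstance

__all__ = [
    "LIPID_COMP_IDS",
    "NONLIPID_COMP_IDS",
    "HEME_COMP_IDS",
    "LabeledPocket",
    "DescriptorTable",
    "label_pockets",
    "assemble_dataset",
    "subsample_pseudo",
    "stratified_split",
]

LIPID_COMP_IDS = frozenset({"CLR", "MYR", "PLM", "STE", "OLA"})
NONLIPID_COMP_IDS = frozenset({"ADN", "B12", "BGC", "COA"})
HEME_COMP_IDS = frozenset({"HEM"})

LABELS = ("LBP", "nLBP", "PP", "HEME")

#: per-ligand-class minimum structure count recommended for curation
MIN_STRUCTURES_PER_LIGAND = 20


def _label_for_comp(comp_id: str) -> str:
    if comp_id in LIPID_COMP_IDS:
        return "LBP"
    if comp_id in HEME_COMP_IDS:
        return "HEME"
    return "nLBP"


@dataclass(frozen=True)
class LabeledPocket:
    descriptor: PocketDescriptorVector
    label: str
    source_structure: str
    pocket_id: int
    matched_ligand: str | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if (self.label == "PP") != (self.matched_ligand is None):
            raise ValueError("PP label must carry no matched ligand and "
                             "vice versa")


class DescriptorTable:
    """Labeled descriptor rows, backed by a pandas DataFrame.

    Columns: ``structure_id``, ``pocket_id``, the 17 descriptor names,
    ``label``, ``matched_ligand``.
    """

    COLUMNS = ("structure_id", "pocket_id", *DESCRIPTOR_NAMES,
               "label", "matched_ligand")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"descriptor table missing columns: {missing}")
        dup = df.duplicated(subset=["structure_id", "pocket_id"])
        if dup.any():
            pairs = df.loc[dup, ["structure_id", "pocket_id"]]
            raise ValueError(
                f"duplicate (structure, pocket) rows: {pairs.values.tolist()[:5]}")
        self.df = df.reset_index(drop=True)[list(self.COLUMNS)]

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_labeled(cls, rows: Iterable[LabeledPocket]) -> "DescriptorTable":
        records = []
        for r in rows:
            rec = {"structure_id": r.source_structure, "pocket_id": r.pocket_id,
                   **r.descriptor.as_dict(), "label": r.label,
                   "matched_ligand": r.matched_ligand}
            records.append(rec)
        df = pd.DataFrame(records, columns=list(cls.COLUMNS))
        return cls(df)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DescriptorTable":
        df = pd.read_csv(path, sep="\t")
        if "matched_ligand" in df.columns:
            df["matched_ligand"] = df["matched_ligand"].where(
                df["matched_ligand"].notna(), None)
        return cls(df)

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    def write_manifest(self, path: str | Path, **extra) -> None:
        payload = {"n_rows": len(self.df),
                   "class_counts": self.class_counts, **extra}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    # -- views -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def class_counts(self) -> dict[str, int]:
        counts = self.df["label"].value_counts().to_dict()
        return {k: int(counts.get(k, 0)) for k in LABELS if counts.get(k, 0)}

    def features(self, feature_names: Sequence[str] = DESCRIPTOR_NAMES) -> np.ndarray:
        return self.df[list(feature_names)].to_numpy(dtype=float)

    def binary_labels(self, positive: str = "LBP") -> np.ndarray:
        """1 for the positive class, 0 otherwise (nLBP and PP jointly
        negative, mirroring how the classifier is framed)."""
        return (self.df["label"] == positive).to_numpy(dtype=int)

    def drop_label(self, label: str) -> "DescriptorTable":
        return DescriptorTable(self.df[self.df["label"] != label])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def label_pockets(
    pockets: Sequence[Pocket],
    ligands: Sequence[LigandInstance],
    contact_cutoff: float = 3.0,
) -> list[tuple[Pocket, str, str | None]]:
    """Assign a class to each pocket by geometric overlap with ligands.

    A pocket matches a ligand iff at least one alpha-sphere center lies
    within ``contact_cutoff`` of any ligand heavy atom; the nearest ligand
    wins multi-matches (ties by comp_id).  Unmatched pockets are pseudo
    pockets (PP).  Returns ``(pocket, label, matched_comp_id)`` triples.
    """
    out = []
    for pocket in pockets:
        centers = pocket.sphere_centers()
        best: tuple[float, str] | None = None
        for lig in ligands:
            lcoords = np.array([a.coords for a in lig.atoms], dtype=float)
            d = np.linalg.norm(
                centers[:, None, :] - lcoords[None, :, :], axis=2).min()
            if d <= contact_cutoff:
                cand = (float(d), lig.comp_id)
                if best is None or cand < best:
                    best = cand
        if best is None:
            out.append((pocket, "PP", None))
        else:
            out.append((pocket, _label_for_comp(best[1]), best[1]))
    return out


def assemble_dataset(
    labeled_sets: Iterable[Iterable[LabeledPocket] | DescriptorTable],
) -> DescriptorTable:
    """Concatenate labeled sets, deduplicate identical rows, and recount.

    The same (structure, pocket) appearing with conflicting labels is a
    curation inconsistency and raises.
    """
    frames = []
    for s in labeled_sets:
        if isinstance(s, DescriptorTable):
            frames.append(s.df)
        else:
            frames.append(DescriptorTable.from_labeled(list(s)).df)
    if not frames:
        return DescriptorTable(pd.DataFrame(columns=list(DescriptorTable.COLUMNS)))
    df = pd.concat(frames, ignore_index=True)
    key = ["structure_id", "pocket_id"]
    labels_per_key = df.groupby(key)["label"].nunique()
    conflicts = labels_per_key[labels_per_key > 1]
    if len(conflicts):
        raise ValueError(
            f"conflicting labels for pockets: {list(conflicts.index)[:5]}")
    df = df.drop_duplicates(subset=key, keep="first")
    return DescriptorTable(df)


def subsample_pseudo(
    table: DescriptorTable,
    ratio: float | str,
    seed: int = 0,
) -> DescriptorTable:
    """Downsample pseudo pockets to ``round(ratio x LBP count)`` rows.

    ``ratio="full"`` is the identity; ``ratio=1`` gives the balanced set,
    5 and 20 the intermediate imbalance regimes.  LBP/nLBP/HEME rows are
    untouched; sampling is without replacement and seeded.
    """
    if ratio == "full":
        return DescriptorTable(table.df)
    ratio = float(ratio)
    if ratio <= 0:
        raise ValueError("ratio must be positive or 'full'")
    n_lbp = int((table.df["label"] == "LBP").sum())
    if n_lbp == 0:
        raise ValueError("table has no LBP rows to balance against")
    pp = table.df[table.df["label"] == "PP"]
    keep_n = min(len(pp), round(ratio * n_lbp))
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(pp.index.to_numpy(), size=keep_n, replace=False)
    mask = (table.df["label"] != "PP") | table.df.index.isin(keep_idx)
    return DescriptorTable(table.df[mask])


def stratified_split(
    table: DescriptorTable,
    test_fraction: float,
    seed: int = 0,
) -> tuple[DescriptorTable, DescriptorTable]:
    """Per-class random split; train and test partition the table exactly."""
    if not 0 <= test_fraction < 1:
        raise ValueError("test_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for label, group in table.df.groupby("label"):
        if len(group) < 2 and test_fraction > 0:
            raise ValueError(
                f"class {label!r} has {len(group)} row(s); cannot stratify")
        n_test = round(test_fraction * len(group))
        chosen = rng.choice(group.index.to_numpy(), size=n_test, replace=False)
        test_idx.extend(int(i) for i in chosen)
    mask = table.df.index.isin(test_idx)
    return (DescriptorTable(table.df[~mask]), DescriptorTable(table.df[mask]))


def curation_report(tables: dict[str, DescriptorTable]) -> dict:
    """Counts per named subset plus warnings for thin ligand classes."""
    report: dict = {"subsets": {}, "warnings": []}
    for name, t in tables.items():
        report["subsets"][name] = t.class_counts
        lig_counts = t.df["matched_ligand"].value_counts()
        for comp, cnt in lig_counts.items():
            n_struct = t.df[t.df["matched_ligand"] == comp]["structure_id"].nunique()
            if n_struct < MIN_STRUCTURES_PER_LIGAND:
                report["warnings"].append(
                    f"{name}: ligand {comp} seen in only {n_struct} structures "
                    f"(<{MIN_STRUCTURES_PER_LIGAND})")
    report["total"] = int(sum(len(t) for t in tables.values()))
    return report
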