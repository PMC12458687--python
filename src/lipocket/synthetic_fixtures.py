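"""Synthetic test inputs: toy cavity structures and descriptor corpora.

Two generators make the whole pipeline testable offline:

* :func:`make_cavity_structure` builds a pseudo-protein whose heavy atoms
  line a spherical cavity, optionally with a planted ligand at the cavity
  center — enough geometry for pocket detection, labeling, and the
  proteome-scan contracts, with no pretense of backbone realism.
* :func:`make_descriptor_table` draws class-conditional descriptor rows
  from diagonal Gaussians, with the lipid-binding class shifted toward
  higher hydrophobicity — the statistical fingerprint the real corpus
  shows — so classifier and metric behavior can be exercised at any
  problem size.

All randomness flows from a single seed per spec, so fixtures are
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from lipocket.dataset_curation import DescriptorTable
from lipocket.descriptors import DESCRIPTOR_NAMES
from lipocket.structure_io import AtomRecord, StructureModel, write_pdb

__all__ = [
    "CavitySpec",
    "TableSpec",
    "make_cavity_structure",
    "make_descriptor_table",
    "default_corpus",
]

# element used for each pseudo-residue's single heavy atom: carbon for
# hydrophobic residues, oxygen for polar-neutral, nitrogen for charged
_RESIDUE_ELEMENT = {
    "ALA": "C", "VAL": "C", "LEU": "C", "ILE": "C", "PHE": "C", "MET": "C",
    "TRP": "C", "PRO": "C", "GLY": "C", "CYS": "C",
    "SER": "O", "THR": "O", "ASN": "O", "GLN": "O", "TYR": "O",
    "ASP": "N", "GLU": "N", "LYS": "N", "ARG": "N", "HIS": "N",
}

DEFAULT_LINING = {"LEU": 0.25, "ILE": 0.15, "PHE": 0.15, "VAL": 0.15,
                  "SER": 0.10, "THR": 0.10, "ASP": 0.05, "LYS": 0.05}

MIN_ATOM_SEPARATION = 1.5


@dataclass(frozen=True)
class CavitySpec:
    """Geometry of a toy cavity structure.

    Atoms fill the shell volume between ``cavity_radius`` and
    ``shell_radius`` (concentrated near the cavity boundary so the cavity
    is lined), leaving an empty interior where alpha spheres can form.
    """

    shell_radius: float = 12.0
    n_shell_atoms: int = 60
    cavity_radius: float = 5.0
    lining_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LINING))
    planted_ligand: str | None = None
    plddt: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cavity_radius >= self.shell_radius:
            raise ValueError("cavity_radius must be < shell_radius")
        if self.n_shell_atoms < 20:
            raise ValueError("need at least 20 shell atoms")


def _shell_points(spec: CavitySpec, jitter: float,
                  rng: np.random.Generator) -> np.ndarray | None:
    """Jittered grid points in the shell volume, the ``n_shell_atoms``
    closest to the cavity boundary; None if min separation is violated."""
    spacing = 2.8
    r = np.arange(-spec.shell_radius, spec.shell_radius + spacing, spacing)
    gx, gy, gz = np.meshgrid(r, r, r, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    dist = np.linalg.norm(grid, axis=1)
    shell = grid[(dist >= spec.cavity_radius + 0.5 * spacing)
                 & (dist <= spec.shell_radius)]
    if len(shell) < spec.n_shell_atoms:
        raise ValueError("shell too thin for the requested atom count")
    order = np.argsort(np.linalg.norm(shell, axis=1))
    pts = shell[order[: spec.n_shell_atoms]].astype(float)
    pts = pts + rng.uniform(-jitter, jitter, size=pts.shape)
    # reject configurations with clashing atoms or cavity intrusions
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < MIN_ATOM_SEPARATION:
        return None
    if np.linalg.norm(pts, axis=1).min() < spec.cavity_radius:
        return None
    return pts


def make_cavity_structure(
    spec: CavitySpec,
    out_path: str | Path | None = None,
) -> StructureModel:
    """Build a toy structure with an engineered interior cavity.

    Each heavy atom is its own pseudo-residue; residue identities are
    drawn from ``lining_composition`` and the atom's element follows the
    residue's character (C hydrophobic, O polar, N charged).  An optional
    ligand is planted as a small carbon cluster at the cavity center.
    If jittered placement clashes (atoms closer than 1.5 A), the jitter is
    reduced and placement retried, failing after 10 attempts.
    """
    rng = np.random.default_rng(spec.seed)
    jitter = 0.9
    pts = None
    for _ in range(10):
        pts = _shell_points(spec, jitter, rng)
        if pts is not None:
            break
        jitter *= 0.7
    if pts is None:
        raise ValueError("could not place shell atoms without clashes")

    names = list(spec.lining_composition)
    probs = np.array([spec.lining_composition[n] for n in names], dtype=float)
    probs = probs / probs.sum()
    residues = rng.choice(names, size=len(pts), p=probs)

    atoms: list[AtomRecord] = []
    for i, (pt, res) in enumerate(zip(pts, residues), start=1):
        el = _RESIDUE_ELEMENT[res]
        atoms.append(AtomRecord(
            serial=i, name="CA" if el == "C" else el, element=el,
            residue_name=res, chain_id="A", residue_index=i,
            coords=tuple(float(c) for c in pt),
            b_factor=spec.plddt, is_hetero=False))

    if spec.planted_ligand is not None:
        # a compact heavy-atom cluster at the cavity center
        offsets = np.array([
            [0.0, 0.0, 0.0], [1.2, 0.0, 0.0], [0.0, 1.2, 0.0],
            [0.0, 0.0, 1.2], [-1.2, 0.0, 0.0]])
        for k, off in enumerate(offsets, start=1):
            atoms.append(AtomRecord(
                serial=len(pts) + k, name=f"C{k}", element="C",
                residue_name=spec.planted_ligand.upper(), chain_id="L",
                residue_index=901,
                coords=tuple(float(c) for c in off),
                b_factor=spec.plddt, is_hetero=True))

    model = StructureModel(
        atoms=atoms, source_id=f"cavity-{spec.seed}", model_kind="predicted")
    if out_path is not None:
        write_pdb(model, out_path)
    return model


# ---------------------------------------------------------------------------
# descriptor corpora
# ---------------------------------------------------------------------------

# baseline (pseudo-pocket) descriptor means and spreads, in descriptor
# units; chosen to resemble small-to-medium surface pockets
_BASE_MEAN = {
    "pock_vol": 300.0, "nb_AS": 40.0, "surf_vdw": 250.0,
    "surf_pol_vdw": 100.0, "surf_apol_vdw": 150.0,
    "hydrophobicity_score": 10.0, "mean_loc_hyd_dens": 15.0,
    "apol_as_prop": 0.5, "prop_polar_atm": 0.45, "mean_as_solv_acc": 0.45,
    "as_dens": 6.0, "as_max_dst": 15.0, "volume_score": 130.0,
    "polarity_score": 15.0, "charge_score": 0.0, "flex": 1.0,
    "n_apol_as": 20.0,
}
_BASE_SD = {
    "pock_vol": 150.0, "nb_AS": 15.0, "surf_vdw": 80.0,
    "surf_pol_vdw": 40.0, "surf_apol_vdw": 60.0,
    "hydrophobicity_score": 15.0, "mean_loc_hyd_dens": 5.0,
    "apol_as_prop": 0.12, "prop_polar_atm": 0.10, "mean_as_solv_acc": 0.10,
    "as_dens": 1.5, "as_max_dst": 4.0, "volume_score": 15.0,
    "polarity_score": 6.0, "charge_score": 0.25, "flex": 0.15,
    "n_apol_as": 8.0,
}

_CLASS_LIGAND = {"LBP": "CLR", "nLBP": "ADN", "HEME": "HEM", "PP": None}


@dataclass(frozen=True)
class TableSpec:
    """Shape of a synthetic descriptor corpus.

    ``separation`` is the standardized shift of the lipid-binding class on
    hydrophobicity_score; mean_loc_hyd_dens moves with it at
    ``secondary_shift`` of the full separation, keeping hydrophobicity the
    dominant signal.
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"LBP": 200, "nLBP": 300, "PP": 4000})
    separation: float = 3.0
    secondary_shift: float = 0.5
    class_means: Mapping[str, Mapping[str, float]] | None = None
    class_sds: Mapping[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if self.class_sds is not None and any(
                s <= 0 for s in self.class_sds.values()):
            raise ValueError("class sds must be > 0")


def _class_mean(label: str, spec: TableSpec,
                sds: Mapping[str, float]) -> dict[str, float]:
    mean = dict(_BASE_MEAN)
    if spec.class_means and label in spec.class_means:
        mean.update(spec.class_means[label])
        return mean
    if label == "LBP":
        mean["hydrophobicity_score"] += spec.separation * sds["hydrophobicity_score"]
        mean["mean_loc_hyd_dens"] += (
            spec.separation * spec.secondary_shift * sds["mean_loc_hyd_dens"])
    elif label == "nLBP":
        mean["polarity_score"] += 1.0 * sds["polarity_score"]
    elif label == "HEME":
        mean["hydrophobicity_score"] += (
            0.6 * spec.separation * sds["hydrophobicity_score"])
    return mean


def make_descriptor_table(spec: TableSpec) -> DescriptorTable:
    """Draw a labeled descriptor corpus from class-conditional Gaussians.

    Rows are truncated into the descriptor invariants: fractions clipped
    to [0, 1], volumes and counts positive, the surface partition made
    exact, and extent >= mean pairwise distance.
    """
    rng = np.random.default_rng(spec.seed)
    sds = dict(_BASE_SD)
    if spec.class_sds:
        sds.update(spec.class_sds)

    import pandas as pd

    frames = []
    for label in ("LBP", "nLBP", "PP", "HEME"):
        n = int(spec.n_per_class.get(label, 0))
        if n == 0:
            continue
        mean = _class_mean(label, spec, sds)
        cols: dict[str, np.ndarray] = {}
        for name in DESCRIPTOR_NAMES:
            cols[name] = rng.normal(mean[name], sds[name], size=n)
        # enforce row-wise invariants by truncation
        for frac in ("apol_as_prop", "prop_polar_atm", "mean_as_solv_acc"):
            cols[frac] = np.clip(cols[frac], 0.0, 1.0)
        cols["pock_vol"] = np.clip(cols["pock_vol"], 10.0, None)
        cols["nb_AS"] = np.clip(np.round(cols["nb_AS"]), 1, None)
        cols["surf_pol_vdw"] = np.clip(cols["surf_pol_vdw"], 0.0, None)
        cols["surf_apol_vdw"] = np.clip(cols["surf_apol_vdw"], 0.0, None)
        cols["surf_vdw"] = cols["surf_pol_vdw"] + cols["surf_apol_vdw"]
        cols["as_dens"] = np.clip(cols["as_dens"], 0.0, None)
        cols["as_max_dst"] = np.maximum(
            np.clip(cols["as_max_dst"], 0.0, None), cols["as_dens"])
        cols["mean_loc_hyd_dens"] = np.clip(cols["mean_loc_hyd_dens"], 0.0, None)
        cols["n_apol_as"] = np.round(cols["apol_as_prop"] * cols["nb_AS"])
        cols["flex"] = np.clip(cols["flex"], 0.0, None)

        df = pd.DataFrame(cols)
        df.insert(0, "structure_id",
                  [f"syn{spec.seed}-{label}-{i:05d}" for i in range(n)])
        df.insert(1, "pocket_id", 1)
        df["label"] = label
        df["matched_ligand"] = _CLASS_LIGAND[label]
        frames.append(df)

    if not frames:
        df = pd.DataFrame(columns=list(DescriptorTable.COLUMNS))
        return DescriptorTable(df)
    return DescriptorTable(pd.concat(frames, ignore_index=True))


def default_corpus(seed: int = 0, separation: float = 3.0) -> DescriptorTable:
    """The small standard corpus (200 LBP / 300 nLBP / 4000 PP, 20:1
    PP:LBP imbalance) used across the test and benchmark workflows."""
    return make_descriptor_table(TableSpec(
        n_per_class={"LBP": 200, "nLBP": 300, "PP": 4000},
        separation=separation, seed=seed))
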