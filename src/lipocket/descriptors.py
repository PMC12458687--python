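"""Per-pocket physicochemical descriptors.

Each detected pocket is summarized by 17 descriptors that feed the
classifier: pocket volume (pock_vol, A^3), alpha-sphere count (nb_AS),
van der Waals surface area and its polar/apolar split (surf_vdw,
surf_pol_vdw, surf_apol_vdw, A^2), residue-scale scores (hydrophobicity,
volume, polarity, charge), mean local hydrophobic density
(mean_loc_hyd_dens), proportion of apolar alpha spheres (apol_as_prop),
proportion of polar contact atoms (prop_polar_atm), mean alpha-sphere
solvent accessibility (mean_as_solv_acc), mean and max pairwise
sphere-center distance (as_dens, as_max_dst, A), flexibility (flex,
contact-residue mean B normalized by the structure mean B), and the count
of apolar alpha spheres (n_apol_as) as the seventeenth slot.

Monte-Carlo and surface-sampling estimates are seeded and therefore
bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dataclass_fields
from typing import Mapping

import numpy as np

from lipocket.pocket_detection import APOLAR_ELEMENTS, Pocket
from lipocket.structure_io import StructureModel

__all__ = [
    "DESCRIPTOR_NAMES",
    "PocketDescriptorVector",
    "ResidueScaleSet",
    "DEFAULT_SCALES",
    "VDW_RADII",
    "compute_descriptors",
    "pocket_volume_mc",
    "vdw_surface_areas",
]

#: polar elements for contact-atom and surface partitions (S stays apolar)
POLAR_ELEMENTS = frozenset({"N", "O"})

#: van der Waals radii, A (Bondi)
VDW_RADII: dict[str, float] = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "FE": 2.00, "ZN": 1.39, "MG": 1.73, "CA": 2.31, "MN": 2.05,
}

#: canonical descriptor column order (classifier feature order)
DESCRIPTOR_NAMES: tuple[str, ...] = (
    "pock_vol", "nb_AS", "surf_vdw", "surf_pol_vdw", "surf_apol_vdw",
    "hydrophobicity_score", "mean_loc_hyd_dens", "apol_as_prop",
    "prop_polar_atm", "mean_as_solv_acc", "as_dens", "as_max_dst",
    "volume_score", "polarity_score", "charge_score", "flex", "n_apol_as",
)


@dataclass(frozen=True)
class PocketDescriptorVector:
    pock_vol: float
    nb_AS: int
    surf_vdw: float
    surf_pol_vdw: float
    surf_apol_vdw: float
    hydrophobicity_score: float
    mean_loc_hyd_dens: float
    apol_as_prop: float
    prop_polar_atm: float
    mean_as_solv_acc: float
    as_dens: float
    as_max_dst: float
    volume_score: float
    polarity_score: float
    charge_score: float
    flex: float
    n_apol_as: float

    def __post_init__(self) -> None:
        if self.pock_vol <= 0:
            raise ValueError("pock_vol must be positive")
        if self.nb_AS < 1:
            raise ValueError("nb_AS must be >= 1")
        total = self.surf_pol_vdw + self.surf_apol_vdw
        if total > 0 and abs(total - self.surf_vdw) > 1e-6 * max(1.0, self.surf_vdw):
            raise ValueError("polar + apolar surface must equal total")
        for name in ("apol_as_prop", "prop_polar_atm", "mean_as_solv_acc"):
            v = getattr(self, name)
            if not -1e-9 <= v <= 1 + 1e-9:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.as_dens < 0 or self.as_max_dst < self.as_dens:
            raise ValueError("need as_max_dst >= as_dens >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], float)

    def as_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in DESCRIPTOR_NAMES}


# residue scales ------------------------------------------------------------

_AA = ("ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
       "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL")

# Monera et al. relative hydrophobicity at pH 7 (Phe = 100)
_MONERA = dict(zip(_AA, (
    41, -14, -28, -55, 49, -10, -31, 0, 8, 99,
    97, -23, 74, 100, -46, -5, 13, 97, 63, 76)))

# Kyte-Doolittle hydropathy (optional alternative)
_KYTE_DOOLITTLE = dict(zip(_AA, (
    1.8, -4.5, -3.5, -3.5, 2.5, -3.5, -3.5, -0.4, -3.2, 4.5,
    3.8, -3.9, 1.9, 2.8, -1.6, -0.8, -0.7, -0.9, -1.3, 4.2)))

# Zamyatnin residue volumes, A^3
_VOLUME = dict(zip(_AA, (
    88.6, 173.4, 114.1, 111.1, 108.5, 143.8, 138.4, 60.1, 153.2, 166.7,
    166.7, 168.6, 162.9, 189.9, 112.7, 89.0, 116.1, 227.8, 193.6, 140.0)))

# Zimmerman polarity
_POLARITY = dict(zip(_AA, (
    0.00, 52.0, 3.38, 49.7, 1.48, 3.53, 49.9, 0.00, 51.6, 0.13,
    0.13, 49.5, 1.43, 0.35, 1.58, 1.67, 1.66, 2.10, 1.61, 0.13)))

# formal side-chain charge at pH 7
_CHARGE = {aa: 0.0 for aa in _AA}
_CHARGE.update({"ASP": -1.0, "GLU": -1.0, "LYS": 1.0, "ARG": 1.0})


@dataclass(frozen=True)
class ResidueScaleSet:
    """Residue-level scales behind the four pocket scores."""

    hydrophobicity: Mapping[str, float]
    volume: Mapping[str, float]
    polarity: Mapping[str, float]
    charge: Mapping[str, float]

    def __post_init__(self) -> None:
        for name in ("hydrophobicity", "volume", "polarity", "charge"):
            missing = set(_AA) - set(getattr(self, name))
            if missing:
                raise ValueError(f"{name} scale missing residues: {missing}")


DEFAULT_SCALES = ResidueScaleSet(
    hydrophobicity=_MONERA, volume=_VOLUME,
    polarity=_POLARITY, charge=_CHARGE)

KYTE_DOOLITTLE_SCALES = ResidueScaleSet(
    hydrophobicity=_KYTE_DOOLITTLE, volume=_VOLUME,
    polarity=_POLARITY, charge=_CHARGE)


# geometry estimates --------------------------------------------------------

def pocket_volume_mc(
    pocket: Pocket, mc_samples: int = 100_000, seed: int = 0,
) -> float:
    """Monte-Carlo volume of the union of a pocket's alpha spheres.

    Uniform samples in the axis-aligned bounding box of the spheres; the
    estimate is hit fraction times box volume, deterministic per seed.
    """
    if mc_samples < 10_000:
        raise ValueError("mc_samples must be >= 10^4 for a stable estimate")
    centers = pocket.sphere_centers()
    radii = np.array([s.radius for s in pocket.spheres])
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    box = float(np.prod(hi - lo))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(mc_samples, 3))
    d2 = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    hit = (d2 <= (radii ** 2)[None, :]).any(axis=1)
    return box * float(hit.mean())


def _sphere_sample_dirs(n: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def vdw_surface_areas(
    pocket: Pocket,
    structure: StructureModel,
    n_points: int = 256,
    seed: int = 0,
    vdw_radii: Mapping[str, float] = VDW_RADII,
) -> tuple[float, float, float]:
    """Exposed van der Waals surface of the pocket's contact atoms.

    Each contact atom's vdW sphere is sampled with ``n_points`` directions;
    a point is exposed if it lies outside every other contact atom's vdW
    sphere.  Totals are split by atom polarity (polar = N, O); polar +
    apolar = total holds exactly because the atoms partition.
    """
    atom_idx = sorted(pocket.contact_atoms)
    coords = np.array([structure.atoms[i].coords for i in atom_idx])
    radii = np.empty(len(atom_idx))
    polar = np.empty(len(atom_idx), dtype=bool)
    for k, i in enumerate(atom_idx):
        el = structure.atoms[i].element.upper()
        if el not in vdw_radii:
            raise KeyError(f"no van der Waals radius for element {el!r}")
        radii[k] = vdw_radii[el]
        polar[k] = el in POLAR_ELEMENTS

    rng = np.random.default_rng(seed)
    total = pol = 0.0
    for k in range(len(atom_idx)):
        dirs = _sphere_sample_dirs(n_points, rng)
        pts = coords[k] + radii[k] * dirs
        exposed = np.ones(n_points, dtype=bool)
        for j in range(len(atom_idx)):
            if j == k:
                continue
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            exposed &= d2 > radii[j] ** 2
        area = 4.0 * np.pi * radii[k] ** 2 * exposed.mean()
        total += area
        if polar[k]:
            pol += area
    return float(total), float(pol), float(total - pol)


def _mean_as_solv_acc(
    pocket: Pocket,
    structure: StructureModel,
    n_points: int,
    rng: np.random.Generator,
    vdw_radii: Mapping[str, float],
) -> float:
    """Mean fraction of each sphere's surface not covered by any polymer
    atom's vdW sphere (a cheap proxy for how solvent-open the probe is)."""
    atom_idx = structure.polymer_atom_indices()
    coords = np.array([structure.atoms[i].coords for i in atom_idx])
    radii = np.array([
        vdw_radii.get(structure.atoms[i].element.upper(), 1.70)
        for i in atom_idx])
    fracs = []
    for s in pocket.spheres:
        pts = np.asarray(s.center) + s.radius * _sphere_sample_dirs(n_points, rng)
        d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        covered = (d2 <= (radii ** 2)[None, :]).any(axis=1)
        fracs.append(1.0 - covered.mean())
    return float(np.mean(fracs))


# the full vector -----------------------------------------------------------

def compute_descriptors(
    pocket: Pocket,
    structure: StructureModel,
    scales: ResidueScaleSet = DEFAULT_SCALES,
    mc_samples: int = 100_000,
    seed: int = 0,
    surface_points: int = 128,
    solv_acc_points: int = 100,
) -> PocketDescriptorVector:
    """Compute the 17-descriptor vector for one pocket."""
    if not pocket.spheres:
        raise ValueError("cannot describe an empty pocket")

    centers = pocket.sphere_centers()
    radii = np.array([s.radius for s in pocket.spheres])
    apolar = np.array([s.apolar for s in pocket.spheres], dtype=bool)
    n = len(pocket.spheres)

    # pairwise sphere-center geometry
    if n > 1:
        diffs = centers[:, None, :] - centers[None, :, :]
        dists = np.sqrt((diffs ** 2).sum(axis=2))
        iu = np.triu_indices(n, k=1)
        as_dens = float(dists[iu].mean())
        as_max_dst = float(dists[iu].max())
    else:
        dists = np.zeros((1, 1))
        as_dens = as_max_dst = 0.0

    # mean local hydrophobic density: for each apolar sphere, the number of
    # apolar spheres overlapping it (center distance < sum of radii),
    # counting itself, averaged over apolar spheres
    if apolar.any():
        ap_idx = np.flatnonzero(apolar)
        sub = dists[np.ix_(ap_idx, ap_idx)]
        rsum = radii[ap_idx][:, None] + radii[ap_idx][None, :]
        mean_loc_hyd_dens = float((sub < rsum).sum(axis=1).mean())
    else:
        mean_loc_hyd_dens = 0.0

    # contact atoms / residues
    atom_idx = sorted(pocket.contact_atoms)
    elements = [structure.atoms[i].element.upper() for i in atom_idx]
    prop_polar_atm = (
        sum(e in POLAR_ELEMENTS for e in elements) / len(elements))

    residue_names = []
    residue_bs = []
    residue_of = structure.residue_of_atom()
    seen = set()
    for i in atom_idx:
        res = residue_of.get(i)
        if res is None or res.key in seen:
            continue
        seen.add(res.key)
        residue_names.append(res.residue_name)
        residue_bs.append(float(np.mean(
            [structure.atoms[j].b_factor for j in res.atom_indices])))

    def scale_mean(scale: Mapping[str, float]) -> float:
        vals = [scale[r] for r in residue_names if r in scale]
        return float(np.mean(vals)) if vals else 0.0

    structure_mean_b = float(np.mean(
        [a.b_factor for a in structure.atoms])) or 1.0
    flex = (float(np.mean(residue_bs)) / structure_mean_b
            if residue_bs and structure_mean_b > 0 else 0.0)

    rng = np.random.default_rng(seed)
    surf, surf_pol, surf_apol = vdw_surface_areas(
        pocket, structure, n_points=surface_points,
        seed=int(rng.integers(2**31)))
    solv_acc = _mean_as_solv_acc(
        pocket, structure, solv_acc_points, rng, VDW_RADII)
    vol = pocket_volume_mc(
        pocket, mc_samples=mc_samples, seed=int(rng.integers(2**31)))

    return PocketDescriptorVector(
        pock_vol=vol,
        nb_AS=n,
        surf_vdw=surf,
        surf_pol_vdw=surf_pol,
        surf_apol_vdw=surf_apol,
        hydrophobicity_score=scale_mean(scales.hydrophobicity),
        mean_loc_hyd_dens=mean_loc_hyd_dens,
        apol_as_prop=float(apolar.mean()),
        prop_polar_atm=prop_polar_atm,
        mean_as_solv_acc=solv_acc,
        as_dens=as_dens,
        as_max_dst=as_max_dst,
        volume_score=scale_mean(scales.volume),
        polarity_score=scale_mean(scales.polarity),
        charge_score=scale_mean(scales.charge),
        flex=flex,
        n_apol_as=float(apolar.sum()),
    )
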