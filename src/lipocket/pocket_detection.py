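"""Alpha-sphere pocket detection.

An alpha sphere is the circumsphere of four heavy atoms that contains no
heavy atom in its interior.  Spheres whose radius falls in a configured
window (default 3.0-6.0 A) probe clefts and cavities: smaller spheres sit
in the packed interior, larger ones in bulk solvent.  Candidate spheres
come from the heavy-atom Delaunay tessellation (a tetrahedron is Delaunay
exactly when its circumsphere is empty), and pockets are single-linkage
clusters of sphere centers, with a second coarse pass merging clusters
whose centroids lie close together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from lipocket.structure_io import StructureModel

__all__ = [
    "AlphaSphere",
    "Pocket",
    "APOLAR_ELEMENTS",
    "compute_alpha_spheres",
    "classify_sphere_polarity",
    "cluster_pockets",
    "detect_pockets",
    "write_pocket_spheres_pdb",
]

#: elements whose atoms count as apolar (hydrophobic) in sphere polarity
#: and descriptor partitions; N and O are polar.
APOLAR_ELEMENTS = frozenset({"C", "S"})

#: default radius window, A
R_MIN_DEFAULT = 3.0
R_MAX_DEFAULT = 6.0
#: single-linkage threshold for sphere-center clustering, A
LINKAGE_DIST_DEFAULT = 1.73
#: second-pass merge threshold between cluster centroids, A
COARSE_MERGE_DIST_DEFAULT = 4.5
#: minimum spheres for a cluster to be reported as a pocket
MIN_SPHERES_DEFAULT = 30

#: atom counted inside a sphere iff distance < radius - EMPTINESS_TOL,
#: so the four defining (co-spherical) atoms never reject their own sphere
EMPTINESS_TOL = 1e-6


@dataclass(frozen=True)
class AlphaSphere:
    """A candidate cavity probe: empty circumsphere of four heavy atoms."""

    center: tuple[float, float, float]
    radius: float
    defining_atoms: tuple[int, int, int, int]  # indices into structure.atoms
    apolar: bool


@dataclass
class Pocket:
    """A cluster of alpha spheres plus the atoms/residues they touch."""

    spheres: list[AlphaSphere]
    contact_atoms: frozenset[int]
    contact_residues: frozenset[tuple[str, int]]
    pocket_id: int = 0

    def __post_init__(self) -> None:
        if not self.spheres:
            raise ValueError("pocket must contain at least one sphere")

    def sphere_centers(self) -> np.ndarray:
        return np.array([s.center for s in self.spheres], dtype=float)

    def centroid(self) -> np.ndarray:
        return self.sphere_centers().mean(axis=0)


def circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the circumsphere of 4 points (rows of a 4x3
    array).  Raises ``np.linalg.LinAlgError`` for degenerate tetrahedra."""
    a = points[0]
    rows = 2.0 * (points[1:] - a)  # |x-a|^2 = |x-p|^2  =>  2x.(p-a) = p.p - a.a
    rhs = np.einsum("ij,ij->i", points[1:], points[1:]) - a @ a
    center = np.linalg.solve(rows, rhs)
    return center, float(np.linalg.norm(center - a))


def compute_alpha_spheres(
    structure: StructureModel,
    r_min: float = R_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
    apolar_elements: frozenset[str] = APOLAR_ELEMENTS,
) -> list[AlphaSphere]:
    """Enumerate alpha spheres of the heavy-atom Delaunay tessellation.

    One candidate per tetrahedron; kept iff its circumsphere radius lies in
    ``[r_min, r_max]`` and no heavy atom sits strictly inside (re-verified
    against the atom set, not trusted from the tessellation).

    Only polymer heavy atoms participate: bound ligands and waters must not
    occlude the cavities they sit in, since pockets are matched to ligands
    afterwards.
    """
    atom_idx = structure.polymer_atom_indices()
    coords = np.array([structure.atoms[i].coords for i in atom_idx])
    if len(coords) < 4:
        raise ValueError("need at least 4 heavy atoms for tessellation")
    try:
        tess = Delaunay(coords)
    except Exception as exc:  # QhullError on degenerate input
        raise ValueError(f"degenerate atom configuration: {exc}") from exc

    tree = cKDTree(coords)
    spheres: list[AlphaSphere] = []
    for simplex in tess.simplices:
        pts = coords[simplex]
        try:
            center, radius = circumsphere(pts)
        except np.linalg.LinAlgError:
            continue
        if not (r_min <= radius <= r_max):
            continue
        # independent emptiness check against all participating atoms
        d, _ = tree.query(center, k=1)
        if d < radius - EMPTINESS_TOL:
            continue
        idx = tuple(sorted(atom_idx[int(i)] for i in simplex))
        n_apolar = sum(
            structure.atoms[i].element in apolar_elements for i in idx)
        spheres.append(AlphaSphere(
            center=tuple(float(c) for c in center),
            radius=radius,
            defining_atoms=idx,
            apolar=n_apolar >= 3,
        ))
    # deterministic order independent of qhull's simplex ordering
    spheres.sort(key=lambda s: (s.center, s.radius))
    return spheres


def classify_sphere_polarity(
    sphere: AlphaSphere,
    structure: StructureModel,
    apolar_elements: frozenset[str] = APOLAR_ELEMENTS,
) -> bool:
    """Apolar iff at least 3 of the 4 defining atoms are apolar elements."""
    n_apolar = sum(
        structure.atoms[i].element in apolar_elements
        for i in sphere.defining_atoms)
    return n_apolar >= 3


def _union_find_clusters(centers: np.ndarray, cutoff: float) -> list[list[int]]:
    """Single-linkage components of the <=cutoff pairwise-distance graph."""
    n = len(centers)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = cKDTree(centers)
    for i, j in tree.query_pairs(cutoff):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return list(groups.values())


def cluster_pockets(
    spheres: list[AlphaSphere],
    structure: StructureModel | None = None,
    linkage_dist: float = LINKAGE_DIST_DEFAULT,
    min_spheres: int = MIN_SPHERES_DEFAULT,
    coarse_merge_dist: float | None = COARSE_MERGE_DIST_DEFAULT,
) -> list[Pocket]:
    """Group alpha spheres into pockets.

    Single-linkage clustering of sphere centers at ``linkage_dist``,
    followed by a coarse pass merging clusters whose centroids lie within
    ``coarse_merge_dist`` (pass ``None`` to disable).  Clusters smaller
    than ``min_spheres`` are discarded; survivors are ranked by sphere
    count descending (ties by centroid x, y, z) and numbered from 1.
    """
    if not spheres:
        raise ValueError("no spheres to cluster")
    centers = np.array([s.center for s in spheres], dtype=float)
    clusters = _union_find_clusters(centers, linkage_dist)

    if coarse_merge_dist is not None and len(clusters) > 1:
        centroids = np.array([centers[c].mean(axis=0) for c in clusters])
        meta = _union_find_clusters(centroids, coarse_merge_dist)
        clusters = [
            [i for ci in group for i in clusters[ci]] for group in meta
        ]

    residue_of = structure.residue_of_atom() if structure is not None else {}
    pockets: list[Pocket] = []
    for members in clusters:
        if len(members) < min_spheres:
            continue
        member_spheres = [spheres[i] for i in members]
        atoms = frozenset(
            i for s in member_spheres for i in s.defining_atoms)
        residues = frozenset(
            residue_of[i].key for i in atoms if i in residue_of)
        pockets.append(Pocket(
            spheres=member_spheres, contact_atoms=atoms,
            contact_residues=residues))
    pockets.sort(key=lambda p: (-len(p.spheres), *p.centroid()))
    for rank, pocket in enumerate(pockets, start=1):
        pocket.pocket_id = rank
    return pockets


def detect_pockets(
    structure: StructureModel,
    r_min: float = R_MIN_DEFAULT,
    r_max: float = R_MAX_DEFAULT,
    linkage_dist: float = LINKAGE_DIST_DEFAULT,
    min_spheres: int = MIN_SPHERES_DEFAULT,
    coarse_merge_dist: float | None = COARSE_MERGE_DIST_DEFAULT,
) -> list[Pocket]:
    """Convenience: alpha spheres + clustering in one call."""
    spheres = compute_alpha_spheres(structure, r_min=r_min, r_max=r_max)
    if not spheres:
        return []
    return cluster_pockets(
        spheres, structure, linkage_dist=linkage_dist,
        min_spheres=min_spheres, coarse_merge_dist=coarse_merge_dist)


def write_pocket_spheres_pdb(pocket: Pocket, path) -> None:
    """Export a pocket's spheres as pseudo-atoms (radius in the occupancy
    column) for visual inspection."""
    lines = []
    for i, s in enumerate(pocket.spheres, start=1):
        lines.append(
            f"HETATM{i:5d}  APS SPH P{pocket.pocket_id % 10000:4d}    "
            f"{s.center[0]:8.3f}{s.center[1]:8.3f}{s.center[2]:8.3f}"
            f"{s.radius:6.2f}{0.0:6.2f}           C"
        )
    lines.append("END")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
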