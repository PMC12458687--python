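import numpy as np
import pytest

from conftest import brute_force_alpha_spheres
from lipocket.pocket_detection import (
    AlphaSphere,
    circumsphere,
    classify_sphere_polarity,
    cluster_pockets,
    compute_alpha_spheres,
    detect_pockets,
)
from lipocket.structure_io import AtomRecord, StructureModel


def _model_from_coords(coords, elements=None):
    elements = elements or ["C"] * len(coords)
    atoms = [
        AtomRecord(serial=i + 1, name="CA", element=el, residue_name="ALA",
                   chain_id="A", residue_index=i + 1,
                   coords=tuple(float(c) for c in xyz))
        for i, (xyz, el) in enumerate(zip(coords, elements))
    ]
    return StructureModel(atoms=atoms, source_id="toy")


def regular_tetrahedron(edge=5.0):
    v = np.array([
        [1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float)
    return v * edge / np.linalg.norm(v[0] - v[1])


class TestCircumsphere:
    def test_regular_tetrahedron_closed_form(self):
        pts = regular_tetrahedron(edge=5.0)
        center, radius = circumsphere(pts)
        assert radius == pytest.approx(5.0 * np.sqrt(3.0 / 8.0), abs=1e-9)
        np.testing.assert_allclose(center, pts.mean(axis=0), atol=1e-9)

    def test_center_equidistant_from_vertices(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-5, 5, size=(4, 3))
        center, radius = circumsphere(pts)
        d = np.linalg.norm(pts - center, axis=1)
        np.testing.assert_allclose(d, radius, atol=1e-8)


class TestAlphaSpheres:
    def test_single_tetrahedron_one_sphere(self):
        m = _model_from_coords(regular_tetrahedron(5.0))
        spheres = compute_alpha_spheres(m, r_min=2.0, r_max=4.0)
        assert len(spheres) == 1
        assert spheres[0].radius == pytest.approx(5.0 * np.sqrt(3.0 / 8.0))

    def test_atom_at_centroid_kills_sphere(self):
        pts = regular_tetrahedron(5.0)
        coords = np.vstack([pts, pts.mean(axis=0)])
        m = _model_from_coords(coords)
        spheres = compute_alpha_spheres(m, r_min=2.0, r_max=4.0)
        # no surviving circumsphere of the original tetrahedron
        assert all(set(s.defining_atoms) != {0, 1, 2, 3} for s in spheres)

    def test_radius_window_excludes(self):
        m = _model_from_coords(regular_tetrahedron(5.0))
        assert compute_alpha_spheres(m, r_min=3.5, r_max=6.0) == []

    def test_too_few_atoms_raise(self):
        m = _model_from_coords(np.eye(3) * 4)
        with pytest.raises(ValueError):
            compute_alpha_spheres(m, 3.0, 6.0)

    def test_matches_brute_force_enumeration(self, cavity_model):
        """Tessellation route equals exhaustive 4-subset enumeration."""
        spheres = compute_alpha_spheres(cavity_model, 3.0, 6.0)
        got = {s.defining_atoms for s in spheres}
        expected = brute_force_alpha_spheres(
            cavity_model.heavy_coords(), 3.0, 6.0)
        assert got == expected

    def test_every_sphere_empty_against_all_atoms(self, cavity_model):
        coords = cavity_model.heavy_coords()
        for s in compute_alpha_spheres(cavity_model, 3.0, 6.0):
            d = np.linalg.norm(coords - np.asarray(s.center), axis=1)
            assert (d >= s.radius - 1e-6).all()
            # and the four defining atoms are on the sphere
            dd = d[list(s.defining_atoms)]
            np.testing.assert_allclose(dd, s.radius, atol=1e-6)


class TestSpherePolarity:
    @pytest.mark.parametrize("elements,expected", [
        (["C", "C", "C", "N"], True),
        (["C", "C", "N", "O"], False),
        (["C", "S", "C", "C"], True),
    ])
    def test_three_of_four_rule(self, elements, expected):
        m = _model_from_coords(regular_tetrahedron(5.0), elements)
        sphere = AlphaSphere(center=(0, 0, 0), radius=3.0,
                             defining_atoms=(0, 1, 2, 3), apolar=False)
        assert classify_sphere_polarity(sphere, m) is expected

    def test_compute_sets_flag_consistently(self, cavity_model):
        for s in compute_alpha_spheres(cavity_model, 3.0, 6.0):
            assert s.apolar == classify_sphere_polarity(s, cavity_model)


def _sphere_at(xyz, radius=3.5):
    return AlphaSphere(center=tuple(float(c) for c in xyz), radius=radius,
                       defining_atoms=(0, 1, 2, 3), apolar=True)


class TestClustering:
    def test_small_cluster_discarded(self):
        rng = np.random.default_rng(0)
        near = [_sphere_at(rng.uniform(-1, 1, 3)) for _ in range(10)]
        far = [_sphere_at(rng.uniform(-1, 1, 3) + 30.0) for _ in range(2)]
        pockets = cluster_pockets(near + far, linkage_dist=4.0, min_spheres=3,
                                  coarse_merge_dist=None)
        assert len(pockets) == 1
        assert len(pockets[0].spheres) == 10

    def test_chain_connectivity_single_pocket(self):
        chain = [_sphere_at((1.5 * i, 0, 0)) for i in range(20)]
        pockets = cluster_pockets(chain, linkage_dist=1.73, min_spheres=3,
                                  coarse_merge_dist=None)
        assert len(pockets) == 1
        assert len(pockets[0].spheres) == 20

    def test_matches_union_find_oracle(self):
        """Single-linkage partition equals brute-force union-find over the
        pairwise-distance graph."""
        rng = np.random.default_rng(11)
        centers = rng.uniform(-15, 15, size=(50, 3))
        spheres = [_sphere_at(c) for c in centers]
        linkage = 5.0

        parent = list(range(50))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for i in range(50):
            for j in range(i + 1, 50):
                if np.linalg.norm(centers[i] - centers[j]) <= linkage:
                    parent[find(i)] = find(j)
        expected = {}
        for i in range(50):
            expected.setdefault(find(i), set()).add(tuple(centers[i]))
        expected_partition = {frozenset(v) for v in expected.values()}

        pockets = cluster_pockets(spheres, linkage_dist=linkage, min_spheres=1,
                                  coarse_merge_dist=None)
        got_partition = {
            frozenset(tuple(c) for c in p.sphere_centers()) for p in pockets}
        assert got_partition == expected_partition

    def test_ranking_by_size_then_centroid(self):
        rng = np.random.default_rng(2)
        big = [_sphere_at(rng.uniform(-1, 1, 3)) for _ in range(8)]
        small = [_sphere_at(rng.uniform(-1, 1, 3) + 40) for _ in range(4)]
        pockets = cluster_pockets(big + small, linkage_dist=4.0, min_spheres=2,
                                  coarse_merge_dist=None)
        assert [len(p.spheres) for p in pockets] == [8, 4]
        assert [p.pocket_id for p in pockets] == [1, 2]

    def test_contact_atoms_are_union_of_defining_atoms(self, cavity_model):
        pockets = detect_pockets(cavity_model, min_spheres=5)
        for p in pockets:
            assert p.contact_atoms == frozenset(
                i for s in p.spheres for i in s.defining_atoms)

    def test_spheres_partition_across_pockets(self, cavity_model):
        spheres = compute_alpha_spheres(cavity_model, 3.0, 6.0)
        pockets = cluster_pockets(spheres, cavity_model, min_spheres=1)
        seen = [id(s) for p in pockets for s in p.spheres]
        assert len(seen) == len(set(seen)) == len(spheres)


def test_cavity_pocket_found_at_origin(cavity_model):
    """Construction guarantee: one detected pocket sits on the cavity."""
    pockets = detect_pockets(cavity_model, min_spheres=5)
    assert pockets
    d = [np.linalg.norm(p.centroid()) for p in pockets]
    assert min(d) < 2.0
    # and it is the top-ranked (largest) pocket
    assert np.argmin(d) == 0
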