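import numpy as np
import pytest

from lipocket.classifier import train_classifier
from lipocket.dataset_curation import stratified_split
from lipocket.synthetic_fixtures import CavitySpec, default_corpus, make_cavity_structure


@pytest.fixture(scope="session")
def cavity_model():
    """60-atom toy structure with a 5 A interior cavity, no ligand."""
    return make_cavity_structure(CavitySpec(seed=1))


@pytest.fixture(scope="session")
def cavity_model_with_ligand():
    """Same cavity geometry with a CLR cluster planted at the center."""
    return make_cavity_structure(CavitySpec(seed=1, planted_ligand="CLR"))


@pytest.fixture(scope="session")
def corpus():
    """Standard synthetic corpus: 200 LBP / 300 nLBP / 4000 PP, separation 3."""
    return default_corpus(seed=7)


@pytest.fixture(scope="session")
def corpus_split(corpus):
    return stratified_split(corpus.drop_label("HEME"), 0.1, seed=7)


@pytest.fixture(scope="session")
def trained_rf(corpus_split):
    train, _ = corpus_split
    return train_classifier(train, algorithm="random_forest", seed=7)


def brute_force_alpha_spheres(coords, r_min, r_max, tol=1e-6):
    """Independent oracle: all 4-atom circumspheres in the radius window
    that contain no atom strictly inside, as a set of sorted index tuples.

    Enumerates every C(n,4) subset; no tessellation involved.
    """
    from itertools import combinations

    coords = np.asarray(coords, dtype=float)
    combos = np.array(list(combinations(range(len(coords)), 4)))
    p = coords[combos]  # (m, 4, 3)
    a = p[:, 0, :]
    rows = 2.0 * (p[:, 1:, :] - a[:, None, :])
    rhs = np.einsum("mij,mij->mi", p[:, 1:, :], p[:, 1:, :]) - np.einsum(
        "mj,mj->m", a, a)[:, None]
    dets = np.linalg.det(rows)
    ok = np.abs(dets) > 1e-10
    centers = np.full((len(combos), 3), np.nan)
    centers[ok] = np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
    radii = np.linalg.norm(centers - a, axis=1)
    in_window = ok & (radii >= r_min) & (radii <= r_max)
    result = set()
    for m in np.flatnonzero(in_window):
        d = np.linalg.norm(coords - centers[m], axis=1)
        if (d < radii[m] - tol).any():
            continue
        result.add(tuple(int(i) for i in combos[m]))
    return result
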