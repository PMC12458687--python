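# lipocket

Structure-based prediction of lipid-binding proteins from pocket
geometry and physicochemistry.

Most lipid-binding proteins are discovered one at a time, by biochemistry.
`lipocket` approaches the problem from structure: it detects candidate
binding pockets in a protein model, summarizes each pocket with 17
physicochemical descriptors, and uses a random-forest classifier to
estimate the probability that the pocket binds a lipid. Run over a whole
proteome of predicted structures, it produces a ranked list of putative
lipid-binding proteins — a hypothesis generator for structural biologists
and lipid biochemists.

## The method

**Pocket detection.** An *alpha sphere* is the circumsphere of four heavy
atoms that contains no heavy atom inside it. Spheres with radius in a
window (default 3.0–6.0 Å) sit in clefts and cavities — smaller ones are
buried in packed protein, larger ones float in bulk solvent. Candidates
come from the heavy-atom Delaunay tessellation (a tetrahedron is Delaunay
exactly when its circumsphere is empty), and pockets are single-linkage
clusters of sphere centers.

**Descriptors.** Each pocket is described by 17 features: volume
(Monte-Carlo over the sphere union), alpha-sphere count, van der Waals
surface area with its polar/apolar split, residue-scale scores
(hydrophobicity, volume, polarity, charge over the lining residues),
mean local hydrophobic density, proportions of apolar spheres and polar
atoms, mean sphere solvent accessibility, mean and maximum sphere-center
distances, flexibility (normalized B-factor), and the apolar-sphere count.

**Classification.** A random forest is trained on pockets labeled by
geometric overlap with bound ligands: lipid-binding pockets (LBP;
cholesterol and free fatty acids), non-lipid-binding pockets (nLBP;
adenosine, cobalamin, glucose, coenzyme A), and *pseudo pockets* (PP) —
detected pockets that overlap no ligand, the dominant negative class.
Pockets with predicted probability ≥ 0.5 are called lipid-binding.

**Proteome scanning.** Predicted models (pLDDT in the B-factor column)
are trimmed of annotated signal peptides, filtered (< 100 residues or
mean pLDDT < 70 removed), and every surviving model's pockets are scored;
the best pocket probability is the protein score.

## Worked example

```python
import numpy as np
from lipocket import (CavitySpec, make_cavity_structure, detect_pockets,
                      compute_descriptors, default_corpus, stratified_split,
                      train_classifier)
from lipocket.classifier import evaluate_model, predict_pocket

# a synthetic structure with an engineered cavity and a planted cholesterol
structure = make_cavity_structure(CavitySpec(seed=1, planted_ligand="CLR"))
pockets = detect_pockets(structure, min_spheres=5)
vec = compute_descriptors(pockets[0], structure, mc_samples=20_000, seed=0)

# train on the standard synthetic corpus (200 LBP / 300 nLBP / 4000 PP)
corpus = default_corpus(seed=7).drop_label("HEME")
train, test = stratified_split(corpus, 0.1, seed=7)
model = train_classifier(train, seed=7)
m = evaluate_model(model, test)
print(predict_pocket(model, vec))
```

prints (with the diagnostics shown in between):

```
5 pockets; top pocket: 97 alpha spheres, centroid [ 0.28 -0.93 -0.21]
pock_vol=2008.8 A^3  hydrophobicity=59.3  apol_as_prop=0.72
held-out AUROC=0.998  sensitivity=0.850  specificity=1.000  precision=1.000  F1=0.919
cavity pocket score: 0.70
```

The detector recovers the engineered cavity (centroid near the origin),
its lining is hydrophobic (score 59 on the Monera scale, 72% apolar
spheres), and the classifier — which has never seen this structure —
scores it 0.70, above the 0.5 lipid-binding call. The held-out metrics
show the signature of the 20:1 pseudo-pocket imbalance: specificity and
precision near 1, sensitivity lower.

The same workflow is available from the shell:

```bash
lipocket fixtures make-table --seed 5 --out table.tsv
lipocket train --table table.tsv --ratio 5 --seed 5 --out model/
lipocket predict --model model/ --table table.tsv --out scores.tsv
lipocket scan --models models/ --model model/ --out scan/
```

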