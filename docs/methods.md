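# Methods

## Pocket model

A pocket is modeled as a cluster of *alpha spheres*: circumspheres of
four heavy atoms that contain no heavy atom strictly inside. The radius
window `[r_min, r_max]` (default 3.0–6.0 Å) selects probes the size of a
solvent-excluded cleft: tighter spheres belong to the packed interior,
wider ones to bulk solvent. Candidates are the tetrahedra of the
heavy-atom Delaunay tessellation (scipy's Qhull wrapper); by the Delaunay
empty-circumsphere property this enumerates exactly the spheres a
brute-force scan over all four-atom subsets would find, which the test
suite verifies by running that scan. Emptiness is nevertheless re-checked
against the full atom set with a tolerance of 1e-6 Å (an atom is "inside"
only if its distance to the center is below radius − 1e-6), so co-spherical
degeneracies never reject a valid sphere.

Only polymer heavy atoms participate in the tessellation: hydrogens are
dropped at parse time, and bound ligands and waters are excluded so that
a ligand does not occlude the cavity it occupies — pockets are matched to
ligands afterwards, not detected around them.

A sphere is **apolar** when at least three of its four defining atoms are
carbon or sulfur; nitrogen and oxygen are polar. The same element
partition drives the polar/apolar surface split and the polar-atom
proportion descriptor.

Clustering is single linkage over sphere centers at 1.73 Å, followed by a
coarse pass that merges clusters whose centroids lie within 4.5 Å —
approximating the multi-pass grouping of established alpha-sphere pocket
finders. Clusters below `min_spheres` (default 30; the small test
fixtures pass lower values explicitly) are dropped, and survivors are
ranked by sphere count with centroid coordinates as the deterministic
tie-break. A known failure mode of this family of detectors — one
continuous pocket split into two clusters, each scoring low — is accepted
behavior here as well.

## Descriptors

Seventeen features per pocket:

| descriptor | units | definition |
|---|---|---|
| pock_vol | Å³ | Monte-Carlo volume of the union of member spheres |
| nb_AS | count | number of alpha spheres |
| surf_vdw, surf_pol_vdw, surf_apol_vdw | Å² | exposed van der Waals area of contact atoms, split by atom polarity |
| hydrophobicity_score | scale units | mean Monera value over lining residues |
| mean_loc_hyd_dens | count | mean, over apolar spheres, of overlapping apolar spheres (center distance < sum of radii) |
| apol_as_prop | 0–1 | fraction of apolar spheres |
| prop_polar_atm | 0–1 | fraction of N/O contact atoms |
| mean_as_solv_acc | 0–1 | mean fraction of sphere surface points uncovered by polymer vdW spheres (100 points/sphere, seeded) |
| as_dens, as_max_dst | Å | mean and max pairwise sphere-center distance |
| volume_score | Å³ | mean Zamyatnin residue volume of the lining |
| polarity_score | scale units | mean Zimmerman polarity of the lining |
| charge_score | e | mean formal side-chain charge at pH 7 (Asp/Glu −1, Lys/Arg +1, His 0) |
| flex | – | lining-residue mean B-factor over structure mean B (reuses pLDDT for predicted models) |
| n_apol_as | count | number of apolar spheres |

The seventeenth slot deserves a note: the descriptor convention this
feature space follows has one more standard output than the sixteen
named geometric/physicochemical quantities above, and the apolar-sphere
count is the natural choice — it is redundant with `apol_as_prop × nb_AS`
by construction and can be excluded by passing a 16-name `feature_order`
to the classifier.

Numerical choices: pocket volume uses ≥10⁴ uniform samples in the
bounding box of the sphere union (1e5 default; relative error well under
2 % against the closed-form two-sphere union in tests). Surface areas
sample each contact atom's vdW sphere (Bondi radii) with 128–256
directions against the other contact atoms; the polar + apolar = total
identity is exact because it partitions atoms, not points. All sampling
flows from a single seed, so descriptor vectors are bit-reproducible.

The hydrophobicity scale defaults to Monera et al. (pH 7, Phe = 100),
the convention of the established pocket-descriptor tools;
Kyte–Doolittle is available via `KYTE_DOOLITTLE_SCALES`. The charge
convention (formal side-chain charge, His neutral) is a design choice —
no titration model is attempted.

## Dataset curation

Pockets are labeled by overlap with standalone ligands: a pocket matches
a ligand when any sphere center lies within 3.0 Å (configurable) of a
ligand heavy atom, the nearest ligand winning multi-matches. "Standalone"
means no ligand heavy atom within 1.9 Å of a polymer heavy atom — longer
than any covalent bond, shorter than any vdW contact. Surface-adsorbed
lipids are removed by the burial filter: a ligand is kept only if at
least 10 distinct residues have an atom within 8 Å of its center of mass
(unweighted heavy-atom centroid by default; mass weighting by flag).

The lipid class comprises cholesterol (CLR) and the free fatty acids
MYR, PLM, STE, OLA; the non-lipid class ADN, B12, BGC, COA; heme (HEM)
pockets are labeled but excluded from default training, since including
them is known not to remove the heme/lipid confusion. Class imbalance is
managed by downsampling pseudo pockets to a chosen multiple of the LBP
count (1×, 5×, 20×, or the full set); splits are stratified per class.

## Classifier

Binary task: LBP versus everything else. The default random forest uses
the toolkit's documented defaults (100 trees, unlimited depth, √p
features per split, bootstrap on), recorded in the model manifest;
persistence is a JSON manifest plus a joblib estimator blob, and the
manifest alone suffices to retrain. The decision threshold is inclusive
at 0.5. Hyperparameter search supports random sampling from ranges
(log-uniform for tree count and depth) and full grid enumeration, scored
by 3-fold cross-validated F1; the reference fine grid enumerates
3·3·3·3·3·1 = 243 candidates.

Evaluation implements the confusion-matrix metrics from their formulas,
AUROC by the rank-sum identity (ties as half-wins), and Cohen's kappa
from the marginals; undefined metrics are surfaced as explicit flags,
never silent zeros. sklearn's implementations serve as independent
cross-checks in the tests, not as the implementation. PCA of descriptor
space standardizes columns first (the features span Å³ to unitless
fractions; an unstandardized decomposition would be dominated by
volume). Feature importance comes two ways: mean decrease in impurity
from the forest, and permutation importance as the drop in F1 over 10
seeded shuffles per column.

## Proteome scan

Signal peptides (annotated externally; a two-column TSV of cut sites) are
trimmed *before* the length filter. "Less than" filters are strict: a
100-residue model and a mean pLDDT of exactly 70.0 survive. Per-residue
confidence is read from the CA atom (first atom fallback); predicted
models carry identical values on all atoms of a residue, so residue-mean
and atom-mean coincide for them. The protein score is the maximum pocket
probability; hit calling is inclusive at the threshold, and the summary
hit percentage is rounded to one decimal with round-half-even.
Per-protein results are independent — scanning any subset in any order
yields identical rows.

## Synthetic fixtures

The cavity generator places one-atom pseudo-residues in the shell volume
between the cavity radius and the outer radius, concentrated at the
cavity boundary, on a jittered grid with a 1.5 Å minimum separation
(jitter shrinks and placement retries on clash, failing after 10
attempts). Residue identities come from a lining-composition map, and
each pseudo-residue's element follows its character (C hydrophobic, O
polar, N charged), so polarity-dependent descriptors vary. An optional
ligand is a compact carbon cluster at the cavity center. These fixtures
exercise geometric contracts; they have no backbone, rotamers, or
packing realism, so passing tests certify the algorithms, not biophysical
accuracy on real proteins.

The corpus generator draws descriptor rows from class-conditional
diagonal Gaussians truncated into the descriptor invariants. The
lipid-binding class is shifted upward on hydrophobicity_score by
`separation` standard deviations (default 3), with mean_loc_hyd_dens
co-shifted at half that amount so hydrophobicity remains the dominant
signal — the single-feature dominance that makes the feature-importance
checks well-posed. The standard corpus is 200 LBP / 300 nLBP / 4000 PP
(20:1 pseudo-to-lipid imbalance), small enough that the whole suite runs
in well under a minute per workflow while still reproducing the
qualitative regime: high specificity and precision, depressed
sensitivity, and the sensitivity/precision reversal between balanced and
imbalanced training.

## Limitations

* Pocket-finder parameters of the original descriptor tools are not
  published exactly; the defaults here mirror their documented
  conventions, not a byte-level reproduction.
* No multimer-interface pockets, no druggability scoring, no solvent
  probes, no electrostatics.
* Real-corpus benchmarks (tens of thousands of curated PDB pockets)
  require bulk structure downloads and are out of scope; the synthetic
  corpus validates pipeline behavior, not real-data accuracy.
* Heme binders are known to be confused with lipid binders by this
  feature space; heme post-filtering is left to external predictors.
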