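# Methods

## Problem and scope

`brs3d` targets intra-family receptor-subtype selectivity of small-molecule
ligands.  For a pair of subtypes (T1, T2) and a compound with binding
affinities pKi(T1) and pKi(T2), the selectivity ratio is

    SR = pKi(T1) − pKi(T2),

a log10 affinity ratio: SR > 1 means ≥10-fold preference for T1, SR < −1 the
converse, and |SR| ≤ 1 is treated as non-selective.  Regression models
predict SR directly; discrimination models classify the selective compounds
(|SR| > 1) into T1- vs T2-selective.  The discrimination subset is therefore
always a strict subset of the regression dataset.

## Data curation

Raw binding records carry a qualifier ("=", ">", "<", "~").  Only exactly
measured ("=") records are kept; censored measurements carry no usable
magnitude for regression.  Compounds outside an inclusive 8–80 heavy-atom
window are removed (below it the shape descriptor is dominated by a single
fragment, above it rigid superposition is meaningless).  Replicate
measurements for the same compound/target are collapsed to their arithmetic
mean pKi — averaging on the log scale, i.e. the geometric mean of Ki.  A
borderline SR of exactly ±1 is read strictly, hence non-selective.

Train/test splitting is uniform at random with |TEST| = round(n·f) for test
fraction f (default 0.2, the 4:1 convention); with n = 548 this yields
438/110.

## The shape-similarity profile descriptor

A molecule's descriptor is its similarity spectrum against an ordered
library of K template conformers ("biologically relevant spectrum", BRS-3D):
element j is the best rigid-superposition similarity against template j, so
the profile lives in [0, 1]^K and is alignment-independent (each element
optimizes its own overlay).  Columns are named BRS001…BRSK.  The classic
library size is K = 300; any K is supported and the test benchmark uses
K = 20.

### Morphological similarity score

Each heavy atom is a spherical Gaussian ρ(r) = p·exp(−α|r−c|²) with
amplitude p = 2.7 and width α = κ/r_vdw² (κ = π(3p/4π)^{2/3} ≈ 2.344), the
standard parametrization that makes each Gaussian integrate to the
hard-sphere van der Waals volume.  For two conformers A, B the overlap is
the product integral O_AB = ∫ρ_Aρ_B dV (a closed-form double sum over atom
pairs), and the shape similarity is the Tanimoto

    T_shape = O_AB / (O_AA + O_BB − O_AB) ∈ [0, 1],

which is exactly 1 for identical, perfectly overlaid conformers.  Charge
character enters through a second Tanimoto T_feat computed the same way over
pharmacophore centres (donor, acceptor, positively and negatively ionizable
atoms; RDKit base feature definitions plus formal charges), each a Gaussian
of radius 1 Å, with overlaps accumulated only within matching channels.  The
pose score is 0.5·T_shape + 0.5·T_feat, or T_shape alone when neither
molecule has any feature centre.  This scorer is the package's own,
fully documented substitute for proprietary morphological-similarity
implementations: same contract (rigid overlay, [0, 1], shape + charge).

### Superposition

The query is rigidly moved (rotation + translation) to maximize the pose
score.  Starts: centroid alignment with the 4 proper principal-axes sign
combinations, topped up to 24 with seeded random rotations.  All starts are
first advanced together by a vectorized Adam ascent (30 iterations, step
0.1) using the local-frame gradient (translation gradient plus the torque
for an infinitesimal rotation); starts that have fallen into the same basin
(pairwise RMSD < 0.3 Å) are merged and one representative per basin is
polished with L-BFGS-B on a rotation-vector + translation parameterization
with analytic gradients (score tolerance 1e-4, ≤200 iterations).  Local
optima closer than 0.25 Å RMSD are deduplicated (ties keep the earlier,
deterministic start) and up to n_poses = 10 poses are returned sorted by
score; only the best enters the profile.  The optimizer is deterministic per
seed; measured contracts: self-similarity 1 ± 1e-3, rigid-motion invariance
of the best score below 1e-3, symmetry |best(a,b) − best(b,a)| below 1e-2.

### Conformer generation

One conformer per molecule: RDKit distance-geometry embedding (ETKDGv3,
seeded) followed by MMFF94 minimization (UFF fallback), hydrogens explicit,
Gasteiger partial charges.  Single-conformer encoding keeps the descriptor
cheap; conformational flexibility is only captured implicitly through the
multiple templates.

### Template library construction

Candidates are compared all-against-all (both orderings, averaged) to give
a self-similarity matrix with unit diagonal.  Average-linkage hierarchical
clustering of d = 1 − s is cut into K clusters and each cluster contributes
its medoid (maximum total within-cluster similarity, ties to the lowest
index).  The choice of average linkage + medoids is deterministic and
standard for similarity-matrix diversity picking; a greedy MaxMin picker is
available behind `method="maxmin"`.

## Models

Random-forest importance ranking (500 trees, seeded, impurity-based) orders
the profile columns; nested subsets of the top 1/5/10/20/40/60/80/100% are
the canonical feature-selection grid (round(f·K), minimum 1).  The estimator
default is `feature_fraction=1.0` (all columns): on a 20-axis benchmark the
literature's 10% fraction would keep only 2 columns, fewer than the planted
signal dimensions, so fractions are opt-in rather than a default.

The SVM uses an RBF kernel.  C ∈ {2⁻²…2¹⁰} and γ ∈ {2⁻¹⁰…2²} (log₂ grid)
are tuned by 10-fold cross-validation on the training set — scored by q²
over pooled out-of-fold predictions for regression and by the rank-statistic
AUC of pooled out-of-fold decision values for discrimination (stratified
folds).  Ties go to smaller C, then smaller γ.  ε-SVR uses ε = 0.1 (library
default).  After selection the model is refit on the whole training set.

## Assessment

* q² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² on out-of-fold or test predictions (≤1, may be
  negative); r² = squared Pearson correlation; RMSE = √(Σ(y−ŷ)²/n).
* SE, SP, ACC, MCC from confusion counts; a metric whose denominator
  vanishes is defined as 0.
* AUC is computed as the Mann–Whitney rank statistic, P(s⁺>s⁻) + ½P(tie).
* Resampling: the 4:1 split + tune + evaluate cycle repeated (default 100×)
  with per-repeat training q²_cv and test r²/RMSE.
* Y-randomization: the training response is permuted (descriptors and the
  y multiset untouched), the SVM refit at the true model's (C, γ) — the grid
  is not re-searched per shuffle; re-tuning 500 shuffles would dominate the
  runtime and only inflate the null — and 10-fold q² plus test metrics
  recorded, 500 shuffles by default.  Because the shuffled-model test-set
  quantity can be negative it is reported in the predictive-q² form
  (1 − PRESS/SS), alongside the squared correlation.
* Applicability domain: the selected-feature design is augmented with an
  intercept column; leverages are diag(X(XᵀX)⁻¹Xᵀ) for training rows and
  xᵀ(XᵀX)⁻¹x for test rows, with warning leverage h* = 3p/n (p = features
  + 1).  Standardized residuals divide by the training residual sd (ddof 1),
  the common Williams-plot convention; |·| > 3 flags a response outlier.  A
  singular Gram matrix falls back to the pseudo-inverse with a warning;
  p ≥ n is an error.
* PCA interpretation: column-standardized PCA over the top-ranked features;
  constant columns are dropped with a warning.

## Synthetic benchmark

The generator emulates a curated pairwise selectivity dataset without any
database access.  Molecules come from a seeded fragment grammar (aromatic/
aliphatic scaffolds × common substituents, one- or two-ring, 8–24 heavy
atoms).  Defaults: 200 compounds, a 20-template library diversity-selected
from 40 held-out grammar molecules, 5 informative axes, noise σ = 0.4.
The planted signal is SR_true = profile[:, informative]·w with w drawn
orthogonal to the profile column-mean direction (so SR_true is exactly the
stated linear form and mean-zero, keeping both selective classes populated)
and scaled to sd 1.25; with σ = 0.4 the attainable test r² lands in the
0.6–0.8 band typical of curated selectivity data.  Affinities are
pKi(T1/T2) = 7 ± SR_true/2 + N(0, σ/√2), so observed SR = SR_true + N(0, σ).
The activity table plants ~10% qualified rows (discarded by curation) and
~5% replicate pairs written as pKi ± δ (averaging back to the planted value
exactly), so curation has a known ground truth.

What the benchmark does *not* emulate: real chemotype diversity,
inter-laboratory assay heterogeneity beyond qualifiers/replicates,
activity-cliff structure, or the 300-template scale.  Passing tests
demonstrate that the machinery recovers a planted shape-linear signal at
desk scale, not that any particular receptor family is predictable.

## Problem sizes and numerical choices

The test suite and the acceptance script run the benchmark at its default
size (200 compounds × 20 templates, ≈4,600 rigid superpositions per profile
pass) and share one generated benchmark per session; the parameter-recovery
check varies ten split/model seeds over it and takes its medians, and the
acceptance script recomputes the full profile table through the transformer
with an independent seed before modeling.  Y-randomization runs 100 shuffles
in the suite and the full 500 in the acceptance script; resampling summary
uses 10 repeats there.  These sizes are the package's choice of a
desk-scale experiment; all counts are parameters.

Degenerate inputs: empty curation output returns an empty list with a
warning; a failed superposition contributes a 0 profile element (lowest
similarity, fixed dimensionality) with a logged warning; constant responses,
single-class label vectors, saturated hat matrices and sub-minimum dataset
sizes raise errors naming the problem.

## Known limitations

* Rigid-body superposition only: no torsional alignment, so conformer
  quality bounds descriptor quality.
* The Gaussian-overlap scorer is a documented stand-in with the same
  contract as proprietary morphological-similarity scorers, not a
  re-implementation of any of them; absolute profile values differ even
  though the workflow's statistical behaviour is preserved.
* Published external-data model statistics (database-scale q²/r² per
  receptor pair) are not reproducible from a desk-scale synthetic benchmark
  and are not claimed; what is reproduced exactly is the assessment
  arithmetic on the published confusion tables and the leverage threshold.
* Training-set CV-aggregated confusion metrics in published tables cannot be
  recomputed from printed counts without the fold assignments; only test-set
  cells are asserted.
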