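# Methods

This note records the model, the numerical choices and the design decisions
behind metchem, and what the synthetic-data tests do and do not establish
about real data.

## Input model and alignment

The unit of analysis is a metabolite panel (name, SMILES, HMDB accession)
aligned by name to a samples × metabolites concentration matrix with a
categorical sample group. Names are the single join key; duplicates are an
error rather than a silent merge, because every downstream table is keyed on
them. SMILES that fail to parse are retained in the panel with
`valid=False` and excluded from all structural computation, so record counts
in reports stay faithful to the input. Missing concentrations are imputed
per metabolite by the column minimum by default — the metabolomics
convention that a missing intensity sits at the detection floor — with
`median` and `none` (strict) selectable.

## Structural distance

Fingerprints default to circular (Morgan) fingerprints, radius 2, 1024
bits; RDKit path fingerprints and MACCS keys are selectable. The radius-2 /
1024-bit choice is the common operating point for small-molecule Tanimoto
similarity: radius 2 captures atom environments up to four bonds wide, and
1024 bits keeps collision rates negligible at panel scale (tens to hundreds
of molecules). Tanimoto dissimilarity on two bit sets is
`1 − |A∩B|/|A∪B|`; two empty fingerprints (feature-free molecules) are
defined to be at distance 0. This dissimilarity is a metric on bit sets,
which the property tests exercise on random triples.

## Classical MDS

The dissimilarity matrix is embedded by deterministic Torgerson scaling:
double-center `−D²/2`, eigendecompose, keep at most 50 strictly positive
eigenvalues (tolerance `1e-12` relative to the spectral radius), order axes
by descending eigenvalue and fix each axis sign by making its
largest-magnitude loading positive. Tanimoto matrices are generally
non-Euclidean, so negative eigenvalues are expected and truncated; an input
with no positive eigenvalue (e.g. all-zero distances) is reported as
degenerate rather than silently embedded. A deterministic spectral method
was preferred over an iterative stress optimizer so that the only
stochastic stage in the pipeline is the accuracy-maximization step.

## Accuracy-maximization embedding

The 2D "chemical distance" map sharpens local cluster structure before
hierarchical clustering. Each of `cycles` (default 20) independent cycles:

1. assign each point a random label from `n_classes` (default 5) classes;
2. relax: visit points in random order, each taking the majority label of
   its `knn` nearest neighbours (default 5, capped at n−1; ties broken by
   stable neighbour order);
3. after each sweep compute the leave-one-out cross-validated accuracy —
   the fraction of points whose label equals their neighbourhood majority —
   and stop when it no longer increases (cap 20 sweeps).

The proximity of two points is the fraction of cycles in which they end
with the same label, so entries lie exactly on the grid {0, 1/cycles, …,
1}. Within a tight cluster the relaxation floods one label and proximity
approaches 1; between clusters labels coincide only by chance
(≈ 1/n_classes). The 2D map is the classical MDS embedding of
`1 − proximity`; a fully degenerate proximity maps all points to the
origin.

The classifier choice matters: a pure 1-nearest-neighbour update was tried
first and rejected, because any mutual-NN pair forms a self-consistent
fragment that never merges with its family's majority, leaving persistent
sub-blocks inside a family; the silhouette criterion then over-splits
(k* = 5–6 on a 3-family panel). Majority vote over k = 5 neighbours lets
the family majority absorb such fragments while still never crossing
between well-separated families, and recovers the planted family count in
every tested seed. All four knobs (cycles, n_classes, knn, sweep cap) are
exposed in the configuration.

Randomness is governed by one integer seed; per-cycle and per-repeat
generators are derived through `numpy` seed sequences, giving one-number
reproducibility without correlated streams.

## Class detection

The structural chain up to MDS is deterministic, so the `repeats` (default
10) re-run only the accuracy-maximization stage, each with a derived seed.
Per repeat, Ward linkage on the 2D coordinates is cut at every k in
[2, kmax] (`kmax` defaults to `min(30, n−1)`; an explicitly requested
kmax ≥ n is a parameter error) and the mean Rousseeuw silhouette recorded;
singleton clusters contribute 0 to the index. k* maximizes the
repeat-averaged profile, ties going to the smallest k (parsimony). Final
labels use all repeats rather than an arbitrary representative run:
average-linkage consensus clustering on `1 − co-association` at k*.
Downstream per-class dendrograms are built by Ward linkage on the
repeat-averaged embedding distance matrix, which is stable across the
stochastic repeats and is saved to disk so a later module stage reproduces
the end-to-end results exactly.

## Modules and eigen-metabolites

Within a selected class, every dendrogram branch with at least `min_size`
(default 3 — a 2-member "module" is just a pair) leaves is a candidate
module, numbered by depth-first traversal from the root so identifiers are
reproducible for a fixed tree. Nested and overlapping modules are all
reported; no pruning or orthogonalization, since a branch and its
sub-branches are distinct hypotheses about where the chemical coherence
lies.

The eigen-metabolite standardizes member columns to zero mean and unit
variance (so concentration scale per metabolite is irrelevant; the tests
assert exact invariance to scaling one member by 10) and takes the first
principal component's sample scores, sign-fixed so the mean correlation
with the member profiles is non-negative. `variance_explained`
(first eigenvalue over trace) measures module coherence. Constant columns
are dropped with a warning; a module left with fewer than two usable
members is degenerate and skipped.

Group screening uses the two-sided Mann–Whitney U test per module (exact
for the tie-free small-n case; Welch's t selectable) with
Benjamini–Hochberg adjustment across the modules of a class. At the
reference design of 6 samples per group the exact test's two-sided p-values
are discrete with minimum 2/C(12,6) ≈ 0.0022, which the calibration keeps
within the nominal level. A completely tied module (no variation at all) is
reported with mid-rank statistic and p = 1.

## Metabocard annotation and enrichment

The parser is namespace-agnostic over HMDB v4/v5 element names and total on
partial cards: absent blocks yield empty fields. Attribute kinds are the
five named blocks — substituents, taxonomy (encoded `rank:value` over
kingdom / super_class / class / sub_class), enzymes (gene symbol, falling
back to protein name), diseases and pathways. Enrichment is the standard
over-representation design: for each (module, attribute value) a one-sided
Fisher's exact test on the 2×2 table over the *annotated universe* (valid
panel metabolites with a parsed card; metabolites without a card are out of
scope rather than counted as non-carriers), testing only values carried by
at least two metabolites in scope, with BH adjustment over all pairs. The
universe is deliberately the panel, not the whole of HMDB: the question
answered is "is this substituent concentrated in this module relative to
the panel", which is self-contained and desk-scale.

## Synthetic data: what it emulates, and what it does not

The generator plants three levels of structure:

* **Structural families** — homologous series (straight-chain fatty acids,
  alpha-amino acids with varied side chains, N9-alkyl adenines) rather than
  random SMILES, so within-family Tanimoto similarity is graded and high
  and between-family similarity low, as in real chemical classes.
* **Module covariance** — members of a planted module share a latent
  per-sample score with configurable loading.
* **Group effects** — an additive shift, expressed in units of the noise
  SD, applied to one group's members of a module.

Concentrations are log-normal (Gaussian structure in log space,
exponentiated), matching the positivity and right skew of real intensities
and giving the floor-imputation path something meaningful to impute. The
default design is 6 samples per group — a typical small animal-study
arm — with noise SD 0.5 in log space and unit loadings.

The generator does **not** simulate instrument drift, batch effects,
heteroscedastic noise, censored (left-truncated) intensities or correlated
families of effects. Passing the planted-recovery and calibration tests
therefore shows the algorithms are correct and well-calibrated under clean
log-normal conditions, not that a real study of this size has the measured
power.

The test-calibration simulation (20 disjoint 5-member modules, 6 vs 6,
one module shifted by 2 noise-SD) sets the latent loading to zero: it
calibrates the *test*, so the eigen-metabolite averages independent member
noise and the planted shift appears at the score level at roughly
`2·√m · σ`-to-`σ` odds. With a strong shared latent score instead, the
latent acts as irreducible between-sample variance — no test statistic can
remove it — and a 2-SD member-level shift is not reliably detectable at
n = 6 per group by any method; module size 5 mirrors the scale of modules
the pipeline is meant to flag.

## Numerical and reproducibility choices

* Exact symmetry of the Tanimoto matrix is enforced (`(D + Dᵀ)/2`) before
  validation; both-empty fingerprint pairs are set to distance 0.
* `cut_tree` (exact cluster counts) is used instead of threshold-based
  cutting, so every k in the silhouette profile has exactly k clusters.
* All CSV output uses a fixed `%.12g` float format; two runs from the same
  manifest are byte-identical, which the test suite asserts via SHA-256.
* Seeds derived from the master seed stay below 2³¹.

## Known limitations

* Fingerprint schemes are 2D-topological only; stereochemistry and 3D shape
  do not influence the distance.
* The accuracy-maximization step guarantees the behavioural contract
  (planted-structure contrast, determinism, grid-valued proximities), not
  parity with any particular prior implementation of the idea.
* Silhouette-based k selection inherits silhouette's bias towards compact,
  balanced clusters; strongly nested class structure may select a coarser k
  than visual inspection would.
* Enrichment treats attribute values independently; hierarchically related
  substituents are tested separately with no ontology-aware pruning.
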