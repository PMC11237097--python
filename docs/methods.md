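# Methods

This note records what the package computes, the conventions and
numerical choices behind it, and what its synthetic study conditions do
and do not establish about real structural data.

## From structure files to ensembles

**Sequence extraction.** Only the first model of a multi-model file is
read. A chain's sequence comes from the entity's declared polymer
sequence when present: residues with resolved backbone coordinates are
uppercase, declared-but-unresolved residues lowercase, unknown or
unmappable residue types `X` (modified residues map to their natural
parent through gemmi's residue table, e.g. MSE→M). A residue missing
any backbone atom other than O is treated as unresolved; a missing
carbonyl O is rebuilt at 1.23 Å from C, in the plane of CA, C and the
next residue's N, opposing the bisector of the CA→C and N(i+1)→C
directions — for chain-terminal residues the CA→C direction is extended
instead and the atom is flagged as reconstructed. Chains with fewer
than 5 resolved residues or fewer than 5 non-`X` letters are dropped.
When entries lack a declared polymer sequence, the observed residues
are emitted with no lowercase encoding (nothing else is knowable).
The *monomer-only* option excludes chains from entries whose first
listed biological assembly contains more than one polymer chain,
falling back to counting the asymmetric unit's polymer chains when no
assembly is annotated.

**Clustering and alignment.** Default thresholds are 80% sequence
identity and 80% bidirectional coverage. The built-in clusterer is
greedy-incremental over descending sequence length: a sequence joins
the first cluster whose representative it matches at both thresholds,
with identity and coverage measured on a semi-global BLOSUM62 alignment
(affine gaps −11/−1). It is intended for moderate input sizes; an
MMseqs2 adapter exists for large collections and fails loudly when the
executable is absent rather than silently substituting. Alignment uses
MAFFT (`--auto --amino --preservecase`) when available, else a built-in
center-star progressive aligner (center = highest total pairwise score;
merge by once-a-gap-always-a-gap). Aligned clusters are post-processed:
columns containing only `X`/gaps are removed and rows are ordered by
structure code. At ensemble construction, columns without a single
*resolved* residue (only lowercase/gap/`X`) are additionally dropped so
every retained position carries at least one real coordinate.

**Reference choice.** The per-column consensus is the modal symbol over
the 20 amino acids plus gap (`X` counts as gap). Frequency ties prefer
an amino acid over a gap, then the higher BLOSUM62 self-score, then the
alphabet; a flag inverts the first two rules to probe the robustness of
the choice. Each row is scored against the consensus with BLOSUM62,
any gap/`X` position contributing the gap score −5 (= matrix minimum
− 1); the argmax row is the reference, ties resolved by the smallest
identifier. Lowercase (unresolved) residues are scored as their amino
acid — the score judges sequences, not coverage.

**Superposition.** Each conformation is fitted to the reference over
the positions resolved in both, minimizing the weight-normalized
squared deviation; the rotation is the SVD-based weighted Kabsch
solution with reflection correction (any exact minimizer would do — the
contract is the minimum, verified against 1000 random rotations and
against an independent solver in the tests). Weighted centroids are
matched exactly. Conformations sharing fewer than `min_aligned` (5)
positions with the reference are dropped and reported. Degenerate
(collinear) fits are flagged but still return the minimizer.

**Redundancy.** A conformation A is removed when some retained B lies
within `rms_cut` (0.1 Å) Cα RMSD over their shared resolved positions
*and* A's sequence is identical to or included in B's (every non-gap
symbol of A matches B, and A resolves nothing outside B's resolved
set). Candidates are visited reference-first, then by descending
resolved length and ascending id, keep-first — the order decides which
of two mutual near-duplicates survives, so it is fixed and documented.
Pairwise RMSDs in the output matrix are computed in the common
superposition frame (per-pair refitting is a documented alternative the
package does not use, keeping the matrix consistent with the ensemble's
coordinates as written).

**Missing data.** Unresolved entries of **R** are imputed with the
centering conformation — the per-column mean over resolved entries by
default, or the reference conformation on request (reference gaps fall
back to the column mean). This choice invents no geometry and shrinks
the variance of poorly covered columns toward zero; a column resolved
in a single member contributes exactly zero variance. The optional
uncertainty weighting multiplies each position's coordinates by its MSA
coverage fraction before the decomposition (and inside the
superposition objective); generated conformations are divided by the
weights on output so they live in Å space — an inverse step the
weighting scheme needs for Å-comparable RMSDs.

## Decomposition and statistics

The covariance eigensystem is obtained from the SVD of the centered
(optionally weighted) coordinate matrix, never materializing the
3m×3m matrix; with mean centering at most min(n−1, 3m) components
exist. A correlation-matrix variant divides centered coordinates by
their ddof-1 standard deviation, making the modes scale-invariant;
zero-variance coordinates are excluded from the normalization with a
warning. Eigenvalue fractions are reported relative to their sum in
both variants (the correlation spectrum is not rescaled to sum to 1 —
its trace is the number of non-degenerate coordinates, and we prefer
reporting raw fractions over hiding that).

Collectivity uses the per-atom convention: the 3 components of each
atom are pooled into one squared displacement before the exponential
entropy. A per-coordinate variant would assign a uniform vector the
value 3 rather than 1 and violate the 1/m single-atom limit, so the
per-atom form is the only one consistent with both boundary cases.

MSA quality is summarized by: column-averaged pair identity (pairs
where either row has a gap or `X` are excluded from the denominator —
counting them would conflate divergence with incompleteness); coverage
as the percentage of columns with strictly less than 20% gaps; and a
sum-of-pairs score (+1 match, −0.5 mismatch, −0.5 residue-vs-gap,
gap-gap pairs 0, `X` as gap) normalized by C(n,2) times the largest
per-row residue count.

## Generation benchmark

Conformations are k-means-clustered (k = l + 2, fixed seed, 10
restarts) in the l-dimensional PCA space, where l explains 90% of the
variance. Each cluster is held out in turn; the model — PCA, or kernel
PCA with an RBF/polynomial/sigmoid kernel (γ = 1/(2σ²), offset c = 1,
degree 3 by default) and a kernel-ridge pre-image regressor of the
training coordinates on their projections (same kernel family and
width, regularization α) — is fitted on the rest. Held-out
conformations are projected, reconstructed, and scored by the RMSD to
the original and by the distance of their projection to the convex
hull of the training projections, divided by √m. Hyperparameter
selection, when requested, grid-searches σ over the median pairwise
distance × {0.25…8} and α over {1e−10…1e−2}, minimizing the mean CV
RMSD of the test clusters themselves — an optimistic protocol, labeled
as such; nested selection is the caller's choice of folds away.
Kernel-PCA components use the standard unit-feature-norm scaling; the
pre-image regressor fits no intercept, so its large-α limit is the
zero conformation.

The hull distance solves min ‖Σθ_i t_i − p‖² s.t. θ ≥ 0, Σθ = 1:
an SLSQP pass identifies the active support, then the
equality-constrained least-squares problem on that support is solved
exactly through its KKT system (support shrinks until feasible). In
the ≤10-dimensional representation spaces involved this matches
exhaustive face enumeration to 1e−8. Holding out one of l + 2 clusters
leaves l + 1, so the training hull spans a full l-polytope.

Interpolation between two states fits the model on the two clusters
only, places the requested number of regularly spaced points strictly
between the cluster centres in representation space, maps each point
back to coordinates, and reports per-point minimum RMSD against a
held-out set when given.

## Synthetic study conditions

The fixture generators emulate the geometry of the problem, not its
chemistry: Cα traces are 3.8 Å self-avoiding walks expanded to
N/CA/C/O by idealized internal coordinates (format-valid, not
stereochemically plausible), sequences are uniform random over the 20
amino acids. Motion directions are drawn orthogonal to the six
rigid-body modes of the base trace, so superposition leaves the
planted motion intact. **Amplitudes are in Å of per-atom RMS
displacement** (the 3m-direction is scaled by √m): a conformation at
amplitude a deviates from the base by RMSD a, and an ensemble spanning
±a has endpoint RMSD ≈ 2a. Defaults — m = 50 positions, n = 30
conformations, amplitude 2 Å, noise 0.2 Å per coordinate (10% of the
amplitude) — give a signal-to-noise ratio at which the planted mode
carries ~93% of the variance, so one component explains 90% and mode
recovery is near-perfect. The hinge generator rotates the second half
of the trace about a pivot, with the axis chosen so the inter-domain
centroid distance grows monotonically with the angle; collectivity of
the resulting first mode is assessed *after* superposition, where the
least-squares frame distributes the apparent motion over both domains
as it does for real hinge proteins. The arc generator bends a
one-parameter path across two directions, giving linear models a
curvature they cannot extrapolate — the condition under which kernel
PCA's advantage and the error-vs-hull-distance relationship are
demonstrated. The gapped-CIF writer declares the full polymer sequence
but omits atoms for a random fraction of residues (keeping every
position resolved somewhere and every chain ≥5 resolved residues), and
plants a rotated second model plus a 4-residue decoy chain to exercise
the parsing rules.

Passing these conditions shows the machinery is correct and
well-calibrated on data whose ground truth is known exactly. It does
not show that real families have low-dimensional motions (that is an
empirical claim about data the user must bring), nor that the
idealized backbones would survive stereochemical checks, nor how the
heuristics of external aligners behave on divergent sequences.

## Numerical choices and limitations

- Coordinates are Å throughout; residue numbering is 1-based, alignment
  columns 0-based internally.
- Mean imputation of gapped columns deliberately deflates their
  variance; with many gaps and few members this can *add* small
  apparent dimensions relative to the fully resolved truth (the
  tail of the imputed columns' residual variance), which is why
  dimensionality-recovery claims are made on fully resolved fixtures.
- Projections of external conformations assume the ensemble frame; a
  centroid offset beyond 100 Å triggers a warning rather than an error.
- The built-in clusterer and aligner are test-scale tools: quadratic in
  the number of sequences and heuristic in quality; for production-size
  collections use the external backends.
- Pipeline stages are deterministic and run sequentially per cluster;
  per-cluster results are independent of processing order, so the run
  report is bit-stable across repeats.
- Singleton and pair collections are built and written but flagged
  `excluded_from_statistics`, since a 1- or 2-member spectrum says
  nothing about dimensionality.
- Problem sizes in the test suite (m ≤ 50, n ≤ 40) are chosen so the
  full suite exercises every stage, including cross-validation, in
  seconds; all quantities scale to real ensembles through the same code
  paths.
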