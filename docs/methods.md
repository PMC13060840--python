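# Methods

This note records the models implemented in `saxsfold`, their assumptions,
the conventions that had to be fixed where the underlying science leaves a
free choice, and what the synthetic test conditions do and do not
demonstrate.

## Scattering model

Atoms are treated as q-independent point scatterers with form factor
`f_i = Z_i`, the electron count, taken from a built-in element table.
Hydrogens absent from an input file are **not** imputed by default; an
optional united-atom mode adds the implicit hydrogens of the 20 standard
amino acids to their bonded heavy atoms (one H on backbone N except proline,
one on CA except glycine's two, side-chain counts from standard valence).
Waters, alternate locations other than blank/'A', and zero-occupancy atoms
are dropped at parse time and logged.  Explicit hydration shells,
excluded-volume corrections, and q-dependent form factors are out of scope;
they are the natural extension points.

**P(r).**  The pair distance distribution is a histogram over unordered
distinct atom pairs, each contributing weight `2 Z_i Z_j` to the bin
containing its distance.  Bins have width `dr` (default 0.5 A, a practical
compromise between resolution and smoothness for protein-sized molecules),
centers at `(k + 1/2) dr`, and a distance exactly on a boundary goes to the
upper bin — a convention that must be fixed somewhere for bit
reproducibility.  The q-independent self term `sum(Z_i^2)` is stored on the
curve rather than folded into the r=0 bin: mixing it into the histogram
would break the exact Fourier relation between the two spaces.

**I(q).**  The Debye sum is evaluated directly over pairs,
`I(q) = sum(Z_i^2) + sum_{i<j} 2 Z_i Z_j sinc(q r_ij)`, with `sinc(0) = 1`,
so `I(0) = (sum Z_i)^2` holds exactly.  `pr_to_intensity` evaluates the same
sum from the binned histogram; the two agree exactly when every distance
sits on a bin center and otherwise differ by a binning error that shrinks
with `dr`.  One caveat the tests encode: the error decreases monotonically
in `dr` only for structures with *generic* distance sets.  An ideal helix
has just `n-1` distinct pair distances (one per sequence separation), so
its snapping errors do not average out and monotonicity can fail; the
reference 30-atom fixture is therefore a seeded random globule.

**Rg.**  The coordinate route is the weighted RMS distance from the
weighted centroid (electron or uniform weights).  The P(r) route uses the
second-moment relation `Rg^2 = \int r^2 P dr / (2 \int P dr)`, which holds for
the *full* pair distribution including zero-distance self pairs.  Because
the stored curve is cross-pairs only, the cross second moment is multiplied
by `W / (W + S)` (W total cross weight, S self term, both carried as
metadata).  The correction is scale-free — scaling the curve leaves Rg
unchanged — and makes the two-atom case exact (`Rg = d/2`); without
metadata the plain cross-only moment is used, whose bias vanishes as
1/n_atoms.

**Soft histogram.**  For gradient-based optimization each pair spreads its
weight over bin centers with a Gaussian kernel (default bandwidth = one bin
width, the simplest smooth kernel with a provable hard-histogram limit),
renormalized per pair so total mass is conserved and the bandwidth -> 0
limit reproduces the hard histogram.  Kernels are computed with a per-pair
max-shift before exponentiation so tiny bandwidths cannot underflow.  The
backward pass (`soft_pr_vjp`) is a hand-derived vector-Jacobian product
through the renormalized kernel and the pair distances; tests verify it
against central differences at 1e-4 relative.  All differentiable pieces in
the package (soft P(r), L1 loss, adapter MLP, surrogate head, chain
penalty) use closed-form analytic gradients — there is no autodiff
dependency anywhere.

## Losses

`saxs_l1` is the total-variation-style distance
`sum_k |p_a(k) - p_b(k)| dr` between unit-area curves.  The `dr` factor
makes the value invariant to re-binning in the fine-grid limit (a raw bin
sum would be grid-dependent); curves on different grids are compared by
resampling the coarser onto the finer grid.  The value is a metric on the
shared grid, bounded by 2 for disjoint supports.

`composite_loss` combines six externally supplied scalars under the fixed
weights (0.5, 0.5, 0.3, 2.0, 0.01, 2.0 for FAPE, auxiliary, distogram, MSA,
confidence, and SAXS terms).  The five trunk terms are consumed as inputs —
their internals belong to the host prediction architecture, not to this
package.  A missing term raises rather than defaulting to zero.

`chi2_fit` uses the closed-form scale `c = sum(I_e I_m / s^2) / sum(I_m^2 / s^2)`
and reports the per-point-averaged chi-square, the convention of standard
profile-fitting tools.  Hydration-layer contrast parameters are out of
scope; the fit is a pure linear scaling.

## Conditioning modules

`embed_pr` turns each P(r) bin into one token: a learned linear map of the
bin density concatenated with a 16-dimensional sinusoidal encoding of the
bin distance.  (How scalar bins become tokens is an implementation choice;
a flagged alternative would tokenize I(q) bins instead.)  Both attention
modules are standard multi-head cross-attention — queries from the trunk
representation (per (cluster, residue) position for the MSA module, per
(i, j) position for the pair module, with no weight sharing across the
symmetric pair), keys and values from the tokens, softmax over bins.
Defaults are 8 heads x 32 (MSA) and 4 heads x 32 (pair); the token width
defaults to `n_heads * c` of the consuming module to avoid an extra
projection.  Output projections are zero-initialized so an untrained module
is exactly the identity on the trunk; the additive update is not gated or
normalized (layer normalization is the host trunk's job).

## Inference-time optimization

The adapter is a residual two-layer MLP, `y = x + tanh(x W1 + b1) W2 + b2`,
with the final layer zero-initialized (identity at iteration 0).  The
optimizer is Adam at learning rate 1e-3 — a first-order adaptive choice
recorded in the trace header.  "Fails to improve" means the best-so-far
SAXS loss has not decreased by at least 1e-6 absolute (an exact-tie rule
would be float-fragile); after 50 consecutive such iterations, or 500
iterations total, the loop stops.  Snapshots are stored every iteration as
CA-only coordinates to bound memory; the top-50 selection is a stable sort
by loss with no deduplication of near-identical snapshots.  A checksum over
all non-adapter parameters verifies the frozen-predictor contract.

No pretrained trunk ships with the package.  `SurrogateFoldHead` is a
deterministic differentiable stand-in: `X(f) = X0 + reshape(A f) * scale`
with a seeded Gaussian `A`, a compact helical base `X0`, and `scale = 5` so
that O(1) feature changes produce Angstrom-scale coordinate moves,
comparable to real conformational transitions.  A smooth chain penalty
`sum_i (|x_{i+1} - x_i| - 3.8)^2` (weight 1e-3) keeps consecutive CA
distances near the virtual-bond length.  The adapter perturbs only this
single feature vector, the smallest faithful reading of "between the trunk
and the structure head"; perturbing the pair representation too is a
possible extension.

The recovery experiment (64 residues, extended-chain target from the
compact base, seed 0) is the standard demonstration: the best loss drops
below its initial value and the best structure's Rg moves strictly toward
the target Rg.  The movement is small — the random linear subspace
reachable by the adapter is 32-dimensional — and over repeated seeds the
Rg direction is correct in most but not all runs (7/8 at the defaults);
the loss decrease itself is robust.  Passing this experiment shows the
gradient chain and the optimization protocol are correct, not that a
surrogate head can fold proteins.

## Curation

Sequence "similarity" is implemented as global-alignment percent identity
(identical columns / alignment length) under unit match, zero mismatch, and
linear gap -1 scoring, via Biopython's pairwise aligner; the scoring is
config-exposed since no single measure is canonical.  Co-optimal alignments
can differ in identity, so the test oracle enumerates *all* score-optimal
alignments and accepts any of their identity values.  The length filter is
strict (`> 256` dropped, 256 kept), as are the apo-holo thresholds (pair
RMSD `> 4`, each conformer RMSD `> 2.5`); the per-conformer baseline RMSD
is accepted as a precomputed input column, since it comes from an external
benchmark collection.  Crops are contiguous in residue order, 1-based and
inclusive, with the window start uniform under a seed derived from the
entry id via CRC32 (stable across processes); every model of an entry gets
the same window, and each record's P(r) is recomputed from exactly its
cropped coordinates, so profiles always match structures bit-for-bit.

## Evaluation

RMSD is computed over CA atoms shared by both structures (matched by chain
and residue index) after Kabsch superposition with the determinant sign
correction (proper rotations only).  Tier boundaries read "<= 1.0 A" as
high and "1.0-5.0 A" as mid closed on the left, so 1.0 is high and 5.0 is
mid.  The unfavoured-conformer metric reports the RMSD to whichever
reference the prediction sits farther from; exact ties break to the
first-listed reference and are flagged.  The divergence-diversity statistic
is the plain Pearson product-moment coefficient and requires at least three
points with variance in both coordinates.

## Synthetic fixtures and what tests show

The generators produce CA-only traces with placeholder electron count 6:
helices (1.5 A rise, 100 deg/residue, 2.3 A radius), extended chains (3.5 A
rise with a zigzag restoring the 3.8 A virtual bond), reflected random-walk
globules, rigid two-arm hinge pairs whose RMSD grows monotonically with
hinge angle, multi-model ensembles (low-frequency bend plus local jitter,
emulating the 20-30 conformers of an NMR deposition), and Debye profiles
with multiplicative Gaussian noise whose sigma column is correctly
specified (so self-fits calibrate to chi-square near 1).  They reproduce
the *geometry* and *statistics* the pipeline consumes — compact vs expanded
P(r), small vs large conformational change, conformer heterogeneity — not
physically relaxed proteins: no side chains, packing, or solvent.  Green
tests therefore certify the correctness of the mathematics and the
protocols on well-controlled inputs; they say nothing about prediction
accuracy on real proteins, which requires a trained trunk and experimental
data and is deliberately outside this package.

## Problem sizes

The shipped tests and the acceptance script use 30-atom fixtures for oracle
comparisons, 64-residue chains for the optimization and CLI chains, and
20-model ensembles for curation — sizes chosen so every check runs in
seconds on one CPU while still exercising each code path at realistic
protein-like geometry.
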