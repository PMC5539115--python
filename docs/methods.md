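# Methods

This note records the models and procedures implemented in `flexens`, the
defaults and why they were chosen, the numerical details that affect
results, and what the synthetic-data tests do and do not demonstrate.

## Coordinate model

All structural operations work on CA-only traces. CA is the minimal
faithful backbone representation, matches TM-score convention, and keeps
ensembles rectangular `(M, L, 3)` arrays. When a multi-model PDB file is
read, residues lacking a CA atom in *any* model are dropped from all
models (intersection), so every downstream array stays rectangular; the
dropped residue ids are logged. Author residue numbering is kept verbatim;
insertion codes are rejected (they are rare in NMR-style entries and
supporting them would make residue identity ambiguous); for alternate
locations the first is kept. Multi-chain files require an explicit chain
choice.

## Superposition and fluctuation profiles

Rigid superposition is the standard SVD-based least-squares (Kabsch)
solution with the sign of the smallest singular value corrected so that
only proper rotations are returned. The degenerate case (no rotational
information, e.g. all points identical) returns the identity rotation and
the centroid-matching translation.

Per-residue fluctuations need a reference structure. We use an
**iteratively refined mean**: all models are superposed on the current
mean, the mean is recomputed, and the loop repeats until the mean moves
less than 1e-6 Å RMS or 20 iterations have run (it converges in a handful
of rounds in practice). Mean-reference RMSF is the standard reading of a
per-residue RMSD for an ensemble; alternatives (first-model reference,
all-vs-all pairwise averages) produce nearly identical rankings but a
less interpretable scale. Superpositions are unweighted.

The **sliding-window profile** applies this machinery to every window of
`window` consecutive residues (default 10, step 1; the final window is
anchored to include the C-terminal residue). Each residue's fluctuation is
averaged over the windows covering it, so interior residues average ~10
window estimates and terminal residues fewer. Because each window is
superposed independently, any per-model rigid motion of the whole chain
cancels exactly — the property the windowed profile exists for. The
**global profile** is the same fluctuation computed after one whole-chain
superposition; comparing the two shows how whole-chain superposition
spreads tail motion into rigid cores.

Window size 10 balances two failure modes: much shorter windows contain
too few atoms for a stable superposition; much longer ones re-admit the
rigid-body leakage the method removes.

## Ensemble extraction

The raw model set is clustered on the pairwise superposed-RMSD matrix with
average-linkage agglomerative clustering; the number of clusters k is
chosen in [2, min(k_max, M−1)] (k_max default 10) to maximise the mean
silhouette width computed from the same matrix. This is a deterministic,
parameter-free-in-spirit stand-in for randomized silhouette-style
clustering procedures; determinism was preferred over fidelity to any
particular published randomized variant so that results are exactly
reproducible. A single cluster is returned only when M < 3 or all
distances vanish (silhouette is undefined there; its quality is reported
as −1). The final ensemble is the most populous cluster; ties go to the
cluster with the smaller mean intra-cluster RMSD, then to the lower
cluster id.

## Profile scoring

Profiles are compared with Spearman's rank correlation (average ranks for
ties). Rank correlation is the only fair comparison across methods whose
outputs live on different scales (angstroms, order-parameter scores,
arbitrary levels). Profiles with mismatched residue coverage are compared
on the inner join of their residue ids, with the number of dropped
residues logged. A constant profile has no defined rank correlation and
raises an error rather than returning a silent NaN; summaries report the
mean, median and the counts of negative, good (≥ 0.6) and excellent
(≥ 0.7) correlations.

A note on attainable values: if the reference profile contains tied
groups, the maximum attainable Spearman correlation is below 1. For a
two-level step profile over 60 residues (40 low + 20 high) the cap is the
point-biserial limit ≈ 0.8165 — reached exactly when the predicted
profile separates the two groups perfectly. Recovery checks against
generator ground truth therefore use tie-free monotone amplitude profiles.

## TM-score

TM = (1/L) Σᵢ 1/(1+(dᵢ/d₀)²) with d₀ = 1.24·(L−15)^⅓ − 1.8 clamped to
≥ 0.5 Å (required for L < 22). Residue correspondence is positional (the
pipeline compares same-protein ensembles), and the score is normalised by
the reference length. The TM-optimal superposition is not the
least-squares one, so it is searched: seeds are the whole chain plus
sliding fragments of length L/2, L/4 and L/8 (stepped by half their
length); from each seed the superposition is iteratively refined on the
inlier set (residues within a distance cutoff; cutoffs d₀, d₀+1 and 2d₀
are each tried, relaxed in 0.5 Å steps if fewer than 3 inliers remain),
and the best score seen is returned. Against an independent brute-force
search (5,000 random rotations, best candidates refined), the
implementation agrees within 0.005 on 30-residue test pairs.

Ensemble-vs-ensemble quality is the mean over predicted models of the
maximum TM-score against any reference model. The protocol is
intentionally asymmetric: neither ensemble need contain all conformations
of the other, so each predicted conformation is credited with its best
match in the reference. Scores are binned at 0.2/0.4/0.6 (half-open
intervals, 0.4 falling in the third bin) following the conventional
interpretation of TM-score ranges from random agreement up to
confidently-same-fold.

## Naive baseline

Predicted secondary structure alone already ranks flexibility: coil >
strand > helix. The numeric levels (3/2/1 by default) are arbitrary —
because scoring is rank-based, any mapping with that ordering yields
identical correlations, which the tests verify.

## Consensus predictor

A classical feed-forward network with one hidden layer (default 10 units),
sigmoid activations, and bias units feeding the hidden and output layers.
Inputs per residue: a 9-residue window × 27 features per position — the
two predictor values (min–max normalised over the training set), a 21-slot
amino-acid one-hot (20 standard + unknown), the three secondary-structure
probabilities, and one missing-residue flag set for positions beyond the
chain ends (all other slots zeroed there) — plus 3 global features:
ln(L) and the distances from the two termini divided by L. Total
9·27+3 = 246. The per-position layout follows from the 246 arithmetic; a
single missing flag per position is the only itemisation consistent with
it.

Regression targets are per-residue RMSD values squashed into (0, 1) with a
logistic y = 1/(1+exp(−(r−m)/s)); predictions are mapped back to
angstroms with the exact inverse m + s·ln(y/(1−y)) (outputs clamped to
[1e−6, 1−1e−6] first, so saturated outputs stay finite — an inverse is
only numerically meaningful within roughly m ± 10s). m and s are fitted
per training split as the median and half-interquartile range of the
training RMSD values (floored at 0.05 Å) and stored inside the model, so a
serialized model is self-contained.

Cross-validation is leave-one-group-out over fold-level structural classes
supplied by the caller; groups with a single member are pooled into one
shared group first. Within each split, 20% of the training *targets*
(whole proteins, never individual residues, to avoid leakage) are held out
for early stopping. Training is full-batch Adam (learning rate 0.01) on
the mean squared error, stopped when the validation MSE has not improved
by 1e-5 for 20 epochs (the recovery tests use a patience of 100 at 1e-6)
or at 2,000 epochs, restoring the best-validation weights. Plain
full-batch gradient descent at a fixed rate was evaluated first and
plateaus well short of the optimum within the epoch budget on planted-
function data (out-of-fold R_S ≈ 0.90 with training MSE still falling);
Adam reaches R_S ≈ 0.98 in seconds and keeps the procedure deterministic
for a fixed seed, so it is the default optimiser. Weight initialisation is
seeded Gaussian scaled by 1/√fan-in.

## Synthetic data

The generator emulates exactly the structures the pipeline consumes:

- **Ensembles**: an ideal α-helix (1.5 Å rise, 100° turn, 2.3 Å radius)
  or a self-avoiding 3.8 Å-step random walk, plus isotropic Gaussian
  displacements with per-residue, per-coordinate standard deviation
  σ(i); optionally a random rotation (uniform over SO(3)) and translation
  (uniform in [−20, 20]³ Å) per model. Under this model the true RMSF is
  σ(i)·√3, so σ is exact ground truth for rank-recovery checks.
- **Predictor stand-ins**: strictly monotone (affine or logistic)
  transforms of a true profile plus Gaussian noise.
- **Training sets**: per target, an ensemble-derived windowed profile as
  the regression target and two predictor profiles carrying either
  redundant or complementary halves of the signal (the true amplitude is
  the sum of two smooth components and each predictor sees one), plus a
  planted-linear control where the target is exactly a noiseless linear
  function of the two predictors.

What this does **not** emulate: correlated or anisotropic displacements,
dihedral-space geometry, excluded volume beyond the walk's self-avoidance,
sequence-dependent flexibility, or realistic secondary-structure error.
Passing tests therefore demonstrate that the algorithms recover what they
are defined to recover under their own noise model — not that predictions
on real proteins reach any particular accuracy. Benchmark-scale claims
(distributions of R_S over real NMR ensembles) require real ensembles and
external predictor runs, which are deliberately outside this package.

## Problem sizes and determinism

Tests and the acceptance script run on small instances chosen to make the
statistics stable: profile recovery uses L=60, M=50 ensembles (5 seeds);
clustering uses planted 8/6/4 partitions with a 10× separation-to-spread
ratio; TM-score checks use 30-residue pairs against a 5,000-rotation
search; consensus recovery uses 20 targets × 60 residues (planted linear)
and 10 independent 12-target complementary sets. Every random draw is
seeded, and the training loop is fully deterministic given its seed.

## Known limitations

- Single-chain, CA-only; no mmCIF, hetero-atoms or insertion codes.
- The clustering stage is a deterministic substitute for randomized
  parameter-free procedures; on data without clear cluster structure the
  silhouette-optimal k is often 2 with near-zero quality, and the
  "largest cluster" is then close to the full set.
- TM-score uses positional correspondence only — no alignment search —
  so it applies to same-protein comparisons.
- The consensus network is a small fully-connected model; it exposes
  window size and hidden-unit count but no other architecture knobs.
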