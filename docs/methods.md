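# Methods

This note documents the models, parameters, numerical choices and known
limitations of featureforge, in the order data flows through the package.

## Chains, labels and the Ø mask

A `Chain` is a per-residue record: three-letter codes preserved verbatim
(so non-canonical residues keep their identity), one-letter codes via an
extensible ncAA mapping table (`data/ncaa_map.tsv`; unknown codes → `X`),
8-state labels, optional backbone N/CA/C coordinates and a `resolved` flag.
Unresolved residues always carry the technical ninth label Ø (rendered
`-`), which is excluded from every loss and every metric; it marks missing
structure, not a biological state. The 8→3 collapse is H,G,I→H; E,B→E;
T,S,C→C — the dominant community convention; blank or polyproline-II DSSP
codes fall into C (the standard loop/irregular convention). Multi-model
(NMR) files use the first model only. Residue indexing in the API is
0-based; author residue numbers are kept solely to reconcile DSSP and
disorder files. Dataset filtering is predicate-based with a `strict()`
preset (X-ray only, resolution ≤ 3.0 Å, length 40–10 000, R-factor ≤ 0.3);
a criteria-free call is the identity, so filtering is always explicit.

## Protein-block geometry

The 16 reference pentapeptides are rebuilt at load time from the vendored
torsion table (`data/pb_dihedrals.tsv`, the published de Brevern structural
alphabet angles) with ideal peptide geometry (N–CA 1.458 Å, CA–C 1.525 Å,
C–N 1.329 Å; angles 111.2°, 116.2°, 121.7°; ω = 180°) via natural-extension
(NeRF) chain building. Self-consistency (rebuild → superpose → RMSD < 1e−6 Å)
is asserted in tests. RMSD is computed over the 15 backbone atoms only
(N, CA, C of 5 residues); Cβ/O are excluded — the minimal convention
consistent with describing backbone configuration.

Superposition uses the Kabsch SVD solution restricted to proper rotations
(determinant correction), with the RMSD evaluated from the *rotated
residuals* rather than the Gram-trace identity: the trace formula loses up
to seven digits to cancellation near zero, while the residual form is
accurate to machine precision (the test suite checks agreement with an
independent quaternion-method oracle to < 1e−9 on 1000 random pairs).

A fragment vector is defined at position p when residues p−2..p+2 exist and
are resolved; otherwise the position carries an explicit NaN marker.
Statistics are accumulated in a single pass with Welford vector updates
(unbiased variance, divisor N−1; a single observation leaves the variance
undefined). Per pattern key the accumulator also counts the argmin-PB
letter strings over the key's window, which feeds the PB-sequence
probability descriptors.

## Reduced alphabets and pattern keys

An alphabet partitions the canonical letters into groups, per fragment
position (central positions usually finer than tails). A fragment maps to
the concatenation of its per-position group ids, so key equality is exactly
fragment equivalence. Definitions live in YAML (`data/alphabets.yaml`);
`full: true`, `all_positions:` and per-`positions:` forms are supported,
with a wildcard class for letters outside the partition (e.g. `X`).
Compilation validates disjointness and coverage. The named `PB_*` alphabets
reserve catalog names whose published group membership is not distributed
here; their placeholder definitions are flagged `unverified` and should be
replaced by users who have the original definitions.

## RMSD-based descriptors

The t-statistic compares a key's mean RMSD to block j against the corpus
mean with the Welch pooled standard error s_j(seq) = sqrt(σ²_j(seq)/N_occ +
σ²_j/N). Keys with N_occ < 2 yield an undefined (NaN) value — imputation is
deferred to the feature-matrix stage. A zero pooled standard error clamps t
to ±38 (Φ saturates far earlier) instead of raising. The probability
transform is the standard normal CDF rather than a Student-t CDF: with
typical N_occ the difference is negligible and it avoids per-key
degrees-of-freedom bookkeeping.

PB-sequence probabilities use Laplace smoothing with α = 1 over the
vocabulary V of distinct PB strings observed for the alphabet — keys are
sparse by construction, and unseen keys fall back to the uniform prior 1/V.

Catalog entries (`data/catalog_rmsd.yaml`) carry an integer `offset` (the
descriptor at position p is evaluated at p + offset; out-of-range → NaN)
and an integer `power`, applied *after* the probability transform so values
stay in [0, 1]. Entries whose PB string has length > 1 are interpreted as
PB-sequence probabilities and single letters as per-block t-statistics;
this interpretation rule is a package choice and is flagged in the catalog.

## Physicochemical descriptors

Property scales are read from AAindex flat files or two-column TSVs.
Scales are z-standardized across the 20 canonical residues by default
(removing AAindex unit heterogeneity; raw mode available); ncAA entries are
transformed with the same affine map. ncAA resolution is two-stage: a value
present in an AAindexNC-style extension TSV is used as-is; otherwise policy
`fallback` inherits the canonical parent's value and policy `strict` leaves
the code absent. The packaged scale files contain the Kyte–Doolittle
hydropathy index plus clearly-labelled synthetic stand-ins for the catalog
accessions (see the file headers); tests are value-agnostic.

The periodicity descriptor uses the symmetric window k = −n..n with
2n+1 = T·n_T rounded to the nearest odd count, n = round((T·n_T − 1)/2),
and the attenuation f(k) = exp(−A (k/n)²), so the window-edge weight is
exp(−A) for every (T, n_T) — consistent with useful A values in
{0.5, 1, 2, 3}. The scan grid mirrors the design space: T ∈ [1.2, 15.0]
(step 0.1), n_T ∈ [2, 9], A ∈ {0.5, 1, 2, 3}. Windowed descriptors decay
with exp(−A (k/m)²), m = max(|left|, |right|). For both families,
off-chain window positions contribute exactly zero (no reflection, no
renormalization) — the simplest contract, recorded per column. Categorical
features set exactly one identity bit (the ncAA code's own bit, never the
parent's); the N-terminal flag marks the first three residues (0-based
positions 0–2). Disorder scores are consumed from external files (the
package never reimplements a disorder predictor), clamped to [0, 1], and
powered.

## Feature matrices and selection

Columns are z-standardized over observed entries, then NaNs are imputed
with 0 — i.e. at the column mean. SDA is the classical Wilks'-Λ stepwise
procedure: enter the candidate with the largest partial F above f_enter
(default 3.84), then re-test entered columns against f_remove (default
2.71); a tolerance check (squared multiple correlation with the entered set
> 1 − 1e−4) blocks collinear candidates, so an exact duplicate can never
join its twin. The thresholds are the classical χ²₁ 5 %/10 % analogues; the
original procedure's exact thresholds are not published, so they are
parameters.

Greedy forward selection evaluates accuracy on a held-out split (default
80/20, seeded) — selection on training rows is available but optimistic.
Only strictly positive gains are accepted (hence the cumulative curve is
non-decreasing by construction); ties break to the lowest column index;
the stop threshold defaults to 5e−5 in accuracy fraction (0.005 percentage
points). The LDA is the standard pooled-within-covariance multiclass
discriminant with ridge 1e−6 · tr(Σ)/d on the diagonal (raising a clear
error, advising a larger ridge, if still not positive-definite).

## Neural head

The labeller is a stacked bidirectional LSTM over variable-length
per-residue feature sequences with a position-wise feed-forward head
(ReLU), ending in 9 logits (8 DSSP states + Ø). It is implemented directly
in numpy — forward, full BPTT, Adam with weight decay — and its gradients
are verified against central differences in the test suite. Padding never
enters the recurrence (state updates are gated per timestep), the backward
direction reverses each sequence within its own length, and batched
vs. unbatched forwards agree to machine precision. Masked cross-entropy
ignores Ø targets entirely; predictions argmax over the 8 biological
classes only. Defaults mirror the full-scale recipe (2 layers, 512 hidden
per direction, head 2048→1024→512→9 with a linear bridge when the Bi-LSTM
output width differs from the head input, dropout 0.7 annealed to 0 by 0.1
per validation plateau — plateau = no improvement ≥ 1e−4 for 5 epochs —
then stepwise learning-rate decay ×0.5 toward a floor of 1e−5, Adam lr
1e−4, weight decay 1e−4, early stopping patience 13); tests and the
acceptance script shrink the dimensions to desk scale (hidden 16, ~20
chains of 15–30 residues), which is sufficient to demonstrate optimisation
correctness but says nothing about full-scale predictive accuracy.

## Metrics

Q is the fraction of unmasked residues predicted correctly; the definition
is class-set agnostic (3-, 8- or 16-state). F1 per class is
2TP/(2TP + FP + FN); a class with no true or predicted members scores 0 and
*still* enters the macro mean over the fixed class set — a conservative
choice that keeps macro-F1 comparable across datasets. Confusion rows are
true classes; the normalized view divides by row totals (zero rows stay
zero). The 3-state confusion equals the 8-state matrix aggregated through
the label collapse, which is asserted in tests.

## Synthetic data

`gen_chain` builds backbones from per-state ideal dihedrals (helix −57/−47,
strand −120/+130, coil uniform over φ ∈ [−180°, −30°], ψ ∈ [−90°, 180°])
plus optional Gaussian angular noise; labels are generator-assigned ground
truth, not derived from hydrogen bonds. This emulates segmentally ideal
local geometry. It does **not** emulate real β-sheet pairing, long-range
contacts, or sequence–structure correlation (residues are uniform unless a
caller biases them), so passing tests demonstrate correctness of the
machinery, not real-data predictive performance. `gen_planted_features`
draws class-labelled rows with a known informative subset: each informative
column shifts a balanced Hadamard class dichotomy by ±effect_size/2 SD, so
every informative column carries an equally strong, complementary signal —
the canonical testbed for selection recovery (defaults: n = 2000, 8
classes, 5 informative / 45 noise, effect 2 SD). All generators are pure
functions of (spec, seed).

## Known limitations

- The vendored PB torsion table is the single geometric authority; tests
  assert qualitative behavior (helix → m, strand → {c, d}) rather than the
  table's provenance.
- The named reduced alphabets beyond the `Full*` family are placeholders.
- Desk-scale training demonstrates correctness only; reproducing published
  benchmark accuracies requires a full non-redundant training corpus,
  precomputed language-model embeddings and long training runs, all outside
  this package's scope.
- Alignment-free descriptors cannot capture long-range β-pairing; confusion
  between E/B and C is expected to dominate errors on real data.
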