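# Methods

## Model overview

The package treats prosthesis sizing as ordinal multiclass classification
(8 femoral, 9 tibial sizes) decomposed by error-correcting output codes.
Encoding, learning and decoding are independent, testable stages:

1. **Encoding.** Each class receives a binary codeword from a block code.
   Two families are supported. The 0/1 Hadamard matrix of order *n* (built
   by the doubling recursion from the 2×2 base [[0,0],[0,1]]) gives a
   constant pairwise distance of *n*/2; with *n* = 16 the code corrects any
   3 wrong bits. The (15, 11) Hamming code gives 2048 candidate codewords
   with minimum distance 3; a greedy procedure selects *N* of them, walking
   a fixed weight schedule [0, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 15] from
   the top (the distinct codeword weights of the code) and restarting with
   a smaller distance requirement whenever the candidate pool empties.
2. **Learning.** One binary task per bit, trained jointly by a single
   network with *n* sigmoid outputs.
3. **Decoding.** Four rules map the output vector to ranked classes:
   hard Hamming at 0.5 (I); hard Hamming at revised per-bit thresholds
   equal to the training positive fraction *N*₊/(*N*₊+*N*₋) (II); Euclidean
   distance on raw probabilities (III); and the per-bit sigmoid distance
   1/(1+e^(−(|p−label|−0.5)·10)) summed over bits (IV). The sigmoid form is
   steepest at |p−label| = 0.5 (value exactly 0.5 there) and saturates at
   the extremes, so clearly-right and clearly-wrong bits contribute almost
   equally while ambiguous bits dominate the ranking.

### Assumptions

- Class labels are ordinal but the codes treat them nominally; ordinal
  structure enters only through the tie-break (equidistant classes rank
  ascending, preferring the smaller size) and through top-k scoring.
- Bits flagged degenerate (constant across the class codewords — e.g. the
  always-zero first Hadamard column) carry no class information; they are
  excluded from training targets, every distance metric, and the per-bit
  diagnostics.
- The revised-threshold rule reads the threshold as the positive fraction
  of the training set for that bit; one-sided bits are clamped to
  (ε, 1−ε), ε = 10⁻⁶, and flagged.

## Codeword assignment and the balance objective

For the Hadamard scheme, class imbalance of the induced binary tasks is
the selection criterion: the assignment of classes to rows minimizes
Σ_active bits |positive ratio − 0.5| where the positive ratio of bit *j* is
the class-frequency mass with codeword bit 1. The search is exhaustive
when the candidate count permits (≤ 10⁶; always for uniform frequencies,
where only the row subset matters), otherwise a seeded steepest-descent
local search (row swaps and assignment swaps) with 16 random restarts.
Exhaustive and greedy agree on the study-scale uniform instance (verified
in the tests).

## Losses

Multiclass head: refined focal loss
L = −α_y (1−P_y)^β log P_y with α_i ∝ (1/N_i)^γ normalized to sum 1.
β focuses on hard samples, γ upweights rare classes; defaults β = 2,
γ = 1 (exposed as config keys `loss.beta`, `loss.gamma`). With
β = γ = 0 the loss is exactly (1/K)·cross-entropy, a useful unit surface.
ECOC head: mean binary cross-entropy over active bits, optionally weighted
per bit by inverse positive fraction (`loss.bit_weighting`); plain BCE is
the default. Natural logarithms everywhere; probabilities clamped to
[10⁻⁷, 1−10⁻⁷].

## The compact learner

The deep trunk of the original clinical system (an 18-layer residual
network with transfer learning) is out of scope; the predictor contract is
filled by a compact fully connected network that preserves every testable
mechanism (codes, losses, decoding): tanh hidden layers (default one of
32 units), Adam (lr 0.01), batch 32, up to 100 epochs with early stopping
(patience 10) on validation loss, best-epoch weights restored. Features
are the concatenation of image descriptors of both preprocessed films
(8×8 block means + row/column intensity profiles, 192 dims per film at
64×64) and the tabular block (one-hot gender, z-scored height and weight;
BMI = kg/m² available behind `preprocessing.use_bmi`, default off).
Training is bit-for-bit deterministic given the seed. A deep backbone can
replace this learner by implementing the same predict-probabilities
surface over raw images.

## Preprocessing

CLAHE (scikit-image, fractional clip limit 0.02, 8×8 tile grid), then a
flat-kernel joint spatial-range mean-shift smoother (square window of
radius 5 px, range bandwidth 10 intensity levels, 3 iterations): each
pixel moves toward the mean of spatial neighbours within the range band,
flattening noise while preserving bone-edge contrast. Finally a central
crop (85% of each dimension) removes burned-in margin annotations. All
parameters are config-exposed; the originating study states none of them,
so the defaults are ordinary practitioner choices. Standardization
statistics for height/weight come from the training split only — the
pipeline test asserts the leakage guard.

## Synthetic cohort

The generator emulates the documented cohort: 308 patients, female
fraction 240/308, gender-conditional Gaussians for height (male 172±6,
female 159±6 cm) and weight (male 75±10, female 65±10 kg — plausible
magnitudes; only the induced correlation structure is a calibration
target). A latent size score

s = w_g·male + w_h·z(height) + w_w·z(weight) + σ·ε

is quantile-binned at the sample's own quantiles into bell-shaped class
frequencies (discretized Gaussian over class indices, spread 2.0 for 8
femoral and 2.25 for 9 tibial classes). The effect weights are frozen at
w_g = 0.6227, w_h = 0.3460, w_w = 0.1763, σ = 0.5732, calibrated once by
large-n least squares so the femoral feature–label correlations are
0.6151 / 0.6345 / 0.4134 (gender / height / weight) in population; tibial
labels share the latent plus jitter (sd 0.25) clamped to ±1 bin of the
monotone 8→9 map, which leaves their correlations within ~0.03 of the
corresponding targets. Toy films are synthetic silhouettes whose condyle
and plateau widths grow strictly with the size labels, with Gaussian pixel
noise and margin text placed inside the default crop stripe.

What passing tests on this cohort do **not** show: performance on real
radiographs. The synthetic films carry the size signal in a single
geometric feature with no anatomical variability, occlusion or projection
effects, so absolute accuracies here (≈0.94–1.0 top-3) say only that the
pipeline's mechanisms work end to end, not that the clinical accuracy is
reproduced — the clinical data are private and its headline numbers are
not targets of this package.

## Numerical and design choices

- 0/1 symbols throughout the code machinery (complement = bitwise NOT);
  no ±1 convention.
- Greedy selection candidate order: ascending (Hamming weight, integer
  value of the bit string, MSB first) — fixed so the procedure is
  deterministic; restarts reinitialize the selected set to {all-zeros}.
- Hamming code construction: parity-check columns are all nonzero m-bit
  vectors, weight-≥2 vectors first in ascending value, identity block
  last; the enumerated *set* of codewords, not the generator, is the
  contract.
- Hardening tie rule: p = threshold → bit 1.
- Method IV sums (rather than averages) per-bit distances over active
  bits; rankings are identical either way.
- Rank ties break to the lower class index (smaller size — conservative).
- The 99%-confidence t threshold is computed from the t distribution at
  the run's df (306 at n = 308 ⇒ 2.592) rather than hard-coded.
- Split sizes by largest-remainder rounding (308 at 4:1:1 → 206/51/51),
  stratified on femoral size, with an unstratified fallback (warning) when
  a class is too small.
- Default end-to-end problem size: 308 patients, 64×64 films, ≤100 epochs —
  a full run takes well under a minute on one CPU; tests use 80-patient
  runs for the orchestration checks and 5 seeds of the full default for
  the above-chance margin check.

## Known limitations

- `enumerate_hamming_codewords` materializes 2^(n−m) rows; m = 4 (2048×15)
  is the intended scale, m ≥ 5 should use the generator/parity-check basis.
- The greedy assignment search is a heuristic: it guarantees determinism
  and local optimality, not the global balance optimum, off the exhaustive
  regime.
- The revised-threshold formula follows the positive-fraction reading of
  an ambiguously printed source expression; the alternative (product)
  reading is not implemented.
- Tibial correlations are inherited from the shared latent rather than
  independently calibrated, so they sit slightly (~0.03) below their
  nominal targets.
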