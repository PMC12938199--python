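# Methods

`ppigray` predicts protein–protein interactions (PPIs) from sequence alone.
Each protein is described by 576 hand-crafted features computed from its
amino-acid sequence, an evolutionary profile (PSSM) and its coding gene
sequence; a protein pair becomes a 36 × 32 "grayscale map" that a small
convolutional network classifies. This note records the model, its
parameters and defaults, the numerical conventions, what the synthetic data
emulate, and the design choices that were genuinely open.

## Feature families

**V1 — amphiphilic pseudo amino acid composition (80 values).**
Hydrophobicity (Tanford) and hydrophilicity (Hopp–Woods) values per residue
are min–max normalized across the 20 residues so each property spans
[0, 1]. For a sequence of length L the first 20 components are the residue
composition terms f_m/(1 + ω Στ) in fixed alphabetical residue order; the
remaining 2λ are ω τ_k/(1 + ω Στ), where τ_{2d−1} (hydrophobicity) and
τ_{2d} (hydrophilicity) are mean products of the property values at
positions separated by d = 1…λ. Defaults ω = 0.5 and λ = 30 (hence 80
values); any sequence must be longer than λ. The whole vector sums to 1 —
a useful invariant the tests exploit. The two hydropathy tables are the
canonical inputs of this descriptor family; alternative scales can be
injected via `HydropathyScale` (two-column TSV loader provided).

**V2 — same-type residue interval statistics (320 values).**
The sequence is cut into four consecutive segments of length l = ⌊L/4⌋
(the fourth absorbs the remainder). Within a segment, for each residue
type, the 1-based occurrence positions α₁ < … < α_q define an
interval-distance sequence: the q−1 gaps for q > 1, the single value
s − α₁ (distance to segment end) for q = 1, and [0] for q = 0. Four
statistics per residue and segment — mean, min, max gap and the segment
frequency q/s (1/s for a single occurrence, 0 if absent) — give
4 × 20 × 4 = 320 values. Conventions worth noting: gap bounds run over all
q−1 adjacent pairs (the descriptor is empty otherwise for q = 2, 3, which
would contradict its definition as adjacent-occurrence distances); min/max
of an absent residue are 0; segment positions are segment-local so the
q = 1 value measures distance to the segment end.

**V3 — PSSM evolutionary descriptors (80 values).**
The raw L × 20 log-odds profile is sigmoid-normalized elementwise,
a* = 1/(1+e^−a). With column means ā_w, the θ-interval deviation product
δ_{i,w}^θ = (a*_{i,w} − ā_w)(a*_{i+θ,w} − ā_w) measures co-variation of
positions at separation θ; its mean over i = 1…L−θ is Z_w^θ. θ ∈ {1, 2, 3}
gives 60 values, plus the 20 column means: 80 total. Z is computed on the
normalized matrix (the raw-score variant is available behind a flag).
Columns are always re-indexed to the fixed alphabet order, so the features
are equivariant to the column order of the source file.

**V4 — coding-sequence features (96 values).**
Overlapping k-mer frequencies for k = 1, 2, 3 with denominators N, N−1,
N−2 (each block sums to 1; 84 values); positional means and population
variances of each nucleotide's 1-based occurrence positions (8 values;
absent nucleotide → 0, 0); and four statistics of a unit-circle mapping:
the r-th letter with running count b_e^r (inclusive) of a letter with total
count b_e lands at angle offset(e) + (π/2)·b_e^r/(b_e+1), with quadrant
offsets 0, π/2, π, 3π/2 for A, C, G, T. The inclusive running count keeps
every point strictly inside its quadrant (an exclusive count would put
first occurrences on quadrant boundaries). Means and population variances
of the x and y coordinates complete the block.

## The grayscale map

Per protein the 576 features fill a 36 × 16 matrix: rows 1–20 the V2
statistics (one residue per row, A B C D per segment), rows 21–25 the V1
vector, rows 26–30 the V3 block with column means first and the three
θ blocks after (the alternative ordering is immaterial to accuracy — the
`rearrange` operation exists to demonstrate arrangement invariance), rows
31–36 the V4 block ending at the TTT trinucleotide. Cell provenance (which
feature sits where) is tracked and exportable. Two protein matrices are
concatenated side by side into a 36 × 32 pair matrix, in the order the
pair table gives (no symmetrization).

**Normalization.** Two min–max conventions are implemented. The
*per-sample* convention scales each pair matrix by its own global min and
max (an all-constant matrix maps to zeros); it is what `build_pair_map`
does by default and what the PNG export visualizes. The training pipeline,
however, uses *per-feature* scaling (`FeatureScaler`): each of the 576
cells is scaled by its own min and max across the study's proteins. The
reason is numerical: interval-gap cells reach O(100) and CDS positional
variances O(10⁴–10⁵) while composition cells are O(10⁻²), so a global
per-sample scale leaves all but a handful of cells indistinguishable from
zero and multiplies every informative cell by an arbitrary,
length-dependent per-sample constant. Per-feature scaling is the reading
consistent with normalizing "because features have different scales" and
with grayscale maps that actually show texture across rows; it is also the
only convention under which the planted-signal benchmark below is
learnable at desk scale.

## Classifier

A small CNN consumes the 36 × 32 map: three 6 × 6 stride-1 valid
convolutions sharing one channel count, each followed by ReLU, with two
overlapping 3 × 3 stride-1 max-pools interleaved
(conv–conv–pool–conv–pool), then one fully connected layer and a softmax
over (interaction, non-interaction) — index 0 is the interaction
probability. The spatial chain is 31×27 → 26×22 → 24×20 → 19×15 → 17×13,
so the flattened vector has length channels × 221 (14,144 at the reference
64 channels). ReLU follows only the convolutions, not the pools.

Layers, backpropagation and Adam are implemented directly on NumPy arrays
(im2col convolutions; the overlapping max-pool scatters gradients to
per-window argmax cells). Parameters default to float32; a float64 mode
exists and the test suite verifies backpropagation against central-difference
numerical gradients at 1e−4 relative tolerance. Weight initialization is
uniform in ±1/√fan_in with a recorded seed.

Training: softmax cross-entropy averaged per batch, batch size 128, Adam
with framework-default moment constants, at most 100 epochs, early
stopping when validation loss fails to strictly improve for 10 consecutive
epochs (no minimum delta), best-validation checkpoint restored. Training
aborts on non-finite loss. Fixed seeds make runs bit-reproducible on one
device.

Hyperparameter search covers learning rate (log-uniform on [1e−5, 1e−3])
and the channel count shared by all three convolutions ({2, 4, …, 64}).
The shipped strategy is seeded random search (the strategy slot is
pluggable); each trial trains from scratch and the configuration with the
highest validation ROC-AUC wins, earliest trial winning ties.

**Imbalance handling.** Negative candidate pairs vastly outnumber curated
positives, so training uses an undersampling ensemble: five balanced sets,
each all training positives plus an equal-size seeded draw (without
replacement within a draw) from the negative pool, train five models whose
interaction probabilities are averaged. Member metrics are also reported
individually with mean, standard deviation and variance across the five.

## Dataset construction

Proteins shorter than 50 residues are removed (inclusive threshold at 50).
Positives are shuffled with a seed and cut 3:1:1 into train/validation/
test (train gets ⌊3n/5⌋, remainder to validation first). Negatives come
from the subcellular-localization strategy: unordered pairs of annotated
proteins whose compartment sets are disjoint, excluding every known
positive pair; proteins without annotation are excluded, and an optional
flag restricts multi-localized proteins to those annotated to both nucleus
and cytoplasm (a dataset-specific curation rule). Pairs are canonicalized
with the lexicographically smaller identifier first. A random-pair
negative baseline, imbalanced test variants (1:5, 1:10), and a
protein-disjoint "new-test" filter (test positives sharing no protein with
any training pair) support the robustness analyses. A CD-HIT `.clstr`
reader can restrict a set to cluster representatives; redundancy removal
itself is out of scope. Negative pairs may reuse proteins that appear in
positive pairs; only exact pair collisions are excluded.

## Synthetic data

No curated interaction data can be bundled, so the `synthetic_fixtures`
module generates every input format the pipeline reads, from one master
seed: protein FASTA, coding sequences (uniform codon back-translation under
the standard genetic code, no stop codon, translation round-trips exactly),
ASCII PSSM files (integer scores in [−8, 12] plus a +6 bias on each
position's own residue column), one-compartment localization tables over
five compartments, and labeled pairs.

Labels carry a planted signal: each protein draws a latent bias
h ~ Beta(0.35, 0.35) — bimodal, so most proteins are clearly hydrophobic-
or hydrophilic-leaning — that tilts its residue composition along the
normalized hydrophobicity axis (weights ∝ exp(effect·(h−½)·φ̂¹)); its
"stickiness" is the realized mean hydrophobicity; a pair interacts when
the stickiness sum exceeds the quantile threshold matching the configured
positive rate, then labels flip independently with the noise rate (default
0, capped below 0.5). Three defaults are calibrated jointly so the planted
dichotomy is clean: effect size 8 makes raw 1152-feature pair vectors
~97% linearly separable; the bimodal bias concentrates proteins into two
latent classes; and positive rate 0.25 equals the weight of the
both-hydrophobic pair mode, so the labeling threshold falls in the gap
between score modes rather than through one. The signal flows through
quantities the feature layer actually computes (composition along the
hydropathy scale), so an end-to-end learnability benchmark is fair.

Compartment annotations are generated *consistently with the planted
biology*: sticky proteins (stickiness above the population median)
co-localize to the membrane compartment and the rest spread uniformly over
the other four, so pairs drawn by the disjoint-localization strategy are
genuinely non-interacting — the synthetic world makes the heuristic true,
mirroring the assumption the strategy rests on for real annotations. (An
earlier design assigned compartments independently of the labels; ~25% of
drawn "negatives" were then pairs the planted model scores as interacting,
which acts as irreducible label noise and caps balanced-test accuracy near
0.875 — worth remembering when interpreting real-data results, where the
heuristic is only approximately true.) The `localization_noise` knob
re-breaks the heuristic for a controllable fraction of proteins.

What the fixtures do *not* emulate: homology/redundancy structure,
organism-specific codon bias, biologically calibrated PSSMs, multi-
compartment localization, and any sequence grammar beyond i.i.d. residues.
Passing benchmarks therefore demonstrate that the pipeline's machinery can
recover a signal expressed through its own features — not field
performance on curated interactomes.

## The learnability benchmark

The reference benchmark (used by the acceptance script and the heavyweight
test) runs the full workflow on a fixture set of 120 proteins of length
60–120 (kept short so PSSM and map construction stay fast), 2400 labeled
pairs at the default positive rate and noise 0, localization-strategy
negatives at 6× the positive count (large enough for five distinct
undersampled draws and a 1:5 imbalanced test variant), the 3:1:1 split,
five balanced undersampled sets, and an ensemble of five 2-channel CNNs
trained at learning rate 1e−3 for at most 100 epochs with patience 10.
These sizes are the package's chosen desk-scale study conditions; the
channel count sits at the low end of the search set because the planted
signal is low-texture and the smallest model trains the fastest per
epoch, allowing the epoch budget that matters more here, and
hyperparameter search is disabled in the benchmark because each trial
retrains from scratch.

Feature-ablation analysis zeroes one feature family in the *inputs of the
already-trained ensemble* (test-time ablation, using the study's fitted
scaler) and re-scores the held-out test pairs. Zeroing V1 collapses
accuracy to chance, confirming the trained model's reliance on the family
carrying the planted signal; V3 and V4 ablations barely move it. Note the
signal is a composition functional, so per-segment frequencies (V2) leak a
weaker copy of it — retraining from scratch without V1 therefore recovers
part of the accuracy, which is why the ablation analysis is defined at
test time, matching the "set features to zero and observe the change"
protocol.

## Numerical conventions and degenerate cases

- Metrics with zero denominators report 0 and set a degeneracy flag
  rather than raising, so threshold sweeps never crash; ROC ties get
  half-credit (Mann–Whitney convention); top-u ties break by stable input
  order; AUPR uses the step-wise area.
- All variances in features and member-dispersion reports use the
  population divisor.
- Constant pair matrices normalize to all zeros; constant features under
  per-feature scaling map to 0; scaled values are clipped to [0, 1].
- Sequence positions are 1-based in every formula and 0-based in storage;
  conversions live in the feature layer only.
- Sub-seeds are derived from the master seed by fixed offsets; all
  generators are NumPy `default_rng`.

## Known limitations

- The NumPy CNN is single-device and desk-scale; it is not meant for
  hundreds of thousands of pairs.
- The per-sample normalization convention is retained for compatibility
  and visualization but is not recommended for training (see above).
- The localization negative strategy inherits its standard caveats:
  same-compartment non-interactions are under-sampled and cross-compartment
  interactions are mislabeled by construction.
- Pair-level splitting lets proteins recur across train and test; the
  protein-disjoint test filter exists precisely to quantify that leakage.
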