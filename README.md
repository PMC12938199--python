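# ppigray

Sequence-based prediction of protein–protein interactions (PPIs) with
hand-crafted feature grayscale maps and a small convolutional-network
ensemble.

Most proteins act through physical interactions, but experimental
interaction screens are expensive and noisy, so computational triage from
sequence alone remains a staple of systems biology. `ppigray` implements a
complete desk-scale pipeline for this task, aimed at researchers who want
an inspectable, fully reproducible reference implementation of the
feature-map approach: every feature is a named, documented quantity; every
sampling step is seeded; and the whole workflow — from FASTA files to a
trained ensemble and evaluation report — runs in minutes on one CPU core.

## The model

Each protein is described by **576 features** in four families:

- **V1 (80)** — amphiphilic pseudo amino acid composition (APAAC): residue
  composition terms f_m/(1 + ω Στ_k) plus 2λ sequence-order correlation
  factors τ_k built from min–max-normalized hydrophobicity and
  hydrophilicity scales (ω = 0.5, λ = 30). The vector sums to 1.
- **V2 (320)** — same-type residue interval statistics: the sequence is cut
  into four consecutive segments; per segment and residue type, the gaps
  between consecutive occurrences α₁ < … < α_q yield a mean, minimum,
  maximum and the segment frequency q/s.
- **V3 (80)** — evolutionary descriptors from a sigmoid-normalized PSSM
  (PSI-BLAST ASCII dialect): the 20 column means ā_w plus the θ-interval
  deviation-product means Z_w^θ = mean over i of
  (a*_{i,w} − ā_w)(a*_{i+θ,w} − ā_w), θ ∈ {1, 2, 3}.
- **V4 (96)** — coding-sequence features: overlapping k-mer frequencies
  (k ≤ 3), per-nucleotide positional means/variances, and statistics of a
  unit-circle mapping that places the r-th occurrence of each nucleotide
  at angle offset(e) + (π/2)·b_e^r/(b_e + 1) inside its letter's quadrant.

The 576 features fill a 36 × 16 matrix; two proteins concatenate to a
**36 × 32 grayscale map**. A CNN with three 6 × 6 convolutions, two
overlapping 3 × 3 max-pools and one fully connected layer (implemented
directly in NumPy, with verified backpropagation) maps it to interaction /
non-interaction probabilities; at 64 channels the flattened pre-classifier
vector has length 14,144. Because curated negatives are scarce, negatives
are drawn from protein pairs annotated to disjoint subcellular
compartments, and training uses an undersampling ensemble: five balanced
sets, five models, averaged probabilities.

## Worked example

No interaction database is bundled; the `synthetic_fixtures` module
generates a complete synthetic study (protein FASTA, coding sequences,
ASCII PSSMs, localization and pair tables) with a planted
hydrophobicity-driven interaction signal:

```sh
ppigray simulate --seed 5 --n-proteins 10 --length-min 60 --length-max 90 \
    --max-pairs 30 --out fx
ppigray extract --seed 5 --in fx --out fx/features.tsv
```

```
INFO wrote fixture set (10 proteins, 30 pairs) to fx
INFO wrote 10 feature vectors to fx/features.tsv
```

`fx/features.tsv` holds one row per protein: an identifier followed by the
576 feature values (V1 | V2 | V3 | V4). From Python, the same objects are
directly inspectable:

```python
>>> from ppigray import FixtureConfig, generate, extract_features
>>> fx = generate(FixtureConfig(n_proteins=10, length_range=(60, 90), seed=5),
...               max_pairs=30)
>>> fv = extract_features(fx.proteins, fx.genes, fx.pssms)["p0001"]
>>> len(fv.concat()), float(fv.v1.sum())
(576, 0.9999999999999999)
```

The second value is the APAAC normalization identity — the 80 V1
components sum to one (up to floating-point round-off). Training and
evaluation on a fixture directory:

```sh
ppigray evaluate --seed 5 --in fx --out report --channels 2 --max-epochs 30
```

which writes `metrics.tsv` (sensitivity, specificity, precision, F1, MCC,
accuracy, AUC), ROC and PR curve tables, top-u precision, per-member
dispersion, and thresholded edge lists for interaction (thresholds
0.5…0.98) and non-interaction (0.5…0.01) network prediction.

## Layout

- `src/ppigray/io_formats.py` — FASTA / ASCII-PSSM / pair / localization IO
- `src/ppigray/protein_features.py`, `gene_features.py` — the four families
- `src/ppigray/graymap.py` — matrix layout, normalization, PNG export
- `src/ppigray/dataset_builder.py` — splits, negatives, undersampling
- `src/ppigray/cnn_classifier.py` — the NumPy CNN, training, search, ensemble
- `src/ppigray/evaluation.py` — metrics, curves, network prediction
- `src/ppigray/synthetic_fixtures.py` — the seeded synthetic world
- `src/ppigray/pipeline.py`, `benchmark.py`, `cli.py` — wiring and CLI
- `docs/methods.md` — full methods note (model, conventions, limitations)
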