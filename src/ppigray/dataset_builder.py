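"""Dataset construction: length filtering, localization-based negative
sampling, 3:1:1 splits, balanced undersampling ensembles and imbalanced
test-set variants.

Negative pairs are drawn between proteins annotated to disjoint subcellular
compartments — the standard assumption that proteins confined to different
compartments do not meet.  Because curated interaction sets contain far
fewer positives than the space of candidate negatives, training uses five
balanced sets, each combining all training positives with an independent
equal-size negative draw; one model is trained per set and predictions are
averaged.

All randomness flows from a single master seed; sub-seeds are derived as
documented on each function so runs are reproducible end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import (LABEL_NEGATIVE, LABEL_POSITIVE, LocalizationTable,
                         Pair, ProteinRecord)


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Unordered-pair canonical form: lexicographically smaller id first."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


@dataclass
class DatasetSplit:
    """Train/validation/test partitions of positive and negative pairs."""

    train_pos: list[Pair]
    val_pos: list[Pair]
    test_pos: list[Pair]
    train_neg: list[Pair] = field(default_factory=list)
    val_neg: list[Pair] = field(default_factory=list)
    test_neg: list[Pair] = field(default_factory=list)
    seed: int = 0


@dataclass
class EnsembleTrainingSets:
    """Five balanced training tables plus the sub-seeds that drew them."""

    sets: list[list[Pair]]
    seeds: list[int]


def filter_by_length(proteins: list[ProteinRecord],
                     min_len: int = 50) -> list[ProteinRecord]:
    """Drop proteins shorter than ``min_len`` residues (inclusive threshold),
    preserving order."""
    return [p for p in proteins if len(p) >= min_len]


def make_negatives(proteins: list[ProteinRecord],
                   localizations: LocalizationTable,
                   n: int | None, seed: int,
                   positives: list[Pair] | None = None,
                   require_nuc_cyt: bool = False) -> list[Pair]:
    """Draw ``n`` non-interacting candidate pairs by disjoint localization.

    Eligible pairs are unordered pairs of annotated proteins whose
    compartment sets are disjoint, excluding every known positive pair.
    Proteins without annotation are excluded.  With ``require_nuc_cyt``,
    multi-compartment proteins are kept only if annotated to both the
    "nucleus" and "cytoplasm" compartments (a dataset-specific curation
    rule, off by default).  The draw is uniform without replacement and
    deterministic given ``seed``; ``n=None`` returns every eligible pair in
    seeded-shuffle order.
    """
    annotated = []
    for p in proteins:
        if p.id not in localizations:
            continue
        comps = localizations[p.id]
        if require_nuc_cyt and len(comps) > 1 and comps != frozenset({"nucleus", "cytoplasm"}):
            continue
        annotated.append(p.id)

    known_pos = set()
    if positives:
        known_pos = {canonical_pair(p.id_a, p.id_b) for p in positives}

    eligible = []
    for i in range(len(annotated)):
        for j in range(i + 1, len(annotated)):
            a, b = canonical_pair(annotated[i], annotated[j])
            if (a, b) in known_pos:
                continue
            if localizations[a] & localizations[b]:
                continue
            eligible.append((a, b))
    if n is None:
        n = len(eligible)
    if len(eligible) < n:
        raise ValueError(
            f"requested {n} negative pairs but only {len(eligible)} eligible"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [Pair(eligible[i][0], eligible[i][1], LABEL_NEGATIVE) for i in idx]


def split_positives(pairs: list[Pair], seed: int,
                    ratios: tuple[int, int, int] = (3, 1, 1)) -> DatasetSplit:
    """Seeded shuffle then contiguous 3:1:1 cut.

    Train receives floor(n * 3/5); the remainder goes to validation first
    and then test, so validation never gets fewer pairs than test.
    """
    if len(pairs) < 5:
        raise ValueError(f"need at least 5 positive pairs, got {len(pairs)}")
    total = sum(ratios)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    shuffled = [pairs[i] for i in order]
    n = len(pairs)
    n_train = n * ratios[0] // total
    remainder = n - n_train
    n_val = (remainder + 1) // 2 if ratios[1] == ratios[2] else remainder * ratios[1] // (
        ratios[1] + ratios[2])
    return DatasetSplit(
        train_pos=shuffled[:n_train],
        val_pos=shuffled[n_train:n_train + n_val],
        test_pos=shuffled[n_train + n_val:],
        seed=seed,
    )


def attach_negatives(split: DatasetSplit, negatives: list[Pair],
                     seed: int, ratio: float = 1.0) -> DatasetSplit:
    """Partition a negative pool across the split's three parts.

    Each part receives ``ratio`` times its positive count (training usually
    gets a large surplus pool for undersampling, so pass the full training
    share via ``ratio``); the assignment is a seeded shuffle then contiguous
    cut proportional to positive counts, keeping the three parts disjoint.
    """
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(negatives))
    shuffled = [negatives[i] for i in order]
    counts = [len(split.train_pos), len(split.val_pos), len(split.test_pos)]
    weights = np.array(counts, dtype=float)
    shares = (weights / weights.sum() * len(shuffled)).astype(int)
    shares[0] = len(shuffled) - shares[1] - shares[2]
    a, b = shares[0], shares[0] + shares[1]
    split.train_neg = shuffled[:a]
    split.val_neg = shuffled[a:b]
    split.test_neg = shuffled[b:]
    return split


def undersample_ensembles(split: DatasetSplit, seed: int,
                          k: int = 5) -> EnsembleTrainingSets:
    """Draw ``k`` balanced training sets (all positives + equal negatives).

    Sub-seed for draw i is ``seed + i``; each draw is without replacement
    within itself but draws may overlap with each other.
    """
    n_pos = len(split.train_pos)
    if len(split.train_neg) < n_pos:
        raise ValueError(
            f"training negatives ({len(split.train_neg)}) fewer than "
            f"positives ({n_pos})"
        )
    sets, seeds = [], []
    for i in range(k):
        sub = seed + i
        rng = np.random.default_rng(sub)
        idx = rng.choice(len(split.train_neg), size=n_pos, replace=False)
        negs = [split.train_neg[j] for j in idx]
        sets.append(list(split.train_pos) + negs)
        seeds.append(sub)
    return EnsembleTrainingSets(sets=sets, seeds=seeds)


def make_imbalanced_test(split: DatasetSplit, ratio: int, seed: int) -> list[Pair]:
    """All test positives plus a seeded draw of ratio x |positives| negatives."""
    n_pos = len(split.test_pos)
    n_neg = ratio * n_pos
    if len(split.test_neg) < n_neg:
        raise ValueError(
            f"need {n_neg} test negatives for ratio 1:{ratio}, "
            f"have {len(split.test_neg)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(split.test_neg), size=n_neg, replace=False)
    return list(split.test_pos) + [split.test_neg[i] for i in idx]


def protein_disjoint_test(split: DatasetSplit) -> list[Pair]:
    """Test positives sharing no protein with any training pair (the
    stricter 'new-test' evaluation)."""
    train_proteins = set()
    for p in split.train_pos + split.train_neg:
        train_proteins.add(p.id_a)
        train_proteins.add(p.id_b)
    kept = [p for p in split.test_pos
            if p.id_a not in train_proteins and p.id_b not in train_proteins]
    if not kept and split.test_pos:
        warnings.warn("protein-disjoint test set is empty", stacklevel=2)
    return kept


def random_negatives(proteins: list[ProteinRecord], n: int, seed: int,
                     positives: list[Pair] | None = None) -> list[Pair]:
    """Baseline random-pair negative strategy (no localization filter)."""
    known_pos = set()
    if positives:
        known_pos = {canonical_pair(p.id_a, p.id_b) for p in positives}
    ids = [p.id for p in proteins]
    rng = np.random.default_rng(seed)
    seen: set = set()
    out: list[Pair] = []
    max_pairs = len(ids) * (len(ids) - 1) // 2 - len(known_pos)
    if max_pairs < n:
        raise ValueError(f"requested {n} random negatives but only {max_pairs} possible")
    while len(out) < n:
        i, j = rng.choice(len(ids), size=2, replace=False)
        key = canonical_pair(ids[i], ids[j])
        if key in seen or key in known_pos:
            continue
        seen.add(key)
        out.append(Pair(key[0], key[1], LABEL_NEGATIVE))
    return out


def read_cdhit_clusters(path) -> list[str]:
    """Representative ids from a CD-HIT ``.clstr`` file (the '*' entries)."""
    reps = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                continue
            if line.rstrip().endswith("*"):
                start = line.index(">") + 1
                end = line.index("...", start)
                reps.append(line[start:end])
    return reps


def write_manifest(path, **entries) -> None:
    """Plain-text key=value run manifest (seeds, counts, parameters)."""
    with open(path, "w") as fh:
        for key, value in entries.items():
            fh.write(f"{key}={value}\n")
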