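"""Coding-sequence (CDS) feature family V4 (96 values).

Three groups are extracted from a gene's ACGT coding sequence:

* overlapping k-mer frequencies for k = 1, 2, 3 (4 + 16 + 64 = 84 values),
* per-nucleotide positional means and population variances (8 values),
* statistics of a unit-circle mapping (4 values): each nucleotide is mapped
  to a point on the unit circle inside the quadrant assigned to its letter
  (A: first, C: second, G: third, T: fourth), at an angle that advances with
  the running count of that letter, so the point cloud encodes both
  composition and positional order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .io_formats import NUCLEOTIDE_ALPHABET, GeneRecord

#: Quadrant angular offsets for A, C, G, T.
_QUADRANT_OFFSET = {"A": 0.0, "C": np.pi / 2, "G": np.pi, "T": 3 * np.pi / 2}

DINUCLEOTIDES = ["".join(p) for p in product(NUCLEOTIDE_ALPHABET, repeat=2)]
TRINUCLEOTIDES = ["".join(p) for p in product(NUCLEOTIDE_ALPHABET, repeat=3)]


@dataclass(frozen=True)
class CirclePoint:
    """One nucleotide mapped onto the unit circle."""

    position: int  # 1-based
    nucleotide: str
    x: float
    y: float


def kmer_frequencies(gene: GeneRecord) -> np.ndarray:
    """Overlapping k-mer frequencies for k = 1, 2, 3 — 84 values.

    Window counts are divided by N, N−1 and N−2 respectively so each
    k-block sums to 1; k-mers are enumerated in lexicographic ACGT order.
    """
    s = gene.nucleotides
    N = len(s)
    if N < 3:
        raise ValueError(f"gene {gene.id!r}: length {N} < 3, cannot count trinucleotides")
    out = np.empty(84)
    out[:4] = [s.count(nt) / N for nt in NUCLEOTIDE_ALPHABET]
    di = {k: 0 for k in DINUCLEOTIDES}
    tri = {k: 0 for k in TRINUCLEOTIDES}
    for i in range(N - 1):
        di[s[i:i + 2]] += 1
    for i in range(N - 2):
        tri[s[i:i + 3]] += 1
    out[4:20] = [di[k] / (N - 1) for k in DINUCLEOTIDES]
    out[20:] = [tri[k] / (N - 2) for k in TRINUCLEOTIDES]
    return out


def position_stats(gene: GeneRecord) -> np.ndarray:
    """Per-nucleotide positional mean and population variance — 8 values.

    Positions are 1-based; a nucleotide absent from the sequence gets mean
    and variance 0.  Output order: μ_A μ_C μ_G μ_T, then σ²_A … σ²_T.
    """
    means = np.zeros(4)
    variances = np.zeros(4)
    arr = np.frombuffer(gene.nucleotides.encode(), dtype=np.uint8)
    for j, nt in enumerate(NUCLEOTIDE_ALPHABET):
        positions = np.flatnonzero(arr == ord(nt)) + 1
        if positions.size:
            means[j] = positions.mean()
            variances[j] = positions.var()  # population divisor
    return np.concatenate([means, variances])


def circle_map(gene: GeneRecord) -> list[CirclePoint]:
    """Map each nucleotide onto the unit circle.

    The r-th occurrence (cumulative count b_e^r, inclusive of position r) of
    a letter with total count b_e lands at angle
    offset(e) + (π/2) · b_e^r / (b_e + 1), which keeps every point strictly
    inside its letter's quadrant.
    """
    s = gene.nucleotides
    totals = {nt: s.count(nt) for nt in NUCLEOTIDE_ALPHABET}
    running = {nt: 0 for nt in NUCLEOTIDE_ALPHABET}
    points = []
    for r, nt in enumerate(s, start=1):
        running[nt] += 1
        angle = _QUADRANT_OFFSET[nt] + (np.pi / 2) * running[nt] / (totals[nt] + 1)
        points.append(CirclePoint(r, nt, float(np.cos(angle)), float(np.sin(angle))))
    return points


def circle_stats(points: list[CirclePoint]) -> np.ndarray:
    """Mean and population variance of the mapped x and y coordinates.

    Output order: μ_x, μ_y, σ²_x, σ²_y.  The sign of μ_x separates A+T from
    G+C content; the sign of μ_y separates A+C from G+T.
    """
    if not points:
        raise ValueError("no mapped points")
    xs = np.array([p.x for p in points])
    ys = np.array([p.y for p in points])
    return np.array([xs.mean(), ys.mean(), xs.var(), ys.var()])


def export_points(path, points: list[CirclePoint]) -> None:
    """Write mapped points as a tab-separated (x, y) table for plotting."""
    with open(path, "w") as fh:
        for p in points:
            fh.write(f"{p.x:.6f}\t{p.y:.6f}\n")


def gene_features(gene: GeneRecord) -> np.ndarray:
    """V4: the full 96-value gene feature vector.

    Order: μ_x μ_y σ²_x σ²_y, positional means μ_A…μ_T, positional
    variances σ²_A…σ²_T, then the 4 + 16 + 64 k-mer frequencies ending at
    the TTT trinucleotide.
    """
    circ = circle_stats(circle_map(gene))
    pos = position_stats(gene)
    kmers = kmer_frequencies(gene)
    return np.concatenate([circ, pos, kmers])
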