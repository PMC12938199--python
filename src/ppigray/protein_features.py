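"""Protein-sequence feature families.

Three families are computed from a protein sequence and its evolutionary
profile:

* **V1 (80)** — amphiphilic pseudo amino acid composition (APAAC): the 20
  residue composition terms plus 2λ sequence-order correlation factors
  built from min–max-normalized hydrophobicity and hydrophilicity scales.
* **V2 (320)** — same-type residue interval-distance statistics: the
  sequence is cut into four consecutive segments; within each segment and
  for each residue type, the gaps between consecutive occurrences form an
  interval-distance sequence whose mean, minimum, maximum and the residue's
  segment frequency are recorded (4 statistics × 20 residues × 4 segments).
* **V3 (80)** — evolutionary-conservation descriptors from a sigmoid-
  normalized PSSM: per-column means plus the θ-interval deviation-product
  means (θ = 1, 2, 3), which quantify co-evolution of positions at
  separation θ.

All formulas index sequence positions from 1; storage is 0-based and the
conversion happens here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import AMINO_ALPHABET, ProteinRecord, Pssm

# ---------------------------------------------------------------------------
# Hydropathy scales

#: Tanford hydrophobicity values, the canonical APAAC hydrophobicity input.
HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

#: Hopp–Woods hydrophilicity values, the canonical APAAC hydrophilicity input.
HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    return (values - lo) / (hi - lo)


@dataclass(frozen=True)
class HydropathyScale:
    """Per-residue hydrophobicity (phi1) and hydrophilicity (phi2) values,
    min–max normalized across the 20 residues so each property spans [0, 1].
    """

    phi1: np.ndarray  # normalized hydrophobicity, AMINO_ALPHABET order
    phi2: np.ndarray  # normalized hydrophilicity, AMINO_ALPHABET order

    @classmethod
    def from_tables(cls, hydrophobicity: dict | None = None,
                    hydrophilicity: dict | None = None) -> "HydropathyScale":
        hb = hydrophobicity or HYDROPHOBICITY
        hl = hydrophilicity or HYDROPHILICITY
        raw1 = np.array([hb[r] for r in AMINO_ALPHABET], dtype=float)
        raw2 = np.array([hl[r] for r in AMINO_ALPHABET], dtype=float)
        return cls(phi1=_minmax(raw1), phi2=_minmax(raw2))

    @classmethod
    def from_file(cls, path) -> "HydropathyScale":
        """Load a scale from a tab-separated (residue, phobicity, philicity) file."""
        hb: dict = {}
        hl: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                res, v1, v2 = line.split("\t")
                hb[res] = float(v1)
                hl[res] = float(v2)
        return cls.from_tables(hb, hl)

    def values_for(self, residues: str) -> tuple[np.ndarray, np.ndarray]:
        idx = np.fromiter((AMINO_ALPHABET.index(c) for c in residues), dtype=int)
        return self.phi1[idx], self.phi2[idx]


DEFAULT_SCALE = HydropathyScale.from_tables()


@dataclass(frozen=True)
class ApaacParams:
    """APAAC weight factor and correlation rank.

    ``weight`` (ω, default 0.5) balances composition terms against the
    sequence-order correlation factors; ``lam`` (λ, default 30) is the
    maximum residue separation at which correlation is measured, so the
    vector has 20 + 2λ components and every sequence must be longer than λ.
    """

    weight: float = 0.5
    lam: int = 30

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"APAAC weight must be positive, got {self.weight}")
        if self.lam < 1:
            raise ValueError(f"APAAC lambda must be >= 1, got {self.lam}")


DEFAULT_APAAC = ApaacParams()


# ---------------------------------------------------------------------------
# V1: APAAC


def apaac(protein: ProteinRecord, scale: HydropathyScale = DEFAULT_SCALE,
          params: ApaacParams = DEFAULT_APAAC) -> np.ndarray:
    """Amphiphilic pseudo amino acid composition (20 + 2λ values).

    Components 1–20 are the residue composition terms f_m/(1 + ω Σ τ_k) in
    alphabet order; components 21…20+2λ are ω τ_k/(1 + ω Σ τ_k) with the
    correlation factors interleaved: τ_{2d−1} is the mean product of the
    normalized hydrophobicity at positions separated by d, τ_{2d} the same
    for hydrophilicity, d = 1…λ.  The full vector sums to 1.
    """
    L = len(protein)
    lam, omega = params.lam, params.weight
    if L <= lam:
        raise ValueError(
            f"protein {protein.id!r}: length {L} must exceed APAAC lambda {lam}"
        )
    phi1, phi2 = scale.values_for(protein.residues)

    tau = np.empty(2 * lam)
    for d in range(1, lam + 1):
        tau[2 * d - 2] = np.mean(phi1[:-d] * phi1[d:])  # hydrophobicity, τ_{2d−1}
        tau[2 * d - 1] = np.mean(phi2[:-d] * phi2[d:])  # hydrophilicity, τ_{2d}

    counts = np.array([protein.residues.count(r) for r in AMINO_ALPHABET], dtype=float)
    f = counts / L
    denom = 1.0 + omega * tau.sum()
    return np.concatenate([f / denom, omega * tau / denom])


# ---------------------------------------------------------------------------
# V2: same-type residue interval-distance statistics


def split_segments(protein: ProteinRecord) -> list[str]:
    """Cut the sequence into four consecutive segments.

    With l = floor(L/4) the segments cover positions [1, l], [l+1, 2l],
    [2l+1, 3l] and [3l+1, L]; the fourth absorbs the remainder.
    """
    L = len(protein)
    if L < 4:
        raise ValueError(f"protein {protein.id!r}: length {L} < 4, cannot segment")
    l = L // 4
    s = protein.residues
    return [s[:l], s[l:2 * l], s[2 * l:3 * l], s[3 * l:]]


def interval_distances(segment: str, residue: str) -> list[int]:
    """The interval-distance sequence g_m for one residue type in a segment.

    Positions are 1-based within the segment.  With q occurrences at
    α₁ < … < α_q: q > 1 gives the q−1 gaps α_{τ+1} − α_τ; q = 1 gives the
    single value s − α₁ (distance to the segment end); q = 0 gives [0].
    """
    s = len(segment)
    positions = [i + 1 for i, c in enumerate(segment) if c == residue]
    q = len(positions)
    if q == 0:
        return [0]
    if q == 1:
        return [s - positions[0]]
    return [positions[t + 1] - positions[t] for t in range(q - 1)]


def interval_stats(segment: str) -> np.ndarray:
    """Per-residue (mean, min, max, frequency) interval statistics — 80 values.

    Output order: for each residue m in alphabet order, A_m (mean gap),
    B_m (min gap), C_m (max gap), D_m (segment frequency q/s; 1/s when the
    residue occurs once; 0 when absent).
    """
    s = len(segment)
    if s == 0:
        raise ValueError("empty segment")
    out = np.zeros(80)
    for j, m in enumerate(AMINO_ALPHABET):
        q = segment.count(m)
        if q == 0:
            continue
        g = interval_distances(segment, m)
        out[4 * j + 0] = float(np.mean(g))
        out[4 * j + 1] = float(min(g))
        out[4 * j + 2] = float(max(g))
        out[4 * j + 3] = (len(g) + 1) / s if q > 1 else 1 / s
    return out


def segment_features(protein: ProteinRecord) -> np.ndarray:
    """V2: interval statistics over the four segments, 320 values.

    Ordering is residue-major: for each residue m in alphabet order, the 16
    values A_{m,1} B_{m,1} C_{m,1} D_{m,1} … A_{m,4} B_{m,4} C_{m,4} D_{m,4},
    i.e. one row of the feature matrix per residue.
    """
    per_segment = [interval_stats(seg) for seg in split_segments(protein)]
    out = np.empty(320)
    for j in range(20):
        for k in range(4):
            out[16 * j + 4 * k: 16 * j + 4 * k + 4] = per_segment[k][4 * j: 4 * j + 4]
    return out


# ---------------------------------------------------------------------------
# V3: PSSM evolutionary descriptors


def normalize_pssm(pssm: Pssm) -> np.ndarray:
    """Sigmoid-normalize the raw scores elementwise: a* = 1/(1+exp(−a)).

    Columns are returned in alphabet order regardless of the file's order.
    """
    return 1.0 / (1.0 + np.exp(-pssm.in_alphabet_order()))


def evolution_features(pssm: Pssm, thetas: tuple[int, ...] = (1, 2, 3),
                       normalize: bool = True) -> np.ndarray:
    """V3: θ-interval deviation-product means plus column means, 80 values.

    On the (by default sigmoid-normalized) matrix with column means ā_w,
    the deviation product at separation θ is
    δ_{i,w}^θ = (a_{i,w} − ā_w)(a_{i+θ,w} − ā_w) and its mean over the
    L − θ position pairs is Z_w^θ.  Output order: Z^1 (20), Z^2 (20),
    Z^3 (20), then ā (20).
    """
    a = normalize_pssm(pssm) if normalize else pssm.in_alphabet_order()
    L = a.shape[0]
    if L <= max(thetas):
        raise ValueError(
            f"PSSM {pssm.protein_id!r}: length {L} must exceed max theta {max(thetas)}"
        )
    abar = a.mean(axis=0)
    dev = a - abar
    blocks = []
    for theta in thetas:
        blocks.append((dev[:-theta] * dev[theta:]).mean(axis=0))
    blocks.append(abar)
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Full per-protein vector


@dataclass
class ProteinFeatureVector:
    """The ordered 576-value feature vector of one protein.

    Blocks: V1 APAAC (80), V2 interval statistics (320), V3 evolutionary
    descriptors (80), V4 gene-sequence features (96, filled by
    :mod:`ppigray.gene_features`).
    """

    protein_id: str
    v1: np.ndarray
    v2: np.ndarray
    v3: np.ndarray
    v4: np.ndarray = field(default_factory=lambda: np.zeros(96))

    def __post_init__(self) -> None:
        for name, block, size in (("v1", self.v1, 80), ("v2", self.v2, 320),
                                  ("v3", self.v3, 80), ("v4", self.v4, 96)):
            if np.asarray(block).shape != (size,):
                raise ValueError(
                    f"{self.protein_id!r}: block {name} must have length {size}"
                )

    def concat(self) -> np.ndarray:
        """The 576-vector in V1 | V2 | V3 | V4 order."""
        return np.concatenate([self.v1, self.v2, self.v3, self.v4])

    def ablated(self, zero_blocks: set[str]) -> "ProteinFeatureVector":
        """A copy with the named blocks ('V1'…'V4') zeroed (ablation studies)."""
        blocks = {"v1": self.v1, "v2": self.v2, "v3": self.v3, "v4": self.v4}
        for name in zero_blocks:
            key = name.lower()
            if key not in blocks:
                raise ValueError(f"unknown feature block {name!r}")
            blocks[key] = np.zeros_like(blocks[key])
        return ProteinFeatureVector(self.protein_id, **blocks)


def extract_protein_features(protein: ProteinRecord, pssm: Pssm,
                             scale: HydropathyScale = DEFAULT_SCALE,
                             params: ApaacParams = DEFAULT_APAAC) -> ProteinFeatureVector:
    """V1–V3 from sequence and PSSM; V4 left zero until the gene is seen."""
    if pssm.length != len(protein):
        raise ValueError(
            f"protein {protein.id!r}: PSSM has {pssm.length} rows "
            f"but sequence length is {len(protein)}"
        )
    return ProteinFeatureVector(
        protein_id=protein.id,
        v1=apaac(protein, scale, params),
        v2=segment_features(protein),
        v3=evolution_features(pssm),
    )
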