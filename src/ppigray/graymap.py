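"""Grayscale feature-map assembly.

Each protein's 576 features are laid out as a 36 x 16 matrix:

* rows 1–20: the interval statistics V2, one residue per row
  (A B C D for segments 1–4);
* rows 21–25: the APAAC vector V1, 16 values per row;
* rows 26–30: the evolutionary block V3 with the PSSM column means first,
  then the θ = 1, 2, 3 deviation-product means, filled row-major;
* rows 31–36: the gene block V4 (circle/positional statistics row, the 16
  dinucleotide frequencies, then the 64 trinucleotide frequencies ending
  at TTT).

Two protein matrices are concatenated side by side into a 36 x 32 pair
matrix and min–max normalized into [0, 1], giving the grayscale map the
classifier consumes.  Two normalization conventions are supported:

* *per-sample* — scale each 36 x 32 matrix by its own global min and max
  (:func:`build_pair_map` without a scaler);
* *per-feature* — scale every cell by that feature's min and max across a
  reference set of proteins (:class:`FeatureScaler`), which is what the
  training pipeline uses: raw features differ in scale by four orders of
  magnitude (interval-gap and positional-variance cells dwarf composition
  cells), and a global per-sample scaling would leave most of the map
  numerically black.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

from .io_formats import AMINO_ALPHABET
from .gene_features import DINUCLEOTIDES, TRINUCLEOTIDES
from .protein_features import ProteinFeatureVector

MAP_ROWS = 36
MAP_COLS = 16
PAIR_COLS = 32


def _feature_names() -> list[str]:
    """Names of the 576 features in matrix row-major order."""
    names: list[str] = []
    for m in AMINO_ALPHABET:  # rows 1-20: V2
        for seg in range(1, 5):
            for stat in "ABCD":
                names.append(f"V2:{stat}_{m},{seg}")
    names += [f"V1:v{t}" for t in range(1, 81)]  # rows 21-25
    names += [f"V3:abar_{w}" for w in range(1, 21)]  # rows 26-30
    for theta in (1, 2, 3):
        names += [f"V3:Z{theta}_{w}" for w in range(1, 21)]
    names += ["V4:mu_x", "V4:mu_y", "V4:var_x", "V4:var_y"]  # rows 31-36
    names += [f"V4:mu_{nt}" for nt in "ACGT"]
    names += [f"V4:var_{nt}" for nt in "ACGT"]
    names += [f"V4:f_{nt}" for nt in "ACGT"]
    names += [f"V4:f_{k}" for k in DINUCLEOTIDES]
    names += [f"V4:f_{k}" for k in TRINUCLEOTIDES]
    return names


#: Provenance: name of the feature at each of the 576 cells, row-major.
FEATURE_NAMES = _feature_names()


@dataclass
class ProteinFeatureMatrix:
    """A 36 x 16 per-protein feature matrix plus cell provenance."""

    protein_id: str
    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (MAP_ROWS, MAP_COLS):
            raise ValueError(f"expected {MAP_ROWS}x{MAP_COLS} matrix, "
                             f"got {self.values.shape}")
        if len(self.names) != MAP_ROWS * MAP_COLS:
            raise ValueError("provenance must name all 576 cells")

    def name_at(self, row: int, col: int) -> str:
        return self.names[row * MAP_COLS + col]


@dataclass
class PairSample:
    """A labeled protein pair with its normalized 36 x 32 grayscale map."""

    id_a: str
    id_b: str
    label: object
    map: np.ndarray

    def __post_init__(self) -> None:
        self.map = np.asarray(self.map, dtype=float)
        if self.map.shape != (MAP_ROWS, PAIR_COLS):
            raise ValueError(f"expected {MAP_ROWS}x{PAIR_COLS} map, "
                             f"got {self.map.shape}")


def matrix_order(fv: ProteinFeatureVector) -> np.ndarray:
    """The 576 features reordered from block order (V1|V2|V3|V4) to the
    row-major matrix order."""
    v3_reordered = np.concatenate([fv.v3[60:80], fv.v3[0:60]])  # column means first
    return np.concatenate([fv.v2, fv.v1, v3_reordered, fv.v4])


def build_matrix(fv: ProteinFeatureVector) -> ProteinFeatureMatrix:
    """Lay a protein's 576-feature vector out as the 36 x 16 matrix."""
    flat = matrix_order(fv)
    return ProteinFeatureMatrix(
        protein_id=fv.protein_id,
        values=flat.reshape(MAP_ROWS, MAP_COLS),
        names=list(FEATURE_NAMES),
    )


def minmax_normalize(matrix: np.ndarray) -> np.ndarray:
    """Min–max scale a matrix to [0, 1]; an all-constant matrix maps to zeros."""
    lo = matrix.min()
    hi = matrix.max()
    if hi == lo:
        return np.zeros_like(matrix)
    return (matrix - lo) / (hi - lo)


class FeatureScaler:
    """Per-feature min–max scaling across a reference set of proteins.

    Fit on the protein matrices of a study; each of the 576 cells is then
    scaled by its own min and max so every feature contributes on a
    comparable [0, 1] scale.  A feature constant across the reference set
    (for example a zeroed ablation block) maps to 0.
    """

    def __init__(self, lo: np.ndarray, hi: np.ndarray):
        self.lo = lo
        self.hi = hi
        span = hi - lo
        self._span = np.where(span > 0, span, 1.0)
        self._constant = span == 0

    @classmethod
    def fit(cls, matrices) -> "FeatureScaler":
        stack = np.stack([m.values for m in matrices])
        return cls(lo=stack.min(axis=0), hi=stack.max(axis=0))

    def transform(self, matrix: ProteinFeatureMatrix) -> np.ndarray:
        scaled = (matrix.values - self.lo) / self._span
        scaled[self._constant] = 0.0
        return np.clip(scaled, 0.0, 1.0)


def build_pair_map(ma: ProteinFeatureMatrix, mb: ProteinFeatureMatrix,
                   label: object = "unknown",
                   scaler: FeatureScaler | None = None) -> PairSample:
    """Concatenate two protein matrices side by side and normalize.

    Without a scaler the whole 36 x 32 matrix is min–max scaled per sample
    (an all-constant matrix maps to zeros); with a :class:`FeatureScaler`
    each protein matrix is scaled per feature before concatenation.
    """
    if scaler is None:
        raw = np.hstack([ma.values, mb.values])
        return PairSample(id_a=ma.protein_id, id_b=mb.protein_id, label=label,
                          map=minmax_normalize(raw))
    return PairSample(id_a=ma.protein_id, id_b=mb.protein_id, label=label,
                      map=np.hstack([scaler.transform(ma), scaler.transform(mb)]))


def export_png(sample: PairSample, path) -> None:
    """Write the map as an 8-bit grayscale PNG, 32 wide x 36 tall."""
    pixels = np.round(sample.map * 255).astype(np.uint8)
    Image.fromarray(pixels, mode="L").save(str(path))


def read_png(path) -> np.ndarray:
    """Read a map PNG back to values in [0, 1] (within 1/255 quantization)."""
    return np.asarray(Image.open(str(path)), dtype=float) / 255.0


def rearrange(matrix: ProteinFeatureMatrix,
              permutation: np.ndarray) -> ProteinFeatureMatrix:
    """Permute the 576 cells (row-major indexing) with updated provenance.

    ``permutation[i] = j`` places the feature currently at flat index j at
    flat index i.  Used for the arrangement-invariance experiments.
    """
    perm = np.asarray(permutation)
    if sorted(perm.tolist()) != list(range(MAP_ROWS * MAP_COLS)):
        raise ValueError("permutation must be a bijection over the 576 cells")
    flat = matrix.values.reshape(-1)[perm]
    names = [matrix.names[j] for j in perm]
    return ProteinFeatureMatrix(protein_id=matrix.protein_id,
                                values=flat.reshape(MAP_ROWS, MAP_COLS),
                                names=names)


def random_permutation(seed: int) -> np.ndarray:
    return np.random.default_rng(seed).permutation(MAP_ROWS * MAP_COLS)


def export_provenance(path, matrix: ProteinFeatureMatrix) -> None:
    """Write the 36 x 16 table of feature names at each cell."""
    with open(path, "w") as fh:
        for r in range(MAP_ROWS):
            fh.write("\t".join(matrix.name_at(r, c) for c in range(MAP_COLS)) + "\n")
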