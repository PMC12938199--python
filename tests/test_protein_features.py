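"""Protein feature families V1-V3 against brute-force scalar oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_protein, random_pssm
from ppigray.io_formats import AMINO_ALPHABET, ProteinRecord, Pssm
from ppigray.protein_features import (DEFAULT_SCALE, ApaacParams,
                                      HydropathyScale, ProteinFeatureVector,
                                      apaac, evolution_features,
                                      interval_distances, interval_stats,
                                      normalize_pssm, segment_features,
                                      split_segments)

protein_strategy = st.text(alphabet=AMINO_ALPHABET, min_size=5, max_size=120)


# ---------------------------------------------------------------------------
# oracles


def apaac_oracle(seq: str, omega: float, lam: int) -> list[float]:
    """Term-by-term scalar evaluation of the APAAC definition."""
    phi1 = {r: v for r, v in zip(AMINO_ALPHABET, DEFAULT_SCALE.phi1)}
    phi2 = {r: v for r, v in zip(AMINO_ALPHABET, DEFAULT_SCALE.phi2)}
    L = len(seq)
    taus = []
    for d in range(1, lam + 1):
        t_odd = sum(phi1[seq[i]] * phi1[seq[i + d]] for i in range(L - d)) / (L - d)
        t_even = sum(phi2[seq[i]] * phi2[seq[i + d]] for i in range(L - d)) / (L - d)
        taus += [t_odd, t_even]
    denom = 1.0 + omega * sum(taus)
    comp = [seq.count(m) / L / denom for m in AMINO_ALPHABET]
    return comp + [omega * t / denom for t in taus]


def interval_stats_oracle(segment: str) -> list[float]:
    """Naive per-residue enumeration of occurrence positions and gaps."""
    s = len(segment)
    out = []
    for m in AMINO_ALPHABET:
        alphas = [i + 1 for i, c in enumerate(segment) if c == m]
        q = len(alphas)
        if q == 0:
            out += [0.0, 0.0, 0.0, 0.0]
            continue
        if q == 1:
            g = [s - alphas[0]]
            d = 1.0 / s
        else:
            g = [alphas[t + 1] - alphas[t] for t in range(q - 1)]
            d = (len(g) + 1) / s
        out += [sum(g) / len(g), float(min(g)), float(max(g)), d]
    return out


def evolution_oracle(scores: np.ndarray, thetas=(1, 2, 3)) -> list[float]:
    """Scalar evaluation of the deviation-product descriptors."""
    L = scores.shape[0]
    a = 1.0 / (1.0 + np.exp(-scores))
    abar = [sum(a[i, w] for i in range(L)) / L for w in range(20)]
    out = []
    for theta in thetas:
        for w in range(20):
            z = sum((a[i, w] - abar[w]) * (a[i + theta, w] - abar[w])
                    for i in range(L - theta)) / (L - theta)
            out.append(z)
    return out + abar


# ---------------------------------------------------------------------------
# V1 APAAC


class TestApaac:
    def test_matches_scalar_oracle(self, rng):
        protein = random_protein(np.random.default_rng(0), 40)
        params = ApaacParams(weight=0.5, lam=2)
        got = apaac(protein, params=params)
        expected = apaac_oracle(protein.residues, 0.5, 2)
        np.testing.assert_allclose(got, expected, rtol=1e-12)
        assert got.shape == (24,)

    def test_default_dimension_is_80(self, rng):
        protein = random_protein(rng, 100)
        assert apaac(protein).shape == (80,)

    @given(seq=st.text(alphabet=AMINO_ALPHABET, min_size=8, max_size=80))
    @settings(max_examples=60, deadline=None)
    def test_components_sum_to_one(self, seq):
        protein = ProteinRecord(id="h", residues=seq)
        v = apaac(protein, params=ApaacParams(lam=5))
        assert math.isclose(v.sum(), 1.0, abs_tol=1e-12)

    def test_zero_hydropathy_homopolymer(self):
        # glycine has Hopp-Woods hydrophilicity 0 but nonzero after scaling;
        # instead pick the residue whose normalized values are both 0 if any;
        # arginine has minimum hydrophobicity (phi1=0), tryptophan minimum
        # hydrophilicity.  Use a custom scale with a true double-zero residue.
        hb = {r: (0.0 if r == "A" else 1.0 + i) for i, r in enumerate(AMINO_ALPHABET)}
        hl = {r: (0.0 if r == "A" else 2.0 + i) for i, r in enumerate(AMINO_ALPHABET)}
        scale = HydropathyScale.from_tables(hb, hl)
        protein = ProteinRecord(id="a", residues="A" * 30)
        v = apaac(protein, scale=scale, params=ApaacParams(lam=4))
        # all correlation factors vanish, so composition carries everything
        assert v[0] == pytest.approx(1.0)
        np.testing.assert_allclose(v[1:], 0.0, atol=1e-15)

    def test_too_short_sequence_is_a_parameter_error(self):
        protein = ProteinRecord(id="s", residues="MKVL")
        with pytest.raises(ValueError, match="lambda"):
            apaac(protein, params=ApaacParams(lam=10))

    def test_scale_normalization_spans_unit_interval(self):
        for prop in (DEFAULT_SCALE.phi1, DEFAULT_SCALE.phi2):
            assert prop.min() == 0.0
            assert prop.max() == 1.0


# ---------------------------------------------------------------------------
# V2 segments and interval statistics


class TestSegments:
    @pytest.mark.parametrize("length,expected", [
        (10, [2, 2, 2, 4]),
        (8, [2, 2, 2, 2]),
        (101, [25, 25, 25, 26]),
    ])
    def test_segment_lengths(self, rng, length, expected):
        protein = random_protein(rng, length)
        segments = split_segments(protein)
        assert [len(s) for s in segments] == expected
        assert "".join(segments) == protein.residues

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            split_segments(ProteinRecord(id="t", residues="MKV"))


class TestIntervalStats:
    def test_homopolymer_segment(self):
        out = interval_stats("AAAA")
        a = AMINO_ALPHABET.index("A")
        assert out[4 * a:4 * a + 4].tolist() == [1.0, 1.0, 1.0, 1.0]
        others = np.delete(out.reshape(20, 4), a, axis=0)
        np.testing.assert_array_equal(others, 0.0)

    def test_single_occurrence_branch(self):
        out = interval_stats("ACCC")
        a = AMINO_ALPHABET.index("A")
        # single A at position 1 of a length-4 segment: gap to end = 3
        assert out[4 * a:4 * a + 4].tolist() == [3.0, 3.0, 3.0, 0.25]

    def test_absent_residue_is_all_zero(self):
        out = interval_stats("ACCC")
        w = AMINO_ALPHABET.index("W")
        assert out[4 * w:4 * w + 4].tolist() == [0.0, 0.0, 0.0, 0.0]

    def test_matches_oracle_on_random_segments(self, rng):
        local = np.random.default_rng(42)
        for _ in range(200):
            length = int(local.integers(1, 40))
            segment = "".join(local.choice(list(AMINO_ALPHABET), size=length))
            np.testing.assert_allclose(interval_stats(segment),
                                       interval_stats_oracle(segment),
                                       rtol=1e-12)

    def test_interval_distances_conventions(self):
        assert interval_distances("AXAXA".replace("X", "C"), "A") == [2, 2]
        assert interval_distances("CCCA", "A") == [0]  # q=1 at segment end
        assert interval_distances("CCCC", "A") == [0]  # q=0


class TestSegmentFeatures:
    def test_length_and_frequency_identity(self, rng):
        protein = random_protein(rng, 87)
        v2 = segment_features(protein)
        assert v2.shape == (320,)
        # per segment, residue frequencies D sum to 1
        for seg in split_segments(protein):
            stats = interval_stats(seg)
            assert math.isclose(stats[3::4].sum(), 1.0, abs_tol=1e-12)

    def test_homopolymer_segments_are_identical(self):
        protein = ProteinRecord(id="a8", residues="A" * 8)
        v2 = segment_features(protein).reshape(20, 4, 4)
        for k in range(1, 4):
            np.testing.assert_array_equal(v2[:, k], v2[:, 0])

    def test_ordering_is_residue_major_segment_inner(self, rng):
        protein = random_protein(rng, 61)
        v2 = segment_features(protein)
        per_segment = [interval_stats(seg) for seg in split_segments(protein)]
        m = AMINO_ALPHABET.index(protein.residues[0])
        # row m of the matrix: A,B,C,D for segments 1..4
        row = v2[16 * m:16 * m + 16]
        expected = np.concatenate([per_segment[k][4 * m:4 * m + 4] for k in range(4)])
        np.testing.assert_array_equal(row, expected)


# ---------------------------------------------------------------------------
# V3 evolutionary descriptors


class TestEvolutionFeatures:
    def test_sigmoid_midpoint_and_symmetry(self):
        pssm = Pssm(protein_id="z", scores=np.zeros((4, 20)))
        np.testing.assert_allclose(normalize_pssm(pssm), 0.5)
        pssm2 = Pssm(protein_id="s", scores=np.vstack([np.full((1, 20), 2.0),
                                                       np.full((1, 20), -2.0)]))
        n = normalize_pssm(pssm2)
        np.testing.assert_allclose(n[0] + n[1], 1.0, rtol=1e-12)

    def test_matches_scalar_oracle(self, rng):
        pssm = random_pssm(np.random.default_rng(5), 9)
        got = evolution_features(pssm)
        np.testing.assert_allclose(got, evolution_oracle(pssm.scores), rtol=1e-10)
        assert got.shape == (80,)

    def test_constant_matrix_gives_zero_deviation_products(self):
        pssm = Pssm(protein_id="c", scores=np.full((6, 20), 3.0))
        v3 = evolution_features(pssm)
        np.testing.assert_allclose(v3[:60], 0.0, atol=1e-15)
        np.testing.assert_allclose(v3[60:], 1 / (1 + math.exp(-3.0)), rtol=1e-12)

    def test_minimal_length_two_by_hand(self):
        scores = np.zeros((2, 20))
        scores[0, 0], scores[1, 0] = 1.0, -1.0
        a1 = 1 / (1 + math.exp(-1.0))
        a2 = 1 / (1 + math.exp(1.0))
        abar = (a1 + a2) / 2
        expected_z = ((a1 - abar) * (a2 - abar))
        v3 = evolution_features(Pssm(protein_id="m", scores=scores), thetas=(1,))
        assert v3[0] == pytest.approx(expected_z, rel=1e-12)
        assert v3[20] == pytest.approx(abar, rel=1e-12)

    def test_column_permutation_equivariance(self, rng):
        base = random_pssm(np.random.default_rng(9), 12)
        perm = np.random.default_rng(10).permutation(20)
        permuted_order = "".join(AMINO_ALPHABET[i] for i in perm)
        permuted = Pssm(protein_id="p", scores=base.scores[:, perm],
                        column_order=permuted_order)
        # reader-order abstraction: both must give alphabet-order output
        np.testing.assert_allclose(evolution_features(base),
                                   evolution_features(permuted), rtol=1e-12)

    def test_outputs_finite_and_column_means_in_unit_interval(self, rng):
        for _ in range(20):
            pssm = random_pssm(rng, int(rng.integers(4, 60)))
            v3 = evolution_features(pssm)
            assert np.all(np.isfinite(v3))
            assert np.all((v3[60:] > 0) & (v3[60:] < 1))

    def test_too_short_for_theta(self):
        with pytest.raises(ValueError):
            evolution_features(Pssm(protein_id="s", scores=np.zeros((3, 20))))


class TestProteinFeatureVector:
    def test_block_sizes_enforced(self):
        with pytest.raises(ValueError):
            ProteinFeatureVector("x", np.zeros(79), np.zeros(320), np.zeros(80))

    def test_concat_order_and_length(self):
        fv = ProteinFeatureVector("x", np.full(80, 1.0), np.full(320, 2.0),
                                  np.full(80, 3.0), np.full(96, 4.0))
        flat = fv.concat()
        assert flat.shape == (576,)
        assert flat[0] == 1.0 and flat[80] == 2.0
        assert flat[400] == 3.0 and flat[480] == 4.0

    def test_ablation_zeroes_only_named_blocks(self):
        fv = ProteinFeatureVector("x", np.full(80, 1.0), np.full(320, 2.0),
                                  np.full(80, 3.0), np.full(96, 4.0))
        ab = fv.ablated({"V1", "V3"})
        assert np.all(ab.v1 == 0) and np.all(ab.v3 == 0)
        assert np.all(ab.v2 == 2.0) and np.all(ab.v4 == 4.0)
        with pytest.raises(ValueError):
            fv.ablated({"V9"})
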