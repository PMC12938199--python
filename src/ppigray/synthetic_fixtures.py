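"""Synthetic inputs for the whole pipeline.

Real runs consume curated interaction data, UniProt localization and
PSI-BLAST profiles; none of those can be bundled, so this module generates
every input format the pipeline reads — protein FASTA, back-translated
coding sequences, ASCII PSSM files, localization tables and labeled pair
tables — from a single master seed.

The interaction labels carry a *planted signal*: each protein receives a
latent hydropathy bias that tilts its residue composition along the
normalized hydrophobicity scale, its "stickiness" is the realized mean
hydrophobicity of the sequence, and a pair interacts when the stickiness
sum exceeds a threshold chosen to hit the configured positive rate (labels
are then flipped with the configured noise rate).  The signal is therefore
expressed through quantities the feature layer actually computes, so a
trained classifier can be benchmarked for learnability on fixtures alone.

The PSSMs are synthetic — integer scores with a positive bias on each
position's own residue — and exist to exercise the evolutionary-feature
formulas and the reader, not to be biologically calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset_builder import canonical_pair, write_manifest
from .io_formats import (AMINO_ALPHABET, LABEL_NEGATIVE, LABEL_POSITIVE,
                         GeneRecord, LocalizationTable, Pair, Pssm,
                         ProteinRecord, write_ascii_pssm, write_fasta,
                         write_localizations, write_pairs)
from .protein_features import DEFAULT_SCALE

#: Standard-genetic-code codons per residue (DNA alphabet).
CODON_TABLE: dict[str, tuple[str, ...]] = {
    "A": ("GCT", "GCC", "GCA", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "M": ("ATG",),
    "N": ("AAT", "AAC"),
    "P": ("CCT", "CCC", "CCA", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "S": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "T": ("ACT", "ACC", "ACA", "ACG"),
    "V": ("GTT", "GTC", "GTA", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

DEFAULT_COMPARTMENTS = ("membrane", "nucleus", "cytoplasm", "mitochondrion",
                        "secreted")


@dataclass
class FixtureConfig:
    """Knobs of the synthetic world.

    ``effect_size`` controls how strongly a protein's latent hydropathy
    bias tilts its composition (0 = no planted signal); ``positive_rate``
    is the fraction of candidate pairs labeled interacting before noise —
    the default 0.25 matches the weight of the both-hydrophobic mode of
    the bimodal latent bias, so the labeling threshold falls in the gap
    between score modes and the planted dichotomy has a margin;
    ``noise_rate`` flips labels independently and must stay below 0.5 or
    the signal would be destroyed.
    """

    n_proteins: int = 100
    length_range: tuple[int, int] = (60, 400)
    effect_size: float = 8.0
    positive_rate: float = 0.25
    noise_rate: float = 0.0
    pssm_score_range: tuple[int, int] = (-8, 12)
    pssm_self_bias: int = 6
    bias_concentration: float = 0.35
    compartments: tuple[str, ...] = DEFAULT_COMPARTMENTS
    localization_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < 50:
            raise ValueError("fixture proteins must be at least 50 residues "
                             "to pass the dataset length filter")
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError(f"noise rate must be in [0, 0.5), got {self.noise_rate}")
        if not 0.0 < self.positive_rate < 1.0:
            raise ValueError("positive rate must be in (0, 1)")


def gen_proteins(config: FixtureConfig, seed: int | None = None) -> list[ProteinRecord]:
    """Seeded i.i.d. residue draws with a per-protein hydropathy tilt.

    Protein p draws a latent bias h_p ~ Beta(c, c) with concentration
    c = ``bias_concentration`` < 1 — a bimodal law, so most proteins are
    clearly hydrophobic- or hydrophilic-leaning and the planted dichotomy
    has a margin; its residue weights are proportional to
    exp(effect_size · (h_p − 0.5) · φ̂¹_m) with φ̂¹ the centered normalized
    hydrophobicity, so high-bias proteins are enriched in hydrophobic
    residues.  Ids are p0001, p0002, …
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    phi1 = DEFAULT_SCALE.phi1 - DEFAULT_SCALE.phi1.mean()
    lo, hi = config.length_range
    records = []
    for i in range(config.n_proteins):
        c = config.bias_concentration
        h = rng.beta(c, c)
        weights = np.exp(config.effect_size * (h - 0.5) * phi1)
        weights /= weights.sum()
        L = int(rng.integers(lo, hi + 1))
        residues = "".join(rng.choice(list(AMINO_ALPHABET), size=L, p=weights))
        records.append(ProteinRecord(id=f"p{i + 1:04d}", residues=residues))
    return records


def stickiness(protein: ProteinRecord) -> float:
    """Mean normalized hydrophobicity of the sequence — the latent trait
    the interaction labels are planted on."""
    phi1, _ = DEFAULT_SCALE.values_for(protein.residues)
    return float(phi1.mean())


def back_translate(protein: ProteinRecord, seed: int) -> GeneRecord:
    """A coding sequence for the protein: per residue, a codon drawn
    uniformly from its standard-genetic-code codons (no stop codon)."""
    rng = np.random.default_rng(seed)
    codons = []
    for res in protein.residues:
        options = CODON_TABLE[res]
        codons.append(options[int(rng.integers(len(options)))])
    return GeneRecord(id=protein.id, nucleotides="".join(codons))


def translate(gene: GeneRecord) -> str:
    """Standard-code translation, for round-trip checks."""
    inverse = {codon: aa for aa, codons in CODON_TABLE.items() for codon in codons}
    seq = gene.nucleotides
    return "".join(inverse[seq[i:i + 3]] for i in range(0, len(seq), 3))


def gen_pssm(protein: ProteinRecord, config: FixtureConfig, seed: int) -> Pssm:
    """L x 20 integer scores in the configured range, with a positive bias
    added to each position's own residue column."""
    rng = np.random.default_rng(seed)
    lo, hi = config.pssm_score_range
    scores = rng.integers(lo, hi + 1, size=(len(protein), 20)).astype(float)
    for i, res in enumerate(protein.residues):
        scores[i, AMINO_ALPHABET.index(res)] += config.pssm_self_bias
    return Pssm(protein_id=protein.id, scores=scores)


def gen_localizations(proteins: list[ProteinRecord], config: FixtureConfig,
                      seed: int) -> LocalizationTable:
    """One compartment per protein, consistent with the planted biology.

    Sticky (hydrophobic-leaning) proteins — stickiness above the population
    median — co-localize to the first compartment; the rest spread
    uniformly over the remaining compartments.  Interacting pairs (both
    sticky) therefore always share a compartment, so the disjoint-
    localization negative strategy draws only genuinely non-interacting
    pairs — the synthetic world makes the heuristic true, as it is assumed
    to be for real compartment annotations.  ``localization_noise`` is the
    fraction of proteins assigned a random compartment instead (breaking
    the heuristic for a controllable minority); non-sticky pairs still
    land in different compartments most of the time, which is what
    exercises the negative sampler.
    """
    rng = np.random.default_rng(seed)
    sticky_home = config.compartments[0]
    others = config.compartments[1:]
    values = np.array([stickiness(p) for p in proteins])
    median = float(np.median(values))
    table = {}
    for p, s in zip(proteins, values):
        if rng.uniform() < config.localization_noise:
            comp = str(rng.choice(config.compartments))
        elif s > median:
            comp = sticky_home
        else:
            comp = str(rng.choice(others))
        table[p.id] = frozenset({comp})
    return LocalizationTable(table)


def gen_interactions(proteins: list[ProteinRecord], config: FixtureConfig,
                     seed: int, max_pairs: int | None = None
                     ) -> tuple[list[Pair], LocalizationTable]:
    """Label (a subset of) all unordered pairs by the planted signal.

    A pair's score is the sum of the two proteins' stickiness values; the
    top ``positive_rate`` fraction of scores is labeled interacting, then
    labels are flipped independently with ``noise_rate``.  With
    ``max_pairs``, a seeded subsample of the candidate pairs is labeled.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    rng = np.random.default_rng(seed)
    stick = {p.id: stickiness(p) for p in proteins}
    ids = [p.id for p in proteins]
    candidates = [(ids[i], ids[j]) for i in range(len(ids))
                  for j in range(i + 1, len(ids))]
    if max_pairs is not None and max_pairs < len(candidates):
        idx = rng.choice(len(candidates), size=max_pairs, replace=False)
        candidates = [candidates[i] for i in sorted(idx)]
    scores = np.array([stick[a] + stick[b] for a, b in candidates])
    threshold = float(np.quantile(scores, 1.0 - config.positive_rate))
    labels = scores > threshold
    if config.noise_rate > 0:
        flips = rng.uniform(size=labels.size) < config.noise_rate
        labels = labels ^ flips
    pairs = [Pair(*canonical_pair(a, b), LABEL_POSITIVE if lab else LABEL_NEGATIVE)
             for (a, b), lab in zip(candidates, labels)]
    localizations = gen_localizations(proteins, config, seed + 1)
    return pairs, localizations


@dataclass
class FixtureSet:
    """Everything one synthetic study needs, in memory."""

    config: FixtureConfig
    proteins: list[ProteinRecord]
    genes: list[GeneRecord]
    pssms: dict[str, Pssm]
    pairs: list[Pair]
    localizations: LocalizationTable


def generate(config: FixtureConfig, max_pairs: int | None = None) -> FixtureSet:
    """Generate a complete fixture set from the master seed.

    Sub-seeds: proteins = seed, CDS of protein i = seed + 10000 + i,
    PSSM of protein i = seed + 20000 + i, interactions = seed + 30000.
    """
    s = config.seed
    proteins = gen_proteins(config, seed=s)
    genes = [back_translate(p, seed=s + 10000 + i) for i, p in enumerate(proteins)]
    pssms = {p.id: gen_pssm(p, config, seed=s + 20000 + i)
             for i, p in enumerate(proteins)}
    pairs, localizations = gen_interactions(proteins, config, seed=s + 30000,
                                            max_pairs=max_pairs)
    return FixtureSet(config=config, proteins=proteins, genes=genes,
                      pssms=pssms, pairs=pairs, localizations=localizations)


def write_fixture_dir(fixture: FixtureSet, outdir) -> None:
    """Write the fixture set as the on-disk formats the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / "proteins.fasta", fixture.proteins)
    write_fasta(outdir / "cds.fasta", fixture.genes)
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    residues = {p.id: p.residues for p in fixture.proteins}
    for pid, pssm in fixture.pssms.items():
        write_ascii_pssm(pssm_dir / f"{pid}.pssm", pssm, residues=residues[pid])
    write_pairs(outdir / "pairs.tsv", fixture.pairs)
    write_localizations(outdir / "localizations.tsv", fixture.localizations)
    cfg = fixture.config
    write_manifest(outdir / "manifest.txt", seed=cfg.seed,
                   n_proteins=cfg.n_proteins,
                   length_range=f"{cfg.length_range[0]}-{cfg.length_range[1]}",
                   effect_size=cfg.effect_size, positive_rate=cfg.positive_rate,
                   noise_rate=cfg.noise_rate, n_pairs=len(fixture.pairs))
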