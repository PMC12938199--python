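"""End-to-end wiring: features -> matrices -> pair maps -> training arrays.

This is the glue the command-line interface, the tests and benchmark
scripts share.  The canonical small-study driver :func:`run_study` performs
the full workflow on an in-memory fixture set: extract the 576 features per
protein, split positives 3:1:1, attach localization-strategy negatives,
build five balanced undersampled training sets, train the CNN ensemble and
evaluate on the held-out balanced test set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dataset_builder as db
from .cnn_classifier import TrainConfig, TrainedEnsemble, fit_ensemble
from .evaluation import ConfusionCounts, MetricReport, confusion_metrics, roc_auc
from .gene_features import gene_features
from .graymap import (FeatureScaler, ProteinFeatureMatrix, build_matrix,
                      build_pair_map)
from .io_formats import GeneRecord, Pair, ProteinRecord, Pssm
from .protein_features import (DEFAULT_APAAC, DEFAULT_SCALE, ApaacParams,
                               HydropathyScale, ProteinFeatureVector,
                               extract_protein_features)
from .synthetic_fixtures import FixtureSet


def extract_features(proteins: list[ProteinRecord], genes: list[GeneRecord],
                     pssms: dict[str, Pssm],
                     scale: HydropathyScale = DEFAULT_SCALE,
                     params: ApaacParams = DEFAULT_APAAC,
                     ablate: set[str] | None = None
                     ) -> dict[str, ProteinFeatureVector]:
    """The 576-feature vector per protein; optionally zero whole families.

    Proteins lacking a PSSM or CDS are skipped with a warning.
    """
    import warnings
    gene_by_id = {g.id: g for g in genes}
    out: dict[str, ProteinFeatureVector] = {}
    for protein in proteins:
        if protein.id not in pssms:
            warnings.warn(f"{protein.id}: no PSSM, skipped", stacklevel=2)
            continue
        if protein.id not in gene_by_id:
            warnings.warn(f"{protein.id}: no CDS, skipped", stacklevel=2)
            continue
        fv = extract_protein_features(protein, pssms[protein.id], scale, params)
        fv.v4 = gene_features(gene_by_id[protein.id])
        if ablate:
            fv = fv.ablated(ablate)
        out[protein.id] = fv
    return out


def build_matrices(features: dict[str, ProteinFeatureVector]
                   ) -> dict[str, ProteinFeatureMatrix]:
    return {pid: build_matrix(fv) for pid, fv in features.items()}


def pair_arrays(pairs: list[Pair], matrices: dict[str, ProteinFeatureMatrix],
                scaler: FeatureScaler | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """Stacked normalized 36x32 maps and integer labels for a pair table."""
    maps, labels = [], []
    for p in pairs:
        sample = build_pair_map(matrices[p.id_a], matrices[p.id_b],
                                label=p.label, scaler=scaler)
        maps.append(sample.map)
        labels.append(1 if p.label == 1 else 0)
    return np.stack(maps), np.array(labels, dtype=int)


@dataclass
class StudyResult:
    """Everything a small end-to-end study produces."""

    ensemble: TrainedEnsemble
    split: db.DatasetSplit
    matrices: dict[str, ProteinFeatureMatrix]
    scaler: FeatureScaler | None
    test_pairs: list[Pair]
    test_probs: np.ndarray
    test_labels: np.ndarray
    report: MetricReport
    auc: float
    extras: dict = field(default_factory=dict)


def run_study(fixture: FixtureSet, seed: int,
              tc: TrainConfig | None = None,
              channels: int = 4, max_trials: int = 0,
              ablate: set[str] | None = None,
              use_localization_negatives: bool = True,
              negatives_per_positive: float = 3.0) -> StudyResult:
    """The five-step workflow on a fixture set.

    1. extract features (with optional family ablation);
    2. split positives 3:1:1 and attach negatives — by default drawn with
       the disjoint-localization strategy from the fixture's annotation,
       excluding all labeled positives;
    3. build grayscale maps (per-feature min–max scaling fit on the
       study's protein matrices);
    4. train the 5-model undersampling ensemble (optionally tuning);
    5. evaluate on the balanced held-out test set.
    """
    tc = tc or TrainConfig(seed=seed)
    features = extract_features(fixture.proteins, fixture.genes, fixture.pssms,
                                ablate=ablate)
    matrices = build_matrices(features)
    scaler = FeatureScaler.fit(matrices.values())

    positives = [p for p in fixture.pairs if p.label == 1]
    labeled_negatives = [p for p in fixture.pairs if p.label == 0]
    split = db.split_positives(positives, seed=seed)
    if use_localization_negatives:
        # negatives: disjoint-compartment pairs, a multiple of the positive
        # count so the training pool supports five distinct undersampled draws
        pool = db.make_negatives(fixture.proteins, fixture.localizations,
                                 n=None, seed=seed + 1, positives=positives)
        negatives = pool[:min(int(negatives_per_positive * len(positives)),
                              len(pool))]
    else:
        negatives = labeled_negatives
    db.attach_negatives(split, negatives, seed=seed + 2)

    ensembles_sets = db.undersample_ensembles(split, seed=seed + 3)
    training_sets = [
        pair_arrays(pair_set, matrices, scaler) for pair_set in ensembles_sets.sets
    ]
    n_val = min(len(split.val_pos), len(split.val_neg))
    val_pairs = split.val_pos[:n_val] + split.val_neg[:n_val]
    val_maps, val_labels = pair_arrays(val_pairs, matrices, scaler)

    ensemble = fit_ensemble(training_sets, val_maps, val_labels, tc,
                            max_trials=max_trials, seed=seed + 4,
                            channels=channels)

    n_test = min(len(split.test_pos), len(split.test_neg))
    test_pairs = split.test_pos[:n_test] + split.test_neg[:n_test]
    test_maps, test_labels = pair_arrays(test_pairs, matrices, scaler)
    probs = ensemble.predict_proba(test_maps)
    counts = ConfusionCounts.from_predictions(test_labels, (probs > 0.5).astype(int))
    report = confusion_metrics(counts)
    area, _, _ = roc_auc(probs, test_labels)
    return StudyResult(ensemble=ensemble, split=split, matrices=matrices,
                       scaler=scaler, test_pairs=test_pairs, test_probs=probs,
                       test_labels=test_labels, report=report, auc=area)


def evaluate_ablated(result: StudyResult, fixture: FixtureSet,
                     ablate: set[str]) -> MetricReport:
    """Feature-ablation evaluation of an already-trained ensemble.

    The named feature families are zeroed in every protein's vector, the
    test maps are rebuilt with the study's original scaler, and the trained
    ensemble re-scores the same held-out test pairs.  The accuracy drop
    measures how much the model relies on the ablated family.
    """
    features = extract_features(fixture.proteins, fixture.genes, fixture.pssms,
                                ablate=ablate)
    matrices = build_matrices(features)
    maps, labels = pair_arrays(result.test_pairs, matrices, result.scaler)
    probs = result.ensemble.predict_proba(maps)
    counts = ConfusionCounts.from_predictions(labels, (probs > 0.5).astype(int))
    return confusion_metrics(counts)
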