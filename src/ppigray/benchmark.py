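"""The reference desk-scale benchmark study.

One canonical configuration — used by the heavyweight end-to-end test and
the acceptance script — that exercises the full workflow on the
planted-signal fixtures: 120 proteins of 60–120 residues, 2400 labeled
pairs at the default positive rate with zero label noise, localization-strategy
negatives, the 3:1:1 split, five balanced undersampled training sets and a
five-member ensemble of 2-channel networks trained at learning rate 1e-3
(at most 100 epochs, patience 10).  The study's problem sizes are chosen
so a full run finishes in minutes on one core while leaving the planted
signal clearly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dataset_builder as db
from .cnn_classifier import TrainConfig
from .evaluation import MetricReport, pr_aupr, top_u_precision
from .pipeline import StudyResult, evaluate_ablated, pair_arrays, run_study
from .synthetic_fixtures import FixtureConfig, FixtureSet, generate

N_PROTEINS = 120
LENGTH_RANGE = (60, 120)
MAX_PAIRS = 2400
CHANNELS = 2
LEARNING_RATE = 1e-3
MAX_EPOCHS = 100
PATIENCE = 10


def benchmark_fixture(seed: int) -> FixtureSet:
    config = FixtureConfig(n_proteins=N_PROTEINS, length_range=LENGTH_RANGE,
                           noise_rate=0.0, seed=seed)
    return generate(config, max_pairs=MAX_PAIRS)


@dataclass
class BenchmarkResult:
    fixture: FixtureSet
    study: StudyResult
    ablated_v1: MetricReport
    aupr_1_5: float
    top_u: dict[int, float]
    imbalanced_n: int


def run_benchmark(seed: int) -> BenchmarkResult:
    """Generate fixtures, train the ensemble, evaluate all reference modes."""
    fixture = benchmark_fixture(seed)
    tc = TrainConfig(seed=seed, learning_rate=LEARNING_RATE,
                     max_epochs=MAX_EPOCHS, patience=PATIENCE)
    study = run_study(fixture, seed=seed, tc=tc, channels=CHANNELS,
                      negatives_per_positive=6.0)

    ablated = evaluate_ablated(study, fixture, {"V1"})

    # imbalanced 1:5 test variant for ranking-quality measures
    imbalanced = db.make_imbalanced_test(study.split, ratio=5, seed=seed + 5)
    maps, labels = pair_arrays(imbalanced, study.matrices, study.scaler)
    probs = study.ensemble.predict_proba(maps)
    aupr, _, _ = pr_aupr(probs, labels)
    top_u = {u: top_u_precision(probs, labels, u)
             for u in (100, 200, 300) if len(labels) >= u}
    return BenchmarkResult(fixture=fixture, study=study, ablated_v1=ablated,
                           aupr_1_5=float(aupr), top_u=top_u,
                           imbalanced_n=len(labels))
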