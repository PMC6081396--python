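"""Canonical synthetic benchmark runs shared by scripts and reports.

The desk-scale benchmark draws 20 independent synthetic datasets from the
default generator configuration (60 drugs, 4 groups, ~0.33 pair density)
and evaluates each under 25% new-drug hold-out with 5 repetitions; the
reported figure per method is the grand mean AUPR over the 100
repetitions.  25% hold-out keeps 45 training drugs, enough for the K = 5
MLKNN neighborhoods every local task needs; the repetition count is a
scaled-down analogue of the full 50-repetition protocol.

The degree-bias probe uses a single dataset with strongly skewed group
sizes (``degree_skew = 1.5``) and leave-one-out evaluation.
"""

from __future__ import annotations

import numpy as np

from .engine import ClassifierConfig
from .evaluation import HoldoutPlan, holdout_cv_many, loocv_degree_bias
from .synthetic import SyntheticConfig, generate_synthetic_ddi

__all__ = [
    "BENCHMARK_RATIO",
    "BENCHMARK_DATASETS",
    "BENCHMARK_REPETITIONS",
    "run_holdout_benchmark",
    "run_degree_bias_benchmark",
]

BENCHMARK_RATIO = 0.25
BENCHMARK_DATASETS = 20
BENCHMARK_REPETITIONS = 5


def run_holdout_benchmark(
    methods,
    base_seed: int = 1,
    n_datasets: int = BENCHMARK_DATASETS,
    repetitions: int = BENCHMARK_REPETITIONS,
    ratio: float = BENCHMARK_RATIO,
    config: ClassifierConfig = ClassifierConfig(),
):
    """Mean AUPR per method over independent synthetic datasets.

    Returns ``(means, per_dataset, prevalence)``: the grand mean per
    method, the per-dataset means (method -> array of length
    ``n_datasets``), and the mean fraction of interacting pairs.
    """
    rng = np.random.default_rng(base_seed)
    per_dataset = {mth: [] for mth in methods}
    prevalences = []
    for _ in range(n_datasets):
        data_seed = int(rng.integers(0, 2**31 - 1))
        ds = generate_synthetic_ddi(SyntheticConfig(seed=data_seed))
        plan = HoldoutPlan(
            ratio=ratio,
            repetitions=repetitions,
            seeds=tuple(int(s) for s in rng.integers(0, 2**31 - 1, repetitions)),
        )
        reports = holdout_cv_many(ds.interactions, ds.similarity, plan,
                                  methods, config)
        for mth in methods:
            per_dataset[mth].append(reports[mth].mean)
        m = ds.config.m
        prevalences.append(ds.interactions.values.sum() / (m * (m - 1)))
    per_dataset = {mth: np.array(v) for mth, v in per_dataset.items()}
    means = {mth: float(v.mean()) for mth, v in per_dataset.items()}
    return means, per_dataset, float(np.mean(prevalences))


def run_degree_bias_benchmark(
    methods=("ns", "svm"),
    seed: int = 7,
    degree_skew: float = 1.5,
    config: ClassifierConfig = ClassifierConfig(),
):
    """LOOCV Spearman(score, training-drug degree) per method.

    Returns a dict method -> (signed mean, absolute mean) over all
    leave-one-out rounds on a degree-skewed synthetic network.
    """
    ds = generate_synthetic_ddi(SyntheticConfig(degree_skew=degree_skew, seed=seed))
    out = {}
    for mth in methods:
        summary = loocv_degree_bias(ds.interactions, ds.similarity, mth, config)
        out[mth] = (summary.spearman_mean, summary.spearman_abs_mean)
    return out
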