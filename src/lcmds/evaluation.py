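"""Evaluation protocols for new-drug DDI prediction.

The central protocol is hold-out cross-validation in the new-drug
setting: a fraction of drugs is withheld together with *all* their
interactions, models train on the remaining network, and every withheld
drug is scored against every training drug.  All withheld pairs of a
repetition are pooled into one precision-recall curve and summarized by
AUPR, the metric of choice under the heavy class imbalance of per-drug
interaction labels.

Also provided: a leave-one-out protocol measuring how strongly a
method's scores track training-drug degree (the degree-induced bias of
similarity-sum baselines), average-rank case summaries, and the naive
similarity (NS) and label propagation (LP) baselines the bias analysis
compares against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import average_precision_score

from .engine import ALL_METHODS, ClassifierConfig, lcm_predict_all
from .io import InteractionMatrix, SimilarityMatrix

__all__ = [
    "HoldoutPlan",
    "EvaluationReport",
    "RankingSummary",
    "aupr",
    "average_rank_of_positives",
    "holdout_cv",
    "holdout_cv_many",
    "loocv_degree_bias",
    "ns_baseline_scores",
    "lp_baseline_scores",
    "ablation_run",
    "BASELINE_METHODS",
]

logger = logging.getLogger(__name__)

BASELINE_METHODS = ("ns", "lp")


# ---------------------------------------------------------------------------
# metrics


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve (step-wise average precision).

    Tied scores are processed as one threshold group; requires at least
    one positive and one negative label.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if y.min() == y.max():
        raise ValueError("AUPR undefined: labels are single-class")
    return float(average_precision_score(y, s))


def average_rank_of_positives(scores, labels) -> float:
    """Mean rank (1 = best, ties get mean ranks) of positively labeled entries."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if y.sum() < 1:
        raise ValueError("need at least one positive label")
    ranks = rankdata(-s, method="average")
    return float(ranks[y == 1].mean())


# ---------------------------------------------------------------------------
# baselines


def ns_baseline_scores(A_train: InteractionMatrix, query: np.ndarray) -> np.ndarray:
    """Naive similarity scores: sum of query similarities to each target's partners.

    ``score(x, d_j) = sum_{i: a_ij = 1} s(x, d_i)`` -- explicitly
    proportional to the target's interaction degree, hence degree-biased.
    """
    q = np.atleast_2d(np.asarray(_vals(query), dtype=float))
    return np.squeeze(q @ A_train.values)


def lp_baseline_scores(
    A_train: InteractionMatrix,
    S_train: SimilarityMatrix,
    query: np.ndarray,
    beta: float = 0.5,
) -> np.ndarray:
    """Label propagation scores through the similarity graph.

    The query node is appended to the training similarity graph with its
    similarity row; each target drug's label column diffuses as
    ``F = (1 - beta) (I - beta W)^{-1} Y`` with W the row-normalized
    similarity, and the query's row of F is the score vector.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError("beta must be in (0, 1)")
    S = S_train.values
    A = A_train.values.astype(float)
    q = np.atleast_2d(np.asarray(_vals(query), dtype=float))
    n_q = q.shape[0]
    m = len(S)
    out = np.empty((n_q, m))
    for r in range(n_q):
        W = np.zeros((m + 1, m + 1))
        W[:m, :m] = S
        W[m, :m] = q[r]
        W[:m, m] = q[r]
        W[m, m] = 1.0
        rowsum = W.sum(axis=1, keepdims=True)
        W /= np.maximum(rowsum, 1e-300)
        Y = np.zeros((m + 1, m))
        Y[:m, :] = A
        F = np.linalg.solve(np.eye(m + 1) - beta * W, (1.0 - beta) * Y)
        out[r] = F[m]
    return np.squeeze(out)


# ---------------------------------------------------------------------------
# hold-out cross-validation


@dataclass(frozen=True)
class HoldoutPlan:
    """Repetitions of random new-drug hold-out.

    ``ratio`` is the fraction of drugs withheld as testing drugs per
    repetition; seeds default to ``1..repetitions``.
    """

    ratio: float = 0.25
    repetitions: int = 50
    seeds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.ratio < 1.0:
            raise ValueError("ratio must be in (0, 1)")
        if self.repetitions < 1:
            raise ValueError("need at least one repetition")
        seeds = self.seeds or tuple(range(1, self.repetitions + 1))
        if len(seeds) != self.repetitions:
            raise ValueError("need exactly one seed per repetition")
        object.__setattr__(self, "seeds", tuple(int(s) for s in seeds))


@dataclass(frozen=True)
class EvaluationReport:
    """Per-repetition AUPR values for one method under one plan."""

    method: str
    plan: HoldoutPlan
    auprs: tuple[float, ...]
    skipped: tuple[int, ...] = ()

    @property
    def mean(self) -> float:
        return float(np.mean(self.auprs))

    @property
    def std(self) -> float:
        return float(np.std(self.auprs, ddof=1)) if len(self.auprs) > 1 else 0.0

    def write(self, path) -> None:
        """Flat key-value summary plus a per-repetition TSV next to it."""
        path = Path(path)
        lines = [
            f"method\t{self.method}",
            f"holdout_ratio\t{self.plan.ratio}",
            f"repetitions\t{self.plan.repetitions}",
            f"seeds\t{','.join(map(str, self.plan.seeds))}",
            f"skipped_seeds\t{','.join(map(str, self.skipped))}",
            f"mean_aupr\t{self.mean:.17g}",
            f"std_aupr\t{self.std:.17g}",
        ]
        path.write_text("\n".join(lines) + "\n")
        pd.DataFrame({
            "seed": [s for s in self.plan.seeds if s not in self.skipped],
            "aupr": self.auprs,
        }).to_csv(path.with_suffix(".repetitions.tsv"), sep="\t", index=False,
                  float_format="%.17g")


def _split(m: int, ratio: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    n_test = max(1, int(round(ratio * m)))
    n_test = min(n_test, m - 2)
    test = np.sort(rng.choice(m, size=n_test, replace=False))
    train = np.setdiff1d(np.arange(m), test)
    return train, test


def _predict_methods(A_tr, S_tr, queries, methods, config, beta):
    """Dispatch engine methods and baselines on one training split."""
    engine_methods = [mth for mth in methods if mth in ALL_METHODS]
    out = {}
    if engine_methods:
        sms = lcm_predict_all(A_tr, S_tr, queries, engine_methods, config)
        out.update({mth: sms[mth].values for mth in engine_methods})
    if "ns" in methods:
        out["ns"] = np.atleast_2d(ns_baseline_scores(A_tr, queries))
    if "lp" in methods:
        out["lp"] = np.atleast_2d(lp_baseline_scores(A_tr, S_tr, queries, beta))
    return out


def holdout_cv_many(
    A: InteractionMatrix,
    S: SimilarityMatrix,
    plan: HoldoutPlan,
    methods,
    config: ClassifierConfig = ClassifierConfig(),
    lp_beta: float = 0.5,
    per_drug_mean: bool = False,
) -> dict[str, EvaluationReport]:
    """Run one hold-out plan for several methods on shared splits/models.

    Per repetition the withheld (test drug x training drug) pairs are
    pooled into a single AUPR; ``per_drug_mean`` switches to averaging
    one AUPR per test drug instead (drugs with single-class truth rows
    are then skipped within the repetition).
    """
    if A.drugs.ids != S.drugs.ids:
        raise ValueError("interaction and similarity catalogs differ")
    methods = list(methods)
    for mth in methods:
        if mth not in ALL_METHODS + BASELINE_METHODS:
            raise ValueError(f"unknown method {mth!r}")
    m = len(A.drugs)
    per_rep: dict[str, list[float]] = {mth: [] for mth in methods}
    skipped: list[int] = []
    for seed in plan.seeds:
        train, test = _split(m, plan.ratio, seed)
        truth = A.values[np.ix_(test, train)].ravel()
        if truth.min() == truth.max() or len(train) < 2:
            logger.warning("repetition seed=%d skipped: degenerate split", seed)
            skipped.append(seed)
            continue
        A_tr = InteractionMatrix(
            _subcatalog(A.drugs, train), A.values[np.ix_(train, train)])
        S_tr = SimilarityMatrix(
            _subcatalog(S.drugs, train), S.values[np.ix_(train, train)])
        queries = S.values[np.ix_(test, train)]
        preds = _predict_methods(A_tr, S_tr, queries, methods, config, lp_beta)
        for mth in methods:
            if per_drug_mean:
                vals = [
                    aupr(preds[mth][i], A.values[np.ix_(test, train)][i])
                    for i in range(len(test))
                    if len(np.unique(A.values[np.ix_(test, train)][i])) == 2
                ]
                per_rep[mth].append(float(np.mean(vals)))
            else:
                per_rep[mth].append(aupr(preds[mth].ravel(), truth))
    if not any(per_rep.values()):
        raise ValueError("every repetition was degenerate; no AUPR computed")
    return {
        mth: EvaluationReport(mth, plan, tuple(per_rep[mth]), tuple(skipped))
        for mth in methods
    }


def holdout_cv(
    A: InteractionMatrix,
    S: SimilarityMatrix,
    plan: HoldoutPlan,
    method: str,
    config: ClassifierConfig = ClassifierConfig(),
    **kwargs,
) -> EvaluationReport:
    """Hold-out cross-validation of a single method (see holdout_cv_many)."""
    return holdout_cv_many(A, S, plan, [method], config, **kwargs)[method]


def ablation_run(
    A: InteractionMatrix,
    S: SimilarityMatrix,
    plan: HoldoutPlan,
    variant: str = "regular",
    config: ClassifierConfig = ClassifierConfig(),
) -> EvaluationReport:
    """Hold-out CV of the DS rule with one fusion factor neutralized."""
    if variant not in ("regular", "no_posterior", "no_proximity", "no_weight"):
        raise ValueError(f"unknown ablation variant {variant!r}")
    method = "ds" if variant == "regular" else f"ds:{variant}"
    rep = holdout_cv(A, S, plan, method, config)
    return EvaluationReport(f"ds[{variant}]", plan, rep.auprs, rep.skipped)


# ---------------------------------------------------------------------------
# LOOCV degree-bias analysis


@dataclass(frozen=True)
class RankingSummary:
    """Leave-one-out ranking diagnostics for one method.

    Per left-out drug: the ranks of its true interaction partners among
    all training drugs, their mean, and the Spearman correlation between
    the predicted scores and the training drugs' degrees.  ``spearman_mean``
    averages the per-round correlations (signed); ``spearman_abs_mean``
    averages their absolute values, which is insensitive to whether ranks
    or scores were correlated with degree.
    """

    method: str
    drug_ids: tuple[str, ...]
    average_ranks: tuple[float, ...]
    spearman_by_round: tuple[float, ...] = field(repr=False)

    @property
    def spearman_mean(self) -> float:
        vals = [v for v in self.spearman_by_round if np.isfinite(v)]
        return float(np.mean(vals))

    @property
    def spearman_abs_mean(self) -> float:
        vals = [abs(v) for v in self.spearman_by_round if np.isfinite(v)]
        return float(np.mean(vals))

    def write(self, path) -> None:
        pd.DataFrame({
            "drug": self.drug_ids,
            "average_rank": self.average_ranks,
            "spearman_score_vs_degree": self.spearman_by_round,
        }).to_csv(path, sep="\t", index=False, float_format="%.17g")


def loocv_degree_bias(
    A: InteractionMatrix,
    S: SimilarityMatrix,
    method: str,
    config: ClassifierConfig = ClassifierConfig(),
    lp_beta: float = 0.5,
) -> RankingSummary:
    """Leave-one-out probe of degree-induced ranking bias.

    Each drug in turn is withheld with its interactions; the method
    scores it against all remaining drugs and the score vector is
    correlated (Spearman) with the training drugs' degrees.  Rounds with
    a constant score vector have undefined correlation and are excluded
    from the averages with a warning.
    """
    m = len(A.drugs)
    if np.any(A.degrees() < 1):
        raise ValueError("every drug needs degree >= 1 for LOOCV")
    corrs, avg_ranks = [], []
    for x in range(m):
        train = np.delete(np.arange(m), x)
        A_tr = InteractionMatrix(
            _subcatalog(A.drugs, train), A.values[np.ix_(train, train)])
        S_tr = SimilarityMatrix(
            _subcatalog(S.drugs, train), S.values[np.ix_(train, train)])
        query = S.values[x, train][None, :]
        preds = _predict_methods(A_tr, S_tr, query, [method], config, lp_beta)
        scores = np.ravel(preds[method])
        degrees = A_tr.degrees()
        truth = A.values[x, train]
        if truth.sum() >= 1:
            avg_ranks.append(average_rank_of_positives(scores, truth))
        else:
            avg_ranks.append(float("nan"))
        if np.ptp(scores) == 0 or np.ptp(degrees) == 0:
            logger.warning("round %s: constant vector, correlation undefined",
                           A.drugs.ids[x])
            corrs.append(float("nan"))
        else:
            corrs.append(float(spearmanr(scores, degrees).statistic))
    return RankingSummary(method, A.drugs.ids, tuple(avg_ranks), tuple(corrs))


def _subcatalog(catalog, idx):
    from .io import DrugCatalog

    return DrugCatalog(tuple(catalog.ids[i] for i in idx))


def _vals(obj):
    return obj.values if hasattr(obj, "values") and not isinstance(obj, np.ndarray) else obj
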