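"""Per-drug local classification tasks and their orchestration.

For every known drug ``d_j`` the engine derives a binary labeling of the
other training drugs (interacts with ``d_j`` or not), trains the requested
member classifier(s) on the training similarity matrix, and scores each
query drug against ``d_j``.  The result is a score matrix: rows are query
drugs, columns are known drugs, entries are calibrated probabilities of
interaction.

The per-target tasks see only training-drug similarities and labels; the
number of instances handled is the number of drugs, never the number of
drug pairs.  A target whose labels are single-class (no positive or no
negative training drug) cannot train a discriminative model and falls
back to the smoothed empirical prior ``(1 + c) / (M + 2)`` for every
query.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fusion as _fusion
from .classifiers import MLKNNModel, RLSModel, SVMModel
from .io import DrugCatalog, InteractionMatrix, QuerySimilarityVector, SimilarityMatrix

__all__ = [
    "ClassifierConfig",
    "ScoreMatrix",
    "MEMBER_METHODS",
    "FUSION_METHODS",
    "ALL_METHODS",
    "lcm_predict_scores",
    "lcm_predict_all",
    "write_score_matrix",
]

logger = logging.getLogger(__name__)

MEMBER_METHODS = ("mlknn", "rls", "svm")
FUSION_METHODS = ("ds", "average", "product", "maximum", "minimum", "dt",
                  "ds:no_posterior", "ds:no_proximity", "ds:no_weight")
ALL_METHODS = MEMBER_METHODS + FUSION_METHODS


@dataclass(frozen=True)
class ClassifierConfig:
    """Member-classifier hyperparameters (defaults follow the study setup)."""

    K: int = 5          # MLKNN neighbor count
    alpha: float = 0.5  # RLS regularization
    C: float = 1.0      # SVM box constraint


@dataclass(frozen=True)
class ScoreMatrix:
    """Predicted interaction scores: query drugs x known (training) drugs."""

    query_ids: tuple[str, ...]
    train_ids: tuple[str, ...]
    values: np.ndarray
    method: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.query_ids), len(self.train_ids)):
            raise ValueError(
                f"score matrix shape {v.shape} does not match "
                f"{len(self.query_ids)} queries x {len(self.train_ids)} drugs"
            )


def write_score_matrix(sm: ScoreMatrix, path) -> None:
    pd.DataFrame(sm.values, index=sm.query_ids, columns=sm.train_ids).to_csv(
        path, sep="\t", float_format="%.17g"
    )


def _query_array(queries, catalog: DrugCatalog) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(queries, np.ndarray):
        q = np.atleast_2d(np.asarray(queries, dtype=float))
        ids = tuple(f"query_{i}" for i in range(q.shape[0]))
        return q, ids
    rows, ids = [], []
    for i, qv in enumerate(queries):
        if isinstance(qv, QuerySimilarityVector):
            if qv.drugs.ids != catalog.ids:
                raise ValueError("query vector catalog differs from training catalog")
            rows.append(qv.values)
        else:
            rows.append(np.asarray(qv, dtype=float))
        ids.append(f"query_{i}")
    return np.vstack(rows), tuple(ids)


def lcm_predict_scores(
    A_train: InteractionMatrix,
    S_train: SimilarityMatrix,
    queries,
    method: str = "svm",
    config: ClassifierConfig = ClassifierConfig(),
) -> ScoreMatrix:
    """Score every query drug against every known drug with one method.

    ``method`` is a member classifier name, a fusion rule, or a DS
    ablation variant spelled ``ds:<variant>`` (see ``ALL_METHODS``).
    """
    return lcm_predict_all(A_train, S_train, queries, [method], config)[method]


def lcm_predict_all(
    A_train: InteractionMatrix,
    S_train: SimilarityMatrix,
    queries,
    methods,
    config: ClassifierConfig = ClassifierConfig(),
) -> dict[str, ScoreMatrix]:
    """Score queries under several methods sharing one training pass.

    All requested methods reuse the same fitted member classifiers per
    local task, so e.g. the DS rule and its ablation variants are
    evaluated on identical decision profiles.
    """
    if A_train.drugs.ids != S_train.drugs.ids:
        raise ValueError("interaction and similarity matrices have different catalogs")
    methods = list(methods)
    for mth in methods:
        if mth not in ALL_METHODS:
            raise ValueError(f"unknown method {mth!r}; choose from {ALL_METHODS}")

    Q, query_ids = _query_array(queries, A_train.drugs)
    m = len(A_train.drugs)
    if Q.shape[1] != m:
        raise ValueError("query vectors must be indexed by the training catalog")

    need_fusion = any(mth in FUSION_METHODS for mth in methods)
    out = {mth: np.empty((Q.shape[0], m)) for mth in methods}

    A = A_train.values
    S = S_train.values
    all_idx = np.arange(m)
    for j in range(m):
        train_idx = np.delete(all_idx, j)
        y = A[train_idx, j].astype(int)
        M = len(train_idx)
        c = int(y.sum())
        if c == 0 or c == M:
            fallback = (1.0 + c) / (M + 2.0)
            logger.info("target %s: single-class labels, prior fallback %.4f",
                        A_train.drugs.ids[j], fallback)
            for mth in methods:
                out[mth][:, j] = fallback
            continue

        S_tt = S[np.ix_(train_idx, train_idx)]
        Qj = Q[:, train_idx]

        K = min(config.K, M - 1)
        mlknn = MLKNNModel.fit(S_tt, y, K)
        rls = RLSModel.fit(S_tt, y, config.alpha)
        svm = SVMModel.fit(S_tt, y, config.C, calibrate=True)

        query_pos = {
            "mlknn": mlknn.score(Qj),
            "rls": np.clip(rls.score(Qj), 0.0, 1.0),
            "svm": svm.score(Qj),
        }
        for mth in methods:
            if mth in MEMBER_METHODS:
                out[mth][:, j] = query_pos[mth]
        if not need_fusion:
            continue

        resub_pos = {
            "mlknn": mlknn.resubstitution_scores(),
            "rls": np.clip(rls.resubstitution_scores(), 0.0, 1.0),
            "svm": svm._apply_calibration(svm.resubstitution_scores_raw()),
        }
        train_profiles = [np.column_stack([resub_pos[n], 1.0 - resub_pos[n]])
                          for n in MEMBER_METHODS]
        refs = _fusion.compute_reference_profiles(train_profiles, y)
        # (n_queries, N, 2) query profiles in member order
        qp = np.stack(
            [np.column_stack([query_pos[n], 1.0 - query_pos[n]])
             for n in MEMBER_METHODS], axis=1)

        for mth in methods:
            if mth in MEMBER_METHODS:
                continue
            if mth == "ds" or mth.startswith("ds:"):
                variant = mth.split(":", 1)[1] if ":" in mth else "regular"
                fused = _fusion._ds_fuse_batch(qp, refs, variant)
                out[mth][:, j] = fused[:, 0]
            elif mth == "dt":
                templates = np.transpose(refs.refs, (1, 0, 2))  # (class, N, 2)
                d2 = ((qp[:, None, :, :] - templates[None, :, :, :]) ** 2).sum(axis=3)
                out[mth][:, j] = 1.0 - d2.mean(axis=2)[:, 0]
            else:  # unsupervised rules on the positive-class posteriors
                e = qp[:, :, 0]
                if mth == "average":
                    out[mth][:, j] = e.mean(axis=1)
                elif mth == "product":
                    out[mth][:, j] = e.prod(axis=1)
                elif mth == "maximum":
                    out[mth][:, j] = e.max(axis=1)
                elif mth == "minimum":
                    out[mth][:, j] = e.min(axis=1)

    return {
        mth: ScoreMatrix(query_ids, A_train.drugs.ids, out[mth], method=mth)
        for mth in methods
    }
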