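"""Member classifiers for the per-drug local classification tasks.

Each classifier is trained on the similarity matrix of the training drugs
(used directly as a kernel / neighborhood structure) with binary labels
"interacts with the target drug" and, for a query drug described by its
similarity vector to the training drugs, emits a normalized 2-dimensional
decision profile ``[p+, p-]`` with ``p+ + p- = 1``.

Three members are provided:

* MLKNN -- a Bayesian posterior over the number of positively labeled
  drugs among the K most similar training drugs, with Laplace-smoothed
  prior ``(1 + c) / (M + 2)`` and smoothed neighbor-count tables;
* RLS -- regularized least squares on the similarity kernel,
  ``f(x) = s_x (S + alpha I)^{-1} y``, with the raw score clipped to
  [0, 1] (the regression targets are 0/1);
* SVM -- a C-SVC on the precomputed similarity kernel, with a
  Platt-style sigmoid mapping the decision value to a probability.

Distances for MLKNN are ``1 - similarity``; neighbor ties at the K-th
position break by ascending drug index, so results are seed-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, NamedTuple

import numpy as np
from scipy.optimize import minimize
from sklearn.svm import SVC

__all__ = [
    "DecisionProfile",
    "CalibrationSpec",
    "MLKNNModel",
    "RLSModel",
    "SVMModel",
    "mlknn_fit_score",
    "rls_fit_score",
    "svm_fit_score",
    "calibrate_to_profile",
    "stabilized_solve",
]


class DecisionProfile(NamedTuple):
    """Normalized per-class posterior ``[p+, p-]`` of one classifier."""

    p_pos: float
    p_neg: float


def _as_profile(p_pos: float) -> DecisionProfile:
    p = float(np.clip(p_pos, 0.0, 1.0))
    return DecisionProfile(p, 1.0 - p)


# ---------------------------------------------------------------------------
# score -> probability calibration


@dataclass(frozen=True)
class CalibrationSpec:
    """How a raw classifier score maps to a decision profile.

    ``identity`` requires scores already in [0, 1]; ``clip`` clamps the
    score to [0, 1]; ``platt`` applies a fitted sigmoid
    ``1 / (1 + exp(a*s + b))``.
    """

    method: Literal["identity", "clip", "platt"] = "clip"
    a: float = -1.0
    b: float = 0.0


def fit_platt(scores: np.ndarray, labels: np.ndarray) -> CalibrationSpec:
    """Fit Platt's sigmoid on training scores with prior-smoothed targets."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    t = np.where(labels == 1, t_pos, t_neg)

    def nll(ab):
        a, b = ab
        z = a * scores + b
        # p = sigma(-z); -log p = log(1+e^z), -log(1-p) = log(1+e^-z)
        return float(np.sum(t * np.logaddexp(0.0, z)
                            + (1.0 - t) * np.logaddexp(0.0, -z)))

    res = minimize(nll, x0=np.array([-1.0, 0.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    a, b = res.x
    if a > 0:  # keep the map monotone increasing in the score
        a, b = -abs(a), b
    return CalibrationSpec("platt", a=float(a), b=float(b))


def calibrate_to_profile(score: float, spec: CalibrationSpec) -> DecisionProfile:
    """Map a raw score to a valid decision profile per the calibration spec."""
    if spec.method == "identity":
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"identity calibration needs score in [0,1], got {score}")
        return _as_profile(score)
    if spec.method == "clip":
        return _as_profile(min(1.0, max(0.0, score)))
    if spec.method == "platt":
        return _as_profile(_platt_apply(np.asarray(score, dtype=float), spec).item())
    raise ValueError(f"unknown calibration method {spec.method!r}")


def _platt_apply(scores: np.ndarray, spec: CalibrationSpec) -> np.ndarray:
    z = spec.a * scores + spec.b
    return 1.0 / (1.0 + np.exp(z))


# ---------------------------------------------------------------------------
# numerical helper


def stabilized_solve(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``mat x = rhs``, adding the smallest ridge needed if singular.

    Similarity matrices need not be positive semidefinite, so a general
    LU solve is used; only a genuinely singular system gets a ridge
    ``delta*I`` doubling from 1e-8 until it becomes solvable.
    """
    delta = 0.0
    for _ in range(40):
        try:
            x = np.linalg.solve(mat + delta * np.eye(len(mat)), rhs)
            if np.all(np.isfinite(x)):
                return x
        except np.linalg.LinAlgError:
            pass
        delta = 1e-8 if delta == 0.0 else delta * 2.0
    cond = np.linalg.cond(mat)
    raise np.linalg.LinAlgError(
        f"linear system remained singular after ridge fix-ups (cond~{cond:.3g})"
    )


# ---------------------------------------------------------------------------
# MLKNN


@dataclass
class MLKNNModel:
    """Similarity-based MLKNN posterior for one local task.

    ``prior_pos = (1 + c) / (M + 2)`` where ``c`` counts positive training
    drugs; ``cond_pos[k]`` / ``cond_neg[k]`` estimate the probability of
    observing ``k`` positively labeled drugs among the K nearest neighbors
    given the instance's own class, with add-one smoothing over the K+1
    possible counts.
    """

    K: int
    prior_pos: float
    prior_neg: float
    cond_pos: np.ndarray
    cond_neg: np.ndarray
    c: int
    S_train: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)

    @classmethod
    def fit(cls, S_train: np.ndarray, labels: np.ndarray, K: int = 5) -> "MLKNNModel":
        S = np.asarray(S_train, dtype=float)
        y = np.asarray(labels).astype(int)
        M = len(y)
        if not 1 <= K < M:
            raise ValueError(f"need 1 <= K < M, got K={K}, M={M}")
        c = int(y.sum())
        prior_pos = (1.0 + c) / (M + 2.0)

        # neighbor counts for each training drug, excluding itself
        counts = np.empty(M, dtype=int)
        for i in range(M):
            counts[i] = y[_top_k_neighbors(S[i], K, exclude=i)].sum()

        cond_pos = np.ones(K + 1)
        cond_neg = np.ones(K + 1)
        for i in range(M):
            (cond_pos if y[i] == 1 else cond_neg)[counts[i]] += 1.0
        cond_pos /= (K + 1.0) + c
        cond_neg /= (K + 1.0) + (M - c)
        return cls(K, prior_pos, 1.0 - prior_pos, cond_pos, cond_neg, c, S, y)

    def posterior(self, n_pos_neighbors: np.ndarray) -> np.ndarray:
        """Bayes posterior of a positive label given the neighbor count."""
        k = np.asarray(n_pos_neighbors, dtype=int)
        num = self.prior_pos * self.cond_pos[k]
        den = num + self.prior_neg * self.cond_neg[k]
        return num / den

    def score(self, s_x: np.ndarray) -> np.ndarray:
        """p+ for query rows ``s_x`` of shape (n, M) or (M,)."""
        s = np.atleast_2d(np.asarray(s_x, dtype=float))
        counts = np.array(
            [self.labels[_top_k_neighbors(row, self.K)].sum() for row in s]
        )
        return self.posterior(counts)

    def resubstitution_scores(self) -> np.ndarray:
        """p+ of each training drug under leave-self-out neighbor search."""
        counts = np.array(
            [
                self.labels[_top_k_neighbors(self.S_train[i], self.K, exclude=i)].sum()
                for i in range(len(self.labels))
            ]
        )
        return self.posterior(counts)


def _top_k_neighbors(sim_row: np.ndarray, K: int, exclude: int | None = None) -> np.ndarray:
    """Indices of the K most similar drugs; ties break by ascending index."""
    row = np.asarray(sim_row, dtype=float)
    if exclude is not None:
        row = row.copy()
        row[exclude] = -np.inf
    order = np.lexsort((np.arange(len(row)), -row))
    return order[:K]


def mlknn_fit_score(S_train, labels, K, s_x) -> DecisionProfile:
    """Fit MLKNN on one local task and score a single query drug."""
    model = MLKNNModel.fit(_values(S_train), _values(labels), K)
    return _as_profile(model.score(_values(s_x))[0])


# ---------------------------------------------------------------------------
# RLS


@dataclass
class RLSModel:
    """Regularized least squares on the similarity kernel."""

    alpha: float
    dual_weights: np.ndarray
    S_train: np.ndarray = field(repr=False)

    @classmethod
    def fit(cls, S_train: np.ndarray, labels: np.ndarray, alpha: float = 0.5) -> "RLSModel":
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        S = np.asarray(S_train, dtype=float)
        y = np.asarray(labels, dtype=float)
        w = stabilized_solve(S + alpha * np.eye(len(S)), y)
        if not np.all(np.isfinite(w)):
            raise np.linalg.LinAlgError("non-finite RLS dual weights")
        return cls(float(alpha), w, S)

    def score(self, s_x: np.ndarray) -> np.ndarray:
        """Raw regression score ``s_x . w`` for query rows (n, M) or (M,)."""
        s = np.atleast_2d(np.asarray(s_x, dtype=float))
        return s @ self.dual_weights

    def resubstitution_scores(self) -> np.ndarray:
        return self.S_train @ self.dual_weights


def rls_fit_score(S_train, labels, alpha, s_x) -> float:
    """Fit RLS and return the raw (uncalibrated) score of one query."""
    model = RLSModel.fit(_values(S_train), _values(labels), alpha)
    return float(model.score(_values(s_x))[0])


# ---------------------------------------------------------------------------
# SVM


@dataclass
class SVMModel:
    """C-SVC on the precomputed similarity kernel with Platt calibration."""

    C: float
    dual_alphas: np.ndarray
    signed_labels: np.ndarray
    support: np.ndarray
    bias: float
    calibration: CalibrationSpec
    S_train: np.ndarray = field(repr=False)
    _svc: SVC = field(repr=False)

    @classmethod
    def fit(cls, S_train: np.ndarray, labels: np.ndarray, C: float = 1.0,
            calibrate: bool = True) -> "SVMModel":
        S = np.asarray(S_train, dtype=float)
        y = np.asarray(labels).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("SVM training requires both classes present")
        svc = SVC(C=C, kernel="precomputed", tol=1e-7)
        svc.fit(S, y)
        signed = np.where(y == 1, 1, -1)
        alphas = np.zeros(len(y))
        alphas[svc.support_] = np.abs(svc.dual_coef_[0])
        cal = CalibrationSpec("clip")
        model = cls(float(C), alphas, signed, svc.support_.copy(),
                    float(svc.intercept_[0]), cal, S, svc)
        if calibrate:
            model.calibration = fit_platt(model.resubstitution_scores_raw(), y)
        return model

    def score_raw(self, s_x: np.ndarray) -> np.ndarray:
        """Signed decision value for query kernel rows (n, M) or (M,)."""
        s = np.atleast_2d(np.asarray(s_x, dtype=float))
        return self._svc.decision_function(s)

    def score(self, s_x: np.ndarray) -> np.ndarray:
        """Calibrated p+ for query kernel rows."""
        return self._apply_calibration(self.score_raw(s_x))

    def resubstitution_scores_raw(self) -> np.ndarray:
        return self._svc.decision_function(self.S_train)

    def _apply_calibration(self, raw: np.ndarray) -> np.ndarray:
        spec = self.calibration
        if spec.method == "platt":
            return _platt_apply(raw, spec)
        return np.clip(raw, 0.0, 1.0)


def svm_fit_score(S_train, labels, C, s_x) -> float:
    """Fit the kernel SVM and return the raw decision value of one query."""
    model = SVMModel.fit(_values(S_train), _values(labels), C, calibrate=False)
    return float(model.score_raw(_values(s_x))[0])


def _values(obj):
    """Accept plain arrays or the io-module container types."""
    for attr in ("values", "bits"):
        if hasattr(obj, attr) and not isinstance(obj, np.ndarray):
            return getattr(obj, attr)
    return np.asarray(obj)
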