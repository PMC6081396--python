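"""Combining member-classifier decision profiles into one evidence per class.

Three families of fusion rules operate on the N per-classifier decision
profiles of a query drug:

* the four classical unsupervised rules (average, product, maximum,
  minimum of the per-class posteriors);
* the decision-template rule, ``e_k = 1 - (1/N) sum_n ||y_n - DT_k||^2``
  with ``DT_k`` the class-wise mean training profile;
* the supervised Dempster-Shafer (DS) rule, which converts each
  classifier's output into a basic belief assignment (BBA) over the frame
  ``Theta = {+, -}`` and combines them with Dempster's conflict-normalized
  rule.

For the DS rule, a classifier's likelihood for class k blends its
posterior with the L2 proximity of its profile to the class-k reference
profile (the mean profile of class-k training instances)::

    s_k = y(k) exp(-||R_k - y||) / sum_i y(i) exp(-||R_i - y||)

Treating s_k as a simple support function with focus {k} and the joint
opposing support with focus {not k} and combining the two BBAs gives the
closed-form per-classifier evidence

    e_k = s_k (1 - s_j) / (1 - s_k (1 - (1 - s_j)))      (binary case)

which across classifiers is multiplied with reference-quality weights
``w_k(n)`` and normalized over classes.

Everything here is implemented for the binary frame; ``dempster_combine``
is generic machinery usable as an independent check on the closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .classifiers import DecisionProfile

__all__ = [
    "BBA",
    "ReferenceProfileSet",
    "LikelihoodVector",
    "FusedEvidence",
    "TotalConflictError",
    "EPS_LIKELIHOOD",
    "EPS_WEIGHT",
    "dempster_combine",
    "compute_reference_profiles",
    "ds_likelihoods",
    "ds_single_classifier_evidence",
    "ds_classifier_weights",
    "ds_combine_evidences",
    "ds_fuse",
    "fuse_unsupervised",
    "decision_template_fuse",
]

EPS_LIKELIHOOD = 1e-9   # clamp for likelihoods: keeps Dempster's Z > 0
EPS_WEIGHT = 1e-6       # floor for classifier weights: no hard veto

Variant = Literal["regular", "no_posterior", "no_proximity", "no_weight"]


class TotalConflictError(ValueError):
    """Dempster combination undefined: the two BBAs fully contradict."""


@dataclass(frozen=True)
class BBA:
    """Belief masses over the subsets of the binary frame {+, -}.

    ``m_empty`` is identically 0; the remaining masses sum to 1.
    """

    m_pos: float
    m_neg: float
    m_theta: float
    m_empty: float = 0.0

    def __post_init__(self) -> None:
        masses = (self.m_empty, self.m_pos, self.m_neg, self.m_theta)
        if self.m_empty != 0.0:
            raise ValueError("m(empty) must be 0")
        if any(m < -1e-12 or m > 1 + 1e-12 for m in masses):
            raise ValueError(f"masses out of [0,1]: {masses}")
        if abs(sum(masses) - 1.0) > 1e-12:
            raise ValueError(f"masses must sum to 1, got {sum(masses)}")


def dempster_combine(m1: BBA, m2: BBA) -> BBA:
    """Dempster's conflict-normalized combination of two BBAs.

    ``m(A) = Z^-1 sum_{B cap C = A} m1(B) m2(C)`` with
    ``Z = sum_{B cap C != empty} m1(B) m2(C)``; raises
    :class:`TotalConflictError` when Z = 0.
    """
    conflict = m1.m_pos * m2.m_neg + m1.m_neg * m2.m_pos
    z = 1.0 - conflict
    if z <= 0.0:
        raise TotalConflictError("total conflict between BBAs (Z = 0)")
    pos = m1.m_pos * (m2.m_pos + m2.m_theta) + m1.m_theta * m2.m_pos
    neg = m1.m_neg * (m2.m_neg + m2.m_theta) + m1.m_theta * m2.m_neg
    theta = m1.m_theta * m2.m_theta
    return BBA(pos / z, neg / z, theta / z)


# ---------------------------------------------------------------------------
# reference profiles


@dataclass(frozen=True)
class ReferenceProfileSet:
    """Per-classifier, per-class mean decision profiles.

    ``refs[n, k]`` is the mean profile (length 2: [p+, p-]) of the
    class-k training instances under classifier n, with k = 0 the
    positive class and k = 1 the negative class.
    """

    refs: np.ndarray           # shape (N, 2, 2): classifier, class, component
    counts: np.ndarray         # shape (N, 2)

    def __post_init__(self) -> None:
        r = np.asarray(self.refs, dtype=float)
        if r.ndim != 3 or r.shape[1:] != (2, 2):
            raise ValueError(f"reference array must be (N,2,2), got {r.shape}")
        if np.any(r < -1e-9) or np.any(r > 1 + 1e-9):
            raise ValueError("reference profile components out of [0,1]")
        if not np.allclose(r.sum(axis=2), 1.0, atol=1e-6):
            raise ValueError("reference profiles must sum to 1 per class")
        if np.any(np.asarray(self.counts) < 1):
            raise ValueError("each class needs >= 1 contributing instance")

    @property
    def n_classifiers(self) -> int:
        return self.refs.shape[0]


class ReferenceUndefinedError(ValueError):
    """A class has no training instance, so its mean profile is undefined."""


def compute_reference_profiles(
    training_profiles: Sequence[np.ndarray], labels: np.ndarray
) -> ReferenceProfileSet:
    """Class-wise mean training profiles per classifier (resubstitution).

    ``training_profiles[n]`` holds classifier n's profiles for the M
    training instances, shape (M, 2); ``labels`` are their 0/1 classes.
    """
    y = np.asarray(labels).astype(int)
    pos = y == 1
    neg = ~pos
    if not pos.any() or not neg.any():
        raise ReferenceUndefinedError("both classes need >= 1 training instance")
    refs = np.empty((len(training_profiles), 2, 2))
    counts = np.empty((len(training_profiles), 2), dtype=int)
    for n, profs in enumerate(training_profiles):
        p = np.asarray(profs, dtype=float)
        refs[n, 0] = p[pos].mean(axis=0)
        refs[n, 1] = p[neg].mean(axis=0)
        counts[n] = (pos.sum(), neg.sum())
    return ReferenceProfileSet(refs, counts)


# ---------------------------------------------------------------------------
# DS rule, step by step


@dataclass(frozen=True)
class LikelihoodVector:
    """Self-normalized class likelihoods (s+, s-) of one profile."""

    s_pos: float
    s_neg: float


def _profile_array(profile) -> np.ndarray:
    if isinstance(profile, DecisionProfile):
        return np.array(profile, dtype=float)
    return np.asarray(profile, dtype=float)


def ds_likelihoods(
    profile, refs: ReferenceProfileSet, classifier: int,
    variant: Variant = "regular",
) -> LikelihoodVector:
    """Likelihood measure blending posterior and reference proximity.

    The ablation variants substitute the neutral element of one factor:
    ``no_posterior`` replaces y(k) with 1/2, ``no_proximity`` replaces
    the exp(-distance) factor with 1.
    """
    y = _profile_array(profile)
    s = _ds_likelihoods_batch(y[None, :], refs.refs[classifier], variant)[0]
    return LikelihoodVector(float(s[0]), float(s[1]))


def _ds_likelihoods_batch(
    y: np.ndarray, refs_n: np.ndarray, variant: Variant
) -> np.ndarray:
    """Vectorized posterior-times-proximity likelihoods; y is (n, 2),
    refs_n is (2, 2)."""
    if variant == "no_posterior":
        post = np.full_like(y, 0.5)
    else:
        post = y
    if variant == "no_proximity":
        prox = np.ones_like(y)
    else:
        d = np.linalg.norm(y[:, None, :] - refs_n[None, :, :], axis=2)
        prox = np.exp(-d)
    raw = post * prox
    total = raw.sum(axis=1, keepdims=True)
    # both posteriors 0 cannot happen for valid profiles; guard anyway
    s = np.where(total > 0, raw / np.maximum(total, 1e-300), 0.5)
    return np.clip(s, EPS_LIKELIHOOD, 1.0 - EPS_LIKELIHOOD)


def ds_single_classifier_evidence(s: LikelihoodVector, k: int = 0) -> float:
    """Evidence for class k from one classifier's likelihoods.

    Closed form of combining the two simple support functions (focus {k}
    with degree s_k, focus {not k} with degree s_j) under Dempster's rule:
    ``e_k = s_k (1 - s_j) / (1 - s_k s_j)``.
    """
    sk, sj = (s.s_pos, s.s_neg) if k == 0 else (s.s_neg, s.s_pos)
    sk = float(np.clip(sk, EPS_LIKELIHOOD, 1 - EPS_LIKELIHOOD))
    sj = float(np.clip(sj, EPS_LIKELIHOOD, 1 - EPS_LIKELIHOOD))
    return sk * (1.0 - sj) / (1.0 - sk * sj)


def _evidence_batch(s: np.ndarray) -> np.ndarray:
    """Per-class evidences from likelihood rows (n, 2) -> (n, 2)."""
    sk = s
    sj = s[:, ::-1]
    return sk * (1.0 - sj) / (1.0 - sk * sj)


def ds_classifier_weights(refs: ReferenceProfileSet,
                          variant: Variant = "regular") -> np.ndarray:
    """Reference-quality weight of each classifier for each class.

    ``w_k(n) = |r_k(k) - sum_{j!=k} r_j(k)| * |r_k(k) - sum_{j!=k} r_k(j)|``
    -- a between-class specificity times a within-class specificity of the
    reference profiles.  Floored at a small epsilon so no classifier is
    hard-vetoed; the ``no_weight`` variant returns all ones.
    """
    n = refs.n_classifiers
    if variant == "no_weight":
        return np.ones((n, 2))
    r = refs.refs
    w = np.empty((n, 2))
    for k in range(2):
        j = 1 - k
        between = np.abs(r[:, k, k] - r[:, j, k])
        within = np.abs(r[:, k, k] - r[:, k, j])
        w[:, k] = between * within
    return np.maximum(w, EPS_WEIGHT)


@dataclass(frozen=True)
class FusedEvidence:
    """Class-normalized fused evidence (e+, e-)."""

    e_pos: float
    e_neg: float


def ds_combine_evidences(evidences, weights=None) -> FusedEvidence:
    """Weighted product of per-classifier evidences, normalized over classes.

    ``evidences`` and ``weights`` are (N, 2) arrays (classifier x class);
    weights default to 1.  ``e_k = Z prod_n w_k(n) e_k(n)`` with Z chosen
    so the two class evidences sum to 1; if both products vanish the
    uninformative [0.5, 0.5] is returned with a warning.
    """
    e = np.asarray(evidences, dtype=float).reshape(-1, 2)
    w = np.ones_like(e) if weights is None else np.asarray(weights, float).reshape(-1, 2)
    prod = (w * e).prod(axis=0)
    total = prod.sum()
    if total <= 0:
        warnings.warn("both fused evidences vanished; returning [0.5, 0.5]",
                      stacklevel=2)
        return FusedEvidence(0.5, 0.5)
    return FusedEvidence(float(prod[0] / total), float(prod[1] / total))


def ds_fuse(
    profiles: Sequence, refs: ReferenceProfileSet,
    variant: Variant = "regular",
) -> FusedEvidence:
    """The full supervised DS fusion of N classifier profiles.

    ``e_k`` is proportional to ``prod_n w_k(n) e_k(y_n)`` and normalized
    over the two classes.  If both raw products vanish the result is the
    uninformative [0.5, 0.5].
    """
    y = np.stack([_profile_array(p) for p in profiles])
    e = _ds_fuse_batch(y[None, :, :], refs, variant)[0]
    return FusedEvidence(float(e[0]), float(e[1]))


def _ds_fuse_batch(
    profiles: np.ndarray, refs: ReferenceProfileSet, variant: Variant
) -> np.ndarray:
    """Vectorized DS fusion; profiles is (n_queries, N, 2) -> (n_queries, 2)."""
    nq, N, _ = profiles.shape
    w = ds_classifier_weights(refs, variant)          # (N, 2)
    log_prod = np.zeros((nq, 2))
    for n in range(N):
        s = _ds_likelihoods_batch(profiles[:, n, :], refs.refs[n], variant)
        e = np.clip(_evidence_batch(s), 1e-300, None)
        log_prod += np.log(w[n]) + np.log(e)
    # normalize over classes in log space
    mx = log_prod.max(axis=1, keepdims=True)
    p = np.exp(log_prod - mx)
    total = p.sum(axis=1, keepdims=True)
    ok = total > 0
    if not ok.all():
        warnings.warn("both fused evidences vanished; returning [0.5, 0.5]",
                      stacklevel=2)
    return np.where(ok, p / np.maximum(total, 1e-300), 0.5)


# ---------------------------------------------------------------------------
# classical fusion baselines


def fuse_unsupervised(evidences: Sequence[float], rule: str) -> float:
    """Average / product / maximum / minimum of per-classifier evidences."""
    e = np.asarray(list(evidences), dtype=float)
    if e.size < 1:
        raise ValueError("need at least one evidence value")
    if rule == "average":
        return float(e.mean())
    if rule == "product":
        return float(e.prod())
    if rule in ("maximum", "max"):
        return float(e.max())
    if rule in ("minimum", "min"):
        return float(e.min())
    raise ValueError(f"unknown fusion rule {rule!r}")


def decision_template_fuse(profiles: Sequence, templates: np.ndarray) -> np.ndarray:
    """Decision-template evidences for both classes.

    ``e_k = 1 - (1/N) sum_n ||y_n - DT_k||^2`` with squared Euclidean
    distance; values may be negative and are used raw for ranking.
    ``templates`` holds the class-k mean training profiles: either
    per-classifier, shape (2, N, 2), or shared across classifiers,
    shape (2, 2).  The per-classifier form is exactly the reference
    profile set reindexed by class.
    """
    y = np.stack([_profile_array(p) for p in profiles])     # (N, 2)
    t = np.asarray(templates, dtype=float)
    if t.shape[0] < 2:
        raise ValueError("need a template for each class")
    if t.ndim == 2:                                          # shared template
        t = np.broadcast_to(t[:, None, :], (2, y.shape[0], 2))
    d2 = ((y[None, :, :] - t) ** 2).sum(axis=2)              # (2, N)
    return 1.0 - d2.mean(axis=1)
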