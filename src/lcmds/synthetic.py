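"""Synthetic DDI benchmarks with planted similarity-cluster structure.

The generator embodies the premise the local classification model relies
on: similar drugs (drugs in the same similarity cluster) tend to interact
with the same drugs.  Drugs are partitioned into groups; each group has a
random binary prototype profile, and each drug's profile is its group
prototype with independent bit flips.  Interactions are sampled pairwise:
pairs of drugs whose groups form a designated interacting group pair
interact with high probability, all other pairs (including within-group
pairs) with a low background probability.  Jaccard similarity of the
noisy profiles then clusters by group, and group membership predicts
interaction partners -- a learnable planted signal.

Defaults (60 drugs, 4 groups, half of the cross-group pairs designated,
0.8 / 0.05 interaction probabilities) give a pair density near 0.3,
mirroring dense curated DDI networks (the study dataset has 569 drugs
and 52,416 of 161,596 possible pairs, density ~0.32).

``degree_skew`` makes group sizes unequal (size of the r-th group
proportional to ``(r+1)^-degree_skew``), which skews node degrees and is
used to probe degree-induced ranking bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BinaryProfileMatrix,
    DrugCatalog,
    InteractionMatrix,
    SimilarityMatrix,
    jaccard_similarity_matrix,
    write_binary_profiles,
    write_interaction_matrix,
    write_similarity_matrix,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_synthetic_ddi"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-structure DDI generator."""

    m: int = 60
    groups: int = 4
    p: int = 64
    bit_flip_noise: float = 0.1
    cross_group_interaction_prob: float = 0.8
    within_group_interaction_prob: float = 0.05
    degree_skew: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2 * self.groups:
            raise ValueError("need m >= 2 * groups")
        if self.groups < 2:
            raise ValueError("need at least 2 groups")
        if not 0.0 <= self.bit_flip_noise <= 0.5:
            raise ValueError("bit_flip_noise must be in [0, 0.5]")
        for prob in (self.cross_group_interaction_prob,
                     self.within_group_interaction_prob):
            if not 0.0 <= prob <= 1.0:
                raise ValueError("interaction probabilities must be in [0, 1]")
        if self.degree_skew < 0:
            raise ValueError("degree_skew must be >= 0")
        if (self.cross_group_interaction_prob == 0.0
                and self.within_group_interaction_prob == 0.0):
            raise ValueError("infeasible config: no interaction can be generated")

    def expected_density(self) -> float:
        """Expected fraction of interacting pairs under the config."""
        sizes = _group_sizes(self.m, self.groups, self.degree_skew)
        pairs = _interacting_group_pairs(self.groups)
        total = self.m * (self.m - 1) / 2
        hot = sum(sizes[a] * sizes[b] for a, b in pairs)
        return (hot * self.cross_group_interaction_prob
                + (total - hot) * self.within_group_interaction_prob) / total


@dataclass(frozen=True)
class SyntheticDataset:
    """Generated profiles, Jaccard similarity, interactions and groups."""

    config: SyntheticConfig
    profiles: BinaryProfileMatrix
    similarity: SimilarityMatrix
    interactions: InteractionMatrix
    group_of: np.ndarray = field(repr=False)

    def write(self, directory) -> None:
        """Write the three matrix TSVs plus the group assignment."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_binary_profiles(self.profiles, d / "profiles.tsv")
        write_similarity_matrix(self.similarity, d / "similarity.tsv")
        write_interaction_matrix(self.interactions, d / "interactions.tsv")
        pd.DataFrame(
            {"drug": self.profiles.drugs.ids, "group": self.group_of}
        ).to_csv(d / "groups.tsv", sep="\t", index=False)


def _group_sizes(m: int, groups: int, skew: float) -> list[int]:
    """Largest-remainder apportionment of m drugs to rank-weighted groups."""
    w = (np.arange(1, groups + 1, dtype=float)) ** (-skew)
    raw = m * w / w.sum()
    sizes = np.floor(raw).astype(int)
    sizes = np.maximum(sizes, 2)                     # every group stays usable
    rem = m - sizes.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    i = 0
    while rem != 0:
        g = order[i % groups]
        if rem > 0:
            sizes[g] += 1
            rem -= 1
        elif sizes[g] > 2:
            sizes[g] -= 1
            rem += 1
        i += 1
    return sizes.tolist()


def _interacting_group_pairs(groups: int) -> list[tuple[int, int]]:
    """Designate half (rounded up) of the cross-group pairs, deterministically.

    Pairs are taken in ascending group-distance order (the path
    0-1, 1-2, ... first), so every group takes part in the planted signal
    and the structure depends only on the group count, not on the seed.
    """
    all_pairs = sorted(
        ((a, b) for a in range(groups) for b in range(a + 1, groups)),
        key=lambda ab: (ab[1] - ab[0], ab[0]),
    )
    want = (len(all_pairs) + 1) // 2
    return all_pairs[:want]


def generate_synthetic_ddi(config: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; fully deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sizes = _group_sizes(config.m, config.groups, config.degree_skew)
    group_of = np.repeat(np.arange(config.groups), sizes)

    prototypes = rng.integers(0, 2, size=(config.groups, config.p))
    flips = rng.random((config.m, config.p)) < config.bit_flip_noise
    bits = np.where(flips, 1 - prototypes[group_of], prototypes[group_of])

    hot = set(_interacting_group_pairs(config.groups))
    prob = np.where(
        np.array([[(min(a, b), max(a, b)) in hot and a != b
                   for b in group_of] for a in group_of]),
        config.cross_group_interaction_prob,
        config.within_group_interaction_prob,
    )
    upper = np.triu(rng.random((config.m, config.m)) < prob, k=1)
    A = (upper | upper.T).astype(np.int8)

    # every known drug must have at least one DDI: wire isolated drugs to a
    # random member of an interacting group (or any other drug as last resort)
    for i in np.flatnonzero(A.sum(axis=1) == 0):
        partners = [j for j in range(config.m)
                    if j != i and (min(group_of[i], group_of[j]),
                                   max(group_of[i], group_of[j])) in hot]
        if not partners:
            partners = [j for j in range(config.m) if j != i]
        j = int(rng.choice(partners))
        A[i, j] = A[j, i] = 1

    catalog = DrugCatalog.from_ids(f"drug{i:03d}" for i in range(config.m))
    profiles = BinaryProfileMatrix(
        catalog, bits, keys=tuple(f"bit{i:03d}" for i in range(config.p))
    )
    similarity = jaccard_similarity_matrix(profiles)
    interactions = InteractionMatrix(catalog, A)
    return SyntheticDataset(config, profiles, similarity, interactions, group_of)
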