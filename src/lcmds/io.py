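"""Matrix containers and TSV input/output for DDI prediction.

The method consumes three dense matrix types over a shared drug catalog:

* an ``InteractionMatrix`` -- the symmetric binary adjacency of known
  drug-drug interactions (DDIs);
* a ``SimilarityMatrix`` -- pairwise drug similarities in [0, 1], either
  supplied directly or computed as the Jaccard index of binary property
  profiles (fingerprint bits, side-effect keyword occurrences, ...);
* a ``BinaryProfileMatrix`` -- the raw 0/1 property profiles.

All files are plain TSV with one header row and one header column of drug
identifiers, UTF-8, ``.`` decimal separator.  Writers mirror readers
bit-exactly so round trips are lossless.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DrugCatalog",
    "InteractionMatrix",
    "BinaryProfileMatrix",
    "SimilarityMatrix",
    "QuerySimilarityVector",
    "CatalogError",
    "MatrixFormatError",
    "MatrixValidationError",
    "read_interaction_matrix",
    "write_interaction_matrix",
    "read_binary_profiles",
    "write_binary_profiles",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "jaccard_similarity_matrix",
    "average_similarity_matrices",
]


class CatalogError(ValueError):
    """Duplicate or inconsistent drug identifiers."""


class MatrixFormatError(ValueError):
    """A file that cannot be parsed into the expected matrix shape."""


class MatrixValidationError(ValueError):
    """A parsed matrix that violates a structural invariant."""


@dataclass(frozen=True)
class DrugCatalog:
    """Ordered set of unique drug identifiers with a position index."""

    ids: tuple[str, ...]
    index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        idx = {d: i for i, d in enumerate(self.ids)}
        if len(idx) != len(self.ids):
            seen: set[str] = set()
            dup = next(d for d in self.ids if d in seen or seen.add(d))
            raise CatalogError(f"duplicate drug identifier: {dup!r}")
        object.__setattr__(self, "index", idx)

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_ids(cls, ids) -> "DrugCatalog":
        return cls(tuple(str(d) for d in ids))


def _check_square(values: np.ndarray, drugs: DrugCatalog, name: str) -> None:
    m = len(drugs)
    if values.shape != (m, m):
        raise MatrixValidationError(
            f"{name}: shape {values.shape} does not match catalog size {m}"
        )


def _first_asymmetric_pair(values: np.ndarray, tol: float = 0.0):
    diff = np.abs(values - values.T)
    bad = np.argwhere(diff > tol)
    if bad.size:
        i, j = bad[0]
        return int(i), int(j)
    return None


@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric binary adjacency of known DDIs with zero diagonal."""

    drugs: DrugCatalog
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values))
        self.validate()

    def validate(self) -> None:
        _check_square(self.values, self.drugs, "interaction matrix")
        if not np.isin(self.values, (0, 1)).all():
            raise MatrixValidationError("interaction matrix entries must be 0/1")
        pair = _first_asymmetric_pair(self.values)
        if pair is not None:
            i, j = pair
            raise MatrixValidationError(
                "interaction matrix not symmetric: "
                f"a[{self.drugs.ids[i]},{self.drugs.ids[j]}] != "
                f"a[{self.drugs.ids[j]},{self.drugs.ids[i]}]"
            )
        if np.any(np.diag(self.values) != 0):
            raise MatrixValidationError("interaction matrix diagonal must be zero")

    def degrees(self) -> np.ndarray:
        """Number of known interaction partners per drug."""
        return self.values.sum(axis=1).astype(int)

    @property
    def n_interactions(self) -> int:
        """Count of interacting unordered pairs."""
        return int(self.values.sum()) // 2


@dataclass(frozen=True)
class BinaryProfileMatrix:
    """Per-drug binary property profiles (rows = drugs, columns = keys)."""

    drugs: DrugCatalog
    bits: np.ndarray
    keys: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "bits", np.asarray(self.bits))
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.drugs):
            raise MatrixValidationError(
                f"profile matrix shape {self.bits.shape} does not match "
                f"catalog size {len(self.drugs)}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise MatrixValidationError("profile entries must be 0/1")
        empty = np.flatnonzero(self.bits.sum(axis=1) == 0)
        for i in empty:
            warnings.warn(
                f"empty profile: drug {self.drugs.ids[i]!r} has no presence bits",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise drug similarities in [0, 1], unit diagonal."""

    drugs: DrugCatalog
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        self.validate()

    def validate(self) -> None:
        _check_square(self.values, self.drugs, "similarity matrix")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise MatrixValidationError("similarities must lie in [0, 1]")
        pair = _first_asymmetric_pair(self.values, tol=1e-12)
        if pair is not None:
            i, j = pair
            raise MatrixValidationError(
                "similarity matrix not symmetric at "
                f"({self.drugs.ids[i]}, {self.drugs.ids[j]})"
            )
        if not np.allclose(np.diag(self.values), 1.0):
            raise MatrixValidationError("similarity diagonal must be 1")


@dataclass(frozen=True)
class QuerySimilarityVector:
    """Similarities of one query (new) drug to every training drug."""

    drugs: DrugCatalog
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.drugs),):
            raise MatrixValidationError(
                f"query vector length {self.values.shape} does not match "
                f"catalog size {len(self.drugs)}"
            )
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise MatrixValidationError("query similarities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# TSV readers / writers


def _read_square_tsv(path) -> tuple[DrugCatalog, pd.DataFrame]:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MatrixFormatError(f"{path}: {exc}") from exc
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise MatrixValidationError(
            f"{path}: header row and header column drug IDs differ"
        )
    return DrugCatalog.from_ids(rows), df


def _parse_binary_body(df: pd.DataFrame, path) -> np.ndarray:
    out = np.empty(df.shape, dtype=np.int8)
    for r, (_, row) in enumerate(df.iterrows()):
        for c, cell in enumerate(row):
            if cell not in ("0", "1"):
                raise MatrixFormatError(
                    f"{path}: non-binary entry {cell!r} at line {r + 2}"
                )
            out[r, c] = int(cell)
    return out


def read_interaction_matrix(path) -> InteractionMatrix:
    """Read a symmetric 0/1 interaction matrix from drug-ID-headed TSV."""
    drugs, df = _read_square_tsv(path)
    values = _parse_binary_body(df, path)
    return InteractionMatrix(drugs, values)


def write_interaction_matrix(mat: InteractionMatrix, path) -> None:
    df = pd.DataFrame(mat.values.astype(int), index=mat.drugs.ids, columns=mat.drugs.ids)
    df.to_csv(path, sep="\t")


def read_similarity_matrix(path) -> SimilarityMatrix:
    """Read a similarity TSV; the diagonal is forced to 1 on load."""
    drugs, df = _read_square_tsv(path)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric entry ({exc})") from exc
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(drugs, values)


def write_similarity_matrix(mat: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(
        mat.values, index=mat.drugs.ids, columns=mat.drugs.ids
    )
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_binary_profiles(path) -> BinaryProfileMatrix:
    """Read drug x property-key binary profiles from TSV."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc
    if df.isna().any().any():
        raise MatrixFormatError(f"{path}: ragged or missing entries")
    drugs = DrugCatalog.from_ids([str(r) for r in df.index])
    bits = _parse_binary_body(df, path)
    return BinaryProfileMatrix(drugs, bits, keys=tuple(str(c) for c in df.columns))


def write_binary_profiles(mat: BinaryProfileMatrix, path) -> None:
    keys = mat.keys or tuple(f"k{i}" for i in range(mat.bits.shape[1]))
    df = pd.DataFrame(mat.bits.astype(int), index=mat.drugs.ids, columns=keys)
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Similarity computation


def jaccard_similarity_matrix(profiles: BinaryProfileMatrix) -> SimilarityMatrix:
    """Pairwise Jaccard (Tanimoto) similarity of binary profiles.

    ``s_ij = |f_i AND f_j| / |f_i OR f_j|``; a pair of all-zero profiles has
    an empty union and is assigned similarity 0 with a warning.  The
    diagonal is set to 1 regardless.
    """
    bits = profiles.bits.astype(np.int64)
    inter = bits @ bits.T
    sizes = bits.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    if np.any((union == 0) & ~np.eye(len(union), dtype=bool)):
        warnings.warn(
            "all-zero profile pair: Jaccard undefined, similarity set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(profiles.drugs, sim)


def average_similarity_matrices(mats: list[SimilarityMatrix]) -> SimilarityMatrix:
    """Element-wise mean of similarity matrices from multiple data sources."""
    if not mats:
        raise ValueError("need at least one similarity matrix")
    cat = mats[0].drugs
    for m in mats[1:]:
        if m.drugs.ids != cat.ids:
            raise CatalogError("similarity matrices have mismatched drug catalogs")
    mean = np.mean([m.values for m in mats], axis=0)
    return SimilarityMatrix(cat, mean)
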