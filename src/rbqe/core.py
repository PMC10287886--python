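"""Core domain types and Euclidean ranking.

A feature database is an ordered collection of image records, each carrying a
dense real-valued feature vector of a common dimension.  Similarity between
two images is the Euclidean distance between their feature vectors,

    ED(X, Y) = sqrt( sum_i (x_i - y_i)^2 ),

and retrieval is a distance-ascending ranking of database records against a
probe vector.  Record order is significant: it defines the deterministic
tie-break used everywhere downstream (equal distances keep database order).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FeatureVector",
    "ImageRecord",
    "FeatureDatabase",
    "RankedList",
    "euclidean_distance",
    "rank_images",
    "top_k",
]

#: A feature vector is a 1-D float array; helpers accept any real sequence.
FeatureVector = np.ndarray


def as_feature_vector(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Coerce to a 1-D float64 vector, rejecting empty or non-finite input."""
    vec = np.asarray(values, dtype=np.float64)
    if vec.ndim != 1 or vec.size < 1:
        raise ValueError(f"feature vector must be 1-D and non-empty, got shape {vec.shape}")
    if not np.all(np.isfinite(vec)):
        raise ValueError("feature vector contains non-finite components")
    return vec


@dataclasses.dataclass(frozen=True)
class ImageRecord:
    """One database image: unique id, class label, feature vector."""

    id: str
    class_label: str
    features: np.ndarray
    source_path: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.class_label:
            raise ValueError(f"record {self.id!r}: class_label must be non-empty")
        object.__setattr__(self, "features", as_feature_vector(self.features))


class FeatureDatabase:
    """Ordered collection of image records with a consistent feature dimension.

    Internally stores ids/labels as lists and features as one (n, dim) float64
    matrix; record order is stable and defines tie-breaking in all rankings.
    """

    def __init__(self, records: Iterable[ImageRecord]):
        records = list(records)
        if not records:
            raise ValueError("a feature database needs at least one record")
        dims = {r.features.size for r in records}
        if len(dims) != 1:
            raise ValueError(f"inconsistent feature dimensions in database: {sorted(dims)}")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes[:5]}")
        self._records = records
        self.ids: list[str] = ids
        self.labels: list[str] = [r.class_label for r in records]
        self.matrix: np.ndarray = np.vstack([r.features for r in records])
        self._index = {rid: i for i, rid in enumerate(ids)}
        # class order = order of first appearance in the record sequence
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        self.classes: list[str] = list(seen)

    @classmethod
    def from_arrays(
        cls,
        ids: Sequence[str],
        labels: Sequence[str],
        matrix: np.ndarray,
        source_paths: Sequence[str | None] | None = None,
    ) -> "FeatureDatabase":
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise ValueError(f"feature matrix must be 2-D, got shape {matrix.shape}")
        if not (len(ids) == len(labels) == matrix.shape[0]):
            raise ValueError(
                f"row mismatch: {len(ids)} ids, {len(labels)} labels, "
                f"{matrix.shape[0]} matrix rows"
            )
        paths = source_paths if source_paths is not None else [None] * len(ids)
        return cls(
            ImageRecord(i, l, row, p)
            for i, l, row, p in zip(ids, labels, matrix, paths)
        )

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[ImageRecord]:
        return iter(self._records)

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._index

    def __getitem__(self, record_id: str) -> ImageRecord:
        try:
            return self._records[self._index[record_id]]
        except KeyError:
            raise KeyError(f"no record with id {record_id!r}") from None

    def index_of(self, record_id: str) -> int:
        if record_id not in self._index:
            raise KeyError(f"no record with id {record_id!r}")
        return self._index[record_id]

    def class_members(self, class_label: str) -> list[str]:
        """Ids of the given class, in database order."""
        if class_label not in self.classes:
            raise KeyError(f"class {class_label!r} not present in database")
        return [i for i, l in zip(self.ids, self.labels) if l == class_label]

    def class_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {c: 0 for c in self.classes}
        for lab in self.labels:
            sizes[lab] += 1
        return sizes


@dataclasses.dataclass(frozen=True)
class RankedList:
    """Distance-ascending sequence of (image id, distance) pairs."""

    ids: tuple[str, ...]
    distances: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=np.float64)
        if len(self.ids) != d.size:
            raise ValueError("ids and distances length mismatch")
        if d.size and (np.any(d < 0) or np.any(np.diff(d) < 0)):
            raise ValueError("distances must be non-negative and non-decreasing")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("ranked list ids must be unique")
        object.__setattr__(self, "distances", d)

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(zip(self.ids, self.distances.tolist()))

    def entries(self) -> list[tuple[str, float]]:
        return list(self)


def euclidean_distance(x: Sequence[float] | np.ndarray, y: Sequence[float] | np.ndarray) -> float:
    """Euclidean distance between two feature vectors of equal dimension."""
    xv = as_feature_vector(x)
    yv = as_feature_vector(y)
    if xv.size != yv.size:
        raise ValueError(f"dimension mismatch: {xv.size} vs {yv.size}")
    return float(np.linalg.norm(xv - yv))


def rank_images(
    probe: Sequence[float] | np.ndarray,
    db: FeatureDatabase,
    candidate_ids: Iterable[str] | None = None,
) -> RankedList:
    """Rank database records by Euclidean distance to a probe vector.

    Candidates default to the whole database; an explicit candidate set must be
    a subset of database ids.  Equal distances keep database record order
    (stable sort), so the result is deterministic for a fixed database.
    """
    pv = as_feature_vector(probe)
    if pv.size != db.dim:
        raise ValueError(f"dimension mismatch: probe {pv.size} vs database {db.dim}")
    if candidate_ids is None:
        rows = np.arange(len(db))
    else:
        wanted = set(candidate_ids)
        missing = wanted - set(db.ids)
        if missing:
            raise KeyError(f"candidate ids not in database: {sorted(missing)[:5]}")
        rows = np.array([i for i, rid in enumerate(db.ids) if rid in wanted], dtype=int)
    if rows.size == 0:
        raise ValueError("empty candidate set")
    dists = cdist(pv[None, :], db.matrix[rows])[0]
    order = np.argsort(dists, kind="stable")
    return RankedList(
        ids=tuple(db.ids[rows[j]] for j in order),
        distances=dists[order],
    )


def top_k(ranked: RankedList, k: int) -> RankedList:
    """First min(k, len) entries of a ranking, order preserved."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    k = min(k, len(ranked))
    return RankedList(ids=ranked.ids[:k], distances=ranked.distances[:k])
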