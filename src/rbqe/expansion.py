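"""The RbQE two-stage retrieval: rapid search, query expansion, final search.

The method reformulates a query automatically (pseudo-relevance feedback):

1. *Rapid search* — rank the whole database against the original query and,
   for each class, keep its top-k nearest images.
2. *Expansion* — for each class, average the feature vectors of those top-k
   images component-wise.  Each mean is a "new query expansion" (NQE).
3. *Selection* — the NQE closest (Euclidean) to the original query becomes
   the final NQE (FNQE); its class is, in effect, the predicted class of the
   query.
4. *Final search* — rank the database against the FNQE mean vector and return
   the top results.

All stages are deterministic given a database (fixed record order) and query.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Sequence

import numpy as np

from .core import (
    FeatureDatabase,
    RankedList,
    as_feature_vector,
    euclidean_distance,
    rank_images,
    top_k,
)

__all__ = [
    "QueryExpansion",
    "RetrievalResult",
    "per_class_top_k",
    "build_nqe",
    "select_fnqe",
    "rbqe_retrieve",
]

#: Default size of each per-class candidate pool in the rapid search.
DEFAULT_K = 10


@dataclasses.dataclass(frozen=True)
class QueryExpansion:
    """A class label with the component-wise mean of its top-ranked members."""

    class_label: str
    mean_vector: np.ndarray
    member_ids: tuple[str, ...]


@dataclasses.dataclass(frozen=True)
class RetrievalResult:
    """Full output of one RbQE retrieval run."""

    query_id: str
    fnqe: QueryExpansion
    per_class_nqes: tuple[QueryExpansion, ...]
    final_ranking: RankedList
    n_retrieved: int


def per_class_top_k(
    query: Sequence[float] | np.ndarray,
    db: FeatureDatabase,
    k: int = DEFAULT_K,
    exclude_id: str | None = None,
) -> dict[str, list[str]]:
    """Top-k nearest ids of every class, from one global ranking.

    Ranks the database once against the query and splits the ranking by class,
    which is equivalent to k separate per-class searches but cheaper.  Classes
    smaller than k contribute all of their members.  ``exclude_id`` removes one
    record (the query itself) from consideration.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    candidates = None
    if exclude_id is not None:
        if exclude_id not in db:
            raise KeyError(f"exclude_id {exclude_id!r} not in database")
        candidates = [i for i in db.ids if i != exclude_id]
        if not candidates:
            raise ValueError("excluding the query leaves an empty database")
    ranking = rank_images(query, db, candidate_ids=candidates)
    out: dict[str, list[str]] = {c: [] for c in db.classes}
    for rid, _ in ranking:
        members = out[db[rid].class_label]
        if len(members) < k:
            members.append(rid)
    return {c: m for c, m in out.items() if m}


def build_nqe(
    member_ids: Sequence[str],
    db: FeatureDatabase,
    class_label: str,
) -> QueryExpansion:
    """Mean-pool the feature vectors of the given same-class members.

    Component j of the expansion is the arithmetic mean of component j over
    the members, accumulated in double precision.
    """
    if not member_ids:
        raise ValueError(f"cannot build an expansion for class {class_label!r} with no members")
    rows = []
    for rid in member_ids:
        rec = db[rid]
        if rec.class_label != class_label:
            raise ValueError(
                f"member {rid!r} has class {rec.class_label!r}, expected {class_label!r}"
            )
        rows.append(rec.features)
    mean = np.mean(np.vstack(rows).astype(np.float64), axis=0)
    return QueryExpansion(class_label=class_label, mean_vector=mean, member_ids=tuple(member_ids))


def select_fnqe(
    query: Sequence[float] | np.ndarray,
    nqes: Sequence[QueryExpansion],
) -> QueryExpansion:
    """The expansion whose mean vector is nearest the original query.

    Ties go to the earliest expansion in the sequence (database class order).
    """
    if not nqes:
        raise ValueError("no expansions to select from")
    qv = as_feature_vector(query)
    dists = [euclidean_distance(qv, n.mean_vector) for n in nqes]
    return nqes[int(np.argmin(dists))]


def rbqe_retrieve(
    query: str | Sequence[float] | np.ndarray,
    db: FeatureDatabase,
    k: int = DEFAULT_K,
    n_retrieved: int = 10,
    include_query: bool = True,
    restrict_to_fnqe_class: bool = False,
) -> RetrievalResult:
    """Run the full two-stage RbQE pipeline for one query.

    ``query`` is either a database record id or a raw feature vector.  With
    ``include_query=False`` and an in-database query, the query's own record is
    excluded from both the rapid and the final search.  The final search ranks
    the whole database by default; ``restrict_to_fnqe_class`` limits it to the
    FNQE's class.
    """
    if n_retrieved < 1:
        raise ValueError(f"n_retrieved must be >= 1, got {n_retrieved}")
    if isinstance(query, str):
        query_id = query
        qv = db[query].features  # raises KeyError for unknown ids
    else:
        query_id = "external"
        qv = as_feature_vector(query)
    exclude = query_id if (query_id != "external" and not include_query) else None

    pools = per_class_top_k(qv, db, k=k, exclude_id=exclude)
    nqes = tuple(build_nqe(pools[c], db, c) for c in db.classes if c in pools)
    fnqe = select_fnqe(qv, nqes)

    candidates: list[str] | None = None
    if restrict_to_fnqe_class:
        candidates = db.class_members(fnqe.class_label)
    if exclude is not None:
        candidates = [i for i in (candidates or db.ids) if i != exclude]
    final = top_k(rank_images(fnqe.mean_vector, db, candidate_ids=candidates), n_retrieved)
    return RetrievalResult(
        query_id=query_id,
        fnqe=fnqe,
        per_class_nqes=nqes,
        final_ranking=final,
        n_retrieved=n_retrieved,
    )
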