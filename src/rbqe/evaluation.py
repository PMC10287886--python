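"""Retrieval metrics and the whole-database evaluation protocol.

Every database image serves once as a query; a retrieved image is relevant
iff it has the same class label as the query.  Precision at a cutoff N is the
same-class fraction of the N retrieved images; recall divides the same-class
count by the class's total size in the database.  Averaging each over all
|DB| queries gives, on a percent scale,

    ARP(%) = 100/|DB| * sum_i P(I_i)      (average retrieval precision)
    ARR(%) = 100/|DB| * sum_i R(I_i)      (average retrieval rate)
    F(%)   = 2 * ARP * ARR / (ARP + ARR)  (harmonic mean)

Group-wise ARP averages precision over the queries of each class separately.
Reports carry all cutoffs of one run plus per-class and optional per-query
breakdowns.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import pandas as pd

from .core import FeatureDatabase, rank_images, top_k
from .expansion import rbqe_retrieve

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "precision_at",
    "recall_at",
    "f_score",
    "evaluate_database",
]


def precision_at(result_ids: Sequence[str], query_class: str, db: FeatureDatabase) -> float:
    """Fraction of retrieved images sharing the query's class."""
    if not result_ids:
        raise ValueError("cannot compute precision over an empty result list")
    relevant = sum(1 for rid in result_ids if db[rid].class_label == query_class)
    return relevant / len(result_ids)


def recall_at(
    result_ids: Sequence[str],
    query_class: str,
    db: FeatureDatabase,
    count_query_in_class: bool = True,
) -> float:
    """Retrieved same-class count over the class's total database size.

    The denominator is the full class size by default; pass
    ``count_query_in_class=False`` to discount the query's own record when
    it was excluded from the index.
    """
    class_size = db.class_sizes().get(query_class)
    if not class_size:
        raise ValueError(f"class {query_class!r} absent from database")
    if not count_query_in_class:
        class_size -= 1
        if class_size == 0:
            raise ValueError(f"class {query_class!r} has no members besides the query")
    relevant = sum(1 for rid in result_ids if db[rid].class_label == query_class)
    return relevant / class_size


def f_score(arp: float, arr: float) -> float:
    """Harmonic mean of ARP and ARR, on the same percent scale.

    Defined as 0 when both inputs are 0 (the harmonic mean's limit), with a
    logged note since that case signals a degenerate evaluation.
    """
    if arp < 0 or arr < 0:
        raise ValueError(f"ARP/ARR must be non-negative, got {arp}, {arr}")
    if arp == 0 and arr == 0:
        logger.info("f_score(0, 0) requested; returning 0 by convention")
        return 0.0
    return 2.0 * arp * arr / (arp + arr)


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """Metrics of one whole-database evaluation at one cutoff."""

    n_retrieved: int
    arp: float
    arr: float
    f_score: float
    per_class_arp: dict[str, float]
    per_class_arr: dict[str, float]
    per_query: pd.DataFrame | None = None

    def to_row(self) -> dict:
        row = {"n_retrieved": self.n_retrieved, "arp": self.arp, "arr": self.arr,
               "f_score": self.f_score}
        for c, v in self.per_class_arp.items():
            row[f"arp[{c}]"] = v
        return row


def _result_ids(db, query_id, method, k, max_n, include_query):
    if method == "direct":
        candidates = None if include_query else [i for i in db.ids if i != query_id]
        ranking = top_k(rank_images(db[query_id].features, db, candidate_ids=candidates), max_n)
        return ranking.ids
    if method == "rbqe":
        result = rbqe_retrieve(query_id, db, k=k, n_retrieved=max_n,
                               include_query=include_query)
        return result.final_ranking.ids
    raise ValueError(f"unknown method {method!r}; expected 'direct' or 'rbqe'")


def evaluate_database(
    db: FeatureDatabase,
    method: str = "rbqe",
    k: int = 10,
    n_list: Sequence[int] = (10,),
    include_query: bool = True,
    count_query_in_class: bool = True,
    per_query: bool = False,
) -> list[MetricsReport]:
    """Evaluate retrieval with every database image as a query.

    Runs the chosen method (``direct`` nearest-neighbour ranking of the raw
    query, or the two-stage ``rbqe`` expansion) once per query at the largest
    requested cutoff, then scores every cutoff in ``n_list`` from the same
    rankings.  Returns one report per cutoff, in ``n_list`` order.
    """
    if len(db) < 2:
        raise ValueError("evaluation needs a database of at least 2 records")
    n_list = list(n_list)
    if not n_list or any(n < 1 for n in n_list):
        raise ValueError(f"cutoffs must all be >= 1, got {n_list}")
    max_n = max(n_list)

    rows = []
    for query_id in db.ids:
        ids = _result_ids(db, query_id, method, k, max_n, include_query)
        qclass = db[query_id].class_label
        for n in n_list:
            prefix = ids[:n]
            rows.append(
                {
                    "query_id": query_id,
                    "class": qclass,
                    "n_retrieved": n,
                    "precision": precision_at(prefix, qclass, db),
                    "recall": recall_at(prefix, qclass, db,
                                        count_query_in_class=count_query_in_class),
                }
            )
    table = pd.DataFrame(rows)

    reports = []
    for n in n_list:
        sub = table[table.n_retrieved == n]
        arp = 100.0 * sub.precision.mean()
        arr = 100.0 * sub.recall.mean()
        by_class = sub.groupby("class", sort=False)
        reports.append(
            MetricsReport(
                n_retrieved=n,
                arp=arp,
                arr=arr,
                f_score=f_score(arp, arr),
                per_class_arp={c: 100.0 * g.precision.mean() for c, g in by_class},
                per_class_arr={c: 100.0 * g.recall.mean() for c, g in by_class},
                per_query=sub.reset_index(drop=True) if per_query else None,
            )
        )
    return reports
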