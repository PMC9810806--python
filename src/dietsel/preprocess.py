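"""Consumer-read removal, rank aggregation, proportions, rarefaction, Venn.

Gut-content libraries are dominated by the consumer's own sequences;
they are subtracted (by taxonomy match, default genus) before any
proportion-based statistic. Counts are never rarefied/subsampled for the
downstream statistics — proportions are computed directly; rarefaction
appears only as the expected-richness curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import RANKS, OtuTable, RelAbundanceTable, TaxonomyMap

__all__ = [
    "ConsumerRemoval",
    "RarefactionCurve",
    "VennSummary",
    "remove_consumer_reads",
    "aggregate_by_rank",
    "relative_abundance",
    "rarefaction_curve",
    "shared_unique",
]

logger = logging.getLogger(__name__)


class ConsumerRemoval(NamedTuple):
    table: OtuTable
    removed_reads: pd.Series  # per-sample tally of subtracted reads
    empty_samples: frozenset[str]  # samples left with zero reads


def remove_consumer_reads(
    table: OtuTable,
    tax: TaxonomyMap,
    consumer: str = "Polyarthra",
    rank: str = "genus",
) -> ConsumerRemoval:
    """Drop every OTU whose lineage at ``rank`` equals ``consumer``.

    Other counts are untouched. Samples left with zero reads are
    retained but flagged empty (they are excluded from proportion-based
    statistics downstream).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    matched = [o for o in table.otu_ids if tax.name_at(o, rank) == consumer]
    removed = table.data[matched].sum(axis=1) if matched else pd.Series(0, index=table.data.index)
    kept = table.data.drop(columns=matched)
    if kept.shape[1] == 0:
        raise ValueError("consumer matched every OTU in the table")
    empties = frozenset(kept.index[kept.sum(axis=1) == 0])
    for sid in sorted(empties):
        logger.warning("sample %s has no reads left after consumer removal", sid)
    logger.info(
        "removed %d consumer OTUs (%s at rank %s); %s reads subtracted",
        len(matched), consumer, rank, int(removed.sum()),
    )
    return ConsumerRemoval(OtuTable(kept), removed.astype(np.int64), empties)


def aggregate_by_rank(table: OtuTable, tax: TaxonomyMap, rank: str) -> OtuTable:
    """Sum counts over OTUs sharing a name at ``rank``.

    OTUs unassigned at that rank pool into ``unclassified <deepest
    assigned ancestor>`` buckets. Per-sample totals are preserved
    exactly.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    labels = [tax.label_at(o, rank) for o in table.otu_ids]
    agg = table.data.T.groupby(pd.Index(labels, name=rank), sort=False).sum().T
    # stable, abundance-descending column order for readable outputs
    agg = agg[agg.sum(axis=0).sort_values(ascending=False, kind="stable").index]
    return OtuTable(agg)


def relative_abundance(table: OtuTable) -> RelAbundanceTable:
    """Divide each non-empty row by its total; empty rows are flagged."""
    totals = table.row_totals
    empties = frozenset(totals.index[totals == 0])
    safe = totals.replace(0, 1)
    return RelAbundanceTable(table.data.div(safe, axis=0), empty_samples=empties)


@dataclass(frozen=True)
class RarefactionCurve:
    """Expected OTU richness at increasing subsample depths."""

    sample_id: str
    depths: tuple[int, ...]
    expected_richness: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_id, "depth": self.depths,
             "expected_richness": self.expected_richness}
        )


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def expected_richness(counts: Iterable[int], depth: int) -> float:
    """Exact hypergeometric expectation of richness in a ``depth``-read
    subsample drawn without replacement:
    E[S] = sum_i [1 - C(N-N_i, n)/C(N, n)].
    """
    x = np.asarray([c for c in counts if c > 0], dtype=float)
    N = x.sum()
    if depth < 0 or depth > N:
        raise ValueError(f"depth {depth} exceeds sample total {int(N)}")
    if depth == 0:
        return 0.0
    keep = N - x >= depth  # otherwise the OTU cannot be missed
    miss = np.zeros_like(x)
    miss[keep] = np.exp(_log_choose(N - x[keep], depth) - _log_choose(np.array(N), depth))
    return float(np.sum(1.0 - miss))


def rarefaction_curve(
    table: OtuTable, sample_id: str, depths: Iterable[int] | None = None, n_points: int = 20
) -> RarefactionCurve:
    """Exact rarefaction curve for one sample.

    Default depth grid: ``n_points`` evenly spaced depths from 1 to the
    sample total.
    """
    counts = table.data.loc[sample_id]
    N = int(counts.sum())
    if N == 0:
        raise ValueError(f"sample {sample_id!r} has no reads")
    if depths is None:
        depths = np.unique(np.linspace(1, N, num=min(n_points, N)).astype(int))
    depths = tuple(int(d) for d in depths)
    if any(d < 1 for d in depths):
        raise ValueError("depths must be >= 1")
    values = tuple(expected_richness(counts.to_numpy(), d) for d in depths)
    return RarefactionCurve(sample_id=sample_id, depths=depths, expected_richness=values)


@dataclass(frozen=True)
class VennSummary:
    """Shared and group-unique OTUs between two sample groups."""

    shared: frozenset[str]
    unique_a: frozenset[str]
    unique_b: frozenset[str]

    @property
    def all_detected(self) -> frozenset[str]:
        return self.shared | self.unique_a | self.unique_b


def shared_unique(
    table_a: OtuTable, table_b: OtuTable, detection_min: int = 1
) -> VennSummary:
    """Venn accounting: an OTU is present in a group iff its summed count
    across the group's samples is >= ``detection_min``."""
    if detection_min < 1:
        raise ValueError("detection_min must be >= 1")
    in_a = {o for o, c in table_a.data.sum(axis=0).items() if c >= detection_min}
    in_b = {o for o, c in table_b.data.sum(axis=0).items() if c >= detection_min}
    return VennSummary(
        shared=frozenset(in_a & in_b),
        unique_a=frozenset(in_a - in_b),
        unique_b=frozenset(in_b - in_a),
    )
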