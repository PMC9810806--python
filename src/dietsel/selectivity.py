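"""Diet selectivity statistics: electivity, dominance, enrichment tests.

The electivity index E = (ri - pi)/(ri + pi) compares a taxon's relative
abundance in the diet (ri) against the ambient water (pi): +1 means the
taxon occurs only in the diet, -1 only in the environment. E > +0.25 is
read as preference, E < -0.25 as discrimination, the interior as
non-selective feeding.

Dominance uses the McNaughton abundance-times-occupancy form
Y_i = (n_i / N) * f_i, with f_i the fraction of samples where taxon i
occurs. Gut-vs-water differential enrichment is a per-taxon two-sided
Wilcoxon rank-sum test on per-sample proportions with Benjamini-Hochberg
FDR control.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OtuTable, RelAbundanceTable, SampleFrame, TaxonomyMap
from .preprocess import aggregate_by_rank, relative_abundance

__all__ = [
    "ElectivityRecord",
    "DominanceRecord",
    "EnrichmentRecord",
    "electivity",
    "classify_electivity",
    "electivity_table",
    "electivity_frame",
    "dominance_index",
    "differential_enrichment",
    "enrichment_frame",
]

logger = logging.getLogger(__name__)

Classification = Literal["preference", "non-selective", "discrimination"]


def electivity(ri: float, pi: float, zero_zero: float | None = 0.0) -> float:
    """Ivlev-style electivity E = (ri - pi)/(ri + pi).

    ``zero_zero`` is returned when ri = pi = 0 (default 0.0; pass
    ``None`` to get NaN for taxa absent from both pools).
    """
    if ri < 0 or pi < 0:
        raise ValueError("relative abundances must be non-negative")
    if ri > 1 or pi > 1:
        raise ValueError("relative abundances must be <= 1")
    if ri + pi == 0.0:
        return math.nan if zero_zero is None else float(zero_zero)
    return (ri - pi) / (ri + pi)


def classify_electivity(E: float, threshold: float = 0.25) -> Classification:
    """Map E to preference / non-selective / discrimination.

    Strict inequalities at the +-threshold; values exactly at the
    threshold are non-selective.
    """
    if not (-1.0 - 1e-12 <= E <= 1.0 + 1e-12):
        raise ValueError(f"E must lie in [-1, 1], got {E}")
    if E > threshold:
        return "preference"
    if E < -threshold:
        return "discrimination"
    return "non-selective"


@dataclass(frozen=True)
class ElectivityRecord:
    taxon: str
    group: str  # season (or "all")
    ri: float
    pi: float
    E: float
    classification: Classification
    missing: bool = False  # group had no usable diet reads


def _pool(table: OtuTable, sample_ids: Sequence[str]) -> pd.Series:
    present = [s for s in sample_ids if s in table.data.index]
    return table.data.loc[present].sum(axis=0)


def electivity_table(
    gut: OtuTable,
    water: OtuTable,
    meta: SampleFrame,
    tax: TaxonomyMap | None = None,
    rank: str = "class",
    grouping: str = "season",
    pooling: Literal["sum", "site-mean"] = "sum",
    threshold: float = 0.25,
) -> list[ElectivityRecord]:
    """Per-group electivity of every taxon, diet vs ambient.

    ``gut`` must already be consumer-removed. If a taxonomy is given,
    both tables are first aggregated at ``rank``. Default grouping pools
    reads per season across sites within each compartment (one E per
    taxon per season); ``grouping="all"`` yields a single pooled E.
    ``pooling="site-mean"`` instead computes E per site and averages.
    """
    if tax is not None:
        gut = aggregate_by_rank(gut, tax, rank)
        water = aggregate_by_rank(water, tax, rank)
    taxa = list(dict.fromkeys(list(gut.otu_ids) + list(water.otu_ids)))
    meta_df = meta.data
    if grouping == "all":
        groups = {"all": list(meta_df.index)}
    else:
        groups = {
            str(g): list(idx)
            for g, idx in meta_df.groupby(grouping, sort=False).groups.items()
        }
    records: list[ElectivityRecord] = []
    for gname, sids in groups.items():
        gut_ids = [s for s in sids if meta_df.at[s, "compartment"] == "gut"]
        water_ids = [s for s in sids if meta_df.at[s, "compartment"] == "water"]
        if pooling == "sum":
            gpool, wpool = _pool(gut, gut_ids), _pool(water, water_ids)
            gtot, wtot = gpool.sum(), wpool.sum()
            missing = gtot == 0 or wtot == 0
            if missing:
                logger.warning("group %s has an empty compartment pool", gname)
            for t in taxa:
                ri = float(gpool.get(t, 0)) / gtot if gtot else 0.0
                pi = float(wpool.get(t, 0)) / wtot if wtot else 0.0
                E = 0.0 if missing else electivity(ri, pi)
                records.append(
                    ElectivityRecord(t, gname, ri, pi, E,
                                     classify_electivity(E, threshold), missing)
                )
        elif pooling == "site-mean":
            per_site: dict[str, list[tuple[float, float, float]]] = {t: [] for t in taxa}
            for site, site_rows in meta_df.loc[sids].groupby("site", sort=False):
                g_ids = [s for s in site_rows.index if site_rows.at[s, "compartment"] == "gut"]
                w_ids = [s for s in site_rows.index if site_rows.at[s, "compartment"] == "water"]
                gpool, wpool = _pool(gut, g_ids), _pool(water, w_ids)
                gtot, wtot = gpool.sum(), wpool.sum()
                if gtot == 0 or wtot == 0:
                    continue
                for t in taxa:
                    ri = float(gpool.get(t, 0)) / gtot
                    pi = float(wpool.get(t, 0)) / wtot
                    per_site[t].append((ri, pi, electivity(ri, pi)))
            for t in taxa:
                vals = per_site[t]
                if not vals:
                    records.append(ElectivityRecord(t, gname, 0.0, 0.0, 0.0,
                                                    "non-selective", True))
                    continue
                ri = float(np.mean([v[0] for v in vals]))
                pi = float(np.mean([v[1] for v in vals]))
                E = float(np.mean([v[2] for v in vals]))
                records.append(
                    ElectivityRecord(t, gname, ri, pi, E,
                                     classify_electivity(E, threshold))
                )
        else:
            raise ValueError(f"unknown pooling {pooling!r}")
    return records


def electivity_frame(records: Iterable[ElectivityRecord]) -> pd.DataFrame:
    """Tidy DataFrame of electivity records."""
    return pd.DataFrame([r.__dict__ for r in records])


@dataclass(frozen=True)
class DominanceRecord:
    taxon: str
    Y: float


def dominance_index(table: OtuTable | RelAbundanceTable) -> list[DominanceRecord]:
    """McNaughton dominance Y_i = (overall share of i) * (occupancy of i).

    Occupancy is the fraction of non-empty samples in which the taxon
    occurs. Records are returned in descending Y order.
    """
    df = table.data
    if isinstance(table, RelAbundanceTable):
        df = table.nonempty().data
    else:
        df = df[df.sum(axis=1) > 0]
    if df.shape[0] == 0:
        raise ValueError("need at least one non-empty sample")
    total = df.to_numpy().sum()
    share = df.sum(axis=0) / total
    occupancy = (df > 0).mean(axis=0)
    Y = (share * occupancy).sort_values(ascending=False, kind="stable")
    return [DominanceRecord(str(t), float(y)) for t, y in Y.items()]


@dataclass(frozen=True)
class EnrichmentRecord:
    taxon: str
    mean_rel_gut: float
    mean_rel_water: float
    statistic: float  # rank-sum of the gut group
    p_raw: float
    q_fdr: float
    significant: bool  # q_fdr <= alpha
    significant_raw: bool  # p_raw <= alpha (as in per-taxon reporting)


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Exact-enumeration null when n1 + n2 <= 12 with no ties, otherwise
    the normal approximation with tie and continuity corrections.
    Returns (rank-sum of x, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[: len(x)].sum())
    if np.all(pooled == pooled[0]):
        return w, 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return w, float(res.pvalue)


def differential_enrichment(
    gut: RelAbundanceTable,
    water: RelAbundanceTable,
    alpha: float = 0.05,
) -> list[EnrichmentRecord]:
    """Per-taxon gut-vs-water comparison of per-sample proportions.

    Two-sided rank-sum tests with Benjamini-Hochberg q-values; a taxon
    present nowhere gets p = 1 by convention.
    """
    g = gut.nonempty().data
    wtr = water.nonempty().data
    if g.shape[0] < 2 or wtr.shape[0] < 2:
        raise ValueError("need >= 2 non-empty samples per compartment")
    taxa = list(dict.fromkeys(list(g.columns) + list(wtr.columns)))
    stats_out: list[tuple[str, float, float, float, float]] = []
    for t in taxa:
        xv = g[t].to_numpy() if t in g.columns else np.zeros(g.shape[0])
        yv = wtr[t].to_numpy() if t in wtr.columns else np.zeros(wtr.shape[0])
        if not (xv.any() or yv.any()):
            logger.info("taxon %s absent everywhere; p = 1 by convention", t)
            w = float(stats.rankdata(np.concatenate([xv, yv]))[: len(xv)].sum())
            stats_out.append((t, float(xv.mean()), float(yv.mean()), w, 1.0))
            continue
        w, p = rank_sum_test(xv, yv)
        stats_out.append((t, float(xv.mean()), float(yv.mean()), w, p))
    pvals = np.array([s[4] for s in stats_out])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    qvals = np.maximum(qvals, pvals)  # BH never reports below raw p
    return [
        EnrichmentRecord(t, mg, mw, w, p, float(q), bool(q <= alpha), bool(p <= alpha))
        for (t, mg, mw, w, p), q in zip(stats_out, qvals)
    ]


def enrichment_frame(records: Iterable[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])
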