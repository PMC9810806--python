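"""Community comparison: Bray-Curtis distances, ANOSIM, cluster order.

ANOSIM is the rank-based permutation test on a dissimilarity matrix:
R = (mean between-group rank - mean within-group rank) / (n(n-1)/4),
with R near 0 meaning no separation and 1 complete separation. The
interpretation bands follow the conventional reading: R > 0.75 large,
0.75 >= R > 0.5 medium, 0.5 >= R > 0.25 small, otherwise negligible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix

from .io import OtuTable, RelAbundanceTable

__all__ = [
    "AnosimResult",
    "bray_curtis",
    "anosim",
    "anosim_band",
    "cluster_order",
]

logger = logging.getLogger(__name__)

Band = Literal["large", "medium", "small", "negligible"]


def bray_curtis(table: OtuTable | RelAbundanceTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y).

    Empty samples are excluded with a warning.
    """
    df = table.data
    totals = df.sum(axis=1)
    empties = list(totals.index[totals == 0])
    if empties:
        logger.warning("excluding empty samples from distances: %s", empties)
        df = df.loc[totals[totals > 0].index]
    if df.shape[0] < 2:
        raise ValueError("need at least 2 non-empty samples")
    d = pdist(df.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=list(df.index))


def anosim_band(R: float) -> Band:
    if R > 0.75:
        return "large"
    if R > 0.5:
        return "medium"
    if R > 0.25:
        return "small"
    return "negligible"


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p: float
    n_permutations: int
    band: Band


def _anosim_r(ranks: np.ndarray, within: np.ndarray) -> float:
    n = (1 + np.sqrt(1 + 8 * len(ranks))) / 2  # pairs -> sample count
    denom = n * (n - 1) / 4.0
    return float((ranks[~within].mean() - ranks[within].mean()) / denom)


def anosim(
    dm: DistanceMatrix,
    grouping: Mapping[str, str] | Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> AnosimResult:
    """Rank-based analysis of similarities under label permutation.

    The p-value carries the +1 correction: p = (1 + #{R* >= R}) /
    (1 + n_perm), so it is never zero.
    """
    ids = list(dm.ids)
    if isinstance(grouping, Mapping):
        labels = np.array([grouping[i] for i in ids])
    else:
        labels = np.asarray(list(grouping))
        if len(labels) != len(ids):
            raise ValueError("grouping length must match the matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 samples each")
    n = len(ids)
    cond = squareform(dm.data, checks=False)
    ranks = rankdata(cond)  # ties -> mean rank
    iu, ju = np.triu_indices(n, k=1)
    if np.allclose(dm.data[iu, ju], dm.data[iu[0], ju[0]]):
        logger.warning("all distances tied; R = 0, p = 1")
        return AnosimResult(0.0, 1.0, n_perm, anosim_band(0.0))
    within = labels[iu] == labels[ju]
    R = _anosim_r(ranks, within)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(ranks, perm[iu] == perm[ju]) >= R:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return AnosimResult(R, p, n_perm, anosim_band(R))


def cluster_order(
    dm: DistanceMatrix, method: str = "average"
) -> tuple[list[str], np.ndarray]:
    """Agglomerative clustering of the distance matrix.

    Returns the leaf order (for heatmap rows/columns) and the scipy
    linkage matrix encoding the merge tree.
    """
    cond = squareform(dm.data, checks=False)
    Z = linkage(cond, method=method)
    order = [dm.ids[i] for i in leaves_list(Z)]
    return order, Z
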