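"""Constrained ordination: CA, DCA gradient length, RDA, CCA, selection.

The workflow mirrors standard gradient-analysis practice: a detrended
correspondence analysis of the community matrix estimates the length of
the dominant compositional gradient in species-turnover (SD) units; a
long gradient (> 4 SD) calls for the unimodal model (CCA), a short one
(< 3 SD) for the linear model (RDA). Environmental variables are then
screened by greedy forward selection, each step validated by a
Monte-Carlo permutation test of the pseudo-F statistic under the
reduced model.

All eigen-decompositions are plain dense SVDs of explicitly formed
matrices, so they can be cross-checked against generic eigensolvers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CAResult",
    "GradientLength",
    "OrdinationResult",
    "ForwardSelectionStep",
    "ForwardSelectionResult",
    "correspondence_analysis",
    "dca_gradient_length",
    "choose_method",
    "rda",
    "cca",
    "forward_select",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


def _as_matrix(Y) -> tuple[np.ndarray, list[str], list[str]]:
    if isinstance(Y, pd.DataFrame):
        return Y.to_numpy(dtype=float), [str(i) for i in Y.index], [str(c) for c in Y.columns]
    arr = np.asarray(Y, dtype=float)
    return arr, [f"row{i}" for i in range(arr.shape[0])], [f"col{j}" for j in range(arr.shape[1])]


def _chi_residuals(Ym: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Chi-square standardised residuals Q of a non-negative matrix:
    Q_ij = (p_ij - r_i c_j) / sqrt(r_i c_j)."""
    total = Ym.sum()
    if total <= 0:
        raise ValueError("matrix has no mass")
    P = Ym / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    if (r <= 0).any() or (c <= 0).any():
        raise ValueError("all-zero rows/columns must be removed first")
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    return Q, r, c


@dataclass(frozen=True)
class CAResult:
    eigenvalues: np.ndarray  # descending, trivial axis excluded
    total_inertia: float
    row_scores: pd.DataFrame  # principal coordinates
    col_scores: pd.DataFrame
    row_weights: np.ndarray
    col_weights: np.ndarray


def correspondence_analysis(Y) -> CAResult:
    """Correspondence analysis via SVD of the chi-square residuals."""
    Ym, rows, cols = _as_matrix(Y)
    keep_r = Ym.sum(axis=1) > 0
    keep_c = Ym.sum(axis=0) > 0
    Ym = Ym[np.ix_(keep_r, keep_c)]
    rows = [x for x, k in zip(rows, keep_r) if k]
    cols = [x for x, k in zip(cols, keep_c) if k]
    if Ym.size == 0 or min(Ym.shape) < 1:
        raise ValueError("rank-0 matrix")
    Q, r, c = _chi_residuals(Ym)
    U, S, Vt = np.linalg.svd(Q, full_matrices=False)
    k = min(Ym.shape) - 1  # at most rank-1 less than min dim (centering)
    S = S[:k]
    eig = S**2
    row_std = U[:, :k] / np.sqrt(r)[:, None]
    col_std = Vt[:k].T / np.sqrt(c)[:, None]
    naxes = [f"CA{i + 1}" for i in range(k)]
    return CAResult(
        eigenvalues=eig,
        total_inertia=float((Q**2).sum()),
        row_scores=pd.DataFrame(row_std * S, index=rows, columns=naxes),
        col_scores=pd.DataFrame(col_std * S, index=cols, columns=naxes),
        row_weights=r,
        col_weights=c,
    )


@dataclass(frozen=True)
class GradientLength:
    """Axis-1 gradient length in SD (species-turnover) units, plus the
    ordination model the decision rule picks for it."""

    length: float
    lower: float = 3.0
    upper: float = 4.0
    midrange_default: Literal["CCA", "RDA"] = "CCA"

    def __post_init__(self) -> None:
        if self.length < 0:
            raise ValueError("gradient length must be >= 0")

    @property
    def chosen_method(self) -> Literal["CCA", "RDA"]:
        if self.length > self.upper:
            return "CCA"
        if self.length < self.lower:
            return "RDA"
        return self.midrange_default


def choose_method(
    length: float, lower: float = 3.0, upper: float = 4.0,
    midrange_default: Literal["CCA", "RDA"] = "CCA",
) -> Literal["CCA", "RDA"]:
    """Unimodal (CCA) above ``upper`` SD, linear (RDA) below ``lower``;
    the in-between zone defaults to the unimodal model."""
    return GradientLength(length, lower, upper, midrange_default).chosen_method


def dca_gradient_length(
    Y, n_segments: int = 26, rescale_iter: int = 4,
    lower: float = 3.0, upper: float = 4.0,
) -> GradientLength:
    """Gradient length of detrended-correspondence axis 1.

    Site scores come from reciprocal averaging (CA axis 1); the axis is
    then nonlinearly rescaled by segments so that the abundance-weighted
    within-species dispersion of site scores (the "tolerance") averages
    one per unit, iterated ``rescale_iter`` times. The returned length
    is the rescaled score range divided by the final global tolerance,
    i.e. the number of species-turnover SD units the gradient spans.
    Detrending of higher axes is irrelevant for the axis-1 length and is
    not performed.
    """
    Ym, _, _ = _as_matrix(Y)
    Ym = Ym[Ym.sum(axis=1) > 0][:, Ym.sum(axis=0) > 0]
    if Ym.shape[0] < 3:
        raise ValueError("need at least 3 non-empty samples")
    ca = correspondence_analysis(Ym)
    if ca.eigenvalues.size == 0 or ca.eigenvalues[0] < _EPS:
        return GradientLength(0.0, lower, upper)
    x = ca.row_scores.iloc[:, 0].to_numpy().copy()
    if np.ptp(x) < _EPS:
        return GradientLength(0.0, lower, upper)

    row_tot = Ym.sum(axis=1)
    col_tot = Ym.sum(axis=0)

    def species_scores(xs: np.ndarray) -> np.ndarray:
        return (Ym.T @ xs) / col_tot

    def tolerances(xs: np.ndarray, u: np.ndarray) -> np.ndarray:
        # weighted squared deviation of site scores about species optima
        return (xs[:, None] - u[None, :]) ** 2

    for _ in range(max(0, rescale_iter)):
        u = species_scores(x)
        dev2 = tolerances(x, u)
        lo, hi = x.min(), x.max()
        if hi - lo < _EPS:
            break
        edges = np.linspace(lo, hi, n_segments + 1)
        seg_of_site = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_segments - 1)
        w_cell = Ym  # abundance weights per (site, species) cell
        seg_var = np.full(n_segments, np.nan)
        for k in range(n_segments):
            mask = seg_of_site == k
            wk = w_cell[mask].sum()
            if wk > 0:
                seg_var[k] = (w_cell[mask] * dev2[mask]).sum() / wk
        global_var = (w_cell * dev2).sum() / w_cell.sum()
        seg_var = np.where(np.isnan(seg_var) | (seg_var < _EPS), global_var, seg_var)
        # 3-segment smoothing stabilises sparse segments
        padded = np.pad(seg_var, 1, mode="edge")
        seg_var = (padded[:-2] + padded[1:-1] + padded[2:]) / 3.0
        widths = np.diff(edges) / np.sqrt(seg_var)
        new_edges = np.concatenate([[0.0], np.cumsum(widths)])
        x = np.interp(x, edges, new_edges)

    u = species_scores(x)
    dev2 = tolerances(x, u)
    global_sd = np.sqrt((Ym * dev2).sum() / Ym.sum())
    if global_sd < _EPS:
        return GradientLength(0.0, lower, upper)
    return GradientLength(float(np.ptp(x) / global_sd), lower, upper)


@dataclass(frozen=True)
class OrdinationResult:
    method: Literal["RDA", "CCA"]
    eigenvalues: np.ndarray  # constrained axes, descending
    total_inertia: float
    constrained_inertia: float
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    biplot_scores: pd.DataFrame  # env-variable arrows
    aliased: tuple[str, ...] = field(default_factory=tuple)

    @property
    def axis_explained(self) -> np.ndarray:
        """Per-axis fraction of the community-environment (constrained)
        variability."""
        if self.constrained_inertia <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / self.constrained_inertia

    @property
    def axis_explained_total(self) -> np.ndarray:
        return self.eigenvalues / self.total_inertia

    @property
    def cum_explained_2axes(self) -> float:
        return float(self.axis_explained[: 2].sum())

    @property
    def constrained_fraction(self) -> float:
        return self.constrained_inertia / self.total_inertia


def _env_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        M = X.to_numpy(dtype=float)
        names = [str(c) for c in X.columns]
    else:
        M = np.asarray(X, dtype=float)
        names = [f"x{j + 1}" for j in range(M.shape[1])]
    if not np.isfinite(M).all():
        raise ValueError("environmental matrix must be complete and finite")
    return M, names


def _drop_aliased(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedily keep a maximal independent column subset."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=1e-9) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        logger.warning("dropping aliased (collinear) variables: %s", dropped)
    return X[:, keep], [names[j] for j in keep], dropped


def _standardize(X: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Column z-scores; with ``w``, weighted mean/variance are used."""
    if w is None:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
    else:
        mu = w @ X
        sd = np.sqrt(w @ (X - mu) ** 2)
    sd = np.where(sd < _EPS, 1.0, sd)
    return (X - mu) / sd


def _project(Xc: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Least-squares projection of M's columns onto the span of Xc."""
    coef, *_ = np.linalg.lstsq(Xc, M, rcond=None)
    return Xc @ coef


def rda(Y, X, scale_species: bool = False, standardize_env: bool = True) -> OrdinationResult:
    """Redundancy analysis: PCA of the env-fitted community matrix.

    Species columns are centred (optionally scaled); env columns are
    z-scored by default since units differ. Inertia is on the variance
    scale (divided by n - 1).
    """
    Ym, rows, cols = _as_matrix(Y)
    Xm, names = _env_matrix(X)
    n = Ym.shape[0]
    if Xm.shape[0] != n:
        raise ValueError("Y and X must have matching samples")
    Yc = Ym - Ym.mean(axis=0)
    if scale_species:
        sd = Yc.std(axis=0, ddof=1)
        Yc = Yc / np.where(sd < _EPS, 1.0, sd)
    Xc = Xm - Xm.mean(axis=0)
    if standardize_env:
        Xc = _standardize(Xm)
    Xc, names, dropped = _drop_aliased(Xc, names)
    if n <= Xc.shape[1]:
        raise ValueError("need more samples than constraining variables")
    if Xc.shape[1] == 0:  # e.g. constant-only constraints: nothing explained
        return OrdinationResult(
            method="RDA", eigenvalues=np.zeros(1),
            total_inertia=float((Yc**2).sum() / (n - 1)), constrained_inertia=0.0,
            site_scores=pd.DataFrame(index=rows), species_scores=pd.DataFrame(index=cols),
            biplot_scores=pd.DataFrame(), aliased=tuple(dropped),
        )
    Yfit = _project(Xc, Yc)
    U, S, Vt = np.linalg.svd(Yfit, full_matrices=False)
    k = int(np.sum(S**2 > _EPS * max(1.0, S.max() ** 2 if S.size else 1.0)))
    k = max(k, 1) if S.size else 0
    S, U, Vt = S[:k], U[:, :k], Vt[:k]
    eig = S**2 / (n - 1)
    axes = [f"RDA{i + 1}" for i in range(k)]
    site = pd.DataFrame(U * S, index=rows, columns=axes)
    species = pd.DataFrame(Vt.T, index=cols, columns=axes)
    with np.errstate(invalid="ignore", divide="ignore"):
        biplot = np.corrcoef(np.hstack([Xc, U * S]), rowvar=False)[: Xc.shape[1], Xc.shape[1]:]
    biplot = np.nan_to_num(biplot)
    return OrdinationResult(
        method="RDA",
        eigenvalues=eig,
        total_inertia=float((Yc**2).sum() / (n - 1)),
        constrained_inertia=float(eig.sum()),
        site_scores=site,
        species_scores=species,
        biplot_scores=pd.DataFrame(biplot, index=names, columns=axes),
        aliased=tuple(dropped),
    )


def cca(Y, X, standardize_env: bool = True) -> OrdinationResult:
    """Canonical correspondence analysis.

    The chi-square residual matrix of the community table is regressed,
    with row-mass weights, on the environmental variables; the fitted
    part is eigen-decomposed. Constrained inertia is bounded by the CA
    total inertia.
    """
    Ym, rows, cols = _as_matrix(Y)
    keep_r = Ym.sum(axis=1) > 0
    keep_c = Ym.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        Ym = Ym[np.ix_(keep_r, keep_c)]
        rows = [x for x, k in zip(rows, keep_r) if k]
        cols = [x for x, k in zip(cols, keep_c) if k]
    Xm, names = _env_matrix(X)
    if isinstance(X, pd.DataFrame) and not keep_r.all():
        Xm = Xm[keep_r]
    n = Ym.shape[0]
    if Xm.shape[0] != n:
        raise ValueError("Y and X must have matching samples")
    if (Ym < 0).any():
        raise ValueError("CCA requires non-negative abundances")
    Q, r, c = _chi_residuals(Ym)
    Xs = _standardize(Xm, w=r) if standardize_env else Xm - r @ Xm
    Xw = np.sqrt(r)[:, None] * Xs
    Xw, names, dropped = _drop_aliased(Xw, names)
    if n <= Xw.shape[1]:
        raise ValueError("need more samples than constraining variables")
    if Xw.shape[1] == 0:
        return OrdinationResult(
            method="CCA", eigenvalues=np.zeros(1),
            total_inertia=float((Q**2).sum()), constrained_inertia=0.0,
            site_scores=pd.DataFrame(index=rows), species_scores=pd.DataFrame(index=cols),
            biplot_scores=pd.DataFrame(), aliased=tuple(dropped),
        )
    Qfit = _project(Xw, Q)
    U, S, Vt = np.linalg.svd(Qfit, full_matrices=False)
    k = int(np.sum(S**2 > 1e-10))
    k = max(k, 1) if S.size else 0
    S, U, Vt = S[:k], U[:, :k], Vt[:k]
    eig = S**2
    axes = [f"CCA{i + 1}" for i in range(k)]
    # weighted (LC) site scores and species scores, scaling-2 flavour
    site = pd.DataFrame((U * S) / np.sqrt(r)[:, None], index=rows, columns=axes)
    species = pd.DataFrame(Vt.T / np.sqrt(c)[:, None], index=cols, columns=axes)
    with np.errstate(invalid="ignore", divide="ignore"):
        biplot = np.corrcoef(np.hstack([Xw, U * S]), rowvar=False)[: Xw.shape[1], Xw.shape[1]:]
    biplot = np.nan_to_num(biplot)
    return OrdinationResult(
        method="CCA",
        eigenvalues=eig,
        total_inertia=float((Q**2).sum()),
        constrained_inertia=float(eig.sum()),
        site_scores=site,
        species_scores=species,
        biplot_scores=pd.DataFrame(biplot, index=names, columns=axes),
        aliased=tuple(dropped),
    )


@dataclass(frozen=True)
class ForwardSelectionStep:
    variable: str
    added_inertia: float
    pseudo_F: float
    p_value: float


@dataclass(frozen=True)
class ForwardSelectionResult:
    selected: tuple[str, ...]
    steps: tuple[ForwardSelectionStep, ...]
    stopping_reason: str

    def trace(self) -> pd.DataFrame:
        return pd.DataFrame([s.__dict__ for s in self.steps])


def _response_and_design(method: str, Y, X):
    """Transformed response matrix M and design columns in the space
    where ordinary projections implement the ordination fit."""
    Ym, _, _ = _as_matrix(Y)
    Xm, names = _env_matrix(X)
    if method.upper() == "RDA":
        M = Ym - Ym.mean(axis=0)
        Xc = _standardize(Xm)
        return M, Xc, names
    if method.upper() == "CCA":
        keep_r = Ym.sum(axis=1) > 0
        keep_c = Ym.sum(axis=0) > 0
        Ym = Ym[np.ix_(keep_r, keep_c)]
        Xm = Xm[keep_r]
        Q, r, _ = _chi_residuals(Ym)
        Xw = np.sqrt(r)[:, None] * _standardize(Xm, w=r)
        return Q, Xw, names
    raise ValueError(f"unknown method {method!r}")


def forward_select(
    Y,
    X,
    method: Literal["RDA", "CCA"] = "RDA",
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> ForwardSelectionResult:
    """Greedy forward selection of constraining variables.

    At each step the candidate adding the most constrained inertia is
    tested with a pseudo-F permutation test that permutes the residuals
    of the current reduced model; selection stops when the best
    candidate's permutation p exceeds ``alpha``.
    """
    M, Xall, names = _response_and_design(method, Y, X)
    n = M.shape[0]
    inertia_scale = 1.0 / (n - 1) if method.upper() == "RDA" else 1.0
    rng = np.random.default_rng(seed)
    selected: list[int] = []
    steps: list[ForwardSelectionStep] = []
    reason = "no candidates left"
    total = float((M**2).sum())

    def resid_against(sel: Sequence[int], A: np.ndarray) -> np.ndarray:
        if not sel:
            return A
        return A - _project(Xall[:, sel], A)

    while True:
        candidates = [j for j in range(Xall.shape[1]) if j not in selected]
        if not candidates:
            break
        df_resid = n - 1 - (len(selected) + 1)
        if df_resid < 1:
            reason = "residual degrees of freedom exhausted"
            break
        R = resid_against(selected, M)
        resid_inertia = float((R**2).sum())
        if resid_inertia < _EPS * max(total, 1.0):
            reason = "no residual inertia left"
            break
        best_j, best_add, best_xres = -1, -1.0, None
        for j in candidates:
            xr = resid_against(selected, Xall[:, [j]])[:, 0]
            nrm = float(xr @ xr)
            if nrm < 1e-10:  # aliased with current model
                continue
            add = float(((xr @ R) ** 2).sum() / nrm)
            if add > best_add:
                best_j, best_add, best_xres = j, add, xr / np.sqrt(nrm)
        if best_j < 0:
            reason = "remaining candidates aliased"
            break
        F_obs = (best_add / 1.0) / ((resid_inertia - best_add) / df_resid)
        hits = 0
        for _ in range(n_perm):
            Rp = R[rng.permutation(n)]
            add_p = float(((best_xres @ Rp) ** 2).sum())
            F_p = add_p / ((resid_inertia - add_p) / df_resid)
            if F_p >= F_obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
        if p > alpha:
            reason = (
                f"best remaining candidate {names[best_j]!r} not significant "
                f"(p={p:.4f} > {alpha})"
            )
            break
        selected.append(best_j)
        steps.append(
            ForwardSelectionStep(names[best_j], best_add * inertia_scale,
                                 float(F_obs), float(p))
        )
    if not steps and reason.startswith("best remaining"):
        reason = "no candidate significant at step 1; " + reason
    return ForwardSelectionResult(
        selected=tuple(s.variable for s in steps),
        steps=tuple(steps),
        stopping_reason=reason,
    )
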