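"""Biomarker-region methylation densities and tissue-of-origin deconvolution.

A plasma methylome is modeled as a non-negative mixture of reference tissue
methylomes: for biomarker region r, the sample density x_r ≈ Σ_t p_t M_rt
with p on the probability simplex.  The mixture is recovered by
constrained least squares (quadratic programming):

    min ||M p - x||²  subject to  p ≥ 0,  Σ p = 1

solved with a primal active-set scheme whose result is certified against
the KKT optimality conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class MethylationProfile:
    """Per-biomarker-region methylation densities for one sample."""

    densities: pd.Series  # region -> density in [0,1]; NaN = missing
    cpg_counts: pd.Series  # retained CpGs per region

    @property
    def n_missing(self) -> int:
        return int(self.densities.isna().sum())


def region_density(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    min_depth: int = 2,
    max_depth: int = 2000,
    snp_mask: Optional[Sequence[tuple[str, int, int]]] = None,
) -> MethylationProfile:
    """Aggregate per-CpG calls into per-region methylation densities.

    ``calls`` columns: contig, position, methylated, total.  ``regions``
    columns: contig, start, end, region (0-based half-open intervals).
    CpGs outside [min_depth, max_depth] total depth, or overlapping the
    SNP mask, are excluded; a region's density is the pooled
    Σ methylated / Σ total over its retained CpGs, NaN when no CpG
    survives.  Overlapping regions each receive every contained CpG
    (with a warning).
    """
    req = {"contig", "position", "methylated", "total"}
    if not req.issubset(calls.columns):
        raise ValueError(f"calls table must have columns {sorted(req)}")
    if ((calls["methylated"] > calls["total"]) | (calls["methylated"] < 0)).any():
        raise ValueError("methylated count outside [0, total]")
    ok = (calls["total"] >= min_depth) & (calls["total"] <= max_depth)
    kept = calls[ok]
    if snp_mask:
        masked = np.zeros(len(kept), dtype=bool)
        pos = kept["position"].to_numpy()
        ctg = kept["contig"].to_numpy()
        for mcontig, mstart, mend in snp_mask:
            masked |= (ctg == mcontig) & (pos >= mstart) & (pos < mend)
        kept = kept[~masked]

    _warn_if_overlapping(regions)
    dens, counts = {}, {}
    for row in regions.itertuples(index=False):
        sel = kept[
            (kept["contig"] == row.contig)
            & (kept["position"] >= row.start)
            & (kept["position"] < row.end)
        ]
        counts[row.region] = len(sel)
        total = int(sel["total"].sum())
        dens[row.region] = (
            float(sel["methylated"].sum()) / total if total > 0 else np.nan
        )
    order = list(regions["region"])
    return MethylationProfile(
        pd.Series(dens).reindex(order), pd.Series(counts).reindex(order)
    )


def _warn_if_overlapping(regions: pd.DataFrame) -> None:
    by = regions.sort_values(["contig", "start"])
    prev_contig, prev_end = None, -1
    for row in by.itertuples(index=False):
        if row.contig == prev_contig and row.start < prev_end:
            warnings.warn(
                "overlapping biomarker regions: CpGs credited to every "
                "containing region",
                stacklevel=3,
            )
            return
        prev_contig, prev_end = row.contig, row.end


# ---------------------------------------------------------------------------
# Quadratic-programming deconvolution


@dataclass
class DeconvolutionResult:
    mixture: pd.Series  # tissue proportions on the simplex
    residual: float  # ||M p - x||_2 over the rows used
    n_regions_used: int
    kkt_violation: float
    unique: bool = True


def _solve_equality_ls(
    Q: np.ndarray, c: np.ndarray, free: np.ndarray
) -> np.ndarray:
    """Solve min ½pᵀQp + cᵀp s.t. Σ p_free = 1, p_fixed = 0, via the
    bordered KKT system on the free coordinates."""
    k = int(free.sum())
    idx = np.flatnonzero(free)
    A = np.zeros((k + 1, k + 1))
    A[:k, :k] = Q[np.ix_(idx, idx)]
    A[:k, k] = 1.0
    A[k, :k] = 1.0
    b = np.zeros(k + 1)
    b[:k] = -c[idx]
    b[k] = 1.0
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    p = np.zeros(len(c))
    p[idx] = sol[:k]
    return p


def qp_deconvolve(
    profile: MethylationProfile | pd.Series,
    reference: pd.DataFrame,
    tol: float = 1e-9,
    max_iter: Optional[int] = None,
) -> DeconvolutionResult:
    """Tissue mixture by simplex-constrained least squares.

    Rows with a missing sample density are dropped pairwise from both the
    sample vector and the reference matrix.  The active-set iteration
    maintains primal feasibility; at convergence the KKT conditions
    (stationarity with non-negative multipliers on the active bounds) are
    checked and the violation magnitude reported.  A rank-deficient
    reference after row dropping yields a valid minimizer flagged as
    possibly non-unique.
    """
    x = profile.densities if isinstance(profile, MethylationProfile) else profile
    x = x.reindex(reference.index)
    keep = ~x.isna()
    M = reference.loc[keep].to_numpy(dtype=float)
    xv = x[keep].to_numpy(dtype=float)
    n_regions, n_tissues = M.shape
    if n_regions < n_tissues:
        raise ValueError(
            f"{n_regions} usable regions for {n_tissues} tissues: underdetermined"
        )
    unique = np.linalg.matrix_rank(M) >= n_tissues
    if not unique:
        warnings.warn("rank-deficient reference matrix: mixture may be non-unique",
                      stacklevel=2)

    Q = M.T @ M
    c = -M.T @ xv
    if max_iter is None:
        max_iter = 50 * n_tissues + 50

    free = np.ones(n_tissues, dtype=bool)
    p = np.full(n_tissues, 1.0 / n_tissues)
    for _ in range(max_iter):
        cand = _solve_equality_ls(Q, c, free)
        if cand[free].min() >= -tol:
            p = np.maximum(cand, 0.0)
            # check multipliers on active bounds; release if profitable
            grad = Q @ p + c
            nu = -grad[free].mean() if free.any() else 0.0
            lam = grad + nu  # multipliers for p_i >= 0 on the active set
            active = ~free
            if active.any() and lam[active].min() < -1e-10:
                j = np.flatnonzero(active)[np.argmin(lam[active])]
                free[j] = True
                continue
            break
        # step from p toward cand until the first bound blocks
        d = cand - p
        neg = d < -tol
        with np.errstate(divide="ignore"):
            alphas = np.where(neg, -p / np.where(neg, d, -1.0), np.inf)
        alpha = min(1.0, float(alphas.min()))
        p = p + alpha * d
        blocked = np.flatnonzero(neg & (alphas <= alpha + 1e-15))
        if len(blocked) == 0:
            blocked = [int(np.argmin(alphas))]
        for j in blocked:
            free[j] = False
            p[j] = 0.0
        if not free.any():  # numerical corner: restart from a vertex
            free[int(np.argmin(np.diag(Q) + 2 * c))] = True
            p[:] = 0.0
            p[free] = 1.0

    p = np.maximum(p, 0.0)
    p /= p.sum()
    grad = Q @ p + c
    support = p > tol
    nu = -grad[support].mean() if support.any() else 0.0
    lam = grad + nu
    kkt = max(
        float(np.max(np.abs(lam[support]))) if support.any() else 0.0,
        float(max(0.0, -lam[~support].min())) if (~support).any() else 0.0,
        abs(float(p.sum()) - 1.0),
    )
    residual = float(np.linalg.norm(M @ p - xv))
    return DeconvolutionResult(
        mixture=pd.Series(p, index=reference.columns),
        residual=residual,
        n_regions_used=n_regions,
        kkt_violation=kkt,
        unique=unique,
    )


def simplex_grid_deconvolve(
    x: pd.Series, reference: pd.DataFrame, resolution: float = 1e-3
) -> pd.Series:
    """Exhaustive simplex-grid minimizer (oracle for 2-3 tissues only)."""
    x = x.reindex(reference.index)
    keep = ~x.isna()
    M = reference.loc[keep].to_numpy(dtype=float)
    xv = x[keep].to_numpy(dtype=float)
    n_t = M.shape[1]
    steps = int(round(1.0 / resolution))
    if n_t == 2:
        i = np.arange(steps + 1)
        P = np.column_stack([i / steps, 1 - i / steps])
    elif n_t == 3:
        ii, jj = np.meshgrid(np.arange(steps + 1), np.arange(steps + 1), indexing="ij")
        keep = ii + jj <= steps
        ii, jj = ii[keep], jj[keep]
        P = np.column_stack([ii / steps, jj / steps, 1 - (ii + jj) / steps])
    else:
        raise ValueError("grid oracle supports 2 or 3 tissues")
    resid = P @ M.T - xv[None, :]
    best = P[int(np.argmin(np.einsum("ij,ij->i", resid, resid)))]
    return pd.Series(best, index=reference.columns)


def replicate_concordance(mixtures: Iterable[pd.Series]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix between replicate mixtures."""
    mixtures = list(mixtures)
    if len(mixtures) < 2:
        raise ValueError("need >= 2 replicate mixtures")
    tissues = mixtures[0].index
    for m in mixtures[1:]:
        if not m.index.equals(tissues):
            raise ValueError("replicate mixtures over different tissue sets")
    names = [m.name or f"rep{i + 1}" for i, m in enumerate(mixtures)]
    k = len(mixtures)
    out = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(k):
            a = mixtures[i].to_numpy(dtype=float)
            b = mixtures[j].to_numpy(dtype=float)
            if a.std() == 0 or b.std() == 0:
                continue  # undefined pair
            out[i, j] = float(np.corrcoef(a, b)[0, 1])
    return pd.DataFrame(out, index=names, columns=names)
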