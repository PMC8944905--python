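"""Immune cell-type deconvolution of bulk expression profiles.

Given a signature matrix S (genes x cell types of reference expression) and
a bulk mixture x, the cell-type fractions f solve the simplex-constrained
least-squares problem

    minimize ||S f - x||_2   subject to  f >= 0,  sum(f) = 1,

the linear mixing model used for bulk deconvolution against a
hematopoietic signature. Fractions over fine types (25 in the default
grouping) are aggregated into the six major immune lineages by summation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["simplex_lsq", "deconvolve", "aggregate_fractions", "DeconvolutionResult"]


@dataclass
class DeconvolutionResult:
    fractions: pd.DataFrame  # samples x cell types, rows on the simplex
    residual_norm: pd.Series  # per-sample ||S f - x||_2
    rank_deficient: bool
    n_genes_used: int


def _solve_free_set(StS: np.ndarray, Stx: np.ndarray, free: np.ndarray) -> tuple[np.ndarray, float]:
    """Equality-constrained LS on the free coordinates via KKT with a
    Lagrange multiplier for the sum-to-one constraint."""
    k = free.sum()
    kkt = np.zeros((k + 1, k + 1))
    kkt[:k, :k] = StS[np.ix_(free, free)]
    kkt[:k, k] = 1.0
    kkt[k, :k] = 1.0
    rhs = np.append(Stx[free], 1.0)
    sol, *_ = np.linalg.lstsq(kkt, rhs, rcond=None)
    return sol[:k], float(sol[k])


def simplex_lsq(S: np.ndarray, x: np.ndarray, tol: float = 1e-9, max_iter: int | None = None):
    """Active-set solver for min ||S f - x|| with f on the probability simplex.

    The sum-to-one constraint is kept in the working set throughout
    (Lagrange multiplier); non-negativity bounds enter and leave the active
    set until the KKT conditions hold to ``tol``. Returns (f, residual_norm).
    """
    S = np.asarray(S, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    n = S.shape[1]
    StS = S.T @ S
    Stx = S.T @ x
    free = np.ones(n, dtype=bool)
    max_iter = max_iter or 6 * n

    f = np.zeros(n)
    lam = 0.0
    for _ in range(max_iter):
        vals, lam = _solve_free_set(StS, Stx, free)
        f = np.zeros(n)
        f[free] = vals
        if vals.size and vals.min() < -tol:
            # clamp the most negative coordinate to the zero bound
            order = np.flatnonzero(free)
            free[order[np.argmin(vals)]] = False
            if not free.any():  # all clamped: restart from the least-bad vertex
                free[np.argmin(np.diag(StS) - 2 * Stx)] = True
            continue
        f = np.clip(f, 0.0, None)
        # dual feasibility of clamped coordinates: mu_i = g_i + lambda >= 0
        g = StS @ f - Stx
        clamped = ~free
        mu = g[clamped] + lam
        if clamped.any() and mu.min() < -tol:
            idx = np.flatnonzero(clamped)[np.argmin(mu)]
            free[idx] = True
            continue
        break
    resid = float(np.linalg.norm(S @ f - x))
    return f, resid


def deconvolve(
    mixtures: pd.DataFrame,
    signature: pd.DataFrame,
    tol: float = 1e-9,
) -> DeconvolutionResult:
    """Estimate cell-type fractions for each sample (column) of ``mixtures``.

    Gene symbols are intersected case-insensitively between mixture and
    signature; a warning is raised if fewer than half the signature genes
    survive the intersection. A rank-deficient signature after intersection
    is solved anyway but flagged (the solution may be non-unique).
    """
    sig_idx = signature.index.str.lower()
    mix_idx = mixtures.index.str.lower()
    if sig_idx.has_duplicates or mix_idx.has_duplicates:
        raise ValueError("duplicate gene symbols after case folding")
    common = sig_idx.intersection(mix_idx)
    if len(common) == 0:
        raise ValueError("no genes shared between mixture and signature")
    if len(common) < 0.5 * len(sig_idx):
        warnings.warn(
            f"only {len(common)}/{len(sig_idx)} signature genes found in the mixture",
            stacklevel=2,
        )
    S = signature.set_axis(sig_idx).loc[common].to_numpy(dtype=float)
    X = mixtures.set_axis(mix_idx).loc[common].to_numpy(dtype=float)

    rank_deficient = np.linalg.matrix_rank(S) < S.shape[1]
    if rank_deficient:
        warnings.warn(
            "signature matrix is rank deficient after gene intersection; "
            "fractions may be non-unique",
            stacklevel=2,
        )

    fracs, resids = [], []
    for j in range(X.shape[1]):
        f, r = simplex_lsq(S, X[:, j], tol=tol)
        fracs.append(f)
        resids.append(r)
    fractions = pd.DataFrame(fracs, index=mixtures.columns, columns=signature.columns)
    return DeconvolutionResult(
        fractions=fractions,
        residual_norm=pd.Series(resids, index=mixtures.columns, name="residual_norm"),
        rank_deficient=bool(rank_deficient),
        n_genes_used=len(common),
    )


def aggregate_fractions(fractions: pd.DataFrame, grouping: dict[str, str]) -> pd.DataFrame:
    """Sum fine-type fractions into major-type fractions (still on the simplex)."""
    missing = [t for t in fractions.columns if t not in grouping]
    if missing:
        raise ValueError(f"cell types missing from the grouping map: {missing}")
    majors = fractions.T.groupby(fractions.columns.map(grouping)).sum().T
    return majors
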