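"""Comparison mapping methods: single-marker regression (SMR), merging of
SMR-significant SNPs into segments, forward stepwise regression ranked by
residual-sum-of-squares reduction, and LASSO ranked by the regularization
strength at which each SNP enters the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import lasso_path

log = logging.getLogger(__name__)


def smr_scan(ds, y: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple OLS of centered y on centered dosage.

    Returns a DataFrame aligned with the SNP map: ``beta_hat``, ``se``,
    ``t_stat`` and two-sided ``p_value`` from the t distribution with
    ``n - 2`` degrees of freedom, plus the training-mean dosage (needed
    later for PRS centering).
    """
    X = ds.dosages
    y = np.asarray(y, dtype=np.float64).ravel()
    n = X.shape[0]
    means = X.mean(axis=0)
    Xc = X - means
    yc = y - y.mean()
    cxx = np.einsum("ij,ij->j", Xc, Xc)
    if (cxx == 0).any():
        bad = np.flatnonzero(cxx == 0)
        raise ValueError(f"zero-variance SNPs at columns {bad[:5].tolist()}")
    cxy = Xc.T @ yc
    beta = cxy / cxx
    rss = float(yc @ yc) - beta * cxy
    rss = np.maximum(rss, 0.0)
    sigma2 = rss / (n - 2)
    se = np.sqrt(sigma2 / cxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    out = ds.snp_map[["snp_id", "chrom", "pos_bp"]].copy()
    out["beta_hat"] = beta
    out["se"] = se
    out["t_stat"] = t
    out["p_value"] = p
    out["mean_dosage"] = means
    return out


def merge_smr_segments(
    scan: pd.DataFrame, p_thresh: float = 5e-8, max_gap_bp: int = 1_000_000
) -> pd.DataFrame:
    """Group significant SNPs into chromosome segments.

    SNPs with ``p < p_thresh`` on the same chromosome are merged
    transitively whenever adjacent significant SNPs lie within
    ``max_gap_bp`` of each other (the classic 1000-kbp merge rule).
    """
    sig = scan.loc[scan["p_value"] < p_thresh].sort_values(["chrom", "pos_bp"])
    rows = []
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos_bp"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            seg = grp.iloc[s:e]
            rows.append(
                {
                    "chrom": chrom,
                    "start_bp": int(seg["pos_bp"].iloc[0]),
                    "end_bp": int(seg["pos_bp"].iloc[-1]),
                    "n_snps": len(seg),
                    "min_p": float(seg["p_value"].min()),
                    "snp_ids": list(seg["snp_id"]),
                }
            )
    return pd.DataFrame(
        rows, columns=["chrom", "start_bp", "end_bp", "n_snps", "min_p", "snp_ids"]
    )


@dataclass
class ForwardPath:
    entry_order: np.ndarray  # SNP column indices in entry order
    rss_reduction: np.ndarray  # RSS drop when each SNP entered
    rss_path: np.ndarray  # RSS after each step (rss_path[0] = y'y)
    skipped: list[int]


def forward_regression(
    X: np.ndarray, y: np.ndarray, max_steps: int, tol: float = 1e-10
) -> ForwardPath:
    """Forward stepwise selection by maximal RSS reduction.

    Implemented by incremental orthogonalization: after a SNP enters, all
    remaining candidate columns and the residual are projected off its
    (orthonormalized) direction, so each step's best candidate maximizes
    the joint-model RSS drop exactly.  Candidates that become numerically
    collinear with the selected set are skipped and logged.
    """
    X = np.array(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    norms0 = np.einsum("ij,ij->j", X, X)
    if (norms0 == 0).any():
        raise ValueError("zero-variance columns; filter first")
    r = y.copy()
    active = np.ones(X.shape[1], dtype=bool)
    order: list[int] = []
    reductions: list[float] = []
    skipped: list[int] = []
    rss = float(r @ r)
    rss_path = [rss]
    for _ in range(max_steps):
        norms = np.einsum("ij,ij->j", X, X)
        degenerate = active & (norms <= tol * np.maximum(norms0, 1.0))
        for j in np.flatnonzero(degenerate):
            log.info("forward_regression: skipping collinear column %d", j)
            skipped.append(int(j))
            active[j] = False
        if not active.any():
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            proj = X.T @ r
            red = np.where(active, proj**2 / np.where(norms > 0, norms, 1.0), -np.inf)
        j_best = int(np.argmax(red))
        best = red[j_best]
        if best <= tol * max(rss_path[0], 1.0):
            break
        q = X[:, j_best] / np.sqrt(norms[j_best])
        r = r - q * (q @ r)
        X = X - np.outer(q, q @ X)
        X[:, j_best] = 0.0
        active[j_best] = False
        rss = float(r @ r)
        order.append(j_best)
        reductions.append(float(best))
        rss_path.append(rss)
    return ForwardPath(
        entry_order=np.array(order, dtype=np.intp),
        rss_reduction=np.array(reductions),
        rss_path=np.array(rss_path),
        skipped=skipped,
    )


def lasso_lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 1000,
    lambda_min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-evenly spaced grid from lambda_max down to lambda_max * ratio.

    ``lambda_max = max_j |x_j' y| / n`` is the smallest penalty with an
    empty active set (KKT bound, for centered inputs).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n = X.shape[0]
    lam_max = np.abs(X.T @ y).max() / n
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def lasso_entry_ranking(
    X: np.ndarray,
    y: np.ndarray,
    n_lambda: int = 1000,
    lambda_min_ratio: float = 1e-4,
    lambda_grid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Largest grid lambda at which each SNP's coefficient is non-zero.

    SNPs never active on the grid get ``entry = 0``.  Pass ``lambda_grid``
    to reuse one grid across tiled windows.  Also returns the number of
    active-set shrink events along the path (drops), which callers may
    log-check against the monotone-growth expectation.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if lambda_grid is None:
        lambda_grid = lasso_lambda_grid(X, y, n_lambda, lambda_min_ratio)
    alphas = np.sort(np.asarray(lambda_grid))[::-1]
    _, coefs, _ = lasso_path(X, y, alphas=alphas, copy_X=True)
    nonzero = coefs != 0.0  # p x n_lambda
    entry = np.zeros(X.shape[1])
    any_active = nonzero.any(axis=1)
    first = np.argmax(nonzero, axis=1)
    entry[any_active] = alphas[first[any_active]]
    sizes = nonzero.sum(axis=0)
    drops = int(np.sum(np.diff(sizes) < 0))
    return entry, np.array([drops, len(alphas)])


def rank_snps(
    snp_map: pd.DataFrame,
    key: np.ndarray,
    method: str,
    ascending: bool,
    unranked: np.ndarray | None = None,
) -> pd.DataFrame:
    """Deterministic method ranking; ties broken by (chrom, pos_bp, snp_id).

    ``unranked`` marks SNPs that never entered a model: they sort after all
    ranked SNPs regardless of key.
    """
    df = snp_map[["snp_id", "chrom", "pos_bp"]].copy()
    df["rank_key"] = np.asarray(key, dtype=np.float64)
    df["method"] = method
    df["_unranked"] = (
        np.asarray(unranked, dtype=bool)
        if unranked is not None
        else np.zeros(len(df), dtype=bool)
    )
    df = df.sort_values(
        ["_unranked", "rank_key", "chrom", "pos_bp", "snp_id"],
        ascending=[True, ascending, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.drop(columns="_unranked")
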