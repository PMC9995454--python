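"""Power-FDR evaluation of mapping methods at multiple resolutions.

A discovery counts as true at resolution ``x`` bp iff it lies within
``x`` bp of some causal variant on the same chromosome; power counts the
fraction of causal loci with at least one true discovery nearby, each
locus at most once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .discovery import DiscoverySet, NoDiscoveriesError

DEFAULT_RESOLUTIONS_BP = (10_000, 100_000, 125_000, 250_000, 500_000, 1_000_000)


def _nearest_causal_gap(
    chrom: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    causal_chrom: np.ndarray,
    causal_pos: np.ndarray,
) -> np.ndarray:
    """Distance from each interval [start, end] to the closest causal
    variant on the same chromosome (0 if inside; inf if none)."""
    out = np.full(len(chrom), np.inf)
    for c in np.unique(causal_chrom):
        cpos = np.sort(causal_pos[causal_chrom == c])
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0 or cpos.size == 0:
            continue
        # nearest causal to the span: check both edges and containment
        s, e = start[sel], end[sel]
        idx = np.searchsorted(cpos, s)
        left = np.where(idx > 0, s - cpos[np.maximum(idx - 1, 0)], np.inf)
        idx_e = np.searchsorted(cpos, e)
        right = np.where(idx_e < cpos.size, cpos[np.minimum(idx_e, cpos.size - 1)] - e, np.inf)
        inside = idx_e > idx  # some causal position within [s, e]
        gap = np.minimum(np.abs(left), np.abs(right))
        gap[inside] = 0.0
        out[sel] = gap
    return out


def truth_assign(
    disc: pd.DataFrame, causal: pd.DataFrame, resolution_bp: float
) -> np.ndarray:
    """Boolean labels for discoveries: true iff within ``resolution_bp`` of
    the closest causal variant on the same chromosome.

    ``disc`` needs columns ``chrom`` and ``pos_bp`` (SNPs) or
    ``start_bp``/``end_bp`` (segments; distance to the span, 0 inside).
    ``causal`` needs ``chrom`` and ``pos_bp``.
    """
    chrom = disc["chrom"].astype(str).to_numpy()
    if "pos_bp" in disc.columns:
        start = disc["pos_bp"].to_numpy(dtype=np.float64)
        end = start
    else:
        start = disc["start_bp"].to_numpy(dtype=np.float64)
        end = disc["end_bp"].to_numpy(dtype=np.float64)
    gap = _nearest_causal_gap(
        chrom,
        start,
        end,
        causal["chrom"].astype(str).to_numpy(),
        causal["pos_bp"].to_numpy(dtype=np.float64),
    )
    return gap < resolution_bp


@dataclass
class PowerFDRCurve:
    method: str
    resolution_bp: float
    table: pd.DataFrame  # columns k, power, fdp

    def __post_init__(self) -> None:
        pw = self.table["power"].to_numpy()
        if len(pw) and np.any(np.diff(pw) < -1e-12):
            raise ValueError("power must be non-decreasing in k")


def power_fdr_curve(
    ranking: pd.DataFrame,
    causal: pd.DataFrame,
    resolution_bp: float,
    max_k: int | None = None,
    method: str | None = None,
) -> PowerFDRCurve:
    """Power and false-discovery proportion of top-k sets along a ranking.

    ``ranking`` is an ordered DataFrame (best first) with ``chrom`` and
    ``pos_bp``.  Power at k = fraction of causal loci with >= 1 discovery
    within ``resolution_bp``; fdp at k = fraction of the k discoveries
    farther than ``resolution_bp`` from every causal variant.
    """
    K = len(ranking) if max_k is None else min(max_k, len(ranking))
    top = ranking.iloc[:K]
    labels = truth_assign(top, causal, resolution_bp)
    chrom = top["chrom"].astype(str).to_numpy()
    pos = top["pos_bp"].to_numpy(dtype=np.float64)
    c_chrom = causal["chrom"].astype(str).to_numpy()
    c_pos = causal["pos_bp"].to_numpy(dtype=np.float64)
    n_causal = len(causal)
    recovered = np.zeros(n_causal, dtype=bool)
    power = np.empty(K)
    n_rec = 0
    by_chrom = {c: np.flatnonzero(c_chrom == c) for c in np.unique(c_chrom)}
    for k in range(K):
        idx = by_chrom.get(chrom[k])
        if idx is not None:
            near = idx[np.abs(c_pos[idx] - pos[k]) < resolution_bp]
            for ci in near:
                if not recovered[ci]:
                    recovered[ci] = True
                    n_rec += 1
        power[k] = n_rec / max(n_causal, 1)
    fdp = np.cumsum(~labels) / np.arange(1, K + 1)
    table = pd.DataFrame({"k": np.arange(1, K + 1), "power": power, "fdp": fdp})
    return PowerFDRCurve(
        method=method or str(ranking.get("method", pd.Series(["?"])).iloc[0]),
        resolution_bp=float(resolution_bp),
        table=table,
    )


def empirical_fdr_of_rule(
    dset: DiscoverySet | pd.DataFrame, causal: pd.DataFrame, resolution_bp: float
) -> tuple[float, int]:
    """Fraction of a fixed rule's discoveries that are false at a resolution.

    Accepts a :class:`DiscoverySet` (segments judged by their span) or any
    DataFrame ``truth_assign`` understands.  Raises
    :class:`NoDiscoveriesError` on an empty set.
    """
    frame = dset.to_frame() if isinstance(dset, DiscoverySet) else dset
    if len(frame) == 0:
        raise NoDiscoveriesError("empty discovery set: FDR undefined")
    labels = truth_assign(frame, causal, resolution_bp)
    return float(1.0 - labels.mean()), int(len(frame))


def aggregate_replicates(tables: list[pd.DataFrame], keys: list[str]) -> pd.DataFrame:
    """Mean over replicate result tables with the replicate count attached."""
    stacked = pd.concat(tables, ignore_index=True)
    out = stacked.groupby(keys, as_index=False).mean(numeric_only=True)
    counts = stacked.groupby(keys, as_index=False).size()
    return out.merge(counts.rename(columns={"size": "n_replicates"}), on=keys)
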