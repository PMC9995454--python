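"""Bayesian FDR decision rules and discovery sets.

Given posterior inclusion probabilities (PIPs), the local FDR of SNP j is
``1 - PIP_j`` and the Bayesian FDR of the decision rule "reject when
PIP > tau" is the average local FDR over the discovery set:

    BFDR(tau) = 1 - (1 / p_tau) * sum_{j: PIP_j > tau} PIP_j

Discovery sets mix individual SNPs with short segments: in high-LD
regions several SNPs may share an elevated but sub-threshold PIP, while
the posterior probability that *at least one* of them is active (the
segment probability) is high enough to clear the same BFDR level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class NoDiscoveriesError(ValueError):
    """Raised when a rule selects nothing and the quantity is undefined."""


@dataclass
class DiscoveryItem:
    kind: str  # "snp" | "segment"
    chrom: str
    start_bp: int
    end_bp: int
    snp_ids: list[str]
    probability: float
    snp_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability outside [0, 1]")
        if self.kind == "segment" and len(self.snp_ids) < 2:
            raise ValueError("segments must contain at least 2 SNPs")


@dataclass
class DiscoverySet:
    items: list[DiscoveryItem]
    set_bfdr: float = np.nan

    def __post_init__(self) -> None:
        if self.items:
            self.set_bfdr = 1.0 - float(
                np.mean([it.probability for it in self.items])
            )

    def __len__(self) -> int:
        return len(self.items)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": it.kind,
                    "chrom": it.chrom,
                    "start_bp": it.start_bp,
                    "end_bp": it.end_bp,
                    "n_snps": len(it.snp_ids),
                    "snp_ids": ",".join(it.snp_ids),
                    "probability": it.probability,
                }
                for it in self.items
            ],
            columns=[
                "kind",
                "chrom",
                "start_bp",
                "end_bp",
                "n_snps",
                "snp_ids",
                "probability",
            ],
        )


def bfdr(pips: np.ndarray, tau: float) -> float:
    """Bayesian FDR of the rule "select SNPs with PIP > tau"."""
    pips = np.asarray(pips, dtype=np.float64)
    sel = pips > tau
    if not sel.any():
        raise NoDiscoveriesError(f"no PIP exceeds tau = {tau}")
    return float(1.0 - pips[sel].mean())


def _snp_items(pips, snp_map, indices) -> list[DiscoveryItem]:
    items = []
    for j in indices:
        row = snp_map.iloc[j]
        items.append(
            DiscoveryItem(
                kind="snp",
                chrom=str(row["chrom"]),
                start_bp=int(row["pos_bp"]),
                end_bp=int(row["pos_bp"]),
                snp_ids=[str(row["snp_id"])],
                probability=float(pips[j]),
                snp_indices=[int(j)],
            )
        )
    return items


def select_by_bfdr(
    pips: np.ndarray, level: float, snp_map: pd.DataFrame | None = None
) -> DiscoverySet:
    """Largest PIP-threshold discovery set whose BFDR is <= ``level``.

    The threshold tau is chosen as the smallest value on the sorted-PIP
    grid with BFDR(tau) <= level (BFDR is non-increasing in tau, so this
    yields the most inclusive admissible set).  An empty set is a valid
    outcome.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    pips = np.nan_to_num(np.asarray(pips, dtype=np.float64), nan=0.0)
    grid = np.unique(pips)
    taus = np.concatenate([[grid[0] - 1.0 if grid[0] <= 0 else 0.0], grid])
    taus = np.unique(taus[taus < pips.max()]) if pips.max() > 0 else np.array([])
    chosen_tau = None
    for tau in np.sort(taus):
        if bfdr(pips, tau) <= level:
            chosen_tau = float(tau)
            break
    if chosen_tau is None:
        return DiscoverySet(items=[])
    idx = np.flatnonzero(pips > chosen_tau)
    if snp_map is None:
        snp_map = pd.DataFrame(
            {
                "snp_id": [f"snp_{j}" for j in range(len(pips))],
                "chrom": "1",
                "pos_bp": np.arange(1, len(pips) + 1),
            }
        )
    return DiscoverySet(items=_snp_items(pips, snp_map, idx))


def segment_probability(delta_draws: np.ndarray, lo: int, hi: int) -> float:
    """Fraction of draws in which any SNP in [lo, hi) is active."""
    if hi <= lo:
        raise ValueError("empty SNP range")
    d = np.asarray(delta_draws, dtype=bool)
    return float(np.any(d[:, lo:hi], axis=1).mean())


def candidate_segments(
    pips: np.ndarray,
    snp_map: pd.DataFrame,
    exclude: set[int],
    pip_floor: float,
    max_span_bp: int,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive non-selected SNPs with PIP >= floor,
    split greedily so each segment spans at most ``max_span_bp`` and holds
    at least 2 SNPs.  Returns half-open index ranges."""
    pips = np.nan_to_num(np.asarray(pips, dtype=np.float64), nan=0.0)
    chrom = snp_map["chrom"].to_numpy()
    pos = snp_map["pos_bp"].to_numpy()
    eligible = pips >= pip_floor
    for j in exclude:
        eligible[j] = False
    runs: list[tuple[int, int]] = []
    j = 0
    p = len(pips)
    while j < p:
        if not eligible[j]:
            j += 1
            continue
        k = j
        while k + 1 < p and eligible[k + 1] and chrom[k + 1] == chrom[j]:
            k += 1
        # greedy bp-span split of run [j, k]
        s = j
        while s <= k:
            e = s
            while e + 1 <= k and pos[e + 1] - pos[s] <= max_span_bp:
                e += 1
            if e > s:
                runs.append((s, e + 1))
            s = e + 1
        j = k + 1
    return runs


def elevated_segments(
    summary,
    draws_provider,
    snp_map: pd.DataFrame,
    level: float,
    pip_floor: float = 0.05,
    max_span_bp: int = 100_000,
) -> DiscoverySet:
    """SNP-level BFDR selection augmented with short high-LD segments.

    Candidate segments (runs of left-over SNPs with elevated PIP) are
    scored by their segment probability and admitted greedily in
    decreasing probability order as long as the combined set's BFDR
    (1 - mean item probability) stays within ``level``.

    ``draws_provider`` needs a ``segment_probability(lo, hi)`` method
    (a :class:`~bvsmap.tiling.TiledResult`) or is a draws x p indicator
    matrix.
    """
    pips = np.nan_to_num(np.asarray(summary.pip, dtype=np.float64), nan=0.0)
    snp_set = select_by_bfdr(pips, level, snp_map)
    selected = {j for it in snp_set.items for j in it.snp_indices}
    cands = candidate_segments(pips, snp_map, selected, pip_floor, max_span_bp)
    if hasattr(draws_provider, "segment_probability"):
        seg_prob = draws_provider.segment_probability
    else:
        dmat = np.asarray(draws_provider, dtype=bool)
        seg_prob = lambda lo, hi: segment_probability(dmat, lo, hi)  # noqa: E731

    scored = []
    for lo, hi in cands:
        try:
            prob = seg_prob(lo, hi)
        except ValueError:
            continue
        scored.append((prob, lo, hi))
    scored.sort(key=lambda t: (-t[0], t[1]))

    items = list(snp_set.items)
    probs = [it.probability for it in items]
    for prob, lo, hi in scored:
        new_probs = probs + [prob]
        if 1.0 - float(np.mean(new_probs)) <= level:
            rows = snp_map.iloc[lo:hi]
            items.append(
                DiscoveryItem(
                    kind="segment",
                    chrom=str(rows["chrom"].iloc[0]),
                    start_bp=int(rows["pos_bp"].iloc[0]),
                    end_bp=int(rows["pos_bp"].iloc[-1]),
                    snp_ids=[str(s) for s in rows["snp_id"]],
                    probability=float(prob),
                    snp_indices=list(range(lo, hi)),
                )
            )
            probs = new_probs
    return DiscoverySet(items=items)
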