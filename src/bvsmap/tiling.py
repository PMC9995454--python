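"""Overlapping local regressions: window planning and genome-wide stitching.

Whole-genome variable selection is made tractable by fitting windows of
contiguous SNPs (default 7000) whose flanks (default 2000 SNPs each side)
absorb cross-window LD; only results from each window's core are retained.
Window starts step by the core size so cores tile every chromosome exactly
once with no gaps.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesc import MCMCConfig, PosteriorDraws, PosteriorSummary, gibbs_bayesc, summarize
from .geno_io import GenotypeDataset

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """Half-open global SNP-index spans; core lies inside the window."""

    chrom: str
    start: int
    end: int
    core_start: int
    core_end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.core_start < self.core_end <= self.end):
            raise ValueError(f"core not inside window: {self}")


@dataclass
class WindowPlan:
    windows: list[Window]
    n_snps: int

    def validate(self) -> None:
        """Assert cores are disjoint and jointly cover every SNP exactly once."""
        covered = np.zeros(self.n_snps, dtype=np.int32)
        for w in self.windows:
            covered[w.core_start : w.core_end] += 1
        if not np.all(covered == 1):
            bad = np.flatnonzero(covered != 1)
            raise ValueError(
                f"cores do not partition the SNP set (first bad index {bad[0]}, "
                f"count {covered[bad[0]]})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": w.chrom,
                    "window_start": w.start,
                    "window_end": w.end,
                    "core_start": w.core_start,
                    "core_end": w.core_end,
                }
                for w in self.windows
            ]
        )


def make_windows(
    snp_map: pd.DataFrame, window_size: int = 7000, flank: int = 2000
) -> WindowPlan:
    """Plan overlapping windows per chromosome in SNP-index space.

    Interior windows hold ``window_size`` SNPs with a core of
    ``window_size - 2 * flank``; the first core extends to the chromosome
    start, the last to its end.  Chromosomes shorter than ``window_size``
    become one whole-chromosome window.
    """
    if 2 * flank >= window_size:
        raise ValueError(
            f"2*flank ({2 * flank}) must be < window_size ({window_size})"
        )
    core = window_size - 2 * flank
    windows: list[Window] = []
    # contiguous chromosome blocks in map order
    offset = 0
    for chrom, grp in snp_map.groupby("chrom", sort=False):
        m = len(grp)
        base = offset
        offset += m
        if m <= window_size:
            windows.append(Window(str(chrom), base, base + m, base, base + m))
            continue
        n_cores = max(1, int(np.ceil((m - 2 * flank) / core)))
        bounds = [0]
        for i in range(1, n_cores):
            bounds.append(flank + i * core)
        bounds.append(m)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            w_lo = max(0, lo - flank)
            w_hi = min(m, hi + flank)
            windows.append(
                Window(str(chrom), base + w_lo, base + w_hi, base + lo, base + hi)
            )
    plan = WindowPlan(windows=windows, n_snps=len(snp_map))
    plan.validate()
    return plan


def window_seed(base_seed: int, window: Window) -> int:
    """Stable per-window seed so results are independent of execution order."""
    key = f"{window.chrom}:{window.start}-{window.end}".encode()
    return (int(base_seed) ^ zlib.crc32(key)) & 0x7FFFFFFF


@dataclass
class TiledResult:
    """Genome-wide stitched summary plus per-window draws for segment queries."""

    summary: PosteriorSummary
    plan: WindowPlan
    window_draws: list[PosteriorDraws | None]
    failed_windows: list[int] = field(default_factory=list)

    def window_for_range(self, lo: int, hi: int) -> tuple[int, Window] | None:
        """Window whose span contains [lo, hi) and whose core holds >= 1 member."""
        for i, w in enumerate(self.plan.windows):
            if w.start <= lo and hi <= w.end and not (
                hi <= w.core_start or lo >= w.core_end
            ):
                if self.window_draws[i] is not None:
                    return i, w
        return None

    def segment_probability(self, lo: int, hi: int) -> float:
        """Posterior probability that any SNP in [lo, hi) is active.

        Uses the draws of the single window containing the whole range;
        short segments always fit because flanks exceed any admissible
        segment length in SNP terms.
        """
        found = self.window_for_range(lo, hi)
        if found is None:
            raise ValueError(
                f"no fitted window fully contains SNP range [{lo}, {hi})"
            )
        i, w = found
        draws = self.window_draws[i]
        deltas = draws.delta_matrix()[:, lo - w.start : hi - w.start]
        return float(np.any(deltas, axis=1).mean())


def run_tiled(
    ds: GenotypeDataset,
    y: np.ndarray,
    plan: WindowPlan | None = None,
    fit=gibbs_bayesc,
    prior=None,
    cfg: MCMCConfig | None = None,
    keep_draws: bool = True,
) -> TiledResult:
    """Fit every window independently and stitch core results genome-wide.

    Each window sees the full adjusted phenotype and its own centered slice
    of dosages.  A failing window is logged and its core SNPs flagged NaN;
    the rest of the genome is unaffected.
    """
    plan = plan or make_windows(ds.snp_map)
    plan.validate()
    cfg = cfg or MCMCConfig()
    p = ds.n_snps
    pip = np.full(p, np.nan)
    post_mean = np.full(p, np.nan)
    window_draws: list[PosteriorDraws | None] = []
    failed: list[int] = []
    for i, w in enumerate(plan.windows):
        Xw = ds.dosages[:, w.start : w.end]
        Xw = Xw - Xw.mean(axis=0)
        wcfg = MCMCConfig(
            n_iter=cfg.n_iter,
            burn_in=cfg.burn_in,
            thin=cfg.thin,
            seed=window_seed(cfg.seed, w),
            update_order=cfg.update_order,
        )
        try:
            draws = fit(Xw, y, prior=prior, cfg=wcfg)
            summ = summarize(draws)
        except Exception:  # noqa: BLE001 - fault isolation per window
            log.exception("window %d (%s:%d-%d) failed", i, w.chrom, w.start, w.end)
            failed.append(i)
            window_draws.append(None)
            continue
        lo, hi = w.core_start - w.start, w.core_end - w.start
        pip[w.core_start : w.core_end] = summ.pip[lo:hi]
        post_mean[w.core_start : w.core_end] = summ.post_mean_beta[lo:hi]
        window_draws.append(draws if keep_draws else None)
    summary = PosteriorSummary(
        pip=pip, post_mean_beta=post_mean, snp_ids=ds.snp_map["snp_id"].to_numpy()
    )
    return TiledResult(
        summary=summary, plan=plan, window_draws=window_draws, failed_windows=failed
    )
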