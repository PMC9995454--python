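"""LD-structured genotype and complex-trait simulation.

Genotypes come from a founder-mosaic copying model: ``K`` founder haplotypes
are drawn with a U-shaped allele-frequency spectrum, and every sample
haplotype is a mosaic of founders, switching between adjacent SNPs at
distance ``d`` bp with probability ``1 - exp(-rho * d)``.  Small ``rho``
gives long-range linkage disequilibrium (LD); large ``rho`` approaches
linkage equilibrium.  Dosage is the sum of two independent haplotypes.

Founder haplotypes themselves are autocorrelated along the chromosome
(latent Gaussian AR(1) thresholded at each SNP's allele frequency), as
real ancestral haplotypes are; with mutually independent founder alleles
the population r^2 could never exceed ~1/K at any distance.  Both the
founder autocorrelation and the mosaic switching decay at rate ``rho``,
so a single parameter sets the LD range.

Traits are additive: a chosen number of causal SNPs receive Gaussian
effects, the genetic score is rescaled to explain a target heritability
``h2`` of the (unit) phenotypic variance, and Gaussian noise supplies the
rest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeDataset


@dataclass
class SimulationScenario:
    """Parameters of one synthetic panel + trait draw.

    ``rho`` (per bp) controls LD decay: between-SNP founder-switch
    probability over ``d`` bp is ``1 - exp(-rho * d)``.  The default is
    calibrated so mean r^2 falls to ~0.1 by ~300 kbp, emulating panels in
    which marginal association signals stretch far beyond the causal site.
    """

    n_samples: int = 6000
    n_snps: int = 6000
    n_causal: int = 20
    h2: float = 0.5
    n_founders: int = 20
    rho: float = 1e-6
    mean_spacing_bp: float = 2000.0
    maf_floor: float = 0.001
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founder haplotypes")
        if self.rho <= 0:
            raise ValueError("rho must be positive")


@dataclass
class SimulatedTrait:
    y: np.ndarray
    causal_indices: np.ndarray
    causal_effects: np.ndarray
    realized_h2: float
    h2_target: float = field(default=np.nan)

    def truth_table(self, snp_map: pd.DataFrame) -> pd.DataFrame:
        """Causal-variant ground truth joined to map positions."""
        rows = snp_map.iloc[self.causal_indices]
        return pd.DataFrame(
            {
                "snp_id": rows["snp_id"].to_numpy(),
                "chrom": rows["chrom"].to_numpy(),
                "pos_bp": rows["pos_bp"].to_numpy(),
                "effect": self.causal_effects,
            }
        )


def _u_shaped_freqs(p: int, maf_floor: float, rng: np.random.Generator) -> np.ndarray:
    """Beta(0.3, 0.3) frequencies truncated to MAF >= maf_floor (rejection)."""
    freqs = np.empty(p)
    filled = 0
    while filled < p:
        cand = rng.beta(0.3, 0.3, size=2 * (p - filled) + 16)
        ok = np.minimum(cand, 1 - cand) >= maf_floor
        take = cand[ok][: p - filled]
        freqs[filled : filled + take.size] = take
        filled += take.size
    return freqs


def simulate_genotypes(scn: SimulationScenario) -> GenotypeDataset:
    """Generate a founder-mosaic dosage panel; deterministic given the seed."""
    rng = np.random.default_rng(scn.seed)
    p, n, K = scn.n_snps, scn.n_samples, scn.n_founders

    freqs = _u_shaped_freqs(p, scn.maf_floor, rng)
    spacing = rng.exponential(scn.mean_spacing_bp, size=p)
    pos = 1 + np.cumsum(np.maximum(1, np.round(spacing))).astype(np.int64)
    gaps = np.diff(pos).astype(np.float64)

    # Founder haplotypes: latent AR(1) per founder, thresholded so SNP j's
    # founder-pool allele frequency targets freqs[j].
    a = np.exp(-scn.rho * gaps)
    z = np.empty((K, p))
    z[:, 0] = rng.standard_normal(K)
    innov = rng.standard_normal((K, p))
    for j in range(1, p):
        z[:, j] = a[j - 1] * z[:, j - 1] + np.sqrt(1.0 - a[j - 1] ** 2) * innov[:, j]
    founders = (z < stats.norm.ppf(freqs)[None, :]).astype(np.int8)

    # per-interval switch probability; first column always "switches"
    switch_p = np.empty(p)
    switch_p[0] = 1.0
    switch_p[1:] = 1.0 - np.exp(-scn.rho * gaps)

    n_hap = 2 * n
    dosages = np.empty((n, p), dtype=np.float64)
    cols = np.arange(p)
    chunk = max(2, (1 << 24) // max(p, 1) // 2 * 2)  # even haplotype chunks
    for lo in range(0, n_hap, chunk):
        hi = min(n_hap, lo + chunk)
        c = hi - lo
        switched = rng.random((c, p)) < switch_p
        switched[:, 0] = True
        new_founder = rng.integers(0, K, size=(c, p))
        last = np.maximum.accumulate(np.where(switched, cols, 0), axis=1)
        path = np.take_along_axis(new_founder, last, axis=1)
        alleles = founders[path, cols]
        # haplotypes 2i, 2i+1 belong to sample i
        pair = alleles.reshape(c // 2, 2, p).sum(axis=1)
        dosages[lo // 2 : hi // 2] = pair

    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp_{j}" for j in range(p)],
            "chrom": scn.chrom,
            "pos_bp": pos,
            "allele_ref": "A",
            "allele_alt": "B",
        }
    )
    return GenotypeDataset(dosages, snp_map)


def simulate_trait(
    ds: GenotypeDataset, n_causal: int, h2: float, seed: int
) -> SimulatedTrait:
    """Draw an additive trait with ``n_causal`` causal SNPs at heritability h2.

    Causal SNPs are sampled uniformly among polymorphic columns; raw effects
    are i.i.d. standard normal, the genetic score is rescaled so its sample
    variance equals ``h2``, noise variance is ``1 - h2``, and y is
    standardized to unit variance.  Returned effects are on the final y
    scale, so ``y ≈ X[:, causal] @ effects + noise``.
    """
    if not 0.0 <= h2 <= 1.0:
        raise ValueError(f"h2 must be in [0, 1], got {h2}")
    rng = np.random.default_rng(seed)
    X = ds.dosages
    n = X.shape[0]
    poly = np.flatnonzero(X.std(axis=0) > 0)
    if poly.size < n_causal:
        raise ValueError(
            f"only {poly.size} polymorphic SNPs; cannot place {n_causal} causals"
        )
    causal = np.sort(rng.choice(poly, size=n_causal, replace=False))
    beta = rng.standard_normal(n_causal)

    if n_causal > 0 and h2 > 0:
        g = X[:, causal] @ beta
        g = g - g.mean()
        sd_g = g.std()
        if sd_g == 0:
            raise ValueError("degenerate genetic score (zero variance)")
        scale = np.sqrt(h2) / sd_g
        g = g * scale
        beta = beta * scale
    else:
        g = np.zeros(n)
        beta = np.zeros(n_causal)

    eps = rng.normal(0.0, np.sqrt(max(1.0 - h2, 0.0)), size=n) if h2 < 1 else np.zeros(n)
    y = g + eps
    sd_y = y.std()
    if sd_y > 0:
        y = (y - y.mean()) / sd_y
        beta = beta / sd_y
        g = g / sd_y
    realized = float(g.var() / y.var()) if y.var() > 0 else 0.0
    return SimulatedTrait(
        y=y,
        causal_indices=causal,
        causal_effects=beta,
        realized_h2=realized,
        h2_target=h2,
    )


def mean_r2_by_distance(
    ds: GenotypeDataset,
    bins_bp: np.ndarray,
    max_pairs_per_snp: int = 200,
) -> pd.DataFrame:
    """Empirical LD-decay curve: mean pairwise r^2 in distance bins.

    For each SNP, correlations with up to ``max_pairs_per_snp`` following
    SNPs are accumulated into ``bins_bp`` (right edges) by pair distance.
    """
    X = ds.dosages
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    keep = sd > 0
    Z = Xc[:, keep] / (sd[keep] * np.sqrt(X.shape[0]))
    pos = ds.snp_map.loc[keep, "pos_bp"].to_numpy()
    p = Z.shape[1]
    edges = np.asarray(bins_bp, dtype=float)
    sums = np.zeros(len(edges))
    counts = np.zeros(len(edges), dtype=np.int64)
    max_d = edges[-1]
    for j in range(p - 1):
        hi = min(p, j + 1 + max_pairs_per_snp)
        dist = pos[j + 1 : hi] - pos[j]
        sel = dist <= max_d
        if not sel.any():
            continue
        r = Z[:, j + 1 : hi][:, sel].T @ Z[:, j]
        b = np.searchsorted(edges, dist[sel])
        np.add.at(sums, b, r * r)
        np.add.at(counts, b, 1)
    with np.errstate(invalid="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return pd.DataFrame(
        {"bin_right_bp": edges, "mean_r2": mean_r2, "n_pairs": counts}
    )


def ld_range_bp(ds: GenotypeDataset, threshold: float = 0.1, max_bp: float = 2e6) -> float:
    """Distance at which binned mean r^2 first falls below ``threshold``."""
    edges = np.linspace(max_bp / 40, max_bp, 40)
    curve = mean_r2_by_distance(ds, edges)
    ok = curve["n_pairs"].to_numpy() > 0
    below = curve.loc[ok & (curve["mean_r2"] < threshold), "bin_right_bp"]
    return float(below.iloc[0]) if len(below) else float("inf")
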