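"""Genotype/phenotype I/O, quality-control filters, and discovery export.

Genotypes are held as an ``n x p`` dosage matrix (allele counts in ``[0, 2]``,
``NaN`` for missing) together with a SNP map — a :class:`pandas.DataFrame`
with columns ``snp_id``, ``chrom``, ``pos_bp`` (1-based physical position),
``allele_ref`` and ``allele_alt``.  The counted allele is ``allele_alt``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SNP_MAP_COLUMNS = ["snp_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]

_BED_MAGIC = bytes([0x6C, 0x1B])
# 2-bit PLINK codes (low bits first sample): 0b00 hom A1, 0b01 missing,
# 0b10 het, 0b11 hom A2.  Dosage counts the A1 allele.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


class GenotypeError(ValueError):
    """Raised for malformed or mutually inconsistent genotype inputs."""


def _validate_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise GenotypeError(f"SNP map missing columns: {missing}")
    if snp_map["snp_id"].duplicated().any():
        dups = snp_map.loc[snp_map["snp_id"].duplicated(), "snp_id"].tolist()
        raise GenotypeError(f"duplicate snp_id values: {dups[:5]}")
    if (snp_map["pos_bp"] < 1).any():
        raise GenotypeError("pos_bp must be >= 1 (1-based coordinates)")
    for _, grp in snp_map.groupby("chrom", sort=False):
        if not grp["pos_bp"].is_monotonic_increasing:
            raise GenotypeError("SNP map must be position-sorted within chromosome")
    return snp_map.reset_index(drop=True)


@dataclass
class GenotypeDataset:
    """Dosage matrix plus SNP map and sample identifiers.

    Parameters
    ----------
    dosages
        ``n x p`` float array of alternate-allele counts; ``NaN`` marks a
        missing genotype (allowed before filtering).
    snp_map
        DataFrame of length ``p`` with :data:`SNP_MAP_COLUMNS`.
    sample_ids
        Length-``n`` array of sample identifiers.
    """

    dosages: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise GenotypeError("dosages must be a 2-D matrix")
        self.snp_map = _validate_snp_map(pd.DataFrame(self.snp_map))
        if self.dosages.shape[1] != len(self.snp_map):
            raise GenotypeError(
                f"dosage columns ({self.dosages.shape[1]}) != SNP map length "
                f"({len(self.snp_map)})"
            )
        if self.sample_ids is None:
            self.sample_ids = np.array(
                [f"sample_{i}" for i in range(self.dosages.shape[0])]
            )
        self.sample_ids = np.asarray(self.sample_ids)
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise GenotypeError("sample_ids length != number of dosage rows")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def take_snps(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset columns by integer index, keeping order."""
        return GenotypeDataset(
            self.dosages[:, index],
            self.snp_map.iloc[index].reset_index(drop=True),
            self.sample_ids,
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            self.dosages[index, :], self.snp_map.copy(), self.sample_ids[index]
        )

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP (missing values ignored)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)


@dataclass
class PhenotypeTable:
    """Phenotype vector with optional covariates (sex, age, center, PCs...)."""

    y: np.ndarray
    covariates: np.ndarray | None = None
    sample_ids: np.ndarray | None = None
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if self.covariates.shape[0] != self.y.shape[0]:
                raise GenotypeError("covariate rows != phenotype length")


def read_plink(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK v1.00 SNP-major BED/BIM/FAM triple.

    Dosages count the BIM A1 allele (``allele_alt``); missing genotypes are
    kept as ``NaN``, never imputed here.
    """
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None, dtype=str)
    n, p = len(fam), len(bim)
    with open(bed_path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise GenotypeError(f"{bed_path}: not a PLINK BED file (bad magic bytes)")
    if raw[2] != 0x01:
        raise GenotypeError(f"{bed_path}: only SNP-major BED (mode 0x01) supported")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * p:
        raise GenotypeError(
            f"BED payload of {body.size} bytes inconsistent with FAM n={n} "
            f"and BIM p={p} (expected {bytes_per_snp * p})"
        )
    # expand each byte into 4 two-bit codes, sample index fastest
    codes = body.reshape(p, bytes_per_snp)
    expanded = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        expanded[:, k::4] = (codes >> (2 * k)) & 0b11
    dosages = _BED_DECODE[expanded[:, :n]].T
    snp_map = pd.DataFrame(
        {
            "snp_id": bim["snp_id"],
            "chrom": bim["chrom"],
            "pos_bp": bim["pos_bp"].astype(np.int64),
            "allele_ref": bim["a2"],
            "allele_alt": bim["a1"],
        }
    )
    return GenotypeDataset(dosages, snp_map, fam.iloc[:, 1].to_numpy())


def read_phenotype_table(
    path, sample_id_col: str = "sample_id", y_col: str = "y"
) -> PhenotypeTable:
    """Read a TSV with header: sample-id column, phenotype column, covariates."""
    tab = pd.read_csv(path, sep="\t", dtype={sample_id_col: str})
    for col in (sample_id_col, y_col):
        if col not in tab.columns:
            raise GenotypeError(f"{path}: missing column {col!r}")
    cov_cols = [c for c in tab.columns if c not in (sample_id_col, y_col)]
    cov = tab[cov_cols].to_numpy(dtype=np.float64) if cov_cols else None
    return PhenotypeTable(
        y=tab[y_col].to_numpy(dtype=np.float64),
        covariates=cov,
        sample_ids=tab[sample_id_col].to_numpy(),
        covariate_names=cov_cols or None,
    )


def filter_variants(
    ds: GenotypeDataset, maf_min: float = 0.001, call_rate_min: float = 0.95
) -> GenotypeDataset:
    """Drop SNPs failing MAF/call-rate thresholds; mean-impute survivors.

    Retains SNPs with MAF strictly above ``maf_min`` and call rate strictly
    above ``call_rate_min``.  Missing dosages in retained SNPs are replaced
    by the per-SNP mean so downstream matrices are dense.
    """
    if ds.n_snps == 0:
        raise GenotypeError("empty dataset")
    keep = (ds.maf() > maf_min) & (ds.call_rate() > call_rate_min)
    if not keep.any():
        raise GenotypeError("all SNPs removed by QC filters")
    out = ds.take_snps(np.flatnonzero(keep))
    X = out.dosages
    nan_mask = np.isnan(X)
    if nan_mask.any():
        col_means = np.nanmean(X, axis=0)
        X[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    return out


def ld_prune(
    ds: GenotypeDataset, r2_max: float = 0.9, window_snps: int = 1000
) -> GenotypeDataset:
    """Greedy left-to-right LD pruning within a sliding SNP-index window.

    The later SNP of any within-window pair with squared Pearson correlation
    >= ``r2_max`` is dropped, so every retained within-window pair has
    r^2 < ``r2_max``.
    """
    X = ds.dosages
    if np.isnan(X).any():
        raise GenotypeError("ld_prune requires no missing dosages (filter first)")
    Xc = X - X.mean(axis=0)
    norms = np.sqrt(np.einsum("ij,ij->j", Xc, Xc))
    if (norms == 0).any():
        bad = np.flatnonzero(norms == 0)
        raise GenotypeError(f"zero-variance SNPs at columns {bad[:5].tolist()}; filter first")
    Z = Xc / norms
    kept: list[int] = []
    chrom = ds.snp_map["chrom"].to_numpy()
    for j in range(ds.n_snps):
        window = [
            i for i in kept if j - i < window_snps and chrom[i] == chrom[j]
        ]
        if window:
            r = Z[:, window].T @ Z[:, j]
            if np.any(r * r >= r2_max):
                continue
        kept.append(j)
    return ds.take_snps(np.array(kept, dtype=np.intp))


def adjust_phenotype(pt: PhenotypeTable) -> np.ndarray:
    """OLS residuals of y on intercept + covariates (mean-centered output)."""
    y = pt.y
    if pt.covariates is None:
        return y - y.mean()
    n = y.shape[0]
    design = np.column_stack([np.ones(n), pt.covariates])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify offending columns via rank growth under QR
        names = pt.covariate_names or [f"cov_{i}" for i in range(pt.covariates.shape[1])]
        collinear = []
        base = np.ones((n, 1))
        for i in range(pt.covariates.shape[1]):
            cand = np.column_stack([base, pt.covariates[:, i]])
            if np.linalg.matrix_rank(cand) == base.shape[1]:
                collinear.append(names[i])
            else:
                base = cand
        raise GenotypeError(
            f"covariate design rank-deficient (rank {rank} < {design.shape[1]}); "
            f"collinear columns: {collinear}"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return resid - resid.mean()


def write_discoveries(dset, path) -> None:
    """Write a discovery set as BED5 (0-based half-open; score = probability).

    Single SNPs become 1-bp intervals ``[pos-1, pos)``; segments span from
    the first member's ``pos-1`` to the last member's ``pos``.
    """
    with open(path, "w") as fh:
        for item in dset.items:
            start = item.start_bp - 1
            end = item.end_bp
            name = item.snp_ids[0] if item.kind == "snp" else (
                f"{item.snp_ids[0]}..{item.snp_ids[-1]}"
            )
            fh.write(
                f"{item.chrom}\t{start}\t{end}\t{name}\t{item.probability:.6g}\n"
            )


def write_plink(ds: GenotypeDataset, prefix: str) -> None:
    """Write a dataset as PLINK BED/BIM/FAM (hard-call dosages only)."""
    X = ds.dosages
    n, p = X.shape
    code = np.full(X.shape, 1, dtype=np.uint8)  # 0b01 missing
    code[X == 2] = 0b00
    code[X == 1] = 0b10
    code[X == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.full((p, bytes_per_snp * 4), 0b11, dtype=np.uint8)
    padded[:, :n] = code.T
    packed = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())
    m = ds.snp_map
    bim = pd.DataFrame(
        {
            "chrom": m["chrom"],
            "snp_id": m["snp_id"],
            "cm": 0,
            "pos_bp": m["pos_bp"],
            "a1": m["allele_alt"],
            "a2": m["allele_ref"],
        }
    )
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": ds.sample_ids,
            "iid": ds.sample_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "phen": -9,
        }
    )
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
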