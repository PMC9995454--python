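"""Polygenic risk score construction and held-out evaluation.

Three strategies, mirroring the mapping pipeline:

1. ``smr``: weights are marginal OLS effects of GWAS-significant SNPs
   (p below a threshold).  Ignores LD, so clusters of correlated
   significant SNPs double-count signal.
2. ``bayesc_on_selected``: the same significance-based selection, but the
   selected SNPs are refit jointly with the spike-slab model and weighted
   by their posterior-mean effects.
3. ``wholegenome_bayesc``: posterior-mean effects from the tiled
   whole-genome fit, keeping SNPs with PIP above a small floor (1/1000 by
   default) to keep the score sparse.

Scoring always centers test dosages at the *training* allele means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayesc import BayesCPrior, MCMCConfig, gibbs_bayesc, summarize
from .geno_io import GenotypeDataset


@dataclass
class PRSModel:
    provenance: str  # "smr" | "bayesc_on_selected" | "wholegenome_bayesc"
    weights: pd.Series  # snp_id -> effect
    train_means: pd.Series  # snp_id -> training mean dosage
    selection: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights.to_numpy(dtype=float))) and len(self.weights):
            raise ValueError("non-finite PRS weights")

    def __len__(self) -> int:
        return len(self.weights)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.weights.index,
                "weight": self.weights.to_numpy(),
                "train_mean": self.train_means.reindex(self.weights.index).to_numpy(),
                "provenance": self.provenance,
            }
        )


def prs_from_smr(scan: pd.DataFrame, p_thresh: float) -> PRSModel:
    """Marginal-effect PRS from SNPs with SMR p-value below ``p_thresh``."""
    sel = scan.loc[scan["p_value"] < p_thresh]
    return PRSModel(
        provenance="smr",
        weights=pd.Series(sel["beta_hat"].to_numpy(), index=sel["snp_id"]),
        train_means=pd.Series(sel["mean_dosage"].to_numpy(), index=sel["snp_id"]),
        selection={"p_thresh": p_thresh},
    )


def prs_bayesc_reestimate(
    ds_train: GenotypeDataset,
    y_train: np.ndarray,
    selected_snp_ids,
    prior: BayesCPrior | None = None,
    cfg: MCMCConfig | None = None,
) -> PRSModel:
    """Joint spike-slab refit of a pre-selected SNP set.

    Weights are posterior-mean effects; SNPs shrunk to (near) zero keep
    their zero weight, which is what protects against the double counting
    of LD-shared signal in the marginal-effect PRS.
    """
    ids = list(selected_snp_ids)
    if len(ids) == 0:
        raise ValueError("empty SNP selection")
    idx = ds_train.snp_map.set_index("snp_id").index.get_indexer(ids)
    if (idx < 0).any():
        missing = [i for i, v in zip(ids, idx) if v < 0]
        raise KeyError(f"selected SNPs absent from training map: {missing[:5]}")
    X = ds_train.dosages[:, idx]
    means = X.mean(axis=0)
    Xc = X - means
    y = np.asarray(y_train, dtype=np.float64)
    yc = y - y.mean()
    draws = gibbs_bayesc(Xc, yc, prior=prior, cfg=cfg or MCMCConfig())
    summ = summarize(draws)
    return PRSModel(
        provenance="bayesc_on_selected",
        weights=pd.Series(summ.post_mean_beta, index=ids),
        train_means=pd.Series(means, index=ids),
        selection={"n_selected": len(ids)},
    )


def prs_wholegenome(
    summary,
    snp_map: pd.DataFrame,
    train_means: np.ndarray,
    pip_min: float = 0.001,
) -> PRSModel:
    """Whole-genome PRS from tiled posterior means, thresholded at a PIP floor."""
    pip = np.nan_to_num(np.asarray(summary.pip, dtype=np.float64), nan=0.0)
    keep = np.flatnonzero(pip > pip_min)
    ids = snp_map["snp_id"].to_numpy()[keep]
    return PRSModel(
        provenance="wholegenome_bayesc",
        weights=pd.Series(summary.post_mean_beta[keep], index=ids),
        train_means=pd.Series(np.asarray(train_means)[keep], index=ids),
        selection={"pip_min": pip_min},
    )


def score_samples(model: PRSModel, ds_test: GenotypeDataset) -> np.ndarray:
    """Per-sample scores: sum_j w_j * (dosage_ij - training mean_j).

    Missing test genotypes contribute zero deviation (training-mean
    imputation).  SNP order in the model is irrelevant.
    """
    if len(model) == 0:
        return np.zeros(ds_test.n_samples)
    idx = ds_test.snp_map.set_index("snp_id").index.get_indexer(model.weights.index)
    if (idx < 0).any():
        missing = model.weights.index[idx < 0]
        raise KeyError(f"model SNPs absent from test map: {list(missing[:5])}")
    X = ds_test.dosages[:, idx]
    dev = X - model.train_means.reindex(model.weights.index).to_numpy()
    dev = np.nan_to_num(dev, nan=0.0)
    return dev @ model.weights.to_numpy()


def score_and_correlate(
    model: PRSModel,
    ds_test: GenotypeDataset,
    y_test: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    train_sample_ids=None,
) -> dict:
    """Test-set scores, Pearson r with the phenotype, and bootstrap SE.

    With an empty model the correlation is undefined (NaN), not zero.
    If ``train_sample_ids`` is given, any overlap with the test samples is
    an error (leakage guard).
    """
    if train_sample_ids is not None:
        overlap = np.intersect1d(np.asarray(train_sample_ids), ds_test.sample_ids)
        if overlap.size:
            raise ValueError(
                f"test samples overlap training set ({overlap.size} shared ids)"
            )
    y = np.asarray(y_test, dtype=np.float64)
    scores = score_samples(model, ds_test)
    if len(model) == 0 or np.std(scores) == 0:
        return {"scores": scores, "r": float("nan"), "se": float("nan"), "n": len(y)}
    r = float(np.corrcoef(scores, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(y)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = rng.integers(0, n, size=n)
        s, t = scores[take], y[take]
        boots[b] = (
            np.corrcoef(s, t)[0, 1] if np.std(s) > 0 and np.std(t) > 0 else np.nan
        )
    return {
        "scores": scores,
        "r": r,
        "se": float(np.nanstd(boots, ddof=1)),
        "n": n,
    }


def train_test_split_ids(
    n: int, test_fraction: float = 0.2, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic held-out split by sample index."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])
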