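"""Spike-and-slab (BayesC) Bayesian variable selection via Gibbs sampling.

The model is the multiple regression ``y = X beta + eps`` with i.i.d.
Gaussian errors and, per SNP effect, a mixture prior with a point mass at
zero and a Gaussian slab:

    p(beta_j | sigma2_beta, pi) = pi * N(0, sigma2_beta) + (1 - pi) * 1(beta_j = 0)

``pi`` (the proportion of non-null SNPs) gets a Beta prior, and both
variances get scaled-inverse-chi-square priors.  Posterior inclusion
probabilities (PIPs) are the per-SNP frequencies of non-zero effects in
the retained Gibbs draws; the local FDR is ``1 - PIP``.

A small-``p`` exact posterior by full model enumeration
(:func:`exact_pip_enumeration`) serves as an independent check of the
sampler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from ._gibbs import gibbs_kernel

_CENTER_TOL = 1e-6


@dataclass
class BayesCPrior:
    """Hyperprior for the spike-slab model.

    ``alpha1, alpha2``: Beta-prior shapes for pi.  The defaults
    Beta(1.1, 99) imply a prior mean of pi of 1.1/100, i.e. about 1% of
    SNPs are expected non-null a priori.

    ``df_beta/scale_beta`` and ``df_eps/scale_eps``: scaled-inverse-chi-
    square priors for the slab variance and error variance.  Scales left
    as ``None`` are set from the data by a variance-partition heuristic:
    the prior mode of sigma2_eps equals half of Var(y), and the prior mode
    of the slab variance spreads the other half over the expected number
    of non-null SNPs.
    """

    alpha1: float = 1.1
    alpha2: float = 99.0
    df_beta: float = 5.0
    scale_beta: float | None = None
    df_eps: float = 5.0
    scale_eps: float | None = None

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "df_beta", "df_eps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def prior_mean_pi(self) -> float:
        return self.alpha1 / (self.alpha1 + self.alpha2)


@dataclass
class MCMCConfig:
    n_iter: int = 12000
    burn_in: int = 2000
    thin: int = 5
    seed: int = 0
    update_order: str = "permuted"  # "fixed" | "permuted"

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.update_order not in ("fixed", "permuted"):
            raise ValueError("update_order must be 'fixed' or 'permuted'")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorDraws:
    """Retained MCMC samples; effects stored sparse, indicators bit-packed."""

    n_snps: int
    beta_values: np.ndarray  # concatenated non-zero effects
    beta_indices: np.ndarray  # their SNP indices
    beta_indptr: np.ndarray  # draw offsets into the two arrays (len draws+1)
    delta_packed: np.ndarray  # draws x ceil(p/8) uint8
    pi_draws: np.ndarray
    sigma2_beta_draws: np.ndarray
    sigma2_eps_draws: np.ndarray
    final_residual: np.ndarray | None = None

    @property
    def n_draws(self) -> int:
        return len(self.beta_indptr) - 1

    def delta_matrix(self) -> np.ndarray:
        """Dense draws x p boolean indicator matrix."""
        bits = np.unpackbits(self.delta_packed, axis=1, count=self.n_snps)
        return bits.astype(bool)

    def beta_matrix(self) -> np.ndarray:
        """Dense draws x p effect matrix reconstructed from the sparse store."""
        out = np.zeros((self.n_draws, self.n_snps))
        for d in range(self.n_draws):
            lo, hi = self.beta_indptr[d], self.beta_indptr[d + 1]
            out[d, self.beta_indices[lo:hi]] = self.beta_values[lo:hi]
        return out

    @classmethod
    def from_dense(
        cls,
        beta_dense: np.ndarray,
        delta_dense: np.ndarray,
        pi_draws: np.ndarray,
        s2b_draws: np.ndarray,
        s2e_draws: np.ndarray,
        final_residual: np.ndarray | None = None,
    ) -> "PosteriorDraws":
        draws, p = beta_dense.shape
        indptr = np.zeros(draws + 1, dtype=np.int64)
        idx_parts = []
        val_parts = []
        for d in range(draws):
            nz = np.flatnonzero(delta_dense[d])
            idx_parts.append(nz.astype(np.int32))
            val_parts.append(beta_dense[d, nz])
            indptr[d + 1] = indptr[d] + nz.size
        return cls(
            n_snps=p,
            beta_values=np.concatenate(val_parts) if val_parts else np.empty(0),
            beta_indices=np.concatenate(idx_parts) if idx_parts else np.empty(0, np.int32),
            beta_indptr=indptr,
            delta_packed=np.packbits(delta_dense.astype(np.uint8), axis=1),
            pi_draws=np.asarray(pi_draws),
            sigma2_beta_draws=np.asarray(s2b_draws),
            sigma2_eps_draws=np.asarray(s2e_draws),
            final_residual=final_residual,
        )


@dataclass
class PosteriorSummary:
    """Per-SNP posterior summaries; ``lfdr = 1 - pip`` elementwise."""

    pip: np.ndarray
    post_mean_beta: np.ndarray
    lfdr: np.ndarray = field(default=None)  # type: ignore[assignment]
    snp_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pip = np.asarray(self.pip, dtype=np.float64)
        self.post_mean_beta = np.asarray(self.post_mean_beta, dtype=np.float64)
        if self.lfdr is None:
            self.lfdr = 1.0 - self.pip

    def to_frame(self) -> pd.DataFrame:
        ids = (
            self.snp_ids
            if self.snp_ids is not None
            else np.array([f"snp_{j}" for j in range(len(self.pip))])
        )
        return pd.DataFrame(
            {
                "snp_id": ids,
                "pip": self.pip,
                "post_mean_beta": self.post_mean_beta,
                "lfdr": self.lfdr,
            }
        )


def default_scales(
    prior: BayesCPrior, var_y: float, mean_var_x: float, p: int
) -> tuple[float, float]:
    """Resolve data-dependent prior scales (variance-partition heuristic).

    The scaled-inv-chi2(df, S) mode is df*S/(df+2); S is chosen so the
    modes hit 0.5*Var(y) for the error variance and 0.5*Var(y) spread over
    E[pi]*p expected non-null SNPs (of average genotype variance) for the
    slab.
    """
    scale_eps = prior.scale_eps
    if scale_eps is None:
        scale_eps = 0.5 * var_y * (prior.df_eps + 2.0) / prior.df_eps
    scale_beta = prior.scale_beta
    if scale_beta is None:
        expected_nonnull = max(prior.prior_mean_pi * p, 1.0)
        target = 0.5 * var_y / (expected_nonnull * max(mean_var_x, 1e-12))
        scale_beta = target * (prior.df_beta + 2.0) / prior.df_beta
    return float(scale_beta), float(scale_eps)


def gibbs_bayesc(
    X: np.ndarray,
    y: np.ndarray,
    prior: BayesCPrior | None = None,
    cfg: MCMCConfig | None = None,
) -> PosteriorDraws:
    """Run the BayesC Gibbs sampler on column-centered ``X`` and centered ``y``.

    Each sweep updates, in (optionally permuted) order, every effect
    jointly with its inclusion indicator from its full conditional, then
    pi from its Beta full conditional and both variances from their
    scaled-inverse-chi-square full conditionals.  Deterministic given
    ``cfg.seed``.
    """
    prior = prior or BayesCPrior()
    cfg = cfg or MCMCConfig()
    X = np.asfortranarray(X, dtype=np.float64)
    y = np.ascontiguousarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if p < 1:
        raise ValueError("need at least one SNP")
    if y.shape[0] != n:
        raise ValueError("X and y dimensions disagree")
    col_means = X.mean(axis=0)
    if np.abs(col_means).max() > _CENTER_TOL:
        raise ValueError(
            "X columns are not centered (max |mean| = "
            f"{np.abs(col_means).max():.3g}); center before sampling"
        )
    if abs(y.mean()) > _CENTER_TOL * max(1.0, np.abs(y).max()):
        raise ValueError("y is not centered")
    c = np.einsum("ij,ij->j", X, X)
    if (c == 0).any():
        bad = np.flatnonzero(c == 0)
        raise ValueError(f"zero-variance columns at {bad[:5].tolist()}; filter first")

    var_y = float(y.var())
    if var_y == 0:
        raise ValueError("y has zero variance")
    scale_beta, scale_eps = default_scales(prior, var_y, float(c.mean()) / n, p)
    pi0 = prior.prior_mean_pi
    s2b0 = scale_beta * prior.df_beta / (prior.df_beta + 2.0)
    s2e0 = scale_eps * prior.df_eps / (prior.df_eps + 2.0)

    beta_d, delta_d, pi_d, s2b_d, s2e_d, e_final = gibbs_kernel(
        X,
        y,
        c,
        prior.alpha1,
        prior.alpha2,
        prior.df_beta,
        scale_beta,
        prior.df_eps,
        scale_eps,
        pi0,
        s2b0,
        s2e0,
        cfg.n_iter,
        cfg.burn_in,
        cfg.thin,
        int(cfg.seed) & 0x7FFFFFFF,
        cfg.update_order == "permuted",
    )
    return PosteriorDraws.from_dense(beta_d, delta_d, pi_d, s2b_d, s2e_d, e_final)


def summarize(draws: PosteriorDraws, snp_ids: np.ndarray | None = None) -> PosteriorSummary:
    """PIPs and posterior-mean effects (zeros included) from retained draws."""
    if draws.n_draws < 1:
        raise ValueError("no retained draws")
    pip = draws.delta_matrix().mean(axis=0)
    beta_sum = np.zeros(draws.n_snps)
    np.add.at(beta_sum, draws.beta_indices, draws.beta_values)
    post_mean = beta_sum / draws.n_draws
    return PosteriorSummary(pip=pip, post_mean_beta=post_mean, snp_ids=snp_ids)


def exact_pip_enumeration(
    X: np.ndarray,
    y: np.ndarray,
    pi_fixed: float,
    sigma2_beta_fixed: float,
    sigma2_eps_fixed: float,
) -> np.ndarray:
    """Exact PIPs by enumerating all 2^p inclusion patterns (p <= 15).

    For each model gamma the effects are integrated out analytically:
    ``y ~ N(0, sigma2_beta * X_g X_g' + sigma2_eps * I)`` with prior weight
    ``pi^|g| (1-pi)^(p-|g|)``.  PIP_j is the normalized probability mass of
    models containing j, aggregated in log space.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if p > 15:
        raise ValueError(f"enumeration limited to p <= 15 (got {p})")
    if pi_fixed <= 0.0:
        return np.zeros(p)
    if pi_fixed >= 1.0:
        return np.ones(p)
    s2b, s2e = float(sigma2_beta_fixed), float(sigma2_eps_fixed)
    G = X.T @ X
    b = X.T @ y
    yy = float(y @ y)
    log_pi, log_1mpi = np.log(pi_fixed), np.log1p(-pi_fixed)
    n_models = 1 << p
    logpost = np.empty(n_models)
    base = -0.5 * n * np.log(2.0 * np.pi)
    for mask in range(n_models):
        idx = [j for j in range(p) if mask >> j & 1]
        k = len(idx)
        if k == 0:
            loglik = base - 0.5 * (n * np.log(s2e) + yy / s2e)
        else:
            sub = np.ix_(idx, idx)
            M = s2e * np.eye(k) + s2b * G[sub]
            L = np.linalg.cholesky(M)
            w = np.linalg.solve(M, b[idx])
            logdet = (n - k) * np.log(s2e) + 2.0 * np.sum(np.log(np.diag(L)))
            quad = (yy - s2b * float(b[idx] @ w)) / s2e
            loglik = base - 0.5 * (logdet + quad)
        logpost[mask] = loglik + k * log_pi + (p - k) * log_1mpi
    total = logsumexp(logpost)
    pips = np.empty(p)
    masks = np.arange(n_models)
    for j in range(p):
        sel = (masks >> j & 1).astype(bool)
        pips[j] = np.exp(logsumexp(logpost[sel]) - total)
    return pips
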