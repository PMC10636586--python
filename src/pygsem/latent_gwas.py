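"""Per-SNP association with a fitted latent genetic factor, with Q_SNP filtering.

Each SNP's standardized per-trait effects are treated as an extra observed
variable appended to the genetic covariance matrix (the SNP-trait covariance
equals the standardized marginal beta when the genotype is scaled to unit
variance). Holding the measurement model fixed at its SNP-free estimates
(two-stage estimation), the common-pathway model — the SNP acts on the
factor only — has the closed-form DWLS solution

    beta_latent = sum(lambda_t b_t / se_t^2) / sum(lambda_t^2 / se_t^2)

with a sandwich variance that propagates the full cross-trait sampling
covariance of the b_t (correlated through sample overlap, as measured by the
cross-trait LDSC intercepts).

Q_SNP is the chi-square difference between the independent-pathways model
(SNP free to hit every indicator; saturated, discrepancy zero) and the
common-pathway model, evaluated under the full sampling covariance; under a
true common pathway it is chi-square with (n_indicators - 1) degrees of
freedom, and SNPs with Q_SNP p below a genome-wide threshold are flagged as
not acting through the factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .factor_models import GenomicFactorResults
from .ldsc import GeneticCovariance
from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)

__all__ = [
    "LatentSnpEffect",
    "snp_augmented_covariance",
    "latent_snp_effects",
    "latent_gwas",
    "qsnp_filter",
]


@dataclass
class LatentSnpEffect:
    """One SNP's estimated effect on a latent factor plus heterogeneity."""

    snp_id: str
    beta_latent: float
    se_latent: float
    p_latent: float
    q_snp: float
    q_snp_df: int
    q_snp_p: float


def snp_augmented_covariance(gc: GeneticCovariance, snp_betas: np.ndarray,
                             snp_ses: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand S and V with one SNP as an extra observed variable.

    The SNP row of S holds the standardized betas (SNP variance normalized
    to 1); the appended sampling variances are se^2-based with cross-trait
    terms implied by the sample-overlap (cross-trait intercept) matrix, and
    zero covariance with the LDSC block of V.
    """
    k = gc.k
    snp_betas = np.asarray(snp_betas, dtype=float)
    snp_ses = np.asarray(snp_ses, dtype=float)
    if snp_betas.shape != (k,) or snp_ses.shape != (k,):
        raise ValueError("need one beta and se per trait")
    S_aug = np.zeros((k + 1, k + 1))
    S_aug[:k, :k] = gc.S
    S_aug[k, :k] = S_aug[:k, k] = snp_betas
    S_aug[k, k] = 1.0
    p_old = k * (k + 1) // 2
    p_new = (k + 1) * (k + 2) // 2
    V_aug = np.zeros((p_new, p_new))
    V_aug[:p_old, :p_old] = gc.V
    omega = _noise_cov_from_intercepts(gc.intercepts, snp_ses)
    # vech positions of the SNP-trait covariances in the expanded matrix
    pos = [p_old + t for t in range(k)]
    V_aug[np.ix_(pos, pos)] = omega
    return S_aug, V_aug


def _noise_cov_from_intercepts(intercepts: np.ndarray, ses: np.ndarray) -> np.ndarray:
    """Sampling covariance of one SNP's per-trait betas.

    cov(b_t, b_s) = I_ts * se_t * se_s, where I is the LDSC intercept matrix
    (1 on the diagonal for a well-calibrated GWAS; off-diagonal terms absorb
    sample overlap).
    """
    corr = intercepts.copy()
    return corr * np.outer(ses, ses)


def _factor_loadings(fit: GenomicFactorResults, factor: str) -> tuple[list[str], np.ndarray]:
    """Indicator names and unstandardized loadings of one factor."""
    sp = fit.spec
    if factor not in sp.latents:
        raise ValueError(f"factor {factor!r} not in the fitted model")
    f = sp.latents.index(factor)
    lam_full = fit.model._unpack(fit.theta)[0][:, f]
    idx = np.nonzero(lam_full != 0)[0]
    return [sp.observed[i] for i in idx], lam_full[idx]


def latent_snp_effects(
    betas: np.ndarray,
    ses: np.ndarray,
    loadings: np.ndarray,
    noise_corr: np.ndarray,
) -> pd.DataFrame:
    """Vectorized two-stage common-pathway fit for many SNPs.

    Parameters
    ----------
    betas, ses : (n_snps, n_indicators)
        Standardized per-trait marginal effects and standard errors.
    loadings : (n_indicators,)
        Fixed (SNP-free) unstandardized loadings of the target factor.
    noise_corr : (n_indicators, n_indicators)
        Cross-trait correlation of estimation noise (the intercept matrix
        restricted to the indicators, unit diagonal enforced).
    """
    lam = np.asarray(loadings, dtype=float)
    c = np.asarray(noise_corr, dtype=float).copy()
    np.fill_diagonal(c, 1.0)
    c_inv = np.linalg.inv(c)
    u = betas / ses                     # (n, k) scaled effects
    v = lam[None, :] / ses              # (n, k) scaled loadings

    w_beta = (v * u).sum(axis=1)        # DWLS numerator sum lam b / se^2 -> (v/se? )
    w_lam = (v * v).sum(axis=1)
    beta_latent = w_beta / w_lam
    # sandwich variance: (v' C v) / (v' v)^2 in scaled coordinates
    vCv = np.einsum("nk,kl,nl->n", v, c, v)
    se_latent = np.sqrt(vCv) / w_lam
    z = beta_latent / se_latent
    p_latent = 2.0 * norm.sf(np.abs(z))

    # GLS chi-square difference: saturated vs common pathway
    uCu = np.einsum("nk,kl,nl->n", u, c_inv, u)
    vCu = np.einsum("nk,kl,nl->n", v, c_inv, u)
    vCv_inv = np.einsum("nk,kl,nl->n", v, c_inv, v)
    q = np.clip(uCu - vCu ** 2 / vCv_inv, 0.0, None)
    df = len(lam) - 1
    q_p = chi2_dist.sf(q, df)
    return pd.DataFrame({
        "BETA": beta_latent, "SE": se_latent, "P": p_latent,
        "Q": q, "Q_DF": df, "Q_P": q_p,
    })


def latent_gwas(
    tables: list[SumstatsTable],
    gc: GeneticCovariance,
    fit: GenomicFactorResults,
    factor: str,
) -> SumstatsTable:
    """Multivariate GWAS of one latent factor across all SNPs.

    ``tables`` must be harmonized (same SNPs, same effect alleles) and in
    standardized units; the measurement model in ``fit`` is held fixed. The
    output is sumstats-shaped (with Q columns appended) so downstream MR
    consumes it like any trait; N is the effective sample size implied by
    the latent SE (1/se^2), the per-SD convention.
    """
    indicators, lam = _factor_loadings(fit, factor)
    by_name = {t.name: t for t in tables}
    missing = [n for n in indicators if n not in by_name]
    if missing:
        raise ValueError(f"missing indicator trait table(s): {missing}")
    base = by_name[indicators[0]].df
    n_snps = len(base)
    betas = np.empty((n_snps, len(indicators)))
    ses = np.empty((n_snps, len(indicators)))
    for j, name in enumerate(indicators):
        df = by_name[name].df
        if len(df) != n_snps or not df["SNP"].equals(base["SNP"]):
            raise ValueError("indicator tables are not harmonized")
        betas[:, j] = df["BETA"].to_numpy()
        ses[:, j] = df["SE"].to_numpy()

    ti = [gc.traits.index(n) for n in indicators]
    noise_corr = gc.intercepts_denoised()[np.ix_(ti, ti)]
    res = latent_snp_effects(betas, ses, lam, noise_corr)
    out = pd.DataFrame({
        "SNP": base["SNP"],
        "CHR": base["CHR"],
        "BP": base["BP"],
        "A1": base["A1"],
        "A2": base["A2"],
        "BETA": res["BETA"],
        "SE": res["SE"],
        "P": res["P"],
        "N": 1.0 / res["SE"] ** 2,
        "Q": res["Q"],
        "Q_DF": res["Q_DF"],
        "Q_P": res["Q_P"],
    })
    out["Z"] = out["BETA"] / out["SE"]
    return SumstatsTable(out, name=f"latent_{factor}", validate=False)


def qsnp_filter(table: SumstatsTable, threshold: float = 5e-8) -> tuple[SumstatsTable, pd.DataFrame]:
    """Drop SNPs whose Q_SNP p-value falls below the genome-wide threshold.

    Returns the filtered table and an exclusion log of the removed SNPs.
    SNPs with heterogeneity this extreme act on individual indicators rather
    than through the factor and would be invalid factor-level instruments.
    """
    df = table.df
    if "Q_P" not in df.columns:
        raise ValueError("table has no Q_SNP columns; run latent_gwas first")
    keep = df["Q_P"] >= threshold
    excluded = df.loc[~keep, ["SNP", "Q", "Q_DF", "Q_P"]].copy()
    if len(excluded):
        logger.info("Q_SNP filter excluded %d of %d SNPs", len(excluded), len(df))
    return SumstatsTable(df.loc[keep].copy(), name=table.name, validate=False), excluded
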