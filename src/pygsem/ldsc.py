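"""LD score regression: heritabilities, genetic covariances, and S/V matrices.

Univariate LDSC regresses chi-square = z^2 on the LD score l_j; the slope is
h2 * Nbar / M and the intercept captures confounding / population structure
(1 under the null). The cross-trait analogue regresses z1 * z2 on l_j; its
slope is the genetic covariance * sqrt(N1 N2) / M and its intercept absorbs
sample-overlap-induced correlation of estimation errors.

Standard errors come from a delete-one block jackknife over contiguous
genome-ordered SNP blocks. :func:`build_S_V` runs every univariate and
bivariate regression on a *shared* set of blocks so that the sampling
covariance matrix V of the half-vectorized genetic covariance matrix S can be
assembled from cross products of the jackknife pseudovalues — the weighting
matrix genomic SEM needs.

Regression weights follow the two-step convention of the standard estimator:
an initial 1/l_j heteroskedasticity weight, then weights rebuilt from the
fitted mean function of the first pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .sumstats import SumstatsTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneticCovariance",
    "CorrelationReport",
    "LDSCResult",
    "univariate_ldsc",
    "bivariate_ldsc",
    "build_S_V",
    "correlation_report",
]

MIN_SNPS_PER_BLOCK = 50


@dataclass
class LDSCResult:
    """One LD score regression: estimate, intercept, jackknife SEs."""

    est: float               # h2 (univariate) or genetic covariance (bivariate)
    intercept: float
    est_se: float
    intercept_se: float
    n_snps: int
    n_blocks: int
    delete_values: np.ndarray = field(repr=False)  # (n_blocks, 2): est, intercept
    mean_chi2: float | None = None

    @property
    def est_z(self) -> float:
        return self.est / self.est_se if self.est_se > 0 else np.nan

    def summary(self) -> str:
        return (f"estimate {self.est:.4f} (SE {self.est_se:.4f}), "
                f"intercept {self.intercept:.4f} (SE {self.intercept_se:.4f}), "
                f"{self.n_snps} SNPs, {self.n_blocks} jackknife blocks")


@dataclass
class GeneticCovariance:
    """Multi-trait genetic covariance S with its sampling covariance V.

    ``S`` has heritabilities on the diagonal. ``V`` is the jackknife sampling
    covariance of vech(S) (row-major lower triangle), dimension
    k(k+1)/2. ``intercepts`` holds univariate intercepts on the diagonal and
    cross-trait intercepts off it.
    """

    traits: list[str]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    n_blocks: int
    subset: str = "all"      # {all, odd_chr, even_chr}
    n_snps: int = 0
    delete_values: np.ndarray | None = field(default=None, repr=False)
    intercept_ses: np.ndarray | None = field(default=None, repr=False)

    def intercepts_denoised(self, z_cut: float = 2.0) -> np.ndarray:
        """Intercept matrix with noise-level deviations snapped to the null.

        Off-diagonal intercepts within ``z_cut`` jackknife SEs of 0 are set
        to 0, and diagonal intercepts within ``z_cut`` SEs of 1 are set to 1.
        The intercepts are nuisance parameters whose estimation noise at
        desk-scale SNP counts would otherwise leak into the per-SNP sampling
        covariance used by the latent-factor GWAS.
        """
        out = self.intercepts.copy()
        if self.intercept_ses is None:
            return out
        se = np.clip(self.intercept_ses, 1e-12, None)
        null = np.eye(self.k)
        snap = np.abs(out - null) < z_cut * se
        out[snap] = null[snap]
        return out

    @property
    def k(self) -> int:
        return len(self.traits)

    def vech_index(self, i: int, j: int) -> int:
        """Position of S[i, j] (i >= j) in the half-vectorization."""
        if i < j:
            i, j = j, i
        return i * (i + 1) // 2 + j

    def vech(self) -> np.ndarray:
        idx = np.tril_indices(self.k)
        return self.S[idx]

    def se_S(self) -> np.ndarray:
        """Elementwise jackknife SEs of S, same shape as S."""
        se = np.zeros_like(self.S)
        d = np.sqrt(np.clip(np.diag(self.V), 0, None))
        idx = np.tril_indices(self.k)
        se[idx] = d
        se = se + se.T - np.diag(np.diag(se))
        return se


def _merge_ld(t: SumstatsTable, ld_scores: pd.DataFrame) -> pd.DataFrame:
    need = {"SNP", "L2"}
    if not need.issubset(ld_scores.columns):
        raise ValueError("LD score table must have SNP and L2 columns")
    df = t.df.merge(ld_scores[["SNP"] + (["CHR"] if "CHR" in ld_scores.columns
                                         and "CHR" not in t.df.columns else []) + ["L2"]],
                    on="SNP", how="inner")
    if "CHR" not in df.columns:
        raise ValueError("chromosome column required for genome-ordered jackknife")
    return df.sort_values(["CHR", "BP"] if "BP" in df.columns else ["CHR"]).reset_index(drop=True)


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    """Start indices of contiguous jackknife blocks (n_blocks + 1 fenceposts)."""
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls_with_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                        bounds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted fit of y on [1, x] plus all delete-one-block refits.

    Returns (theta, delete): theta = (slope, intercept); delete is
    (n_blocks, 2) of delete-one estimates. Weights stay fixed across the
    jackknife.
    """
    design = np.column_stack([x, np.ones_like(x)])
    wx = design * w[:, None]
    xtx = design.T @ wx                      # (2, 2)
    xty = wx.T @ y                           # (2,)
    n_blocks = len(bounds) - 1
    xtx_b = np.empty((n_blocks, 2, 2))
    xty_b = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        s, e = bounds[b], bounds[b + 1]
        db = design[s:e]
        wb = w[s:e]
        xtx_b[b] = db.T @ (db * wb[:, None])
        xty_b[b] = (db * wb[:, None]).T @ y[s:e]
    theta = np.linalg.solve(xtx, xty)
    delete = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        delete[b] = np.linalg.solve(xtx - xtx_b[b], xty - xty_b[b])
    return theta, delete


def _jackknife_se(delete: np.ndarray) -> np.ndarray:
    n = delete.shape[0]
    mean = delete.mean(axis=0)
    return np.sqrt((n - 1) / n * ((delete - mean) ** 2).sum(axis=0))


def _two_step_weights(ell: np.ndarray, mean_fn: np.ndarray) -> np.ndarray:
    """Heteroskedasticity weights 1 / (l_j * fitted^2), fitted floored at 0.1."""
    return 1.0 / (np.clip(ell, 1.0, None) * np.clip(mean_fn, 0.1, None) ** 2)


def _ldsc_core(y: np.ndarray, ell: np.ndarray, scale: float,
               bounds: np.ndarray, mean_fn: np.ndarray | None = None,
               m_ref: int | None = None) -> tuple[LDSCResult, np.ndarray]:
    """Shared machinery: regress y on l, convert slope via ``scale``.

    ``scale`` maps slope -> estimate: est = slope * M / scale (scale = Nbar
    univariate, sqrt(N1bar N2bar) bivariate). ``m_ref`` overrides the SNP
    count used in that conversion — a chromosome-parity subset regresses on
    its own SNPs but still estimates the genome-wide quantity, so it must
    scale by the full frame's M. ``mean_fn`` optionally supplies the
    second-step weight mean function; when None it is taken from the
    first-pass fit of y itself.
    """
    m = len(y)
    if m_ref is None:
        m_ref = m
    if mean_fn is None:
        w = 1.0 / np.clip(ell, 1.0, None)
        design = np.column_stack([ell, np.ones(m)])
        wd = design * w[:, None]
        first = np.linalg.solve(design.T @ wd, wd.T @ y)
        mean_fn = first[1] + first[0] * ell
    w2 = _two_step_weights(ell, np.abs(mean_fn))
    theta, delete = _wls_with_jackknife(ell, y, w2, bounds)
    conv = m_ref / scale
    est, intercept = theta[0] * conv, theta[1]
    delete_conv = np.column_stack([delete[:, 0] * conv, delete[:, 1]])
    se = _jackknife_se(delete_conv)
    res = LDSCResult(est=float(est), intercept=float(intercept),
                     est_se=float(se[0]), intercept_se=float(se[1]),
                     n_snps=m, n_blocks=len(bounds) - 1,
                     delete_values=delete_conv)
    return res, mean_fn


def univariate_ldsc(t: SumstatsTable, ld_scores: pd.DataFrame,
                    n_blocks: int = 200) -> LDSCResult:
    """Estimate SNP heritability (observed scale) and the LDSC intercept."""
    df = _merge_ld(t, ld_scores)
    m = len(df)
    if m < MIN_SNPS_PER_BLOCK * n_blocks:
        raise ValueError(
            f"{m} SNPs is too few for {n_blocks} jackknife blocks "
            f"(need >= {MIN_SNPS_PER_BLOCK * n_blocks})")
    z = df["Z"].to_numpy()
    ell = df["L2"].to_numpy()
    nbar = float(df["N"].mean())
    chi2 = z ** 2
    if np.allclose(chi2, 0.0):
        # degenerate input: all associations exactly null
        return LDSCResult(est=0.0, intercept=0.0, est_se=0.0, intercept_se=0.0,
                          n_snps=m, n_blocks=n_blocks,
                          delete_values=np.zeros((n_blocks, 2)), mean_chi2=0.0)
    bounds = _block_bounds(m, n_blocks)
    res, _ = _ldsc_core(chi2, ell, nbar, bounds)
    res.mean_chi2 = float(chi2.mean())
    if res.est < 0:
        logger.warning("%s: negative heritability estimate %.4g", t.name, res.est)
    return res


def bivariate_ldsc(t1: SumstatsTable, t2: SumstatsTable, ld_scores: pd.DataFrame,
                   n_blocks: int = 200) -> LDSCResult:
    """Cross-trait LDSC: genetic covariance and sample-overlap intercept.

    Requires a harmonized SNP set (same SNPs, same effect alleles); rows are
    inner-joined on SNP id.
    """
    df1 = _merge_ld(t1, ld_scores)
    df2 = _merge_ld(t2, ld_scores)
    df = df1.merge(df2[["SNP", "Z", "N"]], on="SNP", suffixes=("", "_2"))
    m = len(df)
    if m < MIN_SNPS_PER_BLOCK * n_blocks:
        raise ValueError(f"{m} SNPs is too few for {n_blocks} jackknife blocks")
    ell = df["L2"].to_numpy()
    y = (df["Z"] * df["Z_2"]).to_numpy()
    scale = float(np.sqrt(df["N"].mean() * df["N_2"].mean()))
    bounds = _block_bounds(m, n_blocks)
    # second-step weight mean function from the univariate fits + first cross pass
    res, _ = _ldsc_core(y, ell, scale, bounds)
    return res


def _subset_mask(chrom: np.ndarray, subset: str) -> np.ndarray:
    if subset == "all":
        return np.ones(len(chrom), dtype=bool)
    if subset == "odd_chr":
        return chrom % 2 == 1
    if subset == "even_chr":
        return chrom % 2 == 0
    raise ValueError(f"unknown subset {subset!r}")


def build_S_V(tables: list[SumstatsTable], ld_scores: pd.DataFrame,
              subset: str = "all", n_blocks: int = 200) -> GeneticCovariance:
    """Assemble the genetic covariance matrix S and its sampling covariance V.

    All k heritabilities and k(k-1)/2 covariances are estimated on the same
    SNP set restricted to the requested chromosome-parity subset, with one
    shared partition of the genome into jackknife blocks; V is the jackknife
    covariance across the delete-one estimates of every element of vech(S).
    """
    if len(tables) < 1:
        raise ValueError("need at least one trait")
    k = len(tables)
    # shared SNP frame in genome order (tables assumed harmonized upstream)
    base = _merge_ld(tables[0], ld_scores)
    snps = base["SNP"]
    zmat = np.empty((len(base), k))
    nbar = np.empty(k)
    for i, t in enumerate(tables):
        dfi = t.df.set_index("SNP")
        missing = ~snps.isin(dfi.index)
        if missing.any():
            raise ValueError(
                f"trait {t.name!r} is missing {int(missing.sum())} SNPs of the "
                "shared frame; harmonize the panels first")
        sub = dfi.loc[snps]
        zmat[:, i] = sub["Z"].to_numpy()
        nbar[i] = float(sub["N"].mean())
    m_full = zmat.shape[0]
    mask = _subset_mask(base["CHR"].to_numpy(), subset)
    zmat = zmat[mask]
    ell = base["L2"].to_numpy()[mask]
    m = zmat.shape[0]
    if m < MIN_SNPS_PER_BLOCK * n_blocks:
        raise ValueError(
            f"subset {subset!r} leaves {m} SNPs, fewer than "
            f"{MIN_SNPS_PER_BLOCK * n_blocks} required for {n_blocks} blocks")
    bounds = _block_bounds(m, n_blocks)

    p = k * (k + 1) // 2
    S = np.zeros((k, k))
    intercepts = np.zeros((k, k))
    intercept_ses = np.zeros((k, k))
    delete_all = np.zeros((n_blocks, p))

    # univariate first (also yields per-trait fitted chi2 for pair weights)
    fitted = {}
    for i in range(k):
        chi2 = zmat[:, i] ** 2
        res, mean_fn = _ldsc_core(chi2, ell, nbar[i], bounds, m_ref=m_full)
        fitted[i] = mean_fn
        S[i, i] = res.est
        intercepts[i, i] = res.intercept
        intercept_ses[i, i] = res.intercept_se
        col = i * (i + 1) // 2 + i
        delete_all[:, col] = res.delete_values[:, 0]

    for i in range(k):
        for j in range(i):
            y = zmat[:, i] * zmat[:, j]
            scale = float(np.sqrt(nbar[i] * nbar[j]))
            res, _ = _ldsc_core(y, ell, scale, bounds, m_ref=m_full)
            S[i, j] = S[j, i] = res.est
            intercepts[i, j] = intercepts[j, i] = res.intercept
            intercept_ses[i, j] = intercept_ses[j, i] = res.intercept_se
            col = i * (i + 1) // 2 + j
            delete_all[:, col] = res.delete_values[:, 0]

    n = n_blocks
    centered = delete_all - delete_all.mean(axis=0)
    V = (n - 1) / n * centered.T @ centered
    return GeneticCovariance(traits=[t.name for t in tables], S=S, V=V,
                             intercepts=intercepts, n_blocks=n_blocks,
                             subset=subset, n_snps=m, delete_values=delete_all,
                             intercept_ses=intercept_ses)


@dataclass
class CorrelationReport:
    """Pairwise genetic correlations with FDR-adjusted p-values."""

    traits: list[str]
    rg: np.ndarray
    se: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        rows = []
        k = len(self.traits)
        for i in range(k):
            for j in range(i):
                rows.append({
                    "trait1": self.traits[j], "trait2": self.traits[i],
                    "rg": self.rg[i, j], "se": self.se[i, j],
                    "p": self.p[i, j], "p_fdr": self.p_fdr[i, j],
                })
        return pd.DataFrame(rows)


def correlation_report(gc: GeneticCovariance) -> CorrelationReport:
    """Genetic correlations rg = S_ij / sqrt(S_ii S_jj) with jackknife SEs.

    The SE of each ratio is taken over the delete-one values of the ratio
    itself (shared blocks), the p-value from a two-sided normal
    approximation, and multiplicity handled by Benjamini-Hochberg FDR across
    the k(k-1)/2 pairs.
    """
    k = gc.k
    if np.any(np.diag(gc.S) <= 0):
        bad = [gc.traits[i] for i in range(k) if gc.S[i, i] <= 0]
        raise ValueError(f"non-positive heritability for trait(s): {', '.join(bad)}")
    if gc.delete_values is None:
        raise ValueError("GeneticCovariance lacks jackknife delete values")
    rg = np.eye(k)
    se = np.zeros((k, k))
    p = np.ones((k, k))
    pair_p = []
    pairs = []
    for i in range(k):
        for j in range(i):
            rg[i, j] = rg[j, i] = gc.S[i, j] / np.sqrt(gc.S[i, i] * gc.S[j, j])
            dij = gc.delete_values[:, gc.vech_index(i, j)]
            dii = gc.delete_values[:, gc.vech_index(i, i)]
            djj = gc.delete_values[:, gc.vech_index(j, j)]
            with np.errstate(invalid="ignore"):
                dr = dij / np.sqrt(np.clip(dii * djj, 1e-12, None))
            se_ij = _jackknife_se(dr[:, None])[0]
            se[i, j] = se[j, i] = se_ij
            pij = 2.0 * norm.sf(abs(rg[i, j]) / se_ij) if se_ij > 0 else np.nan
            p[i, j] = p[j, i] = pij
            pair_p.append(pij)
            pairs.append((i, j))
    p_fdr = np.ones((k, k))
    if pair_p:
        adj = multipletests(pair_p, method="fdr_bh")[1]
        for (i, j), a in zip(pairs, adj):
            p_fdr[i, j] = p_fdr[j, i] = a
    return CorrelationReport(traits=list(gc.traits), rg=rg, se=se, p=p, p_fdr=p_fdr)
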