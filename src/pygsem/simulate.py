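"""Synthetic multi-trait GWAS summary statistics with a known latent architecture.

The generator is the inverse of the analysis pipeline: a :class:`TruthModel`
declares a factor structure over trait genetic effects (loadings, factor
correlations, residual genetic variances, SNP heritabilities), a
:class:`LDStructure` declares block-diagonal linkage disequilibrium, and the
simulation functions turn those into per-trait GWAS summary-statistic tables
whose LD score regression / factor analysis / Mendelian randomization results
can be checked against the declared truth.

Effects are simulated in standardized (per-SD phenotype, per-SD genotype)
units so that the standard error of every marginal estimate is 1/sqrt(N);
per-allele scaling by sqrt(2 p (1-p)) is applied only when tables are written
to disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TruthModel",
    "LDStructure",
    "InstrumentRegistry",
    "simulate_true_effects",
    "simulate_sumstats",
    "plant_instruments",
    "write_sumstats",
    "write_ld_scores",
    "write_ld_blocks",
    "read_ld_blocks",
]

SUMSTATS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P", "N", "INFO", "FRQ"]

# non-palindromic allele pairs (strand-unambiguous)
_SAFE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
               ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class TruthModel:
    """Ground-truth latent genetic architecture for a set of traits.

    ``loadings`` are on the genetic-covariance (heritability) scale: the
    implied genetic covariance ``loadings @ factor_corr @ loadings.T +
    diag(residual_var)`` must have ``trait_h2`` on its diagonal.
    """

    loadings: np.ndarray                 # (n_traits, n_factors)
    factor_corr: np.ndarray              # (n_factors, n_factors)
    residual_var: np.ndarray             # (n_traits,)
    trait_h2: np.ndarray                 # (n_traits,)
    sample_sizes: np.ndarray             # (n_traits,)
    overlap_frac: np.ndarray | None = None          # (n_traits, n_traits)
    phenotypic_corr_overlap: np.ndarray | None = None
    trait_names: list[str] | None = None
    causal_effect_exposure_to_outcome: float = 0.0

    def __post_init__(self) -> None:
        self.loadings = np.atleast_2d(np.asarray(self.loadings, dtype=float))
        self.factor_corr = np.atleast_2d(np.asarray(self.factor_corr, dtype=float))
        self.residual_var = np.asarray(self.residual_var, dtype=float)
        self.trait_h2 = np.asarray(self.trait_h2, dtype=float)
        self.sample_sizes = np.asarray(self.sample_sizes, dtype=float)
        k = self.n_traits
        if self.overlap_frac is None:
            self.overlap_frac = np.eye(k)
        if self.phenotypic_corr_overlap is None:
            self.phenotypic_corr_overlap = np.eye(k)
        self.overlap_frac = np.asarray(self.overlap_frac, dtype=float)
        self.phenotypic_corr_overlap = np.asarray(self.phenotypic_corr_overlap, dtype=float)
        if self.trait_names is None:
            self.trait_names = [f"trait{i + 1}" for i in range(k)]

    @property
    def n_traits(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def implied_genetic_cov(self) -> np.ndarray:
        """Lambda Phi Lambda' + diag(residual_var), on the heritability scale."""
        return (self.loadings @ self.factor_corr @ self.loadings.T
                + np.diag(self.residual_var))

    def validate(self, atol: float = 1e-8) -> None:
        """Check the structural invariants; raise ``ValueError`` on violation."""
        k, f = self.n_traits, self.n_factors
        if self.factor_corr.shape != (f, f):
            raise ValueError("factor_corr shape does not match number of factors")
        if not np.allclose(self.factor_corr, self.factor_corr.T, atol=atol):
            raise ValueError("factor_corr must be symmetric")
        if not np.allclose(np.diag(self.factor_corr), 1.0, atol=1e-6):
            raise ValueError("factor_corr must have unit diagonal")
        if np.linalg.eigvalsh(self.factor_corr).min() <= 0:
            raise ValueError("factor_corr must be positive definite")
        if np.any(self.trait_h2 < 0) or np.any(self.trait_h2 > 1):
            raise ValueError("trait_h2 must lie in [0, 1]")
        sigma = self.implied_genetic_cov()
        if not np.allclose(np.diag(sigma), self.trait_h2, atol=1e-6):
            raise ValueError(
                "implied genetic covariance diagonal does not equal trait_h2; "
                f"max deviation {np.abs(np.diag(sigma) - self.trait_h2).max():.3g}"
            )
        if not np.allclose(self.overlap_frac, self.overlap_frac.T, atol=atol):
            raise ValueError("overlap_frac must be symmetric")
        if not np.allclose(np.diag(self.overlap_frac), 1.0, atol=1e-6):
            raise ValueError("overlap_frac must have unit diagonal")
        if np.any(self.overlap_frac < 0) or np.any(self.overlap_frac > 1):
            raise ValueError("overlap_frac entries must lie in [0, 1]")
        if len(self.trait_names) != k:
            raise ValueError("trait_names length does not match number of traits")

    @classmethod
    def from_standardized(
        cls,
        std_loadings: np.ndarray,
        factor_corr: np.ndarray,
        trait_h2: np.ndarray,
        sample_sizes: np.ndarray,
        **kwargs,
    ) -> "TruthModel":
        """Build a truth model from standardized loadings.

        ``std_loadings`` are loadings of the *standardized* genetic components
        (correlation scale); they are rescaled by sqrt(h2) so the implied
        covariance diagonal equals ``trait_h2``, and the residual variance is
        set to the heritability not explained by the factors.
        """
        std_loadings = np.atleast_2d(np.asarray(std_loadings, dtype=float))
        factor_corr = np.atleast_2d(np.asarray(factor_corr, dtype=float))
        trait_h2 = np.asarray(trait_h2, dtype=float)
        communality = np.einsum("if,fg,ig->i", std_loadings, factor_corr, std_loadings)
        if np.any(communality > 1 + 1e-9):
            raise ValueError("standardized communalities exceed 1")
        loadings = std_loadings * np.sqrt(trait_h2)[:, None]
        residual = trait_h2 * (1.0 - communality)
        return cls(loadings=loadings, factor_corr=factor_corr,
                   residual_var=residual, trait_h2=trait_h2,
                   sample_sizes=np.asarray(sample_sizes, dtype=float), **kwargs)

    def to_yaml(self, path) -> None:
        payload = {
            "trait_names": list(self.trait_names),
            "loadings": self.loadings.tolist(),
            "factor_corr": self.factor_corr.tolist(),
            "residual_var": self.residual_var.tolist(),
            "trait_h2": self.trait_h2.tolist(),
            "sample_sizes": self.sample_sizes.tolist(),
            "overlap_frac": self.overlap_frac.tolist(),
            "phenotypic_corr_overlap": self.phenotypic_corr_overlap.tolist(),
            "causal_effect_exposure_to_outcome": float(
                self.causal_effect_exposure_to_outcome),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "TruthModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(
            loadings=np.array(payload["loadings"]),
            factor_corr=np.array(payload["factor_corr"]),
            residual_var=np.array(payload["residual_var"]),
            trait_h2=np.array(payload["trait_h2"]),
            sample_sizes=np.array(payload["sample_sizes"]),
            overlap_frac=np.array(payload["overlap_frac"]),
            phenotypic_corr_overlap=np.array(payload["phenotypic_corr_overlap"]),
            trait_names=list(payload["trait_names"]),
            causal_effect_exposure_to_outcome=payload.get(
                "causal_effect_exposure_to_outcome", 0.0),
        )


@dataclass
class LDStructure:
    """Block-diagonal LD: exchangeable within-block r², zero between blocks.

    The LD score of SNP j is ``1 + (block_size - 1) * r2`` (the sum of squared
    correlations with every SNP in its block, including itself). Blocks never
    span a chromosome boundary and positions increase strictly within a
    chromosome.
    """

    block_sizes: np.ndarray              # (n_blocks,)
    within_block_r2: np.ndarray          # (n_blocks,)
    chromosome: np.ndarray               # (n_snps,)
    position: np.ndarray                 # (n_snps,)
    snp_ids: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.block_sizes = np.asarray(self.block_sizes, dtype=int)
        self.within_block_r2 = np.asarray(self.within_block_r2, dtype=float)
        self.chromosome = np.asarray(self.chromosome, dtype=int)
        self.position = np.asarray(self.position, dtype=int)
        if self.snp_ids is None:
            self.snp_ids = [f"rs{i + 1}" for i in range(self.n_snps)]
        if np.any(self.within_block_r2 < 0) or np.any(self.within_block_r2 > 1):
            raise ValueError("within_block_r2 must lie in [0, 1]")
        if self.block_sizes.sum() != self.n_snps:
            raise ValueError("block sizes do not sum to the number of SNPs")
        # blocks must not span chromosomes
        starts = self.block_starts
        for b, (s, m) in enumerate(zip(starts, self.block_sizes)):
            if len(np.unique(self.chromosome[s:s + m])) != 1:
                raise ValueError(f"block {b} spans a chromosome boundary")
        for c in np.unique(self.chromosome):
            pos = self.position[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chr {c}")

    @property
    def n_snps(self) -> int:
        return int(len(self.chromosome))

    @property
    def n_blocks(self) -> int:
        return int(len(self.block_sizes))

    @property
    def block_starts(self) -> np.ndarray:
        return np.concatenate([[0], np.cumsum(self.block_sizes)[:-1]])

    @property
    def block_index(self) -> np.ndarray:
        """Per-SNP block label."""
        return np.repeat(np.arange(self.n_blocks), self.block_sizes)

    @property
    def ld_scores(self) -> np.ndarray:
        per_block = 1.0 + (self.block_sizes - 1) * self.within_block_r2
        return np.repeat(per_block, self.block_sizes)

    @classmethod
    def regular(
        cls,
        snps_per_chr: int = 2000,
        n_chrom: int = 22,
        block_sizes: tuple[int, ...] = (10, 25, 50, 100),
        r2_values: tuple[float, ...] = (0.05, 0.15, 0.3, 0.5),
        spacing_bp: int = 20_000,
    ) -> "LDStructure":
        """A stylized genome: ``n_chrom`` chromosomes tiled with LD blocks.

        Block sizes and within-block r² cycle through the given values with
        coprime-ish strides so that LD scores vary across the genome (a
        constant LD score would leave the LD score regression slope and
        intercept unidentified). ``snps_per_chr`` is a target; each
        chromosome is filled with whole blocks up to it.
        """
        sizes: list[int] = []
        r2s: list[float] = []
        chroms: list[np.ndarray] = []
        positions: list[np.ndarray] = []
        bi = 0
        for c in range(1, n_chrom + 1):
            filled = 0
            while filled < snps_per_chr:
                bs = int(block_sizes[bi % len(block_sizes)])
                r2 = float(r2_values[(bi // len(block_sizes) + bi) % len(r2_values)])
                bs = min(bs, snps_per_chr - filled) if filled + bs > snps_per_chr else bs
                if bs < 1:
                    break
                sizes.append(bs)
                r2s.append(r2)
                filled += bs
                bi += 1
            chroms.append(np.full(filled, c))
            positions.append(np.arange(1, filled + 1) * spacing_bp)
        return cls(
            block_sizes=np.array(sizes),
            within_block_r2=np.array(r2s),
            chromosome=np.concatenate(chroms),
            position=np.concatenate(positions),
        )


def _genetic_cov_factor(sigma: np.ndarray) -> np.ndarray:
    """A factor A with A A' = sigma, tolerant of zero rows (h2 = 0 traits)."""
    w, u = np.linalg.eigh(sigma)
    if w.min() < -1e-8 * max(1.0, w.max()):
        raise ValueError(
            "implied genetic covariance is not positive semidefinite "
            f"(minimum eigenvalue {w.min():.3g})"
        )
    w = np.clip(w, 0.0, None)
    a = u * np.sqrt(w)
    # zero-heritability traits must produce exactly zero effects
    a[np.isclose(np.diag(sigma), 0.0), :] = 0.0
    return a


def simulate_true_effects(
    truth: TruthModel,
    ld: LDStructure,
    polygenicity: float = 1.0,
    seed: int | None = None,
) -> np.ndarray:
    """Draw per-SNP standardized true effects (n_snps x n_traits).

    A ``polygenicity`` fraction of SNPs is causal; causal effects are drawn
    i.i.d. multivariate normal with covariance ``implied_genetic_cov() /
    n_causal`` so that the effects summed over SNPs reproduce the declared
    genetic covariance (and hence the declared per-trait heritabilities).
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    if not (0.0 < polygenicity <= 1.0):
        raise ValueError("polygenicity must lie in (0, 1]")
    truth.validate()
    rng = np.random.default_rng(seed)
    m = ld.n_snps
    n_causal = max(1, int(round(polygenicity * m)))
    sigma = truth.implied_genetic_cov()
    a = _genetic_cov_factor(sigma / n_causal)
    effects = np.zeros((m, truth.n_traits))
    causal = rng.permutation(m)[:n_causal]
    z = rng.standard_normal((n_causal, truth.n_traits))
    effects[causal] = z @ a.T
    return effects


def ld_smooth(effects: np.ndarray, ld: LDStructure) -> np.ndarray:
    """Marginal (LD-smoothed) effects: R @ beta per block.

    Within a block the correlation matrix is exchangeable with off-diagonal
    r = sqrt(r2), so R beta = (1 - r) beta + r * colsum(beta).
    """
    out = np.empty_like(effects)
    starts = ld.block_starts
    for s, m, r2 in zip(starts, ld.block_sizes, ld.within_block_r2):
        r = np.sqrt(r2)
        block = effects[s:s + m]
        out[s:s + m] = (1.0 - r) * block + r * block.sum(axis=0, keepdims=True)
    return out


def _noise_cov(truth: TruthModel) -> np.ndarray:
    """Cross-trait covariance of estimation noise in standardized units.

    Diagonal 1/N_t; off-diagonal overlap_frac * phenotypic_corr_overlap /
    sqrt(N_t N_s) — the term that surfaces as the LDSC cross-trait intercept.
    """
    n = truth.sample_sizes
    corr = truth.overlap_frac * truth.phenotypic_corr_overlap
    np.fill_diagonal(corr, 1.0)
    scale = 1.0 / np.sqrt(np.outer(n, n))
    return corr * scale


def simulate_sumstats(
    true_effects: np.ndarray,
    truth: TruthModel,
    ld: LDStructure,
    seed: int | None = None,
    qc_fail_frac: float = 0.01,
    palindromic_frac: float = 0.01,
    protect: np.ndarray | None = None,
) -> list[pd.DataFrame]:
    """Turn true effects into one summary-statistics table per trait.

    Estimated effect = LD-smoothed true effect + noise with SE 1/sqrt(N);
    noise is correlated across traits according to the declared sample
    overlap. A small fraction of rows is given INFO or allele-frequency
    values below the standard QC thresholds (never rows listed in
    ``protect``), and a small fraction receives palindromic allele pairs, so
    the QC and harmonization stages have something to remove.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    rng = np.random.default_rng(seed)
    m, k = true_effects.shape
    if m != ld.n_snps or k != truth.n_traits:
        raise ValueError("true_effects shape inconsistent with truth/ld")

    smoothed = ld_smooth(true_effects, ld)
    chol = np.linalg.cholesky(_noise_cov(truth) + 1e-18 * np.eye(k))
    noise = rng.standard_normal((m, k)) @ chol.T
    beta_hat = smoothed + noise
    se = np.broadcast_to(1.0 / np.sqrt(truth.sample_sizes), (m, k))

    protected = np.zeros(m, dtype=bool)
    if protect is not None:
        protected[np.asarray(protect, dtype=int)] = True

    # shared per-SNP allele assignment, frequencies and QC columns
    pair_idx = rng.integers(0, len(_SAFE_PAIRS), size=m)
    a1 = np.array([_SAFE_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_SAFE_PAIRS[i][1] for i in pair_idx])
    pal = (rng.random(m) < palindromic_frac) & ~protected
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    a1[pal] = [_PALINDROMIC_PAIRS[i][0] for i in pal_idx[pal]]
    a2[pal] = [_PALINDROMIC_PAIRS[i][1] for i in pal_idx[pal]]

    frq = rng.uniform(0.05, 0.95, size=m)
    info = rng.uniform(0.92, 1.0, size=m)
    low_info = (rng.random(m) < qc_fail_frac) & ~protected
    info[low_info] = rng.uniform(0.5, 0.9, size=int(low_info.sum()))
    low_frq = (rng.random(m) < qc_fail_frac) & ~protected & ~low_info
    frq[low_frq] = rng.uniform(0.001, 0.01, size=int(low_frq.sum()))

    tables = []
    for t in range(truth.n_traits):
        z = beta_hat[:, t] / se[:, t]
        p = 2.0 * _norm_sf(np.abs(z))
        tables.append(pd.DataFrame({
            "SNP": ld.snp_ids,
            "CHR": ld.chromosome,
            "BP": ld.position,
            "A1": a1,
            "A2": a2,
            "BETA": beta_hat[:, t],
            "SE": se[:, t],
            "P": p,
            "N": np.full(m, truth.sample_sizes[t]),
            "INFO": info,
            "FRQ": frq,
        }))
    return tables


def _norm_sf(x: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(x)


@dataclass
class InstrumentRegistry:
    """Which SNPs were planted as instruments and with what effects."""

    table: pd.DataFrame  # snp_index, snp_id, block, exposure_effect, outcome_effect, valid

    @property
    def snp_ids(self) -> list[str]:
        return list(self.table["snp_id"])

    @property
    def snp_indices(self) -> np.ndarray:
        return self.table["snp_index"].to_numpy()


def _role_effect_columns(role, truth: TruthModel) -> tuple[np.ndarray, np.ndarray]:
    """Map an exposure/outcome role to (trait columns, per-trait weights).

    ``role`` is either ``("trait", i)`` — a single observed trait — or
    ``("factor", f)`` — a latent factor, whose per-unit effect is spread over
    the traits through the loading column.
    """
    kind, idx = role
    if kind == "trait":
        cols = np.array([idx], dtype=int)
        weights = np.array([1.0])
    elif kind == "factor":
        lam = truth.loadings[:, idx]
        cols = np.nonzero(lam != 0)[0]
        weights = lam[cols]
    else:
        raise ValueError(f"unknown role kind {kind!r}")
    return cols, weights


def plant_instruments(
    truth: TruthModel,
    ld: LDStructure,
    n_instruments: int,
    effect_size: float | np.ndarray,
    seed: int | None = None,
    exposure=("trait", 0),
    outcome=("trait", 1),
    causal_effect: float | None = None,
    pleiotropy_shift: float | np.ndarray = 0.0,
    true_effects: np.ndarray | None = None,
    exclude_blocks: np.ndarray | None = None,
    clear_block: bool = True,
    effect_sign: str = "random",
) -> tuple[np.ndarray, InstrumentRegistry]:
    """Plant large instrument effects, one per LD block.

    Each chosen block contributes its middle SNP. The SNP's exposure effect is
    set to ``effect_size`` with a random sign; its outcome effect is set
    (overwriting any polygenic background) to ``causal_effect * exposure
    effect + pleiotropy_shift``. Exposure and outcome may each be an observed
    trait ``("trait", i)`` or a latent factor ``("factor", f)`` of the truth
    model; factor effects are spread over indicator traits through the
    loadings, so the latent-factor GWAS recovers the planted per-factor
    effect.
    """
    if seed is None:
        raise ValueError("seed is required for reproducible simulation")
    if n_instruments > ld.n_blocks:
        raise ValueError("n_instruments exceeds the number of LD blocks")
    if causal_effect is None:
        causal_effect = truth.causal_effect_exposure_to_outcome
    rng = np.random.default_rng(seed)
    effects = (np.zeros((ld.n_snps, truth.n_traits))
               if true_effects is None else true_effects.copy())

    candidates = np.arange(ld.n_blocks)
    if exclude_blocks is not None:
        candidates = np.setdiff1d(candidates, np.asarray(exclude_blocks, dtype=int))
    if n_instruments > len(candidates):
        raise ValueError("not enough LD blocks left after exclusions")
    blocks = np.sort(rng.choice(candidates, size=n_instruments, replace=False))
    starts = ld.block_starts
    snp_idx = starts[blocks] + ld.block_sizes[blocks] // 2

    pleio = np.broadcast_to(np.asarray(pleiotropy_shift, dtype=float),
                            (n_instruments,)).copy()
    # "positive" keeps the exposure effects orientation-consistent so a
    # constant pleiotropy_shift stays *directional* after MR orientation;
    # with random signs a constant direct effect becomes balanced pleiotropy
    if effect_sign == "positive":
        signs = np.ones(n_instruments)
    elif effect_sign == "random":
        signs = rng.choice([-1.0, 1.0], size=n_instruments)
    else:
        raise ValueError(f"unknown effect_sign {effect_sign!r}")
    magnitudes = np.broadcast_to(np.asarray(effect_size, dtype=float),
                                 (n_instruments,))
    expo_eff = magnitudes * signs
    out_eff = causal_effect * expo_eff + pleio

    # minimum exposure effect detectable at genome-wide significance
    expo_cols, expo_w = _role_effect_columns(exposure, truth)
    out_cols, out_w = _role_effect_columns(outcome, truth)
    n_expo = truth.sample_sizes[expo_cols].min()
    min_detectable = 5.452 / np.sqrt(n_expo)  # |z| at p = 5e-8
    if np.abs(magnitudes).min() * min(1.0, np.abs(expo_w).max()) < min_detectable:
        warnings.warn(
            "planted effect size may not reach genome-wide significance; "
            f"minimum detectable effect at this N is {min_detectable:.4g}",
            stacklevel=2,
        )

    # Factor-role effects spread over loaded traits first; a trait-role
    # effect then overwrites its own column, so a trait that also loads on
    # the other side's factor carries exactly its designated effect.
    sides = [(exposure[0], expo_cols, expo_w, expo_eff),
             (outcome[0], out_cols, out_w, out_eff)]
    sides.sort(key=lambda s: 0 if s[0] == "factor" else 1)
    for j, (blk, idx) in enumerate(zip(blocks, snp_idx)):
        if clear_block:
            # the planted locus replaces the block's polygenic background, so
            # the instrument's LD-smoothed effect equals the planted effect
            s = starts[blk]
            effects[s:s + ld.block_sizes[blk], :] = 0.0
        effects[idx, :] = 0.0
        for kind, cols, w, eff in sides:
            effects[idx, cols] = w * eff[j]

    registry = InstrumentRegistry(pd.DataFrame({
        "snp_index": snp_idx,
        "snp_id": [ld.snp_ids[i] for i in snp_idx],
        "block": blocks,
        "exposure_effect": expo_eff,
        "outcome_effect": out_eff,
        "pleiotropy_shift": pleio,
        "valid": pleio == 0.0,
    }))
    return effects, registry


# ---------------------------------------------------------------------------
# writers / readers for the on-disk interchange formats


def write_sumstats(table: pd.DataFrame, path, per_allele: bool = True) -> None:
    """Write a sumstats TSV; optionally rescale to per-allele effect units."""
    out = table.copy()
    if per_allele:
        scale = np.sqrt(2.0 * out["FRQ"] * (1.0 - out["FRQ"]))
        out["BETA"] = out["BETA"] / scale
        out["SE"] = out["SE"] / scale
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_ld_scores(ld: LDStructure, path) -> None:
    pd.DataFrame({
        "SNP": ld.snp_ids,
        "CHR": ld.chromosome,
        "L2": ld.ld_scores,
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_ld_blocks(ld: LDStructure, path) -> None:
    """Block list file: one row per SNP with its block label and within-r²."""
    pd.DataFrame({
        "SNP": ld.snp_ids,
        "CHR": ld.chromosome,
        "BP": ld.position,
        "BLOCK": ld.block_index,
        "R2": np.repeat(ld.within_block_r2, ld.block_sizes),
    }).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_ld_blocks(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"SNP", "BLOCK", "R2"}
    if not required.issubset(df.columns):
        raise ValueError(f"LD block file missing columns {required - set(df.columns)}")
    return df
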