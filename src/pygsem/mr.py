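"""Bidirectional two-sample Mendelian randomization on sumstats-shaped inputs.

Instrument selection (p-value threshold + greedy LD clumping), exposure /
outcome harmonization, five estimators (IVW with multiplicative random
effects, MR-Egger with its intercept and I2_GX, weighted median, weighted
mode, robust adjusted profile score), Cochran's Q heterogeneity, and Steiger
directionality filtering. The same machinery runs against ordinary GWAS
summary statistics or a latent-factor GWAS table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .sumstats import PALINDROMES, SumstatsTable

logger = logging.getLogger(__name__)

__all__ = [
    "InstrumentSet",
    "MRResult",
    "MRModel",
    "select_instruments",
    "harmonize_io",
    "mr_ivw",
    "mr_egger",
    "mr_weighted_median",
    "mr_weighted_mode",
    "mr_raps",
    "cochran_q",
    "steiger_filter",
    "bidirectional_mr",
    "BidirectionalResult",
]

MIN_INSTRUMENT_WARN = 10


@dataclass
class InstrumentSet:
    """Per-SNP exposure/outcome effects for an MR analysis."""

    table: pd.DataFrame
    p_threshold: float
    window_kb: float
    r2_cap: float
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"

    def __len__(self) -> int:
        return len(self.table)

    @property
    def bx(self) -> np.ndarray:
        return self.table["beta_exp"].to_numpy()

    @property
    def bxse(self) -> np.ndarray:
        return self.table["se_exp"].to_numpy()

    @property
    def by(self) -> np.ndarray:
        return self.table["beta_out"].to_numpy()

    @property
    def byse(self) -> np.ndarray:
        return self.table["se_out"].to_numpy()

    def oriented(self) -> "InstrumentSet":
        """Flip signs so every exposure beta is positive (estimator convention)."""
        t = self.table.copy()
        flip = t["beta_exp"] < 0
        t.loc[flip, "beta_exp"] = -t.loc[flip, "beta_exp"]
        t.loc[flip, "beta_out"] = -t.loc[flip, "beta_out"]
        return InstrumentSet(t, self.p_threshold, self.window_kb, self.r2_cap,
                             self.exposure_name, self.outcome_name)

    def subset(self, mask: np.ndarray) -> "InstrumentSet":
        return InstrumentSet(self.table.loc[np.asarray(mask)].reset_index(drop=True),
                             self.p_threshold, self.window_kb, self.r2_cap,
                             self.exposure_name, self.outcome_name)


@dataclass
class MRResult:
    """One estimator's causal estimate with its diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snp: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    i2_gx: float | None = None
    overdispersion: float | None = None
    converged: bool = True

    def summary(self) -> str:
        s = (f"{self.method}: beta = {self.beta:.4f} (SE {self.se:.4f}), "
             f"95% CI [{self.ci_low:.4f}, {self.ci_high:.4f}], p = {self.p:.3g}, "
             f"n_snp = {self.n_snp}")
        if self.egger_intercept is not None:
            s += f"; intercept = {self.egger_intercept:.4f} (p = {self.intercept_p:.3g})"
        if self.q is not None:
            s += f"; Q({self.q_df}) = {self.q:.2f}, p = {self.q_p:.3g}"
        return s

    def to_row(self) -> dict:
        return {
            "method": self.method, "n_snp": self.n_snp, "beta": self.beta,
            "se": self.se, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p": self.p, "q": self.q, "q_p": self.q_p,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.intercept_p, "i2_gx": self.i2_gx,
        }


# ---------------------------------------------------------------------------
# instrument selection & harmonization


def _ld_lookup(ld_ref: pd.DataFrame | None):
    """Map SNP -> (block, r2); SNPs outside the reference are independent."""
    if ld_ref is None:
        return {}
    return {s: (b, r) for s, b, r in zip(ld_ref["SNP"], ld_ref["BLOCK"], ld_ref["R2"])}


def select_instruments(
    exposure: SumstatsTable,
    ld_ref: pd.DataFrame | None,
    p_threshold: float = 5e-8,
    window_kb: float = 10_000,
    r2_cap: float = 0.001,
) -> InstrumentSet:
    """Greedy clumping of genome-wide significant exposure SNPs.

    Candidates with p < ``p_threshold`` are visited in ascending p (ties
    broken by position then id); each accepted index SNP removes later
    candidates on the same chromosome within ``window_kb`` whose reference
    r² with it exceeds ``r2_cap``.
    """
    df = exposure.df
    cand = df.loc[df["P"] < p_threshold].copy()
    if len(cand) == 0:
        logger.info("%s: no SNPs reach p < %.3g", exposure.name, p_threshold)
        return InstrumentSet(cand.assign(beta_exp=[], se_exp=[]), p_threshold,
                             window_kb, r2_cap, exposure_name=exposure.name)
    lookup = _ld_lookup(ld_ref)
    uncovered = [s for s in cand["SNP"] if s not in lookup] if ld_ref is not None else []
    if uncovered:
        logger.info("%d candidate SNP(s) missing from the LD reference; "
                    "treated as independent", len(uncovered))
    cand = cand.sort_values(["P", "BP", "SNP"], kind="mergesort").reset_index(drop=True)
    accepted: list[int] = []
    acc_chr: list[int] = []
    acc_bp: list[float] = []
    acc_block: list[int | None] = []
    window_bp = window_kb * 1000.0
    for i, row in cand.iterrows():
        block, r2 = lookup.get(row["SNP"], (None, 0.0))
        clumped = False
        for c, bp, blk in zip(acc_chr, acc_bp, acc_block):
            if c == row["CHR"] and abs(row["BP"] - bp) < window_bp:
                pair_r2 = r2 if (block is not None and block == blk) else 0.0
                if pair_r2 > r2_cap:
                    clumped = True
                    break
        if not clumped:
            accepted.append(i)
            acc_chr.append(row["CHR"])
            acc_bp.append(row["BP"])
            acc_block.append(block)
    out = cand.loc[accepted].reset_index(drop=True)
    out = out.rename(columns={"BETA": "beta_exp", "SE": "se_exp", "P": "p_exp",
                              "N": "n_exp", "Z": "z_exp"})
    return InstrumentSet(out, p_threshold, window_kb, r2_cap,
                         exposure_name=exposure.name)


def harmonize_io(instruments: InstrumentSet, outcome: SumstatsTable) -> InstrumentSet:
    """Attach outcome effects, aligned to the exposure effect allele.

    Outcome rows with swapped alleles are sign-flipped; palindromic or
    allele-mismatched SNPs are dropped, as are instruments absent from the
    outcome.
    """
    t = instruments.table.copy()
    odf = outcome.df.set_index("SNP")
    present = t["SNP"].isin(odf.index)
    if (~present).any():
        logger.info("%d instrument(s) absent from outcome, dropped", int((~present).sum()))
    t = t.loc[present].reset_index(drop=True)
    rows = []
    for _, row in t.iterrows():
        o = odf.loc[row["SNP"]]
        if (row["A1"], row["A2"]) in PALINDROMES:
            continue
        if o["A1"] == row["A1"] and o["A2"] == row["A2"]:
            sign = 1.0
        elif o["A1"] == row["A2"] and o["A2"] == row["A1"]:
            sign = -1.0
        else:
            continue
        r = dict(row)
        r["beta_out"] = sign * o["BETA"]
        r["se_out"] = o["SE"]
        r["p_out"] = o["P"]
        r["n_out"] = o["N"]
        r["z_out"] = sign * o["BETA"] / o["SE"]
        rows.append(r)
    merged = pd.DataFrame(rows)
    if len(merged) < 2:
        raise ValueError(
            f"only {len(merged)} instrument(s) survive harmonization; need >= 2")
    out = InstrumentSet(merged.reset_index(drop=True), instruments.p_threshold,
                        instruments.window_kb, instruments.r2_cap,
                        instruments.exposure_name, outcome.name)
    return out.oriented()


# ---------------------------------------------------------------------------
# estimators


def _ci_p(beta: float, se: float) -> tuple[float, float, float]:
    z = norm.ppf(0.975)
    p = 2.0 * norm.sf(abs(beta) / se) if se > 0 else np.nan
    return beta - z * se, beta + z * se, p


def mr_ivw(iset: InstrumentSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance weighted MR: origin-through weighted regression.

    With multiplicative random effects the SE is inflated by
    max(1, sqrt(Q / (n - 1))), the convention matching routine two-sample MR
    reporting; ``random_effects=False`` gives the fixed-effects SE.
    """
    n = len(iset)
    if n < 2:
        raise ValueError("IVW needs at least 2 instruments")
    if n < MIN_INSTRUMENT_WARN:
        warnings.warn(f"only {n} instruments; MR estimates from few instruments "
                      "are easily biased", stacklevel=2)
    bx, by, syse = iset.bx, iset.by, iset.byse
    w = 1.0 / syse ** 2
    beta = float(np.sum(w * bx * by) / np.sum(w * bx ** 2))
    se_fixed = float(np.sqrt(1.0 / np.sum(w * bx ** 2)))
    q, q_df, q_p = cochran_q(iset, beta, with_intercept=False)
    scale = max(1.0, np.sqrt(q / q_df)) if (random_effects and q_df > 0) else 1.0
    se = se_fixed * scale
    lo, hi, p = _ci_p(beta, se)
    return MRResult("IVW", beta, se, lo, hi, p, n, q=q, q_df=q_df, q_p=q_p)


def mr_egger(iset: InstrumentSet) -> MRResult:
    """MR-Egger: weighted regression with a free (pleiotropy) intercept.

    Requires orientation-positive exposure betas. Reports I2_GX, the
    regression-dilution gauge for the NO-Measurement-Error assumption
    computed from the exposure betas and their SEs.
    """
    n = len(iset)
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    iset = iset.oriented()
    bx, by, syse, sxse = iset.bx, iset.by, iset.byse, iset.bxse
    w = 1.0 / syse ** 2
    X = np.column_stack([np.ones(n), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    intercept, beta = float(coef[0]), float(coef[1])
    q, q_df, q_p = cochran_q(iset, beta, with_intercept=True, intercept=intercept)
    scale = max(1.0, np.sqrt(q / q_df)) if q_df > 0 else 1.0
    cov = np.linalg.inv(xtx) * scale ** 2
    se_int, se = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    lo, hi, p = _ci_p(beta, se)
    _, _, p_int = _ci_p(intercept, se_int)
    # I2_GX: 1 - (n - 1) / Q_GX with Q_GX the weighted heterogeneity of bx
    wx = 1.0 / sxse ** 2
    bx_bar = np.sum(wx * bx) / np.sum(wx)
    q_gx = float(np.sum(wx * (bx - bx_bar) ** 2))
    i2_gx = max(0.0, (q_gx - (n - 1)) / q_gx) if q_gx > 0 else 0.0
    return MRResult("Egger", beta, se, lo, hi, p, n,
                    egger_intercept=intercept, intercept_se=se_int,
                    intercept_p=p_int, q=q, q_df=q_df, q_p=q_p, i2_gx=i2_gx)


def _ratio_estimates(iset: InstrumentSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and delta-method SEs (first order)."""
    bx, by, syse = iset.bx, iset.by, iset.byse
    ratio = by / bx
    se = syse / np.abs(bx)
    return ratio, se


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v = values[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, cum, v))


def mr_weighted_median(iset: InstrumentSet, n_boot: int = 1000,
                       seed: int = 0) -> MRResult:
    """Weighted median of the per-SNP ratio estimates.

    Consistent when instruments contributing at least half the weight are
    valid. SE by parametric bootstrap of (bx, by) with a fixed seed.
    """
    n = len(iset)
    if n < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    ratio, rse = _ratio_estimates(iset)
    w = 1.0 / rse ** 2
    beta = _weighted_median(ratio, w)
    rng = np.random.default_rng(seed)
    bx, by = iset.bx, iset.by
    sxse, syse = iset.bxse, iset.byse
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sxse * rng.standard_normal(n)
        byb = by + syse * rng.standard_normal(n)
        rb = byb / bxb
        sb = syse / np.abs(bxb)
        boots[b] = _weighted_median(rb, 1.0 / sb ** 2)
    se = float(boots.std(ddof=1))
    lo, hi, p = _ci_p(beta, se)
    return MRResult("WeightedMedian", beta, se, lo, hi, p, n)


def _silverman_bw(x: np.ndarray, weights: np.ndarray) -> float:
    """Modified Silverman bandwidth on weighted ratio estimates."""
    wm = np.average(x, weights=weights)
    sd = np.sqrt(np.average((x - wm) ** 2, weights=weights))
    mad = np.median(np.abs(x - np.median(x))) / norm.ppf(0.75)
    s = min(sd, mad) if mad > 0 else sd
    if s <= 0:
        return 1e-6
    return float(0.9 * s * len(x) ** (-1 / 5))


def _kde_mode(x: np.ndarray, weights: np.ndarray, bw: float) -> float:
    # the mode of a Gaussian mixture lies within the convex hull of the data
    span = x.max() - x.min()
    grid = np.linspace(x.min() - 1e-9 * span, x.max() + 1e-9 * span, 2000)
    dens = np.exp(-0.5 * ((grid[:, None] - x[None, :]) / bw) ** 2) @ weights
    return float(grid[np.argmax(dens)])


def mr_weighted_mode(iset: InstrumentSet, bandwidth_factor: float = 1.0,
                     n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Mode of the inverse-variance-weighted kernel density of ratio estimates.

    Consistent when the largest group of instruments sharing a ratio is
    valid (plurality rule). Gaussian kernel with a modified Silverman
    bandwidth scaled by ``bandwidth_factor``; SE by parametric bootstrap.
    """
    n = len(iset)
    if n < 3:
        raise ValueError("weighted mode needs at least 3 instruments")
    ratio, rse = _ratio_estimates(iset)
    w = 1.0 / rse ** 2
    w = w / w.sum()
    bw = _silverman_bw(ratio, w) * bandwidth_factor
    if not np.isfinite(bw) or bw > 100 * (ratio.max() - ratio.min() + 1):
        beta = float(np.average(ratio, weights=w))
    else:
        beta = _kde_mode(ratio, w, bw)
    rng = np.random.default_rng(seed)
    bx, by = iset.bx, iset.by
    sxse, syse = iset.bxse, iset.byse
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + sxse * rng.standard_normal(n)
        byb = by + syse * rng.standard_normal(n)
        rb = byb / bxb
        sb = syse / np.abs(bxb)
        wb = 1.0 / sb ** 2
        wb = wb / wb.sum()
        bwb = _silverman_bw(rb, wb) * bandwidth_factor
        boots[b] = _kde_mode(rb, wb, bwb)
    se = float(boots.std(ddof=1))
    lo, hi, p = _ci_p(beta, se)
    return MRResult("WeightedMode", beta, se, lo, hi, p, n)


def mr_raps(iset: InstrumentSet, overdispersion: bool = True,
            robust: bool = False, huber_c: float = 1.345) -> MRResult:
    """Robust adjusted profile score MR.

    Maximizes the profile (quasi-)likelihood of the causal slope accounting
    for measurement error in the exposure betas, with an optional additive
    overdispersion variance for systematic (balanced) pleiotropy and an
    optional Huber loss for outlying instruments. Designed to stay unbiased
    with many weak instruments, e.g. under a relaxed selection threshold.
    """
    n = len(iset)
    if n < 3:
        raise ValueError("RAPS needs at least 3 instruments")
    bx, by, sxse, syse = iset.bx, iset.by, iset.bxse, iset.byse

    def rho(t: np.ndarray) -> np.ndarray:
        if not robust:
            return 0.5 * t ** 2
        a = np.abs(t)
        return np.where(a <= huber_c, 0.5 * t ** 2, huber_c * a - 0.5 * huber_c ** 2)

    def negloglik(params: np.ndarray) -> float:
        beta = params[0]
        tau2 = np.exp(params[1]) if overdispersion else 0.0
        v = syse ** 2 + beta ** 2 * sxse ** 2 + tau2
        t = (by - beta * bx) / np.sqrt(v)
        return float(np.sum(rho(t) + 0.5 * np.log(v)))

    # IVW start
    w0 = 1.0 / syse ** 2
    b0 = np.sum(w0 * bx * by) / np.sum(w0 * bx ** 2)
    x0 = np.array([b0, -12.0]) if overdispersion else np.array([b0])

    def obj(p):
        return negloglik(np.concatenate([p, [-30.0]])[:2]) if not overdispersion \
            else negloglik(p)

    res = optimize.minimize(obj, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    beta = float(res.x[0])
    tau2 = float(np.exp(res.x[1])) if overdispersion else 0.0
    # observed-information SE for beta (numerical second derivative)
    h = 1e-5 * max(1.0, abs(beta))

    def prof(b):
        p = res.x.copy()
        p[0] = b
        return obj(p)

    d2 = (prof(beta + h) - 2 * prof(beta) + prof(beta - h)) / h ** 2
    se = float(np.sqrt(1.0 / d2)) if d2 > 0 else np.nan
    lo, hi, p = _ci_p(beta, se)
    return MRResult("RAPS", beta, se, lo, hi, p, n, overdispersion=tau2,
                    converged=bool(res.success))


def wald_ratio(bx: float, by: float, byse: float) -> MRResult:
    """Single-instrument fallback: the ratio estimate by / bx."""
    beta = by / bx
    se = byse / abs(bx)
    lo, hi, p = _ci_p(beta, se)
    return MRResult("WaldRatio", beta, se, lo, hi, p, 1)


def cochran_q(iset: InstrumentSet, fitted_beta: float, with_intercept: bool = False,
              intercept: float = 0.0) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity about a fitted slope (and optional intercept).

    Q = sum w_j (by_j - intercept - beta * bx_j)^2 with w = 1/se_out^2;
    df = n - 1 (slope only) or n - 2 (Egger).
    """
    n = len(iset)
    df = n - (2 if with_intercept else 1)
    if df <= 0:
        warnings.warn("Cochran's Q undefined with so few instruments", stacklevel=2)
        return np.nan, df, np.nan
    w = 1.0 / iset.byse ** 2
    resid = iset.by - intercept - fitted_beta * iset.bx
    q = float(np.sum(w * resid ** 2))
    return q, df, float(chi2_dist.sf(q, df))


def steiger_filter(iset: InstrumentSet, n_exposure: float | None = None,
                   n_outcome: float | None = None) -> InstrumentSet:
    """Directionality filter: keep SNPs explaining more exposure than outcome variance.

    Per-SNP r² is approximated as z² / (z² + N); a SNP with larger outcome r²
    than exposure r² likely acts on the outcome first (reverse causation) and
    is flagged ``steiger_keep = False``. Returns the set with flags set; use
    ``.subset(set.table["steiger_keep"])`` to drop them.
    """
    t = iset.table.copy()
    n_exp = t["n_exp"].to_numpy() if n_exposure is None else float(n_exposure)
    if "n_out" not in t.columns and n_outcome is None:
        raise ValueError("outcome sample size required for Steiger filtering")
    n_out = t["n_out"].to_numpy() if n_outcome is None else float(n_outcome)
    z_exp = t["beta_exp"].to_numpy() / t["se_exp"].to_numpy()
    z_out = t["beta_out"].to_numpy() / t["se_out"].to_numpy()
    r2_exp = z_exp ** 2 / (z_exp ** 2 + n_exp)
    r2_out = z_out ** 2 / (z_out ** 2 + n_out)
    t["r2_exp"] = r2_exp
    t["r2_out"] = r2_out
    t["steiger_keep"] = r2_exp > r2_out
    dropped = int((~t["steiger_keep"]).sum())
    if dropped:
        logger.info("Steiger filter flags %d of %d instrument(s)", dropped, len(t))
    return InstrumentSet(t, iset.p_threshold, iset.window_kb, iset.r2_cap,
                         iset.exposure_name, iset.outcome_name)


# ---------------------------------------------------------------------------
# statsmodels-style front door


class MRModel:
    """Two-sample MR for one exposure-outcome direction.

    Wraps an :class:`InstrumentSet`; ``fit(method=...)`` dispatches to the
    individual estimators, ``fit_all`` runs the standard battery.
    """

    METHODS = ("ivw", "egger", "wmedian", "wmode", "raps")

    def __init__(self, iset: InstrumentSet, seed: int = 0):
        self.iset = iset
        self.seed = seed

    def fit(self, method: str = "ivw", **kwargs) -> MRResult:
        method = method.lower()
        if method == "ivw":
            return mr_ivw(self.iset, **kwargs)
        if method == "egger":
            return mr_egger(self.iset, **kwargs)
        if method == "wmedian":
            return mr_weighted_median(self.iset, seed=self.seed, **kwargs)
        if method == "wmode":
            return mr_weighted_mode(self.iset, seed=self.seed, **kwargs)
        if method == "raps":
            return mr_raps(self.iset, **kwargs)
        raise ValueError(f"unknown MR method {method!r}")

    def fit_all(self, methods: tuple[str, ...] = METHODS) -> list[MRResult]:
        out = []
        for m in methods:
            try:
                out.append(self.fit(m))
            except ValueError as err:
                logger.info("method %s skipped: %s", m, err)
        return out


@dataclass
class DirectionReport:
    """All estimators + diagnostics for one causal direction."""

    exposure: str
    outcome: str
    instruments: InstrumentSet | None
    results: list[MRResult] = field(default_factory=list)
    status: str = "ok"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"exposure": self.exposure, "outcome": self.outcome}
            row.update(r.to_row())
            rows.append(row)
        return pd.DataFrame(rows)

    def forest_data(self) -> pd.DataFrame:
        """Per-instrument Wald ratios with CIs, for forest plotting."""
        if self.instruments is None or len(self.instruments) == 0:
            return pd.DataFrame()
        iset = self.instruments
        ratio, rse = _ratio_estimates(iset)
        z = norm.ppf(0.975)
        return pd.DataFrame({
            "snp": iset.table["SNP"],
            "ratio": ratio, "se": rse,
            "ci_low": ratio - z * rse, "ci_high": ratio + z * rse,
        })


@dataclass
class BidirectionalResult:
    forward: DirectionReport
    reverse: DirectionReport

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.forward.to_frame(), self.reverse.to_frame()],
                         ignore_index=True)


def _one_direction(exposure: SumstatsTable, outcome: SumstatsTable,
                   ld_ref: pd.DataFrame | None, p_threshold: float,
                   window_kb: float, r2_cap: float, steiger: bool,
                   seed: int, methods: tuple[str, ...]) -> DirectionReport:
    iset = select_instruments(exposure, ld_ref, p_threshold, window_kb, r2_cap)
    if len(iset) == 0:
        return DirectionReport(exposure.name, outcome.name, None,
                               status="no genome-wide significant instruments")
    try:
        iset = harmonize_io(iset, outcome)
    except ValueError as err:
        return DirectionReport(exposure.name, outcome.name, None, status=str(err))
    if steiger:
        iset = steiger_filter(iset)
        iset = iset.subset(iset.table["steiger_keep"].to_numpy())
        if len(iset) < 2:
            return DirectionReport(exposure.name, outcome.name, iset,
                                   status="fewer than 2 instruments after Steiger")
    results = MRModel(iset, seed=seed).fit_all(methods)
    return DirectionReport(exposure.name, outcome.name, iset, results=results)


def bidirectional_mr(
    a: SumstatsTable,
    b: SumstatsTable,
    ld_ref: pd.DataFrame | None,
    p_threshold: float = 5e-8,
    window_kb: float = 10_000,
    r2_cap: float = 0.001,
    steiger: bool = True,
    seed: int = 0,
    methods: tuple[str, ...] = MRModel.METHODS,
) -> BidirectionalResult:
    """Run the full MR battery in both directions between two traits.

    Each direction runs instrument selection, harmonization, optional Steiger
    filtering, then every requested estimator; a direction without usable
    instruments is reported as not estimable without blocking the other.
    """
    fwd = _one_direction(a, b, ld_ref, p_threshold, window_kb, r2_cap,
                         steiger, seed, methods)
    rev = _one_direction(b, a, ld_ref, p_threshold, window_kb, r2_cap,
                         steiger, seed + 1, methods)
    return BidirectionalResult(forward=fwd, reverse=rev)
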