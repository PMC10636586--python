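"""Genomic factor analysis on LDSC covariance matrices.

The workflow mirrors how multi-trait genetic covariance structure is usually
explored and confirmed: eigenvalue screening (Kaiser's criterion) and
exploratory factor analysis with an oblique rotation on the genetic
correlation matrix from one half of the genome (odd chromosomes), then
confirmatory / structural models fitted to the other half's covariance
matrix S by diagonally weighted least squares, with the full sampling
covariance V entering through sandwich standard errors and a residual-based
chi-square.

Model specification uses a small declarative text syntax::

    NMD =~ adhd + anx + asd + mdd + ptsd
    SUT =~ alc + can + smk
    LONE =~ 1*lone
    lone ~~ 0*lone
    LONE ~ NMD + 0*SUT + DPF

``=~`` defines loadings (a numeric prefix fixes one), ``~`` regressions among
latents, ``~~`` (co)variances. Factors with no fixed loading are identified
by unit variance, so loadings and regression paths are on the standardized
genetic-factor scale.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

from .ldsc import GeneticCovariance

logger = logging.getLogger(__name__)

__all__ = [
    "FactorModelSpec",
    "GenomicFactorModel",
    "GenomicFactorResults",
    "LonelinessModels",
    "smooth_to_pd",
    "pca_scree",
    "efa_fit",
    "fit_indices",
    "loneliness_models",
]


# ---------------------------------------------------------------------------
# matrix utilities


def smooth_to_pd(S: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Nearest-in-spirit positive-definite smoothing by eigenvalue clipping.

    Eigenvalues are floored at ``eps`` and the result rescaled to preserve
    the original diagonal. Already-PD matrices are returned unchanged.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("smooth_to_pd expects a symmetric matrix")
    w, u = np.linalg.eigh(S)
    if w.min() >= eps:
        return S
    w_clipped = np.clip(w, eps, None)
    out = (u * w_clipped) @ u.T
    d = np.sqrt(np.diag(S) / np.diag(out))
    out = out * np.outer(d, d)
    max_change = float(np.abs(out - S).max())
    logger.info("smooth_to_pd: clipped eigenvalues below %.1e (max change %.3g)",
                eps, max_change)
    return (out + out.T) / 2


def _to_correlation(S: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(S))
    if np.any(d <= 0):
        raise ValueError("non-positive diagonal; cannot standardize")
    return S / np.outer(d, d)


def _vech(a: np.ndarray) -> np.ndarray:
    return a[np.tril_indices(a.shape[0])]


# ---------------------------------------------------------------------------
# PCA / Kaiser scree


@dataclass
class ScreeResult:
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    n_retained: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, len(self.eigenvalues) + 1),
            "eigenvalue": self.eigenvalues,
            "variance_explained": self.variance_explained,
        })


def pca_scree(gc: GeneticCovariance) -> ScreeResult:
    """Eigenvalues of the smoothed genetic correlation matrix.

    ``n_retained`` counts eigenvalues strictly greater than one (Kaiser's
    criterion). Intended for the odd-chromosome covariance so that factor
    enumeration and confirmation use disjoint data.
    """
    if gc.subset != "odd_chr":
        warnings.warn(
            f"PCA scree on subset {gc.subset!r}; factor enumeration is usually "
            "done on the odd-chromosome matrix", stacklevel=2)
    R = _to_correlation(smooth_to_pd(gc.S))
    if not np.all(np.isfinite(R)):
        raise ValueError("non-finite genetic covariance")
    ev = np.sort(np.linalg.eigvalsh(R))[::-1]
    return ScreeResult(eigenvalues=ev, variance_explained=ev / len(ev),
                       n_retained=int((ev > 1.0).sum()))


# ---------------------------------------------------------------------------
# EFA: principal-axis extraction + varimax/promax rotation


def _principal_axis(R: np.ndarray, n_factors: int, max_iter: int = 200,
                    tol: float = 1e-6) -> np.ndarray:
    """Iterated principal-axis factoring on a correlation matrix."""
    k = R.shape[0]
    inv_diag = np.diag(np.linalg.inv(R))
    comm = 1.0 - 1.0 / inv_diag          # squared multiple correlations
    for _ in range(max_iter):
        Rh = R.copy()
        Rh[np.diag_indices(k)] = comm
        w, u = np.linalg.eigh(Rh)
        order = np.argsort(w)[::-1][:n_factors]
        lam = u[:, order] * np.sqrt(np.clip(w[order], 0, None))
        new_comm = (lam ** 2).sum(axis=1)
        if np.any(new_comm > 1.0):
            warnings.warn("Heywood case: communality above 1, clipped", stacklevel=3)
            new_comm = np.clip(new_comm, None, 0.999)
        if np.abs(new_comm - comm).max() < tol:
            comm = new_comm
            break
        comm = new_comm
    Rh = R.copy()
    Rh[np.diag_indices(k)] = comm
    w, u = np.linalg.eigh(Rh)
    order = np.argsort(w)[::-1][:n_factors]
    return u[:, order] * np.sqrt(np.clip(w[order], 0, None))


def _varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    p, k = L.shape
    if k == 1:
        return L
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        LR = L @ R
        grad = L.T @ (LR ** 3 - LR @ np.diag((LR ** 2).sum(axis=0)) / p)
        u, s, vt = np.linalg.svd(grad)
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    return L @ R


def _promax(L_varimax: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Oblique promax rotation; returns (pattern loadings, factor corr)."""
    x = L_varimax
    if x.shape[1] == 1:
        return x, np.eye(1)
    q = x * np.abs(x) ** (power - 1)
    u = np.linalg.solve(x.T @ x, x.T @ q)
    d = np.diag(np.linalg.inv(u.T @ u))
    u = u @ np.diag(np.sqrt(d))
    pattern = x @ u
    phi = np.linalg.inv(u.T @ u)
    # normalize to exact unit diagonal against round-off
    dphi = np.sqrt(np.diag(phi))
    phi = phi / np.outer(dphi, dphi)
    return pattern, phi


@dataclass
class EFAResult:
    traits: list[str]
    loadings: np.ndarray            # pattern matrix (trait x factor), oblique
    factor_corr: np.ndarray
    variance_explained: np.ndarray  # per factor, fraction of total
    salience: float
    heywood: bool = False

    @property
    def total_variance_explained(self) -> float:
        return float(self.variance_explained.sum())

    def proposed_pattern(self) -> dict[str, list[str]]:
        """Salient-loading assignment usable as a CFA pattern."""
        out: dict[str, list[str]] = {}
        primary = np.abs(self.loadings).argmax(axis=1)
        for f in range(self.loadings.shape[1]):
            members = [self.traits[i] for i in range(len(self.traits))
                       if abs(self.loadings[i, f]) >= self.salience and primary[i] == f]
            out[f"F{f + 1}"] = members
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.loadings, index=self.traits,
                          columns=[f"F{f + 1}" for f in range(self.loadings.shape[1])])
        return df


def efa_fit(gc: GeneticCovariance, n_factors: int, salience: float = 0.25,
            rotation: str = "promax") -> EFAResult:
    """Exploratory factor analysis of the genetic correlation matrix.

    Principal-axis extraction followed by an oblique promax rotation (the
    retained genetic factors are expected to be intercorrelated); use
    ``rotation="varimax"`` for an orthogonal solution.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be at least 1")
    R = _to_correlation(smooth_to_pd(gc.S))
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        lam = _principal_axis(R, n_factors)
    heywood = any("Heywood" in str(c.message) for c in caught)
    if heywood:
        warnings.warn("Heywood case: communality above 1, clipped", stacklevel=2)
    lam_v = _varimax(lam)
    if rotation == "promax":
        pattern, phi = _promax(lam_v)
    elif rotation == "varimax":
        pattern, phi = lam_v, np.eye(n_factors)
    else:
        raise ValueError(f"unknown rotation {rotation!r}")
    # orient factors so the dominant loading is positive
    signs = np.sign(pattern[np.abs(pattern).argmax(axis=0), np.arange(n_factors)])
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    var_per_factor = (lam_v ** 2).sum(axis=0) / R.shape[0]
    return EFAResult(traits=list(gc.traits), loadings=pattern, factor_corr=phi,
                     variance_explained=var_per_factor, salience=salience,
                     heywood=heywood)


# ---------------------------------------------------------------------------
# model specification


_FIXED_RE = re.compile(r"^\s*([+-]?\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*\*\s*(\S+)\s*$")


def _parse_term(term: str) -> tuple[float | None, str]:
    term = term.strip()
    m = _FIXED_RE.match(term)
    if m:
        return float(m.group(1)), m.group(2)
    return None, term


@dataclass
class FactorModelSpec:
    """Declarative path model over observed traits and latent factors."""

    observed: list[str]
    latents: list[str]
    lam_free: np.ndarray       # (k, m) bool
    lam_fixed: np.ndarray      # (k, m) float, value where not free
    b_free: np.ndarray         # (m, m) bool, row = dependent latent
    b_fixed: np.ndarray
    psi_free: np.ndarray       # (m, m) bool, symmetric
    psi_fixed: np.ndarray
    theta_free: np.ndarray     # (k,) bool
    theta_fixed: np.ndarray    # (k,) float
    text: str = ""

    @property
    def k(self) -> int:
        return len(self.observed)

    @property
    def m(self) -> int:
        return len(self.latents)

    @property
    def n_free(self) -> int:
        return (int(self.lam_free.sum()) + int(self.b_free.sum())
                + int(np.tril(self.psi_free).sum()) + int(self.theta_free.sum()))

    @property
    def df(self) -> int:
        p = self.k * (self.k + 1) // 2
        return p - self.n_free

    def param_names(self) -> list[str]:
        names = []
        for f in range(self.m):
            for i in range(self.k):
                if self.lam_free[i, f]:
                    names.append(f"{self.latents[f]}=~{self.observed[i]}")
        for r in range(self.m):
            for c in range(self.m):
                if self.b_free[r, c]:
                    names.append(f"{self.latents[r]}~{self.latents[c]}")
        for r in range(self.m):
            for c in range(r + 1):
                if self.psi_free[r, c]:
                    names.append(f"{self.latents[r]}~~{self.latents[c]}")
        for i in range(self.k):
            if self.theta_free[i]:
                names.append(f"{self.observed[i]}~~{self.observed[i]}")
        return names

    def validate(self) -> None:
        if self.df < 0:
            raise ValueError(
                f"model not identified: {self.n_free} free parameters exceed "
                f"{self.k * (self.k + 1) // 2} unique moments")
        has_indicator = (self.lam_free | (self.lam_fixed != 0)).any(axis=0)
        has_inbound = (self.b_free | (self.b_fixed != 0)).any(axis=1)
        for f in range(self.m):
            if not has_indicator[f] and not has_inbound[f]:
                raise ValueError(
                    f"latent {self.latents[f]!r} has neither an indicator nor "
                    "an inbound path")

    @classmethod
    def from_text(cls, text: str, observed: list[str]) -> "FactorModelSpec":
        """Parse the declarative syntax against an ordered trait list.

        Only traits actually referenced become the model's observed
        variables (subset models stay well-defined against the full S).
        """
        loadings: list[tuple[str, str, float | None]] = []
        regressions: list[tuple[str, str, float | None]] = []
        covariances: list[tuple[str, str, float | None]] = []
        latents: list[str] = []
        for raw in text.splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "=~" in line:
                lhs, rhs = line.split("=~")
                factor = lhs.strip()
                if factor not in latents:
                    latents.append(factor)
                for term in rhs.split("+"):
                    val, name = _parse_term(term)
                    loadings.append((factor, name, val))
            elif "~~" in line:
                lhs, rhs = line.split("~~")
                val, name = _parse_term(rhs)
                covariances.append((lhs.strip(), name, val))
            elif "~" in line:
                lhs, rhs = line.split("~")
                dep = lhs.strip()
                if dep not in latents:
                    latents.append(dep)
                for term in rhs.split("+"):
                    val, name = _parse_term(term)
                    if name not in latents:
                        latents.append(name)
                    regressions.append((dep, name, val))
            else:
                raise ValueError(f"cannot parse model line: {raw!r}")

        used = [n for _, n, _ in loadings]
        # variance statements can introduce observed variables on their own
        # (e.g. a latent-free diagonal model)
        used += [lhs for lhs, rhs, _ in covariances
                 if lhs == rhs and lhs not in latents]
        obs = [t for t in observed if t in used]
        missing = sorted(set(used) - set(observed))
        if missing:
            raise ValueError(f"indicator(s) not among observed traits: {missing}")
        k, m = len(obs), len(latents)
        oi = {t: i for i, t in enumerate(obs)}
        li = {f: i for i, f in enumerate(latents)}

        lam_free = np.zeros((k, m), dtype=bool)
        lam_fixed = np.zeros((k, m))
        for factor, name, val in loadings:
            i, f = oi[name], li[factor]
            if val is None:
                lam_free[i, f] = True
            else:
                lam_fixed[i, f] = val

        b_free = np.zeros((m, m), dtype=bool)
        b_fixed = np.zeros((m, m))
        for dep, pred, val in regressions:
            r, c = li[dep], li[pred]
            if val is None:
                b_free[r, c] = True
            else:
                b_fixed[r, c] = val

        theta_free = np.ones(k, dtype=bool)
        theta_fixed = np.zeros(k)
        psi_free = np.zeros((m, m), dtype=bool)
        psi_fixed = np.zeros((m, m))

        endogenous = b_free.any(axis=1) | (b_fixed != 0).any(axis=1)
        marker = (lam_fixed != 0).any(axis=0)
        for f in range(m):
            if endogenous[f] or marker[f]:
                psi_free[f, f] = True        # disturbance / marker-scaled variance
            else:
                psi_fixed[f, f] = 1.0        # unit-variance identification
        # free covariances among non-endogenous latent pairs
        for a in range(m):
            for b in range(a):
                if not endogenous[a] and not endogenous[b]:
                    psi_free[a, b] = psi_free[b, a] = True

        for lhs, rhs, val in covariances:
            if lhs in li and rhs in li:
                a, b = li[lhs], li[rhs]
                if val is None:
                    psi_free[a, b] = psi_free[b, a] = True
                else:
                    psi_free[a, b] = psi_free[b, a] = False
                    psi_fixed[a, b] = psi_fixed[b, a] = val
            elif lhs in oi and rhs in oi and lhs == rhs:
                i = oi[lhs]
                if val is None:
                    theta_free[i] = True
                else:
                    theta_free[i] = False
                    theta_fixed[i] = val
            else:
                raise ValueError(f"unsupported covariance statement {lhs}~~{rhs}")

        spec = cls(observed=obs, latents=latents, lam_free=lam_free,
                   lam_fixed=lam_fixed, b_free=b_free, b_fixed=b_fixed,
                   psi_free=psi_free, psi_fixed=psi_fixed,
                   theta_free=theta_free, theta_fixed=theta_fixed, text=text)
        spec.validate()
        return spec


# ---------------------------------------------------------------------------
# the DWLS structural model


class GenomicFactorModel:
    """Structural model for a genetic covariance matrix, fitted by DWLS.

    The discrepancy ``sum_i (s_i - sigma_i(theta))^2 / V_ii`` is minimized
    over the free parameters; the sampling covariance V enters fully through
    sandwich standard errors and the residual-based chi-square, as is
    standard when the weight matrix is only the diagonal of V.
    """

    def __init__(self, gc: GeneticCovariance, spec: FactorModelSpec,
                 v_floor: float = 1e-10):
        spec.validate()
        self.gc = gc
        self.spec = spec
        order = [gc.traits.index(t) for t in spec.observed]
        S = smooth_to_pd(gc.S)[np.ix_(order, order)]
        self.S = S
        self.s = _vech(S)
        # map spec's vech positions into gc's V
        k = spec.k
        pos = []
        for i in range(k):
            for j in range(i + 1):
                pos.append(gc.vech_index(order[i], order[j]))
        self.V = gc.V[np.ix_(pos, pos)]
        self.w = 1.0 / np.clip(np.diag(self.V), v_floor, None)
        self._tril = np.tril_indices(k)

    # -- parameter packing ---------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        sp = self.spec
        lam = sp.lam_fixed.copy()
        b = sp.b_fixed.copy()
        psi = sp.psi_fixed.copy()
        th = sp.theta_fixed.copy()
        i = 0
        lam_idx = np.argwhere(sp.lam_free.T)    # (f, i) pairs in factor-major order
        for f, r in lam_idx:
            lam[r, f] = theta[i]
            i += 1
        for r in range(sp.m):
            for c in range(sp.m):
                if sp.b_free[r, c]:
                    b[r, c] = theta[i]
                    i += 1
        for r in range(sp.m):
            for c in range(r + 1):
                if sp.psi_free[r, c]:
                    psi[r, c] = psi[c, r] = theta[i]
                    i += 1
        for j in range(sp.k):
            if sp.theta_free[j]:
                th[j] = theta[i]
                i += 1
        return lam, b, psi, th

    def implied_cov(self, theta: np.ndarray) -> np.ndarray:
        lam, b, psi, th = self._unpack(theta)
        ib = np.linalg.inv(np.eye(self.spec.m) - b)
        phi = ib @ psi @ ib.T
        return lam @ phi @ lam.T + np.diag(th)

    def latent_cov(self, theta: np.ndarray) -> np.ndarray:
        _, b, psi, _ = self._unpack(theta)
        ib = np.linalg.inv(np.eye(self.spec.m) - b)
        return ib @ psi @ ib.T

    def _sigma_vech(self, theta: np.ndarray) -> np.ndarray:
        return self.implied_cov(theta)[self._tril]

    def _objective(self, theta: np.ndarray) -> float:
        r = self.s - self._sigma_vech(theta)
        return float(np.dot(r * self.w, r))

    def start_values(self, jitter: float = 0.0, rng: np.random.Generator | None = None
                     ) -> np.ndarray:
        sp = self.spec
        diag = np.diag(self.S)
        trait_sd = np.sqrt(np.clip(diag, 1e-6, None))
        vals = []
        lam_idx = np.argwhere(sp.lam_free.T)
        for f, r in lam_idx:
            vals.append(0.5 * trait_sd[r])
        vals.extend([0.0] * int(sp.b_free.sum()))
        for r in range(sp.m):
            for c in range(r + 1):
                if sp.psi_free[r, c]:
                    vals.append(0.05 if r == c else 0.0)
        for j in range(sp.k):
            if sp.theta_free[j]:
                vals.append(0.5 * diag[j])
        theta = np.array(vals)
        if jitter > 0 and rng is not None:
            theta = theta + jitter * rng.standard_normal(len(theta)) * np.maximum(
                np.abs(theta), 0.05)
        return theta

    def _bounds(self) -> list[tuple[float | None, float | None]]:
        sp = self.spec
        bounds: list[tuple[float | None, float | None]] = []
        bounds += [(None, None)] * int(sp.lam_free.sum())
        bounds += [(None, None)] * int(sp.b_free.sum())
        for r in range(sp.m):
            for c in range(r + 1):
                if sp.psi_free[r, c]:
                    bounds.append((1e-8, None) if r == c else (None, None))
        for j in range(sp.k):
            if sp.theta_free[j]:
                bounds.append((0.0, None))
        return bounds

    # -- fitting -------------------------------------------------------------

    def fit(self, n_starts: int = 3, seed: int = 0, maxiter: int = 2000,
            gtol: float = 1e-8) -> "GenomicFactorResults":
        rng = np.random.default_rng(seed)
        best = None
        total_iter = 0
        for attempt in range(n_starts):
            theta0 = self.start_values(jitter=0.0 if attempt == 0 else 0.3, rng=rng)
            res = optimize.minimize(
                self._objective, theta0, method="L-BFGS-B",
                bounds=self._bounds(),
                options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-14})
            total_iter += res.nit
            if best is None or res.fun < best.fun - 1e-12:
                best = res
        converged = bool(best.success or np.max(np.abs(best.jac)) < 1e-5)
        if not converged:
            logger.warning("structural model did not converge: %s", best.message)
        return GenomicFactorResults(self, best.x, converged=converged,
                                    n_iterations=total_iter, fmin=float(best.fun))


def _numeric_jacobian(fun, theta: np.ndarray, h: float = 1e-6) -> np.ndarray:
    f0 = fun(theta)
    jac = np.empty((len(f0), len(theta)))
    for j in range(len(theta)):
        step = h * max(1.0, abs(theta[j]))
        tp = theta.copy(); tp[j] += step
        tm = theta.copy(); tm[j] -= step
        jac[:, j] = (fun(tp) - fun(tm)) / (2 * step)
    return jac


def _pinv_psd(V: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    w, u = np.linalg.eigh((V + V.T) / 2)
    cut = w.max() * rcond
    inv_w = np.where(w > cut, 1.0 / np.clip(w, cut, None), 0.0)
    return (u * inv_w) @ u.T


def _residual_chi2(r: np.ndarray, V: np.ndarray, delta: np.ndarray | None) -> float:
    """Residual-based test statistic: r' [Vi - Vi D (D'Vi D)^-1 D'Vi] r.

    Asymptotically chi-square with p - q degrees of freedom for any
    consistent estimator, which makes it the natural test when the fitting
    weight is only diag(V).
    """
    vi = _pinv_psd(V)
    if delta is None or delta.size == 0:
        return float(r @ vi @ r)
    vid = vi @ delta
    middle = vi - vid @ _pinv_psd(delta.T @ vid) @ vid.T
    return float(r @ middle @ r)


class GenomicFactorResults:
    """Estimates, sandwich SEs and fit indices for a fitted structural model."""

    def __init__(self, model: GenomicFactorModel, theta: np.ndarray,
                 converged: bool, n_iterations: int, fmin: float):
        self.model = model
        self.spec = model.spec
        self.theta = theta
        self.converged = converged
        self.n_iterations = n_iterations
        self.fmin = fmin
        self.param_names = model.spec.param_names()
        self._delta = _numeric_jacobian(model._sigma_vech, theta)
        self._compute_se()
        self._compute_fit()

    # -- inference -----------------------------------------------------------

    def _compute_se(self) -> None:
        m = self.model
        W = m.w
        d = self._delta
        bread = _pinv_psd(d.T @ (d * W[:, None]))
        meat = (d * W[:, None]).T @ m.V @ (d * W[:, None])
        cov = bread @ meat @ bread
        self.cov_params = (cov + cov.T) / 2
        self.bse = np.sqrt(np.clip(np.diag(self.cov_params), 0, None))

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.theta, index=self.param_names)

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return pd.Series(self.theta / self.bse, index=self.param_names)

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * norm.sf(np.abs(self.zvalues.values)),
                         index=self.param_names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        zq = norm.ppf(1 - alpha / 2)
        return pd.DataFrame({
            "low": self.theta - zq * self.bse,
            "high": self.theta + zq * self.bse,
        }, index=self.param_names)

    # -- fit indices ---------------------------------------------------------

    def _compute_fit(self) -> None:
        m = self.model
        sp = self.spec
        r = m.s - m._sigma_vech(self.theta)
        self.df = sp.df
        self.chi2 = max(0.0, _residual_chi2(r, m.V, self._delta)) if sp.df > 0 else 0.0
        self.pvalue = float(chi2_dist.sf(self.chi2, self.df)) if self.df > 0 else 1.0

        # baseline: diagonal model (variances free, covariances zero)
        k = sp.k
        tril = np.tril_indices(k)
        diag_mask = tril[0] == tril[1]
        delta_b = np.zeros((len(m.s), int(diag_mask.sum())))
        delta_b[np.nonzero(diag_mask)[0], np.arange(int(diag_mask.sum()))] = 1.0
        r_b = m.s - np.where(diag_mask, m.s, 0.0)
        self.baseline_chi2 = max(0.0, _residual_chi2(r_b, m.V, delta_b))
        self.baseline_df = len(m.s) - k
        denom = self.baseline_chi2 - self.baseline_df
        numer = max(self.chi2 - self.df, 0.0)
        self.cfi_flag = denom <= 0
        self.cfi = 1.0 if self.cfi_flag else 1.0 - numer / denom
        if not self.cfi_flag:
            self.cfi = float(np.clip(self.cfi, 0.0, 1.0))

        # SRMR on the correlation scale, all unique elements
        d = np.sqrt(np.diag(m.S))
        scale = np.outer(d, d)[tril]
        resid_std = r / scale
        self.srmr = float(np.sqrt(np.mean(resid_std ** 2)))

    # -- standardization -----------------------------------------------------

    def standardized(self) -> pd.DataFrame:
        """Standardized solution: loadings/paths on unit-variance scales."""
        m = self.model
        sp = self.spec
        lam, b, psi, th = m._unpack(self.theta)
        phi = m.latent_cov(self.theta)
        sigma = m.implied_cov(self.theta)
        sd_lat = np.sqrt(np.clip(np.diag(phi), 1e-12, None))
        sd_obs = np.sqrt(np.clip(np.diag(sigma), 1e-12, None))
        rows = []
        for name, est, se in zip(self.param_names, self.theta, self.bse):
            if "=~" in name:
                f, o = name.split("=~")
                fi, ii = sp.latents.index(f), sp.observed.index(o)
                std = est * sd_lat[fi] / sd_obs[ii]
            elif "~~" in name:
                a, bnm = name.split("~~")
                if a in sp.latents:
                    ai, bi = sp.latents.index(a), sp.latents.index(bnm)
                    std = psi[ai, bi] / (sd_lat[ai] * sd_lat[bi]) if ai != bi \
                        else psi[ai, ai] / phi[ai, ai]
                else:
                    ii = sp.observed.index(a)
                    std = est / sigma[ii, ii]
            else:
                dep, pred = name.split("~")
                di, pi = sp.latents.index(dep), sp.latents.index(pred)
                std = est * sd_lat[pi] / sd_lat[di]
            ratio = abs(std / est) if est != 0 else np.nan
            rows.append({"param": name, "est": est, "se": se,
                         "std_est": std, "std_se": se * ratio if np.isfinite(ratio) else np.nan})
        return pd.DataFrame(rows).set_index("param")

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Genomic structural model (DWLS, sandwich SEs)",
            f"  observed: {', '.join(self.spec.observed)}",
            f"  latents:  {', '.join(self.spec.latents)}",
            f"  converged: {self.converged}  iterations: {self.n_iterations}",
            f"  chi2({self.df}) = {self.chi2:.3f}, p = {self.pvalue:.3g}, "
            f"SRMR = {self.srmr:.4f}, CFI = {self.cfi:.4f}"
            + ("  [baseline degenerate]" if self.cfi_flag else ""),
            "",
            f"  {'parameter':<20} {'est':>9} {'SE':>8} {'z':>8} {'p':>10}",
        ]
        for name, est, se, z, p in zip(self.param_names, self.theta, self.bse,
                                       self.zvalues.values, self.pvalues.values):
            lines.append(f"  {name:<20} {est:9.4f} {se:8.4f} {z:8.2f} {p:10.3g}")
        return "\n".join(lines)


def fit_indices(fit: GenomicFactorResults, gc: GeneticCovariance | None = None) -> dict:
    """Convenience accessor for the fit statistics of a fitted model."""
    if not fit.converged:
        warnings.warn("fit indices from a non-converged model", stacklevel=2)
    return {
        "chi2": fit.chi2, "df": fit.df, "p": fit.pvalue,
        "srmr": fit.srmr, "cfi": fit.cfi, "cfi_flag": fit.cfi_flag,
        "baseline_chi2": fit.baseline_chi2, "baseline_df": fit.baseline_df,
    }


# ---------------------------------------------------------------------------
# the three loneliness structural models


@dataclass
class LonelinessModels:
    """Unadjusted, adjusted and constrained loneliness regression fits."""

    unadjusted: list[GenomicFactorResults]
    adjusted: GenomicFactorResults
    constrained: GenomicFactorResults
    target_factor: str

    @property
    def any_nonconverged(self) -> bool:
        fits = list(self.unadjusted) + [self.adjusted, self.constrained]
        return any(not f.converged for f in fits)


def _measurement_lines(pattern: dict[str, list[str]]) -> list[str]:
    return [f"{f} =~ {' + '.join(ind)}" for f, ind in pattern.items()]


def loneliness_models(gc: GeneticCovariance, pattern: dict[str, list[str]],
                      loneliness: str, target_factor: str | None = None,
                      lone_factor: str = "LONE", seed: int = 0) -> LonelinessModels:
    """Fit the three structural regressions of a single-indicator latent.

    ``pattern`` maps factor names to indicator traits. The loneliness trait
    becomes a latent with its loading fixed to 1 and its indicator residual
    fixed to 0. Three models are fitted: (1) separate bivariate regressions
    of the loneliness latent on each factor; (2) a joint regression on all
    factors with free factor intercorrelations; (3) the joint model with
    every path except the one to ``target_factor`` fixed to zero.
    """
    factors = list(pattern)
    if target_factor is None:
        target_factor = factors[0]
    if target_factor not in factors:
        raise ValueError(f"target factor {target_factor!r} not in pattern")
    lone_meas = [f"{lone_factor} =~ 1*{loneliness}", f"{loneliness} ~~ 0*{loneliness}"]

    unadjusted = []
    for f in factors:
        text = "\n".join([f"{f} =~ {' + '.join(pattern[f])}"] + lone_meas
                         + [f"{lone_factor} ~ {f}"])
        spec = FactorModelSpec.from_text(text, gc.traits)
        unadjusted.append(GenomicFactorModel(gc, spec).fit(seed=seed))

    joint = "\n".join(_measurement_lines(pattern) + lone_meas
                      + [f"{lone_factor} ~ {' + '.join(factors)}"])
    adjusted = GenomicFactorModel(
        gc, FactorModelSpec.from_text(joint, gc.traits)).fit(seed=seed)

    terms = [f if f == target_factor else f"0*{f}" for f in factors]
    constrained_text = "\n".join(_measurement_lines(pattern) + lone_meas
                                 + [f"{lone_factor} ~ {' + '.join(terms)}"])
    constrained = GenomicFactorModel(
        gc, FactorModelSpec.from_text(constrained_text, gc.traits)).fit(seed=seed)

    out = LonelinessModels(unadjusted=unadjusted, adjusted=adjusted,
                           constrained=constrained, target_factor=target_factor)
    if out.any_nonconverged:
        warnings.warn("one or more loneliness structural models did not converge",
                      stacklevel=2)
    return out
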