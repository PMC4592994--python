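"""Cumulative-link ordinal regression via Pólya-Gamma Gibbs sampling.

The model.  Each observation j of line i carries an ordinal score
y_ij ∈ {1..C} generated by a latent liability

    l_ij = x_ij'β + b_i + ε_ij,

with ε standard logistic (logit link) or standard normal (probit link), and
y_ij = c iff γ_{c−1} < l_ij < γ_c for strictly increasing thresholds
γ_1 < … < γ_{C−1} (γ_0 = −∞, γ_C = +∞).  β are fixed (or marker) effects
with prior N(β₀, Σ₀σ_β²); b is an optional line-level polygenic effect with
prior N(0, G σ_b²) for a genomic relationship matrix G; the variances carry
scaled inverse chi-square priors and the thresholds are order statistics of
U(γmin, γmax).

Augmenting every logistic observation with ω_ij ~ PG(2, ·) makes all full
conditionals conjugate: liabilities are truncated normal with variance
1/ω_ij, β and b are multivariate normal, the variances scaled inverse
chi-square, and each threshold uniform.  Fixing ω ≡ 1 (and skipping the PG
draw) gives exactly the classic probit threshold sampler, so the probit
model is a special case of the same loop.

When p ≫ n (all markers in X with an i.i.d. shrinkage prior — threshold
Bayesian ridge regression), β is drawn by an n-dimensional auxiliary-
variable algorithm whose output distribution is identical to the p×p
formula; the switch is automatic at p > 2n.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import ndtri

from . import _kernels
from .samplers import RNGStream, sample_scaled_inv_chisq

__all__ = [
    "ValidationError",
    "ThresholdOrderError",
    "DegenerateThresholdError",
    "MatrixConditioningError",
    "OrdinalDataset",
    "PriorSpec",
    "ChainConfig",
    "ChainState",
    "PosteriorSamples",
    "initial_state",
    "update_liabilities",
    "update_omegas",
    "update_beta",
    "update_polygenic",
    "update_sigma_b2",
    "update_thresholds",
    "update_sigma_beta2",
    "run_chain",
]

logger = logging.getLogger(__name__)


class ValidationError(ValueError):
    """Input data or configuration violates a model precondition."""


class ThresholdOrderError(RuntimeError):
    """Thresholds are not strictly increasing / liability interval empty."""


class DegenerateThresholdError(RuntimeError):
    """A threshold full conditional has an empty support interval."""


class MatrixConditioningError(RuntimeError):
    """A posterior precision or relationship matrix is not positive definite."""


# ---------------------------------------------------------------------------
# Data containers


class OrdinalDataset:
    """Ordinal phenotypes with a design matrix and line structure.

    Parameters
    ----------
    y : (n,) int array
        Ordinal categories coded 1..C.
    X : (n, p) float array
        Fixed-effect or (centered) marker design matrix.  Must not contain a
        constant non-zero (intercept) column: the thresholds absorb the
        intercept, so one would make the model unidentifiable.
    line_of : (n,) int array, optional
        Map from observation to line index 0..I−1 (defines the incidence
        matrix Z).  Defaults to each observation being its own line.
    G : (I, I) float array, optional
        Genomic relationship matrix; must be symmetric positive definite.
    C : int, optional
        Number of categories; defaults to ``max(y)``.
    """

    def __init__(self, y, X, line_of=None, G=None, C=None):
        self.y = np.asarray(y, dtype=np.int64)
        self.X = np.ascontiguousarray(X, dtype=float)
        n = self.y.shape[0]
        if line_of is None:
            line_of = np.arange(n)
        self.line_of = np.asarray(line_of, dtype=np.int64)
        self.G = None if G is None else np.asarray(G, dtype=float)
        self.C = int(C) if C is not None else int(self.y.max(initial=0))
        self._validate()
        # category-sorted permutation for fast per-category min/max of l
        order = np.argsort(self.y, kind="stable")
        self._cat_perm = order
        counts = np.bincount(self.y, minlength=self.C + 1)[1:]
        self._cat_starts = np.concatenate(([0], np.cumsum(counts)))[:-1]
        self._cat_counts = counts
        self._g_chol = None
        self._g_inv = None
        self._xxt = None

    # -- derived sizes ----------------------------------------------------
    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def I(self) -> int:  # noqa: E743 - field name from the model
        return int(self.line_of.max()) + 1

    def _validate(self) -> None:
        n = self.y.shape[0]
        if self.X.ndim != 2 or self.X.shape[0] != n:
            raise ValidationError(
                f"X must be 2-d with {n} rows, got shape {self.X.shape}"
            )
        if self.line_of.shape != (n,):
            raise ValidationError("line_of must have one entry per observation")
        if not np.all(np.isfinite(self.X)):
            raise ValidationError(
                "X contains missing/non-finite entries; marker imputation is "
                "not performed here — complete the matrix upstream"
            )
        if self.C < 2:
            raise ValidationError("need at least 2 ordinal categories")
        if self.y.min(initial=1) < 1 or self.y.max(initial=1) > self.C:
            raise ValidationError(f"y must lie in 1..{self.C}")
        counts = np.bincount(self.y, minlength=self.C + 1)[1:]
        if np.any(counts == 0):
            missing = [int(c) + 1 for c in np.flatnonzero(counts == 0)]
            raise ValidationError(
                f"categories {missing} never observed: threshold full "
                "conditionals would be unbounded"
            )
        lines = np.bincount(self.line_of)
        if self.line_of.min(initial=0) < 0 or np.any(lines == 0):
            raise ValidationError("line indices must cover 0..I-1, each with ≥1 obs")
        # intercept check: constant non-zero column
        if self.p > 0:
            col_const = np.all(self.X == self.X[0, :], axis=0)
            bad = col_const & (self.X[0, :] != 0.0)
            if np.any(bad):
                raise ValidationError(
                    f"column(s) {np.flatnonzero(bad).tolist()} of X are constant "
                    "and non-zero; thresholds absorb the intercept, remove it"
                )
        if self.G is not None:
            I = self.I
            if self.G.shape != (I, I):
                raise ValidationError(f"G must be {I}x{I}, got {self.G.shape}")
            if not np.allclose(self.G, self.G.T, atol=1e-8):
                raise ValidationError("G must be symmetric")
            try:
                np.linalg.cholesky(self.G)
            except np.linalg.LinAlgError as exc:
                raise MatrixConditioningError(
                    "G is not positive definite (Cholesky failed)"
                ) from exc

    # -- caches -----------------------------------------------------------
    def g_inverse(self):
        if self.G is None:
            raise ValidationError("dataset has no relationship matrix G")
        if self._g_inv is None:
            c, low = cho_factor(self.G, lower=True)
            self._g_inv = cho_solve((c, low), np.eye(self.I))
        return self._g_inv

    def xxt(self):
        """Cached X X' (n×n), used by the p ≫ n β-sampling path."""
        if self._xxt is None:
            self._xxt = self.X @ self.X.T
        return self._xxt

    def category_min_max(self, l):
        """Per-category (min, max) of liabilities, NaN for impossible slots."""
        ls = l[self._cat_perm]
        mins = np.minimum.reduceat(ls, self._cat_starts)
        maxs = np.maximum.reduceat(ls, self._cat_starts)
        return mins, maxs

    def subset(self, idx) -> "OrdinalDataset":
        """Row subset with lines re-indexed; keeps the original C.

        Used by cross-validation; the subset may miss whole categories, in
        which case constructing the dataset raises and the caller decides.
        """
        idx = np.asarray(idx)
        line_ids = self.line_of[idx]
        uniq, new_line = np.unique(line_ids, return_inverse=True)
        G = None if self.G is None else self.G[np.ix_(uniq, uniq)]
        return OrdinalDataset(self.y[idx], self.X[idx], new_line, G=G, C=self.C)


def _as_sigma0(sigma0, p):
    """Σ₀ as a (p, p) array from scalar shorthand v·I or a full matrix."""
    s = np.asarray(sigma0, dtype=float)
    if s.ndim == 0:
        return float(s) * np.eye(p)
    if s.shape != (p, p):
        raise ValidationError(f"Sigma0 must be scalar or {p}x{p}")
    return s


@dataclass
class PriorSpec:
    """Priors for β, the variance components, and the thresholds.

    ``sigma0`` may be a scalar v (shorthand for v·I_p) or a full p×p matrix.
    ``fix_sigma_beta`` holds σ_β² at 1 and skips its update — the simulation-
    study prior β ~ N(0, 10000·I₃) has a fixed covariance.  With
    ``improper_beta_prior`` the prior on β is flat and the Σ₀⁻¹σ_β⁻² terms
    vanish from the β full conditional.
    """

    beta0: np.ndarray | float = 0.0
    sigma0: np.ndarray | float = 10000.0
    nu_beta: float = 3.0
    S_beta: float = 0.001
    nu_b: float = 3.0
    S_b: float = 0.001
    gamma_min: float = -1000.0
    gamma_max: float = 1000.0
    fix_sigma_beta: bool = False
    improper_beta_prior: bool = False

    def validate(self, p: int, sample_sigma_b: bool) -> None:
        if not self.gamma_min < self.gamma_max:
            raise ValidationError("require gamma_min < gamma_max")
        if not self.improper_beta_prior:
            s0 = _as_sigma0(self.sigma0, p)
            try:
                np.linalg.cholesky(s0)
            except np.linalg.LinAlgError as exc:
                raise ValidationError("Sigma0 must be positive definite") from exc
        if not self.fix_sigma_beta and not (self.nu_beta > 0 and self.S_beta > 0):
            raise ValidationError("nu_beta, S_beta must be > 0 when σβ² is sampled")
        if sample_sigma_b and not (self.nu_b > 0 and self.S_b > 0):
            raise ValidationError("nu_b, S_b must be > 0 when σb² is sampled")

    def beta0_vector(self, p: int) -> np.ndarray:
        b0 = np.asarray(self.beta0, dtype=float)
        if b0.ndim == 0:
            return np.full(p, float(b0))
        if b0.shape != (p,):
            raise ValidationError(f"beta0 must be scalar or length {p}")
        return b0


@dataclass
class ChainConfig:
    """MCMC run configuration.  Thinning is fixed at 1 (chains are stored
    unthinned; subsampling MCMC output only loses precision)."""

    n_iter: int = 20000
    burn_in: int = 10000
    link: str = "logit"
    include_polygenic: bool = False
    seed: int = 0
    pin_omega: bool = False  # testing hook: logit loop with ω forced to 1

    def validate(self) -> None:
        if self.link not in ("logit", "probit"):
            raise ValidationError(f"link must be 'logit' or 'probit', got {self.link!r}")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValidationError("require 0 <= burn_in < n_iter")


@dataclass
class ChainState:
    """Current values of all latent quantities and parameters."""

    l: np.ndarray
    omega: np.ndarray
    beta: np.ndarray
    b: np.ndarray
    sigma_b2: float
    sigma_beta2: float
    gamma: np.ndarray


class PosteriorSamples:
    """Post-burn-in draws with posterior-summary accessors."""

    def __init__(self, draws: dict, C: int, link: str):
        self.draws = draws
        self.C = C
        self.link = link

    @property
    def n_draws(self) -> int:
        return self.draws["beta"].shape[0]

    def mean(self, name: str):
        return self.draws[name].mean(axis=0)

    def sd(self, name: str):
        return self.draws[name].std(axis=0, ddof=1)

    def interval(self, name: str, alpha: float = 0.05):
        lo = np.quantile(self.draws[name], alpha / 2.0, axis=0)
        hi = np.quantile(self.draws[name], 1.0 - alpha / 2.0, axis=0)
        return lo, hi

    def parameter_names(self):
        names = []
        for j in range(self.draws["beta"].shape[1]):
            names.append(f"beta{j + 1}")
        for c in range(self.draws["gamma"].shape[1]):
            names.append(f"gamma{c + 1}")
        return names

    def flat(self) -> pd.DataFrame:
        """One row per scalar parameter: the β's then the γ's (then σ's)."""
        cols = {}
        for j in range(self.draws["beta"].shape[1]):
            cols[f"beta{j + 1}"] = self.draws["beta"][:, j]
        for c in range(self.draws["gamma"].shape[1]):
            cols[f"gamma{c + 1}"] = self.draws["gamma"][:, c]
        if "b" in self.draws:
            for i in range(self.draws["b"].shape[1]):
                cols[f"b{i + 1}"] = self.draws["b"][:, i]
            cols["sigma_b2"] = self.draws["sigma_b2"]
        cols["sigma_beta2"] = self.draws["sigma_beta2"]
        return pd.DataFrame(cols)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        flat = self.flat()
        rows = []
        for name, col in flat.items():
            v = col.to_numpy()
            rows.append(
                {
                    "parameter": name,
                    "mean": v.mean(),
                    "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                    f"{100 * alpha / 2:g}%": np.quantile(v, alpha / 2),
                    f"{100 * (1 - alpha / 2):g}%": np.quantile(v, 1 - alpha / 2),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Initialization


def initial_state(data: OrdinalDataset, priors: PriorSpec, config: ChainConfig) -> ChainState:
    """Deterministic starting point inside the support.

    γ starts at the standard-normal quantiles of the empirical cumulative
    category frequencies (clipped inside (γmin, γmax)); β = 0; b = 0;
    σ_b² = S_b; σ_β² = 1; each liability at the midpoint of its category
    interval (±0.5 beyond the boundary threshold for the end categories);
    ω = 1.
    """
    counts = np.bincount(data.y, minlength=data.C + 1)[1:]
    cumfreq = np.cumsum(counts)[:-1] / data.n
    gamma = ndtri(cumfreq)
    lo = priors.gamma_min + 1e-6
    hi = priors.gamma_max - 1e-6
    gamma = np.clip(gamma, lo, hi)
    # clipping can create ties at the bounds; restore strict order
    for c in range(1, gamma.size):
        if gamma[c] <= gamma[c - 1]:
            gamma[c] = gamma[c - 1] + 1e-6
    g_ext = np.concatenate(([-np.inf], gamma, [np.inf]))
    lower = g_ext[data.y - 1]
    upper = g_ext[data.y]
    l = np.where(
        np.isfinite(lower) & np.isfinite(upper),
        0.5 * (lower + upper),
        np.where(np.isfinite(lower), lower + 0.5, upper - 0.5),
    )
    return ChainState(
        l=l,
        omega=np.ones(data.n),
        beta=np.zeros(data.p),
        b=np.zeros(data.I),
        sigma_b2=float(priors.S_b),
        sigma_beta2=1.0,
        gamma=gamma,
    )


def _eta(state: ChainState, data: OrdinalDataset) -> np.ndarray:
    eta = data.X @ state.beta
    if np.any(state.b != 0.0):
        eta = eta + state.b[data.line_of]
    return eta


# ---------------------------------------------------------------------------
# Conditional updates (each mutates and returns `state`)


def update_liabilities(state: ChainState, data: OrdinalDataset, rng: RNGStream) -> ChainState:
    """Draw each liability from N(x'β + b, 1/ω) truncated to its category
    interval (γ_{y−1}, γ_y), with γ₀ = −∞ and γ_C = +∞."""
    if np.any(np.diff(state.gamma) <= 0.0):
        raise ThresholdOrderError(f"thresholds not increasing: {state.gamma}")
    g_ext = np.concatenate(([-np.inf], state.gamma, [np.inf]))
    lower = g_ext[data.y - 1]
    upper = g_ext[data.y]
    mean = _eta(state, data)
    sd = 1.0 / np.sqrt(state.omega)
    state.l = _kernels.truncnorm_vector(mean, sd, lower, upper, rng.kernel_seed())
    return state


def update_omegas(
    state: ChainState, data: OrdinalDataset, rng: RNGStream,
    link: str = "logit", pin_omega: bool = False,
) -> ChainState:
    """Draw ω_ij ~ PG(2, −l_ij + x_ij'β + b_i).

    Under the probit link (or when pinned for the reduction test) this is the
    identity with ω ≡ 1, which collapses the sampler to the classic probit
    threshold Gibbs loop.  The PG density is symmetric in its tilt, so the
    sign printed in the full conditional is immaterial; we keep it as stated.
    """
    if link == "probit" or pin_omega:
        state.omega = np.ones(data.n)
        return state
    tilt = -state.l + _eta(state, data)
    state.omega = _kernels.pg_vector(2, tilt, rng.kernel_seed())
    return state


def _chol_mvn_draw(precision_chol, mean, z):
    """mean + L⁻ᵀ z where precision = L Lᵀ: a N(mean, precision⁻¹) draw."""
    return mean + solve_triangular(precision_chol, z, trans="T", lower=True)


def update_beta(
    state: ChainState, data: OrdinalDataset, priors: PriorSpec, rng: RNGStream,
) -> ChainState:
    """Draw β from its Gaussian full conditional.

    Posterior covariance Σ̃₀ = (Σ₀⁻¹σ_β⁻² + X'DωX)⁻¹ and mean
    Σ̃₀(Σ₀⁻¹σ_β⁻²β₀ − X'DωZb + X'Dωl), with Dω = diag(ω).  Under the
    improper flat prior the Σ₀⁻¹σ_β⁻² terms are zero.  When p > 2n (ridge /
    whole-genome mode with scalar Σ₀ = v·I) the draw is produced by an
    n-dimensional auxiliary-regression identity instead of a p×p solve; the
    output distribution is identical.
    """
    p, n = data.p, data.n
    resid = state.l - state.b[data.line_of]
    use_fast = (
        p > 2 * n
        and not priors.improper_beta_prior
        and np.asarray(priors.sigma0).ndim == 0
    )
    if use_fast:
        beta0 = priors.beta0_vector(p)
        lam = float(priors.sigma0) * state.sigma_beta2  # prior cov = λ·I_p
        sw = np.sqrt(state.omega)
        yt = sw * (resid - data.X @ beta0)
        g = rng.generator
        u = np.sqrt(lam) * g.standard_normal(p)
        delta = g.standard_normal(n)
        v = sw * (data.X @ u) + delta
        M = lam * (sw[:, None] * data.xxt() * sw[None, :])
        M[np.diag_indices(n)] += 1.0
        try:
            cf = cho_factor(M, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise MatrixConditioningError("n-dim β-draw system not PD") from exc
        w = cho_solve(cf, yt - v)
        state.beta = beta0 + u + lam * (data.X.T @ (sw * w))
        return state

    Xw = data.X * state.omega[:, None]
    A = data.X.T @ Xw  # X'DωX
    rhs = data.X.T @ (state.omega * resid)
    if not priors.improper_beta_prior:
        s0 = _as_sigma0(priors.sigma0, p)
        p0 = np.linalg.inv(s0) / state.sigma_beta2
        A = A + p0
        rhs = rhs + p0 @ priors.beta0_vector(p)
    try:
        L = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise MatrixConditioningError(
            "posterior precision of β is singular (rank-deficient X'DωX "
            "under an improper prior?)"
        ) from exc
    mean = cho_solve((L, True), rhs)
    z = rng.generator.standard_normal(p)
    state.beta = _chol_mvn_draw(L, mean, z)
    return state


def update_polygenic(
    state: ChainState, data: OrdinalDataset, priors: PriorSpec, rng: RNGStream,
) -> ChainState:
    """Draw b from N(F(Z'Dωl − Z'DωXβ), F), F = (σ_b⁻²G⁻¹ + Z'DωZ)⁻¹."""
    ginv = data.g_inverse()
    resid = state.l - data.X @ state.beta
    zt_dw_resid = np.bincount(data.line_of, weights=state.omega * resid,
                              minlength=data.I)
    prec = ginv / state.sigma_b2
    prec = prec + np.diag(np.bincount(data.line_of, weights=state.omega,
                                      minlength=data.I))
    try:
        L = np.linalg.cholesky(prec)
    except np.linalg.LinAlgError as exc:
        raise MatrixConditioningError("polygenic precision not PD") from exc
    mean = cho_solve((L, True), zt_dw_resid)
    z = rng.generator.standard_normal(data.I)
    state.b = _chol_mvn_draw(L, mean, z)
    return state


def update_sigma_b2(
    state: ChainState, data: OrdinalDataset, priors: PriorSpec, rng: RNGStream,
) -> ChainState:
    """Draw σ_b² ~ χ⁻²(ν_b + I, (b'G⁻¹b + ν_b·S_b)/(ν_b + I))."""
    ginv = data.g_inverse()
    quad = float(state.b @ ginv @ state.b)
    df = priors.nu_b + data.I
    scale = (quad + priors.nu_b * priors.S_b) / df
    state.sigma_b2 = float(sample_scaled_inv_chisq(df, scale, rng))
    return state


def update_thresholds(
    state: ChainState, data: OrdinalDataset, priors: PriorSpec, rng: RNGStream,
) -> ChainState:
    """Draw each γ_c uniformly on its current support.

    Support: (max{max(l | y=c), γ_{c−1}, γmin}, min{min(l | y=c+1), γ_{c+1},
    γmax}).  Swept in increasing c, each conditional using the freshest
    neighbor values, which preserves the ordering by construction.
    """
    mins, maxs = data.category_min_max(state.l)
    gamma = state.gamma
    Cm1 = gamma.size
    for c in range(Cm1):
        lower = max(maxs[c], priors.gamma_min)
        if c > 0:
            lower = max(lower, gamma[c - 1])
        upper = min(mins[c + 1], priors.gamma_max)
        if c < Cm1 - 1:
            upper = min(upper, gamma[c + 1])
        if not upper > lower:
            raise DegenerateThresholdError(
                f"empty support for threshold gamma_{c + 1}: "
                f"({lower:.6g}, {upper:.6g})"
            )
        gamma[c] = rng.generator.uniform(lower, upper)
    state.gamma = gamma
    return state


def update_sigma_beta2(
    state: ChainState, priors: PriorSpec, rng: RNGStream,
) -> ChainState:
    """Draw σ_β² ~ χ⁻²(ν_β + p, [(β−β₀)'Σ₀⁻¹(β−β₀) + ν_β·S_β]/(ν_β + p));
    identity when the prior covariance of β is fixed."""
    if priors.fix_sigma_beta:
        return state
    p = state.beta.size
    beta0 = priors.beta0_vector(p)
    d = state.beta - beta0
    s0 = np.asarray(priors.sigma0, dtype=float)
    if s0.ndim == 0:
        quad = float(d @ d) / float(s0)
    else:
        quad = float(d @ np.linalg.solve(s0, d))
    df = priors.nu_beta + p
    scale = (quad + priors.nu_beta * priors.S_beta) / df
    state.sigma_beta2 = float(sample_scaled_inv_chisq(df, scale, rng))
    return state


# ---------------------------------------------------------------------------
# The Gibbs loop


def run_chain(
    data: OrdinalDataset, priors: PriorSpec, config: ChainConfig,
    rng: Optional[RNGStream] = None,
) -> PosteriorSamples:
    """Run the full Gibbs sampler and return post-burn-in draws.

    One sweep updates, in order: liabilities, ω, β, b, σ_b², γ, σ_β².  The
    polygenic steps are skipped entirely when ``include_polygenic`` is off
    (b stays identically 0), and the ω step is the identity under the probit
    link.  Deterministic given ``config.seed`` (or an explicit ``rng``).
    """
    config.validate()
    sample_b = config.include_polygenic
    if sample_b and data.G is None:
        raise ValidationError(
            "include_polygenic requires a relationship matrix G; refusing to "
            "fall back to an identity G silently"
        )
    priors.validate(data.p, sample_b)
    if rng is None:
        rng = RNGStream(config.seed)
    state = initial_state(data, priors, config)
    if config.link == "probit" or config.pin_omega:
        state.omega = np.ones(data.n)

    kept = config.n_iter - config.burn_in
    beta_d = np.empty((kept, data.p))
    gamma_d = np.empty((kept, data.C - 1))
    sb2_d = np.empty(kept) if sample_b else None
    b_d = np.empty((kept, data.I)) if sample_b else None
    sbeta2_d = np.empty(kept)

    for it in range(config.n_iter):
        try:
            update_liabilities(state, data, rng)
            update_omegas(state, data, rng, link=config.link,
                          pin_omega=config.pin_omega)
            update_beta(state, data, priors, rng)
            if sample_b:
                update_polygenic(state, data, priors, rng)
                update_sigma_b2(state, data, priors, rng)
            update_thresholds(state, data, priors, rng)
            update_sigma_beta2(state, priors, rng)
        except Exception as exc:
            raise type(exc)(f"iteration {it}: {exc}") from exc
        if it >= config.burn_in:
            k = it - config.burn_in
            beta_d[k] = state.beta
            gamma_d[k] = state.gamma
            sbeta2_d[k] = state.sigma_beta2
            if sample_b:
                b_d[k] = state.b
                sb2_d[k] = state.sigma_b2
        if (it + 1) % 1000 == 0:
            logger.debug("iteration %d/%d", it + 1, config.n_iter)

    draws = {"beta": beta_d, "gamma": gamma_d, "sigma_beta2": sbeta2_d}
    if sample_b:
        draws["b"] = b_d
        draws["sigma_b2"] = sb2_d
    return PosteriorSamples(draws, C=data.C, link=config.link)
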