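"""Prediction metrics and model comparison for ordinal fits.

Covers: per-category probabilities with equal-tailed credible sets, the
halved Brier score (range [0, 1], lower is better), the deviance
information criterion (DIC) with the classic plug-in at the posterior mean,
and the repeated 90/10 cross-validation protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit, ndtr

from .model_core import (
    ChainConfig,
    OrdinalDataset,
    PosteriorSamples,
    PriorSpec,
    ThresholdOrderError,
    ValidationError,
    run_chain,
)
from .samplers import RNGStream

__all__ = [
    "CategoryProbabilities",
    "EvalReport",
    "category_probabilities",
    "posterior_category_probabilities",
    "brier_score",
    "dic",
    "cross_validate",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


@dataclass
class CategoryProbabilities:
    """n×C matrix of category probabilities, optionally with per-cell
    equal-tailed credible bounds."""

    probs: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    alpha: float | None = None

    def averaged(self) -> np.ndarray:
        """Observation-averaged probabilities (one row per category table)."""
        return self.probs.mean(axis=0)


@dataclass
class EvalReport:
    """Container for the prediction-accuracy outputs of one fit or CV run."""

    brier: float | None = None
    dic: float | None = None
    probabilities: CategoryProbabilities | None = None
    cv_briers: np.ndarray | None = None

    @property
    def cv_mean(self):
        return None if self.cv_briers is None else float(np.mean(self.cv_briers))

    @property
    def cv_min(self):
        return None if self.cv_briers is None else float(np.min(self.cv_briers))

    @property
    def cv_max(self):
        return None if self.cv_briers is None else float(np.max(self.cv_briers))


def _cdf(link):
    if link == "logit":
        return expit
    if link == "probit":
        return ndtr
    raise ValidationError(f"link must be 'logit' or 'probit', got {link!r}")


def category_probabilities(eta, gamma, link: str = "logit") -> CategoryProbabilities:
    """π_c = F(γ_c − η) − F(γ_{c−1} − η) with γ₀ = −∞, γ_C = +∞.

    ``eta`` is the vector of linear predictors x'β + b; F the logistic or
    standard-normal CDF.  Rows sum to 1 by construction.
    """
    gamma = np.asarray(gamma, dtype=float)
    if np.any(np.diff(gamma) <= 0):
        raise ThresholdOrderError(f"thresholds not increasing: {gamma}")
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    F = _cdf(link)
    cum = F(gamma[None, :] - eta[:, None])
    cum = np.concatenate(
        [np.zeros((eta.size, 1)), cum, np.ones((eta.size, 1))], axis=1
    )
    return CategoryProbabilities(probs=np.diff(cum, axis=1))


def posterior_category_probabilities(
    samples: PosteriorSamples,
    data: OrdinalDataset,
    alpha: float = 0.05,
    link: str | None = None,
    scale: float = 1.0,
) -> CategoryProbabilities:
    """Per-cell posterior mean and equal-tailed (α/2, 1−α/2) bounds of the
    category probabilities, computed per stored draw.

    ``scale`` multiplies every draw of (β, b, γ) before applying the link —
    with a probit chain, ``scale=1.75`` and ``link='logit'`` gives the BLOR*
    approximation.
    """
    if samples.n_draws == 0:
        raise ValidationError("no stored draws")
    link = samples.link if link is None else link
    F = _cdf(link)
    n_draws = samples.n_draws
    beta = samples.draws["beta"] * scale
    gamma = samples.draws["gamma"] * scale
    b = samples.draws.get("b")
    pi = np.empty((n_draws, data.n, data.C))
    for t in range(n_draws):
        eta = data.X @ beta[t]
        if b is not None:
            eta = eta + scale * b[t][data.line_of]
        cum = F(gamma[t][None, :] - eta[:, None])
        pi[t, :, 0] = cum[:, 0]
        pi[t, :, 1:-1] = np.diff(cum, axis=1)
        pi[t, :, -1] = 1.0 - cum[:, -1]
    point = pi.mean(axis=0)
    lo = np.quantile(pi, alpha / 2.0, axis=0)
    hi = np.quantile(pi, 1.0 - alpha / 2.0, axis=0)
    return CategoryProbabilities(probs=point, lower=lo, upper=hi, alpha=alpha)


def brier_score(probs, y) -> float:
    """Halved multi-category Brier score, bounded in [0, 1].

    BS = (2n)⁻¹ Σ_i Σ_c (π̂_ic − d_ic)² with d_ic = 1 iff y_i = c; the raw
    sum ranges over [0, 2], so halving maps perfect prediction to 0 and a
    confident wrong prediction to 1.  Lower is better.
    """
    if isinstance(probs, CategoryProbabilities):
        probs = probs.probs
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=np.int64)
    if probs.ndim != 2 or probs.shape[0] != y.shape[0]:
        raise ValidationError(
            f"probability matrix {probs.shape} does not align with y ({y.shape[0]})"
        )
    n, C = probs.shape
    d = np.zeros_like(probs)
    d[np.arange(n), y - 1] = 1.0
    return float(np.mean(np.sum((probs - d) ** 2, axis=1)) / 2.0)


def _deviance(beta, gamma, b, data, F):
    eta = data.X @ beta
    if b is not None:
        eta = eta + b[data.line_of]
    g_ext_lo = np.concatenate(([-np.inf], gamma))
    g_ext_hi = np.concatenate((gamma, [np.inf]))
    u = g_ext_hi[data.y - 1] - eta
    v = g_ext_lo[data.y - 1] - eta
    Fu = np.where(np.isinf(u), 1.0, F(np.where(np.isinf(u), 0.0, u)))
    Fv = np.where(np.isinf(v), 0.0, F(np.where(np.isinf(v), 0.0, v)))
    P = Fu - Fv
    n_floored = int(np.sum(P < _PROB_FLOOR))
    if n_floored:
        logger.warning(
            "%d observed-category probabilities floored at %g in the deviance",
            n_floored, _PROB_FLOOR,
        )
        P = np.maximum(P, _PROB_FLOOR)
    return -2.0 * float(np.sum(np.log(P)))


def dic(samples: PosteriorSamples, data: OrdinalDataset, link: str | None = None) -> float:
    """Deviance information criterion: DIC = 2·D̄ − D(θ̄).

    D(θ) = −2 Σ_i log π_{i,y_i}(θ) is the multinomial ordinal deviance,
    D̄ its posterior mean over stored draws, and θ̄ the posterior mean of
    (β, b, γ) jointly (the classic plug-in).  Lower is better; the implied
    effective number of parameters is p_D = D̄ − D(θ̄).
    """
    if samples.n_draws == 0:
        raise ValidationError("no stored draws")
    link = samples.link if link is None else link
    F = _cdf(link)
    beta = samples.draws["beta"]
    gamma = samples.draws["gamma"]
    b = samples.draws.get("b")
    devs = np.empty(samples.n_draws)
    for t in range(samples.n_draws):
        devs[t] = _deviance(beta[t], gamma[t], None if b is None else b[t], data, F)
    d_bar = float(devs.mean())
    d_at_mean = _deviance(
        beta.mean(axis=0), gamma.mean(axis=0),
        None if b is None else b.mean(axis=0), data, F,
    )
    return 2.0 * d_bar - d_at_mean


def cross_validate(
    data: OrdinalDataset,
    priors: PriorSpec,
    config: ChainConfig,
    n_splits: int = 10,
    train_frac: float = 0.9,
    seed: int = 0,
    k_scale: float = 1.0,
    predict_link: str | None = None,
) -> EvalReport:
    """Repeated random-split cross-validation of prediction accuracy.

    For each of ``n_splits`` independent uniform (unstratified) splits the
    chain is fit on ``train_frac`` of the observations and the held-out
    observations are scored with the halved Brier score, predicting from
    the posterior-mean parameters (so rescaled point estimates — BLOR* with
    ``k_scale=1.75`` and ``predict_link='logit'`` on a probit chain — are
    handled identically).  Reports the per-split scores; mean/min/max are
    accessors on the returned report.

    A held-out line absent from training predicts with b = 0; a test fold
    missing a category only triggers a warning, since the probabilities are
    defined by the thresholds regardless.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValidationError("train_frac must be in (0, 1) — the test set may not be empty")
    if n_splits < 1:
        raise ValidationError("n_splits must be >= 1")
    rng = RNGStream(seed)
    briers = np.empty(n_splits)
    n_train = int(round(train_frac * data.n))
    n_train = min(max(n_train, 1), data.n - 1)
    for s in range(n_splits):
        fold_rng = rng.child(s)
        perm = fold_rng.generator.permutation(data.n)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        try:
            train = data.subset(train_idx)
        except ValidationError as exc:
            raise ValidationError(
                f"split {s}: training fold invalid ({exc}); use a larger "
                "dataset or fewer held-out observations"
            ) from exc
        if len(np.unique(data.y[test_idx])) < data.C:
            logger.warning("split %d: test fold does not contain every category", s)
        fold_cfg = ChainConfig(
            n_iter=config.n_iter, burn_in=config.burn_in, link=config.link,
            include_polygenic=config.include_polygenic,
            seed=int(fold_rng.child(1).generator.integers(0, 2**31 - 1)),
        )
        samples = run_chain(train, priors, fold_cfg)
        beta_hat = samples.mean("beta") * k_scale
        gamma_hat = samples.mean("gamma") * k_scale
        eta_test = data.X[test_idx] @ beta_hat
        if "b" in samples.draws:
            b_hat = samples.mean("b") * k_scale
            # map original line ids of the training subset back
            uniq = np.unique(data.line_of[train_idx])
            b_full = np.zeros(data.I)
            b_full[uniq] = b_hat
            eta_test = eta_test + b_full[data.line_of[test_idx]]
        link = (config.link if predict_link is None else predict_link)
        probs = category_probabilities(eta_test, gamma_hat, link=link)
        briers[s] = brier_score(probs, data.y[test_idx])
    return EvalReport(cv_briers=briers)
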