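"""Low-level random-variate generators for the ordinal Gibbs sampler.

Every conditional update in the sampler draws from one of four families:
Pólya-Gamma (the logistic augmentation variables), truncated normal (latent
liabilities), scaled inverse chi-square (variance components), and bounded
uniform (thresholds).  All of them consume randomness through an explicit
:class:`RNGStream`; there is no hidden global state, so two chains started
from the same seed are bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

from . import _kernels

__all__ = [
    "RNGStream",
    "sample_polya_gamma",
    "sample_truncated_normal",
    "sample_scaled_inv_chisq",
]

_MAX_KERNEL_SEED = 2**31 - 1


class RNGStream:
    """Seeded random stream with deterministic sub-stream derivation.

    Wraps a :class:`numpy.random.Generator` (PCG64).  Identical seeds yield
    identical draw sequences.  Sub-streams for replicates are derived from
    ``(seed, index)`` through :class:`numpy.random.SeedSequence`, so replicate
    results do not depend on execution order.

    The numba-compiled kernels carry their own Mersenne-Twister state; each
    kernel call is seeded with a fresh integer drawn from this stream, which
    keeps the whole pipeline reproducible from the single master seed.
    """

    def __init__(self, seed, _ss: np.random.SeedSequence | None = None):
        if _ss is None:
            _ss = np.random.SeedSequence(seed)
        self.seed = seed
        self._ss = _ss
        self.generator = np.random.Generator(np.random.PCG64(_ss))

    def child(self, index: int) -> "RNGStream":
        """Deterministic sub-stream for replicate/fold ``index``."""
        ss = np.random.SeedSequence(
            entropy=self._ss.entropy, spawn_key=self._ss.spawn_key + (index,)
        )
        return RNGStream(self.seed, _ss=ss)

    def kernel_seed(self) -> int:
        """Fresh 31-bit seed for one numba kernel invocation."""
        return int(self.generator.integers(0, _MAX_KERNEL_SEED))

    def __repr__(self) -> str:  # pragma: no cover
        return f"RNGStream(seed={self.seed!r})"


def _as_stream(rng) -> RNGStream:
    if isinstance(rng, RNGStream):
        return rng
    if isinstance(rng, (int, np.integer)):
        return RNGStream(int(rng))
    raise TypeError(f"expected RNGStream or integer seed, got {type(rng)!r}")


def sample_polya_gamma(b, c, rng, size=None):
    """Draw from the Pólya-Gamma distribution PG(b, c).

    Uses Devroye's exact alternating-series rejection sampler for PG(1, c)
    and sums ``b`` independent PG(1, c) variates (PG is infinitely divisible
    in its shape).  The density is symmetric in the tilt: PG(b, c) = PG(b, −c).
    E[PG(b, c)] = (b / 2c)·tanh(c / 2), with the c → 0 limit b/4.

    Parameters
    ----------
    b : positive int
        Shape parameter.  Only integer shapes are supported (the conditional
        updates need PG(2, ·) only); approximate samplers for fractional
        shapes are deliberately not provided.
    c : float or 1-d array
        Tilt parameter(s); must be finite.
    rng : RNGStream or int
    size : int, optional
        For scalar ``c``, number of i.i.d. draws; ignored when ``c`` is an
        array (one draw per element).

    Returns
    -------
    float or ndarray of positive draws.
    """
    stream = _as_stream(rng)
    b_int = int(b)
    if b_int != b or b_int <= 0:
        raise ValueError(f"PG shape b must be a positive integer, got {b!r}")
    c_arr = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c_arr)):
        raise ValueError("PG tilt c must be finite")
    if c_arr.ndim == 0:
        n = 1 if size is None else int(size)
        out = _kernels.pg_scalar_n(b_int, float(c_arr), n, stream.kernel_seed())
        return float(out[0]) if size is None else out
    if size is not None:
        raise ValueError("size is only valid with scalar c")
    return _kernels.pg_vector(b_int, np.ascontiguousarray(c_arr), stream.kernel_seed())


def sample_truncated_normal(mean, variance, lower, upper, rng, size=None):
    """Draw from N(mean, variance) restricted to the interval (lower, upper).

    Bounds may be ``-inf`` / ``+inf``.  Sampling is exact: plain rejection in
    the bulk, uniform rejection on narrow slivers, and Robert's translated-
    exponential rejection for one-sided regions far in the tail, so draws are
    finite and inside the support even many standard deviations out.
    """
    stream = _as_stream(rng)
    mean_a = np.asarray(mean, dtype=float)
    var_a = np.asarray(variance, dtype=float)
    lo_a = np.asarray(lower, dtype=float)
    hi_a = np.asarray(upper, dtype=float)
    if np.any(~np.isfinite(var_a)) or np.any(var_a <= 0.0):
        raise ValueError("variance must be finite and > 0")
    if np.any(~(lo_a < hi_a)):
        raise ValueError("require lower < upper for every element")
    if mean_a.ndim == 0 and lo_a.ndim == 0 and hi_a.ndim == 0 and var_a.ndim == 0:
        n = 1 if size is None else int(size)
        out = _kernels.truncnorm_scalar_n(
            float(mean_a), math.sqrt(float(var_a)), float(lo_a), float(hi_a),
            n, stream.kernel_seed(),
        )
        return float(out[0]) if size is None else out
    mean_b, var_b, lo_b, hi_b = np.broadcast_arrays(mean_a, var_a, lo_a, hi_a)
    return _kernels.truncnorm_vector(
        np.ascontiguousarray(mean_b, dtype=float),
        np.ascontiguousarray(np.sqrt(var_b), dtype=float),
        np.ascontiguousarray(lo_b, dtype=float),
        np.ascontiguousarray(hi_b, dtype=float),
        stream.kernel_seed(),
    )


def sample_scaled_inv_chisq(df, scale, rng, size=None):
    """Draw from the scaled inverse chi-square χ⁻²(df, scale).

    Defined as df·scale / χ²_df; the conjugate posterior family of the
    variance components σ_b² and σ_β².  Mean df·scale/(df−2) for df > 2.
    """
    stream = _as_stream(rng)
    df = float(df)
    scale = float(scale)
    if not (df > 0.0 and np.isfinite(df)):
        raise ValueError(f"df must be positive and finite, got {df!r}")
    if not (scale > 0.0 and np.isfinite(scale)):
        raise ValueError(f"scale must be positive and finite, got {scale!r}")
    chi2 = stream.generator.chisquare(df, size=size)
    return df * scale / chi2
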