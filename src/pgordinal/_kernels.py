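"""Numba-compiled random-variate kernels.

All kernels are seeded explicitly through numba's internal Mersenne-Twister
state (``np.random.seed`` inside an ``@njit`` function); callers derive the
per-call seed from an :class:`~pgordinal.samplers.RNGStream` so that runs are
bit-reproducible.

The Pólya-Gamma sampler is the exact alternating-series rejection method of
Devroye for PG(1, z); PG(b, z) with integer shape b is the sum of b
independent PG(1, z) draws (PG is infinitely divisible in its shape).
The truncated-normal sampler combines plain rejection, uniform rejection and
one-sided exponential (Robert) rejection so that draws remain exact and
finite arbitrarily far into the tails.
"""

import math

import numpy as np
from numba import njit

# Devroye's truncation point between the inverse-Gaussian body and the
# exponential tail of the Jacobi-theta proposal.
_TRUNC = 0.64

_SQRT_2PI = 2.5066282746310002


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x * 0.7071067811865476)


@njit(cache=True)
def _a_coef(n, x):
    """n-th coefficient of the alternating series for the J*(1,0) density."""
    nph = n + 0.5
    if x > _TRUNC:
        return math.pi * nph * math.exp(-nph * nph * math.pi * math.pi * x * 0.5)
    return math.pi * nph * (2.0 / (math.pi * x)) ** 1.5 * math.exp(-2.0 * nph * nph / x)


@njit(cache=True)
def _mass_texpon(z):
    """P(proposal falls in the exponential tail piece), tilt z >= 0."""
    fz = math.pi * math.pi * 0.125 + z * z * 0.5
    b = math.sqrt(1.0 / _TRUNC) * (_TRUNC * z - 1.0)
    a = -math.sqrt(1.0 / _TRUNC) * (_TRUNC * z + 1.0)
    x0 = math.log(fz) + fz * _TRUNC
    xb = x0 - z + math.log(_norm_cdf(b))
    xa = x0 + z + math.log(_norm_cdf(a))
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, _TRUNC]."""
    x = _TRUNC + 1.0
    if z < 1.0 / _TRUNC:  # mu > truncation point: chi-based rejection
        while True:
            e1 = np.random.standard_exponential()
            e2 = np.random.standard_exponential()
            while e1 * e1 > 2.0 * e2 / _TRUNC:
                e1 = np.random.standard_exponential()
                e2 = np.random.standard_exponential()
            x = _TRUNC / ((1.0 + _TRUNC * e1) * (1.0 + _TRUNC * e1))
            if np.random.random() <= math.exp(-0.5 * z * z * x):
                return x
    else:
        mu = 1.0 / z
        while x > _TRUNC:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu * (1.0 + 0.5 * muy - 0.5 * math.sqrt(4.0 * muy + muy * muy))
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
        return x


@njit(cache=True)
def _pg1(c):
    """One exact draw from PG(1, c); the density is symmetric in c."""
    z = abs(c) * 0.5
    fz = math.pi * math.pi * 0.125 + z * z * 0.5
    p_right = _mass_texpon(z)
    while True:
        if np.random.random() < p_right:
            x = _TRUNC + np.random.standard_exponential() / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break  # reject this proposal, draw a fresh one


@njit(cache=True)
def pg_scalar_n(b, c, n, seed):
    """n i.i.d. draws from PG(b, c) with integer shape b."""
    np.random.seed(seed)
    out = np.empty(n)
    for i in range(n):
        acc = 0.0
        for _ in range(b):
            acc += _pg1(c)
        out[i] = acc
    return out


@njit(cache=True)
def pg_vector(b, c, seed):
    """Elementwise PG(b, c_i) draws for a vector of tilts c."""
    np.random.seed(seed)
    out = np.empty(c.shape[0])
    for i in range(c.shape[0]):
        acc = 0.0
        for _ in range(b):
            acc += _pg1(c[i])
        out[i] = acc
    return out


# ---------------------------------------------------------------------------
# Truncated standard normal


@njit(cache=True)
def _tnorm_lower(a):
    """Standard normal conditioned on x > a (a finite)."""
    if a <= 0.45:
        while True:
            x = np.random.standard_normal()
            if x > a:
                return x
    # Robert (1995) translated-exponential rejection for the far tail
    alpha = 0.5 * (a + math.sqrt(a * a + 4.0))
    while True:
        x = a + np.random.standard_exponential() / alpha
        d = x - alpha
        if np.random.random() <= math.exp(-0.5 * d * d):
            return x


@njit(cache=True)
def _tnorm_two_sided(a, b):
    """Standard normal conditioned on a < x < b, both finite, a < b."""
    if a > 0.0:
        # entirely in the upper tail
        ta = 0.5 * math.erfc(a * 0.7071067811865476)
        tb = 0.5 * math.erfc(b * 0.7071067811865476)
        if ta > 0.0 and (ta - tb) / ta > 0.05:
            while True:
                x = _tnorm_lower(a)
                if x < b:
                    return x
        # narrow sliver: uniform proposal, density maximum at a
        while True:
            x = a + (b - a) * np.random.random()
            if np.random.random() <= math.exp(0.5 * (a * a - x * x)):
                return x
    if b < 0.0:
        return -_tnorm_two_sided(-b, -a)
    # interval straddles 0: density maximum at 0
    mass = _norm_cdf(b) - _norm_cdf(a)
    if mass > 0.2:
        while True:
            x = np.random.standard_normal()
            if a < x < b:
                return x
    while True:
        x = a + (b - a) * np.random.random()
        if np.random.random() <= math.exp(-0.5 * x * x):
            return x


@njit(cache=True)
def _tnorm_std(a, b):
    """Standard normal truncated to (a, b); either bound may be infinite."""
    a_inf = math.isinf(a) and a < 0.0
    b_inf = math.isinf(b) and b > 0.0
    if a_inf and b_inf:
        return np.random.standard_normal()
    if a_inf:
        return -_tnorm_lower(-b)
    if b_inf:
        return _tnorm_lower(a)
    return _tnorm_two_sided(a, b)


@njit(cache=True)
def truncnorm_vector(mean, sd, lower, upper, seed):
    """Elementwise N(mean_i, sd_i^2) truncated to (lower_i, upper_i)."""
    np.random.seed(seed)
    n = mean.shape[0]
    out = np.empty(n)
    for i in range(n):
        a = (lower[i] - mean[i]) / sd[i]
        b = (upper[i] - mean[i]) / sd[i]
        out[i] = mean[i] + sd[i] * _tnorm_std(a, b)
    return out


@njit(cache=True)
def truncnorm_scalar_n(mean, sd, lower, upper, n, seed):
    """n i.i.d. draws from one truncated normal (diagnostic/oracle helper)."""
    np.random.seed(seed)
    out = np.empty(n)
    a = (lower - mean) / sd
    b = (upper - mean) / sd
    for i in range(n):
        out[i] = mean + sd * _tnorm_std(a, b)
    return out
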