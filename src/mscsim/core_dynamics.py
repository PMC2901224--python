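"""Noise-driven differentiation-state dynamics.

Every cell carries a continuous differentiation state α ∈ [0, 1]
(0 = full stem-cell competency, 1 = completely differentiated).  At Poisson
times with rate R the cell redraws α from a Gaussian centred on its current
state, truncated to [0, 1].  The standard deviation σ(α) shrinks with α in
an oxygen-dependent way,

    σ(α) = σ0 · (1 − f(pO2) · α),

so cells accumulate in low-noise states: high oxygen quiets differentiated
states and drives quasi-deterministic differentiation, low oxygen keeps the
landscape shallow and the population plastic.  ``f`` is a Hill function of
the normalized oxygen tension.

These functions are the single code path for the state process; both the
Monte-Carlo agent layer and the master-equation layer build on them.
"""

from __future__ import annotations

from typing import Callable, Union

import numpy as np
from scipy.special import ndtr, ndtri

from .params import DifferentiationParams, OxygenEnvironment

__all__ = [
    "hill_response",
    "noise_amplitude",
    "sample_transition",
    "is_proliferative",
    "evolve_alpha",
    "truncated_gaussian_draw",
]

ArrayLike = Union[float, np.ndarray]

#: Signature of a pluggable noise profile: (alpha, params, env) -> sigma.
NoiseProfile = Callable[[ArrayLike, DifferentiationParams, OxygenEnvironment], ArrayLike]


def hill_response(pO2_norm: ArrayLike, params: DifferentiationParams) -> ArrayLike:
    """Hill response f(pO2) = pO2^n / (k^n + pO2^n) on the normalized scale.

    Approaches 0 at low and 1 at high oxygen; f(k) = 1/2 by construction.
    """
    p = np.asarray(pO2_norm, dtype=float)
    if np.any(p < 0):
        raise ValueError("pO2_norm must be non-negative")
    pn = p ** params.hill_n
    out = pn / (params.hill_k ** params.hill_n + pn)
    return out if out.ndim else float(out)


def noise_amplitude(
    alpha: ArrayLike,
    params: DifferentiationParams,
    env: OxygenEnvironment,
) -> ArrayLike:
    """State-dependent fluctuation amplitude σ(α) = σ0 (1 − f(pO2) α).

    σ(0) = σ0 at every oxygen tension; σ is non-increasing in α and, for any
    α > 0, smaller at higher oxygen (f is monotone in pO2).
    """
    a = np.asarray(alpha, dtype=float)
    out = params.sigma0 * (1.0 - env.f_value * a)
    return out if out.ndim else float(out)


def truncated_gaussian_draw(
    mu: np.ndarray,
    sigma: np.ndarray,
    rng: np.random.Generator,
    lo: float = 0.0,
    hi: float = 1.0,
) -> np.ndarray:
    """Draw from N(mu, sigma) truncated and renormalized on [lo, hi].

    Inverse-CDF sampling; where sigma == 0 the draw is mu itself (degenerate
    kernel).  Vectorized over mu/sigma of equal shape.
    """
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    out = mu.copy()
    live = sigma > 0
    if np.any(live):
        m, s = mu[live], sigma[live]
        a = ndtr((lo - m) / s)
        b = ndtr((hi - m) / s)
        u = rng.uniform(a, b)
        out[live] = m + s * ndtri(u)
    return np.clip(out, lo, hi)


def sample_transition(
    alpha: ArrayLike,
    params: DifferentiationParams,
    env: OxygenEnvironment,
    rng: np.random.Generator,
) -> ArrayLike:
    """One randomization event: redraw α' ~ N(α, σ(α)) truncated to [0, 1]."""
    a = np.asarray(alpha, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)
    sigma = np.atleast_1d(noise_amplitude(a, params, env))
    out = truncated_gaussian_draw(a, sigma, rng)
    return float(out[0]) if scalar else out


def is_proliferative(alpha: ArrayLike, params: DifferentiationParams) -> ArrayLike:
    """True in the open progenitor band alpha_s < α < alpha_d.

    Stem cells (α < alpha_s) and differentiated cells (α > alpha_d) do not
    proliferate; the band boundaries themselves count as non-proliferative.
    """
    a = np.asarray(alpha, dtype=float)
    out = (a > params.alpha_s) & (a < params.alpha_d)
    return bool(out) if out.ndim == 0 else out


def evolve_alpha(
    alpha: ArrayLike,
    dt: float,
    params: DifferentiationParams,
    env: OxygenEnvironment,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance a set of α-states by dt seconds.

    Each cell independently experiences Poisson(R·dt) randomization events,
    applied sequentially.  Returns a new array; the input is not modified.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    a = np.array(alpha, dtype=float, copy=True, ndmin=1)
    counts = rng.poisson(params.rate_R * dt, size=a.shape)
    while True:
        live = counts > 0
        if not np.any(live):
            break
        a[live] = sample_transition(a[live], params, env, rng)
        counts[live] -= 1
    return a
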