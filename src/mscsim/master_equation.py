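"""Population-level master-equation analysis of the α-process.

The continuous state is discretized on M uniform bins of [0, 1]; a
randomization event moves probability mass according to the truncated
Gaussian kernel, giving a row-stochastic matrix P.  Events occur at rate R,
so the chain is a Markov jump process with uniformized skeleton P.  On top
of this the module provides

* the stationary distribution (equilibrium without proliferation, the
  confluent/quiescent limit),
* the low-density equilibrium: the dominant mode of the growth-augmented
  generator with a source term +r·N(α) on the proliferative progenitor band
  (freely proliferating culture, no contact inhibition),
* mean first-passage ("transition") times into the stem or differentiated
  region via the absorbing-boundary approach, and
* time-resolved absorbed fractions.

Proliferation is deliberately absent from the plain chain: it describes the
population average of single-cell dynamics, the role it plays as the
deterministic counterpart of the agent-based model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import ndtr
from scipy.stats import poisson

from .core_dynamics import noise_amplitude
from .params import DifferentiationParams, OxygenEnvironment

__all__ = [
    "MarkovChain",
    "AlphaHistogram",
    "MfptResult",
    "NumericalError",
    "build_chain",
    "stationary_distribution",
    "low_density_equilibrium",
    "mean_transition_times",
    "absorbed_fraction",
]

REGIONS = ("stem", "differentiated")


class NumericalError(RuntimeError):
    """Eigen- or linear-solve failure with diagnostic context."""


@dataclass(frozen=True)
class MarkovChain:
    """Discretized α-chain: uniform grid, per-event transition matrix P."""

    grid: np.ndarray            # M bin midpoints
    edges: np.ndarray           # M+1 bin edges
    P: np.ndarray               # M x M row-stochastic, one randomization event
    rate_R: float               # events per second
    params: DifferentiationParams
    env: OxygenEnvironment

    @property
    def M(self) -> int:
        return self.grid.size

    def region_mask(self, target: str) -> np.ndarray:
        """Boolean mask of bins inside the named α-region."""
        if target == "stem":
            return self.grid < self.params.alpha_s
        if target == "differentiated":
            return self.grid > self.params.alpha_d
        raise ValueError(f"target must be one of {REGIONS}, got {target!r}")


@dataclass
class AlphaHistogram:
    """Probability mass over α-bins with provenance metadata."""

    edges: np.ndarray
    masses: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses < -1e-12):
            raise ValueError("histogram masses must be non-negative")
        total = self.masses.sum()
        if abs(total - 1.0) > 1e-10:
            raise ValueError(f"histogram mass {total} deviates from 1 by > 1e-10")

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def mass_above(self, threshold: float) -> float:
        """Total mass in bins whose midpoint exceeds ``threshold``."""
        return float(self.masses[self.midpoints > threshold].sum())

    def mass_below(self, threshold: float) -> float:
        return float(self.masses[self.midpoints < threshold].sum())

    def rebin(self, nbins: int) -> "AlphaHistogram":
        """Aggregate onto ``nbins`` uniform bins (must divide evenly)."""
        if self.masses.size % nbins:
            raise ValueError(f"cannot rebin {self.masses.size} bins into {nbins}")
        k = self.masses.size // nbins
        masses = self.masses.reshape(nbins, k).sum(axis=1)
        return AlphaHistogram(np.linspace(0, 1, nbins + 1), masses, dict(self.meta))


@dataclass
class MfptResult:
    """Mean transition times ϑ(α) into a target region, in days.

    ``theta_days`` is 0 on bins inside the target; ``computable`` is False
    when the absorbing linear system could not be solved reliably (the
    absorbed fraction converges too slowly), in which case ``theta_days``
    holds NaN on transient bins.
    """

    grid: np.ndarray
    theta_days: np.ndarray
    target: str
    computable: bool = True
    diagnostics: dict = field(default_factory=dict)

    def region_average(self, mask: np.ndarray) -> float:
        """Unweighted mean of ϑ(α) over the initial bins selected by mask."""
        return float(np.mean(self.theta_days[mask]))

    def stem_average(self, params: DifferentiationParams) -> float:
        """Mean transition time of stem-state initial conditions (α < α_s)."""
        return self.region_average(self.grid < params.alpha_s)

    def differentiated_average(self, params: DifferentiationParams) -> float:
        return self.region_average(self.grid > params.alpha_d)


def build_chain(
    M: int,
    params: DifferentiationParams,
    env: OxygenEnvironment,
) -> MarkovChain:
    """Discretize the truncated-Gaussian transition kernel on M uniform bins.

    Row i is the mass of N(grid[i], σ(grid[i])) over each bin, computed as
    differences of Gaussian CDFs and renormalized over [0, 1] — the same
    truncation convention the Monte-Carlo sampler uses.  CDF differences
    (not midpoint densities) keep rows normalized even where σ is far below
    the bin width, as happens near α = 1 at high oxygen; such rows are
    self-mass dominated by construction.
    """
    if M < 50:
        raise ValueError(
            f"M must be >= 50 (kernel under-resolved where sigma is small), got {M}"
        )
    edges = np.linspace(0.0, 1.0, M + 1)
    mid = 0.5 * (edges[:-1] + edges[1:])
    sigma = np.asarray(noise_amplitude(mid, params, env), dtype=float)
    if np.any(sigma <= 0):
        raise NumericalError("noise amplitude vanished on the grid; kernel degenerate")
    z = (edges[None, :] - mid[:, None]) / sigma[:, None]
    cdf = ndtr(z)
    P = np.diff(cdf, axis=1)
    P /= P.sum(axis=1, keepdims=True)
    return MarkovChain(grid=mid, edges=edges, P=P, rate_R=params.rate_R,
                       params=params, env=env)


def _dominant_eigvec(A: np.ndarray, what: str) -> np.ndarray:
    """Real, non-negative, sum-1 eigenvector of the right-most eigenvalue."""
    w, v = np.linalg.eig(A)
    i = int(np.argmax(w.real))
    vec = v[:, i].real
    vec = np.abs(vec)
    s = vec.sum()
    if not np.isfinite(s) or s <= 0:
        raise NumericalError(f"{what}: dominant eigenvector degenerate (sum={s})")
    return vec / s


def stationary_distribution(chain: MarkovChain) -> AlphaHistogram:
    """Equilibrium α-distribution of the chain (no proliferation).

    Left Perron eigenvector of P, normalized to total mass 1.  This is the
    confluent-culture limit in which growth is fully contact inhibited.
    """
    w, v = np.linalg.eig(chain.P.T)
    i = int(np.argmin(np.abs(w - 1.0)))
    if abs(w[i] - 1.0) > 1e-8:
        raise NumericalError(
            f"no unit eigenvalue found: closest is {w[i]} (|Δ|={abs(w[i]-1):.2e})"
        )
    pi = np.abs(v[:, i].real)
    pi /= pi.sum()
    resid = float(np.max(np.abs(pi @ chain.P - pi)))
    if resid > 1e-10:
        raise NumericalError(f"stationary fixed-point residual {resid:.2e} > 1e-10")
    return AlphaHistogram(
        chain.edges, pi,
        meta={"pO2_percent": chain.env.pO2_percent, "proliferation": "none"},
    )


def low_density_equilibrium(
    chain: MarkovChain,
    r_per_day: float,
    params: Optional[DifferentiationParams] = None,
) -> AlphaHistogram:
    """Equilibrium α-distribution of a freely proliferating population.

    Dominant eigenvector (normalized) of the growth-augmented generator

        G = R (Pᵀ − I) + r · diag(1{α_s < α < α_d}),

    i.e. Markov randomization plus an exponential source on the progenitor
    band: in a low-density culture each proliferative cell adds offspring at
    rate r, biasing the population toward the band.  r = 0 reduces exactly
    to the stationary distribution.
    """
    if r_per_day < 0:
        raise ValueError(f"r_per_day must be >= 0, got {r_per_day}")
    params = params or chain.params
    if r_per_day == 0:
        hist = stationary_distribution(chain)
        hist.meta["proliferation"] = "r=0"
        return hist
    r_s = r_per_day / 86400.0
    band = (chain.grid > params.alpha_s) & (chain.grid < params.alpha_d)
    G = chain.rate_R * (chain.P.T - np.eye(chain.M)) + np.diag(r_s * band)
    vec = _dominant_eigvec(G, "low_density_equilibrium")
    return AlphaHistogram(
        chain.edges, vec,
        meta={"pO2_percent": chain.env.pO2_percent,
              "proliferation": f"r={r_per_day}/day, free growth"},
    )


def mean_transition_times(chain: MarkovChain, target: str) -> MfptResult:
    """Mean first-passage times ϑ(α) into the target region, in days.

    Bins inside the target are made absorbing; the expected number of
    randomization events to absorption solves (I − Q) n = 1 on the transient
    bins (Q = transient sub-matrix), and ϑ = n / R.  If the linear system is
    numerically unreliable — absorption converges too slowly to resolve, as
    for the stem-ward passage at high oxygen — the result is flagged not
    computable rather than reported.
    """
    absorbing = chain.region_mask(target)
    transient = ~absorbing
    theta = np.zeros(chain.M)
    diagnostics: dict = {}
    Q = chain.P[np.ix_(transient, transient)]
    A = np.eye(int(transient.sum())) - Q
    ones = np.ones(A.shape[0])
    try:
        n = np.linalg.solve(A, ones)
        resid = float(np.max(np.abs(A @ n - ones)))
        diagnostics["residual"] = resid
        ok = np.all(np.isfinite(n)) and np.all(n > 0) and resid < 1e-6
    except np.linalg.LinAlgError as err:
        diagnostics["error"] = str(err)
        ok = False
    if not ok:
        theta[transient] = np.nan
        return MfptResult(chain.grid, theta, target, computable=False,
                          diagnostics=diagnostics)
    theta[transient] = n / chain.rate_R / 86400.0
    return MfptResult(chain.grid, theta, target, computable=True,
                      diagnostics=diagnostics)


def absorbed_fraction(
    chain: MarkovChain,
    target: str,
    times_days: Sequence[float],
) -> np.ndarray:
    """Fraction absorbed in the target region by each time, per initial bin.

    Returns an array of shape (len(times_days), M).  The discrete absorbing
    skeleton is iterated and mixed over the Poisson(R·t) event count
    (uniformization), matching the continuous-time process exactly.  The
    result is non-decreasing in time and bounded by 1 for every initial bin.
    """
    times = np.asarray(times_days, dtype=float)
    if times.size and np.any(np.diff(times) < 0):
        raise ValueError("times_days must be sorted ascending")
    absorbing = chain.region_mask(target)
    P_abs = chain.P.copy()
    P_abs[absorbing, :] = 0.0
    P_abs[absorbing, absorbing] = 1.0

    lam_max = chain.rate_R * 86400.0 * (times.max() if times.size else 0.0)
    m_max = int(lam_max + 12.0 * np.sqrt(lam_max + 1.0) + 25)
    # F[m, i] = absorbed mass after m skeleton steps from initial bin i
    F = np.empty((m_max + 1, chain.M))
    S = np.eye(chain.M)
    F[0] = S[:, absorbing].sum(axis=1)
    for m in range(1, m_max + 1):
        S = S @ P_abs
        F[m] = S[:, absorbing].sum(axis=1)
    out = np.empty((times.size, chain.M))
    ms = np.arange(m_max + 1)
    for k, t in enumerate(times):
        lam = chain.rate_R * 86400.0 * t
        weights = poisson.pmf(ms, lam)
        out[k] = weights @ F
    return out
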