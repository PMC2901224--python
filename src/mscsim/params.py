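"""Parameter containers for the differentiation-state model and the cell mechanics.

All mechanical quantities are SI (m, s, N, Pa); rates are per second unless a
name says otherwise.  The defaults are the experimentally validated parameter
set for ovine MSC expansion at 5% and 20% oxygen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields

__all__ = [
    "DifferentiationParams",
    "MechanicsParams",
    "OxygenEnvironment",
    "PO2_REFERENCE_PERCENT",
]

#: Oxygen tension (in %) that maps to a normalized pO2 of 1.0.  Standard
#: incubator air-oxygen culture (20% O2) is taken as the saturating reference,
#: so 5% O2 sits at 0.25 on the normalized scale, below the Hill constant
#: k = 0.3, and 20% far above it.
PO2_REFERENCE_PERCENT = 20.0


@dataclass(frozen=True)
class DifferentiationParams:
    """Intracellular regulation of the differentiation state α.

    Parameters
    ----------
    sigma0 : float
        Fluctuation strength in stem cell states (dimensionless width of the
        Gaussian transition kernel at α = 0).
    rate_R : float
        Randomization rate in events per second.  Each cell redraws its α at
        Poisson times with this rate.  Default 2.5e-4 /s ≈ 21.6 events/day,
        which places individual state transitions on the day scale.
    hill_n : float
        Hill coefficient of the oxygen response f(pO2).
    hill_k : float
        Hill half-saturation constant, on the normalized oxygen scale.
    alpha_s : float
        Stem-cell threshold: cells with α < alpha_s are functional stem
        cells.  Must lie in (0, 0.5); the differentiation threshold is the
        mirror value alpha_d = 1 - alpha_s, so the proliferative progenitor
        band (alpha_s, alpha_d) is symmetric about α = 0.5.
    """

    sigma0: float = 0.15
    rate_R: float = 2.5e-4
    hill_n: float = 5.0
    hill_k: float = 0.3
    alpha_s: float = 0.15

    def __post_init__(self) -> None:
        if not self.sigma0 > 0:
            raise ValueError(f"sigma0 must be positive, got {self.sigma0}")
        if not self.rate_R > 0:
            raise ValueError(f"rate_R must be positive, got {self.rate_R}")
        if not self.hill_n >= 1:
            raise ValueError(f"hill_n must be >= 1, got {self.hill_n}")
        if not self.hill_k > 0:
            raise ValueError(f"hill_k must be positive, got {self.hill_k}")
        if not 0.0 < self.alpha_s < 0.5:
            raise ValueError(
                f"alpha_s must lie in (0, 0.5) so that alpha_s < alpha_d; "
                f"got {self.alpha_s}"
            )

    @property
    def alpha_d(self) -> float:
        """Differentiation threshold, exactly 1 - alpha_s."""
        return 1.0 - self.alpha_s

    @property
    def events_per_day(self) -> float:
        return self.rate_R * 86400.0


@dataclass(frozen=True)
class OxygenEnvironment:
    """Global oxygen tension and the cached Hill response it induces.

    pO2 is a single scalar for the whole culture (no gradients).  ``f_value``
    is the Hill response f(pO2_norm) ∈ [0, 1) that scales how strongly
    differentiated states are quieted: at f → 1 fluctuations vanish for
    α → 1, at f = 0 the noise amplitude is state-independent.
    """

    pO2_percent: float
    pO2_norm: float
    f_value: float

    def __post_init__(self) -> None:
        if self.pO2_percent < 0:
            raise ValueError(f"pO2_percent must be >= 0, got {self.pO2_percent}")
        if not 0.0 <= self.f_value <= 1.0:
            raise ValueError(f"f_value must lie in [0, 1], got {self.f_value}")

    @classmethod
    def from_percent(
        cls, pO2_percent: float, params: DifferentiationParams
    ) -> "OxygenEnvironment":
        """Build an environment from an oxygen tension in percent.

        The tension is normalized by 20% O2 (ambient culture conditions) and
        fed through the Hill response defined by ``params``.
        """
        # local import to avoid a cycle: core_dynamics imports params
        from .core_dynamics import hill_response

        norm = pO2_percent / PO2_REFERENCE_PERCENT
        return cls(
            pO2_percent=pO2_percent,
            pO2_norm=norm,
            f_value=float(hill_response(norm, params)),
        )


@dataclass(frozen=True)
class MechanicsParams:
    """Biomechanical constants of the individual cell-based model.

    Cells are elastic adhesive spheres on a flat substrate.  The interaction
    is a modified Hertz contact: classic Hertz repulsion plus an adhesion
    term proportional to the contact area.  Friction against the substrate
    and between cells is proportional to the respective contact areas.

    Units: Pa, m, N, N/m (anchorage = adhesion energy per area),
    N·s/m³ (friction per area), m²/s (diffusion).  ``growth_rate_r`` is per
    day; ``growth_stages_K`` sets the Erlang shape of the stochastic growth
    time (CV = 1/sqrt(K)).
    """

    young_E: float = 450.0
    poisson_nu: float = 0.4
    R0: float = 5e-6
    eps_cc: float = 6e-5
    eps_cs: float = 6e-5
    gamma_cc: float = 3e7
    gamma_cs: float = 1e11
    D_cell: float = 4e-16  # 4e-12 cm^2/s
    F_max: float = 1e-9
    F_q: float = 10.0
    growth_rate_r: float = 1.9  # per day
    growth_stages_K: int = 10
    #: optional second gate: cells whose mean contact pressure exceeds F_q
    #: become permanently quiescent.  Off by default; the force-sum gate
    #: (F_max) is the contact-inhibition mechanism used throughout.
    quiescence_gate: bool = False
    #: whether the always-present substrate contact counts toward the
    #: contact-inhibition force sum.  With the default thresholds the
    #: substrate contact alone contributes ~0.9e-9 N, so including it would
    #: arrest every touching cell; the gate therefore counts cell-cell
    #: contacts only.
    arrest_includes_substrate: bool = False

    def __post_init__(self) -> None:
        positive = (
            "young_E", "R0", "eps_cc", "eps_cs", "gamma_cc", "gamma_cs",
            "D_cell", "F_max", "F_q", "growth_rate_r",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.poisson_nu < 0.5:
            raise ValueError(f"poisson_nu must lie in (0, 0.5), got {self.poisson_nu}")
        if self.growth_stages_K < 1:
            raise ValueError(f"growth_stages_K must be >= 1, got {self.growth_stages_K}")

    @property
    def V0(self) -> float:
        """Minimal cell volume V(R0), m³."""
        return 4.0 / 3.0 * math.pi * self.R0 ** 3

    @property
    def tau_seconds(self) -> float:
        """Mean unconstrained growth time τ = 1/r, in seconds."""
        return 86400.0 / self.growth_rate_r


def params_asdict(obj) -> dict:
    """Flat dict of a frozen parameter dataclass (fields only, no properties)."""
    return {f.name: getattr(obj, f.name) for f in fields(obj)}
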