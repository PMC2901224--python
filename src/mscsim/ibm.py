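"""Off-lattice individual cell-based model (IBM) of MSC monolayer culture.

Cells are elastic adhesive spheres on a flat substrate, tracked by their
in-plane centre positions.  The pieces:

* modified Hertz contact: classic Hertz repulsion plus adhesion proportional
  to the contact area, for cell-cell and cell-substrate contacts,
* overdamped Langevin motion: inertia is negligible at cellular Reynolds
  numbers, so each step solves a linear system in the displacements whose
  friction coefficients are proportional to the contact areas,
* stochastic growth and division: the interphase is a chain of K exponential
  stages (Erlang growth time, CV = 1/sqrt(K)); at twice the minimal volume a
  cell splits into two daughters of minimal volume,
* contact inhibition: a cell whose summed repulsive (deformation) forces
  exceed F_max arrests growth until the load relaxes,
* the differentiation state α of every cell evolves by the shared
  noise-driven process; only progenitor-band cells (α_s < α < α_d) grow.

The module keeps cell attributes in flat numpy arrays for speed; ``Cell`` is
a per-cell record view used at the I/O boundary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import splu
from scipy.spatial import cKDTree

from .core_dynamics import evolve_alpha, is_proliferative
from .params import DifferentiationParams, MechanicsParams, OxygenEnvironment

__all__ = [
    "Cell",
    "Population",
    "Contacts",
    "ContactForce",
    "InstabilityError",
    "pair_force",
    "equilibrium_overlap",
    "total_deformation_force",
    "deformation_forces",
    "step_positions",
    "grow_and_divide",
    "simulate",
]


class InstabilityError(RuntimeError):
    """A mechanics step produced a displacement larger than R0/2."""


class ContactForce(NamedTuple):
    """Decomposed normal contact force: total = repulsive - adhesive (N)."""

    total: float
    repulsive: float
    adhesive: float
    area: float


@dataclass(frozen=True)
class Cell:
    """Read-only record of one agent (I/O boundary view)."""

    id: int
    alpha: float
    position: tuple
    volume: float
    phase: str
    parent_id: int
    founder_id: int
    founder_alpha0: float
    birth_time: float

    @property
    def radius(self) -> float:
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)


def _effective_modulus(params: MechanicsParams, substrate: bool) -> float:
    """Contact modulus E*: two identical cells, or cell against rigid plane."""
    compliance = (1.0 - params.poisson_nu ** 2) / params.young_E
    return 1.0 / (compliance if substrate else 2.0 * compliance)


def _effective_radius(Ri, Rj=None):
    """1/R_eff = 1/Ri + 1/Rj; the substrate (Rj=None) has infinite radius."""
    if Rj is None:
        return Ri
    return Ri * Rj / (Ri + Rj)


def pair_force(
    delta,
    Ri,
    Rj=None,
    params: MechanicsParams = MechanicsParams(),
) -> ContactForce:
    """Signed normal force of the modified Hertz contact at overlap delta.

    F(δ) = (4/3) E* sqrt(R_eff) δ^{3/2} − ε π R_eff, the derivative of the
    Hertz energy plus an adhesion energy −ε·A(δ) with contact area
    A(δ) = π R_eff δ.  Positive = repulsion.  ``Rj=None`` selects the
    substrate contact (flat rigid plane: R_eff = Ri, cell-side elasticity
    only, anchorage eps_cs).  Negative overlap means no contact: zero force
    and zero area.
    """
    substrate = Rj is None
    eps = params.eps_cs if substrate else params.eps_cc
    e_star = _effective_modulus(params, substrate)
    r_eff = _effective_radius(Ri, Rj)
    delta = np.asarray(delta, dtype=float)
    contact = delta > 0
    d = np.where(contact, delta, 0.0)
    rep = np.where(contact, 4.0 / 3.0 * e_star * np.sqrt(r_eff) * d ** 1.5, 0.0)
    adh = np.where(contact, eps * math.pi * np.asarray(r_eff, dtype=float), 0.0)
    area = np.where(contact, math.pi * r_eff * d, 0.0)
    if np.ndim(delta) == 0:
        return ContactForce(float(rep - adh), float(rep), float(adh), float(area))
    return ContactForce(rep - adh, rep, adh, area)


def equilibrium_overlap(Ri, Rj=None, params: MechanicsParams = MechanicsParams()):
    """Overlap at which repulsion balances adhesion, closed form.

    δ_eq = (3 π ε sqrt(R_eff) / (4 E*))^{2/3}.
    """
    substrate = Rj is None
    eps = params.eps_cs if substrate else params.eps_cc
    e_star = _effective_modulus(params, substrate)
    r_eff = _effective_radius(Ri, Rj)
    return (3.0 * math.pi * eps * np.sqrt(r_eff) / (4.0 * e_star)) ** (2.0 / 3.0)


class Population:
    """A population of cells with flat-array storage and an event log."""

    def __init__(
        self,
        alpha: np.ndarray,
        positions: np.ndarray,
        env: OxygenEnvironment,
        volume: np.ndarray,
        ids: Optional[np.ndarray] = None,
        parent_id: Optional[np.ndarray] = None,
        founder_id: Optional[np.ndarray] = None,
        founder_alpha0: Optional[np.ndarray] = None,
        birth_time: Optional[np.ndarray] = None,
        stages_done: Optional[np.ndarray] = None,
        stage_time_left: Optional[np.ndarray] = None,
        t: float = 0.0,
        max_cells: Optional[int] = None,
    ):
        n = len(alpha)
        self.alpha = np.asarray(alpha, dtype=float).copy()
        self.pos = np.asarray(positions, dtype=float).reshape(n, 2).copy()
        self.volume = np.asarray(volume, dtype=float).copy()
        self.env = env
        self.ids = (np.arange(n, dtype=np.int64) if ids is None
                    else np.asarray(ids, dtype=np.int64).copy())
        if len(np.unique(self.ids)) != n:
            raise ValueError("cell ids must be unique")
        self.parent_id = (np.full(n, -1, dtype=np.int64) if parent_id is None
                          else np.asarray(parent_id, dtype=np.int64).copy())
        self.founder_id = (self.ids.copy() if founder_id is None
                           else np.asarray(founder_id, dtype=np.int64).copy())
        self.founder_alpha0 = (self.alpha.copy() if founder_alpha0 is None
                               else np.asarray(founder_alpha0, dtype=float).copy())
        self.birth_time = (np.zeros(n) if birth_time is None
                           else np.asarray(birth_time, dtype=float).copy())
        self.stages_done = (np.zeros(n, dtype=np.int64) if stages_done is None
                            else np.asarray(stages_done, dtype=np.int64).copy())
        self.stage_time_left = (np.full(n, np.inf) if stage_time_left is None
                                else np.asarray(stage_time_left, dtype=float).copy())
        self.arrested = np.zeros(n, dtype=bool)
        self.quiescent = np.zeros(n, dtype=bool)
        self.t = float(t)
        self.next_id = int(self.ids.max()) + 1 if n else 0
        self.max_cells = max_cells
        self.events: list = []
        self._cap_warned = False

    # ------------------------------------------------------------------ #
    @classmethod
    def seed(
        cls,
        alpha: np.ndarray,
        positions: np.ndarray,
        env: OxygenEnvironment,
        mech: MechanicsParams,
        diff_params: DifferentiationParams,
        rng: Optional[np.random.Generator] = None,
        asynchronous: bool = True,
        max_cells: Optional[int] = None,
    ) -> "Population":
        """Fresh population at t=0; founders are their own genealogy roots.

        With ``asynchronous=True`` (and an rng) proliferative cells start at
        a uniformly random growth stage with the matching volume, emulating
        an unsynchronized culture; otherwise all start at minimal volume.
        """
        alpha = np.asarray(alpha, dtype=float)
        n = alpha.size
        K = mech.growth_stages_K
        stages = np.zeros(n, dtype=np.int64)
        time_left = np.full(n, np.nan)
        if asynchronous and rng is not None:
            stages = rng.integers(0, K, size=n)
            stages[~is_proliferative(alpha, diff_params)] = 0
        volume = mech.V0 * (1.0 + stages / K)
        pop = cls(alpha, positions, env, volume,
                  stages_done=stages, stage_time_left=time_left,
                  max_cells=max_cells)
        scale = mech.tau_seconds / K
        if rng is not None:
            pop.stage_time_left = rng.exponential(scale, size=n)
        else:
            pop.stage_time_left = np.full(n, scale)
        return pop

    # ------------------------------------------------------------------ #
    @property
    def n(self) -> int:
        return self.alpha.size

    @property
    def radius(self) -> np.ndarray:
        return (3.0 * self.volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    def phase_of(self, i: int, diff_params: Optional[DifferentiationParams] = None) -> str:
        if self.quiescent[i]:
            return "quiescent"
        if self.arrested[i]:
            return "arrested"
        if diff_params is not None and not is_proliferative(self.alpha[i], diff_params):
            return "resting"
        return f"interphase-{int(self.stages_done[i])}"

    def cell(self, i: int, diff_params: Optional[DifferentiationParams] = None) -> Cell:
        return Cell(
            id=int(self.ids[i]), alpha=float(self.alpha[i]),
            position=(float(self.pos[i, 0]), float(self.pos[i, 1])),
            volume=float(self.volume[i]), phase=self.phase_of(i, diff_params),
            parent_id=int(self.parent_id[i]), founder_id=int(self.founder_id[i]),
            founder_alpha0=float(self.founder_alpha0[i]),
            birth_time=float(self.birth_time[i]),
        )

    def index_of(self, cell_id: int) -> int:
        idx = np.nonzero(self.ids == cell_id)[0]
        if idx.size == 0:
            raise KeyError(f"no cell with id {cell_id}")
        return int(idx[0])


@dataclass
class Contacts:
    """Cell-cell contact list plus per-cell substrate contact, one time step."""

    pair_i: np.ndarray          # indices, pair_i < pair_j
    pair_j: np.ndarray
    delta: np.ndarray           # overlaps, > 0
    normal: np.ndarray          # unit vectors from j toward i, shape (npairs, 2)
    f_total: np.ndarray         # signed normal force (repulsion positive)
    f_rep: np.ndarray           # Hertz (repulsive) component
    area: np.ndarray            # contact areas
    sub_area: np.ndarray        # per-cell substrate contact area
    sub_rep: np.ndarray         # per-cell substrate repulsive force magnitude


def compute_contacts(pop: Population, params: MechanicsParams) -> Contacts:
    """Find all overlapping cell pairs and evaluate contact forces.

    The substrate contact is always on: every cell adheres to the plane at
    its adhesive equilibrium overlap, contributing friction (and a constant
    repulsive load equal to the adhesion pull) but no in-plane force.
    """
    r = pop.radius
    n = pop.n
    sub_delta = equilibrium_overlap(r, None, params)
    sub_area = math.pi * r * sub_delta
    sub_rep = params.eps_cs * math.pi * r  # Hertz term balancing adhesion
    if n >= 2:
        tree = cKDTree(pop.pos)
        pairs = tree.query_pairs(2.0 * float(r.max()), output_type="ndarray")
    else:
        pairs = np.empty((0, 2), dtype=np.int64)
    if pairs.size:
        i, j = pairs[:, 0], pairs[:, 1]
        dvec = pop.pos[i] - pop.pos[j]
        dist = np.sqrt((dvec ** 2).sum(axis=1))
        delta = r[i] + r[j] - dist
        keep = delta > 0
        i, j, dvec, dist, delta = i[keep], j[keep], dvec[keep], dist[keep], delta[keep]
        with np.errstate(invalid="ignore", divide="ignore"):
            normal = np.where(dist[:, None] > 0, dvec / np.maximum(dist, 1e-30)[:, None], 0.0)
        e_star = _effective_modulus(params, substrate=False)
        r_eff = r[i] * r[j] / (r[i] + r[j])
        f_rep = 4.0 / 3.0 * e_star * np.sqrt(r_eff) * delta ** 1.5
        f_adh = params.eps_cc * math.pi * r_eff
        area = math.pi * r_eff * delta
        return Contacts(i, j, delta, normal, f_rep - f_adh, f_rep, area,
                        sub_area, sub_rep)
    empty = np.empty(0)
    return Contacts(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64),
                    empty, np.empty((0, 2)), empty, empty, empty,
                    sub_area, sub_rep)


def deformation_forces(
    pop: Population,
    params: MechanicsParams,
    contacts: Optional[Contacts] = None,
    include_substrate: bool = True,
) -> np.ndarray:
    """Per-cell sum of repulsive (Hertz) force magnitudes over all contacts."""
    c = contacts or compute_contacts(pop, params)
    out = c.sub_rep.copy() if include_substrate else np.zeros(pop.n)
    np.add.at(out, c.pair_i, c.f_rep)
    np.add.at(out, c.pair_j, c.f_rep)
    return out


def total_deformation_force(
    cell_index: int,
    pop: Population,
    params: MechanicsParams,
    include_substrate: bool = True,
) -> float:
    """Summed deformation (repulsive) force on one cell, substrate included."""
    return float(deformation_forces(pop, params,
                                    include_substrate=include_substrate)[cell_index])


def update_contact_inhibition(
    pop: Population, contacts: Contacts, params: MechanicsParams
) -> None:
    """Refresh arrest (and optional quiescence) flags from current contacts.

    Arrest is reversible: a cell is arrested exactly while the summed
    deformation forces exceed F_max.  The optional pressure gate marks cells
    permanently quiescent once their mean contact pressure exceeds F_q.
    """
    load = deformation_forces(pop, params, contacts,
                              include_substrate=params.arrest_includes_substrate)
    pop.arrested = load > params.F_max
    if params.quiescence_gate:
        area = contacts.sub_area.copy()
        np.add.at(area, contacts.pair_i, contacts.area)
        np.add.at(area, contacts.pair_j, contacts.area)
        rep = deformation_forces(pop, params, contacts, include_substrate=True)
        pressure = np.where(area > 0, rep / np.maximum(area, 1e-300), 0.0)
        pop.quiescent |= pressure > params.F_q


def step_positions(
    pop: Population,
    dt: float,
    params: MechanicsParams,
    rng: np.random.Generator,
    contacts: Optional[Contacts] = None,
) -> None:
    """One overdamped Langevin step: solve the coupled friction system.

    For each cell,  (γ_cs A_is + Σ_j γ_cc A_ij) dx_i − Σ_j γ_cc A_ij dx_j
    = (Σ_j F_ij n_ij + F_i^stoch) dt.  The friction matrix couples touching
    cells and is solved exactly (sparse LU, shared by the x and y
    components).  The stochastic force has per-component standard deviation
    γ_cs A_is sqrt(2 D_cell / dt), so an isolated cell diffuses with D_cell.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    c = contacts or compute_contacts(pop, params)
    n = pop.n
    fdet = np.zeros((n, 2))
    if c.pair_i.size:
        fvec = c.f_total[:, None] * c.normal
        np.add.at(fdet, c.pair_i, fvec)
        np.add.at(fdet, c.pair_j, -fvec)
    gamma_sub = params.gamma_cs * c.sub_area
    sd = gamma_sub * math.sqrt(2.0 * params.D_cell / dt)
    fsto = rng.normal(0.0, 1.0, size=(n, 2)) * sd[:, None]
    rhs = (fdet + fsto) * dt

    diag = gamma_sub.copy()
    if c.pair_i.size:
        g = params.gamma_cc * c.area
        np.add.at(diag, c.pair_i, g)
        np.add.at(diag, c.pair_j, g)
        rows = np.concatenate([np.arange(n), c.pair_i, c.pair_j])
        cols = np.concatenate([np.arange(n), c.pair_j, c.pair_i])
        vals = np.concatenate([diag, -g, -g])
        gamma = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
        dx = splu(gamma).solve(rhs)
    else:
        dx = rhs / diag[:, None]
    step = np.sqrt((dx ** 2).sum(axis=1))
    if np.any(step > params.R0 / 2.0):
        raise InstabilityError(
            f"displacement {step.max():.3e} m exceeds R0/2 = {params.R0/2:.3e} m "
            f"at t = {pop.t:.1f} s (n = {n}); reduce dt"
        )
    pop.pos += dx


def grow_and_divide(
    pop: Population,
    dt: float,
    params: MechanicsParams,
    diff_params: DifferentiationParams,
    rng: np.random.Generator,
    contacts: Optional[Contacts] = None,
    refresh_inhibition: bool = False,
) -> int:
    """Advance growth clocks and execute divisions; returns division count.

    Only progenitor-band cells that are neither arrested nor quiescent
    progress.  The interphase is K exponential stages of mean τ/K each, one
    volume increment V0/K per completion (Erlang(K, K/τ) growth time).  At
    volume 2 V0 the mother divides instantaneously into two daughters of
    volume V0 placed symmetrically about her centre, separation R0, along a
    uniformly random in-plane axis; daughters inherit α and the founder
    labels unchanged.
    """
    if refresh_inhibition or contacts is None:
        c = contacts or compute_contacts(pop, params)
        update_contact_inhibition(pop, c, params)
    K = params.growth_stages_K
    scale = params.tau_seconds / K
    active = (is_proliferative(pop.alpha, diff_params)
              & ~pop.arrested & ~pop.quiescent)
    idx = np.nonzero(active)[0]
    if idx.size:
        pop.stage_time_left[idx] -= dt
        while True:
            done = idx[(pop.stage_time_left[idx] <= 0)
                       & (pop.stages_done[idx] < K)]
            if done.size == 0:
                break
            pop.stages_done[done] += 1
            pop.volume[done] += params.V0 / K
            # carry the (negative) remainder into the next stage's clock so
            # stage times compose exactly regardless of dt
            pop.stage_time_left[done] += rng.exponential(scale, size=done.size)

    dividers = np.nonzero(pop.stages_done >= K)[0]
    n_div = 0
    if dividers.size:
        new_rows = []
        removed = []
        for i in dividers:
            if pop.max_cells is not None and pop.n + len(new_rows) - len(removed) >= pop.max_cells:
                if not pop._cap_warned:
                    warnings.warn(
                        f"population cap max_cells={pop.max_cells} reached; "
                        "further divisions suppressed", RuntimeWarning)
                    pop._cap_warned = True
                break
            theta = rng.uniform(0.0, 2.0 * math.pi)
            axis = np.array([math.cos(theta), math.sin(theta)])
            d1 = pop.pos[i] + 0.5 * params.R0 * axis
            d2 = pop.pos[i] - 0.5 * params.R0 * axis
            id1, id2 = pop.next_id, pop.next_id + 1
            pop.next_id += 2
            for did, dpos in ((id1, d1), (id2, d2)):
                new_rows.append(dict(
                    id=did, alpha=pop.alpha[i], pos=dpos, volume=params.V0,
                    parent=pop.ids[i], founder=pop.founder_id[i],
                    falpha=pop.founder_alpha0[i],
                    time_left=rng.exponential(scale),
                ))
            pop.events.append((pop.t, "division", int(pop.ids[i]), id1, id2,
                               float(pop.alpha[i])))
            removed.append(i)
            n_div += 1
        if removed:
            keep = np.ones(pop.n, dtype=bool)
            keep[removed] = False
            _filter_population(pop, keep)
            _append_cells(pop, new_rows)
    return n_div


def _filter_population(pop: Population, keep: np.ndarray) -> None:
    for name in ("alpha", "volume", "ids", "parent_id", "founder_id",
                 "founder_alpha0", "birth_time", "stages_done",
                 "stage_time_left", "arrested", "quiescent"):
        setattr(pop, name, getattr(pop, name)[keep])
    pop.pos = pop.pos[keep]


def _append_cells(pop: Population, rows: list) -> None:
    m = len(rows)
    pop.alpha = np.concatenate([pop.alpha, [r["alpha"] for r in rows]])
    pop.pos = np.vstack([pop.pos, [r["pos"] for r in rows]])
    pop.volume = np.concatenate([pop.volume, [r["volume"] for r in rows]])
    pop.ids = np.concatenate([pop.ids, np.array([r["id"] for r in rows], dtype=np.int64)])
    pop.parent_id = np.concatenate(
        [pop.parent_id, np.array([r["parent"] for r in rows], dtype=np.int64)])
    pop.founder_id = np.concatenate(
        [pop.founder_id, np.array([r["founder"] for r in rows], dtype=np.int64)])
    pop.founder_alpha0 = np.concatenate(
        [pop.founder_alpha0, [r["falpha"] for r in rows]])
    pop.birth_time = np.concatenate([pop.birth_time, np.full(m, pop.t)])
    pop.stages_done = np.concatenate([pop.stages_done, np.zeros(m, dtype=np.int64)])
    pop.stage_time_left = np.concatenate(
        [pop.stage_time_left, [r["time_left"] for r in rows]])
    pop.arrested = np.concatenate([pop.arrested, np.zeros(m, dtype=bool)])
    pop.quiescent = np.concatenate([pop.quiescent, np.zeros(m, dtype=bool)])


def _check_invariants(pop: Population, params: MechanicsParams) -> None:
    if pop.n == 0:
        return
    if np.any(pop.alpha < 0) or np.any(pop.alpha > 1):
        raise AssertionError("alpha left [0, 1]")
    if np.any(pop.volume < params.V0 * (1 - 1e-9)) or np.any(
            pop.volume > 2 * params.V0 * (1 + 1e-9)):
        raise AssertionError("cell volume left [V0, 2 V0]")
    if not np.all(np.isfinite(pop.pos)):
        raise AssertionError("non-finite cell position")


def simulate(
    pop: Population,
    duration_days: float,
    params: MechanicsParams,
    diff_params: DifferentiationParams,
    env: OxygenEnvironment,
    rng: np.random.Generator,
    dt: float = 30.0,
    recorders: Sequence[Callable[[Population], None]] = (),
    record_every_days: Optional[float] = None,
) -> Population:
    """Run the coupled α-dynamics / growth / mechanics simulation in place.

    Per mechanics step of ``dt`` seconds: contacts are rebuilt, contact
    inhibition refreshed, every cell's α advanced (randomization events
    Poisson-thinned onto the step), growth clocks advanced and divisions
    executed, then all positions moved by one Langevin step.  Recorders are
    called at t=0, every ``record_every_days``, and at the end.  Runs are
    bit-reproducible for a given seeded generator.
    """
    if duration_days < 0:
        raise ValueError("duration_days must be >= 0")
    n_steps = int(round(duration_days * 86400.0 / dt))
    interval = (record_every_days * 86400.0) if record_every_days else None
    for rec in recorders:
        rec(pop)
    next_record = interval if interval else math.inf
    for _ in range(n_steps):
        contacts = compute_contacts(pop, params)
        update_contact_inhibition(pop, contacts, params)
        pop.alpha = evolve_alpha(pop.alpha, dt, diff_params, env, rng)
        divided = grow_and_divide(pop, dt, params, diff_params, rng,
                                  contacts=contacts)
        if divided:
            contacts = compute_contacts(pop, params)
        step_positions(pop, dt, params, rng, contacts=contacts)
        pop.t += dt
        _check_invariants(pop, params)
        if interval and pop.t >= next_record - 1e-6:
            for rec in recorders:
                rec(pop)
            next_record += interval
    if n_steps and not interval:
        for rec in recorders:
            rec(pop)
    return pop
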