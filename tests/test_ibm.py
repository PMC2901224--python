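"""Tests of the biomechanical individual-based model.

Closed-form contact mechanics, Newton's third law, the Einstein relation
for isolated-cell motility, Erlang growth-time statistics, division
book-keeping, contact inhibition, determinism and stability guards.
"""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from mscsim import (
    InstabilityError,
    MechanicsParams,
    OxygenEnvironment,
    Population,
    equilibrium_overlap,
    pair_force,
    simulate,
    total_deformation_force,
)
from mscsim.ibm import (
    compute_contacts,
    deformation_forces,
    grow_and_divide,
    step_positions,
    update_contact_inhibition,
)


def _population(alphas, positions, env, mech, diff_params, **kw):
    return Population.seed(np.asarray(alphas, float), np.asarray(positions, float),
                           env, mech, diff_params, **kw)


class TestPairForce:
    def test_no_contact_below_zero_overlap(self, mech):
        f = pair_force(-1e-9, mech.R0, mech.R0, mech)
        assert f.total == 0 and f.area == 0

    def test_zero_overlap_is_pure_adhesive_pull(self, mech):
        """At delta = 0 the Hertz term vanishes and the force is the adhesion
        limit -eps*pi*R_eff."""
        f = pair_force(0.0 + 1e-300, mech.R0, mech.R0, mech)
        r_eff = mech.R0 / 2
        assert f.repulsive == pytest.approx(0.0, abs=1e-20)
        assert f.total == pytest.approx(-mech.eps_cc * math.pi * r_eff, rel=1e-12)

    def test_equilibrium_overlap_closed_form_vs_root_finding(self, mech):
        """The analytic equilibrium overlap solves F(delta) = 0; with the
        default constants the cell-cell value is about 0.9 um."""
        d_eq = equilibrium_overlap(mech.R0, mech.R0, mech)
        root = brentq(lambda d: pair_force(d, mech.R0, mech.R0, mech).total,
                      1e-12, 4e-6)
        assert d_eq == pytest.approx(root, rel=1e-9)
        assert d_eq == pytest.approx(0.9e-6, rel=0.05)

    def test_substrate_contact_uses_cell_elasticity_only(self, mech):
        d_cc = equilibrium_overlap(mech.R0, mech.R0, mech)
        d_cs = equilibrium_overlap(mech.R0, None, mech)
        assert d_cs != d_cc
        assert pair_force(d_cs, mech.R0, None, mech).total == pytest.approx(0, abs=1e-18)


class TestDeformationForces:
    def test_isolated_cell_carries_substrate_load_only(
            self, mech, env5, diff_params):
        """An isolated cell sits at the adhesive substrate equilibrium, so its
        deformation-force sum is the Hertz term there: eps_cs*pi*R0."""
        pop = _population([0.5], [[0, 0]], env5, mech, diff_params)
        f = total_deformation_force(0, pop, mech)
        assert f == pytest.approx(mech.eps_cs * math.pi * mech.R0, rel=1e-12)
        assert total_deformation_force(0, pop, mech, include_substrate=False) == 0

    def test_newton_third_law_on_random_cluster(self, mech, env5, diff_params, rng):
        """Pair forces cancel exactly: the vector sum of all deterministic
        cell-cell forces over a cluster is zero within 1e-12 N."""
        pos = rng.uniform(0, 4 * mech.R0, size=(12, 2))
        pop = _population(np.full(12, 0.5), pos, env5, mech, diff_params)
        c = compute_contacts(pop, mech)
        assert c.pair_i.size > 0
        net = np.zeros((12, 2))
        fvec = c.f_total[:, None] * c.normal
        np.add.at(net, c.pair_i, fvec)
        np.add.at(net, c.pair_j, -fvec)
        assert np.abs(net.sum(axis=0)).max() < 1e-12

    def test_hexagonal_patch_center_is_most_loaded(self, mech, env5, diff_params):
        spacing = 2 * mech.R0 - equilibrium_overlap(mech.R0, mech.R0, mech)
        angles = np.arange(6) * math.pi / 3
        pos = np.vstack([[0.0, 0.0],
                         spacing * np.column_stack([np.cos(angles), np.sin(angles)])])
        pop = _population(np.full(7, 0.5), pos, env5, mech, diff_params)
        loads = deformation_forces(pop, mech, include_substrate=False)
        assert loads[0] > loads[1:].max()


class TestStepPositions:
    def test_no_forces_no_motion(self, mech, env5, diff_params, rng):
        """With the stochastic force switched off (D -> 0) and no contacts,
        positions are unchanged."""
        quiet = MechanicsParams(D_cell=1e-60)
        pop = _population([0.9], [[0, 0]], env5, quiet, diff_params)
        before = pop.pos.copy()
        step_positions(pop, 30.0, quiet, rng)
        assert np.abs(pop.pos - before).max() < 1e-15

    def test_isolated_cell_diffusion_obeys_einstein_relation(
            self, mech, env5, diff_params):
        """Mean-squared in-plane displacement of isolated cells is 4*D*t
        within 5% (2000 replicate cells on a wide grid)."""
        n = 2000
        side = int(math.ceil(math.sqrt(n)))
        pos = 1e-3 * np.column_stack(np.divmod(np.arange(n), side)).astype(float)
        pop = _population(np.full(n, 0.95), pos, env5, mech, diff_params)
        rng = np.random.default_rng(42)
        start = pop.pos.copy()
        steps, dt = 40, 30.0
        for _ in range(steps):
            step_positions(pop, dt, mech, rng)
        msd = ((pop.pos - start) ** 2).sum(axis=1).mean()
        assert msd == pytest.approx(4 * mech.D_cell * steps * dt, rel=0.05)

    def test_two_body_relaxation_toward_equilibrium_overlap(
            self, mech, env5, diff_params):
        """Two overlapping cells, noise off: displacements are antiparallel
        and the overlap decreases monotonically toward delta_eq."""
        quiet = MechanicsParams(D_cell=1e-60)
        d_eq = equilibrium_overlap(mech.R0, mech.R0, quiet)
        pop = _population([0.9, 0.9], [[0, 0], [mech.R0, 0]], env5, quiet, diff_params)
        rng = np.random.default_rng(0)
        overlap_prev = 2 * mech.R0 - mech.R0
        for _ in range(600):
            before = pop.pos.copy()
            step_positions(pop, 60.0, quiet, rng)
            dx = pop.pos - before
            assert np.dot(dx[0], dx[1]) <= 1e-40  # antiparallel (noise is off)
            overlap = 2 * mech.R0 - np.linalg.norm(pop.pos[0] - pop.pos[1])
            assert overlap <= overlap_prev + 1e-15
            overlap_prev = overlap
        assert overlap_prev == pytest.approx(d_eq, rel=0.05)

    def test_instability_guard(self, mech, env5, diff_params, rng):
        pop = _population([0.9, 0.9], [[0, 0], [mech.R0, 0]], env5, mech, diff_params)
        with pytest.raises(InstabilityError):
            step_positions(pop, 1e7, mech, rng)


class TestGrowthAndDivision:
    def test_nonproliferative_states_never_grow(self, mech, env5, diff_params, rng):
        pop = _population([0.05, 0.95], [[0, 0], [1e-3, 0]], env5, mech, diff_params)
        v0 = pop.volume.copy()
        for _ in range(200):
            grow_and_divide(pop, 600.0, mech, diff_params, rng)
        assert np.array_equal(pop.volume, v0)
        assert pop.n == 2

    def test_growth_time_is_erlang(self, mech, env5, diff_params):
        """Unconstrained division times follow Erlang(K, K/tau): mean tau =
        1/1.9 day within 2%, CV = 1/sqrt(K) within 15%."""
        n = 1500
        side = int(math.ceil(math.sqrt(n)))
        pos = 1e-3 * np.column_stack(np.divmod(np.arange(n), side)).astype(float)
        pop = Population.seed(np.full(n, 0.5), pos, env5, mech, diff_params,
                              rng=None, asynchronous=False)
        rng = np.random.default_rng(7)
        dt, t = 120.0, 0.0
        while t < 3.0 * 86400.0 and pop.n:
            grow_and_divide(pop, dt, mech, diff_params, rng)
            pop.t += dt
            t += dt
            if pop.events:
                # keep only cells that have not divided yet (founders)
                keep = pop.parent_id == -1
                if not keep.all():
                    from mscsim.ibm import _filter_population
                    _filter_population(pop, keep)
        times = np.array([e[0] for e in pop.events]) / 86400.0
        assert times.size > 1400
        tau = 1.0 / mech.growth_rate_r
        assert times.mean() == pytest.approx(tau, rel=0.02)
        cv = times.std() / times.mean()
        assert cv == pytest.approx(1.0 / math.sqrt(mech.growth_stages_K), rel=0.15)

    def test_division_conserves_volume_and_inherits_identity(
            self, mech, env5, diff_params):
        pop = Population.seed(np.array([0.5]), np.zeros((1, 2)), env5, mech,
                              diff_params, rng=None, asynchronous=False)
        rng = np.random.default_rng(3)
        while not pop.events:
            grow_and_divide(pop, 300.0, mech, diff_params, rng)
            pop.t += 300.0
        assert pop.n == 2
        assert np.allclose(pop.volume, mech.V0)           # 2 V0 -> V0 + V0
        assert np.all(pop.alpha == 0.5)                   # daughters inherit alpha
        assert np.all(pop.founder_id == 0)
        assert np.all(pop.founder_alpha0 == 0.5)
        assert np.all(pop.parent_id == 0)
        d = np.linalg.norm(pop.pos[0] - pop.pos[1])
        assert d == pytest.approx(mech.R0, rel=1e-9)      # separation R0

    def test_contact_inhibition_arrests_crowded_cells(
            self, mech, env5, diff_params, rng):
        """A centre cell in a close-packed hexagon exceeds F_max and arrests;
        an isolated cell does not."""
        spacing = 2 * mech.R0 - equilibrium_overlap(mech.R0, mech.R0, mech)
        angles = np.arange(6) * math.pi / 3
        pos = np.vstack([[0.0, 0.0],
                         spacing * np.column_stack([np.cos(angles), np.sin(angles)]),
                         [[1e-3, 1e-3]]])
        pop = _population(np.full(8, 0.5), pos, env5, mech, diff_params)
        update_contact_inhibition(pop, compute_contacts(pop, mech), mech)
        assert pop.arrested[0]
        assert not pop.arrested[7]

    def test_population_cap_suppresses_division_with_warning(
            self, mech, env5, diff_params):
        pop = Population.seed(np.array([0.5, 0.5]), [[0, 0], [1e-3, 0]],
                              env5, mech, diff_params, rng=None,
                              asynchronous=False, max_cells=2)
        rng = np.random.default_rng(3)
        with pytest.warns(RuntimeWarning, match="max_cells"):
            for _ in range(2000):
                grow_and_divide(pop, 300.0, mech, diff_params, rng)
        assert pop.n == 2 and not pop.events


class TestSimulate:
    def test_zero_duration_is_identity(self, mech, env5, diff_params, rng):
        pop = _population([0.5, 0.2], [[0, 0], [1e-4, 0]], env5, mech, diff_params)
        a, p = pop.alpha.copy(), pop.pos.copy()
        simulate(pop, 0.0, mech, diff_params, env5, rng)
        assert pop.t == 0.0
        assert np.array_equal(pop.alpha, a) and np.array_equal(pop.pos, p)

    def test_invariants_and_slowed_effective_growth(self, mech, env5, diff_params):
        """After a day of growth: alpha in [0,1], volumes in [V0, 2V0],
        finite positions; and state switching makes the realized per-capita
        division rate smaller than the unconstrained rate r."""
        rng = np.random.default_rng(11)
        n0 = 100
        side = int(math.ceil(math.sqrt(n0)))
        pos = 2e-4 * np.column_stack(np.divmod(np.arange(n0), side)).astype(float)
        alpha = rng.uniform(0, 1, n0)
        pop = Population.seed(alpha, pos, env5, mech, diff_params, rng=rng)
        simulate(pop, 1.0, mech, diff_params, env5, rng, dt=120.0)
        assert np.all((pop.alpha >= 0) & (pop.alpha <= 1))
        assert np.all(pop.volume >= mech.V0 * (1 - 1e-9))
        assert np.all(pop.volume <= 2 * mech.V0 * (1 + 1e-9))
        assert np.all(np.isfinite(pop.pos))
        divisions = len(pop.events)
        mean_n = 0.5 * (n0 + pop.n)
        assert 0 < divisions / mean_n < mech.growth_rate_r

    def test_identical_seeds_reproduce_bitwise(self, mech, env5, diff_params):
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(99)
            pop = Population.seed(np.array([0.4, 0.5, 0.6]),
                                  [[0, 0], [9e-6, 0], [0, 9e-6]],
                                  env5, mech, diff_params, rng=rng)
            simulate(pop, 0.5, mech, diff_params, env5, rng, dt=60.0)
            runs.append((pop.events, pop.pos.copy(), pop.alpha.copy()))
        assert runs[0][0] == runs[1][0]
        assert np.array_equal(runs[0][1], runs[1][1])
        assert np.array_equal(runs[0][2], runs[1][2])
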