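"""Gated two-basin model: energies, gradients, gating contracts, embedding."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize

from cvsteer.errors import ConfigurationError
from cvsteer.model import (GatedModelParams, build_bead_model,
                           build_cv_space_model, initial_condition,
                           reference_pose)
from cvsteer.references import CLOSED_STATE, OPEN_STATE, StateReference


def theta_of(ref, params):
    x = np.array([ref.mean("d1"), ref.mean("d2"), ref.mean("d6"),
                  math.radians(ref.mean("chi1")), params.L_fold])
    return x


class TestEnergySurface:
    def test_closed_means_are_a_local_minimum(self, model):
        x = theta_of(CLOSED_STATE, model.params)
        res = minimize(model.energy, x, jac=model.gradient, method="L-BFGS-B")
        assert np.linalg.norm(model.gradient(res.x)) < 1e-3
        # the minimizer stays within a fraction of a SD of the table means
        assert abs(res.x[0] - 0.93) < 0.1
        assert abs(res.x[2] - 0.41) < 0.05
        assert abs(math.degrees(res.x[3]) - 66.4) < 10.0

    def test_open_means_are_a_local_minimum(self, model):
        x = theta_of(OPEN_STATE, model.params)
        res = minimize(model.energy, x, jac=model.gradient, method="L-BFGS-B")
        assert np.linalg.norm(model.gradient(res.x)) < 1e-3
        assert abs(res.x[0] - 1.92) < 0.15
        assert abs(res.x[2] - 1.04) < 0.1

    def test_gates_off_reduces_to_two_basin_plus_helix(self, gates_off_model):
        """With all gate amplitudes zero the energy equals the log-sum-exp
        basin term plus the helix well, reconstructed independently."""
        p = gates_off_model.params
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = np.array([rng.uniform(0.5, 2.3), rng.uniform(1.2, 2.2),
                          rng.uniform(0.2, 1.3), rng.uniform(-math.pi, math.pi),
                          rng.uniform(1.9, 2.2)])
            got = gates_off_model.energy(x)
            expect = _lse_plus_helix_oracle(x, p)
            assert got == pytest.approx(expect, abs=1e-9)

    def test_gradient_matches_finite_differences(self, model):
        rng = np.random.default_rng(7)
        h = 1e-6
        x0 = theta_of(CLOSED_STATE, model.params)
        for _ in range(100):
            x = x0 + rng.uniform(-1, 1, 5) * np.array([0.5, 0.3, 0.3, 1.5, 0.15])
            g = model.gradient(x)
            fd = np.array([
                (model.energy(x + h * e) - model.energy(x - h * e)) / (2 * h)
                for e in np.eye(5)])
            assert np.all(np.abs(g - fd) / np.maximum(1.0, np.abs(fd)) < 1e-5)

    def test_missing_reference_cv_rejected(self):
        bad = StateReference("closed", {"d1": (0.93, 0.23)})
        with pytest.raises(ConfigurationError):
            build_cv_space_model(refs=(bad, OPEN_STATE))


def _lse_plus_helix_oracle(x, p):
    """Independent reconstruction of the ungated potential."""
    names = ("d1", "d2", "d6", "chi1")
    g_c = g_o = 0.0
    for i, n in enumerate(names):
        mc, sc = CLOSED_STATE.mean(n), CLOSED_STATE.sd(n)
        mo, so = OPEN_STATE.mean(n), OPEN_STATE.sd(n)
        v = x[i]
        if n == "chi1":
            v = math.degrees(x[3])
            dc = ((v - mc + 180) % 360 - 180) * math.pi / 180
            do = ((v - mo + 180) % 360 - 180) * math.pi / 180
            sc, so = math.radians(sc), math.radians(so)
        else:
            dc, do = v - mc, v - mo
        g_c += (dc / (math.sqrt(2) * sc)) ** 2
        g_o += (do / (math.sqrt(2) * so)) ** 2
    u = -p.epsilon * math.log(math.exp(-g_c) + math.exp(-g_o))
    dL = x[4] - p.L_fold
    q = dL * dL / (2 * p.sigma_La3 ** 2)
    u += p.epsilon * q / (1 + q / p.la3_cap)
    c = 0.5 * (p.L_fold + p.L_broken)
    a = 0.5 * (p.L_broken - p.L_fold)
    y = x[4] - c
    if abs(y) <= a:
        u += p.helix_barrier * (y * y - a * a) ** 2 / a ** 4
    else:
        k = 8 * p.helix_barrier / (a * a)
        u += 0.5 * k * (abs(y) - a) ** 2
    u += p.helix_depth_penalty / (1 + math.exp(-y / (0.5 * a)))
    return u


class TestGatingContracts:
    """Direct energy-evaluation versions of the mechanistic couplings."""

    def test_salt_bridge_gates_the_rotamer(self, model):
        """Rotating χ1 to open costs at least A_block/2 more with the salt
        bridge intact (d6 closed) than with it broken (d6 open)."""
        p = model.params
        base = theta_of(CLOSED_STATE, p)

        def cost_of_rotation(d6):
            x_closed = base.copy()
            x_closed[2] = d6
            x_open = x_closed.copy()
            x_open[3] = math.radians(OPEN_STATE.mean("chi1"))
            return model.energy(x_open) - model.energy(x_closed)

        gap = cost_of_rotation(CLOSED_STATE.mean("d6")) \
            - cost_of_rotation(OPEN_STATE.mean("d6"))
        assert gap >= p.A_block / 2

    def test_chi1_locks_d2(self, model):
        """With χ1 closed, the minimum-energy d2 stays within 2σ of the
        closed mean even with d1 held open."""
        x = theta_of(CLOSED_STATE, model.params)
        x[0] = OPEN_STATE.mean("d1")

        def e_of_d2(d2):
            y = x.copy()
            y[1] = d2
            return model.energy(y)

        grid = np.linspace(1.2, 2.2, 401)
        best = grid[int(np.argmin([e_of_d2(v) for v in grid]))]
        assert abs(best - CLOSED_STATE.mean("d2")) <= 2 * CLOSED_STATE.sd("d2")

    def test_broken_helix_is_metastable_and_penalised(self, model):
        """The broken-helix well survives the basin attraction (local
        minimum near L_broken) and lies above the folded well."""
        p = model.params
        x = theta_of(OPEN_STATE, p)
        x[3] = math.radians(OPEN_STATE.mean("chi1"))

        def e_of_L(L):
            y = x.copy()
            y[4] = L
            return model.energy(y)

        grid = np.linspace(p.L_fold + 0.2, p.L_broken + 0.15, 200)
        energies = [e_of_L(v) for v in grid]
        i_min = int(np.argmin(energies))
        assert 0 < i_min < len(grid) - 1  # interior local minimum: metastable
        assert energies[i_min] > e_of_L(p.L_fold)


class TestBeadModel:
    def test_reference_pose_reproduces_closed_means(self, bead_model):
        pose = reference_pose("closed").reshape(-1)
        vals = bead_model.cv_values(pose)
        expect = [0.93, 1.91, 0.41, 66.4, 2.05]
        assert np.allclose(vals, expect, atol=1e-6)

    def test_total_force_sums_to_zero(self, bead_model, rng):
        pose = reference_pose("open").reshape(-1)
        x = pose + 0.01 * rng.standard_normal(pose.shape)
        force = -bead_model.gradient(x).reshape(-1, 3)
        assert np.allclose(force.sum(axis=0), 0.0, atol=1e-8)

    def test_energy_composes_bonds_plus_cv_potential(self, bead_model, model):
        """Along an interpolation of poses, energy minus the bonded part
        equals the CV-space potential evaluated at θ(x) independently."""
        a = reference_pose("closed").reshape(-1)
        b = reference_pose("open").reshape(-1)
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            x = (1 - lam) * a + lam * b
            theta = bead_model.cv_values(x)
            t = theta.copy()
            t[3] = math.radians(t[3])
            u_cv = model.energy(t)
            bonds = bead_model.energy(x) - u_cv
            assert bonds >= -1e-9  # harmonic bonds are non-negative
            assert bead_model.energy(x) == pytest.approx(bonds + u_cv)

    def test_gradient_matches_finite_differences(self, bead_model, rng):
        x = reference_pose("closed").reshape(-1) + 0.003 * rng.standard_normal(54)
        g = bead_model.gradient(x)
        h = 1e-6
        idx = rng.choice(len(x), size=12, replace=False)
        for i in idx:
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] -= h
            fd = (bead_model.energy(xp) - bead_model.energy(xm)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-4)

    def test_bad_topology_rejected(self):
        with pytest.raises(ConfigurationError):
            build_bead_model(topology=[(0, 99, 0.1, 100.0)])


class TestInitialCondition:
    def test_deterministic_per_seed(self, model):
        a = initial_condition(model, "closed", 11)
        b = initial_condition(model, "closed", 11)
        assert np.array_equal(a, b)
        c = initial_condition(model, "closed", 12)
        assert not np.array_equal(a, c)

    def test_zero_jitter_gives_exact_basin_centre(self, model):
        x = initial_condition(model, "open", 5, jitter_scale=0.0)
        assert x[0] == pytest.approx(OPEN_STATE.mean("d1"))
        assert math.degrees(x[3]) == pytest.approx(OPEN_STATE.mean("chi1"))
        assert x[4] == pytest.approx(model.params.L_fold)

    def test_sample_mean_near_basin_centre(self, model):
        draws = np.array([initial_condition(model, "closed", s)
                          for s in range(1000)])
        sd = np.array([CLOSED_STATE.sd("d1"), CLOSED_STATE.sd("d2"),
                       CLOSED_STATE.sd("d6"),
                       math.radians(CLOSED_STATE.sd("chi1")),
                       model.params.sigma_La3])
        centre = theta_of(CLOSED_STATE, model.params)
        se = 0.25 * sd / math.sqrt(1000)
        assert np.all(np.abs(draws.mean(axis=0) - centre) < 3 * se + 1e-12)

    def test_unknown_state_rejected(self, model):
        with pytest.raises(ValueError):
            initial_condition(model, "ajar", 1)
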