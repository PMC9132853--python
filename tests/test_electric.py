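"""Elliptic operator, coupled stepping and current densities vs oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from myofield import electric as el
from myofield import geometry as geo
from myofield import membrane as mb


def _setup(L=1.0, W=0.6, H=0.8, d_fat=0.0, h=0.2, depth=0.4):
    grid = geo.build_grid(L=L, W=W, H=H, d_fat=d_fat, spacing=h, air_padding=1.0)
    cond = geo.build_conductivities(grid, geo.uniform_fibres(grid))
    mus = geo.build_motor_unit_map(grid, depth, mu1_xt_par=W / 2 - 0.1, nmj_xl=L / 2)
    return grid, cond, mus


class TestEllipticOperator:
    def test_pure_neumann_row_sums_zero_before_pinning(self, tiny_model):
        grid, cond, mus = tiny_model
        op = el.assemble_elliptic_operator(grid, cond, mus, pin=False)
        rs = np.abs(op.matrix @ np.ones(op.matrix.shape[0]))
        assert rs.max() < 1e-9

    def test_symmetric_to_machine_precision(self, tiny_model):
        grid, cond, mus = tiny_model
        for pin in (False, True):
            m = el.assemble_elliptic_operator(grid, cond, mus, pin=pin).matrix
            assert abs(m - m.T).max() < 1e-12

    def test_reduces_to_two_conductor_cable_operator(self):
        """Fields constant across the section see the 1-D (σ_e+σ_i) D2 matrix."""
        grid, cond, mus = _setup()
        op = el.assemble_elliptic_operator(grid, cond, mus, pin=False)
        nx = grid.shape[0]
        h = grid.spacing[0]
        u = np.cos(np.linspace(0.0, 2.0, nx))
        u3 = np.repeat(u, grid.shape[1] * grid.shape[2]).reshape(grid.shape)
        got = (op.matrix @ u3.ravel()).reshape(grid.shape)
        # hand-assembled 1-D cable operator, zero-flux ends
        sig = 6.7 + 8.93
        d2 = sp.diags(
            [np.ones(nx - 1), np.r_[-1.0, -2.0 * np.ones(nx - 2), -1.0],
             np.ones(nx - 1)],
            [-1, 0, 1],
        ) * (sig / h**2)
        want = d2 @ u
        assert np.allclose(got, want[:, None, None], atol=1e-9 * abs(want).max())

    def test_grounded_node_pinned_to_zero(self, tiny_model):
        grid, cond, mus = tiny_model
        op = el.assemble_elliptic_operator(grid, cond, mus)
        lu = op.factorise()
        state = mb.MembraneState.resting(grid.muscle_shape)
        state.v_m[0][mus.territory(0)] += 40.0 * np.random.default_rng(0).random(
            mus.territory(0).sum()
        )
        phi = el.solve_extracellular(lu, op, state, mus, 8.93)
        assert phi.ravel()[op.ground_index] == 0.0


class TestSolveExtracellular:
    def test_uniform_vm_gives_zero_potential(self, tiny_model):
        grid, cond, mus = tiny_model
        op = el.assemble_elliptic_operator(grid, cond, mus)
        lu = op.factorise()
        state = mb.MembraneState.resting(grid.muscle_shape)
        phi = el.solve_extracellular(lu, op, state, mus, 8.93)
        assert np.abs(phi).max() == 0.0

    def test_opposite_sources_give_antisymmetric_potential(self):
        """Two equal-and-opposite V_m bumps mirror about the midplane."""
        grid, cond, mus = _setup(L=2.0, h=0.2)
        op = el.assemble_elliptic_operator(grid, cond, mus, pin=False)
        # unpinned solve via least squares on the compatible system
        state = mb.MembraneState.resting(grid.muscle_shape)
        iy, iz = mus.mu1_line
        nx = grid.shape[0]
        bump = np.exp(-0.5 * ((np.arange(nx) - 2.5) / 1.0) ** 2)
        state.v_m[0][:, iy, iz] += 30.0 * (bump - bump[::-1])
        rhs = el.membrane_source(state, mus, 8.93, grid).ravel()
        phi, *_ = np.linalg.lstsq(op.matrix.toarray(), rhs, rcond=None)
        phi = phi.reshape(grid.shape)
        phi -= phi.mean()
        assert np.allclose(phi, -phi[::-1], atol=1e-8 * np.abs(phi).max())

    def test_compact_source_matches_anisotropic_dipole_potential(self):
        """Far potential of a compact V_m profile vs the infinite-medium kernel.

        The elliptic problem is solved on a grid much larger than the source;
        distant nodes on the transverse mid-plane ring are compared against
        the closed-form convolution of the line-source density σ_i V_m''
        with the anisotropic point-source Green's function of the combined
        tensor σ = σ_e + σ_i (conductivity-rescaled 1/r kernel).  The free
        additive constant of the Neumann problem is matched on the ring.
        """
        h = 0.1
        grid = geo.build_grid(L=8.0, W=3.0, H=3.0, spacing=h, air_padding=1.0)
        cond = geo.build_conductivities(grid, geo.uniform_fibres(grid))
        mus = geo.build_motor_unit_map(grid, 1.5, mu1_xt_par=1.5, nmj_xl=4.0)
        op = el.assemble_elliptic_operator(grid, cond, mus)
        lu = op.factorise()
        state = mb.MembraneState.resting(grid.muscle_shape)
        iy, iz = mus.mu1_line
        x = grid.coords(0)
        vm_bump = 50.0 * np.exp(-0.5 * ((x - 4.0) / 0.30) ** 2)
        state.v_m[0][:, iy, iz] += vm_bump
        phi = el.solve_extracellular(lu, op, state, mus, 8.93)

        sig = np.array([6.7 + 8.93, 3.35, 3.35])
        det = np.prod(sig)
        d2v = np.zeros_like(vm_bump)
        d2v[1:-1] = (vm_bump[:-2] - 2 * vm_bump[1:-1] + vm_bump[2:]) / h**2
        src_lin = 8.93 * d2v * grid.spacing[1] * grid.spacing[2]  # per length

        yy, zz = np.meshgrid(grid.coords(1), grid.coords(2), indexing="ij")
        r_t = np.sqrt((yy - 1.5) ** 2 / sig[1] + (zz - 1.5) ** 2 / sig[2])
        ring = (r_t > 0.20) & (r_t < 0.35)  # distant in the scaled metric
        pts = np.stack([np.full(ring.sum(), 4.0), yy[ring], zz[ring]], axis=1)
        r = pts[:, None, :] - np.stack(
            [x, np.full_like(x, 1.5), np.full_like(x, 1.5)], axis=1
        )[None, :, :]
        q = np.sqrt(np.sum(r**2 / sig, axis=-1))
        want = (1.0 / (4.0 * np.pi * np.sqrt(det) * q)) @ src_lin * h
        got = phi[grid.snap(0, 4.0)][ring]
        got = got - (got.mean() - want.mean())
        assert np.max(np.abs(got - want) / np.abs(want)) < 0.05


class TestDiffusion:
    def test_uniform_field_unchanged(self):
        diff = el.FibreDiffusion.build(21, 0.1, 8.93, 1.0, 500.0, 0.1)
        v = np.full((21, 4), -75.0)
        phi = np.full((21, 4), 3.0)
        out = diff.step(v, phi)
        assert np.allclose(out, v, atol=1e-9)

    def test_neumann_conservation(self):
        diff = el.FibreDiffusion.build(31, 0.1, 8.93, 1.0, 500.0, 0.1)
        rng = np.random.default_rng(1)
        v = rng.normal(size=(31, 5))
        out = diff.step(v, np.zeros_like(v))
        assert np.allclose(out.sum(axis=0), v.sum(axis=0), atol=1e-9)

    def test_gaussian_matches_heat_kernel(self):
        """1-D diffusion of a Gaussian vs the closed-form solution after 1 ms.

        A Gaussian of variance s0² becomes one of variance s0² + 2 D t with
        D = σ_i_l/(C_m A_m) = 0.01786 cm²/ms.
        """
        h, dt, n = 0.02, 0.02, 301
        D = 8.93 / (1.0 * 500.0)
        diff = el.FibreDiffusion.build(n, h, 8.93, 1.0, 500.0, dt)
        x = (np.arange(n) - n // 2) * h
        s0 = 0.25
        v = np.exp(-0.5 * (x / s0) ** 2)[:, None]
        t = 0.0
        while t < 1.0 - 1e-12:
            v = diff.step(v, np.zeros_like(v))
            t += dt
        s1 = np.sqrt(s0**2 + 2 * D * t)
        want = (s0 / s1) * np.exp(-0.5 * (x / s1) ** 2)
        err = np.max(np.abs(v[:, 0] - want)) / want.max()
        assert err < 0.01


class TestCurrentDensities:
    def test_linear_potential_constant_current(self, tiny_model):
        grid, cond, mus = tiny_model
        state = mb.MembraneState.resting(grid.muscle_shape)
        phi = 2.0 * grid.coords(0)[:, None, None] * np.ones(grid.shape)
        cur = el.current_densities(phi, state, grid, cond)
        assert np.allclose(cur.j_e[..., 0], -6.7 * 2.0)
        assert np.allclose(cur.j_e[..., 1:], 0.0)

    def test_intracellular_currents_have_no_transverse_component(self, tiny_model):
        grid, cond, mus = tiny_model
        state = mb.MembraneState.resting(grid.muscle_shape)
        rng = np.random.default_rng(2)
        state.v_m += rng.normal(size=state.v_m.shape)
        phi = rng.normal(size=grid.shape)
        cur = el.current_densities(phi, state, grid, cond)
        assert np.abs(cur.j_i[..., 1:]).max() == 0.0

    def test_total_current_solenoidal_under_refinement(self):
        """div(j_e + Σ f_r j_i) → 0 in the muscle interior as h → 0."""
        residuals = []
        for h in (0.2, 0.1):
            grid, cond, mus = _setup(L=2.0, W=0.8, H=0.8, h=h, depth=0.4)
            model = el.MultiDomainModel(
                grid, cond, mus, stimulus=mb.StimulusProtocol(onset=0.5)
            )
            for _ in range(int(4.0 / model.dt_pde)):
                phi = model.step()
            cur = model.currents(phi)
            j = cur.j_e + np.sum(mus.f_r[..., None] * cur.j_i, axis=0)
            div = sum(
                np.gradient(j[..., a], grid.spacing[a], axis=a) for a in range(3)
            )
            interior = (slice(2, -2),) * 3
            scale = max(np.abs(j).max(), 1e-12) / h
            residuals.append(np.abs(div[interior]).max() / scale)
        assert residuals[1] < residuals[0]


class TestCoupledStepping:
    def test_resting_run_stays_identically_silent(self, tiny_model):
        grid, cond, mus = tiny_model
        model = el.MultiDomainModel(grid, cond, mus, stimulus=None)
        for _ in range(30):
            phi = model.step()
            # silent to solver roundoff (signals are O(0.1 mV))
            assert np.abs(phi).max() < 1e-10

    def test_restart_from_snapshot_is_bit_identical(self, tiny_model):
        grid, cond, mus = tiny_model
        stim = mb.StimulusProtocol(onset=0.3)
        m1 = el.MultiDomainModel(grid, cond, mus, stimulus=stim)
        for _ in range(10):
            m1.step()
        snap = m1.state.copy()
        a = [m1.step() for _ in range(10)]
        m2 = el.MultiDomainModel(grid, cond, mus, stimulus=stim)
        m2.state = snap
        b = [m2.step() for _ in range(10)]
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_temporal_self_convergence_of_surface_rms(self):
        """Halving both time steps changes the surface-EMG RMS by < 2 %."""
        grid, cond, mus = _setup(L=2.0, W=0.8, H=0.8, h=0.1, depth=0.4)
        node = (grid.shape[0] // 2 + 3, grid.shape[1] // 2, grid.surface_index)
        out = []
        for dt_pde, dt_ode in ((0.1, 0.01), (0.05, 0.005)):
            model = el.MultiDomainModel(
                grid, cond, mus, stimulus=mb.StimulusProtocol(onset=0.5),
                dt_pde=dt_pde, dt_ode=dt_ode,
            )
            every = int(round(0.1 / dt_pde))
            vals = []
            for i in range(int(round(12.0 / dt_pde))):
                phi = model.step()
                if (i + 1) % every == 0:
                    vals.append(phi[node])
            out.append(np.sqrt(np.mean(np.square(vals))))
        assert abs(out[1] - out[0]) / out[0] < 0.02

    def test_grounding_location_shifts_potential_by_constant(self, tiny_model):
        """EMG differences between nodes are gauge invariant."""
        grid, cond, mus = tiny_model
        state = mb.MembraneState.resting(grid.muscle_shape)
        iy, iz = mus.mu1_line
        state.v_m[0][1:3, iy, iz] += 25.0
        phis = []
        for ground in (0, 17):
            op = el.assemble_elliptic_operator(grid, cond, mus, pin=False)
            m = op.matrix.tolil()
            m[ground, :] = 0.0
            m[:, ground] = 0.0
            m[ground, ground] = 1.0
            op2 = el.EllipticOperator(m.tocsc(), grid, ground)
            phis.append(
                el.solve_extracellular(op2.factorise(), op2, state, mus, 8.93)
            )
        diff = phis[0] - phis[1]
        assert np.ptp(diff) < 1e-8 * max(np.ptp(phis[0]), 1e-12)
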