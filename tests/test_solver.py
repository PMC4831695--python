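"""Stepping schemes, regridding and the simulation driver."""

import numpy as np
import pytest

from uparsim import model_core as mc
from uparsim.cli_io import make_fixture
from uparsim.mesh import MovingMesh
from uparsim.model_core import StateFields, initial_state
from uparsim.observables import total_mass
from uparsim.solver import (
    BlowUpError,
    SolverOptions,
    StabilityError,
    regrid,
    simulate,
    step_explicit,
    step_implicit_split,
)


def mild_params(params):
    """Baseline with slow diffusion and softened MMP/TIMP binding so the
    explicit scheme is affordable on a test-sized mesh."""
    slow = {k: 1e-6 for k in (
        "D_T", "D_V", "D_P", "D_uP", "D_PA", "D_q", "D_p", "D_w", "D_Q", "D_Qr"
    )}
    return params.replace(d_QQr=1e3, d_QrQ=1e3, **slow)


FROZEN = SolverOptions(
    enable_reactions=False,
    enable_diffusion=False,
    enable_advection=False,
    enable_chemotaxis=False,
    enable_robin=False,
)


class TestStepExplicit:
    def test_everything_off_is_identity(self, params, bump_fixture):
        mesh, state = bump_fixture
        new, mesh_new = step_explicit(state, mesh, 0.1, params, FROZEN)
        assert np.array_equal(new.data, state.data)
        assert mesh_new is mesh

    def test_pure_decay_closed_form(self, params):
        # with C = 0 the M-CSF equation is pure decay: X = X0 (1 - d tau)^n
        mesh = MovingMesh.uniform(10, 0.01)
        state = StateFields.zeros(10)
        state["q"] = 1e-6
        opts = FROZEN.replace(enable_reactions=True)
        tau, n = 0.01, 20
        for _ in range(n):
            state, mesh = step_explicit(state, mesh, tau, params, opts)
        expected = 1e-6 * (1 - params.d_q * tau) ** n
        assert np.allclose(state["q"], expected, rtol=1e-12)

    def test_stability_guard(self, params):
        mesh = MovingMesh.uniform(64, 0.01)
        state = initial_state(mesh, params)
        with pytest.raises(StabilityError, match="stability"):
            step_explicit(state, mesh, 0.01, params, SolverOptions())

    def test_diffusion_mass_conservation(self, params, bump_fixture):
        # single diffusing species on a fixed no-flux sphere
        mesh, state = bump_fixture
        opts = FROZEN.replace(enable_diffusion=True)
        p = mild_params(params)
        m0 = total_mass(state["w"], mesh)
        tau = 1e-3
        for _ in range(500):
            state, mesh = step_explicit(state, mesh, tau, p, opts)
        m1 = total_mass(state["w"], mesh)
        assert m1 == pytest.approx(m0, rel=5e-3)


class TestStepImplicitSplit:
    def test_cross_scheme_agreement(self, params):
        # tiny instance, same small step: trajectories within 1% per field
        p = mild_params(params)
        mesh = MovingMesh.uniform(20, 0.01)
        state = initial_state(mesh, p)
        opts = SolverOptions(regrid_every=0)
        se, me = state.copy(), mesh
        si, mi = state.copy(), mesh
        for _ in range(2500):  # 0.25 day at tau = 1e-4
            se, me = step_explicit(se, me, 1e-4, p, opts)
            si, mi = step_implicit_split(si, mi, 1e-4, p, opts)
        assert me.R == pytest.approx(mi.R, rel=1e-3)
        for i, name in enumerate(mc.FIELD_NAMES):
            scale = max(np.abs(si.data[i]).max(), 1e-30)
            assert np.abs(se.data[i] - si.data[i]).max() / scale < 0.01, name

    def test_bump_diffuses_to_uniform(self, params):
        # maximum principle: the peak decays monotonically toward the mean
        mesh, state = make_fixture("bump", 32, seed=5)
        opts = FROZEN.replace(enable_diffusion=True)
        peaks = [state["w"].max()]
        for _ in range(200):
            state, mesh = step_implicit_split(state, mesh, 0.01, params, opts)
            peaks.append(state["w"].max())
        assert np.all(np.diff(peaks) <= 1e-9 * peaks[0])
        assert np.ptp(state["w"]) < 1e-6  # essentially uniform

    def test_no_diffusion_matches_explicit_reactions(self, params):
        # Patankar and explicit Euler agree to O(tau) on the reaction flow
        mesh = MovingMesh.uniform(8, 0.01)
        state = initial_state(mesh, params)
        opts = FROZEN.replace(enable_reactions=True)
        se, si = state.copy(), state.copy()
        tau = 1e-5
        for _ in range(100):
            se, _ = step_explicit(se, mesh, tau, params, opts)
            si, _ = step_implicit_split(si, mesh, tau, params, opts)
        assert np.allclose(se.data, si.data, rtol=1e-3, atol=1e-18)

    def test_positivity_preserved_at_large_step(self, params):
        # the stiff TIMP depletion would wreck explicit Euler at this step
        mesh = MovingMesh.uniform(16, 0.01)
        state = initial_state(mesh, params)
        opts = SolverOptions(clamp_negative=False)
        for _ in range(100):
            state, mesh = step_implicit_split(state, mesh, 0.05, params, opts)
        assert np.all(state.data >= 0)
        assert np.all(np.isfinite(state.data))


class TestConvergence:
    def test_first_order_in_tau(self, params):
        # halving tau roughly halves the deviation from a fine reference
        p = mild_params(params)
        opts = SolverOptions(n_nodes=16, regrid_every=0, output_every=1.0)

        def run(tau):
            return simulate(0.01, p, opts.replace(tau=tau, t_end=1.0)).fields[-1]

        ref = run(0.00125)
        err = []
        for tau in (0.01, 0.005, 0.0025):
            err.append(np.abs(run(tau) - ref).max())
        order = np.log2(err[0] / err[2]) / 2.0
        assert order > 0.8, (err, order)


class TestRegrid:
    def test_same_node_count_near_identity(self, bump_fixture):
        mesh, state = bump_fixture
        new_state, new_mesh = regrid(state, mesh, mesh.n_nodes)
        assert np.allclose(new_mesh.r, mesh.r)
        assert np.allclose(new_state.data, state.data, rtol=1e-10, atol=1e-14)

    def test_uniform_field_any_resolution(self, params):
        mesh, state = make_fixture("uniform", 20, seed=2)
        for n in (8, 33, 64):
            new_state, new_mesh = regrid(state, mesh, n)
            for i in range(17):
                assert np.allclose(new_state.data[i], state.data[i][0])

    def test_mass_conservation(self, bump_fixture):
        mesh, state = bump_fixture
        new_state, new_mesh = regrid(state, mesh, 97)
        for i in range(17):
            m0 = total_mass(state.data[i], mesh)
            m1 = total_mass(new_state.data[i], new_mesh)
            assert m1 == pytest.approx(m0, rel=5e-3)

    def test_minimum_nodes(self, bump_fixture):
        mesh, state = bump_fixture
        with pytest.raises(ValueError):
            regrid(state, mesh, 4)


class TestSimulate:
    def test_zero_end_time_returns_initial(self, params):
        traj = simulate(0.01, params, SolverOptions(t_end=0.0, n_nodes=16))
        assert traj.times.shape == (1,)
        assert traj.R[0] == pytest.approx(0.01)
        mesh = MovingMesh.uniform(16, 0.01)
        assert np.array_equal(traj.fields[0], initial_state(mesh, params).data)

    def test_invalid_radius(self, params):
        with pytest.raises(ValueError):
            simulate(-1.0, params)

    def test_determinism_bit_identical(self, params):
        opts = SolverOptions(n_nodes=16, tau=0.05, t_end=5.0, output_every=1.0)
        a = simulate(0.01, params, opts)
        b = simulate(0.01, params, opts)
        assert np.array_equal(a.fields, b.fields)
        assert np.array_equal(a.radii, b.radii)

    def test_blowup_detection(self, params):
        # an absurd basal plasmin source pushes P past the threshold fast
        bad = params.replace(lam_P=1e7)
        opts = SolverOptions(n_nodes=12, tau=0.05, t_end=20.0, output_every=1.0)
        with pytest.raises(BlowUpError) as err:
            simulate(0.01, bad, opts)
        assert err.value.trajectory is not None
        assert err.value.trajectory.times.size >= 1

    def test_clamp_counts_recorded(self, params):
        opts = SolverOptions(n_nodes=16, tau=0.05, t_end=5.0, output_every=1.0)
        traj = simulate(0.01, params, opts)
        assert traj.clamp_counts.shape == traj.times.shape
        assert np.all(traj.clamp_counts >= 0)

    def test_literal_advection_flag_changes_result(self, params):
        opts = SolverOptions(n_nodes=16, tau=0.05, t_end=5.0, output_every=5.0)
        a = simulate(0.01, params, opts)
        b = simulate(0.01, params, opts.replace(literal_advection=True))
        assert not np.allclose(a.fields[-1], b.fields[-1])
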