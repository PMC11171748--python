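"""Chain construction, bonded forces and the BD integrator."""

import numpy as np
import pytest

from nanoduplex.bd import BDConfig, ChunkRunner, bd_step, noise_stream
from nanoduplex.chain import (build_chain, chain_energy, internal_forces,
                              wlc_end_to_end_sq, wlc_positions)
from nanoduplex.theory import a_like, b_form

KT = 4.0177


class TestBuildChain:
    def test_dd_mapping_at_5bp(self, dd_spec):
        st = build_chain(dd_spec, 3621, 5)
        assert st.n_beads == 725
        assert st.rest_length_nm[0] == pytest.approx(1.7)
        assert st.k_stretch_pN_nm[0] == pytest.approx(1000 / 1.7)
        assert st.k_bend_pN_nm[0] == pytest.approx(50 * KT / 1.7, rel=1e-3)

    def test_rd_uses_cg_rise(self, rd_spec):
        st = build_chain(rd_spec, 720, 5)
        assert st.rest_length_nm[0] == pytest.approx(0.277 * 5)

    def test_contour_conserved(self, dd_spec):
        st = build_chain(dd_spec, 3621, 5)
        assert st.contour_nm == pytest.approx(3621 * 0.34, rel=2e-3)

    def test_total_charge_conserved(self, dd_spec):
        for n_bp in (720, 723):
            st = build_chain(dd_spec, n_bp, 5)
            assert st.charge_e.sum() == pytest.approx(-2.0 * n_bp)

    def test_bad_resolution_rejected(self, dd_spec):
        with pytest.raises(ValueError):
            build_chain(dd_spec, 100, 0)
        with pytest.raises(ValueError):
            build_chain(dd_spec, 5, 5)


class TestInternalForces:
    def test_straight_rest_chain_has_zero_force(self, dd_spec):
        st = build_chain(dd_spec, 200, 5)
        assert np.allclose(internal_forces(st), 0.0, atol=1e-10)

    def test_newtons_third_law(self, dd_spec):
        st = build_chain(dd_spec, 200, 5)
        rng = np.random.default_rng(1)
        x = st.positions_nm + rng.normal(0, 0.4, st.positions_nm.shape)
        F = internal_forces(st, x)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-9)

    def test_matches_numerical_gradient(self, dd_spec):
        st = build_chain(dd_spec, 100, 5)
        rng = np.random.default_rng(2)
        x = st.positions_nm + rng.normal(0, 0.4, st.positions_nm.shape)
        F = internal_forces(st, x)
        eps = 1e-6
        fd = np.zeros_like(F)
        for i in range(x.shape[0]):
            for k in range(3):
                xp = x.copy(); xp[i, k] += eps
                xm = x.copy(); xm[i, k] -= eps
                fd[i, k] = -(chain_energy(st, xp) - chain_energy(st, xm)) \
                    / (2 * eps)
        assert np.max(np.abs(F - fd)) / np.max(np.abs(F)) < 1e-4

    def test_coincident_beads_rejected(self, dd_spec):
        st = build_chain(dd_spec, 100, 5)
        x = st.positions_nm.copy()
        x[3] = x[2]
        with pytest.raises(FloatingPointError):
            internal_forces(st, x)


class TestBDStep:
    def test_free_bead_diffusion(self, dd_spec):
        st = build_chain(dd_spec, 10, 5)
        zero = lambda x: np.zeros_like(x)
        rng = noise_stream(1)
        dt = 0.01
        disp2 = []
        s = st
        for _ in range(3000):
            s2 = bd_step(s, zero, dt, rng, KT)
            disp2.append(np.sum((s2.positions_nm - s.positions_nm) ** 2,
                                axis=1))
            s = s2
        msd = np.mean(disp2)
        D = st.diffusivity_nm2_ns[0]
        assert msd == pytest.approx(6 * D * dt, rel=0.05)

    def test_constant_force_drift(self, dd_spec):
        st = build_chain(dd_spec, 10, 5)
        F0 = 20.0
        field = lambda x: np.tile([0.0, 0.0, F0], (x.shape[0], 1))
        rng = noise_stream(2)
        dt = 0.01
        n = 4000
        s = st.copy()
        runner_start = s.positions_nm[:, 2].mean()
        for _ in range(n):
            s = bd_step(s, field, dt, rng, KT)
        drift = s.positions_nm[:, 2].mean() - runner_start
        D = st.diffusivity_nm2_ns[0]
        expect = D * F0 * dt * n / KT
        assert drift == pytest.approx(expect, rel=0.1)

    def test_seed_determinism(self, dd_spec):
        st = build_chain(dd_spec, 50, 5)
        zero = lambda x: np.zeros_like(x)
        out = []
        for seed in (7, 7, 8):
            s = st.copy()
            rng = noise_stream(seed)
            for _ in range(50):
                s = bd_step(s, zero, 0.01, rng, KT)
            out.append(s.positions_nm.copy())
        assert np.array_equal(out[0], out[1])
        assert not np.array_equal(out[0], out[2])

    def test_nonfinite_force_reported_with_bead(self, dd_spec):
        st = build_chain(dd_spec, 30, 5)
        bad = lambda x: np.where(
            (np.arange(x.shape[0]) == 3)[:, None], np.nan, 0.0)
        with pytest.raises(FloatingPointError, match="bead 3"):
            bd_step(st, bad, 0.01, noise_stream(1), KT)


class TestKernelEnsembles:
    def test_bond_length_boltzmann(self, dd_spec):
        """Free-chain bond lengths follow the harmonic Boltzmann law."""
        from scipy import stats
        st = build_chain(dd_spec, 150, 5)   # 30 beads
        cfg = BDConfig(seed=4, timestep_fs=100.0, excluded_volume=False)
        runner = ChunkRunner(st, cfg)
        runner.run(20000)  # equilibrate
        samples = []
        for _ in range(80):
            runner.run(500)
            b = np.diff(runner.pos, axis=0)
            samples.append(np.linalg.norm(b, axis=1))
        samples = np.concatenate(samples)
        sd = np.sqrt(KT / st.k_stretch_pN_nm[0])
        l0 = st.rest_length_nm[0]
        # exact 3-D Boltzmann bond density p(b) ~ b^2 exp(-k(b-l0)^2/2kT)
        grid = np.linspace(l0 - 6 * sd, l0 + 6 * sd, 4001)
        pdf = grid ** 2 * np.exp(-0.5 * ((grid - l0) / sd) ** 2)
        cdf = np.cumsum(pdf)
        cdf /= cdf[-1]
        p = stats.kstest(samples[::3],
                         lambda v: np.interp(v, grid, cdf)).pvalue
        assert p > 0.01

    def test_com_diffusion_scales_inverse_n(self, dd_spec):
        """Free-draining contract: D_com = D_bead / N."""
        results = {}
        for n_bp in (50, 200):
            st = build_chain(dd_spec, n_bp, 5,
                             friction_per_length_pN_ns_nm2=1.2)
            cfg = BDConfig(seed=5, timestep_fs=500.0, excluded_volume=False)
            runner = ChunkRunner(st, cfg)
            coms = []
            for _ in range(300):
                runner.run(100)
                coms.append(runner.pos.mean(axis=0))
            coms = np.array(coms)
            dt_block = 100 * cfg.dt_ns
            msd = np.mean(np.sum(np.diff(coms, axis=0) ** 2, axis=1))
            results[st.n_beads] = msd / (6 * dt_block)
        n1, n2 = sorted(results)
        assert results[n1] / results[n2] == pytest.approx(n2 / n1, rel=0.25)

    def test_kernel_matches_reference_drift(self, dd_spec):
        """Chunked kernel and bd_step agree on deterministic dynamics.

        With noise scaled to zero both integrators are deterministic and
        must produce the same relaxation of a stretched chain.
        """
        st = build_chain(dd_spec, 60, 5)
        stretched = st.copy()
        stretched.positions_nm[:, 2] *= 1.2
        cfg = BDConfig(seed=1, timestep_fs=200.0, excluded_volume=False)
        runner = ChunkRunner(stretched, cfg)
        runner.sig[:] = 0.0
        runner.run(500)
        s = stretched.copy()
        rng = noise_stream(1)
        for _ in range(500):
            F = internal_forces(s)
            s.positions_nm = s.positions_nm + \
                (s.diffusivity_nm2_ns[:, None] / cfg.kT) * F * cfg.dt_ns
        assert np.allclose(runner.pos, s.positions_nm, atol=1e-8)


class TestWLC:
    def test_end_to_end_matches_closed_form(self):
        rng = np.random.default_rng(11)
        l0, lp, n = 1.7, 50.0, 145
        r2 = [np.sum((wlc_positions(n, l0, lp, rng)[-1]
                      - np.zeros(3)) ** 2) for _ in range(400)]
        expect = wlc_end_to_end_sq((n - 1) * l0, lp)
        assert np.mean(r2) == pytest.approx(expect, rel=0.1)

    def test_rigid_limit(self):
        rng = np.random.default_rng(1)
        pos = wlc_positions(50, 1.7, 1e9, rng)
        ee = np.linalg.norm(pos[-1] - pos[0])
        assert ee == pytest.approx(49 * 1.7, rel=1e-6)
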