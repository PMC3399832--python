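import numpy as np
import pytest

import loopdyn as ld
from loopdyn.cg_ensembles import (
    BDParameters, CGParameters, DMDParameters, ElasticNetwork,
    _pair_event_time, anm_hessian,
)
from loopdyn.synthetic_data import make_chain
from loopdyn.units import kbt_dyn, kbt_kcal
from conftest import two_bead_network


class TestKovacs:
    def test_reference_distance_gives_stiffness(self):
        assert ld.kovacs_force_constant(3.8) == pytest.approx(40.0)

    def test_doubling_distance_scales_by_64(self):
        assert ld.kovacs_force_constant(7.6) == pytest.approx(40.0 / 64.0)

    def test_strictly_decreasing_to_zero(self):
        r = np.linspace(2.0, 60.0, 200)
        k = ld.kovacs_force_constant(r)
        assert np.all(np.diff(k) < 0)
        assert k[-1] < 1e-4

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            ld.kovacs_force_constant(0.0)


class TestBuildNetwork:
    def test_consecutive_pair_at_native_distance_has_k40(self, chain5):
        net = ld.build_network(chain5)
        consec = (net.pairs[:, 1] - net.pairs[:, 0]) == 1
        np.testing.assert_allclose(net.k[consec], 40.0, rtol=1e-12)
        # no cutoff: all pairs present for NMA/BD
        assert len(net.pairs) == 5 * 4 // 2

    def test_dmd_cutoff_excludes_distant_pairs(self):
        chain = make_chain(10, "extended")
        net = ld.build_network(chain, method="dmd",
                               dmd_params=DMDParameters(cutoff=8.0))
        assert np.all(net.r0 < 8.0)
        coords = chain.ca_coords()
        for i in range(10):
            for j in range(i + 1, 10):
                d = np.linalg.norm(coords[i] - coords[j])
                in_list = any((a, b) == (i, j) for a, b in net.pairs)
                assert in_list == (d < 8.0)
        consec = (net.pairs[:, 1] - net.pairs[:, 0]) == 1
        assert np.all(net.sigma[consec] == 0.05)
        assert np.all(net.sigma[~consec] == 0.1)

    def test_connectivity_symmetric_zero_rowsum(self, chain5):
        g = ld.build_network(chain5).connectivity()
        np.testing.assert_allclose(g, g.T)
        np.testing.assert_allclose(g.sum(axis=1), 0.0, atol=1e-12)

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            ld.build_network(make_chain(2, "extended"))


class TestANM:
    def test_two_bead_spring_single_mode_2k(self):
        net = two_bead_network(d=3.8, k=40.0)
        H = anm_hessian(net)
        evals, evecs = np.linalg.eigh(H)
        nonzero = evals[np.abs(evals) > 1e-9]
        assert len(nonzero) == 1
        assert nonzero[0] == pytest.approx(2 * 40.0)
        mode = evecs[:, -1].reshape(2, 3)
        # eigenvector along the bond (x axis), antisymmetric
        np.testing.assert_allclose(np.abs(mode[:, 0]), 1 / np.sqrt(2), atol=1e-9)
        np.testing.assert_allclose(mode[:, 1:], 0.0, atol=1e-9)

    def test_connected_network_has_exactly_six_rigid_modes(self, chain5, helix5):
        for st in (chain5, helix5):
            modes = ld.anm_modes(ld.build_network(st))
            assert modes.n_rigid_discarded == 6

    def test_hessian_matches_central_difference_oracle(self, chain5):
        net = ld.build_network(chain5)
        H = anm_hessian(net)

        def potential(flat):
            c = flat.reshape(-1, 3)
            e = 0.0
            for (i, j), r0, k in zip(net.pairs, net.r0, net.k):
                e += 0.5 * k * (np.linalg.norm(c[j] - c[i]) - r0) ** 2
            return e

        x0 = net.coords.ravel()
        h = 1e-5
        n = len(x0)
        fd = np.zeros((n, n))
        for a in range(n):
            for b in range(a, n):
                def shifted(da, db):
                    x = x0.copy()
                    x[a] += da
                    x[b] += db
                    return potential(x)
                fd[a, b] = fd[b, a] = (
                    shifted(h, h) - shifted(h, -h)
                    - shifted(-h, h) + shifted(-h, -h)
                ) / (4 * h * h)
        assert np.abs(H - fd).max() < 1e-5

    def test_eigenvectors_orthonormal(self, helix5):
        modes = ld.anm_modes(ld.build_network(helix5))
        gram = modes.eigenvectors.T @ modes.eigenvectors
        np.testing.assert_allclose(gram, np.eye(modes.n_modes), atol=1e-8)


class TestNMAEnsemble:
    def test_sampled_covariance_matches_pseudoinverse(self, chain5):
        modes = ld.anm_modes(ld.build_network(chain5))
        ens = ld.nma_ensemble(modes, n_frames=20_000, seed=11)
        X = ens.frames.reshape(ens.n_frames, -1)
        X = X - X.mean(axis=0)
        cov = X.T @ X / len(X)
        ref = modes.covariance(300.0)
        rel = np.linalg.norm(cov - ref) / np.linalg.norm(ref)
        assert rel < 0.05

    def test_zero_temperature_freezes_structure(self, chain5):
        modes = ld.anm_modes(ld.build_network(chain5))
        ens = ld.nma_ensemble(modes, CGParameters(temperature=0.0),
                              n_frames=5, seed=0)
        expected = np.repeat(modes.coords[None], 5, axis=0)
        np.testing.assert_allclose(ens.frames, expected, atol=1e-12)

    def test_fixed_seed_bit_identical(self, chain5):
        modes = ld.anm_modes(ld.build_network(chain5))
        a = ld.nma_ensemble(modes, n_frames=50, seed=42)
        b = ld.nma_ensemble(modes, n_frames=50, seed=42)
        assert np.array_equal(a.frames, b.frames)

    def test_too_few_frames_rejected(self, chain5):
        modes = ld.anm_modes(ld.build_network(chain5))
        with pytest.raises(ValueError):
            ld.nma_ensemble(modes, n_frames=1)


class TestBrownianDynamics:
    def test_free_diffusion_msd_rate(self):
        # single bead, no springs: MSD(t) = 6 D t with D = kT/(m gamma)
        net = ElasticNetwork(np.zeros((1, 3)), np.empty((0, 2), dtype=int),
                             np.empty(0), np.empty(0))
        gamma = 10.0
        cg = CGParameters()
        params = BDParameters(friction=gamma, n_steps=400_000,
                              snapshot_stride=250, seed=5)
        ens = ld.bd_simulate(net, params, cg)
        x = ens.frames[:, 0, :]
        lag = 10  # 2.5 ps, well beyond the 0.1 ps velocity correlation time
        disp = x[lag:] - x[:-lag]
        msd = (disp**2).sum(axis=1).mean()
        dt_frame = params.time_step * 1e-3 * params.snapshot_stride
        D_expected = kbt_dyn(cg.temperature) / (cg.mass * gamma)
        assert msd == pytest.approx(6 * D_expected * lag * dt_frame, rel=0.10)

    def test_two_bead_equipartition(self):
        net = two_bead_network(d=3.8, k=40.0)
        cg = CGParameters()
        ens = ld.bd_simulate(
            net, BDParameters(friction=2.0, n_steps=400_000,
                              snapshot_stride=20, seed=3), cg)
        dist = np.linalg.norm(ens.frames[:, 1] - ens.frames[:, 0], axis=1)
        var = dist[len(dist) // 10:].var()
        assert var == pytest.approx(kbt_kcal(300.0) / 40.0, rel=0.10)

    def test_covariance_matches_anm_in_linear_regime(self, helix5):
        # compact geometry + T = 100 K keeps fluctuations harmonic
        net = ld.build_network(helix5)
        cg = CGParameters(temperature=100.0)
        ens = ld.bd_simulate(
            net, BDParameters(friction=2.0, n_steps=1_200_000,
                              snapshot_stride=40, seed=2), cg)
        ref = ld.anm_modes(net).covariance(100.0)
        frames = ens.ca_frames()[ens.n_frames // 10:].copy()
        for f in range(len(frames)):
            frames[f], _ = ld.superpose(frames[f], net.coords)
        X = frames.reshape(len(frames), -1)
        X = X - X.mean(axis=0)
        cov = X.T @ X / len(X)
        rel = np.linalg.norm(cov - ref) / np.linalg.norm(ref)
        assert rel < 0.10

    def test_unstable_timestep_raises(self, helix5):
        net = ld.build_network(helix5)
        with pytest.raises(RuntimeError, match="dt"):
            ld.bd_simulate(net, BDParameters(time_step=500.0, n_steps=5000,
                                             snapshot_stride=100, seed=0))


class TestDMD:
    def test_two_body_bounce_times_match_ballistic_closed_form(self):
        # head-on approach: hits inner wall, reflects, hits outer wall, ...
        r0, sig, speed = 5.0, 0.1, 2.0
        net = ElasticNetwork(
            np.array([[0.0, 0, 0], [r0, 0, 0]]), np.array([[0, 1]]),
            np.array([r0]), np.array([1.0]), sigma=np.array([sig]),
            method="dmd")
        v = np.array([[speed / 2, 0, 0], [-speed / 2, 0, 0]])
        ens = ld.dmd_simulate(
            net, DMDParameters(total_time=3.0, frame_interval=0.01, seed=0),
            velocities=v)
        d = np.linalg.norm(ens.frames[:, 1] - ens.frames[:, 0], axis=1)
        t = np.arange(ens.n_frames) * 0.01
        r_in, r_out = 4.5, 5.5
        # analytic triangle wave: starts at 5.0 moving inward at |w| = 2,
        # i.e. 0.25 time units into the descending half-period
        period = 2 * (r_out - r_in) / speed
        phase = (t + (r_out - r0) / speed) % period
        expected = np.where(phase < period / 2,
                            r_out - speed * phase,
                            r_in + speed * (phase - period / 2))
        np.testing.assert_allclose(d, expected, atol=1e-9)

    def test_momentum_and_energy_conserved_across_events(self):
        chain = make_chain(6, "helix")
        net = ld.build_network(chain, method="dmd")
        _, diag = ld.dmd_simulate(
            net, DMDParameters(total_time=20.0, frame_interval=0.1, seed=9),
            return_diagnostics=True)
        assert diag["n_events"] > 100
        assert diag["momentum_drift"] < 1e-10 * diag["kinetic_energy"] ** 0.5
        assert diag["energy_drift"] < 1e-8 * diag["kinetic_energy"]

    def test_pair_distances_never_violate_walls(self):
        chain = make_chain(6, "helix")
        net = ld.build_network(chain, method="dmd")
        ens = ld.dmd_simulate(
            net, DMDParameters(total_time=20.0, frame_interval=0.05, seed=1))
        assert ld.dmd_wall_violation(ens, net) <= 1e-6

    def test_event_solver_inner_and_outer(self):
        t, wall = _pair_event_time(np.array([5.0, 0, 0]),
                                   np.array([-1.0, 0, 0]), 4.5, 5.5)
        assert wall == -1 and t == pytest.approx(0.5, abs=1e-12)
        t, wall = _pair_event_time(np.array([5.0, 0, 0]),
                                   np.array([1.0, 0, 0]), 4.5, 5.5)
        assert wall == +1 and t == pytest.approx(0.5, abs=1e-12)


def test_all_three_samplers_yield_interchangeable_ensembles(helix5):
    net_h = ld.build_network(helix5)
    modes = ld.anm_modes(net_h)
    nma = ld.nma_ensemble(modes, n_frames=300, seed=0)
    bd = ld.bd_simulate(net_h, BDParameters(n_steps=3000, snapshot_stride=10,
                                            seed=0))
    dmd_net = ld.build_network(helix5, method="dmd")
    dmd = ld.dmd_simulate(dmd_net, DMDParameters(total_time=5.0,
                                                 frame_interval=0.05, seed=0))
    for ens in (nma, bd, dmd):
        prof = ld.rmsf_profile(ens, filter_fraction=1.0)
        assert len(prof) == 5
        assert np.all(prof.rmsf >= 0)
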