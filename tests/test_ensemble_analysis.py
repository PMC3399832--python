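import numpy as np
import pytest

import loopdyn as ld
from loopdyn.structure_io import Ensemble
from loopdyn.synthetic_data import (
    make_chain, make_planted_covariance_ensemble,
)


def _jitter_ensemble(n_res=20, n_frames=5000, std=0.3, seed=0):
    base = make_chain(n_res, "extended")
    rng = np.random.default_rng(seed)
    frames = base.ca_coords()[None] + rng.normal(
        scale=std, size=(n_frames, n_res, 3))
    return Ensemble(base, frames, provenance="external")


class TestRMSF:
    def test_rigid_ensemble_has_zero_rmsf(self):
        base = make_chain(8, "extended")
        frames = np.repeat(base.ca_coords()[None], 4, axis=0)
        ens = Ensemble(base, frames)
        prof = ld.rmsf_profile(ens, filter_fraction=1.0)
        np.testing.assert_allclose(prof.rmsf, 0.0, atol=1e-12)

    def test_isotropic_jitter_rmsf_is_std_sqrt3(self):
        ens = _jitter_ensemble(std=0.3, n_frames=5000)
        prof = ld.rmsf_profile(ens, fit=False, filter_fraction=1.0)
        np.testing.assert_allclose(prof.rmsf, 0.3 * np.sqrt(3), rtol=0.05)

    def test_full_filter_fraction_equals_unfiltered(self):
        ens = _jitter_ensemble(n_frames=200, seed=3)
        full = ld.rmsf_profile(ens, fit=False, filter_fraction=1.0)
        ca = ens.ca_frames()
        dev = ca - ca.mean(axis=0)
        direct = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
        np.testing.assert_allclose(full.rmsf, direct, rtol=1e-12)

    def test_bfactor_consistency(self):
        ens = _jitter_ensemble(n_frames=100, seed=1)
        prof = ld.rmsf_profile(ens, filter_fraction=1.0)
        np.testing.assert_allclose(
            prof.bfactor, (8 * np.pi**2 / 3) * prof.rmsf**2, rtol=1e-12)

    def test_bad_filter_fraction_rejected(self):
        ens = _jitter_ensemble(n_frames=10)
        with pytest.raises(ValueError):
            ld.rmsf_profile(ens, filter_fraction=0.0)


class TestANMBfactors:
    def test_two_bead_symmetry(self):
        from conftest import two_bead_network
        from loopdyn.cg_ensembles import anm_hessian, ModeSet
        net = two_bead_network()
        evals, evecs = np.linalg.eigh(anm_hessian(net))
        modes = ModeSet(evals[-1:], evecs[:, -1:], 5, net.coords)
        prof = ld.anm_bfactors(modes)
        assert prof.bfactor[0] == pytest.approx(prof.bfactor[1])

    def test_matches_sampled_ensemble(self, chain5):
        modes = ld.anm_modes(ld.build_network(chain5))
        analytic = ld.anm_bfactors(modes)
        ens = ld.nma_ensemble(modes, n_frames=20_000, seed=8)
        sampled = ld.rmsf_profile(ens, fit=False, filter_fraction=1.0)
        np.testing.assert_allclose(sampled.rmsf**2, analytic.rmsf**2, rtol=0.05)

    def test_stiffness_scaling_is_inverse_linear(self, chain5):
        from loopdyn.cg_ensembles import CGParameters
        soft = ld.anm_modes(ld.build_network(chain5, CGParameters(stiffness=40)))
        stiff = ld.anm_modes(ld.build_network(chain5, CGParameters(stiffness=160)))
        np.testing.assert_allclose(
            ld.anm_bfactors(soft).bfactor,
            4 * ld.anm_bfactors(stiff).bfactor, rtol=1e-9)


class TestPCA:
    def test_single_axis_motion_explains_everything(self):
        base = make_chain(6, "extended")
        shifts = np.linspace(-1, 1, 30)
        direction = np.zeros((6, 3))
        direction[2, 0] = 1.0
        frames = base.ca_coords()[None] + shifts[:, None, None] * direction[None]
        res = ld.pca(Ensemble(base, frames), fit=False)
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-10)

    def test_pure_cosine_projection_has_content_one(self):
        T = 500
        t = np.arange(T)
        p = np.cos(np.pi * (t + 0.5) / T)
        assert ld.cosine_content(p, order=1) == pytest.approx(1.0, abs=1e-3)

    def test_identical_halves_have_rmsip_one(self):
        ens = _jitter_ensemble(n_frames=100, seed=4)
        doubled = Ensemble(ens.structure,
                           np.concatenate([ens.frames, ens.frames]))
        res = ld.pca(doubled, fit=False)
        assert res.rmsip_halves == pytest.approx(1.0, abs=1e-9)

    def test_rmsip_bounded(self):
        a = _jitter_ensemble(n_frames=80, seed=5)
        res = ld.pca(a, fit=False)
        assert 0.0 <= res.rmsip_halves <= 1.0 + 1e-12

    def test_single_frame_rejected(self):
        base = make_chain(4, "extended")
        ens = Ensemble(base, base.ca_coords()[None])
        with pytest.raises(ValueError):
            ld.pca(ens)


class TestDCCM:
    def test_planted_correlation_recovered(self):
        ens, _ = make_planted_covariance_ensemble(
            20, [(2, 15, 0.8)], n_frames=10_000, seed=3)
        mat = ld.dccm(ens, window_frames=10_000, fit=False)
        assert mat.averaged[2, 15] == pytest.approx(0.8, abs=0.05)

    def test_duplicated_residue_has_unit_correlation(self):
        base = make_chain(6, "extended")
        rng = np.random.default_rng(0)
        frames = base.ca_coords()[None] + rng.normal(
            scale=0.5, size=(500, 6, 3))
        frames[:, 3, :] = frames[:, 2, :] + 1.0  # rigid copy of residue 2
        mat = ld.dccm(Ensemble(base, frames), window_frames=500, fit=False)
        assert mat.averaged[2, 3] == pytest.approx(1.0, abs=1e-9)

    def test_unit_diagonal_symmetry_bounds_every_window(self):
        ens, _ = make_planted_covariance_ensemble(
            8, [(1, 6, -0.6)], n_frames=900, seed=7)
        mat = ld.dccm(ens, window_frames=300, fit=False)
        assert len(mat.window_matrices) == 3
        for C in mat.window_matrices:
            np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
            np.testing.assert_allclose(C, C.T, atol=1e-12)
            assert np.abs(C).max() <= 1.0 + 1e-12

    def test_zero_variance_residue_warns_and_zeroes(self):
        base = make_chain(5, "extended")
        rng = np.random.default_rng(1)
        frames = base.ca_coords()[None] + rng.normal(scale=0.2, size=(50, 5, 3))
        frames[:, 4, :] = base.ca_coords()[4]  # frozen residue
        with pytest.warns(UserWarning, match="zero-variance"):
            mat = ld.dccm(Ensemble(base, frames), window_frames=50, fit=False)
        assert mat.averaged[4, 0] == 0.0

    def test_significant_long_range_mask(self):
        ens, _ = make_planted_covariance_ensemble(
            20, [(2, 15, 0.8), (0, 3, 0.9)], n_frames=4000, seed=2)
        mat = ld.dccm(ens, window_frames=4000, fit=False)
        mask = mat.significant_long_range()
        assert mask[2, 15] and mask[15, 2]
        assert not mask[0, 3]  # |i-j| = 3 <= 10: excluded as short range


def brute_force_depths(C, roots, threshold, max_depth):
    """Exhaustive shortest-path depth enumeration (independent oracle)."""
    n = len(C)
    adj = np.abs(C) >= threshold
    np.fill_diagonal(adj, False)
    best = {r: 0 for r in roots}
    frontier = set(roots)
    for d in range(1, max_depth + 1):
        nxt = set()
        for p in frontier:
            for c in range(n):
                if adj[p, c] and c not in best:
                    nxt.add(c)
        for c in nxt:
            best[c] = d
        frontier = nxt
    return best


class TestChainedCorrelations:
    def test_single_chain_depths(self):
        C = np.eye(5)
        C[0, 1] = C[1, 0] = 0.6
        C[1, 2] = C[2, 1] = 0.7
        g = ld.chained_correlations(C, [0], threshold=0.5, max_depth=5)
        assert g.depths() == {0: 0, 1: 1, 2: 2}

    def test_threshold_above_max_keeps_roots_only(self):
        rng = np.random.default_rng(0)
        C = rng.uniform(-0.4, 0.4, size=(6, 6))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        g = ld.chained_correlations(C, [1, 4], threshold=0.5)
        assert g.depths() == {1: 0, 4: 0}
        assert g.edges == []

    def test_empty_roots_rejected(self):
        with pytest.raises(ValueError):
            ld.chained_correlations(np.eye(3), [])

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        C = rng.uniform(-1, 1, size=(8, 8))
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        roots = sorted(rng.choice(8, size=rng.integers(1, 3), replace=False))
        g = ld.chained_correlations(C, roots, threshold=0.5, max_depth=5)
        assert g.depths() == brute_force_depths(C, roots, 0.5, 5)

    def test_long_range_partner_report(self):
        C = np.eye(7)
        for i in range(6):
            C[i, i + 1] = C[i + 1, i] = 0.8
        g = ld.chained_correlations(C, [0], threshold=0.5, max_depth=5)
        assert g.long_range_partners(depth_min=3) == [3, 4, 5]


class TestHinges:
    def test_step_profile_hinge_at_boundary(self):
        b = np.array([1.0] * 10 + [9.0] * 10)
        prof = ld.FlexibilityProfile(np.sqrt(b / (8 * np.pi**2 / 3)))
        res = ld.predict_hinges(prof, loop_range=(10, 19))
        assert res.detected
        assert res.hinges and res.hinges[0] in (9, 10)
        assert res.n_terminal in (9, 10)

    def test_kinked_ramp_matches_second_difference_oracle(self):
        # flat then steep ramp: kink at index 12
        b = np.concatenate([np.full(12, 2.0), 2.0 + 3.0 * np.arange(1, 13)])
        prof = ld.FlexibilityProfile(np.sqrt(b / (8 * np.pi**2 / 3)))
        res = ld.predict_hinges(prof, smoothing_window=1)
        oracle = int(np.argmax(np.abs(np.diff(b, 2)))) + 1
        assert any(abs(h - oracle) <= 1 for h in res.hinges)

    def test_flat_profile_reports_no_hinge(self):
        prof = ld.FlexibilityProfile(np.full(30, 1.0))
        res = ld.predict_hinges(prof)
        assert not res.detected and res.hinges == []


class TestReplicaConsistency:
    def test_identical_profiles_correlate_perfectly(self):
        p = ld.FlexibilityProfile(np.linspace(0.5, 2.0, 50))
        out = ld.replica_consistency([p, p])
        assert out["min"] == pytest.approx(1.0)

    def test_reversed_linear_profile_anticorrelates(self):
        a = ld.FlexibilityProfile(np.linspace(0.5, 2.0, 50))
        b = ld.FlexibilityProfile(np.linspace(2.0, 0.5, 50))
        out = ld.replica_consistency([a, b])
        assert out["matrix"][0, 1] == pytest.approx(-1.0)

    def test_jittered_copies_stay_consistent(self):
        rng = np.random.default_rng(6)
        base = np.sin(np.linspace(0, 6, 150)) + 2.0
        noise = 0.1 * (base.max() - base.min())
        profs = [ld.FlexibilityProfile(base + rng.normal(scale=noise, size=150))
                 for _ in range(3)]
        out = ld.replica_consistency(profs)
        assert out["min"] > 0.9

    def test_zero_variance_profile_marked_undefined(self):
        a = ld.FlexibilityProfile(np.ones(20))
        b = ld.FlexibilityProfile(np.linspace(1, 2, 20))
        out = ld.replica_consistency([a, b])
        assert (0, 1) in out["undefined_pairs"]
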