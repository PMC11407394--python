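"""Observable unit tests against analytic fixtures and hand-built configurations."""

import numpy as np
import pytest

from conftest import make_trajectory
from nucshell.observables import (
    SliceSpec,
    SliceTooSparseError,
    chain_compaction,
    contact_map,
    fluctuation_spectrum,
    mean_intra_type_contact_density,
    radial_density_profile,
    slice_radial_displacements,
)
from nucshell.scenarios import (
    AnalyticShellFixture,
    fixture_trajectory,
    generate_analytic_shell,
)
from nucshell.types import BeadType

R_FIX = 42.0
N_FIX = 20_000


class TestSliceDisplacements:
    def test_perfect_sphere_displacements_vanish(self):
        st = generate_analytic_shell(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX), seed=1
        )
        for axis in "xyz":
            _, signal, raw = slice_radial_displacements(
                st.positions, st.types, SliceSpec(normal_axis=axis)
            )
            assert np.abs(raw).max() < 5e-3  # only slice-curvature residue
            assert np.abs(signal).max() < 5e-3

    def test_single_mode_reconstructed(self):
        fix = AnalyticShellFixture(
            base_radius=R_FIX, bead_count=N_FIX, perturbations=[(5, 0.5, 0.0)]
        )
        st = generate_analytic_shell(fix, seed=2)
        theta, signal, _ = slice_radial_displacements(st.positions, st.types)
        expected = 0.5 * np.cos(5 * theta)
        assert np.max(np.abs(signal - expected)) < 0.02 * 0.5

    def test_mean_subtraction(self):
        fix = AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX,
                                   perturbations=[(3, 0.4, 1.0)])
        st = generate_analytic_shell(fix, seed=3)
        _, _, raw = slice_radial_displacements(st.positions, st.types)
        assert abs(raw.mean()) < 1e-12

    def test_sparse_slice_rejected(self):
        st = generate_analytic_shell(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=300), seed=1
        )
        with pytest.raises(SliceTooSparseError):
            slice_radial_displacements(st.positions, st.types)


class TestFluctuationSpectrum:
    def test_static_sphere_spectrum_is_flat_zero(self):
        traj = fixture_trajectory(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX), n_frames=6
        )
        spec = fluctuation_spectrum(traj)
        assert spec.rms < 1e-3
        assert spec.amplitudes.max() < 2e-3

    def test_single_mode_amplitude_recovered(self):
        traj = fixture_trajectory(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX,
                                 perturbations=[(5, 0.5, 0.0)]),
            n_frames=6,
        )
        spec = fluctuation_spectrum(traj)
        assert spec.amplitude(5) == pytest.approx(0.5, rel=0.02)
        others = np.delete(spec.amplitudes, 4)
        assert others.max() < 0.04 * 0.5

    def test_two_modes_recovered_independently(self):
        traj = fixture_trajectory(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX,
                                 perturbations=[(3, 0.4, 0.3), (7, 0.25, 1.1)]),
            n_frames=6,
        )
        spec = fluctuation_spectrum(traj)
        assert spec.amplitude(3) == pytest.approx(0.4, rel=0.02)
        assert spec.amplitude(7) == pytest.approx(0.25, rel=0.02)

    def test_parseval_consistency(self):
        # total spectral power ~ real-space variance (mode truncation < 5%)
        traj = fixture_trajectory(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX,
                                 perturbations=[(2, 0.3, 0.0), (6, 0.2, 0.5)]),
            n_frames=6,
        )
        spec = fluctuation_spectrum(traj)
        power = 0.5 * np.sum(spec.amplitudes ** 2)
        variance = spec.rms ** 2
        assert power == pytest.approx(variance, rel=0.05)

    def test_rotation_invariance_on_isotropic_fixture(self):
        fix = AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX,
                                   noise_sd=0.3)
        traj = fixture_trajectory(fix, n_frames=10)
        rms = {
            ax: fluctuation_spectrum(traj, SliceSpec(normal_axis=ax)).rms
            for ax in "xyz"
        }
        vals = np.array(list(rms.values()))
        assert vals.max() / vals.min() < 1.1

    def test_amplitudes_scale_with_radius(self):
        # shape-preserving x2 rescaling doubles raw amplitudes exactly and
        # leaves radius-normalized amplitudes unchanged
        traj = fixture_trajectory(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX,
                                 perturbations=[(4, 0.5, 0.2)]),
            n_frames=4,
        )
        traj2 = make_trajectory(traj.frames * 2.0, traj.types)
        wide = SliceSpec(width=2.0)  # slice width scales with the shell
        s1 = fluctuation_spectrum(traj)
        s2 = fluctuation_spectrum(traj2, wide)
        np.testing.assert_allclose(s2.amplitudes, 2.0 * s1.amplitudes, rtol=1e-5)
        n1 = fluctuation_spectrum(traj, normalize_by_radius=True)
        n2 = fluctuation_spectrum(traj2, wide, normalize_by_radius=True)
        np.testing.assert_allclose(n2.amplitudes, n1.amplitudes, rtol=1e-5)
        assert n2.rms == pytest.approx(n1.rms, rel=1e-6)

    def test_nyquist_guard(self):
        traj = fixture_trajectory(
            AnalyticShellFixture(base_radius=R_FIX, bead_count=N_FIX), n_frames=4
        )
        with pytest.raises(ValueError):
            fluctuation_spectrum(traj, Q=10_000)


class TestRadialProfile:
    def _with_shell(self, chain_pos, chain_types, seed=0):
        shell = generate_analytic_shell(
            AnalyticShellFixture(base_radius=10.0, bead_count=2000), seed=seed
        )
        pos = np.vstack([chain_pos, shell.positions])
        types = np.concatenate([chain_types,
                                shell.types]).astype(np.int8)
        cid = np.concatenate([np.zeros(len(chain_pos), dtype=np.int64),
                              np.full(2000, -1, dtype=np.int64)])
        return make_trajectory(pos, types, chain_id=cid)

    def test_uniform_beads_give_flat_profile(self):
        rng = np.random.default_rng(3)
        n = 40_000
        u = rng.normal(size=(n, 3))
        r = 10.0 * rng.random(n) ** (1 / 3)
        pos = u / np.linalg.norm(u, axis=1, keepdims=True) * r[:, None]
        traj = self._with_shell(pos, np.full(n, BeadType.E, dtype=np.int8))
        prof = radial_density_profile(traj, types="E", n_bins=11)
        # interior bins (excluding the outermost, beyond the bead region)
        dens = prof.density["E"][:9]
        assert dens.std() / dens.mean() < 0.05

    def test_hand_placed_beads_match_manual_tally(self):
        # 10 beads at hand-chosen radii around a shell of mean radius ~10
        radii = np.array([0.52, 1.57, 1.57, 2.43, 2.43, 2.43, 3.41, 3.41, 3.41, 3.41])
        pos = np.zeros((10, 3))
        pos[:, 0] = radii
        types = np.array([BeadType.E] * 5 + [BeadType.F] * 5, dtype=np.int8)
        traj = self._with_shell(pos, types)
        r_mean = traj.mean_shell_radius[0]
        prof = radial_density_profile(traj, types="EF", n_bins=22)
        edges = prof.bin_edges
        vol = 4 / 3 * np.pi * np.diff(edges ** 3)
        for code, mask in (("E", types == BeadType.E), ("F", types == BeadType.F)):
            manual, _ = np.histogram(radii[mask] / r_mean, bins=edges)
            np.testing.assert_allclose(prof.density[code] * vol, manual, atol=1e-9)

    def test_mass_conservation(self):
        rng = np.random.default_rng(9)
        n = 500
        pos = rng.normal(scale=3.0, size=(n, 3))
        types = np.array([BeadType.E] * 250 + [BeadType.C] * 250, dtype=np.int8)
        traj = self._with_shell(pos, types)
        prof = radial_density_profile(traj, types="EC")
        vol = 4 / 3 * np.pi * np.diff(prof.bin_edges ** 3)
        for code in "EC":
            assert (prof.density[code] * vol).sum() == pytest.approx(250, abs=1e-9)


class TestContactMap:
    def test_straight_rod_touches_only_backbone_neighbors(self):
        n = 20
        pos = np.zeros((n, 3))
        pos[:, 0] = np.arange(n)
        cm = contact_map(pos, np.zeros(n, dtype=np.int64), bin_size=1,
                         contact_cutoff=1.1)
        m = cm.matrix
        off = np.triu_indices(n, k=2)
        assert m[off].sum() == 0
        first_off = np.diag(m, k=1)
        assert np.all(first_off == 1)

    def test_hairpin_matches_bruteforce(self):
        # 8-bead hairpin: two antiparallel strands 0.9 sigma apart
        pos = np.array([
            [0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0],
            [3, 0.9, 0], [2, 0.9, 0], [1, 0.9, 0], [0, 0.9, 0],
        ], dtype=float)
        cid = np.zeros(8, dtype=np.int64)
        cutoff = 1.0
        cm = contact_map(pos, cid, bin_size=1, contact_cutoff=cutoff)
        brute = np.zeros((8, 8))
        for i in range(8):
            brute[i, i] += 1
            for j in range(i + 1, 8):
                if np.linalg.norm(pos[i] - pos[j]) <= cutoff:
                    brute[i, j] += 1
                    brute[j, i] += 1
        np.testing.assert_array_equal(cm.matrix, brute)

    def test_symmetry_and_diagonal_maximal(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 4, size=(60, 3))
        cm = contact_map(pos, np.zeros(60, dtype=np.int64), bin_size=4,
                         contact_cutoff=1.2)
        np.testing.assert_array_equal(cm.matrix, cm.matrix.T)
        assert np.all(np.diag(cm.matrix) >= cm.matrix.max(axis=1) / 2)

    def test_intra_type_contact_density(self):
        # C beads clustered, E beads dispersed: C-C contact density dominates
        rng = np.random.default_rng(5)
        c = rng.normal(scale=0.8, size=(50, 3))
        e = rng.uniform(-8, 8, size=(50, 3))
        pos = np.vstack([c, e])
        types = np.array([BeadType.C] * 50 + [BeadType.E] * 50, dtype=np.int8)
        dens = mean_intra_type_contact_density(
            pos, np.zeros(100, dtype=np.int64), types)
        assert dens["C"] > dens["E"]


class TestChainCompaction:
    def test_straight_rod_gyration_matches_closed_form(self):
        n = 50
        pos = np.zeros((n, 3))
        pos[:, 2] = np.arange(n)  # spacing 1
        traj = make_trajectory(pos, np.full(n, BeadType.E, dtype=np.int8),
                               chain_id=np.zeros(n, dtype=np.int64))
        comp = chain_compaction(traj)
        expected = np.sqrt((n ** 2 - 1) / 12.0)
        assert comp["rg"][0] == pytest.approx(expected, rel=1e-12)

    def test_coincident_single_bead_chains(self):
        pos = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        traj = make_trajectory(pos, np.full(2, BeadType.E, dtype=np.int8),
                               chain_id=np.array([0, 1]))
        comp = chain_compaction(traj)
        assert comp["com_distances"][0] == 0.0
        assert np.all(comp["rg"] == 0.0)
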