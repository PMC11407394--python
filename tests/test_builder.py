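"""Builder unit tests: chain plans, shell meshes, placement, crosslinks."""

import numpy as np
import pytest
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from nucshell.builder import (
    ConstructionError,
    add_crosslinks,
    build_chromosome_plan,
    build_shell_mesh,
    default_shell_count,
    place_compact_chains,
    reassign_heterochromatin_fraction,
)
from nucshell.types import BeadType, InitialConfiguration


class TestChromosomePlan:
    def test_full_scale_composition(self):
        plan = build_chromosome_plan(1000, 5000, 0.5, 40, seed=1)
        assert plan.n_beads == 6002
        counts = plan.type_counts()
        assert counts["C"] == 1000
        assert counts["T"] == 2
        assert counts["E"] + counts["F"] == 5000

    def test_telomeres_at_termini_and_terminal_c_block(self):
        plan = build_chromosome_plan(100, 500, 0.5, 10, seed=2)
        t = plan.bead_types
        assert t[0] == BeadType.T and t[-1] == BeadType.T
        c_idx = np.flatnonzero(t == BeadType.C)
        # contiguous block adjacent to the first telomere
        assert c_idx[0] == 1 and c_idx[-1] == 100
        assert np.all(np.diff(c_idx) == 1)

    def test_empty_body_chain(self):
        plan = build_chromosome_plan(0, 0, 0.0, 1, seed=0)
        assert plan.n_beads == 2
        assert set(plan.bead_types.tolist()) == {int(BeadType.T)}

    def test_f_count_by_exhaustive_tally(self):
        plan = build_chromosome_plan(100, 500, 0.3, 10, seed=3)
        n_f = sum(1 for b in plan.bead_types if b == BeadType.F)
        assert abs(n_f - 150) <= 1

    @pytest.mark.parametrize("f", [0.10, 0.30, 0.45, 0.55, 0.75])
    def test_fraction_accuracy_and_conservation(self, f):
        plan = build_chromosome_plan(200, 1000, f, 15, seed=7)
        counts = plan.type_counts()
        assert sum(counts.values()) == plan.n_beads
        assert abs(plan.f_realized - f) <= 1.0 / plan.n_compartment

    def test_blocks_alternate(self):
        plan = build_chromosome_plan(0, 2000, 0.5, 40, seed=5)
        comp = plan.bead_types[plan.compartment_slice]
        runs = np.diff(np.flatnonzero(np.diff(comp) != 0))
        # mean run length should be in the vicinity of the requested mean
        assert 10 < runs.mean() < 120

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            build_chromosome_plan(-1, 10, 0.5, 10)
        with pytest.raises(ValueError):
            build_chromosome_plan(10, 10, 1.5, 10)
        with pytest.raises(ValueError):
            build_chromosome_plan(10, 10, 0.5, 0.2)


class TestReassignFraction:
    def test_raise_fraction_to_075(self):
        plan = build_chromosome_plan(100, 500, 0.5, 10, seed=1)
        new = reassign_heterochromatin_fraction(plan, 0.75, seed=2)
        assert new.f_realized == pytest.approx(0.75, abs=1.0 / 500)

    def test_noop_preserves_type_multiset(self):
        plan = build_chromosome_plan(100, 500, 0.5, 10, seed=1)
        new = reassign_heterochromatin_fraction(plan, plan.f_realized, seed=9)
        assert new.type_counts() == plan.type_counts()

    def test_exact_count_by_tally(self):
        plan = build_chromosome_plan(50, 500, 0.5, 10, seed=4)
        new = reassign_heterochromatin_fraction(plan, 0.10, seed=5)
        assert int(np.count_nonzero(new.bead_types == BeadType.F)) == 50

    def test_only_compartment_beads_change(self):
        plan = build_chromosome_plan(100, 500, 0.5, 10, seed=1)
        new = reassign_heterochromatin_fraction(plan, 0.2, seed=3)
        changed = plan.bead_types != new.bead_types
        comp = np.zeros(plan.n_beads, dtype=bool)
        comp[plan.compartment_slice] = True
        assert not np.any(changed & ~comp)
        # every change is an E<->F conversion
        pairs = {(int(a), int(b)) for a, b in
                 zip(plan.bead_types[changed], new.bead_types[changed])}
        assert pairs <= {(int(BeadType.E), int(BeadType.F)),
                         (int(BeadType.F), int(BeadType.E))}

    def test_invalid_target(self):
        plan = build_chromosome_plan(10, 100, 0.5, 10, seed=1)
        with pytest.raises(ValueError):
            reassign_heterochromatin_fraction(plan, 1.2, seed=0)


class TestShellMesh:
    def test_degree_bounds_small_mesh(self, small_shell):
        deg = small_shell.degrees()
        assert deg.min() >= 5 and deg.max() <= 8

    def test_bond_list_clean(self, small_shell):
        small_shell.validate()  # raises on self-bonds / duplicates
        b = small_shell.bonds
        assert np.all(b[:, 0] != b[:, 1])

    def test_counts_and_rest_lengths(self, small_shell):
        assert small_shell.n_beads == 500
        lengths = np.linalg.norm(
            small_shell.positions[small_shell.bonds[:, 0]]
            - small_shell.positions[small_shell.bonds[:, 1]], axis=1)
        np.testing.assert_allclose(small_shell.rest_length, 0.7 * lengths)

    def test_bond_lengths_within_band_bruteforce(self):
        mesh = build_shell_mesh(n_shell=500, R0=10.0, seed=21)
        p = mesh.positions
        lengths = np.array([
            np.sqrt(((p[i] - p[j]) ** 2).sum()) for i, j in mesh.bonds
        ])
        assert lengths.min() >= 0.5 * lengths.mean()
        assert lengths.max() <= 1.5 * lengths.mean()

    def test_beads_on_sphere(self, small_shell):
        r = np.linalg.norm(small_shell.positions, axis=1)
        np.testing.assert_allclose(r, 10.0, rtol=1e-9)

    def test_determinism(self):
        a = build_shell_mesh(n_shell=400, R0=9.0, seed=5)
        b = build_shell_mesh(n_shell=400, R0=9.0, seed=5)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.bonds, b.bonds)

    def test_scale_invariance_of_degree_distribution(self):
        small = build_shell_mesh(R0=14.0, seed=2)
        big = build_shell_mesh(R0=28.0, seed=3)
        ks = ks_2samp(small.degrees(), big.degrees()).statistic
        assert ks < 0.1

    def test_too_sparse_bonding_rejected(self):
        with pytest.raises(ConstructionError):
            build_shell_mesh(n_shell=300, R0=10.0, bond_cutoff=0.3, seed=0)


class TestPlacement:
    def test_all_beads_inside_shell_bruteforce(self, small_shell):
        plans = [build_chromosome_plan(10, 80, 0.5, 10, seed=s) for s in (1, 2)]
        config = place_compact_chains(plans, small_shell, seed=3)
        r_chain = np.linalg.norm(config.chain_positions, axis=1)
        r_shell = np.linalg.norm(small_shell.positions, axis=1)
        assert r_chain.max() < r_shell.min()

    def test_shell_only_configuration(self, small_shell):
        config = place_compact_chains([], small_shell, seed=0)
        assert config.n_chain_beads == 0
        assert config.n_beads == small_shell.n_beads

    def test_no_hard_overlaps_after_push(self, small_shell):
        plans = [build_chromosome_plan(10, 120, 0.5, 10, seed=s) for s in (4, 5)]
        config = place_compact_chains(plans, small_shell, seed=6)
        d, _ = cKDTree(config.chain_positions).query(config.chain_positions, k=2)
        assert d[:, 1].min() > 0.7

    def test_backbone_bonds_not_overstretched(self, small_shell):
        plans = [build_chromosome_plan(20, 150, 0.5, 10, seed=s) for s in (1, 2)]
        config = place_compact_chains(plans, small_shell, seed=9)
        off = 0
        for p in config.plans:
            seg = config.chain_positions[off:off + p.n_beads]
            blen = np.linalg.norm(np.diff(seg, axis=0), axis=1)
            assert blen.max() < 1.45
            off += p.n_beads

    def test_determinism(self, small_shell):
        plans = [build_chromosome_plan(10, 80, 0.5, 10, seed=1)]
        a = place_compact_chains(plans, small_shell, seed=7)
        b = place_compact_chains(plans, small_shell, seed=7)
        np.testing.assert_array_equal(a.chain_positions, b.chain_positions)

    def test_overfull_shell_rejected(self, small_shell):
        plans = [build_chromosome_plan(100, 900, 0.5, 10, seed=s) for s in range(4)]
        with pytest.raises(ConstructionError):
            place_compact_chains(plans, small_shell, seed=0)


class TestCrosslinks:
    @pytest.fixture(scope="class")
    def config(self, small_shell):
        plans = [build_chromosome_plan(30, 100, 0.5, 10, seed=s) for s in (1, 2)]
        return place_compact_chains(plans, small_shell, seed=3)

    def test_pairs_are_cc_and_within_cutoff(self, config):
        linked = add_crosslinks(config, crosslink_cutoff=1.3, max_per_bead=2, seed=1)
        types = config.chain_types()
        pos = config.chain_positions
        assert linked.crosslinks.enabled
        for i, j in linked.crosslinks.pairs:
            assert types[i] == BeadType.C and types[j] == BeadType.C
            assert np.linalg.norm(pos[i] - pos[j]) <= 1.3
            assert abs(i - j) != 1  # never duplicates a backbone bond

    def test_max_per_bead_respected(self, config):
        linked = add_crosslinks(config, crosslink_cutoff=2.0, max_per_bead=2, seed=1)
        counts = np.zeros(config.n_chain_beads, dtype=int)
        for i, j in linked.crosslinks.pairs:
            counts[i] += 1
            counts[j] += 1
        assert counts.max() <= 2

    def test_disabled_by_default(self, config):
        assert not config.crosslinks.enabled
        assert config.crosslinks.n_pairs == 0

    def test_determinism(self, config):
        a = add_crosslinks(config, seed=5)
        b = add_crosslinks(config, seed=5)
        np.testing.assert_array_equal(a.crosslinks.pairs, b.crosslinks.pairs)

    def test_cutoff_below_diameter_rejected(self, config):
        with pytest.raises(ValueError):
            add_crosslinks(config, crosslink_cutoff=0.5)


class TestPlanProperties:
    """Composition invariants over the builder's whole input space."""

    from hypothesis import given, settings, strategies as st

    @given(
        n_c=st.integers(0, 300),
        n_comp=st.integers(0, 1500),
        f=st.floats(0.0, 1.0),
        block_mean=st.floats(1.0, 60.0),
        seed=st.integers(0, 2 ** 20),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_composition_conserved_and_fraction_exact(self, n_c, n_comp, f,
                                                      block_mean, seed):
        plan = build_chromosome_plan(n_c, n_comp, f, block_mean, seed)
        counts = plan.type_counts()
        assert sum(counts.values()) == n_c + n_comp + 2
        assert counts["C"] == n_c
        assert counts["T"] == 2
        if n_comp:
            assert abs(plan.f_realized - f) <= 1.0 / n_comp
        # C block contiguous, adjacent to a terminal telomere
        c_idx = np.flatnonzero(plan.bead_types == BeadType.C)
        if n_c:
            assert np.all(np.diff(c_idx) == 1) and c_idx[0] == 1

    @given(
        f0=st.floats(0.0, 1.0), f1=st.floats(0.0, 1.0),
        seed=st.integers(0, 2 ** 20),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_reassignment_reaches_any_target(self, f0, f1, seed):
        plan = build_chromosome_plan(20, 400, f0, 12, seed=1)
        new = reassign_heterochromatin_fraction(plan, f1, seed=seed)
        assert abs(new.f_realized - f1) <= 1.0 / 400
        assert new.type_counts()["C"] == 20


def test_default_shell_count_scales_with_area():
    n42 = default_shell_count(42.0)
    n14 = default_shell_count(14.0)
    assert n42 == pytest.approx(9 * n14, rel=0.01)
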