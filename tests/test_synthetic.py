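"""Synthetic generator: geometry, sampling law, determinism, planted features."""

import numpy as np
import pytest

from allodyn.core import select
from allodyn.ed import align
from allodyn.fluctuation import distance_fluctuations, rigidity_map
from allodyn.hbond import detect_hbonds, pooled_persistence
from allodyn.core import Selection
from allodyn.synthetic import (ToyProteinSpec, build_toy_structure, enm_covariance,
                               make_state_set, model_covariance, rigid_body_images,
                               rigid_blocks_covariance, sample_ensemble)


class TestBuildToyStructure:
    def test_two_blocks_one_hinge_geometry(self):
        spec = ToyProteinSpec(block_sizes=(20, 20))
        st = build_toy_structure(spec)
        assert st.topology.n_residues == 41
        ca = st.ref_coords[st.ca_indices]
        spacing = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all(np.abs(spacing - 3.8) < 0.01)
        assert st.hinge_residues.tolist() == [21]

    def test_single_block_compact(self):
        spec = ToyProteinSpec(block_sizes=(12,))
        st = build_toy_structure(spec)
        ca = st.ref_coords[st.ca_indices]
        assert np.linalg.norm(ca - ca.mean(axis=0), axis=1).max() < 12.0

    def test_planted_chain_residues_validated(self):
        with pytest.raises(ValueError, match="not in topology"):
            build_toy_structure(ToyProteinSpec(block_sizes=(5,), planted_chain=(99,)))


class TestSampling:
    def test_same_seed_bit_identical(self, two_block_structure):
        spec, st = two_block_structure
        a = sample_ensemble(st, spec, "apo", 20, seed=42)
        b = sample_ensemble(st, spec, "apo", 20, seed=42)
        assert np.array_equal(a.coords, b.coords)

    def test_different_seeds_differ(self, two_block_structure):
        spec, st = two_block_structure
        a = sample_ensemble(st, spec, "apo", 5, seed=1)
        b = sample_ensemble(st, spec, "apo", 5, seed=2)
        assert not np.allclose(a.coords, b.coords)

    def test_enm_variance_matches_covariance_diagonal(self, two_block_structure):
        """Law of large numbers: sampled variances track the model covariance."""
        spec, st = two_block_structure
        C = model_covariance(st, spec)
        ens = sample_ensemble(st, spec, "apo", 3000, seed=3)
        emp = ens.coords[:, st.ca_indices].reshape(3000, -1).var(axis=0)
        rel = (emp - np.diag(C)) / np.diag(C)
        assert np.sqrt((rel ** 2).mean()) < 0.07  # ~sqrt(2/n) noise floor

    def test_rigid_blocks_covariance_agrees_with_sampler(self):
        spec = ToyProteinSpec(covariance="rigid_blocks")
        st = build_toy_structure(spec)
        C = rigid_blocks_covariance(st, spec)
        ens = sample_ensemble(st, spec, "apo", 4000, seed=4)
        emp = ens.coords[:, st.ca_indices].reshape(4000, -1).var(axis=0)
        rel = (emp - np.diag(C)) / np.diag(C)
        assert np.sqrt((rel ** 2).mean()) < 0.07

    def test_stiff_limit_small_fluctuations(self):
        spec = ToyProteinSpec(block_sizes=(15,), block_spring=500.0, background_spring=2.0)
        st = build_toy_structure(spec)
        ens = sample_ensemble(st, spec, "stiff", 200, seed=5)
        ca = ens.coords[:, st.ca_indices]
        assert ca.reshape(200, -1).var(axis=0).max() < 0.05

    def test_disconnected_network_fatal(self):
        spec = ToyProteinSpec(block_sizes=(8, 8), hinge_spring=1e-30,
                              background_spring=1e-30)
        st = build_toy_structure(spec)
        with pytest.raises(ValueError, match="disconnected"):
            enm_covariance(st, spec)

    def test_planted_occupancy_recovered_by_detection(self):
        spec = ToyProteinSpec(planted_chain=(3, 24, 41), chain_occupancy=0.9)
        st = build_toy_structure(spec)
        reps = [sample_ensemble(st, spec, "apo", 500, seed=[6, r]) for r in range(3)]
        sel_all = Selection(np.arange(st.topology.n_atoms), "all")
        events = [detect_hbonds(e, sel_all, sel_all) for e in reps]
        frac = pooled_persistence(events, frame_counts=[500] * 3)
        planted = [f for f in frac.values() if f > 0.5]
        assert len(planted) == 3  # LIG->3, 3->24, 24->41
        assert all(0.8 <= f <= 1.0 for f in planted)


class TestMakeStateSet:
    def test_grid_bookkeeping(self):
        spec = ToyProteinSpec(block_sizes=(8, 8))
        sset = make_state_set(spec, {"apo": None, "atp": {"hinge": 10.0},
                                     "adp": {"hinge": 3.0}},
                              replicas=3, n_frames=20, base_seed=1)
        assert len(sset.ensembles) == 9
        assert sset.states == ["adp", "apo", "atp"]
        tops = {id(e.topology) for e in sset.ensembles.values()}
        assert len(tops) == 1
        assert all(isinstance(s, tuple) for s in sset.seeds.values())

    def test_regeneration_is_bit_identical(self):
        spec = ToyProteinSpec(block_sizes=(8, 8))
        s1 = make_state_set(spec, {"apo": None}, replicas=2, n_frames=15, base_seed=7)
        s2 = make_state_set(spec, {"apo": None}, replicas=2, n_frames=15, base_seed=7)
        for key in s1.ensembles:
            assert np.array_equal(s1.ensembles[key].coords, s2.ensembles[key].coords)

    def test_hinge_stiffening_reduces_hinge_mobility(self, two_block_structure):
        from allodyn.strain import geometric_strain, mobility, mobility_difference
        spec, st = two_block_structure
        sel = select(st.topology, "CA")
        sset = make_state_set(spec, {"apo": None, "atp": {"hinge": 10.0}},
                              replicas=3, n_frames=150, base_seed=3)
        mobs = {}
        for state in ("apo", "atp"):
            profs = [geometric_strain(align(e, sel), sel) for e in sset.replicas(state)]
            mobs[state] = mobility(profs)
        diff = mobility_difference(mobs["apo"], mobs["atp"])
        hinge = int(st.hinge_residues[0])
        assert diff.peaks and diff.peaks[0][0] == hinge
        assert diff.peaks[0][1] > 0  # apo hinge more mobile

    def test_block_rigidity_map_recovers_planted_blocks(self):
        spec = ToyProteinSpec(covariance="rigid_blocks")
        st = build_toy_structure(spec)
        sel = select(st.topology, "CA")
        ens = sample_ensemble(st, spec, "apo", 400, seed=9)
        fm = distance_fluctuations(align(ens, sel), sel)
        rm = rigidity_map(fm).values
        b = st.block_of
        m0, m1 = b == 0, b == 1
        assert np.all(rm[np.ix_(m0, m0)] == 1.0)
        assert np.all(rm[np.ix_(m1, m1)] == 1.0)
        assert np.all(rm[np.ix_(m0, m1)] == 0.0)


class TestRigidBodyImages:
    def test_internal_distances_invariant(self, two_block_structure):
        _, st = two_block_structure
        ens = rigid_body_images(st, 5, seed=10)
        ca = ens.coords[:, st.ca_indices]
        d0 = np.linalg.norm(ca[0][:, None] - ca[0][None, :], axis=-1)
        for f in range(1, 5):
            d = np.linalg.norm(ca[f][:, None] - ca[f][None, :], axis=-1)
            assert np.allclose(d, d0, atol=1e-9)
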