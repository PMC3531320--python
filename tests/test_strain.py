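"""Geometric strain, conformational mobility, and significance filtering."""

import numpy as np
import pytest

from allodyn.core import Ensemble
from allodyn.strain import (MobilityProfile, StrainParams, classify_flexibility,
                            geometric_strain, mobility, mobility_difference,
                            sigmoid_weight)
from allodyn.synthetic import build_toy_structure, sample_ensemble, ToyProteinSpec
from allodyn.ed import align

from conftest import all_ca, make_ca_topology, random_ensemble
from test_ed import rigid_images


def brute_force_strain(coords: np.ndarray, params: StrainParams) -> np.ndarray:
    """Triple loop over residues, partners, frames; the independent oracle."""
    T, n, _ = coords.shape
    dbar = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j:
                dbar[i, j] = np.mean([np.linalg.norm(coords[t, i] - coords[t, j])
                                      for t in range(T)])
    p = np.zeros((T, n))
    for t in range(T):
        for i in range(n):
            num = den = 0.0
            for j in range(n):
                if j == i:
                    continue
                w = 1.0 / (1.0 + np.exp((dbar[i, j] - params.d0) / params.w))
                d = np.linalg.norm(coords[t, i] - coords[t, j])
                num += w * (d - dbar[i, j]) ** 2
                den += w
            p[t, i] = num / den if params.normalized else num
    return p


class TestSigmoidWeight:
    def test_midpoint_is_half(self):
        assert sigmoid_weight(7.0) == pytest.approx(0.5, abs=1e-12)

    def test_saturation_at_extremes(self):
        assert sigmoid_weight(0.0) > 0.999
        assert sigmoid_weight(14.0) < 1e-6

    def test_strictly_decreasing(self):
        d = np.linspace(0, 20, 200)
        w = sigmoid_weight(d)
        assert np.all(np.diff(w) < 0)


class TestGeometricStrain:
    def test_rigid_motion_gives_zero_strain(self):
        base = random_ensemble(8, 1, seed=0).coords[0]
        top = make_ca_topology(8)
        ens = Ensemble(topology=top, coords=rigid_images(base, 6, seed=1))
        p = geometric_strain(ens, all_ca(top)).values
        assert np.all(np.abs(p) < 1e-9)

    def test_two_residue_hand_value(self):
        # mean distance 5 Å, instantaneous {4, 6}: deviation² = 1 each frame
        top = make_ca_topology(2)
        c = np.zeros((2, 2, 3))
        c[0, 1, 0] = 4.0
        c[1, 1, 0] = 6.0
        prof = geometric_strain(Ensemble(topology=top, coords=c), all_ca(top))
        assert np.allclose(prof.values, 1.0, atol=1e-12)

    def test_matches_brute_force_oracle(self):
        ens = random_ensemble(10, 20, seed=2)
        params = StrainParams()
        prof = geometric_strain(ens, all_ca(ens.topology), params)
        assert np.allclose(prof.values, brute_force_strain(ens.coords, params), atol=1e-9)

    def test_global_rotation_invariance(self):
        from scipy.spatial.transform import Rotation
        ens = random_ensemble(7, 10, seed=3)
        p0 = geometric_strain(ens, all_ca(ens.topology)).values
        rot = ens.coords.copy()
        for f in range(rot.shape[0]):
            R = Rotation.random(random_state=f).as_matrix()
            rot[f] = rot[f] @ R.T + 5.0
        p1 = geometric_strain(Ensemble(topology=ens.topology, coords=rot),
                              all_ca(ens.topology)).values
        assert np.allclose(p0, p1, atol=1e-9)

    def test_normalization_preserves_ranking_on_homogeneous_ring(self):
        # frames are cyclic rotations of one displacement pattern on a ring,
        # so the mean-distance matrix is circulant, every residue has exactly
        # the same neighbour-weight total, and the two normalizations are
        # proportional residue-wise: the ranking must coincide
        n = 12
        radius = 3.8 / (2 * np.sin(np.pi / n))
        theta = 2 * np.pi * np.arange(n) / n
        base = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                         np.zeros(n)], axis=1)
        rng = np.random.default_rng(4)
        delta = 0.3 * rng.standard_normal((n, 3))
        frames = [np.roll(base + delta, k, axis=0) for k in range(n)]
        ens = Ensemble(topology=make_ca_topology(n), coords=np.stack(frames))
        sel = all_ca(ens.topology)
        prof_n = geometric_strain(ens, sel, StrainParams(normalized=True))
        prof_r = geometric_strain(ens, sel, StrainParams(normalized=False))
        W = sigmoid_weight(prof_n.mean_distances)
        np.fill_diagonal(W, 0)
        wtot = W.sum(axis=1)
        assert np.ptp(wtot) < 1e-9  # homogeneous density: equal weight totals
        # raw sum is the weighted mean times the weight total, residue-wise
        assert np.allclose(prof_r.values, prof_n.values * wtot[None, :], atol=1e-9)
        pn = np.round(prof_n.time_mean, 9)
        pr = np.round(prof_r.time_mean, 9)
        assert np.array_equal(np.argsort(pn, kind="stable"),
                              np.argsort(pr, kind="stable"))


class TestMobility:
    def test_constant_strain_gives_zero_se(self):
        top = make_ca_topology(2)
        c = np.zeros((3, 2, 3))
        c[:, 1, 0] = [4.0, 5.0, 6.0]
        prof = geometric_strain(Ensemble(topology=top, coords=c), all_ca(top))
        prof.values[:] = 2.5
        mob = mobility([prof, prof, prof])
        assert np.allclose(mob.mean, 2.5)
        assert np.allclose(mob.se, 0.0)

    def test_sem_formula(self):
        mob = MobilityProfile(per_run=np.array([[1.0], [2.0], [3.0]]),
                              resids=np.array([1]))
        assert mob.mean[0] == pytest.approx(2.0)
        assert mob.se[0] == pytest.approx(0.5773502692, abs=1e-6)

    def test_single_replica_se_flagged_undefined(self):
        mob = MobilityProfile(per_run=np.array([[1.0, 2.0]]), resids=np.array([1, 2]))
        assert np.all(np.isnan(mob.se))

    def test_replica_mean_within_run_range(self):
        rng = np.random.default_rng(5)
        per_run = rng.uniform(0, 3, (4, 6))
        mob = MobilityProfile(per_run=per_run, resids=np.arange(6))
        assert np.all(mob.mean >= per_run.min(axis=0))
        assert np.all(mob.mean <= per_run.max(axis=0))


class TestMobilityDifference:
    def _profile(self, mean, se, n_runs=3):
        # build per-run values with the requested mean and SE
        mean, se = np.atleast_1d(mean), np.atleast_1d(se)
        # runs at {m+x, m, m-x} have sample std x, hence SE = x/sqrt(3)
        x = se * np.sqrt(n_runs)
        per_run = np.stack([mean + x, mean, mean - x])
        return MobilityProfile(per_run=per_run, resids=np.arange(1, mean.size + 1))

    def test_clear_difference_retained(self):
        a = self._profile([1.0], [0.1])
        b = self._profile([2.0], [0.1])
        d = mobility_difference(a, b)
        assert d.delta[0] == pytest.approx(-1.0, abs=1e-9)
        assert d.error[0] == pytest.approx(np.sqrt(0.02), abs=1e-9)
        assert not d.mask[0]
        assert d.peaks[0][1] == pytest.approx(-1.0, abs=1e-9)

    def test_within_error_masked(self):
        a = self._profile([1.0], [0.5])
        b = self._profile([1.2], [0.5])
        d = mobility_difference(a, b)
        assert d.mask[0]
        assert d.filtered[0] == 0.0
        assert d.peaks == []

    def test_self_comparison_empty(self):
        a = self._profile([1.0, 2.0, 0.5], [0.1, 0.2, 0.1])
        d = mobility_difference(a, a)
        assert np.allclose(d.delta, 0.0)
        assert d.peaks == []

    def test_axis_mismatch_fatal(self):
        a = self._profile([1.0], [0.1])
        b = MobilityProfile(per_run=np.ones((3, 1)), resids=np.array([9]))
        with pytest.raises(ValueError):
            mobility_difference(a, b)


class TestClassifyFlexibility:
    @pytest.mark.parametrize("value,label", [
        (0.39, "rigid"), (0.4, "intermediate"), (1.0, "intermediate"),
        (2.0, "intermediate"), (2.01, "flexible"),
    ])
    def test_band_boundaries_strict(self, value, label):
        mob = MobilityProfile(per_run=np.array([[value]]), resids=np.array([1]))
        assert classify_flexibility(mob)[0] == label

    def test_stiff_limit_all_rigid(self):
        spec = ToyProteinSpec(block_sizes=(15,), block_spring=500.0,
                              background_spring=2.0)
        st = build_toy_structure(spec)
        ens = sample_ensemble(st, spec, "stiff", 100, seed=6)
        sel = all_ca(st.topology)
        mob = mobility([geometric_strain(align(ens, sel), sel)])
        assert np.all(classify_flexibility(mob) == "rigid")


class TestHingeRecovery:
    def test_hinge_is_mobility_maximum(self, two_block_structure):
        """The planted hinge's contact network rearranges most: top strain."""
        spec, st = two_block_structure
        sel = all_ca(st.topology)
        hits = 0
        for seed in range(10):
            ens = sample_ensemble(st, spec, "apo", 200, seed=100 + seed)
            mob = mobility([geometric_strain(align(ens, sel), sel)])
            hits += int(mob.resids[np.argmax(mob.mean)]) == int(st.hinge_residues[0])
        assert hits >= 9
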