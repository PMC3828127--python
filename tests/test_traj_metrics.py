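import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy import stats as sstats

from bridgescope.errors import SuperpositionError
from bridgescope.structure_io import residue_range
from bridgescope.synthetic_data import chain_template, gen_fluctuating_chain
from bridgescope.traj_metrics import (
    GroupComparison,
    ResidueSeries,
    SuperpositionSpec,
    frame_averaged_rmsd,
    per_residue_ttest,
    random_selector,
    rmsd_per_residue,
    rmsf,
    select_alignment_residues,
    state_selector,
    superpose,
)

from conftest import make_ensemble

ANY_ATOM = lambda m: True


def _random_ensemble(n_atoms, n_frames, seed, spread=5.0):
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, spread, (n_frames, n_atoms, 3))
    return make_ensemble(coords, ["CA"] * n_atoms, list(range(1, n_atoms + 1)))


class TestSuperpose:
    def test_pure_rotation_is_recovered_exactly(self):
        ref = _random_ensemble(10, 1, seed=0)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = ref.with_coords((ref.coords[0] @ rot.T)[None])
        both = ref.with_coords(np.concatenate([ref.coords, moved.coords]))
        fitted = superpose(both, SuperpositionSpec(ANY_ATOM))
        np.testing.assert_allclose(fitted.coords[1], ref.coords[0], atol=1e-9)

    def test_reference_to_itself_is_identity(self):
        ens = _random_ensemble(8, 1, seed=1)
        fitted = superpose(ens, SuperpositionSpec(ANY_ATOM))
        np.testing.assert_allclose(fitted.coords, ens.coords, atol=1e-9)

    def test_beats_or_matches_sampled_rotations(self):
        """Kabsch anchor RMSD must match a brute-force minimum over many
        random proper rotations (with optimal translation each time)."""
        rng = np.random.default_rng(7)
        ref = rng.normal(0, 3, (10, 3))
        mob = ref + rng.normal(0, 0.3, (10, 3))
        ens = make_ensemble(np.stack([ref, mob]), ["CA"] * 10, range(1, 11))
        fitted = superpose(ens, SuperpositionSpec(ANY_ATOM))
        kabsch_rmsd = np.sqrt(np.mean(np.sum(
            (fitted.coords[1] - ref) ** 2, axis=1)))
        refc = ref - ref.mean(axis=0)
        mobc = mob - mob.mean(axis=0)

        def score(rot):
            return np.sqrt(np.mean(np.sum((mobc @ rot.as_matrix().T - refc) ** 2,
                                          axis=1)))

        # global sampling then shrinking local perturbations around the best
        best_rot = min(Rotation.random(5000, rng=rng), key=score)
        for angle in (0.3, 0.1, 0.03, 0.01, 0.003):
            for _ in range(3):
                axes = rng.normal(size=(500, 3))
                axes *= angle / np.linalg.norm(axes, axis=1, keepdims=True)
                cands = [Rotation.from_rotvec(a) * best_rot for a in axes]
                best_rot = min(cands + [best_rot], key=score)
        best = score(best_rot)
        assert kabsch_rmsd <= best + 1e-12
        assert kabsch_rmsd == pytest.approx(best, abs=0.005)

    def test_rmsd_invariant_under_rigid_pretransform(self):
        rng = np.random.default_rng(3)
        ens = _random_ensemble(12, 2, seed=3)
        spec = SuperpositionSpec(ANY_ATOM)
        base = superpose(ens, spec)
        rot = Rotation.random(rng=rng).as_matrix()
        moved = ens.coords.copy()
        moved[1] = moved[1] @ rot.T + np.array([5.0, -3.0, 2.0])
        fitted = superpose(ens.with_coords(moved), spec)
        d0 = np.sqrt(np.mean(np.sum((base.coords[1] - base.coords[0]) ** 2, axis=1)))
        d1 = np.sqrt(np.mean(np.sum((fitted.coords[1] - fitted.coords[0]) ** 2, axis=1)))
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_collinear_anchor_rejected(self):
        coords = np.zeros((1, 4, 3))
        coords[0, :, 0] = [0, 1, 2, 3]
        ens = make_ensemble(coords, ["CA"] * 4, range(1, 5))
        with pytest.raises(SuperpositionError, match="collinear"):
            superpose(ens, SuperpositionSpec(ANY_ATOM))


class TestRmsdPerResidue:
    def test_identical_frames_are_zero(self):
        ens = _random_ensemble(6, 2, seed=4)
        ens.coords[1] = ens.coords[0]
        out = rmsd_per_residue(ens, 1, ens)
        assert np.all(out.values == 0)

    def test_single_atom_translation_closed_form(self):
        coords = np.zeros((2, 1, 3))
        coords[1, 0] = (2.0, 0.0, 0.0)
        ens = make_ensemble(coords, ["CA"], [1])
        out = rmsd_per_residue(ens, 1, ens)
        assert out.values[0] == pytest.approx(2.0)

    def test_three_atom_unit_displacements(self):
        coords = np.zeros((2, 3, 3))
        coords[1] = np.eye(3)  # displacements (1,0,0),(0,1,0),(0,0,1)
        ens = make_ensemble(coords, ["N", "CA", "C"], [1, 1, 1])
        out = rmsd_per_residue(ens, 1, ens)
        assert out.values[0] == pytest.approx(1.0)


class TestRmsf:
    def test_static_trajectory_is_zero(self):
        ens = make_ensemble(np.zeros((5, 2, 3)), ["CA", "CA"], [1, 2])
        assert np.all(rmsf(ens).values == 0)

    def test_two_point_oscillation_closed_form(self):
        d = 0.7
        coords = np.zeros((10, 1, 3))
        coords[::2, 0, 0] = d
        coords[1::2, 0, 0] = -d
        ens = make_ensemble(coords, ["CA"], [1])
        assert rmsf(ens).values[0] == pytest.approx(d)

    def test_gaussian_jitter_approaches_sigma_sqrt3(self):
        sigma = 0.4
        rng = np.random.default_rng(12)
        coords = rng.normal(0, sigma, (20000, 1, 3))
        ens = make_ensemble(coords, ["CA"], [1])
        assert rmsf(ens).values[0] == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_single_frame_rejected(self):
        ens = make_ensemble(np.zeros((1, 1, 3)), ["CA"], [1])
        with pytest.raises(ValueError):
            rmsf(ens)


class TestAlignmentResidueSelection:
    def test_quartile_example_by_enumeration(self):
        series = ResidueSeries([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0])
        keep, cutoff = select_alignment_residues(series, 75)
        # linear-interpolation 75th percentile of {1,2,3,4} is 3.25
        assert cutoff == pytest.approx(3.25)
        assert set(keep) == {1, 2, 3}

    def test_all_equal_profile_keeps_everything(self):
        series = ResidueSeries([1, 2, 3], [2.0, 2.0, 2.0])
        keep, cutoff = select_alignment_residues(series)
        assert set(keep) == {1, 2, 3}

    def test_rule_matches_percentile_of_any_profile(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0.5, 8.0, 40)
        series = ResidueSeries(np.arange(1, 41), vals)
        keep, cutoff = select_alignment_residues(series, 75)
        assert set(keep) == set(np.arange(1, 41)[vals < np.percentile(vals, 75)])


class TestFrameAveragedRmsd:
    def _sims(self, n_sims=3, n_frames=20, amp=0.3, seed0=100, n_res=30):
        amps = np.full(n_res, amp)
        return [gen_fluctuating_chain(amps, n_frames, seed=seed0 + i,
                                      anchor=(10, 20))
                for i in range(n_sims)]

    def test_reference_equal_sims_give_zero(self):
        ref = chain_template(20)
        sims = [ref.with_coords(np.repeat(ref.coords, 5, axis=0))]
        spec = SuperpositionSpec(residue_range(5, 15))
        out = frame_averaged_rmsd(sims, spec, ref)
        assert np.allclose(out[0].values, 0, atol=1e-9)

    def test_subsample_fraction_one_is_identity(self):
        ref = chain_template(30)
        sims = self._sims()
        spec = SuperpositionSpec(residue_range(10, 20))
        full = frame_averaged_rmsd(sims, spec, ref)
        sub = frame_averaged_rmsd(sims, spec, ref,
                                  selector=random_selector(1.0, seed=1))
        for a, b in zip(full, sub):
            np.testing.assert_allclose(a.values, b.values)

    def test_amplified_residues_have_higher_mean_rmsd(self):
        n_res = 30
        base = np.full(n_res, 0.25)
        hot = base.copy()
        hot_idx = [3, 4, 25]
        hot[hot_idx] = 0.5
        ref = chain_template(n_res)
        spec = SuperpositionSpec(residue_range(10, 20))
        a = frame_averaged_rmsd(
            [gen_fluctuating_chain(base, 40, seed=s, anchor=(10, 20))
             for s in range(5)], spec, ref)
        b = frame_averaged_rmsd(
            [gen_fluctuating_chain(hot, 40, seed=50 + s, anchor=(10, 20))
             for s in range(5)], spec, ref)
        mean_a = np.mean([s.values for s in a], axis=0)
        mean_b = np.mean([s.values for s in b], axis=0)
        for j in hot_idx:
            assert mean_b[j] > mean_a[j]

    def test_state_filtered_average_independent_of_frame_order(self):
        sims = self._sims(n_sims=1)
        labels = [["A" if i % 3 else "B" for i in range(sims[0].n_frames)]]
        ref = chain_template(30)
        spec = SuperpositionSpec(residue_range(10, 20))
        out1 = frame_averaged_rmsd(sims, spec, ref,
                                   selector=state_selector(labels, "A"))
        perm = np.random.default_rng(0).permutation(sims[0].n_frames)
        sims_p = [sims[0].take_frames(perm)]
        labels_p = [[labels[0][i] for i in perm]]
        out2 = frame_averaged_rmsd(sims_p, spec, ref,
                                   selector=state_selector(labels_p, "A"))
        np.testing.assert_allclose(out1[0].values, out2[0].values, atol=1e-12)

    def test_empty_selection_names_simulation(self):
        sims = self._sims(n_sims=2)
        labels = [["A"] * sims[0].n_frames, ["B"] * sims[1].n_frames]
        ref = chain_template(30)
        spec = SuperpositionSpec(residue_range(10, 20))
        with pytest.raises(Exception, match="simulation 1"):
            frame_averaged_rmsd(sims, spec, ref,
                                selector=state_selector(labels, "A"))


class TestPerResidueTtest:
    def _series(self, rows):
        return [ResidueSeries(np.arange(1, len(r) + 1), r) for r in rows]

    def test_identical_groups_give_p_one(self):
        a = self._series([[1.0, 2.0], [1.0, 2.0]])
        p = per_residue_ttest(GroupComparison(a, a))
        assert np.all(p.values == 1.0)

    def test_textbook_two_sample_pooled(self):
        """a={1..5}, b={2..6}: pooled-variance t = -1.0, df = 8,
        two-tailed p = 2*(1-F_t(1; 8)) = 0.34659 (hand computation)."""
        a = self._series([[v] for v in (1.0, 2.0, 3.0, 4.0, 5.0)])
        b = self._series([[v] for v in (2.0, 3.0, 4.0, 5.0, 6.0)])
        p = per_residue_ttest(GroupComparison(a, b, equal_var=True))
        t_hand = -1.0
        p_hand = 2 * sstats.t.sf(abs(t_hand), df=8)
        assert p.values[0] == pytest.approx(p_hand, abs=1e-3)
        assert p_hand == pytest.approx(0.34659, abs=1e-4)

    def test_type_one_error_calibrated_under_null(self):
        """Null data (both groups same generator): flagged fraction matches
        the nominal level within 3 binomial SDs."""
        rng = np.random.default_rng(77)
        n_trials, alpha, n_sims = 4000, 0.05, 10
        a = [ResidueSeries(np.arange(n_trials), rng.normal(0, 1, n_trials))
             for _ in range(n_sims)]
        b = [ResidueSeries(np.arange(n_trials), rng.normal(0, 1, n_trials))
             for _ in range(n_sims)]
        p = per_residue_ttest(GroupComparison(a, b))
        frac = np.mean(p.values < alpha)
        sd = np.sqrt(alpha * (1 - alpha) / n_trials)
        assert abs(frac - alpha) <= 3 * sd
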