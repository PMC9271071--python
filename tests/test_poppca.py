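"""Subsampled PCA, sign alignment, stability, projections and separations."""

import numpy as np
import pandas as pd
import pytest

from conftest import toy_groups

from twocap.poppca import (
    DEFAULT_EPOCHS,
    PCAError,
    SubsampleDesign,
    align_pc_signs,
    epoch_mean_separation,
    epoch_separation,
    leave_one_out,
    pc_separation,
    pc_stability,
    project_group,
    rate_change_at_changepoint,
    run_separation_analysis,
    run_subsampled_pca,
    shuffle_null,
)
from twocap.preprocess import ConcatenatedProfile


def make_profile(data, groups=None):
    n_units, n_bins = data.shape
    return ConcatenatedProfile(
        data=np.asarray(data, dtype=float),
        unit_ids=[f"u{i}" for i in range(n_units)],
        segment_map={"all": (0, n_bins)},
        groups=groups,
    )


def random_design(n_units, n_iterations=20, n_per_group=10, seed=0):
    return SubsampleDesign(
        group_units={"g": np.asarray([f"u{i}" for i in range(n_units)])},
        n_iterations=n_iterations, n_per_group=n_per_group, seed=seed,
    )


class TestSubsampleDesign:
    def test_group_too_small_raises(self):
        with pytest.raises(PCAError, match="g"):
            SubsampleDesign(group_units={"g": np.arange(5)}, n_per_group=10)

    def test_draws_without_replacement(self):
        d = random_design(30, n_iterations=50, n_per_group=20)
        for sel in d.selections:
            assert len(set(sel["g"])) == 20

    def test_balanced_across_groups(self):
        d = SubsampleDesign(
            group_units={"a": np.arange(30), "b": np.arange(100, 160)},
            n_iterations=5, n_per_group=15, seed=1,
        )
        for k in range(5):
            units = d.iteration_units(k)
            assert len(units) == 30
            assert (units[:15] < 100).all() and (units[15:] >= 100).all()


class TestSubsampledPCA:
    def test_coefficients_orthonormal(self):
        rng = np.random.default_rng(0)
        profile = make_profile(rng.normal(size=(30, 200)))
        res = run_subsampled_pca(profile, random_design(30), n_components=8)
        for k in range(res.n_iterations):
            gram = res.coefficients[k].T @ res.coefficients[k]
            assert np.allclose(gram, np.eye(8), atol=1e-8)

    def test_reconstruction_of_centered_matrix(self):
        rng = np.random.default_rng(1)
        profile = make_profile(rng.normal(size=(20, 100)))
        res = run_subsampled_pca(profile, random_design(20, n_per_group=12),
                                 n_components=None)
        pos = {u: i for i, u in enumerate(profile.unit_ids)}
        for k in range(res.n_iterations):
            rows = [pos[u] for u in res.unit_ids[k]]
            X = profile.data[rows].T
            Xc = X - X.mean(axis=0)
            recon = res.centered_scores(k) @ res.coefficients[k].T
            assert np.allclose(recon, Xc, atol=1e-8)

    def test_rank_one_input_concentrates_on_pc1(self):
        rng = np.random.default_rng(2)
        trace = rng.normal(size=200)
        scal = rng.uniform(0.5, 2.0, size=25)
        data = np.outer(scal, trace) + rng.normal(0, 1e-4, size=(25, 200))
        res = run_subsampled_pca(make_profile(data), random_design(25, n_per_group=15),
                                 n_components=5)
        assert (res.explained_variance_ratio[:, 0] > 0.99).all()


class TestSignAlignment:
    def _result_with_signs(self, signs, seed=3):
        rng = np.random.default_rng(seed)
        trace = np.sin(np.linspace(0, 6, 120))
        data = np.tile(trace, (12, 1)) + rng.normal(0, 0.05, size=(12, 120))
        profile = make_profile(data)
        res = run_subsampled_pca(profile, random_design(12, n_iterations=len(signs),
                                                        n_per_group=8), n_components=3)
        res.scores[:, :, 0] *= np.asarray(signs)[:, None]
        res.coefficients[:, :, 0] *= np.asarray(signs)[:, None]
        return res

    def test_two_inverted_iterations_converge(self):
        res = self._result_with_signs([1.0, -1.0])
        # force the pair to be exact mirrors
        res.scores[1] = -res.scores[0]
        res.coefficients[1] = -res.coefficients[0]
        out = align_pc_signs(res)
        assert np.allclose(out.scores[0], out.scores[1])

    def test_already_aligned_set_unchanged(self):
        res = self._result_with_signs([1.0] * 6)
        aligned = align_pc_signs(res)
        again = align_pc_signs(aligned)
        assert np.array_equal(aligned.scores, again.scores)

    def test_random_sign_flips_all_realigned(self):
        rng = np.random.default_rng(4)
        signs = rng.choice([-1.0, 1.0], size=30)
        res = self._result_with_signs(signs)
        out = align_pc_signs(res)
        mean = out.scores.mean(axis=0)
        mc = mean - mean.mean(axis=0)
        for k in range(30):
            c = out.scores[k, :, 0] - out.scores[k, :, 0].mean()
            assert c @ mc[:, 0] >= 0


class TestStability:
    def test_identical_traces_are_maximally_stable(self):
        res = self._shared_signal_result(noise=0.0)
        stable = pc_stability(res)
        assert npeq_inf(stable.variance_ratio[0]) and stable.stable[0]

    def _shared_signal_result(self, noise, n_iterations=40, seed=5):
        rng = np.random.default_rng(seed)
        trace = np.sin(np.linspace(0, 8, 150))
        data = np.tile(trace, (16, 1)) + (
            rng.normal(0, noise, size=(16, 150)) if noise else 0.0)
        profile = make_profile(data)
        return align_pc_signs(run_subsampled_pca(
            profile, random_design(16, n_iterations=n_iterations, n_per_group=10),
            n_components=4))

    def test_white_noise_rank_unstable_signal_rank_stable(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            trace = np.sin(np.linspace(0, 8, 150))
            # SNR 4 on the shared signal; later ranks are pure noise
            data = (2.0 * np.outer(rng.uniform(0.5, 1.5, 16), trace)
                    + rng.normal(0, 1.0, size=(16, 150)))
            res = align_pc_signs(run_subsampled_pca(
                make_profile(data), random_design(16, n_iterations=30,
                                                  n_per_group=10, seed=seed),
                n_components=4))
            stable = pc_stability(res)
            hits += bool(stable.stable[0]) and not stable.stable[2:].any()
        assert hits >= 9


def npeq_inf(x):
    return np.isinf(x) and x > 0


class TestProjection:
    def test_whole_sample_projection_equals_scores(self):
        rng = np.random.default_rng(6)
        profile = make_profile(rng.normal(size=(10, 80)))
        design = SubsampleDesign(group_units={"g": np.asarray(profile.unit_ids)},
                                 n_iterations=4, n_per_group=10, seed=0)
        res = run_subsampled_pca(profile, design, n_components=3)
        traj = project_group(profile, res, "g")
        assert np.allclose(traj.data, res.scores.mean(axis=0), atol=1e-10)

    def test_hand_dot_product(self):
        profile = make_profile(np.array([[1.0], [2.0]]))
        design = SubsampleDesign(group_units={"g": np.asarray(["u0", "u1"])},
                                 n_iterations=1, n_per_group=2, seed=0)
        res = run_subsampled_pca(profile, design, n_components=1)
        res.coefficients[0][:, 0] = [0.6, 0.8]
        traj = project_group(profile, res, "g")
        assert np.isclose(traj.data[0, 0], 0.6 * 1.0 + 0.8 * 2.0)

    def test_projection_is_linear(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(10, 60))
        b = rng.normal(size=(10, 60))
        design = SubsampleDesign(
            group_units={"g": np.asarray([f"u{i}" for i in range(10)])},
            n_iterations=3, n_per_group=6, seed=1)
        res = run_subsampled_pca(make_profile(a), design, n_components=3)
        ta = project_group(make_profile(a), res, "g").data
        tb = project_group(make_profile(b), res, "g").data
        tab = project_group(make_profile(a + b), res, "g").data
        assert np.allclose(tab, ta + tb, atol=1e-10)

    def test_unknown_group_raises(self):
        rng = np.random.default_rng(8)
        profile = make_profile(rng.normal(size=(10, 40)))
        res = run_subsampled_pca(profile, random_design(10, n_iterations=2,
                                                        n_per_group=5), n_components=2)
        with pytest.raises(PCAError):
            project_group(profile, res, "nope")


class TestSeparation:
    def test_identical_trajectories_zero(self):
        t = np.random.default_rng(9).normal(size=(30, 4))
        assert np.all(pc_separation(t, t).values == 0.0)

    def test_constant_offset_single_pc(self):
        t = np.zeros((10, 1))
        s = pc_separation(t, t - 2.5)
        assert np.allclose(s.values, 2.5)

    def test_pythagoras(self):
        a = np.zeros((1, 2))
        b = np.array([[3.0, 4.0]])
        assert np.isclose(pc_separation(a, b).values[0], 5.0)

    def test_symmetry_bitwise(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(size=(2, 25, 3))
        assert np.array_equal(pc_separation(a, b).values, pc_separation(b, a).values)

    def test_mismatched_windows_error(self):
        with pytest.raises(PCAError):
            pc_separation(np.zeros((5, 2)), np.zeros((6, 2)))

    def test_default_epochs_are_20_bins(self):
        for ep in DEFAULT_EPOCHS.values():
            assert ep.window_a.stop - ep.window_a.start == 20
            assert ep.window_b.stop - ep.window_b.start == 20

    def test_epoch_mean_of_ramp(self):
        from twocap.poppca import SeparationSeries
        series = SeparationSeries(values=np.arange(1.0, 21.0), n_pcs=1)
        summary = epoch_mean_separation(series)
        assert summary.mean == 10.5 and summary.n_bins == 20

    def test_epoch_mean_of_constant(self):
        from twocap.poppca import SeparationSeries
        series = SeparationSeries(values=np.full(20, 3.3), n_pcs=1)
        assert np.isclose(epoch_mean_separation(series).mean, 3.3)


class TestSeparationAnalysis:
    def test_planted_seek_signal_separates_seek_epoch(self):
        groups = toy_groups(seed=0, seek_effect=2.0)
        res = run_separation_analysis(groups, n_iterations=10, n_per_group=20,
                                      n_components=6, seed=0)
        e = res.epoch_summaries.set_index("epoch")["mean_separation"]
        assert e["seeking"] > 3 * e["drink"]
        assert e["seeking"] > 3 * e["approach"]

    def test_shuffle_identity_reproduces_observed(self):
        groups = toy_groups(seed=1)
        kw = dict(n_iterations=8, n_per_group=15, n_components=4, seed=2)
        res = run_separation_analysis(groups, **kw)
        obs = res.epoch_summaries.query("epoch == 'seeking'")["mean_separation"].iloc[0]
        ident = [{"g": np.arange(len(groups["g"].labels["seek"]))}]
        null = shuffle_null(groups, "seeking", permutations=ident, **kw)
        assert np.isclose(null["mean_separation"].iloc[0], obs)

    def test_shuffling_destroys_planted_separation(self):
        groups = toy_groups(seed=2, seek_effect=2.0)
        kw = dict(n_iterations=8, n_per_group=15, n_components=4, seed=3)
        res = run_separation_analysis(groups, **kw)
        obs = res.epoch_summaries.query("epoch == 'seeking'")["mean_separation"].iloc[0]
        null = shuffle_null(groups, "seeking", n_shuffles=20, shuffle_seed=4, **kw)
        assert obs > np.quantile(null["mean_separation"], 0.95)


class TestLeaveOneOut:
    def test_one_recomputation_per_animal(self):
        groups = toy_groups(seed=3, n_units=30)
        out = leave_one_out(groups, n_iterations=6, n_per_group=12,
                            n_components=3, seed=5)
        assert set(out["holdout"]) == {"a0", "a1", "a2"}
        assert len(out) == 3 * len(DEFAULT_EPOCHS)

    def test_cloned_animals_give_identical_summaries(self):
        groups = toy_groups(seed=4, n_units=30, noise=0.0)
        # make every unit identical -> any holdout sees the same data
        for gd in groups.values():
            for t in gd.tensors.values():
                t.data[:] = t.data[0]
        out = leave_one_out(groups, n_iterations=5, n_per_group=10,
                            n_components=2, seed=6)
        spread = out.groupby("epoch")["mean_separation"].agg(lambda s: s.max() - s.min())
        assert (spread < 1e-6).all()

    def test_emptying_holdout_skipped(self):
        groups = toy_groups(seed=5, n_units=30)
        groups["g"].animals = np.asarray(["solo"] * 30)
        out = leave_one_out(groups, n_iterations=5, n_per_group=10,
                            n_components=2, seed=7)
        assert out.empty


class TestRateChangeAtChangePoint:
    def test_exact_step(self):
        rates = np.vstack([np.r_[np.full(10, 5.0), np.full(10, 10.0)]] * 3)
        obs, null = rate_change_at_changepoint(rates, j_scp=11, seed=0)
        assert obs == 5.0
        assert np.all(null == 0.0)

    def test_constant_rates(self):
        rates = np.full((4, 20), 7.0)
        obs, null = rate_change_at_changepoint(rates, j_scp=10, seed=1)
        assert obs == 0.0 and np.all(null == 0.0)

    def test_planted_step_beats_jitter_null(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            rates = np.r_[np.full(24, 4.0), np.full(24, 8.0)] + rng.normal(
                0, 0.5, size=(30, 48))
            obs, null = rate_change_at_changepoint(rates, j_scp=25, seed=seed)
            wins += obs > null.mean()
        assert wins >= 19

    def test_edge_change_point_rejected(self):
        with pytest.raises(PCAError):
            rate_change_at_changepoint(np.zeros((2, 20)), j_scp=3, jitter_max=2)
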