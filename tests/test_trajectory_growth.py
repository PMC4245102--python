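import numpy as np
import pytest

from courttrack.ball_detection import BallCandidate
from courttrack.trajectory_growth import (
    GrowthConfig,
    Trajectory,
    extend,
    extrapolate,
    fit_trajectory,
    grow_trajectories,
    merge_collinear,
    seed_trajectories,
    select_parallel,
)

H = 480  # frame height used throughout


def cand(t, x, y_height):
    return BallCandidate(frame=t, x_px=x, y_px=H - y_height, area=50, margin=0)


def arc_candidates(a2, a1, a0, m, b, frames):
    return [cand(t, m * t + b, a2 * t * t + a1 * t + a0) for t in frames]


class TestFitTrajectory:
    def test_exact_recovery_noiseless(self):
        members = arc_candidates(-0.5, 10, 3, 2, 7, range(6))
        a2, a1, a0, mm, bb = fit_trajectory(members, H)
        assert np.allclose([a2, a1, a0, mm, bb], [-0.5, 10, 3, 2, 7], rtol=1e-9)

    def test_two_members_line_only(self):
        members = arc_candidates(0, 5, 1, 2, 7, range(2))
        a2, a1, a0, mm, bb = fit_trajectory(members, H)
        assert a2 == 0.0
        assert (mm, bb) == pytest.approx((2.0, 7.0))

    def test_single_frame_rank_error(self):
        with pytest.raises(np.linalg.LinAlgError):
            fit_trajectory([cand(3, 1, 1), cand(3, 2, 2), cand(3, 3, 3)], H)

    def test_noisy_coefficients_within_3x_analytic_se(self, rng):
        """sigma=1 px noise: errors bounded by the LS covariance oracle."""
        frames = np.arange(20)
        x_design = np.column_stack([frames, np.ones(20)])
        y_design = np.column_stack([frames**2, frames, np.ones(20)])
        se_x = np.sqrt(np.diag(np.linalg.inv(x_design.T @ x_design)))
        se_y = np.sqrt(np.diag(np.linalg.inv(y_design.T @ y_design)))
        violations = 0
        total = 0
        for _ in range(200):
            noise_x = rng.normal(0, 1, 20)
            noise_y = rng.normal(0, 1, 20)
            members = [
                cand(t, 2 * t + 7 + nx, -0.4 * t * t + 9 * t + 5 + ny)
                for t, nx, ny in zip(frames, noise_x, noise_y)
            ]
            a2, a1, a0, m, b = fit_trajectory(members, H)
            errs = np.abs(
                np.array([a2 + 0.4, a1 - 9, a0 - 5, m - 2, b - 7])
            )
            bounds = 3 * np.concatenate([se_y, se_x])
            violations += int((errs > bounds).sum())
            total += 5
        assert violations / total < 0.02  # 3-sigma band holds ~99.7%


class TestSeeding:
    def test_three_close_collinear_candidates_spawn_one(self):
        buf = [cand(0, 100, 50), cand(1, 108, 50), cand(2, 116, 50)]
        seeds = seed_trajectories(buf, GrowthConfig(), H)
        assert len(seeds) == 1
        assert len(seeds[0].members) == 3

    def test_distance_gate_blocks(self):
        buf = [cand(0, 100, 50), cand(1, 108, 50), cand(2, 125, 50)]
        assert seed_trajectories(buf, GrowthConfig(), H) == []

    def test_collinearity_gate_blocks(self):
        buf = [cand(0, 100, 50), cand(1, 108, 58), cand(2, 100, 66)]
        assert seed_trajectories(buf, GrowthConfig(), H) == []

    def test_four_consistent_candidates_one_trajectory(self):
        cands = {t: [cand(t, 100 + 8 * t, 50)] for t in range(4)}
        trajs = grow_trajectories(cands, GrowthConfig(), H, n_frames=4)
        assert len(trajs) == 1
        assert len(trajs[0].members) == 4


class TestExtend:
    def _growing(self):
        traj = Trajectory(frame_height=H, members=arc_candidates(-0.5, 10, 3, 2, 7, range(3)))
        traj.refit()
        return traj

    def test_candidate_at_prediction_absorbed(self):
        traj = self._growing()
        traj.missing_run = 2
        nxt = arc_candidates(-0.5, 10, 3, 2, 7, [3])
        extend(traj, nxt, GrowthConfig(), 3)
        assert len(traj.members) == 4
        assert traj.missing_run == 0

    def test_four_missing_frames_terminate(self):
        traj = self._growing()
        for t in range(3, 7):
            extend(traj, [], GrowthConfig(), t)
        assert traj.status == "terminated"
        assert traj.frame_end == 2

    def test_three_missing_frames_keep_growing(self):
        traj = self._growing()
        for t in range(3, 6):
            extend(traj, [], GrowthConfig(), t)
        assert traj.status == "growing"

    def test_tie_broken_toward_lower_x(self):
        traj = self._growing()
        px, py = traj.predict(3)
        a = cand(3, px - 3, H - (py + 0))
        b = cand(3, px + 3, H - (py + 0))
        a.y_px, b.y_px = py, py
        extend(traj, [b, a], GrowthConfig(), 3)
        assert traj.members[-1] is a


class TestSelectParallel:
    def _traj(self, f0, f1, n=None, jitter=0.0):
        frames = list(range(f0, f1 + 1))
        if n is not None:
            frames = frames[:n]
        members = arc_candidates(-0.5, 10, 3, 2, 7, frames)
        for i, c in enumerate(members):
            c.y_px += jitter * (-1) ** i
        t = Trajectory(frame_height=H, members=members)
        t.refit()
        return t

    def test_overlapping_keep_higher_count(self):
        a = self._traj(0, 7)
        b = self._traj(2, 5)
        kept = select_parallel([a, b])
        assert kept == [a]

    def test_equal_count_keep_lower_residual(self):
        a = self._traj(0, 5, jitter=2.0)
        b = self._traj(0, 5, jitter=0.5)
        kept = select_parallel([a, b])
        assert kept == [b]

    def test_disjoint_both_kept(self):
        a = self._traj(0, 5)
        b = self._traj(10, 15)
        assert len(select_parallel([a, b])) == 2

    def test_output_overlap_free_on_random_inputs(self, rng):
        trajs = []
        for _ in range(30):
            f0 = int(rng.integers(0, 80))
            f1 = f0 + int(rng.integers(3, 15))
            trajs.append(self._traj(f0, f1))
        kept = select_parallel(trajs)
        for i, a in enumerate(kept):
            for b in kept[i + 1 :]:
                assert a.frame_end < b.frame_start or b.frame_end < a.frame_start


class TestExtrapolate:
    def test_gap_meeting_at_model_intersection(self):
        a = Trajectory(frame_height=H, members=arc_candidates(-1, 20, 0, 1, 0, range(0, 9)))
        b = Trajectory(frame_height=H, members=arc_candidates(-1, 30, -250, 1, 0, range(16, 25)))
        a.refit(), b.refit()
        extrapolate([a, b])
        # height parabolas -t^2+20t and -t^2+30t-250 intersect at t=25,
        # outside the gap (8, 16) -> neighbours meet at the gap midpoint 12
        assert a.ext_end == 12
        assert b.ext_start == 12

    def test_single_trajectory_extends_to_clip_bounds(self):
        a = Trajectory(frame_height=H, members=arc_candidates(-1, 20, 0, 1, 0, range(5, 10)))
        a.refit()
        out = extrapolate([a], clip_start=0, clip_end=30)
        assert a.ext_start == 0 and a.ext_end == 30
        assert a.covers(0) and a.covers(30)

    def test_members_unchanged_by_extension(self):
        a = Trajectory(frame_height=H, members=arc_candidates(-1, 20, 0, 1, 0, range(5, 10)))
        a.refit()
        snapshot = [(c.frame, c.x_px, c.y_px) for c in a.members]
        extrapolate([a], clip_start=0, clip_end=30)
        assert [(c.frame, c.x_px, c.y_px) for c in a.members] == snapshot


class TestMergeCollinear:
    def test_fragments_of_one_arc_fused(self):
        a = Trajectory(frame_height=H, members=arc_candidates(-0.5, 10, 3, 2, 7, range(0, 5)))
        b = Trajectory(frame_height=H, members=arc_candidates(-0.5, 10, 3, 2, 7, range(10, 15)))
        a.refit(), b.refit()
        out = merge_collinear([a, b])
        assert len(out) == 1
        assert len(out[0].members) == 10

    def test_different_arcs_untouched(self):
        a = Trajectory(frame_height=H, members=arc_candidates(-0.5, 10, 3, 2, 7, range(0, 5)))
        b = Trajectory(frame_height=H, members=arc_candidates(-0.5, 40, -200, -1, 300, range(10, 15)))
        a.refit(), b.refit()
        assert len(merge_collinear([a, b])) == 2


def test_six_arc_rally_recovered_end_to_end():
    """Noiseless candidates from 6 ballistic arcs: all arcs recovered with
    >=90% member coverage of the candidate frames."""
    import courttrack.synthetic_scene as ss
    from courttrack.pipeline import BallConfig, ball_from_candidates

    sc = ss.rally_scenario(seed=11)
    df, coeffs = ss.render_rally(sc.ball, sc.homography(), sc.fps, 480)
    cands = ss.truth_candidates(df)
    res = ball_from_candidates(cands, BallConfig(), 480, sc.n_frames)
    trajs = res["growth"]["trajectories"]
    assert len(trajs) == 6
    covered = sum(len(t.members) for t in trajs)
    assert covered >= 0.9 * len(df)
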