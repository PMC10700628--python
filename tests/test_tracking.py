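"""Tests of background subtraction, spot detection, linking and drift removal."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from chemokit import (
    Calibration,
    ImagingParams,
    SimulationParams,
    TrackingConfig,
    TrajectorySet,
    correct_drift,
    detect_spots,
    link,
    median_background,
    render_video,
    simulate_run_and_tumble,
    subtract_background,
    track_stack,
)
from conftest import brute_force_assignment


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

class TestMedianBackground:
    def test_constant_stack_leaves_zero_residual(self):
        stack = np.full((5, 8, 8), 37, dtype=np.uint16)
        bg = median_background(stack)
        np.testing.assert_array_equal(bg, 37)
        np.testing.assert_array_equal(subtract_background(stack, bg), 0)

    def test_transient_particle_does_not_enter_background(self):
        """A pixel occupied < 50% of frames keeps its pattern value."""
        pattern = np.arange(64, dtype=np.uint16).reshape(8, 8)
        stack = np.repeat(pattern[None], 9, axis=0).copy()
        stack[:4, 3, 3] += 1000   # particle present in 4 of 9 frames
        bg = median_background(stack)
        assert bg[3, 3] == pattern[3, 3]

    def test_rendered_video_background_recovered_within_noise_bound(self):
        """Estimated background vs truth, bounded by the brute-force
        per-pixel median of pure noise at the same sd."""
        rng = np.random.default_rng(0)
        pattern = rng.uniform(0, 50, size=(48, 48))
        n_frames, noise_sd = 41, 5.0
        df = pd.DataFrame({"particle": 0, "frame": range(n_frames),
                           "x_um": np.linspace(2, 12, n_frames),
                           "y_um": 8 * 0.326})
        img = ImagingParams(frame_shape=(48, 48), background_level=200.0,
                            background_pattern=pattern, noise_sd=noise_sd, seed=1)
        stack = render_video(TrajectorySet(df), img)
        est = median_background(stack.frames)
        truth = 200.0 + pattern
        # oracle: sd of a median of n_frames noise draws, simulated directly
        sim = np.median(rng.normal(0, noise_sd, size=(200000, n_frames)), axis=1)
        bound = 6 * sim.std() + 1.0   # +1 for uint16 quantisation
        off_track = np.abs(est - truth)
        off_track[6:10, :] = 0        # rows the moving spot visits
        assert off_track.max() <= bound

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            median_background(np.zeros((1, 4, 4)))


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------

def _render_spots(positions_px, shape=(96, 96), amplitude=3000.0, noise=0.0,
                  seed=0):
    df = pd.DataFrame({
        "particle": range(len(positions_px)),
        "frame": 0,
        "x_um": [p[0] * 0.326 for p in positions_px],
        "y_um": [p[1] * 0.326 for p in positions_px],
    })
    img = ImagingParams(frame_shape=shape, spot_amplitude=amplitude,
                        background_level=0.0, noise_sd=noise, seed=seed)
    return render_video(TrajectorySet(df), img).frames[0]


class TestDetectSpots:
    def test_single_spot_centroid_within_tenth_pixel(self):
        frame = _render_spots([(40.3, 55.7)])
        det = detect_spots(frame, TrackingConfig(min_separation=10))
        assert len(det) == 1
        assert abs(det.iloc[0]["x"] - 40.3) < 0.1
        assert abs(det.iloc[0]["y"] - 55.7) < 0.1

    def test_close_pair_keeps_brighter(self):
        frame = _render_spots([(20.0, 48.0)], amplitude=2000.0).astype(np.float64)
        frame += _render_spots([(60.0, 48.0)], amplitude=3000.0)  # 40 px apart
        det = detect_spots(frame, TrackingConfig(min_separation=51))
        assert len(det) == 1
        assert abs(det.iloc[0]["x"] - 60.0) < 0.5   # the brighter one

    def test_blank_frame_detects_nothing(self):
        det = detect_spots(np.zeros((32, 32)), TrackingConfig())
        assert len(det) == 0

    def test_pairwise_separation_invariant(self):
        rng = np.random.default_rng(5)
        pos = [(x, y) for x, y in rng.uniform(10, 86, size=(12, 2))]
        frame = _render_spots(pos, noise=10.0, seed=5)
        det = detect_spots(frame, TrackingConfig(min_separation=15))
        if len(det) > 1:
            assert pdist(det[["x", "y"]].to_numpy()).min() >= 15


# ---------------------------------------------------------------------------
# linking
# ---------------------------------------------------------------------------

class TestLink:
    def test_single_particle_yields_single_full_track(self):
        det = pd.DataFrame({"frame": range(10),
                            "x": np.linspace(0, 20, 10), "y": 5.0})
        trajs = link(det, TrackingConfig())
        assert len(trajs) == 1
        assert trajs.data["frame"].tolist() == list(range(10))

    def test_jump_beyond_gate_breaks_track(self):
        x = [0.0, 5.0, 10.0, 42.5, 47.5]   # 32.5 px jump at frame 3
        det = pd.DataFrame({"frame": range(5), "x": x, "y": 0.0})
        trajs = link(det, TrackingConfig(max_displacement=31.0))
        assert len(trajs) == 2
        lengths = trajs.data.groupby("particle").size().tolist()
        assert sorted(lengths) == [2, 3]

    def test_no_linked_step_exceeds_gate(self):
        rng = np.random.default_rng(2)
        frames = []
        for f in range(12):
            n = rng.integers(2, 6)
            frames.append(pd.DataFrame({
                "frame": f, "x": rng.uniform(0, 100, n),
                "y": rng.uniform(0, 100, n)}))
        trajs = link(pd.concat(frames), TrackingConfig(max_displacement=20.0))
        px = trajs.with_pixel_columns()
        for _, g in px.groupby("particle"):
            contig = g["frame"].diff() == 1
            steps = np.hypot(g["x"].diff(), g["y"].diff())[contig]
            assert (steps <= 20.0 + 1e-9).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_assignment_oracle(self, seed):
        """Frame-pair assignments equal the brute-force gated optimum."""
        rng = np.random.default_rng(seed)
        max_disp = 12.0
        frames = []
        for f in range(10):
            n = rng.integers(1, 7)
            frames.append(pd.DataFrame({
                "frame": f, "x": rng.uniform(0, 60, n),
                "y": rng.uniform(0, 60, n)}))
        det = pd.concat(frames, ignore_index=True)
        trajs = link(det, TrackingConfig(max_displacement=max_disp))
        px = trajs.with_pixel_columns()

        by_frame = {
            f: g[["x", "y"]].to_numpy()
            for f, g in det.groupby("frame")
        }
        for f in range(9):
            want_links, want_cost = brute_force_assignment(
                by_frame[f], by_frame[f + 1], max_disp)
            got_links, got_cost = 0, 0.0
            for _, g in px.groupby("particle"):
                g = g.set_index("frame")
                if f in g.index and f + 1 in g.index:
                    got_links += 1
                    got_cost += ((g.loc[f + 1, ["x", "y"]].to_numpy()
                                  - g.loc[f, ["x", "y"]].to_numpy()) ** 2).sum()
            assert got_links == want_links
            assert got_cost == pytest.approx(want_cost, rel=1e-9)

    def test_memory_bridges_single_frame_gaps(self):
        det = pd.DataFrame({"frame": [0, 1, 3, 4],
                            "x": [0.0, 5.0, 15.0, 20.0], "y": 0.0})
        no_mem = link(det, TrackingConfig(max_displacement=10.0, memory=0))
        with_mem = link(det, TrackingConfig(max_displacement=10.0, memory=1))
        assert len(no_mem) == 2
        assert len(with_mem) == 1

    def test_short_tracks_dropped(self):
        det = pd.DataFrame({"frame": [0, 1, 2, 0],
                            "x": [0.0, 1.0, 2.0, 90.0], "y": 0.0})
        trajs = link(det, TrackingConfig(min_track_length=3))
        assert len(trajs) == 1


# ---------------------------------------------------------------------------
# drift correction
# ---------------------------------------------------------------------------

class TestCorrectDrift:
    @staticmethod
    def _jitter_set(drift=(0.0, 0.0), n_cells=40, n_frames=80, seed=8):
        params = SimulationParams(
            n_cells=n_cells, duration=(n_frames - 1) / 30.0,
            nonmotile_fraction=1.0, nonmotile_jitter_sd=0.05,
            drift_velocity=drift, noise_sd=0.0, seed=seed)
        return simulate_run_and_tumble(params)

    def test_zero_drift_is_near_identity(self):
        ts = self._jitter_set()
        out = correct_drift(ts)
        # the (small, spurious) correction never exceeds the jitter scale
        diff = np.abs(out.data[["x_um", "y_um"]].to_numpy()
                      - ts.data[["x_um", "y_um"]].to_numpy())
        assert diff.max() < 0.5

    def test_constant_drift_removed_up_to_offset(self):
        clean = self._jitter_set(drift=(0.0, 0.0))
        drifted = self._jitter_set(drift=(8.0, -5.0))
        corrected = correct_drift(drifted)
        resid = (corrected.data[["x_um", "y_um"]].to_numpy()
                 - clean.data[["x_um", "y_um"]].to_numpy())
        resid -= resid.mean(axis=0)     # constant offset is allowed
        # residual stays within the spurious-correction scale of the
        # ensemble median over 40 jittering cells
        assert np.abs(resid).max() < 0.5

    def test_single_trajectory_returned_unchanged_with_warning(self):
        df = pd.DataFrame({"particle": 0, "frame": range(5),
                           "x_um": np.arange(5.0), "y_um": 0.0})
        ts = TrajectorySet(df)
        with pytest.warns(UserWarning, match="drift"):
            out = correct_drift(ts)
        pd.testing.assert_frame_equal(out.data, ts.data)


# ---------------------------------------------------------------------------
# full round trip
# ---------------------------------------------------------------------------

def _match_tracks(truth_px: pd.DataFrame, rec_px: pd.DataFrame, radius=2.0):
    """Per-frame nearest-neighbour matching of recovered to true positions.

    Returns (fraction of true positions matched, RMS position error in px,
    per-true-track lists of matched recovered ids).
    """
    n_match, n_tot, sq = 0, 0, []
    id_map: dict = {}
    for f, tg in truth_px.groupby("frame"):
        rg = rec_px[rec_px["frame"] == f].reset_index(drop=True)
        for _, row in tg.iterrows():
            n_tot += 1
            if not len(rg):
                continue
            d = np.hypot(rg["x"] - row["x"], rg["y"] - row["y"])
            j = d.idxmin()
            if d[j] < radius:
                n_match += 1
                sq.append(d[j] ** 2)
                id_map.setdefault(row["particle"], []).append(rg.loc[j, "particle"])
    rms = float(np.sqrt(np.mean(sq))) if sq else np.inf
    return n_match / n_tot, rms, id_map


def _identity_recovery(truth_px, id_map):
    """Fraction of true tracks covered >= 80% by one recovered id."""
    ok = 0
    for pid, ids in id_map.items():
        _, counts = np.unique(ids, return_counts=True)
        if counts.max() / (truth_px["particle"] == pid).sum() >= 0.8:
            ok += 1
    return ok / truth_px["particle"].nunique()


def simulate_render_track(seed, n_cells=12, duration=1.5, min_sep=5.0):
    """One round-trip instance on a 256 x 256 px downscaled field."""
    arena = (250 * 0.326, 250 * 0.326)
    params = SimulationParams(
        n_cells=n_cells, duration=duration, frame_rate=30.0, mean_speed=30.0,
        speed_sd=6.0, tumble_rate=0.5, nonmotile_fraction=0.0, noise_sd=0.0,
        arena=arena, boundary="reflect", seed=seed)
    ts = simulate_run_and_tumble(params)
    img = ImagingParams(frame_shape=(256, 256), psf_sigma=1.5,
                        spot_amplitude=3000.0, background_level=300.0,
                        noise_sd=15.0, seed=seed)
    stack = render_video(ts, img)
    cfg = TrackingConfig(min_separation=min_sep, min_track_length=5)
    rec = track_stack(stack, cfg, drift_correct=False)
    return ts, rec, cfg


def _ground_truth_separated(truth_px, min_sep):
    return all(pdist(g[["x", "y"]].to_numpy()).min() >= min_sep
               for _, g in truth_px.groupby("frame"))


def test_round_trip_recovers_identities_and_positions():
    """simulate -> render -> track: with true tracks staying >= min_separation
    apart and per-frame motion below half the gate, >= 95% of identities are
    recovered and positions agree within 0.5 px RMS."""
    cfg = TrackingConfig(min_separation=5.0)
    chosen = None
    for seed in range(10):    # first scene satisfying the stated precondition
        ts, rec, cfg = simulate_render_track(seed)
        truth_px = ts.with_pixel_columns()
        steps = truth_px.groupby("particle").apply(
            lambda g: np.hypot(g["x"].diff(), g["y"].diff()).max(),
            include_groups=False).max()
        if _ground_truth_separated(truth_px, cfg.min_separation) and \
                steps < cfg.max_displacement / 2:
            chosen = (ts, rec)
            break
    assert chosen is not None, "no scene met the separation precondition"
    ts, rec = chosen
    truth_px = ts.with_pixel_columns()
    rec_px = rec.with_pixel_columns()
    frac, rms, id_map = _match_tracks(truth_px, rec_px)
    assert frac >= 0.95
    assert rms <= 0.5
    assert _identity_recovery(truth_px, id_map) >= 0.95


def test_round_trip_position_rms_with_twenty_spots():
    """20 moving spots: recovered positions within 0.5 px RMS of truth."""
    ts, rec, _ = simulate_render_track(seed=7, n_cells=20, duration=2.0)
    frac, rms, _ = _match_tracks(ts.with_pixel_columns(), rec.with_pixel_columns())
    assert frac >= 0.9
    assert rms <= 0.5


def test_calibration_units_consistent():
    cal = Calibration(pixel_size_um=0.326, frame_rate_hz=25.0)
    df = pd.DataFrame({"particle": 0, "frame": [0, 1], "x_um": [3.26, 6.52],
                       "y_um": [0.0, 0.0]})
    px = TrajectorySet(df, cal).with_pixel_columns()
    np.testing.assert_allclose(px["x"], [10.0, 20.0])
    np.testing.assert_allclose(px["t_s"], [0.0, 0.04])
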