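import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reachfit import (
    MarkerTrajectory,
    TrialFormatError,
    TrialRecording,
    gap_fill,
    mirror_x,
    read_trial,
    smooth,
    write_trial,
)
from reachfit.trial_io import MARKER_LABELS

from conftest import make_trajectory


def _tiny_recording(n=8, rate=120.0, rng=None):
    rng = rng or np.random.default_rng(0)
    markers = {}
    for label in MARKER_LABELS:
        pos = rng.uniform(-500, 500, (n, 3)).round(4)
        valid = np.ones(n, bool)
        markers[label] = MarkerTrajectory(label, pos, valid, rate)
    return TrialRecording(markers=markers, goal_visible_frame=2,
                          condition="90", hand="left", group_label="g",
                          trial_id="t01")


class TestTsvRoundTrip:
    def test_simulated_trial_round_trips_to_6_decimals(self, tmp_path,
                                                       adult_trial):
        rec, _ = adult_trial
        path = tmp_path / "trial.tsv"
        write_trial(rec, path)
        back = read_trial(path)
        assert back.condition == rec.condition
        assert back.goal_visible_frame == rec.goal_visible_frame
        assert back.hand == rec.hand and back.trial_id == rec.trial_id
        for label in MARKER_LABELS:
            a, b = rec.markers[label], back.markers[label]
            assert np.array_equal(a.valid, b.valid)
            assert np.allclose(a.positions[a.valid], b.positions[b.valid],
                               atol=5e-7)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), drop=st.integers(0, 5))
    def test_round_trip_preserves_any_valid_recording(self, tmp_path_factory,
                                                      seed, drop):
        rng = np.random.default_rng(seed)
        rec = _tiny_recording(rng=rng)
        # knock out `drop` interior frames of one marker
        tr = rec.markers["peg_a"]
        for f in rng.integers(1, tr.n_frames - 1, size=drop):
            tr.valid[f] = False
            tr.positions[f] = np.nan
        path = tmp_path_factory.mktemp("io") / "t.tsv"
        write_trial(rec, path)
        back = read_trial(path)
        for label in MARKER_LABELS:
            a, b = rec.markers[label], back.markers[label]
            assert np.array_equal(a.valid, b.valid)
            assert np.allclose(a.positions[a.valid], b.positions[b.valid],
                               atol=5e-7)

    def test_blank_cell_becomes_invalid_frame(self, tmp_path):
        rec = _tiny_recording()
        rec.markers["peg_a"].valid[5] = False
        rec.markers["peg_a"].positions[5] = np.nan
        path = tmp_path / "t.tsv"
        write_trial(rec, path)
        back = read_trial(path)
        assert not back.markers["peg_a"].valid[5]
        assert back.markers["peg_a"].valid[4]

    def test_missing_marker_column_is_a_format_error(self, tmp_path):
        rec = _tiny_recording()
        path = tmp_path / "t.tsv"
        write_trial(rec, path)
        lines = path.read_text().splitlines()
        header = lines[6].replace("peg_a_x", "bogus_x")
        path.write_text("\n".join(lines[:6] + [header] + lines[7:]) + "\n")
        with pytest.raises(TrialFormatError):
            read_trial(path)

    def test_inconsistent_column_count_is_a_format_error(self, tmp_path):
        rec = _tiny_recording()
        path = tmp_path / "t.tsv"
        write_trial(rec, path)
        lines = path.read_text().splitlines()
        lines[8] = lines[8] + "\t1.0"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrialFormatError):
            read_trial(path)


class TestGapFill:
    def _linear_with_gap(self, gap, n=60):
        pos = np.outer(np.arange(n, dtype=float), [2.0, -1.0, 0.5])
        valid = np.ones(n, bool)
        lo = 20
        valid[lo : lo + gap] = False
        pos_nan = pos.copy()
        pos_nan[~valid] = np.nan
        return make_trajectory(pos_nan, valid=valid), pos

    def test_short_gap_in_linear_motion_filled_exactly(self):
        traj, truth = self._linear_with_gap(4)
        out = gap_fill(traj, max_auto=10)
        assert out.valid.all()
        assert np.allclose(out.positions, truth, atol=1e-8)
        assert out.imputed.sum() == 4

    def test_medium_gap_needs_manual_approval(self):
        traj, truth = self._linear_with_gap(15)
        out = gap_fill(traj, max_auto=10, max_manual=20, allow_manual=False)
        assert not out.valid[20:35].any()
        assert out.exclude_reason is None
        out2 = gap_fill(traj, max_auto=10, max_manual=20, allow_manual=True)
        assert out2.valid.all()
        assert np.allclose(out2.positions, truth, atol=1e-8)

    def test_long_gap_marks_trajectory_unusable(self):
        traj, _ = self._linear_with_gap(25, n=80)
        out = gap_fill(traj, max_auto=10, max_manual=20)
        assert out.exclude_reason is not None
        assert not out.valid[20:45].any()

    def test_frames_outside_gaps_are_untouched(self, rng):
        n = 50
        pos = rng.normal(0, 100, (n, 3))
        valid = np.ones(n, bool)
        valid[10:13] = False
        nanpos = pos.copy()
        nanpos[10:13] = np.nan
        traj = make_trajectory(nanpos, valid=valid)
        out = gap_fill(traj)
        keep = out.valid & ~out.imputed
        assert np.array_equal(out.positions[keep], pos[np.nonzero(keep)[0]])
        assert out.imputed.sum() == 3

    def test_max_auto_above_max_manual_rejected(self):
        traj, _ = self._linear_with_gap(4)
        with pytest.raises(ValueError):
            gap_fill(traj, max_auto=25, max_manual=20)


class TestSmooth:
    def test_constant_position_unchanged(self):
        traj = make_trajectory(np.tile([10.0, -5.0, 3.0], (200, 1)))
        out = smooth(traj, cutoff_hz=12, order=2)
        assert np.allclose(out.positions, traj.positions, atol=1e-9)

    @pytest.mark.parametrize("freq,check", [
        (40.0, lambda ratio: ratio < 0.10),
        (2.0, lambda ratio: abs(ratio - 1.0) < 0.05),
    ])
    def test_magnitude_response(self, freq, check):
        t = np.arange(1200) / 120.0
        pos = np.zeros((len(t), 3))
        pos[:, 0] = 20.0 * np.sin(2 * np.pi * freq * t)
        out = smooth(make_trajectory(pos), cutoff_hz=12, order=2)
        core = slice(200, 1000)  # ignore filter edge transients
        ratio = np.abs(out.positions[core, 0]).max() / 20.0
        assert check(ratio)

    def test_linearity(self, rng):
        a = rng.normal(0, 5, (300, 3))
        b = rng.normal(0, 5, (300, 3))
        sa = smooth(make_trajectory(a)).positions
        sb = smooth(make_trajectory(b)).positions
        sab = smooth(make_trajectory(a + b)).positions
        assert np.allclose(sab, sa + sb, atol=1e-9)

    def test_nan_in_span_rejected(self):
        pos = np.zeros((100, 3))
        pos[50] = np.nan
        valid = np.ones(100, bool)
        valid[50] = False
        with pytest.raises(ValueError):
            smooth(make_trajectory(pos, valid=valid))

    def test_cutoff_above_nyquist_rejected(self):
        traj = make_trajectory(np.zeros((50, 3)))
        with pytest.raises(ValueError):
            smooth(traj, cutoff_hz=60.0)


def test_mirror_negates_x_only():
    rec = _tiny_recording()
    mirrored = mirror_x(rec)
    for label in MARKER_LABELS:
        a = rec.markers[label].positions
        b = mirrored.markers[label].positions
        assert np.allclose(b[:, 0], -a[:, 0])
        assert np.allclose(b[:, 1:], a[:, 1:])
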