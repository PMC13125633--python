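"""Segment frames, ISB angle decompositions and the bow-string contact."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from bowkin import kinematics as kin
from bowkin import synthetic as syn
from bowkin.errors import ConfigurationError, DegenerateGeometryError

from conftest import make_series


def _frame(rotations, origins=None):
    n = rotations.shape[0] if rotations.ndim == 3 else 1
    if origins is None:
        origins = np.zeros((n, 3))
    return kin.SegmentFrame(origins, rotations)


def _frames_from_euler(seq, angles_deg):
    mats = Rotation.from_euler(seq, angles_deg, degrees=True).as_matrix()
    return _frame(np.eye(3)[None]), _frame(mats[None] if mats.ndim == 2 else mats)


class TestBuildFrames:
    def test_canonical_placement_gives_identity(self, teacher_short):
        """Markers emitted at known joint angles rebuild exactly the
        composed segment orientations."""
        frames = kin.build_frames(teacher_short.markers)
        rec = kin.joint_angle_series(frames, 120.0)
        for ch in rec.CHANNELS:
            err = np.max(np.abs(rec.channel(ch) - teacher_short.angles.channel(ch)))
            assert err < 1e-6, ch

    def test_global_rotation_composes(self, teacher_short):
        """Rigidly rotating every marker rotates every frame identically
        and leaves all joint angles unchanged."""
        series = teacher_short.markers
        rot = Rotation.from_euler("xyz", [17.0, -33.0, 54.0], degrees=True)
        moved = make_series(
            series.positions @ rot.as_matrix().T + np.array([100.0, -50.0, 30.0]),
            labels=list(series.labels),
        )
        base = kin.build_frames(series)
        turned = kin.build_frames(moved)
        for seg in base:
            composed = rot.as_matrix() @ base[seg].rotations
            assert np.max(np.abs(turned[seg].rotations - composed)) < 1e-9
        a0 = kin.joint_angle_series(base, 120.0)
        a1 = kin.joint_angle_series(turned, 120.0)
        for ch in a0.CHANNELS:
            assert np.max(np.abs(a0.channel(ch) - a1.channel(ch))) < 1e-9

    def test_collinear_markers_raise(self, teacher_short):
        series = teacher_short.markers
        pos = series.positions.copy()
        labels = list(series.labels)
        # drop the bow's plane marker onto its long axis
        j_mid = labels.index("BOW_MID")
        j_frog, j_tip = labels.index("BOW_FROG"), labels.index("BOW_TIP")
        pos[:, j_mid] = 0.5 * (pos[:, j_frog] + pos[:, j_tip])
        bad = make_series(pos, labels=labels)
        with pytest.raises(DegenerateGeometryError, match="frame 0"):
            kin.build_frames(bad)

    def test_missing_role_names_it(self, teacher_short):
        mm = dict(kin.DEFAULT_MARKER_MAP)
        del mm["c7"]
        with pytest.raises(ConfigurationError, match="c7"):
            kin.build_frames(teacher_short.markers, mm)


class TestShoulderAngles:
    def test_identity_is_zero(self):
        thorax, humerus = _frames_from_euler("YXY", [0.0, 30.0, 0.0])
        aa, e, ie, _ = kin.shoulder_angles(_frame(np.eye(3)[None]), _frame(np.eye(3)[None]))
        assert aa[0] == pytest.approx(0.0, abs=1e-9)
        assert e[0] == pytest.approx(0.0, abs=1e-9)
        assert ie[0] == pytest.approx(0.0, abs=1e-9)

    def test_pure_vertical_rotation(self):
        thorax, humerus = _frames_from_euler("y", [30.0])
        aa, e, ie, gimbal = kin.shoulder_angles(thorax, humerus)
        assert aa[0] == pytest.approx(30.0, abs=1e-6)
        assert e[0] == pytest.approx(0.0, abs=1e-6)
        assert gimbal[0]  # zero elevation is the gimbal case, flagged

    @pytest.mark.parametrize("angles", [(25.0, 40.0, -15.0), (-60.0, 130.0, 75.0),
                                        (110.0, 12.0, -170.0)])
    def test_recomposes_original_rotation(self, angles):
        """Forward-compose oracle: the decomposed YXY angles rebuild the
        relative rotation matrix to 1e-9."""
        thorax, humerus = _frames_from_euler("YXY", list(angles))
        aa, e, ie, _ = kin.shoulder_angles(thorax, humerus)
        rebuilt = Rotation.from_euler("YXY", [aa[0], e[0], ie[0]], degrees=True).as_matrix()
        assert np.max(np.abs(rebuilt - humerus.rotations[0])) < 1e-9


class TestElbowWristAngles:
    def test_full_extension_zero(self):
        fe, ps = kin.elbow_angles(_frame(np.eye(3)[None]), _frame(np.eye(3)[None]))
        assert fe[0] == pytest.approx(0.0, abs=1e-9)
        assert ps[0] == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_flexion(self):
        humerus, forearm = _frames_from_euler("z", [90.0])
        fe, _ = kin.elbow_angles(humerus, forearm)
        assert fe[0] == pytest.approx(90.0, abs=1e-6)

    @pytest.mark.parametrize("angles", [(35.0, 0.0, 20.0), (120.0, 0.0, -65.0)])
    def test_elbow_recomposes(self, angles):
        humerus, forearm = _frames_from_euler("ZXY", list(angles))
        fe, ps = kin.elbow_angles(humerus, forearm)
        rebuilt = Rotation.from_euler("ZXY", [fe[0], 0.0, ps[0]], degrees=True).as_matrix()
        assert np.max(np.abs(rebuilt - forearm.rotations[0])) < 1e-9

    def test_wrist_identity_and_pure_flexion(self):
        fe, aa = kin.wrist_angles(_frame(np.eye(3)[None]), _frame(np.eye(3)[None]))
        assert (fe[0], aa[0]) == (pytest.approx(0.0, abs=1e-9), pytest.approx(0.0, abs=1e-9))
        forearm, hand = _frames_from_euler("z", [20.0])
        fe, aa = kin.wrist_angles(forearm, hand)
        assert fe[0] == pytest.approx(20.0, abs=1e-6)
        assert aa[0] == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("angles", [(25.0, 10.0, 0.0), (-40.0, -18.0, 0.0)])
    def test_wrist_recomposes(self, angles):
        forearm, hand = _frames_from_euler("ZXY", list(angles))
        fe, aa = kin.wrist_angles(forearm, hand)
        rebuilt = Rotation.from_euler("ZXY", [fe[0], aa[0], 0.0], degrees=True).as_matrix()
        assert np.max(np.abs(rebuilt - hand.rotations[0])) < 1e-9


def _bow_series(frog, tip, mid, bridge_mid, string_dir):
    labels = ["BOW_FROG", "BOW_MID", "BOW_TIP", "VIO_SCROLL", "VIO_BRL", "VIO_BRR", "VIO_TAIL"]
    string_dir = np.asarray(string_dir, float) / np.linalg.norm(string_dir)
    w = np.cross(string_dir, [0.0, 1.0, 0.0])
    w /= np.linalg.norm(w)
    rows = [frog, mid, tip,
            bridge_mid + 300 * string_dir,
            bridge_mid + 25 * w, bridge_mid - 25 * w,
            bridge_mid - 100 * string_dir]
    return make_series(np.array(rows, dtype=float)[None, :, :], labels=labels)


class TestBowTrace:
    def test_midpoint_crossing_is_half(self):
        s = _bow_series(
            frog=[0, 0, 0], tip=[740, 0, 0], mid=[370, 20, 0],
            bridge_mid=[370, 0, 0], string_dir=[0, 0, 1])
        trace = kin.bow_trace(s)
        assert trace.b[0] == pytest.approx(0.5, abs=1e-9)

    def test_crossing_at_frog_is_zero(self):
        s = _bow_series(
            frog=[0, 0, 0], tip=[740, 0, 0], mid=[370, 20, 0],
            bridge_mid=[0, 0, 0], string_dir=[0, 0, 1])
        trace = kin.bow_trace(s)
        assert trace.b[0] == pytest.approx(0.0, abs=1e-9)

    def test_random_skew_lines_match_dense_sampling(self, rng):
        """Brute-force oracle: densely sample 1e5 points along the bow
        axis and pick the one closest to the string line."""
        for _ in range(5):
            frog = rng.normal(scale=200, size=3)
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            tip = frog + 740 * u
            mid = frog + 370 * u + 30 * _any_perp(u, rng)
            bridge = rng.normal(scale=200, size=3)
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            if abs(np.dot(u, d)) > 0.95:
                continue
            s = _bow_series(frog, tip, mid, bridge, d)
            trace = kin.bow_trace(s)
            ss = np.linspace(-0.25, 1.25, 100_001) * 740
            pts = frog[None, :] + ss[:, None] * u[None, :]
            rel = pts - bridge[None, :]
            dist2 = np.sum((rel - (rel @ d)[:, None] * d[None, :]) ** 2, axis=1)
            b_brute = np.clip(ss[np.argmin(dist2)] / 740, 0, 1)
            assert trace.b[0] == pytest.approx(b_brute, abs=1e-3)

    def test_invariant_to_lab_frame(self, teacher_short):
        series = teacher_short.markers
        rot = Rotation.from_euler("zyx", [40.0, -20.0, 65.0], degrees=True)
        moved = make_series(series.positions @ rot.as_matrix().T + 500.0,
                            labels=list(series.labels))
        t0 = kin.bow_trace(series)
        t1 = kin.bow_trace(moved)
        assert np.max(np.abs(t0.b - t1.b)) < 1e-9

    def test_near_parallel_carries_previous(self):
        # frame 0 fine, frame 1 bow parallel to string
        base = _bow_series([0, 0, 0], [740, 0, 0], [370, 20, 0],
                           [370, 0, 0], [0, 0, 1])
        pos2 = np.concatenate([base.positions, base.positions], axis=0)
        # rotate bow onto the string direction in frame 1
        pos2[1, 0] = [0, 0, 0]
        pos2[1, 2] = [0, 0, 740]
        pos2[1, 1] = [20, 0, 370]
        s = make_series(pos2, labels=list(base.labels))
        trace = kin.bow_trace(s)
        assert trace.parallel_flags[1]
        assert trace.b[1] == trace.b[0]


def _any_perp(u, rng):
    v = rng.normal(size=3)
    v -= (v @ u) * u
    return v / np.linalg.norm(v)


def test_joint_angle_export_tidy(teacher_short, tmp_path):
    import pandas as pd

    path = tmp_path / "angles.tsv"
    kin.write_joint_angles_tsv(teacher_short.angles, path)
    table = pd.read_csv(path, sep="\t")
    assert list(table.columns) == ["frame", "time_s", "channel", "value_deg"]
    assert set(table.channel) == set(teacher_short.angles.CHANNELS)
    sub = table[table.channel == "elbow_fe"]
    assert np.allclose(sub.value_deg.to_numpy(), teacher_short.angles.elbow_fe, atol=1e-5)


class TestGeneratorRoundTrip:
    def test_noise_free_angles_recovered_to_microdegrees(self, teacher_ex1):
        frames = kin.build_frames(teacher_ex1.markers)
        rec = kin.joint_angle_series(frames, 120.0)
        for ch in rec.CHANNELS:
            assert np.max(np.abs(rec.channel(ch) - teacher_ex1.angles.channel(ch))) < 1e-6

    def test_one_mm_marker_noise_stays_under_half_degree(self, teacher_short, rng):
        """1 mm white marker noise, smoothed at the movement bandwidth
        (6 Hz for a 0.5 Hz bowing task), leaves every channel's RMS
        angle error under 0.5 deg."""
        from bowkin.mocap_io import lowpass

        series = teacher_short.markers
        noisy = make_series(series.positions + rng.normal(scale=1.0, size=series.positions.shape),
                            labels=list(series.labels))
        smooth = lowpass(noisy, cutoff=6.0)
        rec = kin.joint_angle_series(kin.build_frames(smooth), 120.0)
        mid = slice(20, -20)  # filter edge transients excluded
        for ch in rec.CHANNELS:
            err = np.sqrt(np.mean(
                (rec.channel(ch)[mid] - teacher_short.angles.channel(ch)[mid]) ** 2))
            assert err < 0.5, ch
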