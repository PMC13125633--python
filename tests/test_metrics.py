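"""The 17 performance metrics against independent oracles."""

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.special import iv
from scipy.stats import vonmises

from bowkin import metrics as met
from bowkin import synthetic as syn
from bowkin.kinematics import BowTrace
from bowkin.strokes import Stroke


class TestRom:
    def test_sinusoid_twice_amplitude(self):
        t = np.linspace(0, 4, 500)
        assert met.rom(20.0 * np.sin(2 * np.pi * t)) == pytest.approx(40.0, rel=1e-3)

    def test_constant_is_zero(self):
        assert met.rom(np.full(50, 3.7)) == 0.0

    def test_masked_equals_enumeration(self, rng):
        x = rng.normal(size=300)
        mask = rng.random(300) < 0.4
        expected = max(x[i] for i in range(300) if mask[i]) - min(
            x[i] for i in range(300) if mask[i])
        assert met.rom(x, mask) == pytest.approx(expected, abs=1e-12)

    def test_shift_invariant_gain_linear(self, rng):
        x = rng.normal(size=200)
        assert met.rom(x + 100.0) == pytest.approx(met.rom(x), abs=1e-9)
        assert met.rom(3.0 * x) == pytest.approx(3.0 * met.rom(x), abs=1e-9)

    def test_too_few_samples_undefined(self):
        assert np.isnan(met.rom(np.array([1.0])))


class TestSpatialBlock:
    def _series(self, elbow, shoulder, b, rate=120.0):
        n = len(b)
        from bowkin.kinematics import JointAngleSeries

        zeros = np.zeros(n)
        angles = JointAngleSeries(rate, shoulder, zeros, zeros, elbow, zeros, zeros, zeros)
        return angles, BowTrace(rate=rate, b=np.asarray(b, float))

    def test_proportional_signals_ratio_two(self):
        t = np.linspace(0, 4, 480)
        b = 0.5 + 0.45 * np.sin(2 * np.pi * 0.5 * t)
        shoulder = 10.0 + 20.0 * np.sin(2 * np.pi * 0.5 * t)
        angles, trace = self._series(2.0 * shoulder, shoulder, b)
        out = met.spatial_block(angles, trace)
        assert out["m4"] == pytest.approx(2.0, rel=1e-9)
        assert out["m5"] == pytest.approx(2.0, rel=1e-9)

    def test_no_upper_frames_marks_undefined(self):
        b = np.full(100, 0.2)
        b[:50] = np.linspace(0.1, 0.3, 50)
        angles, trace = self._series(np.linspace(0, 10, 100), np.linspace(0, 5, 100), b)
        out = met.spatial_block(angles, trace)
        assert np.isnan(out["m4"]) and np.isnan(out["m6"]) and np.isnan(out["m8"])
        assert np.isfinite(out["m5"])

    def test_zero_noise_participant_matches_closed_form(self, teacher_ex1):
        """Generator algebra: a noise-free learner at amplitude 0.8
        reproduces the mapping's closed-form ROMs and ratios to 1e-3."""
        profile = syn.ParticipantProfile(amplitude_scale=0.8, coordination_ratio=0.6)
        trial = syn.generate_participant(teacher_ex1, profile, seed=0)
        out = met.spatial_block(trial.angles, trial.trace)
        expected = syn.expected_spatial(0.8, k_elbow=0.6 * syn.K_SHOULDER)
        # whole-trial ROMs hit the stroke endpoints exactly; half-mask
        # ratios carry an O(v/rate) discretisation at the 0.5 boundary
        for key in ("m1", "m2", "m3"):
            assert out[key] == pytest.approx(expected[key], rel=1e-9), key
        for key in ("m4", "m5", "m6", "m7", "m8", "m9"):
            assert out[key] == pytest.approx(expected[key], rel=0.02), key


class TestVariability:
    def test_identical_profiles_zero(self):
        p = np.linspace(0, 1, 101)
        assert met.variability([p, p.copy(), p.copy()]) == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_sqrt_two(self):
        p = np.linspace(0, 1, 101)
        assert met.variability([p, p + 2.0]) == pytest.approx(np.sqrt(2.0), rel=1e-9)

    def test_gaussian_offsets_recover_sd(self, rng):
        base = np.zeros(101)
        offsets = rng.normal(0.0, 3.0, size=200)
        profiles = [base + o for o in offsets]
        # constant offsets: metric equals the sample SD of the offsets
        assert met.variability(profiles) == pytest.approx(np.std(offsets, ddof=1), rel=1e-9)
        assert met.variability(profiles) == pytest.approx(3.0, rel=0.15)


class TestCoordinationVariability:
    def test_identical_strokes_zero(self):
        e = np.linspace(0, 10, 101)
        s = np.linspace(0, 5, 101)
        assert met.coordination_variability([e, e.copy()], [s, s.copy()]) == 0.0

    def test_four_orthogonal_coupling_angles_hit_cap(self):
        """Coupling angles 0, 90, 180, 270 deg at the single step: the
        mean resultant vanishes and the circular SD takes the documented
        cap sqrt(-2 ln 1e-12)."""
        deltas = [(1.0, 0.0), (0.0, 1.0), (-1.0, 0.0), (0.0, -1.0)]
        elbow = [np.array([0.0, de]) for de, _ in deltas]
        shoulder = [np.array([0.0, ds]) for _, ds in deltas]
        out = met.coordination_variability(elbow, shoulder)
        cap = np.degrees(np.sqrt(-2.0 * np.log(1e-12)))
        assert out == pytest.approx(cap, rel=1e-9)

    def test_small_jitter_limit_recovers_sigma(self, rng):
        """Coupling angles jittered by sigma -> circular SD ~ sigma."""
        sigma = 0.5  # deg
        gammas = np.radians(rng.normal(30.0, sigma, size=400))
        elbow = [np.array([0.0, np.cos(g)]) for g in gammas]
        shoulder = [np.array([0.0, np.sin(g)]) for g in gammas]
        out = met.coordination_variability(elbow, shoulder)
        assert out == pytest.approx(sigma, rel=0.15)

    def test_zero_motion_step_skipped(self):
        elbow = [np.array([0.0, 1.0, 2.0]), np.array([0.0, 0.0, 1.0])]
        shoulder = [np.array([0.0, 0.0, 0.0]), np.array([0.0, 0.0, 0.0])]
        # first step: stroke 2 has no motion in either joint, so only the
        # moving stroke remains and the step is skipped; second step both
        # strokes move with identical coupling -> SD 0
        out = met.coordination_variability(elbow, shoulder)
        assert out == pytest.approx(0.0, abs=1e-12)


class TestTimingDifference:
    def test_identical_trains_zero(self):
        ev = np.array([1.0, 2.0, 3.5])
        assert met.timing_difference(ev, ev) == pytest.approx(0.0, abs=1e-12)

    def test_uniform_lateness_accumulates(self):
        t = np.arange(10, dtype=float)
        assert met.timing_difference(t + 0.5, t) == pytest.approx(5.0, rel=1e-12)

    def test_greedy_matches_hungarian_on_jittered_trains(self, rng):
        """Exhaustive-assignment oracle on trains of <= 8 events."""
        for _ in range(20):
            n = rng.integers(3, 9)
            teacher = np.sort(rng.uniform(0, 10, size=n))
            while np.any(np.diff(teacher) < 0.5):
                teacher = np.sort(rng.uniform(0, 10, size=n))
            participant = np.sort(teacher + rng.normal(0, 0.15, size=n))
            cost = np.abs(participant[None, :] - teacher[:, None])
            rows, cols = linear_sum_assignment(cost)
            optimal = sorted(zip(rows.tolist(), cols.tolist()))
            assert met.match_events(participant, teacher) == optimal
            expected = sum(participant[j] - teacher[k] for k, j in optimal)
            assert met.timing_difference(participant, teacher) == pytest.approx(expected)

    def test_empty_train_undefined(self):
        assert np.isnan(met.timing_difference(np.array([]), np.array([1.0])))


class TestEuclideanDistance:
    def test_identity_zero_and_symmetry(self, rng):
        x = rng.random(500)
        y = rng.random(500)
        assert met.euclidean_distance(x, x) == 0.0
        assert met.euclidean_distance(x, y) == met.euclidean_distance(y, x)

    def test_constant_offset(self):
        a = np.full(200, 0.5)
        assert met.euclidean_distance(a + 0.25, a) == pytest.approx(25.0, rel=1e-12)

    def test_matches_direct_formula(self, rng):
        x, y = rng.random(300), rng.random(300)
        direct = 100.0 * np.sqrt(np.sum((x - y) ** 2) / 300)
        assert met.euclidean_distance(x, y) == pytest.approx(direct, abs=1e-9)


def sparc_reference(speed, fs, padlevel=4, fc=10.0, amp_th=0.05):
    """Independent transcription of the published spectral-arc-length
    definition (adaptive cutoff variant), kept deliberately separate
    from the implementation under test."""
    nfft = int(2 ** (np.ceil(np.log2(len(speed))) + padlevel))
    f = np.arange(0, fs, fs / nfft)
    mag = np.abs(np.fft.fft(speed, nfft))
    mag = mag / max(mag)
    sel = f <= fc
    f_sel, mag_sel = f[sel], mag[sel]
    above = np.nonzero(mag_sel >= amp_th)[0]
    keep = np.arange(above[0], above[-1] + 1)
    f_sel, mag_sel = f_sel[keep], mag_sel[keep]
    df = np.diff(f_sel) / (f_sel[-1] - f_sel[0])
    return -np.sum(np.sqrt(df**2 + np.diff(mag_sel) ** 2))


class TestSparc:
    def _gauss_bump(self, n=240, rate=120.0):
        t = np.arange(n) / rate
        return np.exp(-0.5 * ((t - 1.0) / 0.25) ** 2), rate

    def test_matches_independent_transcription(self):
        speed, rate = self._gauss_bump()
        assert met.sparc(speed, rate) == pytest.approx(
            sparc_reference(speed, rate), abs=1e-6)

    def test_matches_transcription_on_rough_profiles(self, rng):
        for _ in range(5):
            speed = np.abs(rng.normal(1.0, 0.3, size=180)
                           + 0.5 * np.sin(np.linspace(0, 20, 180)))
            assert met.sparc(speed, 120.0) == pytest.approx(
                sparc_reference(speed, 120.0), abs=1e-6)

    def test_amplitude_scale_invariant(self):
        speed, rate = self._gauss_bump()
        assert met.sparc(2.0 * speed, rate) == pytest.approx(met.sparc(speed, rate), abs=1e-12)

    def test_two_bumps_rougher_than_one(self):
        n, rate = 480, 120.0
        t = np.arange(n) / rate
        one = np.exp(-0.5 * ((t - 2.0) / 0.3) ** 2)
        two = one + np.exp(-0.5 * ((t - 1.0) / 0.3) ** 2)
        assert met.sparc(two, rate) < met.sparc(one, rate)

    def test_degenerate_inputs_undefined(self):
        assert np.isnan(met.sparc(np.zeros(100), 120.0))
        assert np.isnan(met.sparc(np.ones(4), 120.0))


class TestSynchronization:
    def test_coincident_events(self):
        ev = np.arange(10, dtype=float)
        strength, phase = met.synchronization(ev, ev)
        assert strength == pytest.approx(1.0, abs=1e-12)
        assert phase == pytest.approx(0.0, abs=1e-12)

    def test_balanced_phases_cancel(self):
        teacher = np.arange(5, dtype=float)  # 4 unit intervals
        participant = teacher[:-1] + np.array([0.0, 0.25, 0.5, -0.25])
        strength, _ = met.synchronization(np.sort(participant), teacher)
        assert strength == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_strength_matches_analytic(self):
        """Strength of kappa=5 von Mises phases ~ A(5) = I1(5)/I0(5)."""
        kappa, n = 5.0, 200
        phases = vonmises.rvs(kappa, size=n, random_state=77)
        teacher = np.arange(n + 1, dtype=float)
        participant = teacher[:-1] + phases / (2 * np.pi)
        strength, phase = met.synchronization(np.sort(participant), teacher)
        expected = iv(1, kappa) / iv(0, kappa)
        assert strength == pytest.approx(expected, abs=0.05)
        assert abs(phase) < 0.15

    def test_invariant_to_common_shift(self, rng):
        teacher = np.cumsum(rng.uniform(0.8, 1.2, size=12))
        participant = teacher + rng.normal(0, 0.1, size=12)
        s0 = met.synchronization(participant, teacher)
        s1 = met.synchronization(participant + 5.0, teacher + 5.0)
        assert s0 == pytest.approx(s1, abs=1e-12)

    def test_too_few_intervals_undefined(self):
        s, p = met.synchronization(np.array([1.0]), np.array([0.0, 1.0]))
        assert np.isnan(s) and np.isnan(p)


class TestComputeAll:
    def test_teacher_self_comparison(self, teacher_ex1):
        mv = met.compute_all(
            (teacher_ex1.angles, teacher_ex1.trace),
            (teacher_ex1.angles, teacher_ex1.trace))
        assert mv.m13 == pytest.approx(0.0, abs=1e-9)
        assert mv.m14 == 0.0
        assert mv.m16 == pytest.approx(1.0, abs=1e-9)
        assert mv.m17 == pytest.approx(0.0, abs=1e-9)
        assert mv.m10 == pytest.approx(0.0, abs=1e-6)
        assert mv.m12 == pytest.approx(0.0, abs=1e-6)

    def test_no_strokes_degrades_gracefully(self, teacher_ex1):
        n = 400
        flat = BowTrace(rate=120.0, b=np.full(n, 0.4))
        from bowkin.kinematics import JointAngleSeries

        zeros = np.zeros(n)
        angles = JointAngleSeries(120.0, np.linspace(0, 5, n), zeros, zeros,
                                  np.linspace(0, 9, n), zeros, zeros, zeros)
        with pytest.warns(UserWarning):
            mv = met.compute_all((angles, flat), (angles, flat))
        for mid in ("m10", "m11", "m12", "m13", "m15", "m16", "m17"):
            assert np.isnan(getattr(mv, mid)), mid
        assert np.isfinite(mv.m2)
        assert np.isfinite(mv.m5)  # lower-half ratios still defined

    def test_m14_grows_with_noise(self, teacher_ex1, rng):
        prev = -1.0
        for sd in (0.0, 0.02, 0.05, 0.1):
            noisy = np.clip(teacher_ex1.trace.b + rng.normal(0, sd, teacher_ex1.trace.n_frames),
                            0, 1)
            val = met.euclidean_distance(noisy, teacher_ex1.trace.b)
            assert val > prev
            prev = val
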