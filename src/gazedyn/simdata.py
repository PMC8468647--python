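"""Synthetic jumping-point gaze recordings.

Emulates the recording protocol used throughout the package: a dark point
jumps between 29 screen locations (the 9th and 29th coincide), each shown
for 3 s, while both gaze coordinates are sampled at 1000 Hz.  A simulated
subject is a bundle of oculomotor parameters (saccadic peak velocity and
latency, microsaccade rate/amplitude/speed, ocular drift, tremor) drawn
from the physiological ranges reported for human eye movements, so that
different subjects produce distinguishable signal dynamics and the whole
identification pipeline can be exercised without human recordings.

Saccades follow a minimum-jerk trajectory whose duration is set so that
peak velocity tracks a main-sequence curve anchored at the subject's
10-degree peak velocity.  Fixations superimpose three micromovements:

* microsaccades — Poisson-timed minimum-jerk jumps (< 0.5 deg, 15-50 deg/s),
* drift — a per-axis Ornstein-Uhlenbeck wander (~0.5 deg/s, < 0.13 deg),
* tremor — a sinusoidal micro-oscillation (~1.7e-4 deg, 40-100 Hz),

plus white measurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter
from scipy.stats import qmc

from .exceptions import ConfigurationError, InvalidGeometryError, ProtocolError

GENERATOR_VERSION = "1.0"

SAMPLING_RATE_HZ = 1000.0
DISPLAY_DURATION_MS = 3000
N_POINTS = 29
DEFAULT_FIELD_EXTENT = (40.0, 32.0)  # horizontal x vertical, deg

# physiological parameter ranges (deg, deg/s, ms, Hz)
PEAK_VELOCITY_RANGE = (300.0, 500.0)
SACCADE_DURATION_RANGE = (30.0, 80.0)
LATENCY_MEAN_RANGE = (140.0, 260.0)
LATENCY_SD_RANGE = (15.0, 25.0)
LATENCY_TRUNC = (80.0, 400.0)
MICROSACCADE_RATE_RANGE = (1.0, 2.0)
MICROSACCADE_AMP_RANGE = (0.15, 0.4)   # < 0.5 deg
MICROSACCADE_SPEED_RANGE = (15.0, 50.0)
DRIFT_SPEED_RANGE = (0.30, 0.70)       # ~0.5 deg/s
DRIFT_AMP_RANGE = (0.06, 0.13)         # < 0.13 deg
TREMOR_AMPLITUDE = 0.00017             # nominal; cohort draws bracket it
TREMOR_AMP_RANGE = (1.0e-4, 2.5e-4)
TREMOR_FREQ_RANGE = (40.0, 100.0)

NOISE_SD_DEG = 1e-4  # measurement noise at noise_scale = 1
NOISE_SCALE_RANGE = (0.1, 1.0)

# main-sequence saturation constant: peak velocity ~ Vp10 * (1-exp(-A/A0))
_MAIN_SEQ_A0 = 6.0
_MIN_JERK_VFACTOR = 1.875  # peak of d/dt of the minimum-jerk unit profile
_SACCADE_GAIN = 0.92       # population undershoot gain of primary saccades
_CORRECTIVE_MIN_AMP = 1.0  # deg; smaller jumps land without correction
# the profile's peak velocity is realised by the primary saccade of a
# 10-degree target jump, whose amplitude after undershoot is 9.2 degrees
_MAIN_SEQ_ANCHOR = 10.0 * _SACCADE_GAIN


def _main_sequence_velocity(vp10: float, amplitude: float) -> float:
    """Peak velocity for a saccade of the given amplitude.

    Anchored so that the primary saccade of a 10-degree target jump
    (amplitude 9.2 degrees after undershoot) peaks at ``vp10``.
    """
    return vp10 * (-math.expm1(-amplitude / _MAIN_SEQ_A0)) / (
        -math.expm1(-_MAIN_SEQ_ANCHOR / _MAIN_SEQ_A0)
    )


@dataclass(frozen=True)
class SubjectProfile:
    """Generative oculomotor parameters of one simulated subject.

    ``saccade_duration`` is the duration of a 10-degree saccade; it is tied
    to ``saccade_peak_velocity`` through the minimum-jerk identity
    v_peak = 1.875 * A / D, which keeps both inside their physiological
    ranges simultaneously.
    """

    subject_id: int
    saccade_peak_velocity: float   # deg/s, peak velocity of a 10-deg saccade
    saccade_duration: float        # ms, duration of a 10-deg saccade
    latency_mean: float            # ms
    latency_sd: float              # ms
    microsaccade_rate: float       # Hz
    microsaccade_amplitude: float  # deg
    microsaccade_speed: float      # deg/s
    drift_speed: float             # deg/s
    drift_amplitude: float         # deg
    tremor_amplitude: float        # deg
    tremor_freq: float             # Hz
    noise_scale: float = 1.0
    seed: int = 0

    def validate_ranges(self) -> None:
        """Assert every parameter lies inside its physiological interval."""
        checks = [
            (self.saccade_peak_velocity, PEAK_VELOCITY_RANGE),
            (self.saccade_duration, SACCADE_DURATION_RANGE),
            (self.latency_mean, LATENCY_MEAN_RANGE),
            (self.latency_sd, LATENCY_SD_RANGE),
            (self.microsaccade_rate, MICROSACCADE_RATE_RANGE),
            (self.microsaccade_amplitude, (0.0, 0.5)),
            (self.microsaccade_speed, MICROSACCADE_SPEED_RANGE),
            (self.drift_speed, DRIFT_SPEED_RANGE),
            (self.drift_amplitude, (0.0, 0.13)),
            (self.tremor_freq, TREMOR_FREQ_RANGE),
        ]
        for value, (lo, hi) in checks:
            if not lo <= value <= hi:
                raise ConfigurationError(
                    f"profile parameter {value!r} outside [{lo}, {hi}]"
                )

    @classmethod
    def quiet(cls, subject_id: int = 0, **overrides) -> "SubjectProfile":
        """A motionless profile (no micromovements, no noise) for tests."""
        params = dict(
            subject_id=subject_id,
            saccade_peak_velocity=400.0,
            saccade_duration=1.875 * 9.2 / 400.0 * 1000.0,
            latency_mean=200.0,
            latency_sd=0.0,
            microsaccade_rate=0.0,
            microsaccade_amplitude=0.0,
            microsaccade_speed=30.0,
            drift_speed=0.5,
            drift_amplitude=0.0,
            tremor_amplitude=0.0,
            tremor_freq=70.0,
            noise_scale=0.0,
            seed=0,
        )
        params.update(overrides)
        return cls(**params)


@dataclass(frozen=True)
class StimulusSequence:
    """Ordered jumping-point layout: 29 positions, the 9th and 29th equal."""

    positions: np.ndarray                       # (29, 2) deg, screen-centred
    display_duration: int = DISPLAY_DURATION_MS  # ms
    field_extent: tuple[float, float] = DEFAULT_FIELD_EXTENT

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.shape != (N_POINTS, 2):
            raise InvalidGeometryError(
                f"expected {N_POINTS} positions, got shape {pos.shape}"
            )
        if not np.array_equal(pos[8], pos[28]):
            raise InvalidGeometryError("positions 9 and 29 (1-based) must coincide")
        half = np.asarray(self.field_extent) / 2.0
        if np.any(np.abs(pos) > half):
            raise InvalidGeometryError("positions fall outside the field extent")


@dataclass
class GazeRecording:
    """One session's two-channel 1000 Hz gaze trace with stimulus onsets."""

    subject_id: int
    session_id: int
    sampling_rate: float           # Hz
    horizontal: np.ndarray         # deg
    vertical: np.ndarray           # deg
    onsets: np.ndarray             # sample indices, one per stimulus point

    def __post_init__(self) -> None:
        self.horizontal = np.asarray(self.horizontal, dtype=float)
        self.vertical = np.asarray(self.vertical, dtype=float)
        self.onsets = np.asarray(self.onsets, dtype=int)
        if self.horizontal.shape != self.vertical.shape:
            raise ConfigurationError("horizontal/vertical length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.horizontal)


def make_stimulus_layout(
    field_extent: tuple[float, float] = DEFAULT_FIELD_EXTENT,
    seed: int = 0,
) -> StimulusSequence:
    """Generate a jumping-point layout on a jittered grid.

    28 unique points on a 7x4 grid (jittered inside their cells) cover the
    field evenly; a random presentation order makes consecutive saccade
    amplitudes vary; the 29th point repeats the 9th.
    """
    w, h = float(field_extent[0]), float(field_extent[1])
    if w <= 0 or h <= 0:
        raise InvalidGeometryError(f"field extent must be positive, got {field_extent}")
    rng = np.random.default_rng(seed)
    ncols, nrows = 7, 4
    cw, ch = w / ncols, h / nrows
    centres_x = (np.arange(ncols) + 0.5) * cw - w / 2.0
    centres_y = (np.arange(nrows) + 0.5) * ch - h / 2.0
    gx, gy = np.meshgrid(centres_x, centres_y)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    pts[:, 0] += rng.uniform(-0.3 * cw, 0.3 * cw, size=len(pts))
    pts[:, 1] += rng.uniform(-0.3 * ch, 0.3 * ch, size=len(pts))
    order = rng.permutation(len(pts))
    seq = pts[order]
    positions = np.vstack([seq, seq[8]])  # 29th repeats the 9th
    return StimulusSequence(positions=positions, field_extent=(w, h))


def _min_jerk_profile(n: int) -> np.ndarray:
    """Unit minimum-jerk displacement profile s(tau), tau in (0, 1]."""
    tau = np.arange(1, n + 1) / n
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _saccade_timing(profile: SubjectProfile, amplitude: float) -> float:
    """Saccade duration (ms) so peak velocity follows the main sequence."""
    vp = _main_sequence_velocity(profile.saccade_peak_velocity, amplitude)
    d_ms = _MIN_JERK_VFACTOR * amplitude / vp * 1000.0
    return float(np.clip(d_ms, 12.0, 100.0))


def _fixational_offsets(profile: SubjectProfile, n: int, rng: np.random.Generator):
    """Microsaccade + drift + tremor + noise offset paths, (n,) per axis."""
    dt = 1.0 / SAMPLING_RATE_HZ
    t = np.arange(n) * dt
    off = np.zeros((n, 2))

    # microsaccades: Poisson-timed minimum-jerk jumps to points inside the
    # amplitude disc around the target, so excursions stay bounded
    if profile.microsaccade_rate > 0 and profile.microsaccade_amplitude > 0:
        current = np.zeros(2)
        pos = 0
        while True:
            gap = rng.exponential(1.0 / profile.microsaccade_rate)
            pos += int(round(gap / dt))
            if pos >= n:
                break
            r = profile.microsaccade_amplitude * math.sqrt(rng.uniform())
            phi = rng.uniform(0, 2 * math.pi)
            target = np.array([r * math.cos(phi), r * math.sin(phi)])
            step = target - current
            dist = float(np.hypot(*step))
            if dist > 0:
                dur = int(round(_MIN_JERK_VFACTOR * dist / profile.microsaccade_speed
                                / dt))
                dur = max(dur, 2)
                end = min(pos + dur, n)
                s = _min_jerk_profile(dur)[: end - pos]
                off[pos:end] = current + np.outer(s, step)
                off[end:] = target
            current = target
            pos += max(int(round(_MIN_JERK_VFACTOR * dist
                                 / profile.microsaccade_speed / dt)), 2)

    # drift: bounded slow wander modelled as an Ornstein-Uhlenbeck position
    # process; at 1 kHz its sample-to-sample velocity is broadband with RMS
    # set by the subject's drift speed (drift proper plus the physiological
    # instability of fixation seen at this sampling rate)
    if profile.drift_amplitude > 0 and profile.drift_speed > 0:
        sigma = profile.drift_speed * math.sqrt(dt * math.pi / 2.0)
        sd = profile.drift_amplitude / 3.0
        theta = sigma**2 / (2.0 * sd**2)
        d0 = rng.normal(0.0, sd, size=2)
        shocks = rng.normal(0.0, sigma * math.sqrt(dt), size=(n - 1, 2))
        decay = 1.0 - theta * dt
        tail, _ = lfilter([1.0], [1.0, -decay], shocks, axis=0,
                          zi=(decay * d0)[None, :])
        off += np.vstack([d0, tail])

    # tremor: sinusoidal micro-oscillation
    if profile.tremor_amplitude > 0:
        phases = rng.uniform(0, 2 * math.pi, size=2)
        off[:, 0] += profile.tremor_amplitude * np.sin(
            2 * math.pi * profile.tremor_freq * t + phases[0])
        off[:, 1] += profile.tremor_amplitude * np.sin(
            2 * math.pi * profile.tremor_freq * t + phases[1])

    if profile.noise_scale > 0:
        off += rng.normal(0.0, NOISE_SD_DEG * profile.noise_scale, size=(n, 2))
    return off


def simulate_trial(
    profile: SubjectProfile,
    from_pos,
    to_pos,
    duration_ms: int = DISPLAY_DURATION_MS,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one stimulus-point response: latency, saccade, fixation.

    Returns ``(horizontal, vertical)`` position arrays of
    ``duration_ms`` samples (1000 Hz), in degrees.
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    from_pos = np.asarray(from_pos, dtype=float)
    to_pos = np.asarray(to_pos, dtype=float)
    amplitude = float(np.hypot(*(to_pos - from_pos)))
    n = int(round(duration_ms * SAMPLING_RATE_HZ / 1000.0))

    # primary saccades of sizeable jumps undershoot (population gain ~0.92)
    # and are followed by a corrective saccade after an intersaccadic
    # latency tied to the subject's reaction-time parameters
    correct = amplitude >= _CORRECTIVE_MIN_AMP
    landing = (from_pos + _SACCADE_GAIN * (to_pos - from_pos) if correct
               else to_pos)
    primary_amp = float(np.hypot(*(landing - from_pos)))
    sacc_ms = _saccade_timing(profile, primary_amp) if amplitude > 0 else 0.0
    if duration_ms < LATENCY_TRUNC[0] + sacc_ms:
        raise ProtocolError(
            f"trial of {duration_ms} ms cannot contain latency plus a "
            f"{sacc_ms:.0f} ms saccade"
        )

    if profile.latency_sd > 0:
        # truncated-normal saccadic latency
        lat = float(rng.normal(profile.latency_mean, profile.latency_sd))
        while not LATENCY_TRUNC[0] <= lat <= LATENCY_TRUNC[1]:
            lat = float(rng.normal(profile.latency_mean, profile.latency_sd))
    else:
        lat = profile.latency_mean
    lat = min(lat, duration_ms - sacc_ms - 1.0)

    backbone = np.empty((n, 2))
    if amplitude == 0:
        backbone[:] = from_pos
    else:
        i0 = int(round(lat * SAMPLING_RATE_HZ / 1000.0))
        nsacc = max(int(round(sacc_ms * SAMPLING_RATE_HZ / 1000.0)), 2)
        i1 = min(i0 + nsacc, n)
        backbone[:i0] = from_pos
        s = _min_jerk_profile(nsacc)[: i1 - i0]
        backbone[i0:i1] = from_pos + np.outer(s, landing - from_pos)
        backbone[i1:] = landing
        if correct:
            isi = max(80.0, rng.normal(0.75 * profile.latency_mean,
                                       max(profile.latency_sd, 1.0)))
            amp2 = float(np.hypot(*(to_pos - landing)))
            d2_ms = _saccade_timing(profile, amp2)
            j0 = i1 + int(round(isi * SAMPLING_RATE_HZ / 1000.0))
            nsacc2 = max(int(round(d2_ms * SAMPLING_RATE_HZ / 1000.0)), 2)
            j1 = min(j0 + nsacc2, n)
            if j0 < n - 2:
                s2 = _min_jerk_profile(nsacc2)[: j1 - j0]
                backbone[j0:j1] = landing + np.outer(s2, to_pos - landing)
                backbone[j1:] = to_pos

    backbone += _fixational_offsets(profile, n, rng)
    return backbone[:, 0].copy(), backbone[:, 1].copy()


def simulate_session(
    profile: SubjectProfile,
    stimulus: StimulusSequence,
    session_id: int = 1,
    seed: int = 0,
) -> GazeRecording:
    """Simulate one full session: 29 back-to-back trials, no gaps.

    The gaze starts at screen centre; each trial saccades from the previous
    stimulus position to the next.  The result is deterministic in
    ``(profile, stimulus, seed)``.
    """
    rng = np.random.default_rng(seed)
    samples_per_point = int(round(
        stimulus.display_duration * SAMPLING_RATE_HZ / 1000.0))
    xs, ys = [], []
    prev = np.zeros(2)
    for pos in stimulus.positions:
        x, y = simulate_trial(profile, prev, pos, stimulus.display_duration, rng)
        xs.append(x)
        ys.append(y)
        prev = pos
    onsets = np.arange(len(stimulus.positions)) * samples_per_point
    return GazeRecording(
        subject_id=profile.subject_id,
        session_id=session_id,
        sampling_rate=SAMPLING_RATE_HZ,
        horizontal=np.concatenate(xs),
        vertical=np.concatenate(ys),
        onsets=onsets,
    )


_COHORT_RANGES = (
    ("saccade_peak_velocity", PEAK_VELOCITY_RANGE),
    ("latency_mean", LATENCY_MEAN_RANGE),
    ("latency_sd", LATENCY_SD_RANGE),
    ("microsaccade_rate", MICROSACCADE_RATE_RANGE),
    ("microsaccade_amplitude", MICROSACCADE_AMP_RANGE),
    ("microsaccade_speed", MICROSACCADE_SPEED_RANGE),
    ("drift_speed", DRIFT_SPEED_RANGE),
    ("drift_amplitude", DRIFT_AMP_RANGE),
    ("tremor_amplitude", TREMOR_AMP_RANGE),
    ("tremor_freq", TREMOR_FREQ_RANGE),
    ("noise_scale", NOISE_SCALE_RANGE),
)


def _profile_from_unit(subject_id: int, unit_row, seed: int) -> SubjectProfile:
    params = {name: lo + (hi - lo) * float(u)
              for (name, (lo, hi)), u in zip(_COHORT_RANGES, unit_row)}
    vp = params["saccade_peak_velocity"]
    prof = SubjectProfile(
        subject_id=subject_id,
        saccade_duration=float(_MIN_JERK_VFACTOR * _MAIN_SEQ_ANCHOR / vp * 1000.0),
        seed=seed,
        **params,
    )
    prof.validate_ranges()
    return prof


def draw_profile(subject_id: int, seed: int) -> SubjectProfile:
    """Draw one subject's parameters uniformly from the physiological ranges."""
    rng = np.random.default_rng(seed)
    return _profile_from_unit(subject_id, rng.uniform(size=len(_COHORT_RANGES)),
                              seed)


def draw_cohort(n_subjects: int, seed: int) -> list[SubjectProfile]:
    """Draw a cohort of subjects on a Latin-hypercube design.

    Each oculomotor parameter is stratified across subjects, so the cohort
    spreads over parameter space and no two simulated subjects collapse
    onto near-identical generative parameters — the property that makes a
    synthetic identification experiment meaningful.
    """
    if n_subjects < 1:
        raise ConfigurationError("need at least 1 subject")
    sampler = qmc.LatinHypercube(d=len(_COHORT_RANGES), seed=seed,
                                 optimization="random-cd")
    unit = sampler.random(n_subjects)
    return [_profile_from_unit(i + 1, unit[i], seed + i)
            for i in range(n_subjects)]


_DRIFTABLE = (
    ("saccade_peak_velocity", PEAK_VELOCITY_RANGE),
    ("latency_mean", LATENCY_MEAN_RANGE),
    ("latency_sd", LATENCY_SD_RANGE),
    ("microsaccade_rate", MICROSACCADE_RATE_RANGE),
    ("microsaccade_amplitude", MICROSACCADE_AMP_RANGE),
    ("microsaccade_speed", MICROSACCADE_SPEED_RANGE),
    ("drift_speed", DRIFT_SPEED_RANGE),
    ("drift_amplitude", DRIFT_AMP_RANGE),
    ("tremor_amplitude", TREMOR_AMP_RANGE),
    ("tremor_freq", TREMOR_FREQ_RANGE),
    ("noise_scale", NOISE_SCALE_RANGE),
)

_DRIFT_REL_SD = 0.15  # relative parameter perturbation per unit drift factor


def perturb_profile(
    profile: SubjectProfile, drift_factor: float, seed: int
) -> SubjectProfile:
    """Session-to-session parameter drift: relative Gaussian perturbation.

    Each generative parameter is multiplied by ``1 + drift_factor * eta``
    with eta ~ N(0, 0.15) and clipped back into its physiological range.
    ``drift_factor = 0`` returns the profile unchanged.
    """
    if drift_factor == 0:
        return profile
    rng = np.random.default_rng(seed)
    changes = {}
    for name, (lo, hi) in _DRIFTABLE:
        value = getattr(profile, name)
        eta = rng.normal(0.0, _DRIFT_REL_SD)
        changes[name] = float(np.clip(value * (1.0 + drift_factor * eta), lo, hi))
    vp = changes["saccade_peak_velocity"]
    changes["saccade_duration"] = float(
        _MIN_JERK_VFACTOR * _MAIN_SEQ_ANCHOR / vp * 1000.0)
    return replace(profile, **changes)


def simulate_dataset(
    n_subjects: int = 24,
    n_sessions: int = 2,
    master_seed: int = 0,
    session_drift: float = 0.0,
    field_extent: tuple[float, float] = DEFAULT_FIELD_EXTENT,
) -> tuple[list[GazeRecording], dict]:
    """Simulate the full jumping-point experiment.

    Returns ``n_subjects * n_sessions`` recordings sharing one stimulus
    layout, plus a manifest recording every derived seed.  With
    ``session_drift > 0`` sessions after the first use per-subject
    parameters perturbed by :func:`perturb_profile`; session 1 is
    unaffected by the drift factor.
    """
    if n_subjects < 2:
        raise ConfigurationError("need at least 2 subjects")
    if n_sessions < 1:
        raise ConfigurationError("need at least 1 session")
    seeder = np.random.default_rng(master_seed)
    layout_seed = int(seeder.integers(0, 2**31 - 1))
    stimulus = make_stimulus_layout(field_extent, seed=layout_seed)
    cohort_seed = int(seeder.integers(0, 2**31 - 1))
    cohort = draw_cohort(n_subjects, cohort_seed)
    recordings: list[GazeRecording] = []
    entries = []
    for sid in range(1, n_subjects + 1):
        profile_seed = cohort_seed
        base = cohort[sid - 1]
        for sess in range(1, n_sessions + 1):
            session_seed = int(seeder.integers(0, 2**31 - 1))
            drift_seed = int(seeder.integers(0, 2**31 - 1))
            prof = base
            if sess > 1 and session_drift:
                prof = perturb_profile(base, session_drift, drift_seed)
            recordings.append(simulate_session(prof, stimulus, sess, session_seed))
            entries.append({
                "subject_id": sid,
                "session_id": sess,
                "profile_seed": profile_seed,
                "session_seed": session_seed,
                "file": None,
            })
    manifest = {
        "generator_version": GENERATOR_VERSION,
        "master_seed": master_seed,
        "layout_seed": layout_seed,
        "session_drift": session_drift,
        "field_extent": list(field_extent),
        "layout": stimulus.positions.tolist(),
        "display_duration_ms": stimulus.display_duration,
        "entries": entries,
    }
    return recordings, manifest
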