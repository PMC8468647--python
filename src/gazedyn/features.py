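"""Dynamic gaze features per 100-sample segment.

The first 1000 samples after each stimulus onset (latency + saccade +
fixation at 1000 Hz) are cut into ten 100-sample segments.  Each segment is
described by 23 values:

* 16 kinematic statistics — max/min/mean/range of horizontal, vertical and
  resultant velocity, and of resultant acceleration (deg/s, deg/s^2);
* 6 spectral values — the first six values of the discrete Fourier
  transform z[n] = sum_k x[k] exp(-i 2 pi k n / N) of the horizontal
  velocity series (real parts by default, magnitudes optionally);
* 1 nonlinear value — the largest Lyapunov exponent (LLE) of the horizontal
  velocity series, treating the oculomotor plant as a nonlinear dynamical
  system.

The LLE is estimated by delay embedding y_i = (x_i, x_{i+tau}, ...,
x_{i+(m-1)tau}) with tau from the first minimum of average mutual
information and m from the false-nearest-neighbours criterion, then
tracking the mean log separation <ln d_j(i)> of neighbouring state pairs
as the system evolves; the exponent is the slope of that divergence curve
over its initial linear region (d_j(i) ~ d_j(0) * exp(lambda * i * dt)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import DegenerateInputError, EmbeddingError, TruncationError
from .simdata import GazeRecording

SEGMENT_LEN = 100
SEGMENTS_PER_POINT = 10
ANALYSIS_WINDOW = SEGMENT_LEN * SEGMENTS_PER_POINT  # samples per stimulus point

FEATURE_NAMES: tuple[str, ...] = (
    "vx_max", "vx_min", "vx_mean", "vx_range",
    "vy_max", "vy_min", "vy_mean", "vy_range",
    "vr_max", "vr_min", "vr_mean", "vr_range",
    "ar_max", "ar_min", "ar_mean", "ar_range",
    "dft_1", "dft_2", "dft_3", "dft_4", "dft_5", "dft_6",
    "lle",
)
N_FEATURES = len(FEATURE_NAMES)  # 23


@dataclass
class Segment:
    """One 100-sample two-channel gaze excerpt (positions in deg)."""

    x: np.ndarray
    y: np.ndarray
    dt: float = 0.001  # s

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if len(self.x) != SEGMENT_LEN or len(self.y) != SEGMENT_LEN:
            raise DegenerateInputError(
                f"segment must have {SEGMENT_LEN} samples per channel, "
                f"got {len(self.x)}/{len(self.y)}"
            )
        if self.dt <= 0:
            raise DegenerateInputError("dt must be positive")


@dataclass(frozen=True)
class SegmentFeatures:
    """The 23-value descriptor of one segment, in canonical order."""

    values: np.ndarray          # (23,)
    lle_valid: bool = True      # False when the LLE sentinel was applied

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (N_FEATURES,):
            raise DegenerateInputError(
                f"expected {N_FEATURES} feature values, got {vals.shape}"
            )

    def __getattr__(self, name: str):
        try:
            return self.values[FEATURE_NAMES.index(name)]
        except ValueError:
            raise AttributeError(name) from None


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters (lag tau and dimension m, in samples)."""

    tau: int
    m: int

    def __post_init__(self) -> None:
        if self.tau < 1 or self.m < 1:
            raise EmbeddingError(f"invalid embedding (m={self.m}, tau={self.tau})")

    def n_states(self, n: int) -> int:
        """M = N - (m - 1) * tau reconstructed states for a length-N series."""
        return n - (self.m - 1) * self.tau


@dataclass
class DivergenceCurve:
    """Mean log neighbour separation vs evolution step, and its fitted slope."""

    steps: np.ndarray         # evolution times i (samples)
    mean_log_sep: np.ndarray  # <ln d_j(i)> per step
    initial_sep: float        # mean initial separation d_j(0)
    slope: float              # lambda estimate, 1/s
    fit_range: tuple[int, int]


@dataclass(frozen=True)
class LleResult:
    """LLE estimate plus validity flag; invalid results carry no exponent."""

    value: float
    valid: bool
    curve: DivergenceCurve | None = None


@dataclass(frozen=True)
class LleConfig:
    """Estimator settings used per segment (data-poor 99-sample series)."""

    max_tau: int = 5
    max_m: int = 4
    eps_frac: float = 0.10        # neighbour radius as fraction of amplitude
    theiler: int | None = None    # temporal exclusion window; default = tau
    fit_steps: int = 10           # evolution steps tracked
    ami_bins: int = 16
    fnn_rtol: float = 10.0
    fnn_threshold: float = 0.01
    min_sep_frac: float = 1e-8    # numerical floor on neighbour separation
    rise_frac: float = 0.75       # fraction of total curve rise kept in the fit
    sentinel: float = 0.0         # value substituted for invalid estimates


DEFAULT_LLE_CONFIG = LleConfig()


def extract_analysis_window(recording: GazeRecording, onset: int) -> list[Segment]:
    """Cut the 1000 samples after a stimulus onset into ten 100-sample segments."""
    if onset < 0 or onset + ANALYSIS_WINDOW > recording.n_samples:
        raise TruncationError(
            f"need {ANALYSIS_WINDOW} samples after onset {onset}, recording has "
            f"{recording.n_samples}"
        )
    dt = 1.0 / recording.sampling_rate
    return [
        Segment(
            x=recording.horizontal[onset + i * SEGMENT_LEN:
                                   onset + (i + 1) * SEGMENT_LEN],
            y=recording.vertical[onset + i * SEGMENT_LEN:
                                 onset + (i + 1) * SEGMENT_LEN],
            dt=dt,
        )
        for i in range(SEGMENTS_PER_POINT)
    ]


def differentiate(series, dt: float) -> np.ndarray:
    """First derivative by forward difference; output one sample shorter."""
    series = np.asarray(series, dtype=float)
    if len(series) < 2:
        raise DegenerateInputError("need at least 2 samples to differentiate")
    return np.diff(series) / dt


def _stats4(v: np.ndarray) -> list[float]:
    vmax, vmin = float(np.max(v)), float(np.min(v))
    return [vmax, vmin, float(np.mean(v)), vmax - vmin]


def kinematic_features(segment: Segment) -> np.ndarray:
    """16 velocity/acceleration statistics of one segment.

    Max/min/mean/range for horizontal and vertical velocity, resultant
    velocity sqrt(vx^2 + vy^2), and resultant acceleration (derivative of
    resultant velocity).
    """
    vx = differentiate(segment.x, segment.dt)
    vy = differentiate(segment.y, segment.dt)
    vr = np.hypot(vx, vy)
    ar = differentiate(vr, segment.dt)
    return np.array(_stats4(vx) + _stats4(vy) + _stats4(vr) + _stats4(ar))


def dft_features(velocity, mode: str = "real") -> np.ndarray:
    """First six values of the DFT of a velocity series.

    ``mode='real'`` (default) returns the real parts of z[0]..z[5];
    ``mode='magnitude'`` returns |z[0]|..|z[5]|.
    """
    velocity = np.asarray(velocity, dtype=float)
    if len(velocity) < 6:
        raise DegenerateInputError("need at least 6 samples for 6 DFT values")
    z = np.fft.fft(velocity)[:6]
    if mode == "real":
        return z.real.copy()
    if mode == "magnitude":
        return np.abs(z)
    raise ValueError(f"unknown dft mode {mode!r}")


def average_mutual_information(series, lag: int, bins: int = 16) -> float:
    """AMI (nats) between the series and its lagged copy, histogram estimate."""
    series = np.asarray(series, dtype=float)
    a, b = series[:-lag], series[lag:]
    edges = np.linspace(series.min(), series.max(), bins + 1)
    joint, _, _ = np.histogram2d(a, b, bins=[edges, edges])
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1)
    py = pxy.sum(axis=0)
    nz = pxy > 0
    denom = np.outer(px, py)
    return float(np.sum(pxy[nz] * np.log(pxy[nz] / denom[nz])))


def ami_lag(series, max_lag: int, bins: int = 16) -> int:
    """Embedding lag: first local minimum of average mutual information.

    Falls back to tau = 1 when the AMI profile is structureless (range
    below 0.05 nat, as for iid noise) or strictly decreasing without an
    interior minimum.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 4 * max_lag:
        raise DegenerateInputError(
            f"series of {len(series)} too short for max_lag={max_lag}")
    if np.ptp(series) == 0:
        raise DegenerateInputError("constant series has no mutual information")
    ami = np.array([average_mutual_information(series, k, bins)
                    for k in range(1, max_lag + 1)])
    if np.ptp(ami) < 0.05:
        return 1
    for k in range(len(ami) - 1):
        if ami[k] < ami[k + 1]:
            return k + 1
    return 1


def fnn_dim(series, tau: int, max_m: int,
            rtol: float = 10.0, threshold: float = 0.01) -> int:
    """Embedding dimension by the false-nearest-neighbours criterion.

    Returns the smallest m whose false-neighbour fraction falls below
    ``threshold``; a neighbour pair is false when adding the (m+1)-th delay
    coordinate stretches its distance by more than ``rtol``.  If no m
    qualifies, ``max_m`` is returned with a warning.
    """
    series = np.asarray(series, dtype=float)
    n = len(series)
    if n - max_m * tau < 2:
        raise EmbeddingError(
            f"series of {n} too short for m={max_m}, tau={tau}")
    for m in range(1, max_m + 1):
        n_states = n - m * tau  # states for which the (m+1)-th coordinate exists
        Y = takens_embed(series[: n_states + (m - 1) * tau], m, tau)
        nxt = series[m * tau: m * tau + n_states]
        d = cdist(Y, Y)
        np.fill_diagonal(d, np.inf)
        # exclude numerically coincident states (e.g. exactly periodic
        # series), whose distance ratios are dominated by float rounding
        d[d < 1e-8 * max(np.ptp(series), np.finfo(float).tiny)] = np.inf
        nn = np.argmin(d, axis=1)
        dn = d[np.arange(n_states), nn]
        extra = np.abs(nxt - nxt[nn])
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dn > 0, extra / dn, np.where(extra > 0, np.inf, 0.0))
        frac = float(np.mean(ratio > rtol))
        if frac < threshold:
            return m
    warnings.warn(
        f"false-neighbour fraction never fell below {threshold}; using m={max_m}")
    return max_m


def takens_embed(series, m: int, tau: int) -> np.ndarray:
    """Delay-embed a series: row i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})."""
    series = np.asarray(series, dtype=float)
    M = len(series) - (m - 1) * tau
    if m < 1 or tau < 1:
        raise EmbeddingError(f"invalid embedding (m={m}, tau={tau})")
    if M < 1:
        raise EmbeddingError(
            f"series of {len(series)} cannot embed with m={m}, tau={tau}")
    idx = np.arange(M)[:, None] + tau * np.arange(m)[None, :]
    return series[idx]


def estimate_lle(series, dt: float,
                 params: EmbeddingParams | None = None,
                 config: LleConfig = DEFAULT_LLE_CONFIG) -> LleResult:
    """Largest Lyapunov exponent from the divergence of neighbouring states.

    The series is delay-embedded (estimating tau and m when ``params`` is
    None); each state's nearest neighbour within radius eps — outside a
    Theiler exclusion window — is tracked forward, and the exponent is the
    least-squares slope of <ln d_j(i)> against i*dt over the initial linear
    region of the divergence curve (before it saturates at the attractor
    size).  Degenerate inputs (constant series, no neighbour pairs, an
    infeasible embedding) yield a flagged sentinel, never a bare number.
    """
    series = np.asarray(series, dtype=float)
    amp = float(np.ptp(series))
    if len(series) < 10 or amp == 0:
        return LleResult(config.sentinel, valid=False)

    if params is None:
        try:
            max_lag = max(2, min(config.max_tau, len(series) // 4))
            tau = min(ami_lag(series, max_lag, config.ami_bins), config.max_tau)
            max_m = config.max_m
            while len(series) - max_m * tau < 2 and max_m > 1:
                max_m -= 1
            m = fnn_dim(series, tau, max_m, config.fnn_rtol, config.fnn_threshold)
        except (DegenerateInputError, EmbeddingError):
            return LleResult(config.sentinel, valid=False)
    else:
        tau, m = params.tau, params.m

    try:
        Y = takens_embed(series, m, tau)
    except EmbeddingError:
        return LleResult(config.sentinel, valid=False)
    M = len(Y)
    if M < m + 2:
        return LleResult(config.sentinel, valid=False)

    theiler = config.theiler if config.theiler is not None else tau
    eps = config.eps_frac * amp

    d = cdist(Y, Y)
    ii, jj = np.indices(d.shape, sparse=True)
    d[np.abs(ii - jj) <= theiler] = np.inf
    d[d < config.min_sep_frac * amp] = np.inf  # below the numerical floor
    d[d > eps] = np.inf
    nn = np.argmin(d, axis=1)
    ref = np.flatnonzero(np.isfinite(d[np.arange(M), nn]))
    if len(ref) == 0:
        return LleResult(config.sentinel, valid=False)
    nn = nn[ref]

    steps = np.arange(config.fit_steps + 1)
    mean_log = np.full(len(steps), np.nan)
    for k in steps:
        ok = (ref + k < M) & (nn + k < M)
        if not np.any(ok):
            break
        sep = np.linalg.norm(Y[ref[ok] + k] - Y[nn[ok] + k], axis=1)
        sep = sep[sep > 0]
        if len(sep) == 0:
            break
        mean_log[k] = float(np.mean(np.log(sep)))
    valid_steps = np.flatnonzero(~np.isnan(mean_log))
    if len(valid_steps) < 2:
        return LleResult(config.sentinel, valid=False)
    steps = steps[valid_steps]
    mean_log = mean_log[valid_steps]

    # fit only the initial linear region: once the curve has climbed most of
    # its total rise, pairs are saturating at the attractor size and the
    # local slope no longer reflects the exponent
    rise = float(np.max(mean_log) - mean_log[0])
    if rise < 1.0:  # no appreciable divergence: the whole curve is the region
        k_end = len(steps) - 1
    else:
        below = np.flatnonzero(mean_log <= mean_log[0] + config.rise_frac * rise)
        k_end = int(below[-1]) if len(below) else len(steps) - 1
    k_end = max(k_end, 1)
    slope = float(np.polyfit(steps[: k_end + 1] * dt,
                             mean_log[: k_end + 1], 1)[0])
    curve = DivergenceCurve(
        steps=steps,
        mean_log_sep=mean_log,
        initial_sep=float(np.exp(mean_log[0])),
        slope=slope,
        fit_range=(int(steps[0]), int(steps[k_end])),
    )
    return LleResult(slope, valid=True, curve=curve)


def segment_features(segment: Segment,
                     lle_config: LleConfig = DEFAULT_LLE_CONFIG,
                     dft_mode: str = "real") -> SegmentFeatures:
    """All 23 features of one segment, in canonical order.

    The DFT values and the LLE are computed on the horizontal velocity
    series.  An invalid LLE (constant velocity, no neighbour pairs) is
    mapped to the configured sentinel with ``lle_valid=False`` so feature
    vectors stay NaN-free.
    """
    kin = kinematic_features(segment)
    vx = differentiate(segment.x, segment.dt)
    dft = dft_features(vx, mode=dft_mode)
    lle = estimate_lle(vx, segment.dt, config=lle_config)
    values = np.concatenate([kin, dft, [lle.value if lle.valid
                                        else lle_config.sentinel]])
    return SegmentFeatures(values=values, lle_valid=lle.valid)


def features_table(recordings, lle_config: LleConfig = DEFAULT_LLE_CONFIG,
                   dft_mode: str = "real"):
    """Segment-level feature table for a list of recordings.

    Returns a pandas DataFrame with one row per (subject, session, point,
    segment) and the 23 canonical feature columns plus an ``lle_valid``
    flag.  Stimulus points and segments are numbered from 1.
    """
    import pandas as pd

    rows = []
    for rec in recordings:
        for p, onset in enumerate(rec.onsets, start=1):
            for s, seg in enumerate(extract_analysis_window(rec, int(onset)),
                                    start=1):
                feats = segment_features(seg, lle_config, dft_mode)
                rows.append((rec.subject_id, rec.session_id, p, s,
                             *feats.values, feats.lle_valid))
    return pd.DataFrame(
        rows,
        columns=["subject", "session", "point", "segment",
                 *FEATURE_NAMES, "lle_valid"],
    )
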