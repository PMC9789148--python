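"""Gait parameters from vertical trunk acceleration.

Implements the full wearable-sensor gait panel used in knee-osteoarthritis
cohorts: spatiotemporal measures (speed, cadence, step length, stride /
stance / swing timing), symmetry (autocorrelation step and stride
regularity, step symmetry, swing-time gait asymmetry), variability
(stride- and stance-time CVs, phase coordination index), complexity
(sample entropy, short-term Lyapunov exponent) and spectral descriptors of
the 0.5-3 Hz walking band.

All operations accept a :class:`~gaitpain.types.RawGaitSignal` and, where
timing is needed, a :class:`~gaitpain.types.GaitEventSeries`.  Events can
come from a generator's ground truth, from sidecar annotations, or from
:func:`detect_gait_events`.  Features that cannot be computed on a given
trial (too short, no locatable peak, ...) come back as ``NaN`` and are
treated as missing downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigError, InsufficientDataError, NoGaitError
from .synth import GAIT_FEATURES
from .types import GaitEventSeries, RawGaitSignal

__all__ = [
    "FeatureConfig",
    "detect_gait_events",
    "spatiotemporal",
    "gait_asymmetry",
    "regularity_autocorrelation",
    "variability_cv",
    "sample_entropy",
    "phase_coordination",
    "psd_features",
    "rosenstein_lyapunov",
    "lyapunov_short",
    "extract_trial",
    "extract_all",
    "speed_validity_filter",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants of the extraction stage.

    The walking band (0.5-3 Hz) bounds both event detection and the
    spectral peak search.  Sample entropy uses the field-standard
    ``m = 2``, ``r = 0.2 sd`` on the band-passed trace resampled to 50 Hz.
    The regularity peak search looks within +/-25% of the expected step and
    stride lags.  Toe-offs, when not annotated, are placed one
    double-support interval (default 10% of the stride) after the
    contralateral heel strike.
    """

    band_low_hz: float = 0.5
    band_high_hz: float = 3.0
    min_step_interval_s: float = 0.25
    sampen_m: int = 2
    sampen_r_fraction: float = 0.2
    sampen_resample_hz: float = 50.0
    psd_segment_s: float = 5.0
    psd_overlap: float = 0.5
    regularity_window_fraction: float = 0.25
    lyapunov_embedding_dim: int = 5
    lyapunov_fit_stride_fraction: float = 0.5
    lyapunov_min_duration_s: float = 30.0
    double_support_fraction: float = 0.10


DEFAULT_CONFIG = FeatureConfig()


def _bandpass(x: np.ndarray, fs: float, lo: float, hi: float) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(hi, 0.99 * nyq)
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


# --------------------------------------------------------------------------
# Event detection
# --------------------------------------------------------------------------

def detect_gait_events(
    signal: RawGaitSignal, config: FeatureConfig = DEFAULT_CONFIG
) -> GaitEventSeries:
    """Detect heel strikes from the trunk signal; estimate toe-offs.

    The trace is band-passed to the walking band (zero-phase) and heel
    strikes are taken as its prominent local maxima, at least one minimum
    step interval apart.  Sides are assigned by strict alternation starting
    from ``signal.first_side`` -- a trunk sensor alone cannot disambiguate
    sides, so the convention must come from trial metadata.  Toe-offs are
    estimated kinematically: each leg's toe-off is placed one
    double-support interval after the contralateral heel strike within the
    stride.

    Raises
    ------
    NoGaitError
        If no periodic peaks are found (e.g. a constant trace).
    InsufficientDataError
        If the trial is shorter than 4 s.
    """
    if signal.duration < 4.0:
        raise InsufficientDataError(
            f"trial {signal.trial_id}: need >= 4 s of signal, got {signal.duration:.2f} s"
        )
    x = signal.samples - np.mean(signal.samples)
    if np.ptp(x) == 0:
        raise NoGaitError(f"trial {signal.trial_id}: constant signal, no gait content")
    xf = _bandpass(x, signal.sampling_rate, config.band_low_hz, config.band_high_hz)
    sd = np.std(xf)
    if sd == 0:
        raise NoGaitError(f"trial {signal.trial_id}: no band-limited walking content")
    peaks, _ = sps.find_peaks(
        xf,
        distance=max(1, int(config.min_step_interval_s * signal.sampling_rate)),
        prominence=0.5 * sd,
    )
    if peaks.size < 2:
        raise NoGaitError(f"trial {signal.trial_id}: no gait peaks found")
    strikes = peaks / signal.sampling_rate

    sides = np.empty(strikes.size, dtype=object)
    first = 0 if signal.first_side == "left" else 1
    sides[first::2] = "left"
    sides[1 - first::2] = "right"
    left_hs = strikes[sides == "left"]
    right_hs = strikes[sides == "right"]

    left_to = _estimate_toe_offs(left_hs, right_hs, config.double_support_fraction)
    right_to = _estimate_toe_offs(right_hs, left_hs, config.double_support_fraction)
    return GaitEventSeries(left_hs, right_hs, left_to, right_to)


def _estimate_toe_offs(
    ipsi: np.ndarray, contra: np.ndarray, ds_fraction: float
) -> np.ndarray:
    """Toe-off of the ipsilateral leg = contralateral strike + double support."""
    offs = []
    for h0, h1 in zip(ipsi[:-1], ipsi[1:]):
        inside = contra[(contra > h0) & (contra < h1)]
        if inside.size != 1:
            continue
        offs.append(inside[0] + ds_fraction * (h1 - h0))
    return np.asarray(offs)


# --------------------------------------------------------------------------
# Spatiotemporal parameters
# --------------------------------------------------------------------------

def _stride_cycles(
    events: GaitEventSeries, side: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-stride (stride duration, stance duration, swing duration) arrays."""
    hs = events.heel_strikes(side)
    to = events.toe_offs(side)
    strides, stances, swings = [], [], []
    for h0, h1 in zip(hs[:-1], hs[1:]):
        inside = to[(to > h0) & (to < h1)]
        if inside.size != 1:
            continue
        strides.append(h1 - h0)
        stances.append(inside[0] - h0)
        swings.append(h1 - inside[0])
    return np.asarray(strides), np.asarray(stances), np.asarray(swings)


def spatiotemporal(events: GaitEventSeries, signal: RawGaitSignal) -> dict[str, float]:
    """Speed, cadence, step length and per-side timing from gait events.

    Speed is walk distance over the time from first to last heel strike;
    cadence is steps per minute over the same interval; step length is
    distance per step.
    """
    times, _ = events.merged_heel_strikes()
    out: dict[str, float] = {}
    n_steps = times.size
    min_strides = min(events.left_heel_strikes.size, events.right_heel_strikes.size) - 1
    if min_strides < 4:
        raise InsufficientDataError(
            f"trial {signal.trial_id}: need >= 4 strides per side, got {min_strides}"
        )
    walking_time = times[-1] - times[0]
    out["gait_speed"] = signal.walk_distance / walking_time
    out["cadence"] = n_steps / (walking_time / 60.0)
    out["step_length"] = signal.walk_distance / n_steps

    all_strides = []
    for side in ("left", "right"):
        strides, stances, swings = _stride_cycles(events, side)
        hs = events.heel_strikes(side)
        all_strides.append(np.diff(hs))
        if strides.size == 0:
            out[f"stance_time_{side}"] = np.nan
            out[f"swing_time_{side}"] = np.nan
            out[f"stance_percent_{side}"] = np.nan
            out[f"swing_percent_{side}"] = np.nan
            continue
        out[f"stance_time_{side}"] = float(np.mean(stances))
        out[f"swing_time_{side}"] = float(np.mean(swings))
        out[f"stance_percent_{side}"] = float(100.0 * np.mean(stances / strides))
        out[f"swing_percent_{side}"] = float(100.0 * np.mean(swings / strides))
    out["stride_time"] = float(np.mean(np.concatenate(all_strides)))
    return out


def gait_asymmetry(left_swing: float, right_swing: float) -> float:
    """``100 * |ln(right swing / left swing)|``; 0 is perfect symmetry."""
    if not (left_swing > 0 and right_swing > 0):
        raise ValueError("swing times must be positive")
    return float(100.0 * abs(np.log(right_swing / left_swing)))


# --------------------------------------------------------------------------
# Autocorrelation regularity
# --------------------------------------------------------------------------

def _unbiased_autocorrelation(x: np.ndarray, max_lag: int) -> np.ndarray:
    """r(k) = c(k)/c(0) with c(k) the unbiased autocovariance of demeaned x."""
    x = x - np.mean(x)
    n = x.size
    full = sps.correlate(x, x, mode="full", method="fft")
    c = full[n - 1 : n + max_lag] / (n - np.arange(max_lag + 1))
    if c[0] == 0:
        return np.full(max_lag + 1, np.nan)
    return c / c[0]


def regularity_autocorrelation(
    signal: RawGaitSignal,
    events: GaitEventSeries,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> dict[str, float]:
    """Step and stride regularity of the trunk signal, and their ratio.

    The unbiased autocorrelation of the demeaned trace is evaluated at the
    lag windows +/-25% around the mean step and mean stride durations; the
    window maximum is the regularity value.  Step symmetry is step over
    stride regularity (1 = symmetric centre-of-mass motion).  Values come
    back NaN when a window cannot be evaluated.
    """
    times, _ = events.merged_heel_strikes()
    if times.size < 13:  # 6 strides = 12 steps
        raise InsufficientDataError("need >= 6 strides of signal for regularity")
    step = float(np.mean(np.diff(times)))
    stride = 2.0 * step
    fs = signal.sampling_rate
    frac = config.regularity_window_fraction
    max_lag = int(np.ceil(stride * (1 + frac) * fs))
    if max_lag >= signal.samples.size:
        return {"step_regularity": np.nan, "stride_regularity": np.nan,
                "step_symmetry": np.nan}
    r = _unbiased_autocorrelation(signal.samples, max_lag)

    def window_peak(center_s: float) -> float:
        lo = max(1, int(np.floor(center_s * (1 - frac) * fs)))
        hi = min(max_lag, int(np.ceil(center_s * (1 + frac) * fs)))
        if hi <= lo:
            return np.nan
        seg = r[lo : hi + 1]
        return float(np.nanmax(seg))

    step_reg = window_peak(step)
    stride_reg = window_peak(stride)
    sym = step_reg / stride_reg if stride_reg not in (0.0,) and np.isfinite(stride_reg) else np.nan
    return {
        "step_regularity": step_reg,
        "stride_regularity": stride_reg,
        "step_symmetry": sym,
    }


# --------------------------------------------------------------------------
# Variability
# --------------------------------------------------------------------------

def _cv_percent(values: np.ndarray) -> float:
    """100 * sample sd / mean."""
    m = np.mean(values)
    if m == 0:
        raise ValueError("zero mean interval in CV computation")
    return float(100.0 * np.std(values, ddof=1) / m)


def variability_cv(events: GaitEventSeries) -> dict[str, float]:
    """Stride-time CV (both legs pooled) and per-side stance-time CVs, in %."""
    stride_intervals = np.concatenate([
        np.diff(events.left_heel_strikes),
        np.diff(events.right_heel_strikes),
    ])
    out: dict[str, float] = {}
    if stride_intervals.size < 5:
        raise InsufficientDataError("need >= 5 stride intervals for stride_time_cv")
    out["stride_time_cv"] = _cv_percent(stride_intervals)
    for side in ("left", "right"):
        _, stances, _ = _stride_cycles(events, side)
        out[f"stance_time_cv_{side}"] = (
            _cv_percent(stances) if stances.size >= 5 else np.nan
        )
    return out


# --------------------------------------------------------------------------
# Sample entropy
# --------------------------------------------------------------------------

def sample_entropy(series, m: int = 2, r: float | None = None) -> float:
    """Sample entropy ``-ln(A/B)`` of a 1-D series.

    ``B`` counts pairs of length-``m`` templates within Chebyshev distance
    ``r`` of each other (self-matches excluded), ``A`` the same pairs at
    length ``m + 1``.  Both counts run over the first ``N - m`` templates so
    every length-``m`` template has a length-``m+1`` extension.  ``r``
    defaults to 0.2 times the series sd.  Returns NaN (undefined) when no
    template pair matches at length ``m + 1``.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < m + 2:
        raise InsufficientDataError(f"sample entropy needs >= {m + 2} points, got {n}")
    if r is None:
        r = 0.2 * np.std(x)
    if r < 0:
        raise ValueError("tolerance r must be >= 0")

    emb = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (n - m, m + 1)
    n_templates = emb.shape[0]
    a_count = 0
    b_count = 0
    chunk = 512
    for start in range(0, n_templates, chunk):
        block = emb[start : start + chunk]
        # Chebyshev distances of this block against all later templates
        diff = np.abs(block[:, None, :] - emb[None, :, :])
        d_m = diff[:, :, :m].max(axis=2)
        d_m1 = diff.max(axis=2)
        rows = np.arange(block.shape[0])[:, None] + start
        upper = rows < np.arange(n_templates)[None, :]
        b_count += int(np.count_nonzero((d_m <= r) & upper))
        a_count += int(np.count_nonzero((d_m1 <= r) & upper))
    if b_count == 0 or a_count == 0:
        return np.nan
    return float(-np.log(a_count / b_count))


# --------------------------------------------------------------------------
# Phase coordination
# --------------------------------------------------------------------------

def phase_coordination(events: GaitEventSeries) -> dict[str, float]:
    """Phase coordination index of bilateral stepping, in %.

    For each left-leg stride containing exactly one right heel strike, the
    step phase is ``phi = 360 * (right strike - left strike) / stride``;
    perfect anti-phase walking has ``phi = 180`` degrees.  Then

    * ``phase_cv`` = 100 * sd(phi) / mean(phi)
    * ``phase_abs_diff`` = 100 * mean(|phi - 180|) / 180
    * ``pci`` = phase_cv + phase_abs_diff.

    Strides without a single interior contralateral strike are skipped;
    if more than half are skipped the values are undefined (NaN).
    """
    left = events.left_heel_strikes
    right = events.right_heel_strikes
    if left.size < 6:
        raise InsufficientDataError("need >= 5 full stride cycles for PCI")
    phis = []
    skipped = 0
    for h0, h1 in zip(left[:-1], left[1:]):
        inside = right[(right > h0) & (right < h1)]
        if inside.size != 1:
            skipped += 1
            continue
        phis.append(360.0 * (inside[0] - h0) / (h1 - h0))
    total = left.size - 1
    if skipped > 0.5 * total or len(phis) < 2:
        return {"pci": np.nan, "phase_cv": np.nan, "phase_abs_diff": np.nan}
    phi = np.asarray(phis)
    phase_cv = float(100.0 * np.std(phi, ddof=1) / np.mean(phi))
    phase_abs_diff = float(100.0 * np.mean(np.abs(phi - 180.0)) / 180.0)
    return {
        "pci": phase_cv + phase_abs_diff,
        "phase_cv": phase_cv,
        "phase_abs_diff": phase_abs_diff,
    }


# --------------------------------------------------------------------------
# Spectral features
# --------------------------------------------------------------------------

def psd_features(
    signal: RawGaitSignal, config: FeatureConfig = DEFAULT_CONFIG
) -> dict[str, float]:
    """Dominant frequency in the walking band, its PSD amplitude and width.

    The PSD is estimated by Welch's averaged-periodogram method (Hann
    window, 5 s segments, 50% overlap, so 0.2 Hz bins at default).  The
    width is measured at half of the peak power by linear interpolation,
    clipped to the band.
    """
    if signal.duration < 10.0:
        raise InsufficientDataError("need >= 10 s of signal for spectral features")
    fs = signal.sampling_rate
    nperseg = int(config.psd_segment_s * fs)
    f, pxx = sps.welch(
        signal.samples,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(config.psd_overlap * nperseg),
        detrend="constant",
    )
    band = (f >= config.band_low_hz) & (f <= config.band_high_hz)
    fb, pb = f[band], pxx[band]
    if pb.size == 0 or np.ptp(pb) == 0:
        return {"dominant_frequency": np.nan,
                "amplitude_dominant_frequency": np.nan,
                "width_dominant_frequency": np.nan}
    k = int(np.argmax(pb))
    peak_f, peak_p = fb[k], pb[k]
    half = peak_p / 2.0

    def cross(idx_range, reverse: bool) -> float:
        prev_f, prev_p = peak_f, peak_p
        for i in idx_range:
            if pb[i] <= half:
                # linear interpolation between (prev_f, prev_p) and (fb[i], pb[i])
                return prev_f + (half - prev_p) * (fb[i] - prev_f) / (pb[i] - prev_p)
            prev_f, prev_p = fb[i], pb[i]
        return fb[idx_range[-1]] if len(idx_range) else (fb[0] if reverse else fb[-1])

    left_edge = cross(range(k - 1, -1, -1), True) if k > 0 else fb[0]
    right_edge = cross(range(k + 1, pb.size), False) if k < pb.size - 1 else fb[-1]
    return {
        "dominant_frequency": float(peak_f),
        "amplitude_dominant_frequency": float(peak_p),
        "width_dominant_frequency": float(right_edge - left_edge),
    }


# --------------------------------------------------------------------------
# Short-term Lyapunov exponent (Rosenstein nearest-neighbour divergence)
# --------------------------------------------------------------------------

def rosenstein_lyapunov(
    series,
    emb_dim: int,
    delay: int,
    min_tsep: int,
    fit_start: int,
    fit_end: int,
    dt: float = 1.0,
) -> float:
    """Largest short-term Lyapunov exponent by nearest-neighbour divergence.

    The series is delay-embedded; each state's nearest neighbour at
    temporal separation > ``min_tsep`` is tracked forward and the mean log
    Euclidean divergence curve is fit by least squares over steps
    ``fit_start .. fit_end``.  The slope, divided by ``dt``, estimates the
    exponent per unit time.

    Returns NaN if too few neighbour pairs can be followed.
    """
    x = np.asarray(series, dtype=float)
    m_pts = x.size - (emb_dim - 1) * delay
    if m_pts < max(10, fit_end + 2):
        raise InsufficientDataError("series too short for the requested embedding")
    idx = np.arange(m_pts)[:, None] + np.arange(emb_dim)[None, :] * delay
    emb = x[idx]  # (m_pts, emb_dim)

    dists = np.sqrt(((emb[:, None, :] - emb[None, :, :]) ** 2).sum(axis=2))
    sep = np.abs(np.arange(m_pts)[:, None] - np.arange(m_pts)[None, :])
    dists[sep <= min_tsep] = np.inf
    # initial separations at machine precision (exact repeats of a periodic
    # orbit) carry no dynamical information and their logs drift randomly
    floor = 1e-9 * np.sqrt(emb_dim) * max(np.std(x), np.finfo(float).tiny)
    dists[dists < floor] = np.inf
    # neighbours must be trackable through the fit horizon
    horizon = fit_end
    usable = m_pts - horizon
    if usable < 10:
        raise InsufficientDataError("series too short for the divergence horizon")
    dists[:, usable:] = np.inf
    nn = np.argmin(dists[:usable, :], axis=1)
    finite = np.isfinite(dists[np.arange(usable), nn])
    if finite.sum() < 10:
        return np.nan

    ks = np.arange(horizon + 1)
    log_div = np.full(ks.size, np.nan)
    base = np.arange(usable)[finite]
    partner = nn[finite]
    for k in ks:
        d = np.sqrt(((emb[base + k] - emb[partner + k]) ** 2).sum(axis=1))
        d = d[d > 0]
        if d.size:
            log_div[k] = np.mean(np.log(d))
    fit_ks = ks[fit_start : fit_end + 1]
    fit_y = log_div[fit_start : fit_end + 1]
    ok = np.isfinite(fit_y)
    if ok.sum() < 2:
        return np.nan
    slope = np.polyfit(fit_ks[ok], fit_y[ok], 1)[0]
    return float(slope / dt)


def lyapunov_short(
    signal: RawGaitSignal,
    events: GaitEventSeries | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> float:
    """Short-term Lyapunov exponent of the walking trace, per second.

    The band-passed trace is delay-embedded (dimension 5, delay at the
    first autocorrelation zero crossing) and the divergence slope is fit
    over the first half stride.  Requires at least 30 s of signal.
    """
    if signal.duration < config.lyapunov_min_duration_s:
        raise InsufficientDataError(
            f"need >= {config.lyapunov_min_duration_s:.0f} s of signal for the "
            f"Lyapunov exponent, got {signal.duration:.1f} s"
        )
    fs = signal.sampling_rate
    x = _bandpass(signal.samples - np.mean(signal.samples), fs,
                  config.band_low_hz, config.band_high_hz)

    # delay: first zero crossing of the autocorrelation
    r = _unbiased_autocorrelation(x, int(2.0 * fs))
    below = np.where(r <= 0)[0]
    delay = int(below[0]) if below.size else max(1, int(0.1 * fs))

    if events is not None:
        times, _ = events.merged_heel_strikes()
        stride_s = 2.0 * float(np.mean(np.diff(times)))
    else:
        stride_s = 1.1
    fit_end = max(2, int(config.lyapunov_fit_stride_fraction * stride_s * fs))
    try:
        return rosenstein_lyapunov(
            x,
            emb_dim=config.lyapunov_embedding_dim,
            delay=delay,
            min_tsep=int(stride_s * fs),
            fit_start=0,
            fit_end=fit_end,
            dt=1.0 / fs,
        )
    except InsufficientDataError:
        return np.nan


# --------------------------------------------------------------------------
# Per-trial extraction and trial averaging
# --------------------------------------------------------------------------

def extract_trial(
    signal: RawGaitSignal,
    events: GaitEventSeries | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.Series:
    """Compute every gait parameter for one trial.

    ``events`` may be supplied (annotations or generator ground truth);
    otherwise heel strikes are detected from the trunk trace.  Feature
    groups that cannot be computed yield NaN.
    """
    if events is None:
        events = detect_gait_events(signal, config)
    out = {name: np.nan for name in GAIT_FEATURES}

    def attempt(fn, *args):
        try:
            out.update(fn(*args))
        except (InsufficientDataError, ValueError) as exc:
            log.info("trial %s: %s", signal.trial_id, exc)

    attempt(spatiotemporal, events, signal)
    if np.isfinite(out["swing_time_left"]) and np.isfinite(out["swing_time_right"]):
        out["gait_asymmetry"] = gait_asymmetry(
            out["swing_time_left"], out["swing_time_right"]
        )
    attempt(regularity_autocorrelation, signal, events, config)
    attempt(variability_cv, events)
    attempt(phase_coordination, events)
    attempt(psd_features, signal, config)

    # sample entropy on the band-passed trace resampled to 50 Hz
    try:
        fs = signal.sampling_rate
        xb = _bandpass(signal.samples - np.mean(signal.samples), fs,
                       config.band_low_hz, config.band_high_hz)
        n_out = int(round(signal.duration * config.sampen_resample_hz))
        xr = sps.resample(xb, n_out) if n_out != xb.size else xb
        out["sample_entropy"] = sample_entropy(
            xr, m=config.sampen_m, r=config.sampen_r_fraction * np.std(xr)
        )
    except (InsufficientDataError, ValueError) as exc:
        log.info("trial %s: sample entropy: %s", signal.trial_id, exc)

    try:
        out["lyapunov_short"] = lyapunov_short(signal, events, config)
    except InsufficientDataError as exc:
        log.info("trial %s: lyapunov: %s", signal.trial_id, exc)

    return pd.Series(out, index=list(GAIT_FEATURES), dtype=float)


def extract_all(
    trials: list[RawGaitSignal],
    events: list[GaitEventSeries | None] | None = None,
    config: FeatureConfig = DEFAULT_CONFIG,
) -> pd.Series:
    """Average the per-trial gait parameters over one participant's trials.

    Undefined values propagate as missing: a feature defined in only one
    trial takes that trial's value; a feature defined in neither stays
    NaN.  A single-trial participant is accepted with a logged notice.
    """
    if not trials:
        raise InsufficientDataError("at least one trial is required")
    if events is None:
        events = [None] * len(trials)
    if len(events) != len(trials):
        raise ConfigError("events list must match trials list")
    if len(trials) == 1:
        log.info("participant has a single trial; using it unaveraged")
    vectors = [extract_trial(s, e, config) for s, e in zip(trials, events)]
    mat = pd.concat(vectors, axis=1)
    n_missing = int(mat.isna().sum().sum())
    if n_missing:
        log.info("%d undefined feature values across %d trials", n_missing, len(trials))
    with np.errstate(invalid="ignore"):
        return mat.mean(axis=1, skipna=True)


def speed_validity_filter(
    table: pd.DataFrame, low: float = 0.3, high: float = 2.3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop rows whose gait speed falls outside ``[low, high]`` m/s.

    Returns the retained table and an exclusion log (id + speed per
    excluded row).  The default bounds exclude physically implausible
    over-ground walks; ``high = 1.8`` reproduces the common fast-walker
    sensitivity restriction.
    """
    if low >= high:
        raise ConfigError(f"speed filter misconfigured: low={low} >= high={high}")
    speed = table["gait_speed"]
    keep = (speed >= low) & (speed <= high)
    excluded = table.loc[~keep, [c for c in ("id", "gait_speed") if c in table.columns]]
    if len(excluded):
        log.info("speed filter excluded %d rows", len(excluded))
    return table.loc[keep].copy(), excluded.copy()
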