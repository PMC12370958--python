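"""Spectro-temporal signal descriptors for long (4 s) motion clips.

Implements the six operators used in the spectro-temporal analysis —
Ricker-wavelet entropy, fundamental frequency, wavelet standard deviation at
scale 5, 95%-power PSD bandwidth, zero-lag autocorrelation (the plain sum of
squares) and the unnormalised zero-crossing count — plus the shared
min/max/mean/std statistics, applied over a configurable registry of core
signals (chest/neck velocity and acceleration, tail angle, tip velocity,
hands 3D and feet 2D distance).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .kinematics import METADATA_COLUMNS, compute_signals
from .segmentation import Episode, MotionClip, episode_temporal_params
from .pose import PoseSequence

__all__ = [
    "ricker_cwt",
    "wavelet_entropy",
    "fundamental_frequency",
    "cwt_scale_std",
    "psd_bandwidth",
    "autocorr_zero_lag",
    "zero_crossings",
    "CORE_SIGNALS",
    "core_signal_frame",
    "spectro_feature_table",
]

CWT_WIDTHS = np.arange(1, 10)  # discrete Ricker scales, widths 1..9


def _ricker(points: int, width: float) -> np.ndarray:
    """Sampled Ricker (Mexican hat) wavelet, matching the classic scipy kernel."""
    a = width
    A = 2 / (np.sqrt(3 * a) * np.pi ** 0.25)
    x = np.arange(points) - (points - 1.0) / 2
    mod = 1 - (x / a) ** 2
    return A * mod * np.exp(-(x ** 2) / (2 * a ** 2))


def ricker_cwt(x: np.ndarray, widths: np.ndarray = CWT_WIDTHS) -> np.ndarray:
    """Continuous wavelet transform by direct convolution with the Ricker
    kernel at each width; output shape (len(widths), len(x))."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise ValueError("signal must have at least 2 samples")
    out = np.empty((len(widths), len(x)))
    for i, w in enumerate(widths):
        npts = min(10 * int(w), len(x))
        out[i] = sps.convolve(x, _ricker(npts, w), mode="same")
    return out


def wavelet_entropy(x: np.ndarray) -> float:
    """Shannon entropy of the normalised per-scale Ricker CWT energy.

    Per-scale energy E_i = sum_t |W(a_i, t)|; entropy = -sum d_i ln d_i with
    d_i = E_i / sum_j E_j. Bounded by ln 9; defined as 0 for a zero-energy
    signal.
    """
    W = ricker_cwt(x)
    energy = np.sum(np.abs(W), axis=1)
    total = energy.sum()
    if total <= 0:
        return 0.0
    d = energy / total
    d = d[d > 0]
    return float(-np.sum(d * np.log(d)))


def fundamental_frequency(x: np.ndarray, fs: float) -> float:
    """Lowest positive DFT frequency whose magnitude exceeds 30% of the peak.

    The signal is mean-removed first. Returns NaN when no positive-frequency
    component qualifies (e.g. constant input).
    """
    x = np.asarray(x, float)
    x = x - x.mean()
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    if mag.max() <= 0:
        return float("nan")
    peaks = freqs[(mag > 0.3 * mag.max()) & (freqs > 0)]
    return float(peaks.min()) if peaks.size else float("nan")


def cwt_scale_std(x: np.ndarray, width: int = 5) -> float:
    """Sample std (denominator T-1) of the Ricker CWT coefficients at one width."""
    W = ricker_cwt(x, np.array([width]))
    return float(np.std(W[0], ddof=1))


def psd_bandwidth(x: np.ndarray, fs: float) -> float:
    """Width of the frequency interval containing 95% of the signal's power.

    Welch density with segment length = signal length (Hann window, i.e. a
    modified periodogram); the signal is normalised by its std first. The
    lower bound is the first frequency at which the cumulative power from
    the bottom of the spectrum reaches 95% of the total; the upper bound is
    the frequency at which the cumulative power from the top of the
    spectrum reaches 95%. The bandwidth is the absolute difference, so a
    narrowband signal scores near 0 and broadband noise near the Nyquist
    range. A constant signal has bandwidth 0.
    """
    x = np.asarray(x, float)
    if x.size < 8:
        raise ValueError("signal must have at least 8 samples")
    sd = x.std()
    if sd == 0:
        return 0.0
    f, psd = sps.welch(x / sd, fs=fs, nperseg=len(x))
    pcum = np.cumsum(psd)
    total = pcum[-1]
    if total <= 0:
        return 0.0
    lo = int(np.argmax(pcum >= 0.95 * total))
    rcum = np.cumsum(psd[::-1])
    hi = len(psd) - 1 - int(np.argmax(rcum >= 0.95 * total))
    return float(abs(f[hi] - f[lo]))


def autocorr_zero_lag(x: np.ndarray) -> float:
    """Zero-lag autocorrelation: the plain sum of squares sum_t x_t^2."""
    x = np.asarray(x, float)
    return float(np.sum(x * x))


def zero_crossings(x: np.ndarray) -> int:
    """Unnormalised zero-crossing count: steps where |sgn(x_t)-sgn(x_{t-1})| = 2."""
    s = np.sign(np.asarray(x, float))
    return int(np.sum(np.abs(np.diff(s)) == 2))


# ---------------------------------------------------------------------------

CORE_SIGNALS = [
    "chest_speed_3d", "chest_accel_3d", "neck_speed_3d", "neck_accel_3d",
    "tail_angle", "tip_speed_3d", "hands_dist_3d", "feet_dist_2d",
]


def core_signal_frame(seq: PoseSequence,
                      core: list[str] | None = None) -> pd.DataFrame:
    """Per-frame values of the core spectro-temporal signals.

    Accelerations are forward differences of the corresponding speed scaled
    by fs (first element duplicated).
    """
    core = CORE_SIGNALS if core is None else core
    signals = compute_signals(seq)
    out = {}
    for name in core:
        if name.endswith("_accel_3d"):
            sp = signals[name.replace("_accel_3d", "_speed_3d")].to_numpy()
            acc = np.diff(sp) * seq.fs
            out[name] = np.concatenate(([acc[0]], acc))
        else:
            out[name] = signals[name].to_numpy()
    return pd.DataFrame(out)


_OPERATORS = ("wavelet_entropy", "fundamental_freq", "cwt_std_w5",
              "psd_bandwidth", "autocorr", "zero_crossings",
              "min", "max", "mean", "std")


def _apply_operator(op: str, x: np.ndarray, fs: float) -> float:
    if op == "wavelet_entropy":
        return wavelet_entropy(x)
    if op == "fundamental_freq":
        return fundamental_frequency(x, fs)
    if op == "cwt_std_w5":
        return cwt_scale_std(x, 5)
    if op == "psd_bandwidth":
        return psd_bandwidth(x, fs)
    if op == "autocorr":
        return autocorr_zero_lag(x)
    if op == "zero_crossings":
        return float(zero_crossings(x))
    if op == "min":
        return float(np.min(x))
    if op == "max":
        return float(np.max(x))
    if op == "mean":
        return float(np.mean(x))
    return float(np.std(x, ddof=1))


def spectro_feature_table(seq: PoseSequence, episodes: list[Episode],
                          clips: list[MotionClip], clip_len: int = 120,
                          core: list[str] | None = None) -> pd.DataFrame:
    """Spectro-temporal feature table over long clips.

    Columns: |core signals| x 10 operators + 8 episode temporal parameters.
    Operator failures on degenerate inputs are coded as NaN.
    """
    core = CORE_SIGNALS if core is None else core
    frame = core_signal_frame(seq, core)
    temporal = episode_temporal_params(episodes, seq, clip_len)
    temporal = temporal.set_index("episode_ordinal") if len(temporal) else temporal
    rows = []
    for clip in clips:
        if clip.n_frames != clip_len:
            raise ValueError("spectro features require fixed long clips")
        rec = {}
        for name in core:
            x = frame[name].to_numpy()[clip.start_frame:clip.end_frame]
            x = x[np.isfinite(x)]
            for op in _OPERATORS:
                key = f"{name}__{op}"
                try:
                    rec[key] = _apply_operator(op, x, seq.fs) if x.size >= 8 \
                        else float("nan")
                except ValueError:
                    rec[key] = float("nan")
        for tname in temporal.columns:
            rec[tname] = temporal.loc[clip.episode_ordinal, tname]
        rec["episode_ordinal"] = float(clip.episode_ordinal)
        rec["clip_index"] = clip.clip_index
        rec["mouse_id"] = seq.mouse_id
        rec["group"] = seq.group
        rec["week"] = seq.week
        rows.append(rec)
    cols = METADATA_COLUMNS + [f"{n}__{op}" for n in core for op in _OPERATORS] \
        + ["motion_duration_s", "motion_interval_s", "clip_count",
           "onset_time_s", "chest_path_length_cm", "mean_chest_speed_2d",
           "rest_ratio", "episode_ordinal"]
    return pd.DataFrame(rows, columns=cols)
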