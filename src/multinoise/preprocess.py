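"""Reverse-correlation preprocessing: from raw stimulus + spikes to a
binned input/count dataset.

The linear filter is the spike-triggered average decorrelated by the
stimulus autocovariance (whitened regression), optionally smoothed by a
zero-phase low-pass.  Time is then partitioned into windows of twice the
filter's half-max width — long enough that neighboring filtered-stimulus
values are nearly uncorrelated — and each window contributes one (mean
filtered value, summed spike count) pair; filtered values are z-scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.linalg import solve_toeplitz

from .model import BinnedDataset

__all__ = ["StimulusTrace", "LinearFilter", "estimate_filter", "smooth_filter",
           "bin_dataset", "spike_times_to_frame_counts"]


def spike_times_to_frame_counts(times, frame_dt: float, n_frames: int) -> np.ndarray:
    """Convert spike times (seconds) to per-frame counts.

    Frames are half-open intervals [k*dt, (k+1)*dt); a spike exactly on a
    boundary belongs to the later frame.  Spikes outside the recording are
    rejected.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (times.min() < 0 or times.max() >= n_frames * frame_dt):
        raise ValueError("spike times fall outside the recording")
    idx = np.floor(times / frame_dt).astype(int)
    return np.bincount(idx, minlength=n_frames)


@dataclass
class StimulusTrace:
    """A single-pixel contrast trace; one value per stimulus frame."""

    values: np.ndarray
    frame_dt: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("stimulus values must be finite")
        if not (self.frame_dt > 0):
            raise ValueError("frame_dt must be positive")


@dataclass
class LinearFilter:
    """A temporal filter: tap weights over lags 0..n-1 (frames), spacing dt."""

    taps: np.ndarray
    dt: float

    def __post_init__(self):
        self.taps = np.asarray(self.taps, dtype=float)
        if not np.all(np.isfinite(self.taps)):
            raise ValueError("filter taps must be finite")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")

    @property
    def half_max_width(self) -> float:
        """Width (seconds) of the absolute filter at half its peak magnitude.

        Measured around the global extremum of |taps|; secondary lobes beyond
        the half-max crossings are ignored.
        """
        a = np.abs(self.taps)
        peak = int(np.argmax(a))
        if a[peak] <= 0:
            raise ValueError("degenerate (all-zero) filter has no half-max width")
        half = a[peak] / 2.0
        left = peak
        while left > 0 and a[left - 1] >= half:
            left -= 1
        right = peak
        n = len(a)
        while right < n - 1 and a[right + 1] >= half:
            right += 1
        # linear interpolation to the crossing points
        lo = left - (a[left] - half) / (a[left] - a[left - 1]) if left > 0 else 0.0
        hi = right + (a[right] - half) / (a[right] - a[right + 1]) if right < n - 1 else float(n - 1)
        return float((hi - lo) * self.dt)


def estimate_filter(stim: StimulusTrace, spike_counts_per_frame, n_lags: int,
                    ridge: float = 0.0) -> LinearFilter:
    """Reverse-correlation filter estimate: the spike-triggered average
    corrected for stimulus autocorrelation.

    Solves the Toeplitz system C a = sta, where C is the stimulus
    autocovariance over the filter lags; for white stimuli the correction
    reduces to a scalar.  A ridge term stabilizes ill-conditioned stimuli
    (applied automatically, with a warning, if the plain solve fails).
    """
    s = stim.values
    r = np.asarray(spike_counts_per_frame, dtype=float)
    if len(s) != len(r):
        raise ValueError("stimulus and spike arrays must have equal length")
    if len(s) < 10 * n_lags:
        raise ValueError("trace too short relative to n_lags")
    n = len(s)
    s0 = s - s.mean()
    # cross-correlation: sta[k] = mean over t of r[t] * s[t-k]
    nsp = r.sum()
    if nsp <= 0:
        raise ValueError("no spikes in the recording")
    sta = np.array([np.dot(r[k:], s0[: n - k]) for k in range(n_lags)]) / n
    # stimulus autocovariance at lags 0..n_lags-1
    acov = np.array([np.dot(s0[k:], s0[: n - k]) for k in range(n_lags)]) / n
    acov0 = acov.copy()
    acov0[0] += ridge
    try:
        taps = solve_toeplitz(acov0, sta)
        if not np.all(np.isfinite(taps)):
            raise np.linalg.LinAlgError("non-finite solution")
    except Exception:
        warnings.warn("singular stimulus autocovariance; using ridge regularization",
                      RuntimeWarning)
        acov0[0] = acov[0] * (1 + 1e-3)
        taps = solve_toeplitz(acov0, sta)
    return LinearFilter(taps=taps, dt=stim.frame_dt)


def smooth_filter(f: LinearFilter, cutoff_hz: float = 13.0,
                  numtaps: int = 61) -> LinearFilter:
    """Zero-phase low-pass smoothing of the filter taps (windowed-sinc FIR).

    The symmetric Hamming-windowed sinc kernel is applied by reflection-padded
    convolution, giving zero phase shift; energy above the cutoff is
    attenuated by well over 20 dB.
    """
    fs = 1.0 / f.dt
    if cutoff_hz >= fs / 2:
        raise ValueError(f"cutoff {cutoff_hz} Hz is at or above Nyquist ({fs / 2} Hz)")
    numtaps = min(numtaps, 2 * (len(f.taps) // 2) + 1)
    kernel = signal.firwin(numtaps, cutoff_hz, fs=fs)
    pad = numtaps // 2
    padded = np.concatenate([f.taps[pad:0:-1], f.taps, f.taps[-2:-pad - 2:-1]])
    smoothed = np.convolve(padded, kernel, mode="valid")
    return LinearFilter(taps=smoothed, dt=f.dt)


def bin_dataset(f: LinearFilter, stim: StimulusTrace, spike_counts_per_frame,
                window_s: float | None = None) -> BinnedDataset:
    """Convolve, window, and z-score into a BinnedDataset.

    The window length defaults to twice the filter's half-max width, rounded
    down to whole frames (this makes neighboring filtered values nearly
    uncorrelated for white-noise stimuli).  Each window stores the mean
    filtered value and the summed spike count; a trailing partial window is
    dropped and reported in ``meta``.  Filtered values are z-scored.
    """
    r = np.asarray(spike_counts_per_frame, dtype=float)
    if len(r) != len(stim.values):
        raise ValueError("stimulus and spike arrays must have equal length")
    if window_s is None:
        window_s = 2.0 * f.half_max_width
    win_frames = int(np.floor(window_s / stim.frame_dt))
    if win_frames < 1:
        raise ValueError(f"window {window_s:.4g} s is shorter than one frame "
                         f"({stim.frame_dt:.4g} s)")
    filt = signal.lfilter(f.taps, [1.0], stim.values)
    n_win = len(r) // win_frames
    used = n_win * win_frames
    xw = filt[:used].reshape(n_win, win_frames).mean(axis=1)
    rw = r[:used].reshape(n_win, win_frames).sum(axis=1)
    xz = (xw - xw.mean()) / xw.std()
    return BinnedDataset(
        inputs=xz,
        counts=rw.astype(int),
        bin_width=win_frames * stim.frame_dt,
        meta={
            "window_frames": win_frames,
            "dropped_frames": int(len(r) - used),
            "dropped_spikes": float(r[used:].sum()),
            "x_mean": float(xw.mean()),
            "x_sd": float(xw.std()),
        },
    )
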