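"""Epoch preprocessing and z-baselined time-frequency representations.

Low frequencies (1-30 Hz, 1 Hz steps) are estimated with a sliding
Hann-tapered Fourier transform (300 ms window, 50 ms steps); high frequencies
(31-100 Hz) with a sliding multitaper estimate (200 ms window, 50 ms steps,
+-15 Hz spectral smoothing, K = 5 Slepian tapers from the 2*T*W - 1 rule).
Power is evaluated at exactly the requested frequencies via windowed inner
products with complex exponentials, so the 1 Hz stepping is independent of
the window length.  Windows that would need data outside the epoch are
dropped; epochs are never padded.

z-baselining subtracts, per subject-channel-frequency, the mean of the
all-trial-average power over a baseline window and divides by its sample
standard deviation.  The cue-locked baseline is (-650, -150) ms; the
stimulus-locked baseline shifts it by the maximum cue-to-stimulus interval
(500 ms cue + 1400 ms blank = 1900 ms) to (-2550, -2050) ms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.signal

from . import design
from .synth import EpochsSet

__all__ = [
    "TrialTFR",
    "TFRSet",
    "epoch_and_detrend",
    "bandpass",
    "rereference_common_average",
    "timelock",
    "tfr_hanning",
    "tfr_multitaper",
    "average_by_condition",
    "stack_subjects",
    "zbaseline",
    "cue_locked_baseline",
    "stimulus_locked_baseline",
    "LOW_BAND_FREQS",
    "HIGH_BAND_FREQS",
]

LOW_BAND_FREQS = np.arange(1, 31)
HIGH_BAND_FREQS = np.arange(31, 101)

CUE_BASELINE_MS = (-650.0, -150.0)


def cue_locked_baseline() -> tuple[float, float]:
    """Baseline window for cue-locked data, ms relative to cue onset.

    500 ms of pre-cue data ending 150 ms before the cue: the 150 ms gap is
    the half-length of the 300 ms analysis window, so no baseline estimate
    mixes in post-cue samples.
    """
    return CUE_BASELINE_MS


def stimulus_locked_baseline(
    cue_baseline_ms: tuple[float, float] = CUE_BASELINE_MS,
    cue_duration_ms: float = 500.0,
    max_blank_ms: float = 1400.0,
) -> tuple[float, float]:
    """Derive the stimulus-locked baseline from the cue-locked one.

    The same pre-cue data segment expressed on the stimulus-locked axis:
    shifted by the maximum cue-to-stimulus interval (cue duration plus the
    longest blank), so the window is guaranteed to precede the cue on every
    trial.  With the defaults this is (-2550, -2050) ms.
    """
    shift = cue_duration_ms + max_blank_ms
    return (cue_baseline_ms[0] - shift, cue_baseline_ms[1] - shift)


# ---------------------------------------------------------------------------
# preprocessing

def epoch_and_detrend(epochs: EpochsSet) -> EpochsSet:
    """Center and linearly detrend every trial-channel trace.

    Closed-form least squares: the mean and the projection onto the centered
    time ramp are subtracted, leaving residuals orthogonal to (1, t).
    """
    n_t = epochs.data.shape[2]
    if n_t < 2:
        raise ValueError("need at least 2 samples per epoch to detrend")
    data = epochs.data.astype(np.float64)
    t = np.arange(n_t, dtype=np.float64)
    t -= t.mean()
    data = data - data.mean(axis=-1, keepdims=True)
    slope = (data @ t)[..., None] / (t @ t)
    data -= slope * t
    return epochs.copy_with(data=data)


def bandpass(epochs: EpochsSet, lo: float, hi: float) -> EpochsSet:
    """Zero-phase 4th-order Butterworth band-pass (forward-backward)."""
    nyq = epochs.srate / 2.0
    if not (0.0 < lo < hi < nyq):
        raise ValueError(f"invalid band ({lo}, {hi}) for srate {epochs.srate}")
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=epochs.srate, output="sos")
    data = scipy.signal.sosfiltfilt(sos, epochs.data.astype(np.float64), axis=-1)
    return epochs.copy_with(data=data)


def rereference_common_average(epochs: EpochsSet) -> EpochsSet:
    """Re-reference to the common average of all channels."""
    if epochs.data.shape[1] < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return epochs.copy_with(data=data)


def timelock(
    epochs: EpochsSet,
    lock: str,
    schedule: pd.DataFrame,
    soa_bounds_ms: tuple[float, float] | None = (1500.0, 1900.0),
) -> EpochsSet:
    """Re-express the trial time axes relative to the requested lock event.

    Each trial is shifted by its cue-to-stimulus interval (``soa_ms`` in the
    schedule, rounded to whole samples) and the trials are cropped to their
    common time range.  Data values are unchanged.  ``soa_bounds_ms`` guards
    against offsets outside the design's jitter range; pass ``None`` to skip.
    """
    if lock not in ("cue", "stimulus"):
        raise ValueError("lock must be 'cue' or 'stimulus'")
    if lock == epochs.lock:
        return epochs.copy_with(data=epochs.data.copy())

    soa = schedule["soa_ms"].to_numpy(dtype=float)[epochs.schedule_ref]
    if np.any(~np.isfinite(soa)):
        bad = epochs.schedule_ref[~np.isfinite(soa)]
        raise ValueError(f"missing cue-to-stimulus offset for schedule rows {bad.tolist()}")
    if soa_bounds_ms is not None:
        lo, hi = soa_bounds_ms
        if np.any((soa < lo) | (soa > hi)):
            raise ValueError(f"cue-to-stimulus offsets outside [{lo}, {hi}] ms")

    dt = 1000.0 / epochs.srate
    # stimulus -> cue: cue-locked time = stimulus-locked time + soa
    sign = 1.0 if lock == "cue" else -1.0
    shifts = np.round(sign * soa / dt).astype(int)
    smin, smax = shifts.min(), shifts.max()
    n_t = epochs.data.shape[2]
    n_keep = n_t - (smax - smin)
    if n_keep < 1:
        raise ValueError("no common time range after re-locking")
    new_times = epochs.times[0] + (np.arange(n_keep) + smax) * dt
    # trial i contributes samples starting at index smax - shifts[i]
    out = np.empty(epochs.data.shape[:2] + (n_keep,), dtype=epochs.data.dtype)
    for i, s in enumerate(shifts):
        start = smax - s
        out[i] = epochs.data[i, :, start:start + n_keep]
    return epochs.copy_with(data=out, times=new_times, lock=lock)


# ---------------------------------------------------------------------------
# time-frequency estimation

@dataclass
class TrialTFR:
    """Per-trial power: trials x channels x frequencies x times (raw units)."""

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray  # window-center times, ms
    lock: str
    subject_id: str
    schedule_ref: np.ndarray
    channel_names: tuple[str, ...]


def _window_centers(times: np.ndarray, srate: float, n_win: int, step_ms: float,
                    center_windows_ms=None):
    """Window-center times on the step grid, with their start sample indices.

    Centers lie on integer multiples of ``step_ms`` (t = 0 is always on the
    grid); a center is kept only if the full window fits inside the epoch.
    ``center_windows_ms``, when given, restricts the centers to the union of
    the listed closed time intervals (a pure computational restriction).
    """
    dt = 1000.0 / srate
    half = n_win // 2
    n_t = len(times)
    k0 = int(np.floor(times[0] / step_ms)) - 1
    k1 = int(np.ceil(times[-1] / step_ms)) + 1
    centers, starts = [], []
    for k in range(k0, k1 + 1):
        t_c = k * step_ms
        if center_windows_ms is not None and not any(
            w0 <= t_c <= w1 for w0, w1 in center_windows_ms
        ):
            continue
        c_idx = int(np.round((t_c - times[0]) / dt))
        start = c_idx - half
        if start >= 0 and start + n_win <= n_t and abs(times[0] + c_idx * dt - t_c) <= dt / 2 + 1e-9:
            centers.append(t_c)
            starts.append(start)
    return np.asarray(centers, dtype=float), np.asarray(starts, dtype=int)


def _sliding_power(data: np.ndarray, srate: float, starts: np.ndarray,
                   tapers: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Mean over tapers of squared windowed inner products at exact frequencies.

    ``tapers`` is (K, n_win); returns (trials, channels, n_freqs, n_centers).
    Projection matrices are combined into a single complex matmul per call.
    """
    n_win = tapers.shape[1]
    n_k = tapers.shape[0]
    n_f = len(freqs)
    t_rel = np.arange(n_win) / srate
    # (n_win, K * n_freqs): taper k modulated by each analysis frequency
    basis = np.exp(-2j * np.pi * np.outer(t_rel, freqs))  # (n_win, n_freqs)
    proj = (tapers[:, :, None] * basis[None, :, :]).transpose(1, 0, 2).reshape(
        n_win, n_k * n_f
    )
    proj_re = np.ascontiguousarray(proj.real, dtype=np.float32)
    proj_im = np.ascontiguousarray(proj.imag, dtype=np.float32)
    n_tr, n_ch = data.shape[:2]
    n_c = len(starts)
    idx = starts[:, None] + np.arange(n_win)[None, :]
    segs = data.reshape(-1, data.shape[2]).astype(np.float32)[:, idx]
    segs = segs.reshape(-1, n_win)  # (tr*ch*n_c, n_win)
    # two real GEMMs instead of one complex one: same inner products
    power = (segs @ proj_re) ** 2 + (segs @ proj_im) ** 2
    power = power.reshape(n_tr, n_ch, n_c, n_k, n_f).mean(axis=3)
    return power.transpose(0, 1, 3, 2).astype(np.float64)


def tfr_hanning(
    epochs: EpochsSet,
    freqs: np.ndarray | None = None,
    window_ms: float = 300.0,
    step_ms: float = 50.0,
    center_windows_ms=None,
) -> TrialTFR:
    """Sliding Hann-window Fourier power for the low-frequency band."""
    if freqs is None:
        freqs = LOW_BAND_FREQS
    freqs = np.asarray(freqs, dtype=float)
    n_win = int(np.round(window_ms * epochs.srate / 1000.0))
    if n_win > epochs.data.shape[2]:
        raise ValueError("analysis window longer than epoch")
    taper = np.hanning(n_win)
    taper = taper / taper.sum() * 2.0  # unit-amplitude sinusoid at f -> power ~ 1
    centers, starts = _window_centers(epochs.times, epochs.srate, n_win, step_ms,
                                      center_windows_ms)
    if len(centers) == 0:
        raise ValueError("epoch too short for a single full window")
    power = _sliding_power(epochs.data, epochs.srate, starts, taper[None, :], freqs)
    return TrialTFR(power, freqs, centers, epochs.lock, epochs.subject_id,
                    epochs.schedule_ref, epochs.channel_names)


def tfr_multitaper(
    epochs: EpochsSet,
    freqs: np.ndarray | None = None,
    window_ms: float = 200.0,
    step_ms: float = 50.0,
    smoothing_hz: float = 15.0,
    center_windows_ms=None,
) -> TrialTFR:
    """Sliding-window multitaper power for the high-frequency band.

    The time-bandwidth product NW = T * W (T the window length in s, W the
    half-bandwidth in Hz) gives K = floor(2*NW) - 1 Slepian tapers; with the
    defaults NW = 3 and K = 5.
    """
    if freqs is None:
        freqs = HIGH_BAND_FREQS
    freqs = np.asarray(freqs, dtype=float)
    n_win = int(np.round(window_ms * epochs.srate / 1000.0))
    if n_win > epochs.data.shape[2]:
        raise ValueError("analysis window longer than epoch")
    nw = (window_ms / 1000.0) * smoothing_hz
    k = int(np.floor(2 * nw)) - 1
    if k < 1:
        raise ValueError("smoothing too small for the window length (no tapers)")
    tapers = scipy.signal.windows.dpss(n_win, nw, Kmax=k)
    centers, starts = _window_centers(epochs.times, epochs.srate, n_win, step_ms,
                                      center_windows_ms)
    if len(centers) == 0:
        raise ValueError("epoch too short for a single full window")
    power = _sliding_power(epochs.data, epochs.srate, starts, tapers, freqs)
    return TrialTFR(power, freqs, centers, epochs.lock, epochs.subject_id,
                    epochs.schedule_ref, epochs.channel_names)


# ---------------------------------------------------------------------------
# condition averaging and baselining

@dataclass
class TFRSet:
    """Condition-averaged power: subjects x 9 conditions x channels x freqs x times.

    ``counts`` records trials per subject and condition (used as weights when
    pooling conditions for the baseline statistics).  Before baselining the
    values are raw power; afterwards they are z-units relative to the
    baseline window.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    band: str  # "low" or "high"
    lock: str
    baselined: bool
    baseline_window: tuple[float, float] | None
    counts: np.ndarray
    channel_names: tuple[str, ...]
    subject_ids: tuple[str, ...]

    def __post_init__(self):
        if self.power.ndim != 5:
            raise ValueError("power must be subjects x conditions x channels x freqs x times")
        if self.power.shape[1] != 9:
            raise ValueError("expected 9 condition cells")

    def time_slice(self, window: tuple[float, float]) -> "TFRSet":
        """Restrict to window-center times within the closed interval."""
        keep = (self.times >= window[0]) & (self.times <= window[1])
        if not keep.any():
            raise ValueError(f"no TFR samples inside window {window}")
        return replace(self, power=self.power[..., keep], times=self.times[keep])


def _infer_band(freqs: np.ndarray) -> str:
    return "low" if freqs.max() <= 30.0 else "high"


def average_by_condition(trial_tfr: TrialTFR, schedule: pd.DataFrame) -> TFRSet:
    """Average trial power within each of the 9 cue x stimulus cells.

    Cells follow the canonical grid order of :func:`design.build_condition_grid`.
    An empty cell is an error naming the cell.
    """
    cells = design.build_condition_grid()
    cue_col = schedule["cue_intensity"].to_numpy()[trial_tfr.schedule_ref]
    stim_col = schedule["stim_intensity"].to_numpy()[trial_tfr.schedule_ref]
    out = np.empty((1, 9) + trial_tfr.power.shape[1:], dtype=np.float64)
    counts = np.zeros((1, 9), dtype=int)
    for i, cell in enumerate(cells):
        sel = (cue_col == cell.cue_intensity) & (stim_col == cell.stim_intensity)
        if not sel.any():
            raise ValueError(
                f"no trials in condition cell (cue={cell.cue_intensity}, "
                f"stim={cell.stim_intensity})"
            )
        out[0, i] = trial_tfr.power[sel].mean(axis=0)
        counts[0, i] = int(sel.sum())
    return TFRSet(
        power=out,
        freqs=trial_tfr.freqs.copy(),
        times=trial_tfr.times.copy(),
        band=_infer_band(trial_tfr.freqs),
        lock=trial_tfr.lock,
        baselined=False,
        baseline_window=None,
        counts=counts,
        channel_names=trial_tfr.channel_names,
        subject_ids=(trial_tfr.subject_id,),
    )


def stack_subjects(tfrs: list[TFRSet]) -> TFRSet:
    """Concatenate single-subject TFRSets along the subject axis."""
    if not tfrs:
        raise ValueError("no TFRSets to stack")
    first = tfrs[0]
    for t in tfrs[1:]:
        if (t.band, t.lock, t.baselined) != (first.band, first.lock, first.baselined):
            raise ValueError("cannot stack TFRSets with differing band/lock/baseline state")
        if not (np.array_equal(t.freqs, first.freqs) and np.array_equal(t.times, first.times)):
            raise ValueError("cannot stack TFRSets with differing axes")
    return replace(
        first,
        power=np.concatenate([t.power for t in tfrs], axis=0),
        counts=np.concatenate([t.counts for t in tfrs], axis=0),
        subject_ids=tuple(sid for t in tfrs for sid in t.subject_ids),
    )


def zbaseline(tfr: TFRSet, window: tuple[float, float]) -> TFRSet:
    """z-score the power against a baseline window, per subject-channel-frequency.

    The baseline mean and sample standard deviation (N-1 denominator) are
    computed from the all-trial average power - the trial-count-weighted mean
    over the nine condition cells - restricted to the window's time points,
    then applied to every data point of that subject-channel-frequency.
    """
    if tfr.baselined:
        raise ValueError("TFRSet is already baselined")
    keep = (tfr.times >= window[0]) & (tfr.times <= window[1])
    if keep.sum() < 2:
        raise ValueError(f"baseline window {window} covers fewer than 2 TFR samples")
    weights = tfr.counts.astype(np.float64)  # (S, 9)
    pooled = np.einsum("sc,scxft->sxft", weights, tfr.power) / weights.sum(axis=1)[
        :, None, None, None
    ]
    base = pooled[..., keep]  # (S, ch, F, n_base)
    mu = base.mean(axis=-1)
    sd = base.std(axis=-1, ddof=1)
    bad = sd <= 0
    if bad.any():
        s, c, f = np.argwhere(bad)[0]
        raise ValueError(
            f"zero baseline SD for subject {tfr.subject_ids[s]!r}, "
            f"channel {tfr.channel_names[c]!r}, frequency {tfr.freqs[f]} Hz"
        )
    power = (tfr.power - mu[:, None, :, :, None]) / sd[:, None, :, :, None]
    return replace(tfr, power=power, baselined=True, baseline_window=tuple(window))
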