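"""Synthetic cue-stimulus EEG and ratings with known injected effects.

The generator emulates the oscillatory phenomenology the analysis is built to
detect: stimulus-locked event-related desynchronization (ERD) of alpha-to-beta
power that deepens with stimulus intensity (INT) and with cued intensity
(EXP), and gamma synchronization (ERS) that grows with the absolute
prediction error (PE).  Each trial is 1/f background noise (independent per
channel) plus band-limited sinusoids with per-trial random phase and
frequency, weighted across the montage by smooth topographies.  During the
two-second stimulus window the alpha and beta amplitudes are multiplied by::

    1 + g_pe_low * PE - g_int * INT - g_exp * EXP

and the gamma amplitude by ``1 + g_pe_gamma * PE``; outside the window the
amplitudes equal their baseline values.  Because the modulation is
multiplicative on amplitude, band power scales as ``(1 + m)**2`` - the
closed form the Monte-Carlo tests use as an oracle.

Only trials in which a picture was cued and a picture was shown receive EEG;
pain-modality rows exist in the schedule but are not synthesized, mirroring
the restriction of the analysis to modality-congruent picture trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.fft

from . import design

__all__ = [
    "Montage",
    "EffectSpec",
    "EpochsSet",
    "make_montage",
    "simulate_subject_eeg",
    "simulate_ratings",
]


@dataclass(frozen=True)
class Montage:
    """EEG channel layout with a spatial neighbor relation.

    ``neighbors`` must be symmetric and irreflexive and contain every channel
    as a key (possibly with an empty set).
    """

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 2), arbitrary units
    neighbors: dict[str, frozenset[str]]

    def __post_init__(self):
        names = set(self.channel_names)
        if set(self.neighbors) != names:
            raise ValueError("neighbor map must cover exactly the montage channels")
        for ch, nbs in self.neighbors.items():
            if ch in nbs:
                raise ValueError(f"channel {ch} listed as its own neighbor")
            for nb in nbs:
                if ch not in self.neighbors[nb]:
                    raise ValueError(f"neighbor relation not symmetric for ({ch}, {nb})")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean channel x channel adjacency in ``channel_names`` order."""
        idx = {ch: i for i, ch in enumerate(self.channel_names)}
        adj = np.zeros((self.n_channels, self.n_channels), dtype=bool)
        for ch, nbs in self.neighbors.items():
            for nb in nbs:
                adj[idx[ch], idx[nb]] = True
        return adj

    def edges(self) -> list[tuple[int, int]]:
        """Undirected neighbor pairs as channel indices (i < j)."""
        idx = {ch: i for i, ch in enumerate(self.channel_names)}
        out = set()
        for ch, nbs in self.neighbors.items():
            for nb in nbs:
                i, j = idx[ch], idx[nb]
                out.add((min(i, j), max(i, j)))
        return sorted(out)


def make_montage(n_rows: int, n_cols: int) -> Montage:
    """Rectangular grid montage with 4-connected spatial adjacency."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    names = []
    positions = []
    for r in range(n_rows):
        for c in range(n_cols):
            names.append(f"ch_{r}_{c}")
            positions.append((float(r), float(c)))
    neighbors: dict[str, set[str]] = {nm: set() for nm in names}
    for r in range(n_rows):
        for c in range(n_cols):
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    neighbors[f"ch_{r}_{c}"].add(f"ch_{rr}_{cc}")
    return Montage(
        tuple(names),
        np.asarray(positions, dtype=float),
        {k: frozenset(v) for k, v in neighbors.items()},
    )


@dataclass(frozen=True)
class EffectSpec:
    """Band structure and condition-dependent amplitude modulation gains.

    ``bands`` maps a band name to (center Hz, half-width Hz); per-trial
    oscillation frequencies are drawn uniformly within the band.  ``g_int``,
    ``g_exp`` and ``g_pe_low`` modulate the alpha and beta amplitudes,
    ``g_pe_gamma`` the gamma amplitude.  All modulations must keep amplitudes
    positive over the nine condition cells.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"alpha": (10.0, 2.0), "beta": (20.0, 4.0), "gamma": (55.0, 10.0)}
    )
    amplitudes: dict[str, float] = field(
        default_factory=lambda: {"alpha": 2.5, "beta": 2.0, "gamma": 1.2}
    )
    g_int: float = 0.25
    g_exp: float = 0.22
    g_pe_low: float = 0.15
    g_pe_gamma: float = 0.45
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    topography_smoothness: float = 2.0

    def __post_init__(self):
        if set(self.bands) != {"alpha", "beta", "gamma"} or set(self.amplitudes) != {
            "alpha", "beta", "gamma",
        }:
            raise ValueError("bands and amplitudes must define alpha, beta and gamma")
        for cell in design.build_condition_grid():
            if abs(self.low_modulation(cell)) >= 1.0:
                raise ValueError(
                    f"alpha/beta modulation magnitude >= 1 in cell "
                    f"(cue={cell.cue_intensity}, stim={cell.stim_intensity})"
                )
            if abs(self.gamma_modulation(cell)) >= 1.0:
                raise ValueError(
                    f"gamma modulation magnitude >= 1 in cell "
                    f"(cue={cell.cue_intensity}, stim={cell.stim_intensity})"
                )

    def low_modulation(self, cell: design.ConditionCell) -> float:
        """Fractional alpha/beta amplitude change in the stimulus window."""
        return self.g_pe_low * cell.pe_code - self.g_int * cell.int_code - self.g_exp * cell.exp_code

    def gamma_modulation(self, cell: design.ConditionCell) -> float:
        """Fractional gamma amplitude change in the stimulus window."""
        return self.g_pe_gamma * cell.pe_code

    @classmethod
    def null(cls, **kwargs) -> "EffectSpec":
        """Spec with all condition-dependent gains zero (null data)."""
        return cls(g_int=0.0, g_exp=0.0, g_pe_low=0.0, g_pe_gamma=0.0, **kwargs)


@dataclass
class EpochsSet:
    """Epoched multichannel EEG for one subject.

    ``data`` is trials x channels x samples; ``times`` are milliseconds
    relative to the lock event with a uniform step of 1000/srate.
    ``schedule_ref`` holds the row position of each trial in the schedule it
    was generated from.
    """

    data: np.ndarray
    srate: float
    times: np.ndarray
    lock: str
    subject_id: str
    schedule_ref: np.ndarray
    channel_names: tuple[str, ...]

    def __post_init__(self):
        if self.lock not in ("cue", "stimulus"):
            raise ValueError("lock must be 'cue' or 'stimulus'")
        if self.data.shape[0] != len(self.schedule_ref):
            raise ValueError("one data row required per referenced trial")
        if self.data.shape[2] != len(self.times):
            raise ValueError("time axis length mismatch")
        step = np.diff(self.times)
        if len(step) and not np.allclose(step, 1000.0 / self.srate):
            raise ValueError("times must increase uniformly with step 1000/srate")

    def copy_with(self, **kwargs) -> "EpochsSet":
        return replace(self, **kwargs)


def _stimulus_window_envelope(times_ms: np.ndarray, onset: float = 0.0,
                              duration: float = 2000.0, ramp: float = 100.0) -> np.ndarray:
    """Cosine-ramped indicator of the stimulus window (0..1).

    100 ms raised-cosine ramps at both edges avoid spectral splatter from the
    amplitude step; the plateau covers [onset+ramp, onset+duration-ramp].
    """
    t = np.asarray(times_ms, dtype=float)
    w = np.zeros_like(t)
    rise = (t >= onset) & (t < onset + ramp)
    plateau = (t >= onset + ramp) & (t <= onset + duration - ramp)
    fall = (t > onset + duration - ramp) & (t <= onset + duration)
    w[rise] = 0.5 * (1 - np.cos(np.pi * (t[rise] - onset) / ramp))
    w[plateau] = 1.0
    w[fall] = 0.5 * (1 - np.cos(np.pi * (onset + duration - t[fall]) / ramp))
    return w


def _one_over_f_noise(rng: np.random.Generator, shape: tuple[int, ...], n_samples: int,
                      exponent: float, scale: float) -> np.ndarray:
    """Spectrally shaped white noise with power ~ 1/f**exponent, unit-SD x scale.

    Synthesized at an FFT-friendly length and cropped, so the cost does not
    depend on the prime factorization of the epoch length.
    """
    n_fast = scipy.fft.next_fast_len(n_samples)
    white = rng.standard_normal(shape + (n_fast,), dtype=np.float32)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n_fast)
    gain = np.zeros(len(freqs), dtype=np.float32)
    gain[1:] = freqs[1:].astype(np.float32) ** np.float32(-exponent / 2.0)
    spec *= gain
    x = np.fft.irfft(spec, n=n_fast, axis=-1)[..., :n_samples].astype(np.float32)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * x / sd


def _band_topography(montage: Montage, band: str, smoothness: float) -> np.ndarray:
    """Smooth, strictly positive spatial weighting for one band.

    A Gaussian bump over the montage positions, with a fixed per-band center
    offset so bands are not perfectly collinear in space; deterministic.
    """
    pos = montage.positions
    center = pos.mean(axis=0)
    offset = {"alpha": (0.4, 0.0), "beta": (-0.4, 0.2), "gamma": (0.0, -0.4)}[band]
    center = center + np.asarray(offset)
    d2 = ((pos - center) ** 2).sum(axis=1)
    return 0.4 + 0.6 * np.exp(-d2 / (2.0 * smoothness ** 2))


def _picture_trial_rows(schedule: pd.DataFrame) -> np.ndarray:
    """Positions of analyzable trials: non-catch, picture cued and shown."""
    mask = (
        (~schedule["is_catch"].astype(bool))
        & (schedule["cue_modality"] == "picture")
        & (schedule["stim_modality"] == "picture")
    )
    return np.flatnonzero(mask.to_numpy())


def simulate_subject_eeg(
    schedule: pd.DataFrame,
    montage: Montage,
    effects: EffectSpec,
    srate: float = 250.0,
    epoch_window_ms: tuple[float, float] = (-2750.0, 2200.0),
    seed: int = 0,
    subject_id: str = "s00",
) -> EpochsSet:
    """Simulate stimulus-locked epochs for the picture-congruent trials.

    The epoch window must cover the stimulus-locked baseline and the full
    0-2000 ms stimulus window.  Deterministic given ``seed``.
    """
    w0, w1 = epoch_window_ms
    if w0 > -2550.0 or w1 < 2000.0:
        raise ValueError(
            "epoch window must cover the stimulus-locked baseline (-2550 ms) "
            "and the 0-2000 ms stimulus window"
        )
    rows = _picture_trial_rows(schedule)
    if len(rows) == 0:
        raise ValueError("schedule contains no picture-congruent trials")

    dt = 1000.0 / srate
    n0 = int(np.round(w0 / dt))
    n1 = int(np.round(w1 / dt))
    times = np.arange(n0, n1 + 1) * dt
    n_t = len(times)
    n_ch = montage.n_channels
    n_trials = len(rows)

    rng = np.random.default_rng(seed)
    data = _one_over_f_noise(
        rng, (n_trials, n_ch), n_t, effects.noise_exponent, effects.noise_scale
    )

    cells = design.build_condition_grid()
    cell_of = {(c.cue_intensity, c.stim_intensity): c for c in cells}
    cue_col = schedule["cue_intensity"].to_numpy()
    stim_col = schedule["stim_intensity"].to_numpy()
    trial_cells = [cell_of[(cue_col[r], stim_col[r])] for r in rows]

    window = _stimulus_window_envelope(times)
    t_s = times / 1000.0
    for band, (center, half_width) in effects.bands.items():
        a0 = effects.amplitudes[band]
        topo = _band_topography(montage, band, effects.topography_smoothness)
        freqs = rng.uniform(center - half_width, center + half_width, size=n_trials)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=n_trials)
        if band == "gamma":
            mods = np.array([effects.gamma_modulation(c) for c in trial_cells])
        else:
            mods = np.array([effects.low_modulation(c) for c in trial_cells])
        env = a0 * (1.0 + mods[:, None] * window[None, :])
        osc = env * np.sin(2.0 * np.pi * freqs[:, None] * t_s[None, :] + phases[:, None])
        data += topo[None, :, None] * osc[:, None, :]

    return EpochsSet(
        data=data.astype(np.float32),
        srate=float(srate),
        times=times,
        lock="stimulus",
        subject_id=subject_id,
        schedule_ref=rows,
        channel_names=montage.channel_names,
    )


def simulate_ratings(
    schedule: pd.DataFrame,
    beta0: float = 2.5,
    beta_int: float = 0.6,
    beta_pe: float = 0.25,
    sigma: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Ordinal 1-4 aversiveness ratings for the picture-congruent trials.

    A latent ``u = beta0 + beta_int*INT + beta_pe*PE + N(0, sigma)`` is
    rounded half-up and clipped to [1, 4].  By construction the expectation
    factor does not enter, matching the behavioural pattern the analysis
    should recover (INT and PE effects, no EXP effect).

    The default betas centre the latent cell means on the scale midpoint and
    keep them clear of the 1 and 4 bounds: asymmetric clipping of extreme
    cells would otherwise leak a small systematic trend into the EXP factor
    (the clipped cells sit in the extreme-expectation columns), which
    identical simulated subjects would resolve as a spurious effect.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rows = _picture_trial_rows(schedule)
    if len(rows) == 0:
        raise ValueError("schedule contains no picture-congruent trials")
    rng = np.random.default_rng(seed)
    cue_col = schedule["cue_intensity"].to_numpy()[rows]
    stim_col = schedule["stim_intensity"].to_numpy()[rows]
    code = np.vectorize(design.LEVEL_CODE.get)
    int_codes = code(stim_col).astype(float)
    exp_codes = code(cue_col).astype(float)
    pe_codes = np.abs(exp_codes - int_codes)
    latent = beta0 + beta_int * int_codes + beta_pe * pe_codes
    if sigma > 0:
        latent = latent + rng.normal(0.0, sigma, size=len(rows))
    rating = np.clip(np.floor(latent + 0.5), 1, 4).astype(int)
    return pd.DataFrame(
        {
            "schedule_row": rows,
            "cue_intensity": cue_col,
            "stim_intensity": stim_col,
            "rating": rating,
        }
    )
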