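"""Complex Morlet wavelet evoked power and per-electrode group statistics.

Evoked power is the time-frequency power of the *across-trial average*
waveform, transformed with a family of complex Morlet wavelets whose
centre-frequency to spectral-bandwidth ratio is fixed at f0/sigma_f = 7.
Averaging before transforming keeps only activity that is both
time-locked and phase-locked to stimulus onset; non-phase-locked
activity cancels roughly as 1/N across N trials.

Wavelets are L2 (unit-energy) normalised, which makes power scale
exactly quadratically with signal amplitude. A wavelet at frequency f0
has temporal width sigma_t = 1 / (2 pi sigma_f); cells closer than
2 sigma_t to either epoch edge are contaminated by edge effects and are
flagged invalid in ``validity_mask`` — every aggregate in this module is
taken over valid cells only. At the default grid's lowest frequencies
(fractions of a Hz) sigma_t exceeds the epoch length entirely, so those
rows are computed but fully masked.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .epochs import EpochSet

__all__ = [
    "WaveletSpec",
    "TimeFreqMap",
    "morlet_power",
    "evoked_power",
    "band_window_mean",
    "channel_band_window_mean",
    "electrode_p_map",
    "ElectrodePMap",
]


def default_grid() -> np.ndarray:
    """0.1-30 Hz grid in 0.5 Hz steps (0.1, 0.6, ..., 29.6)."""
    return np.arange(0.1, 30.0, 0.5)


@dataclass
class WaveletSpec:
    """Morlet family: centre-frequency grid and f0/sigma_f ratio."""

    ratio: float = 7.0
    grid: np.ndarray = field(default_factory=default_grid)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")
        if self.grid.size == 0 or np.any(np.diff(self.grid) <= 0):
            raise ValueError("frequency grid must be strictly increasing")

    def sigma_t(self, f0: float) -> float:
        """Temporal width of the wavelet at centre frequency ``f0`` (s)."""
        return self.ratio / (2.0 * np.pi * f0)


@dataclass
class TimeFreqMap:
    """Channel x frequency x time evoked-power map (microvolts squared)."""

    power: np.ndarray            # (n_channels, n_freqs, n_times), >= 0
    freqs: np.ndarray            # Hz
    times: np.ndarray            # ms, aligned to the source EpochSet
    validity_mask: np.ndarray    # (n_freqs, n_times) bool, True = valid
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.power.ndim != 3:
            raise ValueError("power must be (channel, freq, time)")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        if self.validity_mask.shape != self.power.shape[1:]:
            raise ValueError("validity_mask must be (freq, time)")


def _morlet_kernel(f0: float, sigma_t: float, fs: float) -> np.ndarray:
    """Discretely unit-energy complex Morlet wavelet at ``f0`` Hz."""
    half = int(np.ceil(4.0 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    w = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2)) * np.exp(2j * np.pi * f0 * t)
    w /= np.sqrt(np.sum(np.abs(w) ** 2))
    return w


def morlet_power(signal: np.ndarray, fs: float, spec: WaveletSpec | None = None,
                 t0: float = 0.0,
                 channel_labels: list[str] | None = None) -> TimeFreqMap:
    """Squared-magnitude Morlet transform of a multichannel waveform.

    Parameters
    ----------
    signal
        ``(n_channels, n_samples)`` real array (typically a trial
        average).
    fs
        Sampling rate, Hz; must exceed twice the top grid frequency.
    spec
        Wavelet family; defaults to ratio 7 on the 0.1-30 Hz grid.
    t0
        Time of the first sample in ms, used to build the time axis.
    """
    spec = spec or WaveletSpec()
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    if not np.isfinite(signal).all():
        raise ValueError("signal contains NaN/Inf")
    if fs <= 2.0 * spec.grid.max():
        raise ValueError("grid frequency at or above Nyquist")
    n_ch, n_samp = signal.shape
    times = t0 + np.arange(n_samp) * 1000.0 / fs
    power = np.empty((n_ch, spec.grid.size, n_samp))
    mask = np.zeros((spec.grid.size, n_samp), dtype=bool)
    for fi, f0 in enumerate(spec.grid):
        st = spec.sigma_t(f0)
        kern = _morlet_kernel(f0, st, fs)
        conv = sps.fftconvolve(signal, kern[None, :], mode="same", axes=1)
        power[:, fi, :] = np.abs(conv) ** 2
        guard = 2.0 * st * 1000.0  # ms
        mask[fi] = (times >= times[0] + guard) & (times <= times[-1] - guard)
    return TimeFreqMap(power, spec.grid.copy(), times, mask,
                       channel_labels or [f"ch{i}" for i in range(n_ch)])


def evoked_power(epochs: EpochSet, spec: WaveletSpec | None = None) -> TimeFreqMap:
    """Evoked (phase-locked) power: transform of the across-trial mean.

    The trial average is computed first and then wavelet-transformed, so
    activity with random phase across trials cancels before squaring.
    With a single trial this degenerates to total power (a warning is
    issued).
    """
    if epochs.n_trials < 2:
        warnings.warn("single trial: evoked power equals total power",
                      stacklevel=2)
    avg = epochs.data.mean(axis=2)
    return morlet_power(avg, epochs.fs, spec, t0=epochs.t0,
                        channel_labels=list(epochs.channel_labels))


def _select(tf: TimeFreqMap, band: tuple[float, float],
            window: tuple[float, float],
            channels: list[str] | None) -> tuple[np.ndarray, np.ndarray]:
    fsel = (tf.freqs >= band[0]) & (tf.freqs <= band[1])
    tsel = (tf.times >= window[0]) & (tf.times < window[1])
    if not fsel.any() or not tsel.any():
        raise ValueError("band/window selects no grid cells")
    if channels is None:
        csel = np.arange(tf.power.shape[0])
    else:
        csel = np.asarray([tf.channel_labels.index(c) for c in channels])
    sub = tf.power[np.ix_(csel, np.flatnonzero(fsel), np.flatnonzero(tsel))]
    m = tf.validity_mask[np.ix_(np.flatnonzero(fsel), np.flatnonzero(tsel))]
    return sub, m


def band_window_mean(tf: TimeFreqMap, band: tuple[float, float],
                     window: tuple[float, float],
                     channels: list[str] | None = None) -> float:
    """Mean power over valid cells in band x window x channel subset.

    Raises if every selected (frequency, time) cell is masked invalid.
    """
    sub, m = _select(tf, band, window, channels)
    if not m.any():
        raise ValueError("all selected time-frequency cells are masked")
    return float(sub[:, m].mean())


def channel_band_window_mean(tf: TimeFreqMap, band: tuple[float, float],
                             window: tuple[float, float]) -> np.ndarray:
    """Per-channel mean power over valid cells in band x window."""
    sub, m = _select(tf, band, window, None)
    if not m.any():
        raise ValueError("all selected time-frequency cells are masked")
    return sub[:, m].mean(axis=1)


@dataclass
class ElectrodePMap:
    """Per-electrode two-sample t map with Bonferroni adjustment."""

    t: np.ndarray
    p_raw: np.ndarray
    p_adj: np.ndarray        # Bonferroni: min(1, p * n_electrodes)
    undefined: np.ndarray    # True where both groups had zero variance
    channel_labels: list[str] = field(default_factory=list)


def electrode_p_map(group_a: np.ndarray, group_b: np.ndarray,
                    channel_labels: list[str] | None = None) -> ElectrodePMap:
    """Independent two-sample t-test per electrode (two-tailed).

    Parameters
    ----------
    group_a, group_b
        ``(n_subjects, n_electrodes)`` per-subject scalars (e.g. alpha
        power in the 100-300 ms window) for each group.

    Electrodes where both groups have exactly zero variance yield an
    undefined test; they are flagged and returned with ``p = nan``.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ValueError("electrode counts differ between groups")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    n_el = a.shape[1]
    undefined = (a.var(axis=0) == 0) & (b.var(axis=0) == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = spstats.ttest_ind(a, b, axis=0, equal_var=True)
    t = np.where(undefined, np.nan, t)
    p = np.where(undefined, np.nan, p)
    # equal constant samples: t = 0 / 0 -> define as no difference
    both_const = undefined & (np.abs(a.mean(axis=0) - b.mean(axis=0)) == 0)
    t = np.where(both_const, 0.0, t)
    p = np.where(both_const, 1.0, p)
    undefined = undefined & ~both_const
    p_adj = np.minimum(1.0, p * n_el)
    return ElectrodePMap(t, p, p_adj, undefined,
                         channel_labels or [f"ch{i}" for i in range(n_el)])
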