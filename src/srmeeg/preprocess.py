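"""Filtering, re-referencing, epoching, and spectral-distortion checks.

The preprocessing chain mirrors a conventional event-related EEG
workflow: broad band-pass filtering (0.1-30 Hz), offline re-reference to
the averaged mastoids, segmentation into -300..+800 ms epochs around
stimulus onset, and a power-spectrum distortion metric |dP| that
quantifies how much an artifact-cleaning reconstruction (e.g. ICA
back-projection) altered each channel's spectrum.

The band-pass is a zero-phase forward-backward Butterworth (order 4 per
direction): zero-phase filtering is required downstream so that Hilbert
instantaneous phases are not biased by filter delay.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .epochs import MASTOIDS, EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "bandpass",
    "rereference",
    "segment",
    "spectral_distortion",
    "SpectralDistortion",
]


def _butter_sos(lo: float, hi: float, fs: float, order: int = 4):
    nyq = fs / 2.0
    if not (0.0 <= lo < hi):
        raise ValueError(f"need 0 <= lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"high edge {hi} Hz >= Nyquist {nyq} Hz")
    if lo == 0.0:
        return sps.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(epochs: EpochSet, lo: float, hi: float, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass along the sample axis.

    Parameters
    ----------
    epochs
        Input epochs (any band).
    lo, hi
        Pass-band edges in Hz; ``0 <= lo < hi < fs/2``. ``lo = 0``
        degenerates to a low-pass.
    order
        Butterworth order per direction (default 4; the effective
        forward-backward response is order 8 with zero phase).
    """
    sos = _butter_sos(lo, hi, epochs.fs, order)
    out = sps.sosfiltfilt(sos, epochs.data, axis=1)
    return epochs.with_data(out)


def rereference(epochs: EpochSet, scheme: str = "averaged_mastoid") -> EpochSet:
    """Re-reference to the averaged mastoids (or pass through).

    With ``scheme="averaged_mastoid"`` every channel has the mean of the
    two mastoid channels (labels ``M1``/``M2``) subtracted, after which
    the mastoids are dropped from the analysis set. ``scheme="none"``
    returns an identical copy.
    """
    if scheme == "none":
        return epochs.with_data(epochs.data.copy())
    if scheme != "averaged_mastoid":
        raise ValueError(f"unknown re-reference scheme {scheme!r}")
    try:
        m_idx = epochs.channel_index(MASTOIDS)
    except KeyError:
        raise ValueError(
            f"averaged-mastoid re-reference needs channels {MASTOIDS}"
        ) from None
    ref = epochs.data[m_idx].mean(axis=0)
    keep = np.setdiff1d(np.arange(epochs.n_channels), m_idx)
    data = epochs.data[keep] - ref[None]
    labels = [epochs.channel_labels[i] for i in keep]
    return EpochSet(
        data,
        epochs.fs,
        epochs.t0,
        labels,
        condition=epochs.condition,
        subject_id=epochs.subject_id,
        group=epochs.group,
        n_rejected=epochs.n_rejected,
    )


def segment(
    continuous: np.ndarray,
    fs: float,
    event_onsets: np.ndarray,
    pre_ms: float = 300.0,
    post_ms: float = 800.0,
    channel_labels: list[str] | None = None,
    **meta,
) -> EpochSet:
    """Cut a continuous recording into stimulus-locked epochs.

    Parameters
    ----------
    continuous
        ``(n_channels, n_samples)`` array.
    event_onsets
        Stimulus-onset sample indices into ``continuous``.
    pre_ms, post_ms
        Epoch extent before/after onset; the default reproduces the
        -300..+800 ms study window. Each epoch spans samples
        ``[onset - pre, onset + post)`` so its length is exactly
        ``(pre_ms + post_ms) / 1000 * fs`` samples.

    Onsets whose window would exceed the recording bounds are rejected;
    the rejection count is logged and stored on the returned
    :class:`~srmeeg.epochs.EpochSet` as ``n_rejected``.
    """
    continuous = np.asarray(continuous, dtype=np.float64)
    if continuous.ndim != 2:
        raise ValueError("continuous data must be (n_channels, n_samples)")
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    onsets = np.asarray(event_onsets, dtype=int)
    ok = (onsets - n_pre >= 0) & (onsets + n_post <= continuous.shape[1])
    n_rej = int((~ok).sum())
    if n_rej:
        logger.warning("segment: rejected %d of %d events (out of bounds)",
                       n_rej, onsets.size)
    onsets = onsets[ok]
    if onsets.size == 0:
        raise ValueError("no usable events after bounds rejection")
    trials = np.stack(
        [continuous[:, o - n_pre:o + n_post] for o in onsets], axis=-1
    )
    return EpochSet(
        trials, fs, -float(pre_ms),
        channel_labels or [], n_rejected=n_rej, **meta,
    )


@dataclass
class SpectralDistortion:
    """Per-channel power-spectrum distortion |dP| between two recordings.

    ``delta_p[c]`` is the sum over the 0.1-30 Hz frequency grid of the
    absolute difference between the trial-averaged power spectral
    densities of the reconstructed and raw data on channel ``c``. Zero
    iff the two inputs have identical spectra on that grid; used to
    check that artifact cleaning (e.g. ICA back-projection) did not
    distort the spectrum.
    """

    delta_p: np.ndarray
    freqs: np.ndarray
    channel_labels: list[str]


def _trial_psd(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged Welch PSD, 1 s windows (full epoch if shorter)."""
    nper = min(data.shape[1], int(round(fs)))
    freqs, psd = sps.welch(data, fs=fs, nperseg=nper, axis=1)
    return freqs, psd.mean(axis=-1)  # average over trials


def spectral_distortion(raw: EpochSet, reconstructed: EpochSet,
                        band: tuple[float, float] = (0.1, 30.0)) -> SpectralDistortion:
    """|dP| = sum_f |P_recon(f) - P_raw(f)| per channel over ``band``.

    Symmetric in its arguments and zero when the inputs have identical
    power spectra (e.g. a phase-scrambled surrogate of the raw data).
    """
    if raw.data.shape != reconstructed.data.shape:
        raise ValueError("raw and reconstructed shapes differ")
    if raw.fs != reconstructed.fs:
        raise ValueError("raw and reconstructed sampling rates differ")
    if raw.channel_labels != reconstructed.channel_labels:
        raise ValueError("raw and reconstructed channel labels differ")
    freqs, p_raw = _trial_psd(raw.data, raw.fs)
    _, p_rec = _trial_psd(reconstructed.data, reconstructed.fs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    delta = np.abs(p_rec[:, sel] - p_raw[:, sel]).sum(axis=1)
    return SpectralDistortion(delta, freqs[sel], list(raw.channel_labels))
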