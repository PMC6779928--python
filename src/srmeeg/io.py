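"""Fixture container, ground-truth sidecars, and real-recording readers.

The documented array container for synthetic fixtures is a NumPy
``.npz`` archive per subject x condition holding the epoch tensor and
its metadata, with a JSON sidecar describing the planted ground truth
of the whole cohort. Real recordings (BrainVision ``.vhdr`` or EDF)
are read through MNE and handed to :func:`srmeeg.preprocess.segment`.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .epochs import EpochSet
from .synth import SimulationConfig, iter_cohort, _ground_truth

__all__ = [
    "save_epoch_set",
    "load_epoch_set",
    "write_cohort_fixtures",
    "read_raw",
    "epoch_set_to_edf",
]


def save_epoch_set(path, epochs: EpochSet) -> None:
    """Write one EpochSet to a ``.npz`` container.

    Keys: ``data`` (channel x sample x trial, microvolts), ``fs``,
    ``t0`` (ms), ``channel_labels``, and the cell metadata strings.
    """
    np.savez_compressed(
        path,
        data=epochs.data,
        fs=np.float64(epochs.fs),
        t0=np.float64(epochs.t0),
        channel_labels=np.asarray(epochs.channel_labels),
        condition=np.asarray(epochs.condition or ""),
        subject_id=np.asarray(epochs.subject_id or ""),
        group=np.asarray(epochs.group or ""),
    )


def load_epoch_set(path) -> EpochSet:
    """Read an EpochSet written by :func:`save_epoch_set`."""
    with np.load(path, allow_pickle=False) as z:
        return EpochSet(
            z["data"],
            float(z["fs"]),
            float(z["t0"]),
            [str(c) for c in z["channel_labels"]],
            condition=str(z["condition"]) or None,
            subject_id=str(z["subject_id"]) or None,
            group=str(z["group"]) or None,
        )


def write_cohort_fixtures(config: SimulationConfig, out_dir) -> Path:
    """Generate a cohort and write one ``.npz`` per subject x condition.

    A ``ground_truth.json`` sidecar records the planted effect sizes,
    the coupled edge set, and the expected contrast signs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, group, cond, es in iter_cohort(config):
        save_epoch_set(out / f"{sid}_{cond}.npz", es)
    gt = _ground_truth(config)
    gt["seed"] = config.seed
    (out / "ground_truth.json").write_text(
        json.dumps(gt, indent=2, default=_jsonable))
    return out


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def read_raw(path):
    """Read a continuous recording (BrainVision ``.vhdr`` or EDF).

    Returns ``(data_uv, fs, channel_labels)`` with data in microvolts,
    ready for :func:`srmeeg.preprocess.segment`.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported recording format: {path.suffix}")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), \
        list(raw.ch_names)


def epoch_set_to_edf(epochs: EpochSet, path) -> None:
    """Export an EpochSet as a continuous EDF file (trials concatenated).

    Interoperability convenience; requires MNE's EDF export backend
    (the ``edfio`` package). Raises ImportError with guidance when the
    backend is unavailable.
    """
    import mne

    try:
        import edfio  # noqa: F401
    except ImportError as exc:
        raise ImportError(
            "EDF export requires the 'edfio' package "
            "(pip install edfio)") from exc
    data = np.concatenate(
        [epochs.data[:, :, k] for k in range(epochs.n_trials)], axis=1)
    info = mne.create_info(epochs.channel_labels, epochs.fs, "eeg")
    raw = mne.io.RawArray(data * 1e-6, info, verbose="error")
    mne.export.export_raw(str(path), raw, fmt="edf", overwrite=True,
                          verbose="error")
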