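"""Reading, preprocessing and segmenting multichannel EEG.

The pipeline front end: read a recording (EDF/EDF+ or an HDF5 array
container), restrict it to the 19 canonical 10-20 channels, resample to
256 Hz, band-pass filter to 0.5-32 Hz with a zero-phase FIR, and cut it
into 5-second epochs overlapping by 50%.

File containers
---------------
* EDF/EDF+ files are read through :mod:`mne`; a minimal EDF writer is
  provided so synthetic datasets can round-trip through the same format.
* The HDF5 array container is a dataset ``data`` of shape
  (channels, samples) with attributes ``fs``, ``channels``, ``label`` and
  ``subject_id``; multi-recording files hold one such layout per group.
"""

from __future__ import annotations

import logging
import warnings
from fractions import Fraction
from pathlib import Path
from typing import Iterable

import h5py
import numpy as np
import pandas as pd
from scipy import signal as sps

from .records import (
    CANONICAL_CHANNELS,
    EPOCH_SAMPLES,
    EPOCH_STEP,
    N_CHANNELS,
    TARGET_FS,
    ClassLabel,
    EEGRecording,
    Epoch,
    EpochSet,
    FormatError,
    MontageError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_recording",
    "resample",
    "bandpass",
    "segment_epochs",
    "preprocess_recording",
    "write_recording_h5",
    "read_dataset_h5",
    "write_edf",
    "write_epochs_h5",
    "read_epochs_h5",
    "epoch_count",
]


# ---------------------------------------------------------------------------
# channel-name handling


def _normalize_channel(name: str) -> str:
    """Reduce vendor-decorated channel labels to bare 10-20 names."""
    s = name.strip()
    for prefix in ("EEG ", "EEG"):
        if s.upper().startswith(prefix.upper()) and len(s) > len(prefix):
            s = s[len(prefix):]
            break
    for sep in ("-",):
        if sep in s:
            s = s.split(sep)[0]
    return s.strip().upper()


def _select_canonical(data: np.ndarray, names: Iterable[str]) -> np.ndarray:
    """Return rows of `data` reordered to the canonical 19-channel montage."""
    lookup: dict[str, int] = {}
    for i, raw in enumerate(names):
        key = _normalize_channel(raw)
        lookup.setdefault(key, i)
    missing = [ch for ch in CANONICAL_CHANNELS if ch.upper() not in lookup]
    if missing:
        raise MontageError(
            f"recording is missing required 10-20 channel(s): {', '.join(missing)}"
        )
    rows = [lookup[ch.upper()] for ch in CANONICAL_CHANNELS]
    return np.asarray(data)[rows]


# ---------------------------------------------------------------------------
# readers


def read_recording(
    path: str | Path,
    label: ClassLabel | int | str,
    subject_id: str,
) -> EEGRecording:
    """Read one EEG recording and restrict it to the canonical montage.

    Parameters
    ----------
    path
        An EDF/EDF+ file or an HDF5 array container (see module docstring).
    label
        Diagnostic class of the subject (``ES``/``PNES``/``CS``).
    subject_id
        Opaque identifier attached to every epoch cut from this recording.

    Returns
    -------
    EEGRecording
        19 rows in canonical order, original sampling rate preserved.

    Raises
    ------
    MontageError
        If any of the 19 canonical channels is absent.
    FormatError
        If the file cannot be parsed.
    """
    path = Path(path)
    if path.suffix.lower() in {".h5", ".hdf5"}:
        return _read_recording_h5(path, label, subject_id)
    return _read_recording_edf(path, label, subject_id)


def _read_recording_edf(path: Path, label, subject_id: str) -> EEGRecording:
    import mne  # deferred: slow import, only needed for EDF

    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except MontageError:
        raise
    except Exception as exc:  # mne raises various types on corrupt files
        raise FormatError(f"cannot read {path} as EDF: {exc}") from exc
    data_uv = raw.get_data() * 1e6  # mne works in volts
    data = _select_canonical(data_uv, raw.ch_names)
    return EEGRecording(
        subject_id=subject_id,
        label=ClassLabel.coerce(label),
        fs=float(raw.info["sfreq"]),
        data=data,
    )


def _read_recording_h5(path: Path, label, subject_id: str) -> EEGRecording:
    try:
        with h5py.File(path, "r") as f:
            if "data" not in f:
                raise FormatError(f"{path}: HDF5 container has no 'data' dataset")
            dset = f["data"]
            data = dset[()]
            fs = float(dset.attrs["fs"])
            channels = [
                c.decode() if isinstance(c, bytes) else str(c)
                for c in dset.attrs["channels"]
            ]
    except (OSError, KeyError) as exc:
        raise FormatError(f"cannot read {path} as HDF5 EEG container: {exc}") from exc
    data = _select_canonical(data, channels)
    return EEGRecording(
        subject_id=subject_id, label=ClassLabel.coerce(label), fs=fs, data=data
    )


def write_recording_h5(rec: EEGRecording, path: str | Path, group: str | None = None) -> None:
    """Write a recording in the HDF5 array-container layout."""
    with h5py.File(path, "a") as f:
        target = f.require_group(group) if group else f
        if "data" in target:
            del target["data"]
        dset = target.create_dataset("data", data=rec.data)
        dset.attrs["fs"] = rec.fs
        dset.attrs["channels"] = [c.encode() for c in rec.channel_names]
        dset.attrs["label"] = rec.label.name
        dset.attrs["subject_id"] = rec.subject_id


def read_dataset_h5(path: str | Path) -> list[EEGRecording]:
    """Read every recording group from a multi-recording HDF5 file."""
    recs: list[EEGRecording] = []
    with h5py.File(path, "r") as f:
        names = sorted(k for k in f.keys() if isinstance(f[k], h5py.Group))
        for name in names:
            dset = f[name]["data"]
            recs.append(
                EEGRecording(
                    subject_id=str(dset.attrs["subject_id"]),
                    label=ClassLabel.coerce(str(dset.attrs["label"])),
                    fs=float(dset.attrs["fs"]),
                    data=dset[()],
                )
            )
    return recs


# ---------------------------------------------------------------------------
# minimal EDF writer (16-bit, one data record per second)


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a plain EDF file.

    Signals are scaled to the full 16-bit digital range per channel; the
    record duration is 1 s, so ``fs`` must be a positive integer.  Trailing
    samples that do not fill a whole record are dropped.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9 or fs <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {rec.fs}")
    n_records = rec.n_samples // fs
    if n_records == 0:
        raise ValueError("recording shorter than one EDF data record (1 s)")
    data = rec.data[:, : n_records * fs]
    ns = data.shape[0]

    def field(value: str, width: int) -> bytes:
        b = value.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # guard degenerate flat channels
    flat = phys_max - phys_min < 1e-12
    phys_max = np.where(flat, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            field("0", 8),  # version
            field(rec.subject_id, 80),
            field("emdnet", 80),
            field("01.01.00", 8),
            field("00.00.00", 8),
            field(str(256 + ns * 256), 8),
            field("", 44),
            field(str(n_records), 8),
            field("1", 8),  # record duration, seconds
            field(str(ns), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(field(ch, 16) for ch in rec.channel_names),
            b"".join(field("AgAgCl electrode", 80) for _ in range(ns)),
            b"".join(field("uV", 8) for _ in range(ns)),
            b"".join(field(f"{phys_min[i]:.4g}", 8) for i in range(ns)),
            b"".join(field(f"{phys_max[i]:.4g}", 8) for i in range(ns)),
            b"".join(field(str(dig_min), 8) for _ in range(ns)),
            b"".join(field(str(dig_max), 8) for _ in range(ns)),
            b"".join(field("", 80) for _ in range(ns)),
            b"".join(field(str(fs), 8) for _ in range(ns)),
            b"".join(field("", 32) for _ in range(ns)),
        ]
    )
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.round((data - phys_min[:, None]) * gain[:, None] + dig_min),
        dig_min,
        dig_max,
    ).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        f.write(sig)
        for r in range(n_records):
            block = digital[:, r * fs : (r + 1) * fs]
            f.write(block.tobytes())  # channel-major within record


# ---------------------------------------------------------------------------
# preprocessing


def resample(rec: EEGRecording, target_fs: float = TARGET_FS) -> EEGRecording:
    """Resample a recording with polyphase anti-aliased resampling.

    Duration is preserved to within one sample period.  Upsampling is
    permitted but logged, since the pipeline only ever downsamples.
    """
    if target_fs <= 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if rec.fs == target_fs:
        return rec
    if target_fs > rec.fs:
        logger.warning(
            "upsampling %s from %g Hz to %g Hz", rec.subject_id, rec.fs, target_fs
        )
    ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.data, ratio.numerator, ratio.denominator, axis=1)
    return EEGRecording(
        subject_id=rec.subject_id,
        label=rec.label,
        fs=float(target_fs),
        data=out,
        channel_names=rec.channel_names,
    )


def _firwin_zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with reflect padding; exact zero phase."""
    half = (len(taps) - 1) // 2
    n = x.shape[-1]
    pad = min(half, n - 1)
    xp = np.pad(x, [(0, 0)] * (x.ndim - 1) + [(pad, pad)], mode="reflect")
    if pad < half:  # very short signal: extend further with edge values
        extra = half - pad
        xp = np.pad(xp, [(0, 0)] * (x.ndim - 1) + [(extra, extra)], mode="edge")
    y = sps.fftconvolve(xp, taps[np.newaxis, :], mode="valid", axes=-1)
    return y[..., : n] if y.shape[-1] >= n else y


def _odd_taps(fs: float, transition_hz: float) -> int:
    # Hamming window: transition width ~ 3.3 / numtaps (normalized)
    n = int(np.ceil(3.3 * fs / transition_hz))
    return n + 1 if n % 2 == 0 else n


def bandpass(
    rec: EEGRecording, low: float = 0.5, high: float = 32.0
) -> EEGRecording:
    """Zero-phase FIR band-pass filter.

    Implemented as a cascade of a windowed-sinc (Hamming) high-pass with a
    0.5 Hz transition band and a low-pass with an 8 Hz transition band; each
    stage is a symmetric kernel applied once with reflect padding, so the
    cascade is exactly zero phase.
    """
    if low <= 0:
        raise ValueError(f"low edge must be positive, got {low}")
    if high >= rec.fs / 2:
        raise ValueError(
            f"high edge {high} Hz must be below Nyquist ({rec.fs / 2} Hz)"
        )
    if high <= low:
        raise ValueError(f"band edges out of order: {low} >= {high}")
    hp = sps.firwin(
        _odd_taps(rec.fs, 0.5), low, window="hamming", pass_zero=False, fs=rec.fs
    )
    lp = sps.firwin(
        _odd_taps(rec.fs, 8.0), high, window="hamming", pass_zero=True, fs=rec.fs
    )
    out = _firwin_zero_phase(_firwin_zero_phase(rec.data, hp), lp)
    return EEGRecording(
        subject_id=rec.subject_id,
        label=rec.label,
        fs=rec.fs,
        data=out,
        channel_names=rec.channel_names,
    )


def epoch_count(n_samples: int, epoch_samples: int = EPOCH_SAMPLES, step: int = EPOCH_STEP) -> int:
    """Number of full epochs available in a recording of `n_samples`."""
    if n_samples < epoch_samples:
        return 0
    return (n_samples - epoch_samples) // step + 1


def segment_epochs(
    rec: EEGRecording,
    epoch_s: float = 5.0,
    overlap: float = 0.5,
    on_short: str = "warn",
) -> EpochSet:
    """Cut a 256 Hz recording into fixed-length overlapping epochs.

    Epochs start at offsets 0, 640, 1280, ... (for the default 5 s / 50%),
    each holds exactly ``epoch_s * fs`` samples, and any trailing remainder
    shorter than one epoch is discarded.

    Parameters
    ----------
    on_short : {"warn", "error"}
        What to do when the recording is shorter than one epoch.
    """
    if rec.fs != TARGET_FS:
        raise ValueError(
            f"segmentation expects {TARGET_FS:g} Hz input, got {rec.fs:g} Hz; resample first"
        )
    epoch_samples = int(round(epoch_s * rec.fs))
    step = int(round(epoch_samples * (1 - overlap)))
    if step <= 0:
        raise ValueError(f"overlap {overlap} leaves a non-positive step")
    n = rec.n_samples
    out = EpochSet()
    if n < epoch_samples:
        msg = (
            f"recording {rec.subject_id}: {n} samples is shorter than one "
            f"epoch ({epoch_samples}); no epochs produced"
        )
        if on_short == "error":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
        return out
    for start in range(0, n - epoch_samples + 1, step):
        out.epochs.append(
            Epoch(
                subject_id=rec.subject_id,
                label=rec.label,
                start_sample=start,
                data=rec.data[:, start : start + epoch_samples],
            )
        )
    return out


def preprocess_recording(
    rec: EEGRecording,
    target_fs: float = TARGET_FS,
    low: float = 0.5,
    high: float = 32.0,
    epoch_s: float = 5.0,
    overlap: float = 0.5,
) -> EpochSet:
    """Resample -> band-pass -> segment, in the pipeline's documented order."""
    return segment_epochs(
        bandpass(resample(rec, target_fs), low, high), epoch_s, overlap
    )


# ---------------------------------------------------------------------------
# epoch store


def write_epochs_h5(epochs: EpochSet, path: str | Path, manifest_csv: str | Path | None = None) -> None:
    """Write an epoch set (and optionally its CSV manifest) to disk."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.stack())
        f.create_dataset("label", data=epochs.labels)
        f.create_dataset(
            "subject_id", data=np.array([s.encode() for s in epochs.subject_ids])
        )
        f.create_dataset("start_sample", data=epochs.start_samples)
    if manifest_csv is not None:
        pd.DataFrame(epochs.manifest()).to_csv(manifest_csv, index=False)


def read_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        labels = f["label"][()]
        subjects = [s.decode() for s in f["subject_id"][()]]
        starts = f["start_sample"][()]
    out = EpochSet()
    for i in range(data.shape[0]):
        out.epochs.append(
            Epoch(
                subject_id=subjects[i],
                label=ClassLabel(int(labels[i])),
                start_sample=int(starts[i]),
                data=data[i],
            )
        )
    return out
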