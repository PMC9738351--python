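"""Core domain containers: recordings, epochs and epoch sets.

An :class:`EEGRecording` is one subject's continuous 19-channel scalp EEG in
the standard 10-20 montage, in microvolts.  An :class:`Epoch` is a fixed
5-second (1280 samples at 256 Hz) window cut from a recording; overlapping
epochs are the classification unit of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np

#: Canonical 10-20 channel order used for every tensor the package builds.
CANONICAL_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

N_CHANNELS = len(CANONICAL_CHANNELS)  # 19

#: Pipeline constants: 256 Hz sampling, 5 s epochs, 50% overlap.
TARGET_FS = 256.0
EPOCH_SECONDS = 5.0
EPOCH_SAMPLES = 1280  # 5 s * 256 Hz
EPOCH_OVERLAP = 0.5
EPOCH_STEP = 640  # samples between successive epoch starts


class ClassLabel(IntEnum):
    """Three-way diagnostic class.

    ES: epileptic seizures; PNES: psychogenic non-epileptic seizures;
    CS: control subjects.  The integer codes are fixed (ES=0, PNES=1, CS=2)
    and used everywhere a class is stored numerically.
    """

    ES = 0
    PNES = 1
    CS = 2

    @classmethod
    def coerce(cls, value: "ClassLabel | int | str") -> "ClassLabel":
        if isinstance(value, cls):
            return value
        if isinstance(value, str):
            try:
                return cls[value.upper()]
            except KeyError:
                raise ValueError(
                    f"unknown class label {value!r}; expected one of "
                    f"{[m.name for m in cls]}"
                ) from None
        return cls(int(value))


class MontageError(ValueError):
    """Raised when a recording does not provide the 19 canonical channels."""


class FormatError(ValueError):
    """Raised when an input file cannot be parsed as EEG."""


@dataclass
class EEGRecording:
    """One subject's continuous multichannel EEG.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    label : ClassLabel
        Diagnostic class of the subject.
    fs : float
        Sampling rate in Hz.
    data : ndarray, shape (19, n_samples)
        Signal in microvolts, one row per canonical channel.
    channel_names : sequence of str
        Channel names, row-aligned with ``data``.
    """

    subject_id: str
    label: ClassLabel
    fs: float
    data: np.ndarray
    channel_names: tuple[str, ...] = CANONICAL_CHANNELS

    def __post_init__(self) -> None:
        self.label = ClassLabel.coerce(self.label)
        self.data = np.asarray(self.data, dtype=np.float64)
        self.channel_names = tuple(self.channel_names)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.data.ndim != 2:
            raise ValueError(f"data must be 2-D (channels x samples), got {self.data.shape}")
        if self.data.shape[0] != len(self.channel_names):
            raise MontageError(
                f"{self.data.shape[0]} data rows but {len(self.channel_names)} channel names"
            )
        if len(self.channel_names) != N_CHANNELS:
            raise MontageError(
                f"expected {N_CHANNELS} channels, got {len(self.channel_names)}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Epoch:
    """A fixed-length window of one recording (the classification unit)."""

    subject_id: str
    label: ClassLabel
    start_sample: int  # 0-based offset into the source recording
    data: np.ndarray  # (19, 1280)

    def __post_init__(self) -> None:
        self.label = ClassLabel.coerce(self.label)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.shape != (N_CHANNELS, EPOCH_SAMPLES):
            raise ValueError(
                f"epoch data must be ({N_CHANNELS}, {EPOCH_SAMPLES}), got {self.data.shape}"
            )


@dataclass
class EpochSet:
    """An ordered collection of epochs with per-epoch provenance."""

    epochs: list[Epoch] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self) -> Iterator[Epoch]:
        return iter(self.epochs)

    def __getitem__(self, i: int) -> Epoch:
        return self.epochs[i]

    def extend(self, other: "EpochSet") -> None:
        self.epochs.extend(other.epochs)

    @property
    def labels(self) -> np.ndarray:
        """Integer class codes, shape (n_epochs,)."""
        return np.array([e.label for e in self.epochs], dtype=np.int64)

    @property
    def subject_ids(self) -> np.ndarray:
        return np.array([e.subject_id for e in self.epochs])

    @property
    def start_samples(self) -> np.ndarray:
        return np.array([e.start_sample for e in self.epochs], dtype=np.int64)

    def stack(self) -> np.ndarray:
        """All epoch signals as one (n_epochs, 19, 1280) array."""
        if not self.epochs:
            return np.empty((0, N_CHANNELS, EPOCH_SAMPLES))
        return np.stack([e.data for e in self.epochs])

    def manifest(self) -> "list[dict]":
        """Provenance rows: subject, label, epoch index, start sample."""
        return [
            {
                "epoch_index": i,
                "subject_id": e.subject_id,
                "label": e.label.name,
                "start_sample": e.start_sample,
            }
            for i, e in enumerate(self.epochs)
        ]


def labels_to_names(codes: Sequence[int]) -> list[str]:
    return [ClassLabel(int(c)).name for c in codes]
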