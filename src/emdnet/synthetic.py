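"""Seeded synthetic 19-channel EEG with controllable class separability.

Stands in for the clinical cohort (42 ES / 42 PNES / 19 CS subjects,
which is not publicly available): each synthetic subject is 19 channels
of 1/f^beta background noise plus class-dependent band-limited
oscillations, at 256 Hz, scaled to a physiological amplitude range.

The class profiles are deliberately distinct fixtures, not models of
real pathophysiology:

* ES   — excess 3-5 Hz and 14-18 Hz power;
* PNES — excess 8-12 Hz power;
* CS   — background-dominated (a weak broad alpha component).

Difficulty presets move the oscillation-to-background SNR from well
separated (``easy``) through ``moderate`` to ``hard``, where all three
classes share one profile and classification is chance level by
construction.  Every signal is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .records import CANONICAL_CHANNELS, ClassLabel, EEGRecording

__all__ = [
    "OscillatoryComponent",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_recording",
    "generate_dataset",
    "pink_noise",
    "DEFAULT_PROFILES",
]


@dataclass(frozen=True)
class OscillatoryComponent:
    """One band-limited oscillation: center (Hz), bandwidth (Hz), relative power."""

    center_hz: float
    bandwidth_hz: float
    rel_power: float

    def __post_init__(self) -> None:
        if not 0.5 < self.center_hz < 32.0:
            raise ValueError(
                f"component center {self.center_hz} Hz outside the (0.5, 32) band"
            )
        if self.bandwidth_hz <= 0 or self.rel_power <= 0:
            raise ValueError("bandwidth and relative power must be positive")


#: Class-dependent oscillatory content (easy/moderate presets).
DEFAULT_PROFILES: dict[ClassLabel, tuple[OscillatoryComponent, ...]] = {
    ClassLabel.ES: (
        OscillatoryComponent(4.0, 1.0, 1.0),
        OscillatoryComponent(16.0, 1.5, 0.8),
    ),
    ClassLabel.PNES: (
        OscillatoryComponent(10.0, 1.0, 1.0),
    ),
    ClassLabel.CS: (
        OscillatoryComponent(9.0, 4.0, 0.3),
    ),
}

#: A single shared profile: classes are indistinguishable by construction.
_HARD_PROFILE = (OscillatoryComponent(10.0, 2.0, 0.5),)

_PRESET_SNR = {"easy": 3.0, "moderate": 1.0, "hard": 1.0}


@dataclass
class SyntheticConfig:
    """Generator settings.

    ``snr`` is the ratio of total oscillatory power to background power
    per channel; ``rms_uv`` sets the overall channel RMS in microvolts.
    """

    n_subjects_per_class: int = 4
    duration_s: float = 60.0
    fs: float = 256.0
    difficulty: str = "easy"
    snr: float | None = None  # None: taken from the difficulty preset
    background_beta: float = 1.0
    rms_uv: float = 30.0
    amplitude_jitter: float = 0.1  # per-channel amplitude spread
    seed: int = 0
    class_counts: dict | None = None  # optional per-class override, e.g. cohort 42/42/19

    def __post_init__(self) -> None:
        if self.difficulty not in _PRESET_SNR:
            raise ValueError(f"unknown difficulty preset {self.difficulty!r}")
        if self.n_subjects_per_class < 1 or self.duration_s <= 0:
            raise ValueError("need at least one subject and a positive duration")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive")

    @property
    def effective_snr(self) -> float:
        return self.snr if self.snr is not None else _PRESET_SNR[self.difficulty]

    def profiles(self) -> dict[ClassLabel, tuple[OscillatoryComponent, ...]]:
        if self.difficulty == "hard":
            return {c: _HARD_PROFILE for c in ClassLabel}
        return DEFAULT_PROFILES

    def manifest(self) -> dict:
        return {
            "n_subjects_per_class": self.n_subjects_per_class,
            "duration_s": self.duration_s,
            "fs": self.fs,
            "difficulty": self.difficulty,
            "snr": self.effective_snr,
            "background_beta": self.background_beta,
            "rms_uv": self.rms_uv,
            "amplitude_jitter": self.amplitude_jitter,
            "seed": self.seed,
            "class_counts": self.class_counts,
            "profiles": {
                c.name: [[o.center_hz, o.bandwidth_hz, o.rel_power] for o in prof]
                for c, prof in self.profiles().items()
            },
        }


@dataclass
class SyntheticDataset:
    recordings: list[EEGRecording]
    manifest: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.recordings], dtype=np.int64)

    def manifest_json(self) -> str:
        return json.dumps(self.manifest, indent=2, sort_keys=True)


def _shaped_noise(
    rng: np.random.Generator, n: int, fs: float, amplitude: np.ndarray
) -> np.ndarray:
    """Gaussian noise with the given one-sided spectral amplitude profile."""
    re = rng.standard_normal(len(amplitude))
    im = rng.standard_normal(len(amplitude))
    spec = (re + 1j * im) * amplitude
    spec[0] = 0.0  # no DC
    x = np.fft.irfft(spec, n=n)
    return x


def pink_noise(
    rng: np.random.Generator, n: int, fs: float, beta: float = 1.0
) -> np.ndarray:
    """1/f^beta background noise, unit RMS."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    nz = freqs > 0
    amp[nz] = freqs[nz] ** (-beta / 2.0)
    x = _shaped_noise(rng, n, fs, amp)
    return x / (np.std(x) + 1e-30)


def _band_component(
    rng: np.random.Generator, n: int, fs: float, comp: OscillatoryComponent
) -> np.ndarray:
    """Unit-RMS narrow-band oscillation: Gaussian spectral bump at the center."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    sigma = comp.bandwidth_hz / 2.355  # FWHM -> sigma
    amp = np.exp(-0.5 * ((freqs - comp.center_hz) / sigma) ** 2)
    x = _shaped_noise(rng, n, fs, amp)
    return x / (np.std(x) + 1e-30)


def generate_recording(
    label: ClassLabel | int | str,
    cfg: SyntheticConfig,
    subject_seed: int,
    subject_id: str | None = None,
) -> EEGRecording:
    """One synthetic subject: 19 channels of profile oscillations + noise.

    Each channel gets independent noise and independently phased
    oscillations with mild amplitude variation; the channel mix of
    oscillatory vs background power is set by ``cfg.effective_snr`` and
    the whole channel is scaled to ``cfg.rms_uv`` microvolts RMS.
    """
    label = ClassLabel.coerce(label)
    profile = cfg.profiles()[label]
    rng = np.random.default_rng(subject_seed)
    n = int(round(cfg.duration_s * cfg.fs))
    total_rel = sum(c.rel_power for c in profile)
    data = np.empty((len(CANONICAL_CHANNELS), n))
    for ch in range(len(CANONICAL_CHANNELS)):
        bg = pink_noise(rng, n, cfg.fs, cfg.background_beta)
        osc = np.zeros(n)
        for comp in profile:
            gain = 1.0 + cfg.amplitude_jitter * rng.standard_normal()
            # power share within the oscillatory budget
            share = comp.rel_power / total_rel
            osc += _band_component(rng, n, cfg.fs, comp) * abs(gain) * np.sqrt(share)
        # mix at the configured oscillation:background power ratio
        s = cfg.effective_snr
        x = np.sqrt(s / (1 + s)) * osc / (np.std(osc) + 1e-30) + np.sqrt(
            1 / (1 + s)
        ) * bg
        data[ch] = cfg.rms_uv * x / (np.std(x) + 1e-30)
    return EEGRecording(
        subject_id=subject_id or f"{label.name}-{subject_seed}",
        label=label,
        fs=cfg.fs,
        data=data,
    )


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """A labeled cohort of synthetic recordings.

    By default each class has ``cfg.n_subjects_per_class`` subjects;
    ``cfg.class_counts`` (e.g. ``{"ES": 42, "PNES": 42, "CS": 19}``)
    overrides the balance.  Subject seeds are spawned deterministically
    from ``cfg.seed``, so the dataset is bit-reproducible.
    """
    counts = {
        c: (cfg.class_counts or {}).get(c.name, cfg.n_subjects_per_class)
        for c in ClassLabel
    }
    root = np.random.SeedSequence(cfg.seed)
    recordings: list[EEGRecording] = []
    children = root.spawn(sum(counts.values()))
    i = 0
    for c in ClassLabel:
        for k in range(counts[c]):
            sseed = int(children[i].generate_state(1)[0] % (2**31))
            recordings.append(
                generate_recording(c, cfg, sseed, subject_id=f"{c.name}-{k:02d}")
            )
            i += 1
    manifest = cfg.manifest()
    manifest["n_recordings"] = len(recordings)
    return SyntheticDataset(recordings=recordings, manifest=manifest)
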