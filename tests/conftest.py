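"""Shared fixtures: small synthetic signals and recordings."""

from __future__ import annotations

import numpy as np
import pytest

from emdnet.records import CANONICAL_CHANNELS, ClassLabel, EEGRecording


FS = 256.0


def two_tone(duration_s: float = 5.0, fs: float = FS,
             f_hi: float = 16.0, f_lo: float = 1.0) -> np.ndarray:
    """Sum of two well-separated tones; the classic separability probe."""
    t = np.arange(int(duration_s * fs)) / fs
    return np.sin(2 * np.pi * f_hi * t) + np.sin(2 * np.pi * f_lo * t)


def band_limited_noise(rng: np.random.Generator, n: int = 1280,
                       fs: float = FS, low: float = 0.5, high: float = 32.0) -> np.ndarray:
    """Random signal with support only in [low, high] Hz."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    spec = (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    spec[(freqs < low) | (freqs > high)] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / (np.std(x) + 1e-30)


def count_extrema_bruteforce(x: np.ndarray) -> int:
    """Independent O(n) scan for strict interior extrema (plateaus once)."""
    n_ext = 0
    i = 1
    n = len(x)
    while i < n - 1:
        j = i
        while j < n - 1 and x[j + 1] == x[j]:
            j += 1
        if j < n - 1:
            left, right = x[i - 1], x[j + 1]
            if x[i] > left and x[i] > right:
                n_ext += 1
            elif x[i] < left and x[i] < right:
                n_ext += 1
        i = j + 1
    return n_ext


def count_zero_crossings_bruteforce(x: np.ndarray) -> int:
    """Independent sign-change count, zeros ignored."""
    signs = [1 if v > 0 else -1 for v in x if v != 0]
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def fft_peak_hz(x: np.ndarray, fs: float = FS) -> float:
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return float(freqs[np.argmax(np.abs(np.fft.rfft(x)))])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_recording(rng: np.random.Generator, fs: float = FS,
                   duration_s: float = 10.0, label=ClassLabel.ES,
                   subject_id: str = "S01") -> EEGRecording:
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    data = np.empty((19, n))
    for c in range(19):
        data[c] = (
            20 * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
            + 5 * rng.standard_normal(n)
        )
    return EEGRecording(subject_id=subject_id, label=label, fs=fs, data=data)


@pytest.fixture
def recording(rng) -> EEGRecording:
    return make_recording(rng)
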