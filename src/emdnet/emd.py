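"""Empirical mode decomposition by iterative sifting.

EMD expresses a signal x(t) as a sum of intrinsic mode functions (IMFs)
plus a final low-frequency residual,

    x(t) = sum_i h_i(t) + r_n(t),

where each IMF must (1) have extrema and zero-crossing counts that differ
by at most one, and (2) have a locally zero mean between its upper and
lower cubic-spline envelopes.  Sifting extracts one IMF at a time:
subtract the envelope mean from the current signal and repeat until the
candidate satisfies the IMF conditions and a Cauchy-type convergence
criterion; then start again on the residual.

The decomposition is fully deterministic: no randomness enters anywhere.

Design choices (the method itself leaves these open):

* stopping: normalized squared difference between successive sift iterates,
  SD = sum((d_prev - d_new)^2) / sum(d_prev^2), threshold 0.2, at most 100
  sift iterations per IMF — the classical criterion of the original EMD
  literature;
* boundaries: the two extrema nearest each end are mirrored across the
  signal edge before spline fitting, the standard low-distortion choice;
* envelopes: natural cubic splines through the (extended) extrema;
* plateaus: a flat run of equal samples contributes a single extremum at
  its midpoint, keeping condition (1) well defined on quantized signals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .records import EPOCH_SAMPLES, N_CHANNELS, Epoch

logger = logging.getLogger(__name__)

__all__ = [
    "SiftConfig",
    "IMFSet",
    "find_extrema",
    "zero_crossings",
    "envelope_mean",
    "sift_imf",
    "emd_decompose",
    "build_imf_tensor",
    "IMFTensorizer",
]

N_IMF = 3  # IMF planes fed to the classifier


@dataclass(frozen=True)
class SiftConfig:
    """Sifting parameters.

    stop_threshold : normalized squared-difference convergence level (SD);
    max_sift_iterations : cap on sift passes per IMF;
    max_imfs : number of IMFs to extract before stopping;
    boundary_mode : extrema extension scheme (only mirroring is provided).
    """

    stop_threshold: float = 0.2
    max_sift_iterations: int = 100
    max_imfs: int = N_IMF
    boundary_mode: str = "mirror_extrema"

    def __post_init__(self) -> None:
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")
        if self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1")
        if self.boundary_mode != "mirror_extrema":
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


@dataclass
class IMFSet:
    """Result of one decomposition: ordered IMFs plus the final residual."""

    imfs: list[np.ndarray]
    residual: np.ndarray

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    def reconstruct(self) -> np.ndarray:
        """sum of IMFs + residual; equals the input to numerical precision."""
        out = self.residual.copy()
        for h in self.imfs:
            out += h
        return out

    def orthogonality_index(self) -> float:
        """Diagnostic: largest normalized inner product between components.

        EMD components only *tend* to be locally orthogonal; this is
        reported for inspection, never asserted.
        """
        comps = [*self.imfs, self.residual]
        worst = 0.0
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                a, b = comps[i], comps[j]
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na > 0 and nb > 0:
                    worst = max(worst, abs(float(a @ b)) / (na * nb))
        return worst


def _compress_plateaus(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse runs of equal consecutive samples to their midpoints.

    Returns (indices, values) where each run of identical samples is
    represented once, at the integer midpoint of the run.
    """
    n = len(x)
    change = np.empty(n, dtype=bool)
    change[0] = True
    change[1:] = x[1:] != x[:-1]
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n) - 1
    mids = (starts + ends) // 2
    return mids, x[starts]


def find_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Locate strict local maxima and minima of a 1-D signal.

    Plateaus count once, at their midpoint.  Endpoints are never extrema.

    Returns
    -------
    (max_idx, max_val, min_idx, min_val), indices strictly increasing.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or len(x) < 3:
        raise ValueError("find_extrema expects a 1-D signal of length >= 3")
    idx, val = _compress_plateaus(x)
    if len(val) < 3:
        e = np.empty(0, dtype=np.int64)
        return e, np.empty(0), e.copy(), np.empty(0)
    d = np.sign(np.diff(val))
    interior = np.arange(1, len(val) - 1)
    is_max = (d[:-1] > 0) & (d[1:] < 0)
    is_min = (d[:-1] < 0) & (d[1:] > 0)
    max_i = idx[interior[is_max]]
    min_i = idx[interior[is_min]]
    return max_i, x[max_i], min_i, x[min_i]


def zero_crossings(x: np.ndarray) -> int:
    """Count sign changes, ignoring exact zeros (a touch counts once)."""
    s = np.sign(x)
    s = s[s != 0]
    if len(s) < 2:
        return 0
    return int(np.count_nonzero(s[1:] != s[:-1]))


def _mirror_extend(
    idx: np.ndarray, val: np.ndarray, n: int, n_mirror: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Reflect up to `n_mirror` extrema across each signal edge."""
    left_i = 2 * 0 - idx[:n_mirror][::-1]
    left_v = val[:n_mirror][::-1]
    right_i = 2 * (n - 1) - idx[-n_mirror:][::-1]
    right_v = val[-n_mirror:][::-1]
    return (
        np.concatenate([left_i, idx, right_i]),
        np.concatenate([left_v, val, right_v]),
    )


class MonotoneResidual(Exception):
    """Signal has too few extrema to continue sifting."""


def envelope_mean(x: np.ndarray) -> np.ndarray:
    """Mean of the upper and lower cubic-spline envelopes, m(t).

    Envelopes are natural cubic splines through the maxima (resp. minima)
    after mirror extension of the two extrema nearest each end.

    Raises
    ------
    MonotoneResidual
        If the signal has fewer than 2 maxima or 2 minima.
    """
    x = np.asarray(x, dtype=np.float64)
    max_i, max_v, min_i, min_v = find_extrema(x)
    if len(max_i) < 2 or len(min_i) < 2:
        raise MonotoneResidual(
            f"{len(max_i)} maxima / {len(min_i)} minima: cannot build envelopes"
        )
    t = np.arange(len(x))
    mi, mv = _mirror_extend(max_i, max_v, len(x))
    ni, nv = _mirror_extend(min_i, min_v, len(x))
    # mirroring can duplicate knots when an extremum sits on the edge
    mi, keep = np.unique(mi, return_index=True)
    mv = mv[keep]
    ni, keep = np.unique(ni, return_index=True)
    nv = nv[keep]
    e_max = CubicSpline(mi, mv, bc_type="natural")(t)
    e_min = CubicSpline(ni, nv, bc_type="natural")(t)
    return (e_max + e_min) / 2.0


def _is_imf(candidate: np.ndarray) -> bool:
    """Condition (1): extrema and zero-crossing counts differ by <= 1."""
    max_i, _, min_i, _ = find_extrema(candidate)
    n_ext = len(max_i) + len(min_i)
    return abs(n_ext - zero_crossings(candidate)) <= 1


def sift_imf(x: np.ndarray, cfg: SiftConfig = SiftConfig()) -> tuple[np.ndarray, np.ndarray]:
    """Extract one IMF from `x` by iterative sifting.

    Repeats d <- d - m(d) until the candidate satisfies the IMF count
    condition and the normalized squared difference between successive
    iterates falls below ``cfg.stop_threshold`` (or the iteration cap is
    hit).  Returns ``(imf, residual)`` with ``residual = x - imf`` exactly.

    Raises
    ------
    MonotoneResidual
        If `x` has too few extrema to sift at all.
    """
    x = np.asarray(x, dtype=np.float64)
    d = x - envelope_mean(x)  # raises MonotoneResidual if unsiftable
    for _ in range(cfg.max_sift_iterations - 1):
        try:
            m = envelope_mean(d)
        except MonotoneResidual:
            break
        d_new = d - m
        denom = float(np.sum(d * d))
        if denom == 0.0:
            d = d_new
            break
        sd = float(np.sum((d - d_new) ** 2)) / denom
        d = d_new
        if sd < cfg.stop_threshold and _is_imf(d):
            break
    return d, x - d


def emd_decompose(x: np.ndarray, cfg: SiftConfig = SiftConfig()) -> IMFSet:
    """Decompose a signal into up to ``cfg.max_imfs`` IMFs plus a residual.

    Stops early when the running residual becomes monotone or has fewer
    than 2 maxima / 2 minima.  Constant input yields zero IMFs.  The
    reconstruction identity sum(IMFs) + residual == x holds to machine
    precision because each residual is formed by exact subtraction.
    """
    x = np.asarray(x, dtype=np.float64)
    imfs: list[np.ndarray] = []
    residual = x.copy()
    for _ in range(cfg.max_imfs):
        try:
            h, residual = sift_imf(residual, cfg)
        except MonotoneResidual:
            break
        imfs.append(h)
    return IMFSet(imfs=imfs, residual=residual)


def build_imf_tensor(epoch: Epoch, cfg: SiftConfig | None = None) -> np.ndarray:
    """Per-channel EMD of one epoch, assembled as a (19, 1280, 3) tensor.

    Plane k holds IMF k+1 of each channel.  A channel yielding fewer than
    3 IMFs (e.g. a constant channel) has its missing planes zero-filled,
    with a warning, so the classifier input shape never varies.
    """
    cfg = cfg or SiftConfig(max_imfs=N_IMF)
    if cfg.max_imfs != N_IMF:
        raise ValueError(f"classifier tensor requires max_imfs={N_IMF}")
    tensor = np.zeros((N_CHANNELS, EPOCH_SAMPLES, N_IMF))
    for c in range(N_CHANNELS):
        dec = emd_decompose(epoch.data[c], cfg)
        if dec.n_imfs < N_IMF:
            warnings.warn(
                f"channel {c} of epoch (subject {epoch.subject_id}, "
                f"start {epoch.start_sample}) yielded {dec.n_imfs} IMF(s); "
                "missing planes zero-filled",
                stacklevel=2,
            )
        for k in range(dec.n_imfs):
            tensor[c, :, k] = dec.imfs[k]
    return tensor


class IMFTensorizer:
    """Transformer turning epoch signals into stacked IMF tensors.

    sklearn-style: ``transform`` maps an (n, 19, 1280) array of epoch
    signals to an (n, 19, 1280, 3) array of IMF planes.  Stateless, so
    ``fit`` is a no-op; provided for pipeline composability.
    """

    def __init__(self, sift_config: SiftConfig | None = None):
        self.sift_config = sift_config

    def get_params(self, deep: bool = True) -> dict:
        return {"sift_config": self.sift_config}

    def set_params(self, **params) -> "IMFTensorizer":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X: np.ndarray, y=None) -> "IMFTensorizer":
        self.n_features_in_ = int(np.prod(np.shape(X)[1:]))
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1:] != (N_CHANNELS, EPOCH_SAMPLES):
            raise ValueError(
                f"expected (n, {N_CHANNELS}, {EPOCH_SAMPLES}) epochs, got {X.shape}"
            )
        cfg = self.sift_config or SiftConfig(max_imfs=N_IMF)
        out = np.zeros(X.shape + (N_IMF,))
        for i in range(X.shape[0]):
            for c in range(N_CHANNELS):
                dec = emd_decompose(X[i, c], cfg)
                for k in range(min(dec.n_imfs, N_IMF)):
                    out[i, c, :, k] = dec.imfs[k]
        return out

    def fit_transform(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X, y).transform(X)
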