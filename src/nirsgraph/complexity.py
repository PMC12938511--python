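"""Sliding-window nonlinear complexity metrics.

Three complementary measures are computed per 30 s window, per channel:

* Higuchi fractal dimension (HFD) — slope of log curve length against
  log(1/k); 1 for a smooth curve, 2 for white noise.
* Spectral entropy (SE) — Shannon entropy of the Welch power spectrum,
  normalized to [0, 1] by log2 of the number of frequency bins.
* Wavelet entropy (WE) — Shannon entropy of relative detail-band energies
  of a discrete wavelet decomposition, normalized by log2 of the number of
  decomposition levels.

All three are computed on every overlapping window (30 s length, 1 s step
by default), yielding per-channel complexity *trajectories* whose
co-fluctuation across channels defines the graph edges downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps

from .config import RunConfig
from .session import RecordingSession

METRICS = ("HFD", "SE", "WE")


@dataclass(frozen=True)
class WindowPlan:
    """Placement of overlapping analysis windows in a recording."""

    win_len: int
    step: int
    n_windows: int
    start_indices: tuple[int, ...]


def make_windows(n_samples: int, fs: float, window_s: float, step_s: float) -> WindowPlan:
    """Plan overlapping windows: length and step round to the nearest sample.

    At 8.138 Hz a 30 s window is 244 samples and a 1 s step is 8 samples,
    which places 224 windows in a 2033-sample recording.
    """
    win_len = int(round(window_s * fs))
    step = max(int(round(step_s * fs)), 1)
    if n_samples < win_len:
        raise ValueError(f"{n_samples} samples < window length {win_len}")
    n_windows = (n_samples - win_len) // step + 1
    starts = tuple(range(0, n_windows * step, step))
    return WindowPlan(win_len=win_len, step=step, n_windows=n_windows, start_indices=starts)


@dataclass(frozen=True)
class HFDParams:
    kmax: int = 8


@dataclass(frozen=True)
class SEParams:
    welch_segment: int | None = None   # default win_len // 4
    welch_overlap: float = 0.5
    detrend: bool = True


@dataclass(frozen=True)
class WEParams:
    wavelet: str = "db4"
    levels: int | None = None          # default floor(log2(win_len)) - 2


@dataclass
class ComplexityTrajectory:
    """windows x channels x metrics array of window-wise complexity values."""

    values: np.ndarray                 # [n_windows, n_channels, 3]
    window_plan: WindowPlan
    channel_labels: list[str]
    excluded_channels: set[int] = field(default_factory=set)

    def metric(self, name: str) -> np.ndarray:
        return self.values[:, :, METRICS.index(name)]


# ---------------------------------------------------------------------------
# Higuchi fractal dimension


def _higuchi_curve_lengths(x: np.ndarray, kmax: int) -> np.ndarray:
    """Mean curve length L(k) for k = 1..kmax, vectorized over leading axes.

    For delay k and offset m (1..k), the curve length is
    ``L_m(k) = (sum_i |x[m+ik] - x[m+(i-1)k]|) * (N-1) / (floor((N-m)/k) * k^2)``
    and L(k) averages over offsets.
    """
    N = x.shape[-1]
    L = np.empty(x.shape[:-1] + (kmax,))
    for k in range(1, kmax + 1):
        # |x[j+k] - x[j]| once per lag; offset sums are strided slices of it
        d_k = np.abs(x[..., k:] - x[..., :-k])
        acc = 0.0
        for m in range(1, k + 1):
            n_i = (N - m) // k
            dist = d_k[..., m - 1 : m - 1 + n_i * k : k].sum(axis=-1)
            acc = acc + dist * (N - 1) / (n_i * k * k)
        L[..., k - 1] = acc / k
    return L


def higuchi_fd(x: np.ndarray, params: HFDParams = HFDParams()) -> np.ndarray:
    """Higuchi fractal dimension of one window (or a stack of windows).

    Estimated as the slope of the regression of log L(k) on log(1/k).
    Raises on an exactly constant single window; in stacked input constant
    windows yield NaN with a warning.
    """
    x = np.asarray(x, dtype=float)
    kmax = params.kmax
    if x.shape[-1] < 4 * kmax:
        raise ValueError(f"window of {x.shape[-1]} samples too short for kmax={kmax}")
    L = _higuchi_curve_lengths(x, kmax)
    zero = L <= 0
    scalar = x.ndim == 1
    if zero.any():
        if scalar:
            raise ValueError("zero curve length: constant window")
        warnings.warn("constant window(s): HFD set to NaN", RuntimeWarning, stacklevel=2)
    logk = np.log(1.0 / np.arange(1, kmax + 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logL = np.log(L)
    logL = np.where(zero, np.nan, logL)
    # least-squares slope against log(1/k)
    xc = logk - logk.mean()
    slope = np.nansum(xc * (logL - np.nanmean(logL, axis=-1, keepdims=True)), axis=-1)
    slope = slope / (xc**2).sum()
    slope = np.where(np.isnan(logL).any(axis=-1), np.nan, slope)
    return float(slope) if scalar else slope


# ---------------------------------------------------------------------------
# Spectral entropy


def normalized_entropy(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy of a distribution, normalized by log2 of its size.

    Zero-probability bins contribute nothing; a one-hot distribution gives
    0 and a uniform distribution gives 1.
    """
    p = np.asarray(p, dtype=float)
    n = p.shape[axis]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log2(p), 0.0)
    return terms.sum(axis=axis) / np.log2(n)


def spectral_entropy(
    x: np.ndarray, fs: float, params: SEParams = SEParams()
) -> np.ndarray:
    """Normalized spectral entropy of one window (or a stack).

    The power spectral density is estimated with Welch's method (Hann
    window, segment = win_len/4, 50% overlap, linear detrend); the DC bin
    is dropped (band-passed signals carry no DC power), the spectrum is
    normalized to sum to one and its entropy divided by log2 of the number
    of retained bins.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    var = x.var(axis=-1)
    if scalar and var == 0:
        raise ValueError("zero-variance window")
    nper = params.welch_segment or max(x.shape[-1] // 4, 8)
    nover = int(nper * params.welch_overlap)
    detrend = "linear" if params.detrend else "constant"
    _, P = sps.welch(
        x, fs=fs, nperseg=nper, noverlap=nover, window="hann", detrend=detrend, axis=-1
    )
    P = P[..., 1:]  # drop DC
    tot = P.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = normalized_entropy(P / tot)
    se = np.where(np.asarray(var) == 0, np.nan, se)
    return float(se) if scalar else se


# ---------------------------------------------------------------------------
# Wavelet entropy


def default_levels(win_len: int) -> int:
    return int(np.floor(np.log2(win_len))) - 2


def wavelet_energies(x: np.ndarray, params: WEParams, win_len: int | None = None) -> np.ndarray:
    """Per-scale detail energies E_j of a J-level DWT, stacked over scales."""
    x = np.asarray(x, dtype=float)
    J = params.levels or default_levels(win_len or x.shape[-1])
    if J < 2:
        raise ValueError("need at least 2 decomposition levels")
    if x.shape[-1] < 2**J:
        raise ValueError(f"window of {x.shape[-1]} samples < 2^{J}")
    coeffs = pywt.wavedec(x, params.wavelet, level=J, axis=-1)
    details = coeffs[1:]  # finest..coarsest detail bands; approximation excluded
    E = np.stack([(c**2).sum(axis=-1) for c in details], axis=-1)
    return E


def wavelet_entropy_from_energies(energies: np.ndarray) -> np.ndarray:
    """WE from per-scale energies: entropy of p_j = E_j / sum(E), over log2 J."""
    E = np.asarray(energies, dtype=float)
    tot = E.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, E / tot, np.nan)
    return normalized_entropy(p)


def wavelet_entropy(x: np.ndarray, params: WEParams = WEParams()) -> np.ndarray:
    """Normalized wavelet entropy of one window (or a stack)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    E = wavelet_energies(x, params)
    tot = E.sum(axis=-1)
    if scalar and tot == 0:
        raise ValueError("zero-energy window")
    we = wavelet_entropy_from_energies(E)
    return float(we) if scalar else we


# ---------------------------------------------------------------------------
# Trajectories


def trajectories(
    session: RecordingSession,
    config: RunConfig,
    hfd: HFDParams = HFDParams(),
    se: SEParams = SEParams(),
    we: WEParams = WEParams(),
) -> ComplexityTrajectory:
    """Window-wise HFD/SE/WE for every channel of a preprocessed session.

    Excluded channels are filled with NaN. The result is a
    [n_windows x n_channels x 3] array in metric order (HFD, SE, WE).
    """
    plan = make_windows(session.n_samples, session.fs, config.window_s, config.step_s)
    # [n_channels, n_windows, win_len] view, then metric axes moved to front
    wins = sliding_window_view(session.data, plan.win_len, axis=-1)[:, :: plan.step, :]
    wins = wins[:, : plan.n_windows, :]

    values = np.full((plan.n_windows, session.n_channels, 3), np.nan)
    usable = session.usable_channels
    if usable:
        w = np.ascontiguousarray(wins[usable])        # [C_use, W, L]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            values[:, usable, 0] = higuchi_fd(w, hfd).T
            values[:, usable, 1] = spectral_entropy(w, session.fs, se).T
            values[:, usable, 2] = wavelet_entropy(w, we).T
    return ComplexityTrajectory(
        values=values,
        window_plan=plan,
        channel_labels=list(session.channel_labels),
        excluded_channels=set(session.excluded_channels),
    )
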