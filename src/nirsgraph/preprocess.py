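"""Optical-to-hemoglobin conversion, motion QC and band-pass filtering.

The chain is: raw dual-wavelength intensity -> optical density (OD) ->
modified Beer-Lambert law (MBLL) inversion to HbO/HbR concentration
changes -> sliding-window motion masking with a 10% channel-exclusion
rule -> zero-phase 4th-order Butterworth band-pass (0.0018-0.15 Hz).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import Chromophore
from .session import RecordingSession


@dataclass(frozen=True)
class MBLLParams:
    """Modified Beer-Lambert law parameters.

    ``extinction`` is wavelength x {HbO, HbR} in cm^-1 * uM^-1 (i.e. values
    of order 1e-3); defaults are standard tabulated molar extinction
    coefficients at 780/850 nm. ``dpf`` is the differential pathlength
    factor per wavelength and ``distance`` the source-detector separation
    in cm.
    """

    wavelengths: tuple[float, float] = (780.0, 850.0)
    extinction: tuple[tuple[float, float], tuple[float, float]] = (
        (735.0e-6, 1104.0e-6),   # 780 nm: (eps_HbO, eps_HbR)
        (1058.0e-6, 691.0e-6),   # 850 nm
    )
    dpf: tuple[float, float] = (6.0, 6.0)
    distance: float = 3.0

    def __post_init__(self) -> None:
        E = np.asarray(self.extinction, dtype=float)
        if E.shape != (2, 2) or abs(np.linalg.det(E)) < 1e-18:
            raise ValueError("extinction matrix must be 2x2 and invertible")
        if min(self.dpf) <= 0 or self.distance <= 0:
            raise ValueError("dpf and distance must be positive")

    @property
    def extinction_matrix(self) -> np.ndarray:
        return np.asarray(self.extinction, dtype=float)


class QCError(RuntimeError):
    """Raised when quality control leaves no usable channels."""


def intensity_to_od(
    intensity: np.ndarray,
    baseline: str = "temporal_mean",
    mask: np.ndarray | None = None,
    i0: float | np.ndarray | None = None,
) -> np.ndarray:
    """Convert light intensity to optical-density change.

    dOD = -log10(I / I0) per channel, with I0 the per-channel temporal mean
    (or first sample, or an explicit reference via ``i0``). Masked samples
    are ignored when forming I0 and pass through (the mask itself
    propagates separately).
    """
    I = np.asarray(intensity, dtype=float)
    if mask is None:
        mask = np.ones(I.shape, dtype=bool)
    bad = (I <= 0) & mask
    if bad.any():
        ch, s = np.argwhere(bad)[0]
        raise ValueError(f"non-positive intensity at channel {ch}, sample {s}")
    if i0 is not None:
        pass
    elif baseline == "temporal_mean":
        masked = np.where(mask, I, np.nan)
        i0 = np.nanmean(masked, axis=-1, keepdims=True)
    elif baseline == "first_sample":
        i0 = I[..., :1]
    else:
        raise ValueError(f"unknown baseline {baseline!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        od = -np.log10(I / i0)
    return od


def mbll(
    od_lambda1: np.ndarray,
    od_lambda2: np.ndarray,
    params: MBLLParams = MBLLParams(),
) -> tuple[np.ndarray, np.ndarray]:
    """Invert the modified Beer-Lambert law.

    Solves, per channel and sample, the 2x2 system
    ``dOD_lambda / (d * DPF_lambda) = E @ [dHbO, dHbR]`` and returns the
    concentration changes in uM.
    """
    od1 = np.asarray(od_lambda1, dtype=float)
    od2 = np.asarray(od_lambda2, dtype=float)
    if od1.shape != od2.shape:
        raise ValueError("wavelength OD matrices must share a shape")
    E = params.extinction_matrix
    scale = params.distance * np.asarray(params.dpf, dtype=float)
    rhs = np.stack([od1 / scale[0], od2 / scale[1]], axis=-1)[..., None]
    conc = np.linalg.solve(E[None, None, :, :], rhs)[..., 0]
    return conc[..., 0], conc[..., 1]


def mbll_forward(
    hbo: np.ndarray, hbr: np.ndarray, params: MBLLParams = MBLLParams()
) -> tuple[np.ndarray, np.ndarray]:
    """Forward MBLL: concentrations (uM) -> per-wavelength OD changes."""
    E = params.extinction_matrix
    scale = params.distance * np.asarray(params.dpf, dtype=float)
    od1 = (E[0, 0] * hbo + E[0, 1] * hbr) * scale[0]
    od2 = (E[1, 0] * hbo + E[1, 1] * hbr) * scale[1]
    return od1, od2


def _moving_std(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving standard deviation along the last axis."""
    from scipy.ndimage import uniform_filter1d

    win = max(int(win), 2)
    m = uniform_filter1d(x, win, axis=-1, mode="nearest")
    m2 = uniform_filter1d(x**2, win, axis=-1, mode="nearest")
    return np.sqrt(np.maximum(m2 - m**2, 0.0))


def motion_mask_and_qc(
    session: RecordingSession,
    window_s: float = 2.0,
    z_thresh: float = 3.0,
    exclude_frac: float = 0.10,
) -> RecordingSession:
    """Mask motion-contaminated samples and exclude bad channels.

    The motion index is a moving standard deviation per channel; samples
    whose index exceeds ``z_thresh`` robust z-scores above the channel
    median are masked. Channels whose masked fraction exceeds
    ``exclude_frac`` (default 10% of the recording) are added to
    ``excluded_channels``. Masked spans are linearly interpolated so the
    subsequent band-pass filter sees finite data.
    """
    win = int(round(window_s * session.fs))
    idx = _moving_std(session.data, win)
    med = np.median(idx, axis=-1, keepdims=True)
    mad = np.median(np.abs(idx - med), axis=-1, keepdims=True)
    robust_sd = 1.4826 * mad
    robust_sd = np.where(robust_sd <= 0, np.std(idx, axis=-1, keepdims=True) + 1e-12, robust_sd)
    z = (idx - med) / robust_sd
    motion = z > z_thresh

    new_mask = session.qc_mask & ~motion
    masked_frac = 1.0 - new_mask.mean(axis=-1)
    excluded = set(session.excluded_channels)
    excluded.update(np.nonzero(masked_frac > exclude_frac)[0].tolist())
    if len(excluded) >= session.n_channels:
        raise QCError("quality control excluded every channel")

    data = session.data.copy()
    t = np.arange(session.n_samples)
    for c in range(session.n_channels):
        bad = ~new_mask[c]
        if bad.any() and not bad.all():
            data[c, bad] = np.interp(t[bad], t[~bad], data[c, ~bad])
        elif bad.all():
            data[c] = 0.0
    return session.copy_with(data=data, qc_mask=new_mask, excluded_channels=excluded)


def bandpass(
    session: RecordingSession,
    band: tuple[float, float] = (0.0018, 0.15),
    order: int = 4,
) -> RecordingSession:
    """Zero-phase Butterworth band-pass of every channel.

    A 4th-order Butterworth is applied forward-backward (``filtfilt``), so
    the magnitude response is squared (effective order 8) and the phase is
    zero, preserving temporal alignment of complexity windows across
    channels.
    """
    low, high = band
    nyq = session.fs / 2.0
    if high >= nyq:
        raise ValueError(f"band high {high} Hz >= Nyquist {nyq} Hz")
    sos = sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")
    data = sps.sosfiltfilt(sos, session.data, axis=-1)
    return session.copy_with(data=data)


def preprocess_intensity_pair(
    session: RecordingSession,
    params: MBLLParams = MBLLParams(),
    band: tuple[float, float] = (0.0018, 0.15),
) -> tuple[RecordingSession, RecordingSession]:
    """Full chain for a dual-wavelength intensity session.

    The intensity matrix must interleave wavelengths as two blocks of
    ``n_channels`` rows (lambda1 block then lambda2 block). Returns
    band-passed HbO and HbR sessions.
    """
    n = session.n_channels // 2
    od = intensity_to_od(session.data, mask=session.qc_mask)
    hbo, hbr = mbll(od[:n], od[n:], params)
    labels = session.channel_labels[:n]
    out = []
    for chrom, mat in ((Chromophore.HBO, hbo), (Chromophore.HBR, hbr)):
        s = RecordingSession(
            subject_id=session.subject_id,
            group=session.group,
            chromophore=chrom,
            data=mat,
            fs=session.fs,
            channel_labels=labels,
            qc_mask=session.qc_mask[:n] & session.qc_mask[n:],
        )
        s = motion_mask_and_qc(s)
        out.append(bandpass(s, band=band))
    return out[0], out[1]
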