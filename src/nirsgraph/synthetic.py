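"""Synthetic three-group fNIRS cohorts with planted complexity coupling.

Real clinical recordings of this kind are not publicly distributable, so
the generator emulates their analysis-relevant structure: 48 prefrontal
channels sampled at 8.138 Hz for ~250 s, three diagnostic groups (HC,
MCI, AD), and — crucially — *complexity co-fluctuation* planted inside
designated channel modules with group-dependent coupling strength.

Each channel's signal is a time-varying mixture

    s_c(t) = (1 - lam_c(t)) * pink_c(t) + lam_c(t) * osc_c(t) + noise

where ``lam_c(t)`` in [0, 1] is a smooth latent "regularity" process: when
it is high the channel is dominated by a narrow-band oscillation (low
complexity), when low by 1/f noise (high complexity). Channels inside a
planted module combine a shared latent with a private one,

    lam_c = squash(c * z_module + sqrt(1 - c^2) * z_private),

with ``c`` the subject's coupling strength. The variance-preserving
combination keeps each channel's marginal complexity distribution
independent of ``c``, so group information lives only in the *coupling*
(i.e. the graph), not in node-feature marginals. Because every channel
draws its own pink-noise and oscillation realizations, raw amplitude
correlations stay near zero: RAW_FC graphs are uninformative while
COMPLEXITY_FC graphs carry the planted structure.

Group couplings default to HC 0.9, MCI 0.4, and per-subject AD couplings
drawn uniformly from [0.1, 0.9] — mirroring strong coordination in
healthy aging, attenuated coordination in MCI, and heterogeneous
reorganization across AD individuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .config import Chromophore, Group, substream
from .preprocess import MBLLParams, mbll_forward
from .session import RecordingSession, default_channel_labels

DEFAULT_MODULES: tuple[tuple[int, ...], ...] = (
    tuple(range(0, 8)),
    tuple(range(16, 24)),
    tuple(range(32, 40)),
)


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort. Defaults match the study conditions."""

    n_per_group: dict = field(
        default_factory=lambda: {Group.HC: 20, Group.MCI: 20, Group.AD: 20}
    )
    n_channels: int = 48
    n_samples: int = 2033
    fs: float = 8.138
    planted_modules: tuple[tuple[int, ...], ...] = DEFAULT_MODULES
    coupling_strength: dict = field(
        default_factory=lambda: {Group.HC: 0.9, Group.MCI: 0.4}
    )
    ad_coupling_range: tuple[float, float] = (0.1, 0.9)
    latent_smoothness_s: float = 20.0
    osc_band: tuple[float, float] = (0.04, 0.10)
    osc_bw: float = 0.003
    noise_sd: float = 0.1
    hbr_gain: float = -0.6
    hbr_noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for mod in self.planted_modules:
            for ch in mod:
                if not 0 <= ch < self.n_channels:
                    raise ValueError(f"module channel {ch} >= n_channels {self.n_channels}")
                if ch in seen:
                    raise ValueError("planted modules must be disjoint")
                seen.add(ch)
        for g, c in self.coupling_strength.items():
            if not 0 <= c <= 1:
                raise ValueError(f"coupling for {g} outside [0, 1]")


@dataclass
class PlantedTruth:
    """Ground truth: within-module edges and each subject's coupling."""

    edge_list: set[tuple[int, int]]
    per_subject_coupling: dict


def planted_truth(spec: CohortSpec) -> set[tuple[int, int]]:
    """All unordered within-module channel pairs."""
    edges: set[tuple[int, int]] = set()
    for mod in spec.planted_modules:
        mod = sorted(mod)
        for i, a in enumerate(mod):
            for b in mod[i + 1 :]:
                edges.add((a, b))
    return edges


def _smooth_unit_latent(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    """Standardized Gaussian-smoothed random walk (zero mean, unit variance)."""
    z = gaussian_filter1d(np.cumsum(rng.standard_normal(n)), sigma, mode="nearest")
    z = z - z.mean()
    sd = z.std()
    return z / sd if sd > 0 else z


def _pink_noise(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """1/f-amplitude noise, unit variance per row, via spectral shaping."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = spec / np.sqrt(f)
    x = np.fft.irfft(spec, n=n, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    return x / x.std(axis=-1, keepdims=True)


def _narrowband_osc(
    rng: np.random.Generator, n: int, fs: float, f0: float, bw: float
) -> np.ndarray:
    """Narrow-band Gaussian noise centered at f0, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.exp(-0.5 * ((f - f0) / bw) ** 2)
    x = np.fft.irfft(spec * gain, n=n)
    x = x - x.mean()
    sd = x.std()
    return x / (sd if sd > 0 else 1.0)


#: bit-reversed slot order: consecutive channels get maximally separated
#: oscillator frequencies, so channels inside one (contiguous) planted
#: module never share a spectral line and their raw signals decorrelate
_SLOT_ORDER = (0, 4, 2, 6, 1, 5, 3, 7)


def _channel_osc_freq(ch: int, band: tuple[float, float]) -> float:
    lo, hi = band
    n_slots = len(_SLOT_ORDER)
    slot = _SLOT_ORDER[ch % n_slots]
    return lo + (hi - lo) * (slot + 0.5) / n_slots


def _squash(z: np.ndarray) -> np.ndarray:
    """Map a standardized latent into (0, 1), centered at 0.5.

    The gain of 3 makes the regularity process spend most of its time
    near one of the two regimes (noise-dominated vs oscillation-
    dominated), so window complexity swings over most of its dynamic
    range and co-fluctuation is resolvable above estimator noise.
    """
    return 1.0 / (1.0 + np.exp(-3.0 * z))


def _subject_coupling(spec: CohortSpec, group: Group, rng: np.random.Generator) -> float:
    if group in spec.coupling_strength:
        return float(spec.coupling_strength[group])
    lo, hi = spec.ad_coupling_range
    return float(rng.uniform(lo, hi))


def generate_subject(
    spec: CohortSpec, subject_id: str, group: Group, rng: np.random.Generator
) -> tuple[RecordingSession, RecordingSession, float]:
    """One subject's paired HbO/HbR sessions plus the coupling used."""
    C, T = spec.n_channels, spec.n_samples
    sigma = spec.latent_smoothness_s * spec.fs
    coupling = _subject_coupling(spec, group, rng)

    module_of = {}
    for m, mod in enumerate(spec.planted_modules):
        for ch in mod:
            module_of[ch] = m
    z_mod = np.stack(
        [_smooth_unit_latent(rng, T, sigma) for _ in spec.planted_modules]
    ) if spec.planted_modules else np.zeros((0, T))

    lam = np.empty((C, T))
    for ch in range(C):
        z_own = _smooth_unit_latent(rng, T, sigma)
        if ch in module_of:
            c = coupling
            # mixture with within-module latent correlation c, re-standardized
            # exactly so every channel's regularity path has identical first
            # and second moments whatever the coupling — group information
            # lives in the *coupling* (the graph), not in per-channel marginals
            z = np.sqrt(c) * z_mod[module_of[ch]] + np.sqrt(1.0 - c) * z_own
            z = (z - z.mean()) / z.std()
        else:
            z = z_own
        lam[ch] = _squash(z)

    pink = _pink_noise(rng, (C, T))
    # per-channel oscillator frequencies (separated within any module) so
    # raw amplitude correlations stay near zero even when regularity
    # latents are shared — coupling lives in complexity space only
    osc = np.stack(
        [
            _narrowband_osc(
                rng, T, spec.fs, _channel_osc_freq(ch, spec.osc_band), spec.osc_bw
            )
            for ch in range(C)
        ]
    )
    hbo = (1.0 - lam) * pink + lam * osc + spec.noise_sd * rng.standard_normal((C, T))
    hbr = spec.hbr_gain * hbo + spec.hbr_noise_sd * rng.standard_normal((C, T))

    labels = default_channel_labels(C)
    common = dict(subject_id=subject_id, group=group, fs=spec.fs, channel_labels=labels)
    s_hbo = RecordingSession(chromophore=Chromophore.HBO, data=hbo, **common)
    s_hbr = RecordingSession(chromophore=Chromophore.HBR, data=hbr, **common)
    return s_hbo, s_hbr, coupling


def generate_cohort(spec: CohortSpec) -> tuple[list[RecordingSession], PlantedTruth]:
    """Generate the full cohort (HbO and HbR session per subject).

    Returns the sessions in subject order (HbO then HbR for each subject)
    and the planted ground truth. Deterministic given ``spec.seed``.
    """
    rng = substream(spec.seed, "cohort")
    sessions: list[RecordingSession] = []
    per_subject: dict[str, float] = {}
    for group in (Group.HC, Group.MCI, Group.AD):
        n = spec.n_per_group.get(group, 0)
        for i in range(n):
            sid = f"{group.value}{i + 1:03d}"
            s_hbo, s_hbr, c = generate_subject(spec, sid, group, rng)
            sessions.extend([s_hbo, s_hbr])
            per_subject[sid] = c
    return sessions, PlantedTruth(edge_list=planted_truth(spec), per_subject_coupling=per_subject)


def generate_intensity(
    hbo: RecordingSession,
    hbr: RecordingSession,
    params: MBLLParams = MBLLParams(),
    baseline_intensity: float = 1.0,
) -> RecordingSession:
    """Forward optical model: concentrations -> dual-wavelength intensity.

    Emits a 2*n_channels x n_samples intensity matrix (lambda1 block then
    lambda2 block) such that OD conversion followed by MBLL inversion
    recovers the input concentration changes.
    """
    if hbo.data.shape != hbr.data.shape:
        raise ValueError("HbO/HbR sessions must share a shape")
    od1, od2 = mbll_forward(hbo.data, hbr.data, params)
    i1 = baseline_intensity * 10.0 ** (-od1)
    i2 = baseline_intensity * 10.0 ** (-od2)
    labels = [f"{lab}@{int(w)}" for w in params.wavelengths for lab in hbo.channel_labels]
    return RecordingSession(
        subject_id=hbo.subject_id,
        group=hbo.group,
        chromophore=Chromophore.INTENSITY,
        data=np.vstack([i1, i2]),
        fs=hbo.fs,
        channel_labels=labels,
        wavelengths=params.wavelengths,
    )
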