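"""The in-memory recording container shared by every pipeline stage."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import Chromophore, Group


@dataclass
class RecordingSession:
    """One subject's multichannel recording.

    ``data`` is channels x samples, in micromolar for hemoglobin signals or
    arbitrary units for raw intensity. ``qc_mask`` marks usable samples
    (True = usable); ``excluded_channels`` are channels dropped by QC and
    carried forward so that downstream stages can skip them while keeping
    channel indexing stable.
    """

    subject_id: str
    group: Group
    chromophore: Chromophore
    data: np.ndarray
    fs: float
    channel_labels: list[str]
    qc_mask: np.ndarray | None = None
    excluded_channels: set[int] = field(default_factory=set)
    wavelengths: tuple[float, float] | None = None  # intensity sessions only

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] == 0:
            raise ValueError("data must be a non-empty channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )
        if self.qc_mask is None:
            self.qc_mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.qc_mask = np.asarray(self.qc_mask, dtype=bool)
            if self.qc_mask.shape != self.data.shape:
                raise ValueError("qc_mask shape must equal data shape")
        bad = {c for c in self.excluded_channels if not 0 <= c < self.n_channels}
        if bad:
            raise ValueError(f"excluded channel indices out of range: {sorted(bad)}")
        if not np.isfinite(self.data[self.qc_mask]).all():
            raise ValueError("non-finite values outside masked spans")
        self.group = Group(self.group)
        self.chromophore = Chromophore(self.chromophore)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def usable_channels(self) -> list[int]:
        return [c for c in range(self.n_channels) if c not in self.excluded_channels]

    def copy_with(self, **kw) -> "RecordingSession":
        base = dict(
            subject_id=self.subject_id,
            group=self.group,
            chromophore=self.chromophore,
            data=self.data.copy(),
            fs=self.fs,
            channel_labels=list(self.channel_labels),
            qc_mask=self.qc_mask.copy(),
            excluded_channels=set(self.excluded_channels),
            wavelengths=self.wavelengths,
        )
        base.update(kw)
        return RecordingSession(**base)


def default_channel_labels(n: int) -> list[str]:
    """1-based channel labels ("Ch1".."ChN") matching montage numbering."""
    return [f"Ch{i + 1}" for i in range(n)]
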