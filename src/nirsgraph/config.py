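"""Run configuration and deterministic random-stream management.

All randomness in a pipeline run flows from a single integer seed through
named substreams, so two runs with the same :class:`RunConfig` are
bit-identical regardless of the order in which stages execute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class Group(str, Enum):
    HC = "HC"
    MCI = "MCI"
    AD = "AD"


class Chromophore(str, Enum):
    HBO = "HBO"
    HBR = "HBR"
    INTENSITY = "INTENSITY"


class EdgeType(str, Enum):
    RAW_FC = "RAW_FC"
    COMPLEXITY_FC = "COMPLEXITY_FC"


class ChromophoreMode(str, Enum):
    HBO = "HBO"
    HBR = "HBR"
    BOTH = "BOTH"


class ModelArch(str, Enum):
    GCN = "GCN"
    GAT = "GAT"
    STGNN = "STGNN"


GROUPS = (Group.HC, Group.MCI, Group.AD)

#: Canonical feature-set catalogue: MS is always present; complexity blocks
#: are added incrementally (FS0 = summary stats only, FS7 = all three metrics).
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "FS0": ("MS",),
    "FS1": ("MS", "SE"),
    "FS2": ("MS", "HFD"),
    "FS3": ("MS", "WE"),
    "FS4": ("MS", "SE", "HFD"),
    "FS5": ("MS", "SE", "WE"),
    "FS6": ("MS", "HFD", "WE"),
    "FS7": ("MS", "SE", "HFD", "WE"),
}


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    Defaults follow the analysis protocol: 8.138 Hz sampling, 30 s windows
    with a 1 s step, a 0.0018-0.15 Hz band, an absolute correlation
    threshold of 0.3, 5-fold cross-validation, top-10% edge deletion with
    1000 random-deletion null draws, a 0.6 consensus proportion and 5000
    label permutations.
    """

    fs: float = 8.138
    window_s: float = 30.0
    step_s: float = 1.0
    band: tuple[float, float] = (0.0018, 0.15)
    r_threshold: float = 0.3
    feature_set: str = "FS4"
    edge_type: EdgeType = EdgeType.COMPLEXITY_FC
    chromophore_mode: ChromophoreMode = ChromophoreMode.HBO
    model: ModelArch = ModelArch.GAT
    k_folds: int = 5
    seed: int = 0
    top_k_fraction: float = 0.10
    n_random_deletions: int = 1000
    consensus_rho: float = 0.6
    n_permutations: int = 5000

    def __post_init__(self) -> None:
        if self.window_s * self.fs < 2:
            raise ValueError("window must span at least 2 samples")
        if not 0 < self.r_threshold < 1:
            raise ValueError("r_threshold must lie in (0, 1)")
        if not 0 < self.consensus_rho <= 1:
            raise ValueError("consensus_rho must lie in (0, 1]")
        if not 0 < self.top_k_fraction < 1:
            raise ValueError("top_k_fraction must lie in (0, 1)")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        for k, v in d.items():
            if isinstance(v, Enum):
                d[k] = v.value
        return d

    def config_hash(self) -> str:
        """Stable hash of the configuration (used in output manifests)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def rng(self, name: str) -> np.random.Generator:
        return substream(self.seed, name)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from a base seed.

    The stream identity is ``(seed, crc32(name))`` so streams for distinct
    stage names ("folds", "model_init", "permutations", ...) never collide
    and never depend on call order.
    """
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2^31) derived from a named substream."""
    return int(substream(seed, name).integers(0, 2**31 - 1))
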