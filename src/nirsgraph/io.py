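"""On-disk formats: CSV + JSON sidecar sessions, a minimal SNIRF subset,
and the graph bundle (arrays + JSON manifest).

CSV sessions are channels-as-rows with a leading ``channel`` label column
(header ``channel,s0,s1,...``) and a ``<stem>.meta.json`` sidecar holding
sampling rate, chromophore, group and QC state — diff-able and
fixture-friendly. SNIRF support reads/writes the small subset of the
HDF5 layout this pipeline needs (one data block, time vector, per-channel
measurement lists, metadata tags) for interoperability; it is not a full
implementation of the format.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import Chromophore, Group, RunConfig
from .graphs import SubjectGraph
from .session import RecordingSession


class FormatError(ValueError):
    """Malformed or inconsistent on-disk data."""


# ---------------------------------------------------------------------------
# CSV + sidecar


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_session_csv(session: RecordingSession, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        session.data,
        index=pd.Index(session.channel_labels, name="channel"),
        columns=[f"s{i}" for i in range(session.n_samples)],
    )
    df.to_csv(path, float_format="%.10g")
    meta = {
        "subject_id": session.subject_id,
        "group": session.group.value,
        "chromophore": session.chromophore.value,
        "fs": session.fs,
        "excluded_channels": sorted(session.excluded_channels),
        "masked_spans": _mask_to_spans(session.qc_mask),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def read_session_csv(path: str | Path) -> RecordingSession:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("fs", "group", "chromophore"):
        if key not in meta:
            raise FormatError(f"sidecar lacks required key {key!r}")
    df = pd.read_csv(path, index_col="channel")
    data = df.to_numpy(dtype=float)
    mask = _spans_to_mask(meta.get("masked_spans", []), data.shape)
    return RecordingSession(
        subject_id=meta.get("subject_id", path.stem),
        group=Group(meta["group"]),
        chromophore=Chromophore(meta["chromophore"]),
        data=data,
        fs=float(meta["fs"]),
        channel_labels=[str(c) for c in df.index],
        qc_mask=mask,
        excluded_channels=set(meta.get("excluded_channels", [])),
    )


def _mask_to_spans(mask: np.ndarray) -> list[list[int]]:
    """Masked (unusable) spans as [channel, start, stop) triples."""
    spans = []
    for c in range(mask.shape[0]):
        bad = ~mask[c]
        if not bad.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], bad.view(np.int8), [0]])))
        for lo, hi in zip(edges[::2], edges[1::2]):
            spans.append([int(c), int(lo), int(hi)])
    return spans


def _spans_to_mask(spans: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    mask = np.ones(shape, dtype=bool)
    for c, lo, hi in spans:
        mask[c, lo:hi] = False
    return mask


# ---------------------------------------------------------------------------
# minimal SNIRF subset

_DATATYPE_LABEL = {Chromophore.HBO: "HbO", Chromophore.HBR: "HbR"}


def write_session_snirf(session: RecordingSession, path: str | Path) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=session.subject_id)
        meta.create_dataset("Group", data=session.group.value)
        meta.create_dataset("LengthUnit", data="cm")
        meta.create_dataset("TimeUnit", data="s")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=session.data.T)   # time x channel
        data.create_dataset("time", data=np.arange(session.n_samples) / session.fs)
        for i, label in enumerate(session.channel_labels):
            ml = data.create_group(f"measurementList{i + 1}")
            ml.create_dataset("sourceIndex", data=i + 1)
            ml.create_dataset("detectorIndex", data=i + 1)
            if session.chromophore == Chromophore.INTENSITY:
                ml.create_dataset("dataType", data=1)
            else:
                ml.create_dataset("dataType", data=99999)
                ml.create_dataset(
                    "dataTypeLabel", data=_DATATYPE_LABEL[session.chromophore]
                )
            ml.create_dataset("channelLabel", data=label)
    return path


def read_session_snirf(path: str | Path) -> RecordingSession:
    path = Path(path)
    with h5py.File(path, "r") as f:
        data_grp = f["nirs"]["data1"]
        ts = np.asarray(data_grp["dataTimeSeries"]).T
        time = np.asarray(data_grp["time"])
        if time.size < 2:
            raise FormatError("SNIRF time vector too short to infer sampling rate")
        fs = 1.0 / float(np.median(np.diff(time)))
        labels, chrom = [], Chromophore.INTENSITY
        for i in range(ts.shape[0]):
            ml = data_grp[f"measurementList{i + 1}"]
            if "channelLabel" in ml:
                labels.append(ml["channelLabel"][()].decode())
            else:
                labels.append(f"Ch{i + 1}")
            if int(ml["dataType"][()]) == 99999:
                lab = ml["dataTypeLabel"][()].decode()
                chrom = Chromophore.HBO if lab == "HbO" else Chromophore.HBR
        meta = f["nirs"]["metaDataTags"]
        sid = meta["SubjectID"][()].decode() if "SubjectID" in meta else path.stem
        group = meta["Group"][()].decode() if "Group" in meta else "HC"
    if len(labels) != ts.shape[0]:
        raise FormatError("channel label count does not match data rows")
    return RecordingSession(
        subject_id=sid, group=Group(group), chromophore=chrom,
        data=ts, fs=fs, channel_labels=labels,
    )


def read_session(path: str | Path, format: str | None = None) -> RecordingSession:
    """Dispatch on format ("SNIRF" or "CSV"); inferred from suffix if None."""
    path = Path(path)
    if format is None:
        format = "SNIRF" if path.suffix.lower() == ".snirf" else "CSV"
    if format.upper() == "SNIRF":
        return read_session_snirf(path)
    return read_session_csv(path)


# ---------------------------------------------------------------------------
# graph bundle


def write_graph_bundle(
    graphs: list[SubjectGraph], path: str | Path, config: RunConfig
) -> dict:
    """Serialize graphs (one NPZ per subject) plus a JSON manifest.

    The manifest records subject ids, groups, provenance and the config
    hash; identical configs (including seed) produce byte-identical
    manifests.
    """
    if not graphs:
        raise ValueError("no graphs to write")
    n_nodes = {g.n_nodes for g in graphs}
    fsets = {g.feature_set for g in graphs}
    if len(fsets) > 1:
        raise ValueError("graphs mix feature sets")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for g in graphs:
        fname = f"{g.subject_id}.npz"
        np.savez(
            path / fname,
            adjacency=g.adjacency,
            node_features=g.node_features,
            node_labels=np.array(g.node_labels),
        )
        entries.append(
            {
                "subject_id": g.subject_id,
                "group": g.group.value,
                "file": fname,
                "n_nodes": g.n_nodes,
                "edge_type": g.edge_type.value,
                "feature_set": g.feature_set,
                "chromophore_mode": g.chromophore_mode.value,
                "threshold": g.threshold,
            }
        )
    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "n_graphs": len(graphs),
        "graphs": entries,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def read_graph_bundle(path: str | Path) -> list[SubjectGraph]:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    graphs = []
    for entry in manifest["graphs"]:
        with np.load(path / entry["file"], allow_pickle=False) as z:
            graphs.append(
                SubjectGraph(
                    subject_id=entry["subject_id"],
                    group=Group(entry["group"]),
                    node_labels=[str(x) for x in z["node_labels"]],
                    adjacency=z["adjacency"],
                    node_features=z["node_features"],
                    edge_type=entry["edge_type"],
                    feature_set=entry["feature_set"],
                    chromophore_mode=entry["chromophore_mode"],
                    threshold=entry["threshold"],
                )
            )
    return graphs
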