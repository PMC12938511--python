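"""Subject-level graph construction.

Two edge definitions are supported on the same node set (fNIRS channels):

* RAW_FC — Pearson correlation of the full-length band-passed hemoglobin
  time series (conventional amplitude coupling);
* COMPLEXITY_FC — Pearson correlation between channels' sliding-window
  complexity trajectories (co-fluctuation of dynamical state), averaged
  elementwise over the HFD/SE/WE metric matrices.

Correlation matrices are thresholded at a fixed absolute value
(|r| >= 0.3 by default) keeping the sign; node features are mean/SD
summaries of the window-mean signal (MS block) and of each requested
complexity trajectory, per chromophore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .complexity import METRICS, ComplexityTrajectory, make_windows
from .config import ChromophoreMode, EdgeType, FEATURE_SETS, Group, RunConfig
from .session import RecordingSession


@dataclass
class SubjectGraph:
    """Weighted undirected graph for one subject.

    ``adjacency`` holds signed correlation weights (zero below threshold,
    zero diagonal); ``node_labels`` carries channel identity so graphs
    with different QC-excluded channels remain comparable across subjects.
    """

    subject_id: str
    group: Group
    node_labels: list[str]
    adjacency: np.ndarray
    node_features: np.ndarray
    edge_type: EdgeType
    feature_set: str
    chromophore_mode: ChromophoreMode
    threshold: float

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.shape[0] != A.shape[1] or not np.allclose(A, A.T, equal_nan=True):
            raise ValueError("adjacency must be square and symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("adjacency diagonal must be zero")
        self.adjacency = A
        self.group = Group(self.group)
        self.edge_type = EdgeType(self.edge_type)
        self.chromophore_mode = ChromophoreMode(self.chromophore_mode)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edge_set(self) -> set[tuple[str, str]]:
        """Unordered node-label pairs with a nonzero weight."""
        edges = set()
        idx = np.argwhere(np.triu(self.adjacency, k=1) != 0)
        for i, j in idx:
            a, b = self.node_labels[i], self.node_labels[j]
            edges.add((a, b) if a <= b else (b, a))
        return edges


def _corrcoef_nan_guard(x: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation; zero-variance rows become NaN rows."""
    sd = x.std(axis=-1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance channel(s): correlation set to NaN",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r[degenerate, :] = np.nan
    r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)


def raw_fc(session: RecordingSession) -> np.ndarray:
    """Amplitude-based connectivity: correlation of full-length signals.

    Returned over *usable* channels only, in channel order.
    """
    usable = session.usable_channels
    if len(usable) < 2:
        raise ValueError("need at least 2 usable channels")
    return _corrcoef_nan_guard(session.data[usable])


def complexity_fc(
    traj: ComplexityTrajectory,
    metrics: tuple[str, ...] = METRICS,
    combine: str = "mean",
) -> np.ndarray | dict[str, np.ndarray]:
    """Complexity-fluctuation coupling between channels.

    For each metric, the Pearson correlation between channels' window-wise
    trajectories; ``combine="mean"`` averages the per-metric matrices
    elementwise (default), ``"per_metric"`` returns them keyed by metric.
    Computed over channels not excluded by QC.
    """
    if traj.window_plan.n_windows < 10:
        raise ValueError("need at least 10 windows for complexity coupling")
    usable = [c for c in range(traj.values.shape[1]) if c not in traj.excluded_channels]
    if len(usable) < 2:
        raise ValueError("need at least 2 usable channels")
    mats = {}
    for m in metrics:
        series = traj.metric(m)[:, usable].T  # [channels, windows]
        mats[m] = _corrcoef_nan_guard(series)
    if combine == "per_metric":
        return mats
    if combine == "mean":
        return np.mean([mats[m] for m in metrics], axis=0)
    raise ValueError(f"unknown combine rule {combine!r}")


def threshold_graph(corr: np.ndarray, r_abs: float) -> np.ndarray:
    """Zero out sub-threshold entries (sign kept) and the diagonal."""
    if not 0 < r_abs < 1:
        raise ValueError("threshold must lie in (0, 1)")
    A = np.asarray(corr, dtype=float).copy()
    A[np.isnan(A)] = 0.0
    A[np.abs(A) < r_abs] = 0.0
    np.fill_diagonal(A, 0.0)
    return A


def _window_mean_signal(session: RecordingSession, config: RunConfig) -> np.ndarray:
    """Window-mean signal per channel: [n_windows, n_channels]."""
    plan = make_windows(session.n_samples, session.fs, config.window_s, config.step_s)
    wins = sliding_window_view(session.data, plan.win_len, axis=-1)[:, :: plan.step, :]
    return wins[:, : plan.n_windows, :].mean(axis=-1).T


def slice_trajectory(traj: ComplexityTrajectory, sl: slice) -> ComplexityTrajectory:
    """Restrict a trajectory to a contiguous window range (for snapshots)."""
    values = traj.values[sl]
    plan = traj.window_plan
    starts = plan.start_indices[sl]
    from .complexity import WindowPlan

    new_plan = WindowPlan(
        win_len=plan.win_len, step=plan.step, n_windows=values.shape[0],
        start_indices=tuple(starts),
    )
    return ComplexityTrajectory(
        values=values, window_plan=new_plan,
        channel_labels=traj.channel_labels,
        excluded_channels=set(traj.excluded_channels),
    )


def node_features(
    session: RecordingSession,
    traj: ComplexityTrajectory,
    feature_set: str,
    config: RunConfig,
    channels: list[int] | None = None,
    window_slice: slice = slice(None),
) -> np.ndarray:
    """Per-channel feature matrix for one chromophore.

    Block order follows the feature-set definition: the MS block is the
    mean and SD over windows of the window-mean signal; each complexity
    block is the mean and SD over windows of that metric's trajectory
    (2 values per block).
    """
    blocks = FEATURE_SETS[feature_set]
    if channels is None:
        channels = [c for c in range(session.n_channels) if c not in session.excluded_channels]
    cols = []
    for b in blocks:
        if b == "MS":
            series = _window_mean_signal(session, config)[window_slice][:, channels]
        else:
            if b not in METRICS:
                raise ValueError(f"metric {b} missing from trajectory")
            series = traj.metric(b)[window_slice][:, channels]
        cols.append(series.mean(axis=0))
        cols.append(series.std(axis=0))
    return np.stack(cols, axis=1)


def assemble_subject_graph(
    sessions: dict[ChromophoreMode, RecordingSession],
    trajs: dict[ChromophoreMode, ComplexityTrajectory],
    config: RunConfig,
    window_slice: slice = slice(None),
) -> SubjectGraph:
    """Compose connectivity, thresholding and node features into a graph.

    ``sessions``/``trajs`` are keyed by HBO/HBR; BOTH mode averages the
    HbO and HbR correlation matrices before thresholding and concatenates
    HbO-then-HbR feature blocks. ``window_slice`` restricts the analysis
    to a contiguous window range (used for temporal snapshots).
    """
    mode = config.chromophore_mode
    keys = (
        [ChromophoreMode.HBO, ChromophoreMode.HBR]
        if mode == ChromophoreMode.BOTH
        else [mode]
    )
    ref = sessions[keys[0]]
    excluded = set()
    for k in keys:
        excluded |= sessions[k].excluded_channels
    channels = [c for c in range(ref.n_channels) if c not in excluded]
    if len(channels) < 2:
        raise ValueError("fewer than 2 channels survived QC")

    corrs, feats = [], []
    for k in keys:
        sess = sessions[k].copy_with(excluded_channels=set(excluded))
        if config.edge_type == EdgeType.RAW_FC:
            plan = trajs[k].window_plan
            starts = plan.start_indices[window_slice]
            if len(starts) < plan.n_windows:
                sub = sess.copy_with(
                    data=sess.data[:, starts[0] : starts[-1] + plan.win_len],
                    qc_mask=sess.qc_mask[:, starts[0] : starts[-1] + plan.win_len],
                )
            else:
                sub = sess
            corrs.append(raw_fc(sub))
        else:
            tr = slice_trajectory(trajs[k], window_slice)
            tr.excluded_channels = set(excluded)
            corrs.append(complexity_fc(tr))
        feats.append(
            node_features(sess, trajs[k], config.feature_set, config, channels,
                          window_slice=window_slice)
        )
    corr = np.mean(corrs, axis=0)
    A = threshold_graph(corr, config.r_threshold)
    X = np.concatenate(feats, axis=1)
    return SubjectGraph(
        subject_id=ref.subject_id,
        group=ref.group,
        node_labels=[ref.channel_labels[c] for c in channels],
        adjacency=A,
        node_features=X,
        edge_type=config.edge_type,
        feature_set=config.feature_set,
        chromophore_mode=mode,
        threshold=config.r_threshold,
    )


def temporal_snapshots(
    sessions: dict[ChromophoreMode, RecordingSession],
    trajs: dict[ChromophoreMode, ComplexityTrajectory],
    config: RunConfig,
    T: int = 3,
) -> list[SubjectGraph]:
    """Split the window sequence into T contiguous segments and rebuild
    adjacency and node features per segment (input for the STGNN).

    224 windows at T = 3 give segments of 75/75/74 windows (earlier
    segments absorb the remainder, as in ``np.array_split``).
    """
    mode = config.chromophore_mode
    key = ChromophoreMode.HBO if mode == ChromophoreMode.BOTH else mode
    n_windows = trajs[key].window_plan.n_windows
    if n_windows < T * 10:
        raise ValueError(f"{n_windows} windows too few for {T} snapshots")
    bounds = [len(part) for part in np.array_split(np.arange(n_windows), T)]
    snaps, lo = [], 0
    for size in bounds:
        snaps.append(
            assemble_subject_graph(sessions, trajs, config,
                                   window_slice=slice(lo, lo + size))
        )
        lo += size
    return snaps
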