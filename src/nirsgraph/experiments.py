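"""End-to-end synthetic-cohort experiments.

These functions tie the full pipeline together on generated cohorts with
planted complexity coupling: graph construction under both edge
definitions, GNN cross-validation, attention-based edge recovery, the
perturbation sensitivity test and permutation-test calibration. They are
what the validation suite and the results-reproduction script run.

Problem sizes here (20 subjects per group, 5 replicate seeds, 200-draw
nulls) are the package's standard validation scale: large enough for the
planted effects to be resolvable, small enough to run on one CPU in
minutes.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold

from .config import (
    ChromophoreMode,
    EdgeType,
    Group,
    ModelArch,
    RunConfig,
    substream,
    substream_seed,
)
from .explain import EdgeImportanceMap, aggregate_importance, attention_importance, perturbation_test
from .graphs import SubjectGraph, assemble_subject_graph
from .complexity import trajectories
from .nn.models import ModelSpec
from .nn.training import batch_graphs, cross_validate, pooled_metrics
from .preprocess import bandpass, motion_mask_and_qc
from .stats import FoldEdgeSets, edge_support, label_permutation_test
from .synthetic import CohortSpec, PlantedTruth, generate_cohort


def preprocess_session(session, config: RunConfig):
    """Motion QC + band-pass, the standard chain for concentration data."""
    return bandpass(motion_mask_and_qc(session), band=config.band)


def build_cohort_graphs(
    spec: CohortSpec, config: RunConfig
) -> tuple[dict[EdgeType, list[SubjectGraph]], PlantedTruth]:
    """Generate a cohort and build RAW_FC and COMPLEXITY_FC graphs.

    Sessions are preprocessed once and complexity trajectories computed
    once per chromophore; both edge types share them.
    """
    sessions, truth = generate_cohort(spec)
    graphs: dict[EdgeType, list[SubjectGraph]] = {e: [] for e in EdgeType}
    need_hbr = config.chromophore_mode != ChromophoreMode.HBO
    for i in range(0, len(sessions), 2):
        hbo = preprocess_session(sessions[i], config)
        sess = {ChromophoreMode.HBO: hbo}
        trajs = {ChromophoreMode.HBO: trajectories(hbo, config)}
        if need_hbr:
            hbr = preprocess_session(sessions[i + 1], config)
            sess[ChromophoreMode.HBR] = hbr
            trajs[ChromophoreMode.HBR] = trajectories(hbr, config)
        for edge_type in EdgeType:
            graphs[edge_type].append(
                assemble_subject_graph(sess, trajs, config.replace(edge_type=edge_type))
            )
    return graphs, truth


def planted_edge_rank_test(
    importance: EdgeImportanceMap, truth: PlantedTruth, channel_labels: list[str]
) -> dict:
    """Do planted within-module edges outrank the rest by phi?

    Mann-Whitney rank-sum of phi for planted vs non-planted edges
    (one-sided: planted greater). ``channel_labels`` is the full original
    channel-label list, indexed by the planted channel indices.
    """
    planted_keys = set()
    for a, b in truth.edge_list:
        la, lb = channel_labels[a], channel_labels[b]
        planted_keys.add((la, lb) if la <= lb else (lb, la))
    phi_planted = [v for k, v in importance.phi.items() if k in planted_keys]
    phi_rest = [v for k, v in importance.phi.items() if k not in planted_keys]
    if not phi_planted or not phi_rest:
        raise ValueError("importance map misses planted or background edges")
    res = sstats.mannwhitneyu(phi_planted, phi_rest, alternative="greater")
    ranks = sstats.rankdata(list(importance.phi.values()))
    keys = list(importance.phi.keys())
    planted_mean_rank = float(
        np.mean([r for k, r in zip(keys, ranks) if k in planted_keys])
    )
    rest_mean_rank = float(
        np.mean([r for k, r in zip(keys, ranks) if k not in planted_keys])
    )
    return {
        "p": float(res.pvalue),
        "planted_mean_rank": planted_mean_rank,
        "background_mean_rank": rest_mean_rank,
        "n_planted_scored": len(phi_planted),
    }


def recovery_experiment(
    seed: int,
    n_per_group: int = 20,
    spec_model: ModelSpec | None = None,
    n_random_deletions: int = 200,
) -> dict:
    """One full recovery run on a planted cohort at a given seed.

    Trains the GAT under both edge definitions with 5-fold CV, extracts
    attention importance from the complexity-graph models, ranks planted
    edges, and runs the top-10% perturbation test.
    """
    spec_model = spec_model or ModelSpec(arch=ModelArch.GAT, epochs=120, patience=30)
    cohort = CohortSpec(
        n_per_group={Group.HC: n_per_group, Group.MCI: n_per_group, Group.AD: n_per_group},
        seed=substream_seed(seed, "cohort_seed"),
    )
    config = RunConfig(seed=seed)
    graphs, truth = build_cohort_graphs(cohort, config)

    results = {}
    fold_results = {}
    for edge_type in EdgeType:
        fr = cross_validate(graphs[edge_type], spec_model, k=config.k_folds, seed=seed)
        fold_results[edge_type] = fr
        results[edge_type.value] = {
            "macro_f1": pooled_metrics(fr)["macro_f1"],
            "fold_macro_f1": [r.macro_f1 for r in fr],
        }

    # attention importance from the complexity-graph models (held-out subjects)
    cplx = fold_results[EdgeType.COMPLEXITY_FC]
    per_fold_maps = {}
    subject_maps_all = []
    hc_maps = []
    for r in cplx:
        smaps, _ = attention_importance(r.model, r.test_batch, spec_model)
        subject_maps_all.extend(smaps)
        hc_maps.extend(m for m in smaps if m.provenance["label"] == 0)
        per_fold_maps[r.fold_id] = aggregate_importance(smaps)
    global_map = aggregate_importance(subject_maps_all)
    # rank recovery is evaluated where planted structure exists by design:
    # the strong-coupling (HC) group's mean attention map
    from .session import default_channel_labels

    channel_labels = default_channel_labels(cohort.n_channels)
    rank = planted_edge_rank_test(aggregate_importance(hc_maps), truth, channel_labels)
    rank_all_groups = planted_edge_rank_test(global_map, truth, channel_labels)

    perturb = perturbation_test(
        cplx, global_map, spec_model,
        top_frac=config.top_k_fraction,
        n_random=n_random_deletions,
        seed=seed,
    )
    return {
        "seed": seed,
        "edge_type_results": results,
        "complexity_macro_f1": results[EdgeType.COMPLEXITY_FC.value]["macro_f1"],
        "raw_macro_f1": results[EdgeType.RAW_FC.value]["macro_f1"],
        "planted_rank": rank,
        "planted_rank_all_groups": rank_all_groups,
        "perturbation": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                         for k, v in perturb.items() if k != "delta_random"},
        "per_fold_importance": per_fold_maps,
        "subject_importance": subject_maps_all,
        "truth": truth,
        "channel_labels": channel_labels,
    }


def run_recovery_suite(base_seed: int = 0, n_seeds: int = 5, **kw) -> dict:
    """Recovery experiments across replicate seeds, with summary statistics."""
    runs = [recovery_experiment(base_seed + i, **kw) for i in range(n_seeds)]
    gains = [r["complexity_macro_f1"] - r["raw_macro_f1"] for r in runs]
    return {
        "runs": runs,
        "mean_complexity_macro_f1": float(np.mean([r["complexity_macro_f1"] for r in runs])),
        "mean_raw_macro_f1": float(np.mean([r["raw_macro_f1"] for r in runs])),
        "mean_macro_f1_gain": float(np.mean(gains)),
        "perturbation_p": [r["perturbation"]["p_empirical"] for r in runs],
        "n_perturbation_significant": int(
            sum(r["perturbation"]["p_empirical"] < 0.05 for r in runs)
        ),
        "planted_rank_p": [r["planted_rank"]["p"] for r in runs],
    }


def determinism_run(seed: int, out_dir, n_per_group: int = 6) -> dict:
    """A compact full-pipeline run for reproducibility checks.

    Generates a small cohort, builds complexity graphs, writes a graph
    bundle, and cross-validates a GCN; returns the manifest bytes and the
    pooled metrics so two runs with the same seed can be compared
    byte-for-byte.
    """
    from pathlib import Path

    from .io import write_graph_bundle

    cohort = CohortSpec(
        n_per_group={Group.HC: n_per_group, Group.MCI: n_per_group, Group.AD: n_per_group},
        seed=substream_seed(seed, "determinism_cohort"),
    )
    config = RunConfig(seed=seed)
    graphs, _ = build_cohort_graphs(cohort, config)
    gs = graphs[EdgeType.COMPLEXITY_FC]
    out_dir = Path(out_dir)
    write_graph_bundle(gs, out_dir, config)
    spec_model = ModelSpec(arch=ModelArch.GCN, epochs=40, patience=40)
    from .nn.training import cross_validate, pooled_metrics

    results = cross_validate(gs, spec_model, k=3, seed=seed)
    pooled = pooled_metrics(results)
    return {
        "manifest_bytes": (out_dir / "manifest.json").read_bytes(),
        "macro_f1": pooled["macro_f1"],
        "per_class_recall": pooled["per_class_recall"],
        "confusion": pooled["confusion"].tolist(),
        "fold_predictions": [r.y_pred.tolist() for r in results],
    }


# ---------------------------------------------------------------------------
# permutation calibration


def discriminability_pipeline(k_folds: int = 5, top_fraction: float = 0.10):
    """A cheap fold-wise edge-ranking pipeline for permutation testing.

    Within each stratified fold's training subjects, edges are ranked by
    the one-way ANOVA F statistic of |edge weight| across groups, and the
    top fraction retained. Fast enough to rerun hundreds of times inside
    a label-permutation loop.
    """

    def pipeline(weights_and_edges, labels, seed) -> FoldEdgeSets:
        W, edge_keys = weights_and_edges      # W: subjects x edges
        labels = np.asarray(labels)
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=int(seed) % (2**31))
        sets = {}
        for fold_id, (tr, _) in enumerate(skf.split(W, labels)):
            Wt, lt = W[tr], labels[tr]
            groups = [Wt[lt == g] for g in np.unique(lt)]
            overall = Wt.mean(axis=0)
            n = Wt.shape[0]
            k = len(groups)
            ssb = sum(g.shape[0] * (g.mean(axis=0) - overall) ** 2 for g in groups)
            ssw = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
            with np.errstate(divide="ignore", invalid="ignore"):
                F = (ssb / (k - 1)) / np.where(ssw > 0, ssw / (n - k), np.inf)
            order = np.argsort(-F, kind="stable")
            top = order[: int(len(edge_keys) * top_fraction)]
            sets[fold_id] = frozenset(edge_keys[i] for i in top)
        return FoldEdgeSets(sets=sets)

    return pipeline


def edge_weight_matrix(graphs: list[SubjectGraph]) -> tuple[np.ndarray, list]:
    """Stack |adjacency| into subjects x edges over the union of channels.

    Graphs may have different QC-excluded channels; edges touching a
    channel absent from a subject's graph get weight 0 for that subject.
    """
    labels = sorted({lab for g in graphs for lab in g.node_labels})
    n = len(labels)
    pos = {lab: i for i, lab in enumerate(labels)}
    iu = np.triu_indices(n, k=1)
    keys = [tuple(sorted((labels[i], labels[j]))) for i, j in zip(*iu)]
    W = np.zeros((len(graphs), len(keys)))
    for s, g in enumerate(graphs):
        full = np.zeros((n, n))
        idx = np.array([pos[lab] for lab in g.node_labels])
        full[np.ix_(idx, idx)] = np.abs(g.adjacency)
        W[s] = full[iu]
    return W, keys


def permutation_calibration(
    seed: int = 0,
    n_per_group: int = 20,
    n_perm: int = 200,
    coupling: float = 0.6,
) -> dict:
    """Null calibration of the edge-support permutation test.

    All groups share one coupling strength, so diagnostic labels are
    independent of graph structure; under this null the fraction of edges
    with p_perm < 0.05 should sit near 5% before FDR and near zero after.
    """
    cohort = CohortSpec(
        n_per_group={Group.HC: n_per_group, Group.MCI: n_per_group, Group.AD: n_per_group},
        coupling_strength={Group.HC: coupling, Group.MCI: coupling},
        ad_coupling_range=(coupling, coupling),
        seed=substream_seed(seed, "null_cohort"),
    )
    config = RunConfig(seed=seed)
    graphs, _ = build_cohort_graphs(cohort, config)
    gs = graphs[EdgeType.COMPLEXITY_FC]
    W, keys = edge_weight_matrix(gs)
    labels = np.array([{"HC": 0, "MCI": 1, "AD": 2}[g.group.value] for g in gs])
    df = label_permutation_test(
        discriminability_pipeline(), (W, keys), labels, n_perm=n_perm, seed=seed,
    )
    return {
        "frac_p_below_05": float((df["p_perm"] < 0.05).mean()),
        "frac_significant_fdr": float(df["significant"].mean()),
        "n_edges": int(len(df)),
        "table": df,
    }
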