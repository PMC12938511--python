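"""Fold-wise stability, consensus networks and group statistics.

Covers: top-edge sets per cross-validation fold, pairwise Jaccard
stability, consensus networks at a fold-support proportion rho,
label-permutation testing of edge support, edge-wise group comparisons
(Welch / Mann-Whitney / Kruskal-Wallis with BH-FDR) and age-adjusted
ANCOVA for channel-level complexity features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .config import substream
from .explain import EdgeImportanceMap

EdgeKey = tuple[str, str]


@dataclass
class FoldEdgeSets:
    """Top-ranked edge set per cross-validation fold."""

    sets: dict[int, frozenset]
    top_rule: str = "top_fraction"

    @property
    def K(self) -> int:
        return len(self.sets)

    def all_edges(self) -> frozenset:
        out: set = set()
        for s in self.sets.values():
            out |= s
        return frozenset(out)


@dataclass
class ConsensusNetwork:
    """Edges whose fold-support ratio meets the consensus proportion."""

    support: dict[EdgeKey, float]          # all observed edges
    rho: float
    edges: dict[EdgeKey, float] = field(init=False)   # retained
    p_perm: dict[EdgeKey, float] | None = None
    fdr_flags: dict[EdgeKey, bool] | None = None

    def __post_init__(self) -> None:
        self.edges = {e: s for e, s in self.support.items() if s >= self.rho}


def fold_top_edges(
    importances: dict[int, EdgeImportanceMap],
    top_n: int | None = None,
    top_fraction: float | None = 0.10,
) -> FoldEdgeSets:
    """Rank each fold's edges by phi (descending, lexicographic ties) and
    truncate to ``top_n`` edges or the ``top_fraction`` of that fold's edges."""
    if len(importances) < 2:
        raise ValueError("need at least 2 folds")
    sets = {}
    for k, imp in importances.items():
        if top_n is not None:
            if top_n > len(imp.phi):
                warnings.warn(f"fold {k}: fewer edges than top_n, using all", stacklevel=2)
            sets[k] = frozenset(imp.top_edges(n=min(top_n, len(imp.phi))))
        else:
            sets[k] = frozenset(imp.top_edges(fraction=top_fraction))
    rule = "top_n" if top_n is not None else "top_fraction"
    return FoldEdgeSets(sets=sets, top_rule=rule)


def jaccard(a: frozenset, b: frozenset) -> float:
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)


def jaccard_stability(sets: FoldEdgeSets) -> dict:
    """Pairwise fold-set Jaccard matrix and its mean/SD over fold pairs."""
    folds = sorted(sets.sets)
    K = len(folds)
    M = np.eye(K)
    vals = []
    for i in range(K):
        for j in range(i + 1, K):
            J = jaccard(sets.sets[folds[i]], sets.sets[folds[j]])
            M[i, j] = M[j, i] = J
            vals.append(J)
    return {"pairwise": M, "mean": float(np.mean(vals)), "sd": float(np.std(vals))}


def edge_support(sets: FoldEdgeSets) -> dict[EdgeKey, float]:
    counts: dict[EdgeKey, int] = {}
    for s in sets.sets.values():
        for e in s:
            counts[e] = counts.get(e, 0) + 1
    return {e: c / sets.K for e, c in counts.items()}


def consensus_network(sets: FoldEdgeSets, rho: float = 0.6) -> ConsensusNetwork:
    """Edges selected in at least a proportion rho of folds."""
    return ConsensusNetwork(support=edge_support(sets), rho=rho)


def label_permutation_test(
    pipeline,
    graphs,
    labels: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Permutation test of per-edge fold support under shuffled labels.

    ``pipeline(graphs, labels, seed) -> FoldEdgeSets`` is rerun on each of
    ``n_perm`` label shuffles; the per-edge p-value is the proportion of
    permutations whose support meets or exceeds the observed support
    (minimum attainable p is 1/n_perm), BH-adjusted across edges.
    """
    if n_perm < 20:
        warnings.warn("n_perm < 20 gives very coarse p-value resolution", stacklevel=2)
    labels = np.asarray(labels)
    obs_sets = pipeline(graphs, labels, seed)
    obs_support = edge_support(obs_sets)
    edges = sorted(obs_support)
    exceed = {e: 0 for e in edges}
    rng = substream(seed, "label_permutations")
    for it in range(n_perm):
        perm = rng.permutation(labels)
        perm_sets = pipeline(graphs, perm, int(rng.integers(0, 2**31 - 1)))
        psup = edge_support(perm_sets)
        for e in edges:
            if psup.get(e, 0.0) >= obs_support[e]:
                exceed[e] += 1
    p = np.array([exceed[e] / n_perm for e in edges])
    rej, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return pd.DataFrame(
        {"edge": edges, "support": [obs_support[e] for e in edges],
         "p_perm": p, "p_adj": p_adj, "significant": rej}
    )


# ---------------------------------------------------------------------------
# group statistics


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> dict:
    """Benjamini-Hochberg step-up adjusted p-values and q-level flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    rej, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return {"p_adjusted": p_adj, "significant": rej}


def edge_group_tests(
    values_by_edge: dict[EdgeKey, dict[str, np.ndarray]],
    pair: tuple[str, str] | None = None,
    alpha_normality: float = 0.05,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-edge group comparison of importance distributions.

    Pairwise (``pair`` given): Welch's t-test when Shapiro-Wilk accepts
    normality in both groups at ``alpha_normality``, Mann-Whitney U
    otherwise. Three-group (``pair`` None): Kruskal-Wallis with
    tie-corrected ranks. BH-FDR across edges.
    """
    rows = []
    for edge, groups in sorted(values_by_edge.items()):
        if pair is not None:
            a = np.asarray(groups[pair[0]], float)
            b = np.asarray(groups[pair[1]], float)
            if min(a.size, b.size) < 3:
                raise ValueError(f"edge {edge}: fewer than 3 subjects in a group")
            constant = a.std() == 0 or b.std() == 0
            if constant:
                warnings.warn(f"edge {edge}: constant group, nonparametric branch",
                              stacklevel=2)
            normal = (
                not constant
                and sstats.shapiro(a).pvalue > alpha_normality
                and sstats.shapiro(b).pvalue > alpha_normality
            )
            if np.array_equal(np.sort(a), np.sort(b)) and a.std() == 0 and b.std() == 0:
                stat, p, test = 0.0, 1.0, "welch_t"
            elif normal:
                res = sstats.ttest_ind(a, b, equal_var=False)
                stat, p, test = float(res.statistic), float(res.pvalue), "welch_t"
                if np.isnan(p):   # identical constant samples
                    stat, p = 0.0, 1.0
            else:
                try:
                    res = sstats.mannwhitneyu(a, b, alternative="two-sided")
                    stat, p, test = float(res.statistic), float(res.pvalue), "mannwhitney"
                except ValueError:   # all values identical
                    stat, p, test = 0.0, 1.0, "mannwhitney"
            diff = float(a.mean() - b.mean())
            rows.append({"edge": edge, "test": test, "statistic": stat, "p": p,
                         "diff": diff, "direction": int(np.sign(diff))})
        else:
            samples = [np.asarray(v, float) for v in groups.values()]
            if min(s.size for s in samples) < 2:
                raise ValueError(f"edge {edge}: fewer than 2 subjects in a group")
            try:
                H, p = sstats.kruskal(*samples)
            except ValueError:   # all values identical across groups
                H, p = 0.0, 1.0
            rows.append({"edge": edge, "test": "kruskal", "statistic": float(H),
                         "p": float(p),
                         "group_means": {g: float(np.mean(v)) for g, v in groups.items()}})
    df = pd.DataFrame(rows)
    adj = bh_fdr(df["p"].to_numpy(), q=q)
    df["p_adj"] = adj["p_adjusted"]
    df["significant"] = adj["significant"]
    return df


def ancova_age_adjusted(
    feature: np.ndarray, groups: list[str], age: np.ndarray
) -> dict:
    """Parallel-slopes ANCOVA: feature ~ group + age, type-II F for group.

    Also reports the Pearson correlation between age and the feature as
    the confound-validation check.
    """
    feature = np.asarray(feature, float)
    age = np.asarray(age, float)
    if not np.isfinite(age).all():
        raise ValueError("age must be finite")
    counts = pd.Series(groups).value_counts()
    if counts.min() < 3:
        raise ValueError("need at least 3 subjects per group")
    df = pd.DataFrame({"y": feature, "group": groups, "age": age})
    model = ols("y ~ C(group) + age", data=df).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        raise ValueError("degenerate (collinear) design")
    table = anova_lm(model, typ=2)
    r, r_p = sstats.pearsonr(age, feature)
    return {
        "F_group": float(table.loc["C(group)", "F"]),
        "p": float(table.loc["C(group)", "PR(>F)"]),
        "F_age": float(table.loc["age", "F"]),
        "age_corr": float(r),
        "age_corr_p": float(r_p),
    }


def channelwise_ancova(
    features: np.ndarray, groups: list[str], age: np.ndarray, q: float = 0.05
) -> pd.DataFrame:
    """ANCOVA per channel with BH-FDR across channels.

    ``features`` is subjects x channels (e.g. each subject's mean
    complexity per channel).
    """
    features = np.asarray(features, float)
    rows = [ancova_age_adjusted(features[:, c], groups, age)
            for c in range(features.shape[1])]
    df = pd.DataFrame(rows)
    adj = bh_fdr(df["p"].to_numpy(), q=q)
    df.insert(0, "channel", np.arange(features.shape[1]))
    df["p_adj"] = adj["p_adjusted"]
    df["significant"] = adj["significant"]
    return df
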