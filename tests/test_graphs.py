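"""Graph construction: connectivity definitions, thresholding, node
features and the planted-structure recovery oracle."""

import numpy as np
import pytest

from nirsgraph.complexity import trajectories
from nirsgraph.config import ChromophoreMode, EdgeType, Group, RunConfig, substream
from nirsgraph.graphs import (
    assemble_subject_graph,
    complexity_fc,
    node_features,
    raw_fc,
    temporal_snapshots,
    threshold_graph,
)
from nirsgraph.synthetic import CohortSpec, generate_subject
from nirsgraph.topology import edge_jaccard_overlap


@pytest.fixture(scope="module")
def planted_subject(run_config):
    spec = CohortSpec(
        n_channels=8,
        planted_modules=((0, 1, 2),),
        coupling_strength={Group.HC: 1.0, Group.MCI: 0.4},
        noise_sd=0.0,
        seed=2,
    )
    hbo, hbr, _ = generate_subject(spec, "s", Group.HC, substream(2, "fix"))
    trajs = {
        ChromophoreMode.HBO: trajectories(hbo, run_config),
        ChromophoreMode.HBR: trajectories(hbr, run_config),
    }
    return spec, {ChromophoreMode.HBO: hbo, ChromophoreMode.HBR: hbr}, trajs


class TestRawFC:
    def test_duplicate_and_negated_channels(self, run_config):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(2033)
        from nirsgraph.session import RecordingSession, default_channel_labels
        from nirsgraph.config import Chromophore

        sess = RecordingSession(
            "s", Group.HC, Chromophore.HBO, np.stack([x, x, -x]),
            8.138, default_channel_labels(3),
        )
        r = raw_fc(sess)
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(r, r.T)
        np.testing.assert_allclose(np.diag(r), 1.0)

    def test_independent_noise_is_weakly_correlated(self):
        # sampling-distribution oracle: SD of r is about 1/sqrt(n)
        rng = np.random.default_rng(1)
        rs = []
        for _ in range(500):
            a, b = rng.standard_normal((2, 2033))
            rs.append(np.corrcoef(a, b)[0, 1])
        assert np.quantile(np.abs(rs), 0.95) < 0.08


class TestComplexityFC:
    def test_shared_latent_gives_strong_coupling(self, planted_subject, run_config):
        _, _, trajs = planted_subject
        se_corr = complexity_fc(trajs[ChromophoreMode.HBO], metrics=("SE",))
        assert se_corr[0, 1] > 0.8
        np.testing.assert_allclose(np.diag(se_corr), 1.0)

    def test_mean_combination_arithmetic(self):
        # elementwise mean of [[1,.4],[.4,1]] and [[1,.2],[.2,1]]
        m1 = np.array([[1.0, 0.4], [0.4, 1.0]])
        m2 = np.array([[1.0, 0.2], [0.2, 1.0]])
        assert np.mean([m1, m2], axis=0)[0, 1] == pytest.approx(0.3)

    def test_too_few_windows_rejected(self, planted_subject, run_config):
        from nirsgraph.graphs import slice_trajectory

        _, _, trajs = planted_subject
        short = slice_trajectory(trajs[ChromophoreMode.HBO], slice(0, 5))
        with pytest.raises(ValueError, match="windows"):
            complexity_fc(short)


class TestThreshold:
    def test_keeps_signed_entries_above_threshold(self):
        corr = np.array(
            [[1.0, 0.5, 0.2], [0.5, 1.0, -0.4], [0.2, -0.4, 1.0]]
        )
        A = threshold_graph(corr, 0.3)
        assert A[0, 1] == 0.5
        assert A[1, 2] == -0.4
        assert A[0, 2] == 0.0
        assert np.all(np.diag(A) == 0)

    def test_extreme_threshold_empties_noise_graph(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((10, 500))
        A = threshold_graph(np.corrcoef(x), 0.999)
        assert np.count_nonzero(A) == 0

    def test_edges_nested_across_thresholds(self):
        rng = np.random.default_rng(2)
        corr = np.corrcoef(rng.standard_normal((12, 100)))
        prev = None
        for t in np.arange(0.2, 0.61, 0.05):
            edges = set(map(tuple, np.argwhere(threshold_graph(corr, t) != 0)))
            if prev is not None:
                assert edges <= prev
            prev = edges

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_graph(np.eye(3), 1.5)


class TestNodeFeatures:
    def test_dimensions_per_feature_set(self, planted_subject, run_config):
        spec, sessions, trajs = planted_subject
        f4 = node_features(sessions[ChromophoreMode.HBO], trajs[ChromophoreMode.HBO],
                           "FS4", run_config)
        assert f4.shape == (8, 6)  # MS + SE + HFD, 2 values each
        f0 = node_features(sessions[ChromophoreMode.HBO], trajs[ChromophoreMode.HBO],
                           "FS0", run_config)
        assert f0.shape == (8, 2)

    def test_both_mode_concatenates_chromophores(self, planted_subject, run_config):
        _, sessions, trajs = planted_subject
        g = assemble_subject_graph(
            sessions, trajs,
            run_config.replace(feature_set="FS7", chromophore_mode=ChromophoreMode.BOTH),
        )
        assert g.node_features.shape[1] == 16  # 4 blocks x 2 values x 2 chromophores


class TestAssemble:
    def test_graph_contract_and_determinism(self, planted_subject, run_config):
        _, sessions, trajs = planted_subject
        cfg = run_config.replace(edge_type=EdgeType.COMPLEXITY_FC)
        g1 = assemble_subject_graph(sessions, trajs, cfg)
        g2 = assemble_subject_graph(sessions, trajs, cfg)
        np.testing.assert_array_equal(g1.adjacency, g2.adjacency)
        A = g1.adjacency
        np.testing.assert_allclose(A, A.T)
        assert np.all(np.diag(A) == 0)
        nz = np.abs(A[A != 0])
        assert nz.min() >= cfg.r_threshold

    def test_raw_and_complexity_edge_sets_differ(self, planted_subject, run_config):
        _, sessions, trajs = planted_subject
        g_raw = assemble_subject_graph(
            sessions, trajs, run_config.replace(edge_type=EdgeType.RAW_FC))
        g_cplx = assemble_subject_graph(
            sessions, trajs, run_config.replace(edge_type=EdgeType.COMPLEXITY_FC))
        assert edge_jaccard_overlap(g_raw, g_cplx) < 1.0

    def test_group_ordering_of_planted_edge_weights(self, run_config):
        """Mean within-module coupling weight is higher for HC than MCI."""
        weights = {}
        for group, c in ((Group.HC, 0.9), (Group.MCI, 0.4)):
            vals = []
            rng = substream(9, f"order-{group.value}")
            spec = CohortSpec(
                n_channels=8,
                planted_modules=((0, 1, 2, 3),),
                coupling_strength={Group.HC: 0.9, Group.MCI: 0.4},
                seed=9,
            )
            for _ in range(30):
                hbo, _, _ = generate_subject(spec, "s", group, rng)
                corr = complexity_fc(trajectories(hbo, run_config))
                vals.append(np.mean([corr[a, b] for a in range(4) for b in range(a + 1, 4)]))
            weights[group] = np.mean(vals)
        assert weights[Group.HC] > weights[Group.MCI]


class TestTemporalSnapshots:
    def test_segment_sizes_and_t1_equivalence(self, planted_subject, run_config):
        _, sessions, trajs = planted_subject
        snaps = temporal_snapshots(sessions, trajs, run_config, T=3)
        sizes = [75, 75, 74]  # 224 windows split into 3 contiguous segments
        assert len(snaps) == 3
        single = temporal_snapshots(sessions, trajs, run_config, T=1)
        static = assemble_subject_graph(sessions, trajs, run_config)
        np.testing.assert_allclose(single[0].adjacency, static.adjacency)

    def test_too_few_windows_rejected(self, planted_subject, run_config):
        _, sessions, trajs = planted_subject
        with pytest.raises(ValueError):
            temporal_snapshots(sessions, trajs, run_config, T=40)
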