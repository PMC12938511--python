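# nirsgraph

Complexity–fluctuation graph analysis for resting-state functional
near-infrared spectroscopy (fNIRS).

Resting-state fNIRS measures slow cortical hemodynamics (HbO/HbR
concentration changes) from multichannel optical recordings. Conventional
connectivity correlates the raw hemoglobin amplitudes between channels
(`RAW_FC`). This package implements an alternative network representation
in which an edge measures how two channels' *signal complexity*
co-fluctuates over time: each channel's recording is scanned with
overlapping 30 s windows (1 s step), three nonlinear complexity measures
are computed per window —

- **HFD** — Higuchi fractal dimension, the slope of log curve length
  `L(k)` against `log(1/k)`;
- **SE** — spectral entropy, `−Σ P'(f) log₂ P'(f) / log₂ F` of the
  Welch-normalized power spectrum;
- **WE** — wavelet entropy, `−Σ p_j log₂ p_j / log₂ J` over relative
  detail-band energies of a J-level discrete wavelet transform —

and the Pearson correlation between two channels' complexity
*trajectories* defines the `COMPLEXITY_FC` edge weight. Correlation
matrices are thresholded at a fixed `|r| ≥ 0.3`, nodes carry mean/SD
summaries of the windowed signal and complexity metrics (feature sets
FS0–FS7), and the resulting subject-level graphs feed graph neural
networks (GCN, GAT, STGNN) that decode diagnostic stage (healthy
control / mild cognitive impairment / Alzheimer's disease) under
stratified subject-independent 5-fold cross-validation.

Because classification alone is not a biomarker, the package also
implements the reproducibility layer: edge-importance maps from GAT
attention (head-mean coefficients) or from a soft-edge-mask explainer for
non-attention models; a top-K (10%) edge-deletion perturbation test
against a random-deletion null; fold-wise Jaccard stability; consensus
networks (edges selected in at least a proportion ρ of folds); a
label-permutation test of edge support; and edge/channel group statistics
(Welch's t, Mann–Whitney, Kruskal–Wallis, age-adjusted ANCOVA, all with
Benjamini–Hochberg FDR control).

Clinical recordings of this kind are not publicly distributable, so the
package ships a synthetic-cohort generator that emulates 48-channel
prefrontal recordings (8.138 Hz, 2033 samples) with *planted*,
group-dependent complexity coupling inside designated channel modules —
strong coupling for HC (0.9), attenuated for MCI (0.4), heterogeneous
per-subject coupling for AD (uniform on [0.1, 0.9]). The planted edges
are exact ground truth for recovery experiments.

## Worked example

```python
from nirsgraph import CohortSpec, RunConfig
from nirsgraph.experiments import build_cohort_graphs
from nirsgraph.config import EdgeType, Group
from nirsgraph.topology import graph_metrics

spec = CohortSpec(n_per_group={Group.HC: 2, Group.MCI: 2, Group.AD: 2}, seed=7)
graphs, truth = build_cohort_graphs(spec, RunConfig(seed=7))

g = graphs[EdgeType.COMPLEXITY_FC][0]          # first HC subject
m = graph_metrics(g)
print(g.subject_id, g.group.value, g.n_nodes, "nodes")
print(f"density={m.density:.3f}  clustering={m.clustering:.3f}  "
      f"efficiency={m.global_efficiency:.3f}")
```

prints (numbers produced by this exact snippet):

```
HC001 HC 47 nodes
density=0.102  clustering=0.255  efficiency=0.355
```

i.e. the complexity graph of the first healthy-control subject keeps
10.2% of channel pairs at `|r| ≥ 0.3` (one channel was dropped by motion
QC), with local clustering (0.255) well above the graph's density — the
signature of the planted within-module coupling. The same pipeline is available from the shell:

```bash
nirsgraph simulate --out cohort/ --n-per-group 5 --seed 1
nirsgraph graphs cohort/ --out bundle/ --edge-type complexity --feature-set FS4
nirsgraph train bundle/ --model gat --folds 5 --seed 1
```

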