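# Methods

This note records the model, the numerical choices, and the reasoning
behind design decisions that the interface alone does not show.

## Signal model and preprocessing

Input recordings are channels × samples matrices: either dual-wavelength
light intensity (780/850 nm) or already-converted HbO/HbR concentration
changes, at a nominal 8.138 Hz over ~250 s (2033 samples, 48 prefrontal
channels). Intensity is converted to optical density
(ΔOD = −log₁₀ I/I₀, per-channel temporal-mean baseline) and inverted
through the modified Beer–Lambert law by solving the per-sample 2×2
system ΔOD_λ/(d·DPF_λ) = E·[ΔHbO, ΔHbR]. Defaults: tabulated extinction
coefficients at 780/850 nm, DPF 6.0 at both wavelengths, 3 cm
source–detector separation; all configurable because devices differ.

Motion artifacts are detected with a moving-standard-deviation index
(2 s window): samples whose index exceeds 3 robust z-scores above the
channel median are masked, and a channel is excluded once its masked
fraction exceeds 10% of the recording. Masked spans are linearly
interpolated so the subsequent filter sees finite data; the QC mask is
carried forward and masks are never lifted. The exact index and
threshold are package choices (only the 10% exclusion rule is part of
the protocol); both are parameters.

Band-pass filtering uses a 4th-order Butterworth (0.0018–0.15 Hz)
applied forward–backward (`sosfiltfilt`), so the phase is zero — which
preserves the temporal alignment of complexity windows across channels —
at the cost of squaring the magnitude response (effective order 8).

## Windowed complexity

Windows are 30 s with a 1 s step, rounded to the nearest sample (244 and
8 samples at 8.138 Hz), which places exactly 224 windows in a
2033-sample recording. Per window and channel:

- **HFD** with kmax = 8: curve lengths
  L_m(k) = [Σᵢ |x(m+ik) − x(m+(i−1)k)|]·(N−1)/(⌊(N−m)/k⌋·k²),
  averaged over offsets m, with the dimension the least-squares slope of
  log L(k) on log(1/k). A constant window has zero curve length and is
  an error (NaN with a warning inside stacked trajectories).
- **SE**: Welch spectrum with segment length win/4, 50% overlap, Hann
  window, linear detrending; the DC bin is excluded (band-passed signals
  carry no DC power, and its inclusion destabilizes normalization); the
  spectrum is normalized to sum to one and its Shannon entropy divided
  by log₂ of the retained bin count, so SE ∈ [0, 1].
- **WE**: db4 discrete wavelet transform with J = ⌊log₂ win⌋ − 2 = 5
  levels; relative energies are computed over the J *detail* bands (the
  approximation band is excluded: band-passed signals are near zero-mean
  and the approximation mostly holds boundary effects), entropy
  normalized by log₂ J.

Entropy sums use base 2 in both numerator and denominator, making the
normalized ratio base-invariant and confined to [0, 1].

A measured property worth knowing: at 8.138 Hz with a 0.15 Hz low-pass,
the signal is ~27× oversampled. HFD with kmax = 8 probes 0.12–1 s scales
and is therefore nearly constant (≈1.01) for any band-passed input, and
the J = 5 detail bands all lie above 0.127 Hz, so WE likewise carries
little in-band information; SE is the metric with usable dynamic range
in this regime. This is a property of the protocol's parameter set, not
of the implementation, and it bounds how much planted coupling can be
recovered downstream (see *Recovery experiments* below).

## Graphs

`RAW_FC` is the Pearson correlation of the full-length band-passed
hemoglobin series; `COMPLEXITY_FC` is the Pearson correlation between
channels' windowed complexity trajectories, computed per metric and
combined by elementwise mean (per-metric matrices remain available).
Matrices are thresholded at a fixed |r| ≥ 0.3 keeping the sign;
learning layers consume |r|. Node features follow the feature-set
catalogue FS0–FS7: the MS block is the mean and SD over windows of the
window-mean signal; each complexity block is the mean and SD of that
metric's trajectory; "both" chromophore mode averages the HbO and HbR
correlation matrices before thresholding and concatenates HbO-then-HbR
feature blocks. Channels excluded by QC are dropped from the node set
(graphs may have fewer than 48 nodes); node identity is carried by
channel label so edges remain comparable across subjects.

## Models and training

All three classifiers run on dense node-padded batches with node masks,
on an in-package numpy reverse-mode autodiff tape (float32 working
precision; gradients are verified against float64 central finite
differences in the test suite).

- **GCN**: four stacked symmetric-degree-normalized convolutions
  (D^(−1/2)(A+I)D^(−1/2), hidden 64, ReLU), global mean pooling, linear
  head. No dropout — the reference configuration specifies dropout only
  for the attention and temporal models, and empirically dropout 0.5 on
  this GCN causes a train/eval mismatch that collapses predictions on
  weak-feature graphs.
- **GAT**: four multi-head attention layers (4 heads, hidden 64 split
  across heads, dropout 0.5, ELU). Attention logits are
  LeakyReLU(a_src·z_i + a_dst·z_j) + log w_ij, i.e. the edge weight
  biases the softmax so stronger edges attract more attention mass;
  self-loops have weight 1. Coefficients are retrievable per
  layer/head/edge.
- **STGNN**: the window sequence is split into T = 3 contiguous segments
  (earlier segments absorb the remainder, so 224 windows give 75/75/74)
  and adjacency/features are rebuilt per segment; a graph convolution
  feeds a GRU cell carrying node state across snapshots, followed by a
  final convolution, mean pooling and a linear head.

Training (schedule unspecified by the protocol, chosen once): Adam,
lr 5·10⁻³, at most 200 epochs with early stopping when the training loss
fails to improve by 10⁻⁴ for 40 consecutive epochs; cross-entropy
weighted inversely to training-fold class frequencies. Cross-validation
is stratified and subject-independent (5 folds); node features are
z-scored with training-fold statistics only — a leakage canary in the
tests verifies that perturbing a held-out subject leaves the trained
weights bit-identical. An optional ensemble (`n_ensemble`) averages
logits over independently initialized members to damp optimization
noise; the default is a single model. All randomness flows from one seed
through named substreams, so identical configurations reproduce
byte-identical results.

## Explainability and statistics

GAT edge importance is the attention coefficient averaged over heads,
then over layers (a last-layer-only option exists); rows are
renormalized over non-self edges before the directed matrix is
symmetrized, and group maps average subject maps. For non-attention
models, a sigmoid-parameterized soft edge mask is optimized (Adam,
200 steps, lr 0.01) to preserve the model's own prediction under the
masked graph, with L1 sparsity (5·10⁻³) and elementwise-entropy
(10⁻³) regularizers; φ is the final mask value per edge.

The perturbation test deletes the top 10% of each evaluation graph's
edges by φ, measures the pooled held-out macro-F1 drop, and compares it
with equal-count random deletions; the empirical p is the plain
proportion of random draws matching or exceeding the observed drop (no
+1 correction, so the smallest attainable p is 1/n_random).

Stability uses pairwise Jaccard similarity of fold-wise top-edge sets
(ties at the cutoff resolved lexicographically); the consensus network
keeps edges selected in at least a proportion ρ (default 0.6) of folds.
The label-permutation test reruns a caller-supplied pipeline on shuffled
labels and reports, per edge, the proportion of permutations whose
support meets the observed support, BH-adjusted across edges. Group
comparisons use Welch's t when Shapiro–Wilk accepts normality in both
groups (α = 0.05) and Mann–Whitney otherwise; three-group comparisons
use Kruskal–Wallis with tie correction; channel-level complexity
features are tested with a parallel-slopes ANCOVA (feature ~ group +
age, type-II F) with BH-FDR across channels.

## Synthetic cohorts

The generator emulates the *analysis-relevant* structure of prefrontal
resting recordings, not their physiology. Each channel mixes 1/f noise
with a narrow-band oscillation under a smooth latent "regularity"
process λ(t) ∈ [0, 1] (Gaussian-smoothed random walk, 20 s smoothness,
squashed with gain 3 so the channel genuinely switches between
noise-dominated and oscillation-dominated regimes). Channels inside a
planted module combine a shared latent with a private one with
within-module correlation equal to the subject's coupling strength; the
mixture is re-standardized exactly, so a channel's marginal complexity
distribution is independent of coupling and group information lives
only in the *coupling structure*. Oscillator frequencies are assigned
per channel from bit-reversal-interleaved slots over 0.04–0.10 Hz
(bandwidth 0.003 Hz), so channels within a module never share a
spectral line and raw amplitude correlations stay near zero even when
regularity latents are shared — this is what keeps the RAW_FC condition
honest. HbR is emitted as −0.6·HbO plus independent noise. Default
planted modules are three blocks of eight channels; group couplings are
HC 0.9, MCI 0.4, AD per-subject uniform on [0.1, 0.9].

What the generator does **not** emulate: neurovascular coupling
physiology, systemic oscillations (Mayer waves, respiration, cardiac),
scalp contamination, or spatial correlation from optode geometry.
Passing recovery tests therefore demonstrate that the pipeline recovers
planted coupling structure through its own preprocessing and windowing —
not that the method works on clinical data.

## Recovery experiments and their observed limits

The validation suite runs five replicate cohorts (20 subjects per
group) through the full pipeline: graphs under both edge definitions,
GAT cross-validation, attention-based edge ranking, the top-10%
perturbation test (200 random-deletion draws per run) and a
permutation-test calibration on a null cohort at n_perm = 200. These
problem sizes are the package's standard validation scale; the protocol
settings of 1000 deletions and 5000 permutations remain the library
defaults.

Two honest caveats, both measured and reproducible with the shipped
experiments. First, because only SE retains dynamic range after the
band-pass (see above), the three-metric mean caps planted
COMPLEXITY_FC edge weights near SE-correlation/3; at coupling 0.9 the
within-module edge-retention rate at |r| ≥ 0.3 is ≈0.19 against a
≈0.06 background. Second, mean-pooled graph networks of the prescribed
shape are weakly sensitive to *localized* edge-density contrasts of
that size (a control experiment with idealized block graphs at the same
densities and pure-noise features stays near chance). Consequently the
decoding advantage of COMPLEXITY_FC over RAW_FC on the synthetic
cohorts, and the perturbation test's significance, are both
seed-dependent at this coupling strength: the attention-based
planted-edge ranking and the permutation-null calibration are the
robustly reproducible recovery results. The ranking oracle is evaluated
on the strong-coupling (HC) group's mean attention map — planted
structure exists in the other groups only weakly by design, so the
group-specific map is the right place to ask whether attention
concentrates on it (the all-groups variant is also computed and
reported). The acceptance script reports
all of these quantities as computed.

## Known limitations

- No short-separation regression, wavelet/spline motion correction, or
  physiological-noise regression; no partial correlation, coherence or
  directed coupling measures.
- The SNIRF reader/writer covers the minimal subset this pipeline needs
  (one data block, time vector, per-channel measurement lists, metadata
  tags); it is not a general SNIRF implementation.
- Graph metrics are computed on binarized topology; weighted variants
  are out of scope. Clustering is mean nodal clustering (not
  transitivity).
- The empirical p-values (perturbation, permutation) use plain
  proportions; their resolution is 1/n draws.
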