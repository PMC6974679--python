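# Methods note

This note records the model implemented by `nmstate`, the numerical and
design decisions taken, and what the synthetic generator does and does not
emulate.

## Model

### Connectivity estimator

For channels x, y with instantaneous Hilbert phases φ_x, φ_y, the imaginary
phase-locking value over a window of N samples is

    iPLV_xy = | Im( Σ_t e^{i(φ_x(t) − φ_y(t))} ) | / N  ∈ [0, 1].

iPLV is insensitive to zero-lag coupling (volume conduction); for a constant
relative lag d it equals |sin d| exactly, which also means lags of 0 and π
are invisible — a property the synthetic generator must respect (below).
Phases are computed once on the full-length signal and sliced per window,
avoiding per-window Hilbert edge artifacts. Windows are half-open sample
ranges; the defaults are 2 s windows advancing by 2 s.

### Statistical filtering

Each window's edges are tested against surrogates built by *cut-splicing*
(circularly rotating) every channel's full-length phase series at an
independent random cut drawn from the central 80% of the recording, then
recomputing the window's iPLV. The add-one estimator
p = (1 + #{surr ≥ obs}) / (1 + S) avoids zero p-values; the window's
edge family is corrected by Benjamini–Hochberg FDR and non-survivors are
zeroed.

Two consequences shaped the defaults:

- **Resolution constraint.** The smallest achievable p-value is 1/(S+1).
  BH rejects the m-th smallest p-value only if p ≤ m·q/M (M = n(n−1)/2
  candidate edges), so if 1/(S+1) > m·q/M the filter can never reject
  *anything*, regardless of effect size. With 12 nodes (M = 66) and ~6
  truly coupled edges, S = 200 at q = 0.01 is mathematically powerless;
  the pipeline default is therefore S = 400 with q = 0.05. Study-scale
  runs should use thousands of surrogates and may then tighten q.
- **Power requires intermittent coupling.** Rotating the full series has
  power because a surrogate window mixes segments recorded far apart —
  which destroys coupling only if the coupling is *not* constant over the
  whole recording. A pair locked for 100% of the recording largely
  survives rotation (the surrogate merely re-randomizes the constant
  offset). This is the correct null for dynamic connectivity, where
  coupling is state-dependent, but the filter should not be expected to
  certify tonic, recording-long coupling.

### Topological filtering (OMST)

On distances 1/w, edge-disjoint minimum spanning trees are extracted by a
deterministic Kruskal (lexicographic tie-breaking) until no spanning tree
remains, capped at ⌊M/(N−1)⌋ rounds. The union of the first m trees is
scored by J(m) = GE(m)/GE(full) − cost(m), where GE is weighted global
efficiency and cost the selected fraction of total edge weight; the first
maximum of J is kept. Graphs arriving disconnected (routine after
statistical filtering) are filtered per connected component.

### Microstates

Each filtered window graph is summarized by the ascending eigenvalues of
its normalized Laplacian L = I − D^{−1/2} G D^{−1/2} (isolated nodes
contribute zero rows, hence one zero eigenvalue each, consistent with
component counting; spectra are clipped to the theoretical [0, 2] range
against floating-point underflow). The spectrum is invariant under node
permutation: it encodes *structure*, not node identity. This is a feature
for cross-subject comparability and a constraint on experiment design —
two states coupling different node sets with the *same* topology are
indistinguishable at this stage.

The spectra are quantized by neural gas (rank-based soft competitive
learning; λ: 10 → 0.01, ε: 0.5 → 0.005, 50 adaptation steps per window,
prototypes initialized from k distinct data columns). For k = 1 the
optimal prototype is the data mean in closed form and the distortion error
DE = Σ‖v − v_rec‖² / Σ‖v − v̄‖² equals 1 by construction, anchoring the
DE scale; useful codebooks have DE ≪ 1.

Cross-subject alignment pools all prototypes, K-means-clusters them on
unit-normalized vectors with the cluster count chosen by maximum cosine
silhouette over 2–5, and Hungarian-matches each subject's prototypes to
the cluster centers by **Euclidean** distance of the unit-normalized
vectors. Cosine similarity is deliberately not used for the matching:
sorted Laplacian spectra are globally similar, so pairwise cosines are all
close to 1 and the assignment becomes numerically fragile, while the
clustering geometry itself (Euclidean on the unit sphere) separates the
states cleanly.

### Chronnectomics

For the per-window label sequence: FI = changes/(T−1); OT = label
fractions; DT = mean run length per state; CI = number of distinct
contiguous substrings of lengths 1..10; PT[a,b] = count of (a,b) pairs
divided by the **total** pair count, so ΣPT = 1 and FI + trace(PT) = 1
exactly (a row-stochastic variant exists for Markov diagrams). The printed
reference example [1,2,2,1,2] gives PT₁₂ = 0.5, PT₂₁ = 0.25. Significance
uses label-shuffling nulls (which preserve OT exactly, so OT p-values are
1 by construction) with two-sided add-one p-values and BH correction over
the PT entries.

### Cartography and statistics

Per window: Louvain partition (seeded, resolution 1) with Newman weighted
modularity Q; within-module degree z-score W (population SD; zero-spread
modules give 0); participation coefficient B. Per state, pooled (B, W)
node-window points are binned on a fixed 20×20 grid (B ∈ [0,1],
W ∈ [−3,3], out-of-range values clipped into edge bins) and normalized to
percent. Group contrasts report the relative difference on the reference
support and the percentage of positively/negatively differing bins.

Feature-wise group tests are routed by a Lilliefors normality check to
Student's t or Mann–Whitney U (U converted to a signed z for comparable
ranking), BH-corrected. Classification is iterated stratified k-fold k-NN
(Euclidean, strict-majority vote, ties to the control class) with pooled
per-iteration confusion matrices; optional rank-based feature selection is
re-fit inside every training fold so test subjects never influence it.
k must be small relative to the training folds: with tiny cohorts a large
k makes every vote tie and predictions collapse to the control class.

## Synthetic generator: realism and limits

The generator plants a first-order Markov chain over latent coupling
states. In a state, each connected component of the coupling graph runs an
independent driver phase Φ(t) = 2πf_c t + random walk (σ = 0.3/sample) +
uniform offset; the m-th node of a component carries Φ + m·lag + small
phase jitter, so every coupled pair has a distinct nonzero lag and the
component appears to iPLV as a weighted clique. Uncoupled nodes run
independent phase processes at their own within-band frequencies. Signals
are cos(phase) plus Gaussian observation noise. State switches are aligned
to window boundaries (generator step defaults to the window length), so
the per-window ground-truth labels are exact. `StateSpec` rejects lag
configurations where any multiple of the lag up to the largest component
size is ≡ 0 (mod π), which would be invisible to iPLV.

The reference cohort (12 nodes, beta band, 128 Hz) plants one 4-clique
state and one two-3-cliques state — deliberately *structurally* different,
because the spectral fingerprint cannot distinguish relabeled copies of
the same topology — and two groups differing only in transition matrices
(controls switch more readily), planting a flexibility-index difference.

What the generator does **not** emulate: volume conduction / field spread
(signals are noisy phases, not mixed source topographies), realistic 1/f
spectra or amplitude dynamics (unit-amplitude oscillators), within-window
coupling onset/offset, 90-node whole-brain scale (desk-scale defaults use
12 nodes), and inter-subject anatomical variability. Consequently the
honest expectation is that chronnectomic features classify planted
switching differences well, while single-state prototype spectra sit at
chance when both groups share the same repertoire — which is what the
acceptance run shows.

## Numerical choices

- All randomness flows from one master seed through
  `numpy.random.SeedSequence` fan-out; derived stage seeds are < 2³¹ and
  recorded in the run manifest together with a configuration hash.
- Surrogate iPLV recomputation is vectorized in batches of 64 surrogates
  (rotation indices + one batched matmul per batch).
- Kruskal tie-breaking is lexicographic on (distance, i, j), making OMST
  deterministic; comparisons against a brute-force oracle use continuous
  random weights so ties are measure-zero.
- Eigenvalues come from `eigvalsh` (symmetric solver), sorted and clipped
  to [0, 2].
- k-NN uses strict majority with ties broken toward the control class —
  a conservative choice that biases *against* reporting sensitivity.

## Limitations

- Desk-scale surrogate counts (hundreds) limit attainable FDR levels; the
  q = 0.01 regime needs thousands of surrogates (see the resolution
  constraint above).
- The silhouette-based cluster-count selection assumes the pooled
  prototypes actually cluster; with degenerate (e.g. all-identical)
  prototypes the alignment falls back to identity permutations with a
  warning.
- Chronnectomic significance uses full label shuffles (exchangeable null);
  it tests temporal structure, not the Markov order.
- The per-window Louvain partition is seeded but partitions are not
  matched across windows; W and B are therefore per-window quantities, as
  in the cartographic-profile literature, and should not be read as
  node trajectories through a fixed module structure.
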