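# Methods

## Model

The dynamics are a delay-coupled Kuramoto network

    dθ_j/dt = ω_j(t) + λ Σ_k w_jk sin(θ_k(t − τ_jk) − θ_j(t)),

a standard whole-brain phase-oscillator model: each parcellated region is a
self-sustained oscillator, coupling is weighted by structural connectivity,
and interactions are retarded by axonal conduction delays `τ_jk = L_jk / v`.
Phase noise is absent; the only stochasticity is the intrinsic-frequency
schedule, which redraws `f_j ~ N(f₀, σ_f)` i.i.d. per region every
`epoch_len` seconds. This intermittent resampling emulates state-dependent
drift of regional excitability and is what makes the wave pattern re-organize
on a sub-second timescale.

Assumptions worth keeping in mind: a single conduction velocity for all
tracts; symmetric weights; sinusoidal (first-harmonic) coupling; phase-only
dynamics (no amplitude). These are shared with the broader family of
connectome Kuramoto models and are not relaxed here.

### Integration

Forward Euler with step `dt` and a ring buffer holding the last
`max(τ)/dt` phases. Delays are rounded to the nearest integer step;
zero-weight pairs are skipped (the weight matrix is sparse by
construction). The configuration is rejected when `dt` is not smaller than
the shortest positive delay of a coupled pair, because such delays would
silently become instantaneous. The default `dt = 0.5 ms` resolves the
10 Hz period (2000 steps) and the shortest synthetic-geometry delays
(≈0.6–1.2 ms).

Pre-history (t < 0) is initialized by extrapolating each node's initial
phase backward at its initial intrinsic rate; this is deterministic and
avoids injecting an artificial synchrony transient. Initial phases are
uniform on (−π, π].

Convergence is verified by step-halving in the dispersionless locked
regime with delays snapped to a common grid (max circular discrepancy
0.017 rad over 5 s). Two caveats, both properties of the dynamics rather
than the scheme: with generic delays, changing `dt` perturbs the rounded
delay pattern itself, and partially synchronized epochs are chaotic, so
trajectory-level agreement between step sizes cannot be expected there.
Likewise, the textbook full-synchronization limit (R → 1 at large λ,
σ_f = 0) holds only without delays; with conduction delays the
dispersionless network settles into a frozen *wave* state (R ≈ 0.95,
constant relative phases) — delay frustration is the wave-generating
mechanism, not a numerical artifact.

### Operating point

Weights are rescaled so the mean nonzero weight is 1, which ties the
effective per-node coupling to the connection count (≈ 0.25·N neighbours).
The default global coupling λ = 0.5 places the standard 150-node network in
the partially synchronized traveling-wave regime (order parameter ≈ 0.8–0.9,
single-peaked relative-phase distribution of width < π, median propagation
speed in the axonal 1–10 m/s band). Both λ and σ_f/f₀ are swept by
`run_sweep`; the regime is broad, with segmentation strengthening and
sequencing weakening as λ grows (the two effects trade off across coupling).

## Synthetic connectome

The generator reproduces the statistical features the analyses actually
use, not anatomy:

- **Geometry** — N nodes (default 468; the scaled profile uses 150) on two
  spherical caps of radius 55 mm, one per hemisphere, with a 30° medial
  wall left empty and the caps separated so they clear the midline.
  Placement is jittered Fibonacci with a minimum separation of half the
  mean spacing (this floor is what guarantees delays resolvable at the
  default `dt`). Region volumes are Gaussian (mean 2144 mm³, SD 399,
  clipped to 753–3077).
- **Weights** — `exp(−d/ℓ) · g_j g_k / d / sqrt(vol_j vol_k)` with decay
  length ℓ = 45 mm (connection probability in tractography falls off over
  tens of mm), divided by distance as a stream-length correction and by
  volume symmetric in the endpoints. The strongest 25% of pairs are kept;
  survivors are rescaled to mean weight 1.
- **Hubs** — a `hub_fraction` (default 20%) of nodes get a 3× endpoint
  gain, placed as homotopic left/right pairs (a left node and its mirror's
  nearest right neighbour). Bilateral hub symmetry is a robust property of
  cortical connectivity, and it matters dynamically: with i.i.d. hub
  placement, individual network realizations can fall out of the wave
  regime entirely, whereas homotopic placement keeps every tested seed in
  it.
- **Tract lengths** — Euclidean distance × 1.15 (fixed tortuosity; tracts
  are curved). Delays are `L/v` for *all* pairs (the UCI needs the full
  delay matrix), weights only for coupled ones.
- **Labels** — seven spatially contiguous, roughly bilateral classes grown
  by multi-source Dijkstra (graph Voronoi) from greedily spread left-
  hemisphere seeds on a within-hemisphere kNN graph augmented with
  homotopic mirror edges. Graph-Voronoi cells are connected by
  construction, so contiguity holds for every seed.

What the generator does **not** emulate: true tractography weight
distributions, subject variability, geometric asymmetries between
hemispheres, distinct thalamic connectivity (all nodes are homogeneous),
and sulcal/gyral folding. Passing tests therefore show that the *methods*
behave correctly on networks with the right coarse statistics; they are
not evidence about any individual empirical connectome.

## Wave-field estimation

The 2-D map is Lambert's azimuthal equal-area projection of each
hemisphere's radially normalized node directions about a configurable pole
(default: lateral-superior directions approximating central-electrode
positions), scaled back to mm and offset onto disjoint half-planes. Equal
area is exact for this projection; near-pole distances are within 2% of
geodesics.

Phase gradients come from circular-linear regression: for each node, the
planar model `θ'(x) ≈ φ₀ + a·(x − x_j)` is fitted to same-hemisphere
neighbours under a Gaussian window (SD 20 mm — "window of size 20 mm" is
read as the SD, the common convention; it is a parameter) by maximizing the
weighted resultant `|Σ w_i exp(i(θ'_i − a·Δx_i))|`, which is wrap-proof.
The optimizer is a coarse grid over gradient vectors (bounded by a 1 m/s
speed floor), two local grid refinements, and a damped Newton polish; the
polish makes the estimate grid-independent (rotation equivariance to
~1e−9). Nodes with fewer than 3 usable neighbours or collinear geometry
are marked missing.

Speed uses the iso-phase contour identity `v = |dθ/dt| / |∇θ'|`, with
`dθ/dt` taken from the model right-hand side at the snapshot — snapshots
are 0.5 s apart and statistically independent, so finite differencing
across them would be meaningless. Gradient magnitudes below 1e−4 rad/mm
are treated as near-synchronous and the speed marked missing. Propagation
direction is `−∇θ'` for advancing phase (waves travel from phase-leading
to phase-lagging regions).

The SSI at radius r is the mean of `(x_k − x_j)·g_k` over the annulus
`(r − Δr, r + Δr)` (Δr = 10 mm, at least 5 valid members), where `g` is
the outward-positive propagation field `−∇θ'·sign(dθ/dt)`; a raw-gradient
variant is a flag. A radial source `θ' = −β|x − x_j|` gives exactly βr.

## Statistics

- **UCI** — `U_j = (1/N) Σ_k (0.5 cos(θ_j − θ_k − 2π f₀ τ_jk) + 0.5)`.
  The delay offset is the delay expressed as phase at the mean frequency,
  `2π f₀ τ`; the dimensionally inconsistent variant `2π τ / f₀` is kept
  behind `literal_delay_term` for comparison. Sequencing is the per-epoch
  OLS slope of `U_j` on `f_j`, summarized by a one-sample t test across
  epochs. In the σ_f = 0 control the scheduled frequencies are constant,
  so the slope is undefined; the control instead regresses on sham
  frequency vectors drawn from the reference schedule independently of the
  dynamics, which must (and does) yield a slope statistically
  indistinguishable from zero.
- **Segmentation** — relative phases are treated as linear quantities,
  justified when their per-sample distribution is single-peaked with bulk
  width < π (checked; a warning fires when the central-95% range exceeds π
  in more than 5% of samples). Pairwise Cohen's d uses pooled variance
  divided by `N_i + N_j` (as defined for this analysis, slightly smaller
  than the usual `N_i + N_j − 2` denominator), unbiased group variances,
  and is computed per sample then time-averaged. Inference: label-shuffling
  permutation tests (2000 resamples) on the time-averaged pairwise d with
  Benjamini–Hochberg FDR at 0.05, plus a one-way ANOVA across classes on
  node time-mean phases. Type-I error of the permutation machinery is
  verified to sit in the binomial 95% interval of the nominal 5%.
- **PCA** — ordinary PCA of the samples × nodes relative-phase matrix
  (sample-mean centred), reported as node-space components and explained
  fractions.
- **Grouping scan** — for circular areas A around a centre, the disk-mean
  relative phase is regressed on the disk-mean intrinsic frequency across
  samples. Because relative phases are globally centred, this curve is
  peaked: too-small disks average too few frequencies (attenuation),
  too-large disks converge on the global mean (which the relative phase
  cannot reflect). The argmax estimates the spatial scale over which
  phases integrate intrinsic frequencies; planted-scale experiments show
  it tracks the true scale with an upward bias of roughly 2–4× (the
  captured-weight curve saturates gradually), so optima should be read as
  scale indicators, not sharp estimates. Default scan: 12 log-spaced
  areas, 10–400 cm².
- **Gradient-frequency coupling** — per centre, the signed component of
  the propagation field along the centre's mean propagation direction is
  regressed on the grouped-disk mean frequency; the null shuffles epoch
  frequency vectors across epochs (2000 resamples, two-sided). The signed-
  component construction is one of several defensible readings (magnitude
  and direction variants exist); it is the one exposed.

## Problem sizes and determinism

The package's standard study condition (`profile="ci"`) is 150 nodes and
21 s (40 retained epochs); `profile="full"` is 468 nodes and 101 s (200
epochs) with identical code paths. Headline numbers at the standard scale
across seeds: median speed ≈ 5–9 m/s, mean UCI slope ≈ 0.06–0.12 per Hz,
mean pairwise segmentation d ≈ 0.4–0.9 against a shuffled-null 95th
percentile ≈ 0.33, network-phase/degree correlation ≈ −0.75 to −0.93,
median optimal grouping area ≈ 100–300 cm². The first principal
component's share is scale-dependent (≈ 10–30% at 40 epochs).

All randomness flows from one root seed through named substreams
(connectome, schedule, initial phases, permutations), so every run,
including permutation inference, is bit-reproducible; derived seeds stay
below 2³¹.

## Known limitations

- Forward Euler is first-order; the convergence guarantee is empirical and
  regime-dependent (see above).
- The gradient fit assumes a locally planar wave within the 20 mm window;
  spiral or strongly curved wavefronts are estimated only as their local
  plane approximation (wave classification is out of scope).
- Relative-phase linearization fails in weakly synchronized regimes
  (e.g. high f₀ sweeps, where R drops); the PCA/ANOVA outputs there should
  be read qualitatively, and the spread warning flags this.
- The equal-area map distorts shapes far from the poles; SSI annuli and
  grouping disks are therefore approximate at the map periphery, and
  centre nodes with too few disk members are skipped.
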