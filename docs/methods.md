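# Methods

`hsegmod` delineates a closed organ boundary from a handful of user-clicked
seed points, in two stages: a **constrained closed polygonal principal
curve** (CCPS) that turns the unordered clicks into an ordered vertex
sequence, and a small **adaptive-learning-rate backpropagation network**
(ABPNN), initialized by a differential-evolution search (IAMCDE), that turns
that sequence into a smooth closed parametric contour
f(t) = (x(t), y(t)), t ∈ [0, 1], with an explicit closed-form expression in
the network coefficients.

## Stage 1 — closed polygonal principal curve

Seed points are Z-scored per axis (population standard deviation), so all
tolerances below live in normalized units. The curve starts as the closed
square with vertices (±0.1, ±0.1) and grows by alternating four steps:

1. **Projection.** Every point is assigned to its nearest curve element — a
   vertex or the interior of a segment (the closing edge from last to first
   vertex always included). Ties break toward the lower element index, with
   all vertices preceding all segments. Δn denotes the mean squared
   projection distance; the k-segments family leaves this quantity's exact
   definition open and the mean is the standard choice.
2. **Vertex optimization.** Each vertex in turn is repositioned to reduce
   the *total* squared projection distance, by a deterministic Nelder–Mead
   search of that global objective started from the current position and
   from the centroid of the points assigned to the vertex and its two
   adjacent segments; a move is accepted only if the total decreases. A
   plain centroid step was rejected during development: it biases every
   vertex inward on convex arcs (chord shrinkage), which caps the
   achievable overlap. Candidate positions are confined to the **data
   disk** — the circle of the data radius r (max distance from the point
   centroid) — clipped fractionally inside (0.999 r); this keeps the curve
   from growing the "abnormal" vertices the filter exists to remove, and
   keeps the optimizer and the filter mutually consistent. Sweeps stop
   when a full sweep improves the total by less than Δs = 0.002.
3. **Vertex filtering.** A vertex is removed when (a) it lies farther than
   r from the data centroid, or (b) fewer than 5 points project onto it
   and its two adjacent segments. Endpoints of the longest segment are
   exempt from rule (b) — the longest segment is retained so it keeps
   collecting projection points — but not from rule (a), which targets
   genuinely distorted geometry. The curve never drops below 3 vertices.
4. **Vertex insertion.** The segment carrying the greatest total squared
   projection distance (among segments with ≥ 2 points) is split at the
   centroid of its points.

The outer loop stops when (i) the segment count k exceeds the bound
k > β·n^⅓·Δn^(−½)·r with β = 0.3, (ii) the outer improvement in total
squared distance falls below Δs = 0.002, or (iii) a safety cap of 50
segments is hit. The bound (i) is evaluated with one nuance: at the
4-vertex initialization Δn is still large, which makes the bound tiny and
spuriously "exceeded"; the bound is therefore *armed* the first time the
growing curve satisfies it and stops the loop only when the count outgrows
it again at the fitted Δn. (The open-curve ancestors of this algorithm
start from k = 1, where the same transient exists but is never binding.)

The final vertices are oriented counterclockwise, rotated to start at the
vertex with the largest x (ties: largest y), parameterized t_i = i/m, and
the first vertex is appended again at t = 1 so closure is part of the
training data.

## Stage 2 — evolution-initialized adaptive backprop network

The network is one hidden layer of q sigmoid units on the scalar input t
and two tanh outputs:

    h_i = σ(t·ω_i − T_i),  g_k = tanh(Σ_i h_i a_{ik} − b_k),  k = 1, 2.

Training targets are the sequence coordinates min-max scaled into
[0.1, 0.9] per axis; the loss E is the sum of squared differences between
the mapped outputs (1 + g)/2 and those targets, over all entries and both
axes. The scaled-target margin keeps every target strictly reachable.

**Initialization (IAMCDE).** The flat parameter vector (length 4q + 2) is
searched by a differential-evolution variant with two mutation operators —
rand/1 and rand/2 with fresh uniform factors in [0, 1] — chosen per trial
with a probability that ramps linearly over the generations, a sine/cosine
crossover-rate schedule, elitist selection, and a keep-best-half population
randomization restart after 10 generations without improvement. The search
box is per-dimension: |ω_i|, |T_i| ≤ m (the number of sequence entries) and
|a_{ik}|, |b_k| ≤ 1. The input-weight range follows from the unit parameter
interval: a sigmoid transition at position T/ω with width ∼1/ω must be able
to sit anywhere in [0, 1] and be as sharp as the spacing of m entries, so
|ω| up to ≈ m is required; the output layer works on (0, 1) activations and
stays order 1. Defaults for the weight search: population 50, 500
generations. (The generic optimizer defaults are population 30, 100
generations, box [−1, 1]; all settings are exposed in `DEConfig`.)

**Backprop with multiplicative rate adaptation.** Full-batch gradient
descent (gradients are exact; they are verified against central finite
differences in the tests) with learning rate η adapted each epoch: ×1.5
after the error fell, ×0.5 after it rose, unchanged on a tie, clamped to
[1e−8, 10] against overflow under repeated multiplication. A proposed step
is **accepted only if it improves on the best error so far** — the usual
step-rejection reading of this adaptation rule; always stepping diverges
into tanh saturation at the stated initial rate η₀ = 0.5 and never
recovers. The recorded learning-rate trace replays exactly from the
recorded error trace under the rule above. Defaults: q = 10 hidden units,
η₀ = 0.5, 20 000 epochs. The loss is multimodal in 4q + 2 dimensions, so
the whole two-phase run is repeated `n_restarts = 3` times (independent
draws from one seeded stream) and the run with the lowest final error
wins — the same best-of-restarts convention as k-means `n_init`. An epoch
costs microseconds (≤ ~30 training pairs), so generous epoch counts are the
cheap way to buy convergence; a clinical-scale configuration with 1000
epochs remains one `TrainConfig` away.

## The closed-form contour

The output map from g ∈ (−1, 1) to a unit-interval coordinate is the
rational expression (g + 1 − (1 − g²)) / (2g), which simplifies to
(1 + g)/2; the singularity at g = 0 is removable and the simplified form is
what the code evaluates (the rational form is kept as a test oracle).
Composing forward pass → output map → inverse target scaling → inverse
Z-score gives pixel coordinates, and because every step is an explicit
formula, `expression_text` renders the whole contour as evaluable text:
two core lines x(t), y(t) inlining all 4q + 2 network coefficients, plus
two affine lines X(t), Y(t) mapping to pixels when a scaler is supplied.

The model has no hard closure constraint; closure is learned through the
t = 1 duplicate and enforced at the polygon level (the sampled contour's
closing edge is implicit). Fitted closure gaps on the synthetic conditions
run 0.2–3% of the contour diameter; the repository policy asserts < 5%.
Sampling default: 360 points, deduplicated, canonical counterclockwise
orientation.

## Metrics

Contours are rasterized with a pixel-center inclusion rule (pixel (r, c)
is set when its center (c + 0.5, r + 0.5) is inside the polygon; 0-based,
x = column). From the pixelwise confusion counts: DSC = 2TP/(2TP+FP+FN),
Jaccard Ω = TP/(TP+FP+FN), ACC = (TP+TN)/all. ACC is frame-dependent
through TN; the evaluation frame is always the full image extent. The
curve-to-data distance Δf is the mean squared Euclidean distance from the
seed points to the sampled contour *polyline* (point-to-segment, not
point-to-sample), in normalized units.

## Synthetic study conditions

The clinical data behind the method is private, so the generator emulates
it: ground truth is a star-shaped radial-harmonic contour
r(θ) = r0·(1 + Σ_{k=2..5} ε_k cos(kθ + φ_k)) with Σ|ε_k| ≤ 0.3 (guaranteed
simple), rasterized on a 256×256 frame. Random shapes draw r0 ∈ [60, 90] px
and harmonic amplitudes decaying as k⁻² with total 0.08–0.22 — mostly
ellipticity plus mild asymmetry, the smoothness class of soft-organ
cross-sections. Seed points subsample the 512-vertex truth contour at a
given fraction (study condition: 8%, i.e. 41 points) with isotropic
Gaussian jitter (study condition: 1% of r0); the "offset" placement adds an
outward half-normal shift of scale 3× the jitter, emulating clicks drawn
toward bright shadow boundaries. What the generator does **not** emulate:
speckle texture, shadowing/attenuation artifacts, calcifications, missing
boundary sections, or reader-specific click habits — passing on these
fixtures shows the geometry pipeline works at realistic sparsity and noise,
not that the method is robust to ultrasound image artifacts.

Under these conditions (10 random shapes, defaults) the pipeline reaches
median DSC ≈ 0.97 with ≥ 9/10 fixtures above 0.95; runtime is a few
seconds per case on one CPU, dominated by the stage-1 Nelder–Mead sweeps.

## Known limitations

- The segment-count stop bound is calibrated (β = 0.3) for the dense-data
  regime of its ancestors; with a few dozen seed points the Δs improvement
  rule is what usually terminates growth, and the bound mostly serves as a
  complexity cap (see the arming nuance above).
- On the unimodal sphere benchmark, classic DE with fixed F = 0.5, CR = 0.9
  out-converges IAMCDE by orders of magnitude at equal budgets: fresh
  uniform mutation factors are a global-search device and slow final
  contraction. IAMCDE's advantage appears on multimodal objectives
  (e.g. ~2× lower median on 10-D Rastrigin) and in the weight search.
- Contours must be star-shaped-ish and simple; the pipeline has no notion
  of multiple objects, holes, or self-intersecting boundaries.
- ACC depends on the frame size and is reported for completeness; DSC and
  Jaccard carry the comparative weight.
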