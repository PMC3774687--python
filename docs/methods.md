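# Methods

`thermotrack` tracks multiple untagged mice in top-view thermal video and
classifies each animal's social / non-social behaviour per frame. This note
documents the models and procedures, the parameters that matter, the
numerical choices made where the design was genuinely open, and what the
synthetic studies do and do not demonstrate.

## Tracking pipeline

### Foreground threshold (blob detection)

Warm bodies are separated from the cooler arena by a single global
temperature threshold estimated once, at initialisation. Candidate
thresholds are the midpoints between consecutive unique temperature values
observed in a window of `init_window` consecutive frames (subsampled to at
most 512 candidates), scanned from high to low. A candidate is feasible when
every frame in the window shows exactly `n_mice` 8-connected foreground
components and a total foreground area within
`[n_mice * min_mouse_area, n_mice * area_upper_factor * min_mouse_area]`.
The window slides forward from the start of the video until a feasible
candidate exists; the first (largest) feasible candidate is kept. Scanning
high-to-low makes the threshold settle just below the coolest body
temperature, far from the background noise floor, which keeps whole bodies
in the foreground while leaving the inter-body gap dark when two animals
nearly touch. (The alternative — smallest feasible candidate — sits at the
noise floor and makes the foreground noise-dominated; we measured that
directly and rejected it.)

After thresholding, a morphological opening with a 5 px linear structuring
element at 0°, 45° and 90° (pixels survive if they pass at least one
orientation) removes tails and speckle. Structures smaller than
`min_mouse_area / 2` are then discarded as unfeasible: no candidate mouse
body can be that small, while stray tail remnants (a thin tail momentarily
aligned with one structuring element survives the opening) and rare noise
clusters always are. Blob-count mismatches are reconciled by up to
`max_dilations` 3×3 dilations when there are too many blobs (a split body)
— the dilation only corrects the count; segmentation continues on the
undilated mask — or deferred to the temporal watershed when there are too
few (touching bodies). If dilation cannot reconcile the count the frame is
flagged `reinit` and excluded from analysis.

Defaults: `min_mouse_area` 120 px² (a 20×8 px ellipse is ≈126 px²),
`init_window` 90 frames (3 s), `area_upper_factor` 4, `max_dilations` 5.

### Temporal watershed

Touching mice form one blob; their individual shapes are recovered by
marker-controlled watershed iterated in an EM loop:

- **Initialisation.** Each mouse's seed is three collinear points — the
  nose, centroid and genitals positions from the previous frame — with the
  end points pulled in so the seed spans the history-smoothed body length
  (arithmetic mean over `history_window` frames) minus a `slack` constant.
  The shrunken seed tolerates between-frame displacement and body flexion
  without leaking into a neighbour. Seed points that fall on background are
  snapped to the nearest foreground pixel; conflicting claims go to the
  mouse with the nearer previous centroid. The background seed is the
  eroded (3×3, 2 iterations) complement of the foreground.
- **E step.** Watershed on the relief, restricted to the foreground mask.
  The default relief is the Gaussian gradient magnitude of the temperature
  image (σ = `relief_sigma` = 1 px): the contact line between two bodies is
  a temperature step or dip and therefore a ridge, so neither basin can
  flood a differently-warm neighbour. A negated-temperature relief
  (`relief="neg_temp"`) is also available; it is the more obvious choice
  for bright bodies but in practice lets the warmer animal's deeper basin
  swallow a cooler touching neighbour, which we observed directly on
  touching-pair simulations. Foreground components reached by no seed are
  assigned whole to the mouse with the nearest centroid, so the per-mouse
  shapes always partition the foreground exactly.
- **M step.** Per-shape moments give the centroid (first order), the major
  axis and length `L = 4·sqrt(λ₁)` (eigen-decomposition of the second-order
  central moment matrix; for a solid ellipse λ₁ = (a/2)²), and the two axis
  end points. Nose/genitals are the end points, ordered to minimise the
  summed distance to the previous frame's keypoints. Eigenvalue ties
  (circular shapes) keep the previous axis, or +x with no history.

The loop stops when the fraction of changed shape pixels falls below
`convergence_tol` (0.01) or after `max_em_iters` (10); disjoint frames
converge in ≤2 iterations because the watershed cannot cross background.

A movement-direction vote guards the nose/genitals assignment: over the last
`k` = 10 frames each frame contributes `sign⟨movement vector, heading⟩`
(stationary frames contribute 0), and a negative total vote swaps nose and
genitals. Because the vote needs a majority of disagreeing frames, at most
one swap occurs per true inversion event; the post-swap vote is already
non-negative, so no oscillation is possible.

Defaults: `slack` 6 px, `history_window` 10, `vote_window` 10,
`max_em_iters` 10, `convergence_tol` 0.01 — all config-exposed.

### Identity matching

Frame-to-frame identity follows a greedy global-minimum-first assignment on
the 6-D keypoint distance matrix (nose, genitals, centroid stacked). The
greedy rule — repeatedly fix the globally smallest remaining entry, ties
broken row-then-column — approximates the optimal assignment and coincides
with it whenever its choices are consistent with the optimum; on
distance-structured matrices (small same-identity, large cross-identity
costs, the regime tracking produces) it recovers the optimum essentially
always. On uniformly random matrices the two differ in roughly a third of
3×3 cases; this is an intrinsic property of greedy selection, irrelevant to
tracking but worth knowing if the routine is reused.

Mistracking is detected by shape statistics: the first Hu moment
(η₂₀ + η₀₂) of every accepted shape feeds a running record to which a
Student's t distribution is fitted by maximum likelihood (refitted every 100
accepted shapes, active after 100). A mouse is flagged when the two-sided
tail probability of its current Hu moment falls below α = 0.01; the global
misdetection state requires two or more simultaneous flags. The statistic is
deliberately fitted jointly over all mice (one baseline body-shape
distribution); per-mouse fitting is a config switch.

While the misdetection state is active — and additionally while the blob
count is below the mouse count (a merged-blob occlusion episode) and on the
first clean frame after either condition ends — identity is checked against
**heat signatures**: per-mouse buffers of in-shape temperature samples over
the last `B` = 9 frames (0.3 s at 30 fps). The cost of assigning signature
*i* to current shape *j* is the two-sample Kolmogorov–Smirnov statistic
(distribution-free, computed directly on samples); greedy assignment on this
matrix proposes a correction. A proposal that differs from the distance
assignment is adopted only when its total KS cost undercuts the distance
assignment's by `heat_margin` = 0.3 — inside a deep occlusion the split
shapes are temperature mixtures and the KS evidence is ambiguous, and the
margin prevents the heat check from introducing spurious switches there,
while a genuine swap between animals whose body temperatures differ by a
noise standard deviation or more produces near-maximal KS separation and
passes easily. Signature buffers take samples only from frames at least `B`
clean frames away from any episode, so a transient swap cannot contaminate
the reference distributions.

### Pair features

For every ordered (reference, target) pair and frame, 13 measurements:

| group | features | notes |
|---|---|---|
| relative position | head2head, head2body, head2genitals, genitals2genitals | keypoint distances, px |
| | body2body_nearest | centroid distance to the *nearest* other mouse, not the pair target |
| shape | hu1, area of the reference | "attitude" of the animal |
| movement | centroid displacement at offsets −15, −5, −1, +1, +5, +15 frames | multi-scale speed/acceleration proxy |

Offsets beyond the video bounds clamp to the first/last valid frame, so
every frame stays classifiable at the cost of attenuated edge estimates.
Distances stay in pixels: the classifier learns from examples at the same
scale, so physical calibration is never needed.

### Temporal Random Forest

For each offset δ ∈ [−w, +w], an ensemble of N unpruned decision trees
(information-gain splits) is trained on pairs (features at frame t+δ, label
at frame t), pooled over all training pairs and frames; each tree draws its
own random subspace of d of the 13 features and a bootstrap resample of the
rows. At inference the (2w+1)·N votes — offset-δ trees evaluated on frame
t+δ — are pooled and the mode wins, ties broken by the behaviour priority
order, then lexicographically. The windowed vote is a temporal regulariser:
an isolated single-frame feature flip inside a stable context is outvoted by
the neighbouring frames' evidence.

Defaults: N = 5, w = 15, d = 4 (≈√13), giving 155 votes per frame. Subspace
per tree (per-split available as a flag); bagging on by default; no class
reweighting — rare classes degrade, which is a property of the method worth
seeing, not silently fixing. A balanced-bootstrap flag exists but is off.

### Combination and metrics

With M mice each animal carries M−1 pairwise labels per frame; the reported
behaviour is the one with the highest priority. Default order (1 = highest):
Above, Nose2Genitals, Nose2Nose, Nose2Body, Following, StandTogether,
WalkAlone, StandAlone — contact behaviours dominate locomotion and rest,
consistent with collapsing {Nose2Body, StandAlone} to Nose2Body. The table
is fully config-overridable and serialised with results.

Agreement metrics: frame-wise accuracy over the eight classes; accuracy and
per-class precision after grouping into social {Nose2Body, Nose2Nose,
Nose2Genitals, Above, Following} vs non-social {WalkAlone, StandAlone}
meta-classes (StandTogether counts as non-social for these metrics by
default and is reported in its own bucket in summaries — its social status
is genuinely arguable); absolute total-duration differences per meta-class,
in seconds and as a percentage of video length. `unknown` frames are
excluded pairwise. Cross-validation folds are contiguous frame blocks, never
shuffled, to avoid temporal leakage.

Identity quality is measured by matching true to estimated poses one-to-one
(greedy on centroid distances — a bijection, so a deep occlusion cannot
collapse two true animals onto one estimate) and reporting (a) the fraction
of frames whose correspondence equals the one established at bootstrap and
(b) the number of maximal disagreement episodes, i.e. the number of manual
interventions a curator would need to restore identities.

## The synthetic generator

`thermotrack.synth` renders scripted scenarios: warm ellipses (default
20×8 px ≈ 5×2.5 cm at the default 4 px/cm scale) with thin wiggly tails, at
5–6.5 units above a background with Gaussian pixel noise (σ = 0.5 units), on
a 160×160 px arena (40 cm), 30 fps. Temperature units are abstract linear
units — every algorithm in the pipeline is threshold- or distribution-based,
so the camera's count-to-temperature calibration is irrelevant. Trajectories
are piecewise-linear with scripted headings; each segment declares the
ground-truth behaviour label per ordered pair, and the prebuilt scenario
factories place the animals so the labels satisfy the ethogram's distance
conventions (sniffing < 0.5 cm, standing together < 3 cm, alone > 10 cm).
Generation is a pure function of spec + seed.

What the generator does *not* emulate: body deformation (real mice bend,
rear and huddle; ellipses do not), fur-temperature gradients and cold
extremities, reflections and excreta in the arena, camera vignetting, and
genuinely ambiguous behaviours. Consequently the passing studies show that
the algorithms are implemented correctly and behave as designed under their
stated assumptions — not that the pipeline reaches any particular accuracy
on real recordings, where shape statistics are broader, behaviours grade
into one another, and even trained human scorers disagree on a substantial
fraction of frames.

Study sizes (chosen to exercise every code path at desk scale): threshold
study 300 frames / 3 mice; touching-pair study 200 frames; crossing-paths
suite 4 seeds × 300 frames at M = 2 and M = 3; orientation study 50 trials;
heat-recovery study 100 trials at a one-σ temperature gap; regularisation
study 20 replicates; end-to-end study 5,400 frames (3 min of video, twelve
450-frame cycles through StandAlone / WalkAlone / Nose2Nose / StandTogether)
with training on folds 1–2 and testing on fold 3.

## Known limitations

- The Hu-moment sanity model is hypersensitive on synthetic data: rendered
  bodies are nearly identical, so the fitted t distribution is very tight
  and mild split-shape variation triggers the misdetection state far more
  often than gross mistracking does. The KS margin guard makes the frequent
  heat consultations harmless, but on real video the baseline shape
  distribution would be broader and the trigger rarer.
- Greedy assignment is an approximation of the optimal assignment; see
  above.
- The priority numbers, the six movement offsets, and several window
  constants are field-reasonable defaults, config-exposed; different choices
  change the ethogram at the margins (tie-breaks, transition frames).
- Occlusion deeper than a brushing pass (one animal fully covering another
  for many frames) leaves identity genuinely undetermined until the bodies
  separate; the occlusion-exit heat resync then recovers it only if the
  animals' temperatures differ.
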