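# Methods

This note documents the models implemented in `courttrack`, the parameter
choices that matter, what the synthetic scene generator does and does not
emulate, and the numerical and design decisions taken where the design was
genuinely open.

## Court geometry

The court plane and the image plane are related by a 3×3 projective
homography estimated from the four clicked court corners with the normalized
direct linear transform (both point sets translated to their centroid and
scaled to RMS √2 before the SVD null-space solve). Four non-degenerate
correspondences make the solve exact; corner round trips reproduce the
inputs to ~1e-9 m / 1e-6 px. World corners default to the axis-aligned
8 × 16 m rectangle (0,0), (8,0), (8,16), (0,16) — origin at one corner, y
along the court length — and are user-overridable. Pixel coordinates are
0-based, origin top-left, y down.

`local_scale(p)` is defined as pixels per meter at world point `p`: the image
length of a 1 m segment centered at `p` along the court x-axis, by finite
difference at ±0.5 m. Player boxes are squares of side
`height_m × local_scale` (default height 2.0 m, covering an upright adult),
anchored bottom-center at the image of the foot point, because calibration
clicks are placed between the feet. The box is split into `NS = 4`
equal-height horizontal subwindows that tile it exactly (band edges from
rounded fractional positions, so heights differ by ≤ 1 px).

## Background model and cue images

Each pixel keeps up to 16 weighted Gaussian color modes (scalar variance per
mode, initialized at 15² intensity², floored at 16). A mode matches when the
squared color distance is below `2.5² · 3 · var`; the highest-weight matching
mode is updated (`w ← w + ρ(1−w)` after a global `(1−ρ)` decay, mean and
variance blended with the same rate), unmatched pixels replace their weakest
mode. Weights are renormalized each ingestion, and the background image is
the per-pixel highest-weight mean.

Three design elements shape the model's dynamics:

* **Feed stride** `N = 10`: only every 10th frame is ingested, so player
  motion between inputs averages out instead of smearing into the model.
* **Feedback** every 3rd ingestion replaces the input with the current
  background image, stabilizing the memory and keeping slow-moving players
  out of the background. A side effect worth knowing: if a foreground object
  is present in the very first ingested frame it is locked in until enough
  clean inputs outvote it (the synthetic benchmark therefore starts with an
  empty-court lead-in, see below).
* **Adaptive learning rate**: the foreground fraction of the last frame is
  monitored; above `fg_spike_fraction = 0.3` the learning rate switches from
  0.01 to 0.1 until the count settles. After a 40 % global illumination step
  the model re-converges in ~12 ingestions with the switch versus ~138
  without (numbers from `scripts/acceptance.py`).

The foreground mask is `|frame − background|` → luminance grayscale
(0.299/0.587/0.114) → threshold at 25/255 → binary opening with a 3×3 square
element; applied to the frame it gives the masked color frame (background
zero-valued). The movement mask runs the identical binarize/open pipeline on
consecutive-frame differences (`movement_source="frame_diff"`, the default;
`"model_diff"` diffs against the background image instead — the textual
sources admit either reading, so both are implemented behind the switch).
Threshold, opening radius, learning rates and the spike fraction are
unpublished in the original description; the defaults above are standard
mixture-model practice and all sit in `BackgroundConfig`.

## Appearance model

Per subwindow, a 1-D HSV histogram: an `N_H × N_S` joint hue/saturation
block with `N_V` value bins appended, `B = N_H·N_S + N_V` (110 with the
10/10/10 default). Hue spans [0,360), S and V [0,1], uniform bins,
top-of-range values in the last bin. Every nonzero-mask pixel contributes
one chroma count **and** one value count, so integer bins sum to
`2 · n_pixels`; a saturation-gated variant (achromatic pixels counted in the
value block only) exists in the literature but is off by default. Histograms
are compared after normalization with the Bhattacharyya distance
`D = sqrt(1 − Σ√(p·q)) ∈ [0,1]`; two empty histograms carry no evidence and
are defined maximally distant (`D = 1`).

The integral histogram stores cumulative per-bin counts with a zero padding
row/column; any axis-aligned rectangle's histogram is four integer corner
lookups per bin and is bitwise-identical to direct binning (tested on
thousands of random rectangles).

Per-subwindow color scores are `s_k = c(1 − D_k)` with `c = 100` (an
`exp(−λD²)` form is available via `score_form="exp"`; since each cue is
normalized to its per-frame maximum, any monotone decreasing form is
order-equivalent within a frame). The upper `NS−1` subwindows multiply, the
lowest adds: the legs' subwindow often misses the spread legs entirely, so
it must not veto the match. Count cues sum non-zero mask pixels per
subwindow divided by the subwindow width. The total particle weight is
`α_color·color_n + α_mask·mask_n + α_mov·mov_n` with (1, 0.4, 0.1).

## Particle filter

State = the player's foot point on the court plane, 30 particles per player
(20–50 supported). Per frame: score, normalize per cue within the set, sum;
estimate = weighted mean of particle positions; then roulette-wheel
(multinomial) resampling with isotropic Gaussian jitter — σ = 0.2 m, or
0.04 m for particles whose weight is within 0.1 % of the set's maximum. An
all-zero-cue frame flags the track lost and redraws the set uniformly over
the court. Each set owns a PCG64 stream seeded by (run seed, player id), so
results are independent of evaluation order and bit-reproducible.

The confusion guard counts, per set pair, consecutive frames with estimates
closer than `guard_overlap_dist_m = 0.5` m (the same radius as the
evaluation's correctness criterion — "tracking the same player" is read as
"both inside one correctness radius"); strictly more than 10 such frames
reset the set with the smaller particle-averaged raw color score to a
uniform redraw. The per-particle mean (rather than the score at the
estimate) is the default reading of "average color weight"; the alternative
is a config switch.

**Precision envelope.** With σ = 0.2 m re-injected every frame and a
weighted mean over soft normalized-cue weights, the estimator keeps a
steady-state fluctuation of roughly 0.1–0.2 m even on a stationary,
high-texture target — decimeter precision is reached but not held every
frame. This is consistent with the method's half-meter correctness radius
and is asserted as such in the test suite. A related structural property:
because normalized histograms are scale-invariant and the background is
masked away, any hypothesis box that fully contains the player sees nearly
identical color and count cues, so lateral localization sharper than
`(box_width − player_width)/2` comes only from box-edge effects and the
movement cue.

## Rigid-grid integral-histogram tracker

A fixed lattice of world offsets around the last estimate: 6 rows × 7
columns over 2 × 2 m by default, particles on 3 rows (evaluation presets
3 × 5 = 15 and 3 × 11 = 33, same grid area, different horizontal density).
The particle block is centered on the anchor in both axes; an off-center
block would bias the weighted-mean estimate by a constant fraction of the
grid height, so the non-particle rows are treated purely as context area
above the player. Offsets never change — the grid is rigid — while the image
footprint follows `local_scale` automatically because offsets are metric.

Cells are scored exactly like particles, with subwindow histograms served by
the frame's integral histogram (equal to brute force, tested bitwise), then
multiplied by the quadratic positional factor
`1 − β((col − center)/center)²` with `β = 0.5`, damping capture by a
similarly colored player passing the grid's edge. The estimate is the
weighted mean of particle positions and becomes the next anchor; the same
confusion guard applies across the four grids (reset = anchor redrawn
uniformly).

**Lag envelope.** The weighted-mean update closes a measured ~14 % of the
anchor-to-target displacement per frame on the synthetic blobs, so the
steady-state lag is ≈ speed/0.14: ~0.15 m at a slow walk (0.02 m/frame),
~0.35 m at 0.05 m/frame. Tracking accuracy under the half-meter criterion is
unaffected (the benchmark holds 100 %), but sub-quarter-meter precision only
holds for slow motion, and the test suite asserts exactly that.

## Ball candidate detection

Connected components (8-connectivity) of the movement mask are gated by
area: expected ball area = `π(d/2)²` with `d = 0.21 m × local_scale` at the
blob's back-projected ground point, accepted within [0.25, 4] × expected.
The isolation test centers a 40×40 and a 60×60 window on the centroid: inner
count must exceed `Q = 30` and the outer count may exceed the inner by at
most `R = 5`. The default compares outer against `inner + R` — the printed
rule `Q + R` would reject large-but-isolated blobs whose inner count far
exceeds Q; the literal mode is available as `isolation_mode="q_plus_r"`.
`Q` is not published; 30 corresponds to a solid blob of ~6 px diameter.
Window sizes are fixed in pixels; only the area gate is perspective-scaled.

A physical consequence of frame differencing: a moving ball lights up both
its new and its old position. If the displacement is below ~14 px both blobs
fall inside the inner window and detection is unaffected (the ghost merely
adds a second candidate lying on the same trajectory one frame back); in a
band of displacements around 20–35 px the ghost lands in the outer ring and
the isolation test rejects the frame. The candidate centroid of the merged
difference blob sits between the old and new ball positions, i.e. on the
trajectory at ~t−½ — harmless for fitting, visible as a ~v/2 pixel offset
against instantaneous ground truth.

## Trajectory growth

Seeding requires three candidates from three distinct frames with pairwise
image distance < 20 px whose x–t positions are collinear within 2 px
(least-squares line residual). Gaps up to the missing-frame budget are
allowed inside a seed window. A growing trajectory predicts `(x(t), y(t))`
from its current fit, absorbs the nearest candidate within 10 px (ties:
lower x, then lower y), refits by full least squares on every absorption
(clips are short — no recursive update needed), counts a missing frame
otherwise, and terminates after more than 3 consecutive misses. Heights are
fit as `frame_height − y_px` so gravity gives `a₂ < 0`. Time-overlapping
trajectories are resolved by member count, then RMS residual. Consecutive
survivors whose models mutually predict each other's members within 5 px RMS
are fragments of one arc (apex stall, brief occlusion) and are merged and
refit before extrapolation — without this, near-identical fragment parabolas
intersect at numerically unstable frames and pollute the contact list.
Extrapolation extends each survivor's model into the inter-trajectory gaps
(meeting at the height-parabola intersection when one lies in the gap, else
the gap midpoint) and to the clip bounds at the ends; extension ranges are
marked interpolated and member points are never altered.

The 20 px seeding gate implies a structural limit: a trajectory can only
begin once the ball moves slower than ~10 px/frame (two frames of spacing
must fit in 20 px), so serve contacts estimated from the first trajectory
frame lag high-speed launches. The synthetic rally preset is deliberately
lob-like (launch speeds just inside the gate) so that clean-rally contact
recovery is limited by the algorithm, not the scenario.

## Hough-line trajectories

Candidates are plotted as binary scatter images — x vs t and height vs t, t
horizontal, one pixel per candidate. Near-horizontal probabilistic-Hough
segments (|angle| ≤ 5°) in either image mark stationary flicker; candidates
within 3 px of such a segment are removed (disjunctive reading — removal if
close in either image). Non-horizontal segments of length ≥ 20 px with gaps
≤ 10 px in the cleaned x–t image define candidate sets (each candidate joins
its nearest segment within 3 px; sets under 3 members drop). Per set, a
least-squares line in x–t and parabola in height–t; consecutive sets join
iff their x–t lines intersect strictly inside the inter-set frame gap and
the height models differ by < 15 px there. Accumulator resolution is 1 px /
1°, and `skip_horizontal_removal` exposes the known trade-off that the
cleanup also deletes true apex candidates (locally horizontal in y–t) —
which is the main reason this estimator fragments arcs more than trajectory
growth.

## Contact estimation

Between consecutive trajectories the difference of height parabolas
`(a₂−a₂′)t² + (a₁−a₁′)t + (a₀−a₀′) = 0` is solved; among real roots within
the inter-trajectory gap ± 15 frames slack, the one closest to the gap
midpoint is the contact. Height intersections localize contacts much more
sharply than the shallow x-line crossings. Identical parabolas are
degenerate and yield no event. The serve has no preceding arc: the first
trajectory's initial frame is the first contact. Events report both the
fractional and the rounded frame; evaluation uses the rounded one.

## Evaluation protocol

Players: a frame is correct within 0.5 m world distance **or** 20 px image
distance (the pixel branch matters in the far court, where 0.5 m is under
10 px); evaluation starts at the frame where all four players complete two
consecutive correct frames, then samples every 3rd frame; same-team identity
swaps are forgiven per frame when `allow_team_swaps` is set (per-team best
assignment, which provably never lowers a score). Ball: every 3rd frame,
correct within 20 px; frames uncovered by any trajectory count as untracked,
and percentages are reported against both total and tracked frames.
Contacts: greedy one-to-one matching in time order, correct strictly within
10 frames.

## Synthetic scenes

The generator emulates the scene properties the trackers rely on: a
textured sand background (static spatial texture σ = 6 plus per-frame noise
σ = 2, below the binarization threshold), a thin static net at 2.4 m, four
players as 4-band colored rectangles (0.6 × 1.8 m) sized by the homography
and moving along piecewise-linear waypoint paths, a ball disk at its
physical 21 cm scale flying image-space arcs that are exactly linear in x
and parabolic in height with `a₂ = −g·s/(2·fps²)` (s = pixel scale at arc
midpoint), optional global illumination steps and spectator flicker.
Ground-truth player pixels equal `world_to_image` of the world positions
bitwise; contact frames equal the schedule.

The benchmark scene (340 frames at 320 × 240, 25 fps) begins with 40
empty-court frames so the background model settles before calibration — the
fixed-camera equivalent of starting the model before the rally. Players
then stand 20 frames (calibration at frame 45, clicks = ground truth) and
walk paths containing one front-pair and one back-pair crossing at
~0.05 m/frame. Team hue families are well separated (reds/blues vs
greens/purples).

What the generator does **not** emulate — articulated limbs, jumps, shadows,
motion blur, camera shake, perspective distortion of the players' vertical
extent, crowd backgrounds — is exactly what separates the synthetic
benchmark accuracies (≈99–100 %) from accuracies on real match footage;
passing the synthetic benchmark validates the machinery, not real-world
performance.

## Problem sizes and reproducibility

The shipped tests and the acceptance script use 320 × 240 player scenes
(340 frames), 640 × 480 ball rallies (~160 frames), 50-rally noise sweeps,
10⁴–10⁵-draw resampling statistics and 20 × 100 integral-histogram
rectangle checks; these sizes were chosen so the whole suite reruns in a few
minutes on one core while keeping every statistical bound comfortably
non-trivial. All randomness flows from explicit PCG64 seeds (per-player
streams split by id); identical (input, config, seed) runs are
bit-identical, including the track CSVs.

## Known limitations

* Lateral player localization is fundamentally soft within
  `(box_width − player_width)/2` (see the particle-filter precision
  envelope); both trackers are half-meter-class instruments.
* The rigid grid trails fast targets with lag ≈ speed/0.14 per frame.
* Ball detection has a blind displacement band (~20–35 px/frame) where the
  frame-difference ghost breaks the isolation test, and serve estimates lag
  launches faster than the seeding gate.
* The Hough estimator's horizontal-line cleanup removes true apex
  candidates; it is kept faithful to the described behavior, with a switch
  to disable it for experimentation.
* No velocity or rotation in the player state (rejected upstream for this
  domain: fast direction changes make velocity models counterproductive),
  no 3-D ball reconstruction, no multi-camera fusion, no lens-distortion
  correction.
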