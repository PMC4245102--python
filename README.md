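# courttrack

Multi-cue tracking of the four players and the ball in fixed-camera court-sport
video (beach volleyball being the motivating case), with automatic estimation of
ball-contact time points.

## Who this is for

Sports scientists and video analysts who have a single fixed camera behind (or
beside) a court and want, per rally: the players' positions on the court plane
in meters, the ball's image trajectory, and the frames at which the ball was
hit — without manual annotation of every frame.

## What it computes

**Geometry.** Clicking the four court corners in one frame calibrates a planar
homography `H` between image pixels and court-plane meters (normalized DLT).
All player state lives in world coordinates; box sizes in the image follow the
local pixel scale, so hypotheses in the near court are larger than in the far
court.

**Cue images.** An adaptive per-pixel Gaussian-mixture background model
(16 modes, fed every 10th frame, with every 3rd input replaced by the current
background image and a spike-triggered high learning rate) yields per frame a
*foreground mask* (|frame − background| → grayscale → threshold → morphological
opening) and a *movement mask* (the same pipeline on consecutive-frame
differences).

**Player trackers.** Each player hypothesis is a square box of physical height
2 m anchored at the feet, split into `NS = 4` horizontal subwindows. Per
subwindow a 1-D HSV histogram with `N_H·N_S + N_V = 10·10 + 10 = 110` bins is
compared to the calibration reference by the Bhattacharyya distance

    D = sqrt(1 − Σ_b sqrt(ĥ_ref,b · ĥ_hyp,b)),

and the per-subwindow scores `s_k = c(1 − D_k)` are combined as
`∏_{k<NS} s_k + s_NS` (upper subwindows tightly coupled, legs loosely). The
foreground and movement cues count non-zero mask pixels per subwindow,
normalized to the subwindow width. Each cue is normalized to the set's
per-frame maximum and mixed with `α_color = 1`, `α_mask = 0.4`, `α_mov = 0.1`.
Two trackers share this weighting:

* a classical **particle filter** (default 30 particles/player) with
  roulette-wheel resampling and two-tier Gaussian jitter — 0.2 m normally,
  0.04 m for particles within the top 0.1 % of the set's maximum weight;
* a **rigid-grid integral-histogram tracker**: fixed world-offset grid (e.g.
  3 particle rows × 5 or 11 columns) around the last estimate, scored through
  an integral histogram (any rectangle's histogram from four corner lookups,
  exactly equal to brute force) with a quadratic center-column bias.

Both use a confusion guard: two trackers sitting on the same spot for more
than 10 frames reset the one with the weaker color score.

**Ball.** Movement-mask blobs are gated by the expected pixel area of a 21 cm
ball at their court position and by a concentric-square isolation test
(40×40 inner window must hold > Q non-zero pixels; 60×60 outer at most
`inner + R`). Candidates feed two estimators built on the ballistic image
model `x(t) = m·t + b`, `y_height(t) = a₂t² + a₁t + a₀` with `a₂ < 0`:
*trajectory growth* (seed from ≤20 px collinear triples, predict/absorb with a
10 px gate, terminate after >3 missing frames, keep the best of time-parallel
tracks, extrapolate across gaps) and a *Hough-line* variant (remove candidates
near horizontal scatter lines, group the rest by probabilistic-Hough segments,
least-squares fit, join consistent neighbours). Contacts are the intersections
of consecutive height parabolas; the serve is the first trajectory's first
frame.

**Evaluation.** A player frame is correct within 0.5 m or 20 px, sampled every
3rd frame after all four players have been correct twice in a row, optionally
forgiving same-team identity swaps; ball frames are correct within 20 px;
contacts within (strictly) 10 frames.

**Synthetic scenes.** A seeded generator renders the whole study substrate —
textured sand, net, four banded-color players on waypoint paths, a ball on
gravity-consistent arcs between scheduled contacts, illumination steps,
spectator flicker — together with exact ground truth.

## Worked example

Track a synthetic four-player rally scene and score it:

```python
import numpy as np
import courttrack.synthetic_scene as ss
from courttrack.pipeline import TrackerConfig, track_players
from courttrack.evaluation import EvalConfig, player_accuracy
from courttrack.geometry import world_to_image

sc = ss.benchmark_players_scenario(seed=0)      # 340 frames, two crossings
frames, gt = ss.generate(sc)
h = sc.homography()
clicks = [world_to_image(h, p.position(45)) for p in sc.players]

tracks = track_players(frames, h, clicks,
                       TrackerConfig(method="grid", seed=0), calib_frame=45)
rep = player_accuracy(tracks, gt.players, EvalConfig(allow_team_swaps=True))
print(rep["front_avg_pct"], rep["back_avg_pct"], rep["evaluated_frames"])
```

prints

```
100.0 100.0 98
```

— on this clean synthetic scene the grid tracker holds all four players inside
the 0.5 m / 20 px correctness radius on every one of the 98 evaluated frames
(real match footage is far harder; the synthetic scene has no limbs, jumps or
lighting gradients). The same run with `method="particle"` scores 99.5 %.

Ball and contacts on a ball-only rally, through the full pixel pipeline
(movement mask → candidates → trajectory growth → parabola intersections):

```python
from courttrack.pipeline import BallConfig, track_ball
from courttrack.evaluation import contact_accuracy

sc = ss.rally_scenario(seed=2)                  # 6 ballistic arcs, 7 contacts
frames, gt = ss.generate(sc)
res = track_ball(frames, sc.homography(), BallConfig(method="growth"))
events = [e.frame for e in res["growth"]["contacts"]]
print(events, gt.contacts)
print(contact_accuracy(events, gt.contacts)["correct_contacts"])
```

```
[5, 8, 30, 53, 78, 86, 101, 130] [5, 29, 53, 77, 101, 125, 149]
6
```

— eight estimated events of which six match a true contact within the
10-frame correctness radius (the serve and five intersections; the final
scheduled contact ends the clip, so no following arc exists to intersect it).
The extra events at 8 and 86 come from arc fragments whose near-identical
parabolas intersect at unstable frames — the same failure mode the method
shows on real footage. On noiseless candidates (bypassing the pixel
detector) the six recoverable contacts are all found within one frame; run
`scripts/acceptance.py` to see both numbers computed fresh.

There is also a CLI (`courttrack synth | calibrate | track-players |
track-ball | eval`) operating on PNG frame directories or video files plus a
YAML calibration file.

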