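# Methods

## Setting and data model

The package analyzes one-on-one keyboard-based therapy sessions recorded as
three synchronized streams: (1) a per-frame 17-landmark skeleton of the
client in image pixel coordinates, as emitted by COCO-convention pose
estimators (flat `[x, y, score] × 17` arrays, origin top-left, y down);
(2) note events from the instrument's MIDI stream (note-on/off with
millisecond timestamps, read from a Standard MIDI File or a TSV table);
(3) mono audio, or pre-annotated silence intervals (Praat TextGrid / TSV).

The session clock is the video frame grid: frame *f* owns the half-open
window `[f·Δ, (f+1)·Δ)` ms with `Δ = 1000/fps` and the default 50 fps
(Δ = 20 ms). All intervals in the package are half-open and all frame
indices 0-based, so adjacent epochs never double-count a frame. Frames
where the tracked person is missing are emitted with zero confidence
rather than dropped, keeping the timeline dense for causal repair.

## Keypoint repair

Pose estimators occasionally misplace single joints for a frame. A joint at
frame *t* is replaced by its value at *t−1* (already repaired, so
consecutive dropouts chain-copy the last valid value) when either

* its confidence is below `score_min` (default 0.3), or
* its displacement from frame *t−1* exceeds `jump_threshold` × median
  shoulder width (default 1.0 per frame).

The scale-free jump criterion makes the same threshold work at any camera
distance. The first frame must be valid; a session whose first frame has no
confident joint raises a calibration error asking for a longer lead-in.
Note the rule is deliberately causal and therefore cannot distinguish a
genuine very fast movement from an estimator glitch; movements faster than
one shoulder width per 20 ms are treated as glitches.

## Stream synchronization

* **Playing.** Frame *f* is playing iff at least one note's
  `[onset, offset)` interval overlaps the frame window. A configurable
  `midi_offset_ms` (default 0) shifts the event clock onto the video clock;
  no drift model is applied. Frame/event overlap is computed in exact
  integer units of 1/fps ms, so boundary frames are unambiguous.
* **Silence.** When raw audio is supplied, windows of `silence_window_ms`
  (default 20 ms, one video frame) whose RMS level is below
  `silence_threshold_db` (default −40 dBFS) are silent; adjacent silent
  windows merge into epochs. Epochs shorter than `min_silence_ms`
  (default 100 ms, inclusive: a 100 ms epoch is retained) are discarded —
  short gaps between notes of slow playing still count toward silence only
  once they reach that length. A frame is silent iff at least half of its
  window is covered by a surviving epoch (majority coverage avoids double
  counting at epoch edges). Playing and silent can both be false on a
  frame — that is the talking state — and on audio rendered exactly from
  the notes no frame is both.

## Behavioral classifiers

All cutoffs live in `ClassifierThresholds` and are normalized by body
scale: shoulder width `w` = d(left_shoulder, right_shoulder), torso length
`h` = distance between shoulder midpoint and hip midpoint (session
medians).

* **Body pose** (sitting default / standing): the sitting baseline is the
  median hip-midpoint height over the first `calibration_s` seconds
  (default 10 s; sessions are assumed to start seated at the keyboard).
  Standing iff the hips are above baseline by more than
  `stand_rise_ratio·h` (default 0.5). "Walking away" is not distinguished
  from standing.
* **Self-touch**: a wrist within `touch_radius_ratio·w` (default 0.5) of
  any of nose/eyes/ears/shoulders → *head & upper torso*; else within the
  same radius of a hip or of the torso midpoint (mean of shoulders and
  hips) → *middle torso*; else none. The *while playing* sub-flag is the
  conjunction with the playing attribute — self-touch and playing hand are
  independent tracks, because a client can do both at once (one hand
  playing, the other touching), so no suppression is applied between them.
* **Playing hand**: on playing frames, hands whose wrist lies inside the
  configured keyboard span (a pixel x-range and y-band) are active; both →
  `both`, one → that hand. If neither wrist qualifies (keypoint failure),
  per-partition keyboard-occlusion flags — when the image-based estimator
  is used — vote for the same-side hand, and failing that the wrist nearest
  the span is taken, so playing frames always carry a hand. Non-playing
  frames are `not_playing` by definition.
* **Head pose**: the tilt is the signed angle between the ear-midpoint →
  nose vector and the image horizontal, positive when the nose is above
  the ear line; the horizontal distance enters as a magnitude so the sign
  does not depend on which way the client faces. Up iff tilt > +15°, down
  iff < −15°, else neutral. Head pose is evaluated on all frames,
  including while standing.
* **Torso pose**: defined only while playing with both hands (otherwise
  neutral, by definition): open iff elbow-spread / shoulder-width ≥ 1.8,
  closed iff ≤ 1.1.

The numeric cutoffs (±15°, 1.8/1.1, 0.5, 0.5) are package defaults chosen
to sit between the clearly-separated poses of the synthetic template (see
below) while remaining plausible for seated keyboard play; the attribute
*categories* are fixed, the cutoffs are configuration, and every summary
JSON echoes the configuration that produced it.

### Smoothing

Each attribute's label stream is smoothed independently: runs shorter than
`smooth_ms` (default 100 ms) are repeatedly absorbed into the longer of
their neighboring runs (shortest run first, earliest on ties; the
preceding neighbor on neighbor-length ties). Because independent smoothing
can break cross-attribute invariants, they are re-established afterwards
deterministically: `playing_hand = not_playing` exactly off playing frames
(orphaned playing frames take the hand of the nearest resolved frame),
torso open/closed is demoted to neutral off both-hand frames, and the
touch-while-playing flag is recomputed. The full invariant set is
re-validated on every frame after smoothing.

## Keyboard-image occlusion (optional stream)

When calibrated video frames are available, keyboard use is also estimated
photometrically: within a configured keyboard rectangle, the fraction of
pixels whose Chebyshev (max-channel) distance from pure white is ≤
`white_tolerance` (default 60/255) is computed per vertical partition
(default two: left/right keyboard half). The per-partition baseline is the
0.9 quantile of the fraction over the session; a partition is occluded when
its fraction drops below 80% of baseline (`drop_fraction` 0.2). Max-channel
distance was chosen because it is the simplest color proximity that is
provably monotone in the tolerance; the keyboard rectangle comes from
calibration configuration, not automatic detection.

## Session summaries and comparison

Category percentages are `100 × frames-in-category / n_frames`; within each
exhaustive attribute they sum to exactly 100 before rounding. Display
follows the conventions of per-session clinical tables: session cells round
half-up to integers, cross-session averages to one decimal; exact 0 and 100
print plainly while values in (0, 0.5) print `∼0` and values in (99.5, 100)
print `∼100` — the near-zero marker is deliberately distinct from exact
zero. Averages are computed on unrounded percentages and only displayed
rounded, so integer-printed sessions can still produce half-point averages
(37 and 30 → 33.5). After integer rounding an exhaustive attribute's cells
may sum to 100 ± k for k categories; this is a display artifact, not a
computation error.

## Session graphics

The timeline figure puts one horizontal track per attribute over a shared
abscissa in minutes, with the session percentages in the right margin and
optional numbered event annotations. SVG is the output of record: it is
assembled as a plain string with fixed number formatting, so identical
inputs produce byte-identical files, and each run is a `rect` tagged with
its track and category — tests re-parse the figure and check the run count
equals the label-run count of the state stream. PNG export (Pillow) is a
convenience raster. The palette is a fixed per-category mapping in
`GraphSpec`; track order defaults to the attribute-table order and is
configurable.

## The synthetic-session generator

The study's recordings are not publicly available, so correctness is
established on generated sessions with exact ground truth.

A `SessionScript` tiles the session with half-open, frame-grid-aligned
segments of constant state, validated against the same invariants the
classifier guarantees (torso open/closed requires both hands, self-touch
requires a free wrist, silent segments cannot play, every attribute run ≥
200 ms, scripted silences ≥ 100 ms, sessions start seated). The skeleton is
a seated 2D profile with shoulder width 100 px and torso length 150 px;
poses are placed on the far side of every classifier cutoff (head ±45° vs
±15°; elbow ratios 1.9/1.0 vs 1.8/1.1; standing rise 0.6 h vs 0.5 h; touch
contact 7 px vs 50 px radius), so default noise cannot flip a label.

Wrists move between stations (rest, keyboard, head, middle torso) along
fixed waypoint routes. Two properties of the routes make the generator a
sharp oracle:

* every per-frame step is ≤ ~0.76 shoulder widths, far enough below the
  repair jump threshold (1.0 w) that Gaussian jitter cannot fake an
  outlier; and
* travel frames are scheduled inside the *inactive* segment adjacent to
  each transition (approach ends exactly on the boundary frame; departure
  leaves the touch bubble / keyboard span on the boundary frame), so at
  zero noise the classified stream equals the script on 100% of frames.

Scripts must route a wrist through rest between two active stations; the
validator rejects direct active-to-active hops, and the layout builder
inserts the needed gaps automatically.

On top of the posed template the generator adds Gaussian jitter (default
std 0.02 shoulder widths per coordinate) and injects single-frame outlier
spikes (default 2 per 1000 frames, ±500 px per axis — seven shoulder
widths, well beyond three times the repair threshold) whose (frame, joint)
log supports exact precision/recall scoring of the repair stage. Note
events are one sustained note per playing run; audio is rendered at
8 kHz — pure tone at −12 dBFS during notes (only energy matters to the
silence detector), speech-band noise at −30 dBFS during scripted talking,
and a −80 dBFS floor during scripted silence. All randomness flows from the
script's seed; identical scripts produce byte-identical artifacts.

`build_script` lays out a session from percentage budgets
(largest-remainder rounding onto the frame grid, so realized fractions
match budgets to one frame): not-playing gaps alternate with one bout per
playing hand, silence fills the gaps front to back, touches and the
standing spell are centered inside gaps, and the while-playing head touch
sits inside the right-hand bout, touched by the left wrist.
`published_profile_script` instantiates the four published case-study session
profiles. Where the published integer table is internally inconsistent
(independent per-cell rounding), the profiles resolve it frame-exactly: the
playing total is the sum of the per-hand percentages, the no-self-touch
share is the residual of its attribute, and `∼0`/`∼100` cells are taken as
0.25 / 99.75.

What the generator does *not* emulate: real pose-estimator error structure
(correlated drift, left/right swaps, partial occlusion), camera
perspective, a moving therapist, expressive playing dynamics, or
reverberant audio. Passing the recovery tests therefore demonstrates that
the pipeline's geometry, synchronization and aggregation are correct under
the stated noise model — not that the default thresholds are clinically
validated on real video.

## Problem sizes and numerical choices

Tests and the acceptance script use 2-minute (6,000-frame) zero-noise and
5-minute (15,000-frame) default-noise sessions — large enough that every
scripted state appears with multi-second runs, small enough to keep the
suite fast; the pipeline itself is linear in frames and handles the
150,000-frame standard session. Percentages are exact rational counts over
frames; frame/interval overlap uses integer arithmetic in 1/fps-ms units;
medians are used for all calibration statistics (scale, baseline) for
robustness to outlier frames. Ties in smoothing resolve toward the earlier
run and the preceding neighbor, making the filter deterministic.

## Known limitations

* Client/therapist disambiguation is by explicit `person_id`; no automatic
  selection heuristic is provided.
* The causal repair freezes a joint that genuinely moves faster than the
  jump threshold; the threshold trades glitch rejection against fast-motion
  fidelity.
* The silence detector is energy-based and does not separate speech from
  music; "talking" is inferred only as non-playing, non-silent time.
* Head pose uses the 2D ear-nose geometry; extreme yaw toward the camera
  (dx → 0) degrades the tilt estimate.
* MIDI reading covers format 0/1 note streams with tempo maps; SMPTE
  division and exotic meta events are rejected rather than guessed.
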