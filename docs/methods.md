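# Methods

This note documents the models, numerical choices and open design decisions
behind `respmech`, and what the synthetic-data validation does and does not
establish about real laboratory data.

## Data model and units

Internally everything is SI-adjacent and fixed: marker positions in mm,
forces in N, moments in N·m about the plate origin, EMG in mV, COP/COM in m,
angles in degrees (radians internally), time in s. Axes: X anteroposterior,
Y mediolateral, Z vertical. Converters live only at the I/O boundary.
Kinematics are analyzed at 100 Hz (the camera rate); plate and EMG streams
stay at their native ≥1000 Hz until their derived quantities (COP ranges,
iEMG) are computed, to avoid interpolating moments and high-bandwidth EMG.
Streams sharing t = 0 are trimmed to their common duration; mismatches
above 5% are treated as acquisition errors, not silently clipped.

Marker tracking gaps are read as NaN, never repaired on read. Before
volumetry, gaps of ≤ 10 samples (0.1 s at 100 Hz) are bridged by cubic
interpolation; longer gaps invalidate the frame, which is excluded from
breath detection rather than imputed.

## Chest-wall volumetry

The trunk surface is modelled as R rings × C columns of markers (default
4 × 8; the three compartments split at the xiphoid and 10th-rib rings).
Each frame becomes a closed triangulated surface: lateral quads split into
two triangles, ring openings capped by centroid fans. The enclosed volume
is the signed-tetrahedron sum to the mesh centroid (divergence theorem) —
valid for the non-convex trunk shapes that occur during flexion, where a
convex hull would overestimate. A convex hull is used only as a *test
oracle* on convex fixtures.

Compartment additivity is structural, not numerical: adjacent bands share
their boundary ring, the two facing centroid caps cancel in the signed sum,
and the total is defined as the sum of the three band volumes. The suite
asserts additivity to 1e-9 L.

Degeneracy (self-intersecting rings after marker swaps, or inconsistent
ring orientation) is detected through the signed horizontal projection area
of each ring; such frames are flagged invalid, not raised, because single
corrupted frames should not kill a trial.

The "respiratory volume" passed downstream is the total-volume signal
relative to the first valid frame. Absolute trunk volume is carried but
not interpreted: the mesh encloses the marker shell, not the lungs, so only
volume *changes* are physiologically meaningful without spirometric
calibration (a known limitation; see below).

## Breath segmentation and timing

Detection runs on a zero-phase 4th-order Butterworth low-pass at 1.0 Hz —
well above breathing (~0.15–0.4 Hz), well below marker jitter. Peaks and
troughs are local extrema with prominence ≥ 0.2 × the robust amplitude
(p95 − p5 of the valid signal); the percentile scale keeps the threshold
stable when sway artefacts stretch the raw range. A record edge counts as
a trough only if it sits in the lowest quarter of the amplitude range, so a
breath cut mid-limb is dropped rather than half-counted.

Heavy smoothing drags the extremum of an asymmetric breath toward its
flatter limb (the inspiratory and expiratory limbs meet in a curvature
jump), which biases Ti/Te by several percent. Extremum times are therefore
refined on a lightly smoothed (3 Hz) twin of the signal by fitting a
two-sided parabola with a free corner location over a ±0.5 s window — the
structurally correct local model, which averages noise without the
asymmetry bias of a single-vertex fit. Volume *values* (tidal volume,
contributions) are still read from the 1 Hz-smoothed signal, whose
amplitude attenuation at breathing frequencies is negligible.

Compartment contributions are trough-to-peak excursion shares,
`100 · ΔV_k / ΔV_total`; they may legitimately be negative (paradoxical
compartment motion) and are renormalized to sum to exactly 100 to absorb
float residue. "Maximum respiratory volume" over a movement cycle is the
largest breath-wise tidal volume in that cycle — a windowed total-volume
range would conflate breathing with posture change; both interpretations
were considered and the per-breath one is exported.

## Posture kinematics

COP: `cop_x = −M_y/F_z + o_x`, `cop_y = M_x/F_z + o_y`, masked where
`F_z < 20 N` (the ratio is meaningless on an unloaded plate). COM: a
14-segment proportional model (standard adult male anthropometric mass and
COM-location fractions, shipped as editable YAML) applied to joint markers;
subject-specific models can be substituted by editing the YAML.

Joint angles decompose `R_proxᵀ R_dist` in the intrinsic X–Y–Z (flexion →
abduction → rotation) Cardan sequence, the dominant gait-analysis
convention; the source protocol names the planes but not the sequence, so
the sequence is a declared choice. Angles are unwrapped over time; frames
with the middle angle beyond 85° are flagged (gimbal proximity), not
raised. Segment frames come from three-marker triads via Gram–Schmidt.

Range statistics (ROM, COP displacement) are max − min over a movement
cycle, which *amplifies wide-band sensor noise*: the expected range of
white noise grows with the number of samples. Angle series are therefore
zero-phase low-passed at 2 Hz and COP at 10 Hz before windowing — both far
above the movement bandwidth of slow whole-body exercise (< 0.5 Hz), and
this is what brings ROM recovery under 1° at realistic jitter.

## EMG

Band-pass 20–450 Hz (zero-phase), mean removal, full-wave rectification,
trapezoidal integration over the movement cycle at the native rate — no
envelope smoothing before integration. Normalization divides by
(reference peak × cycle duration), making `iemg_norm` a duty-cycle-like
fraction comparable across cycles of different lengths; the reference
voluntary-contraction peak is a required input, never computed, because the
reference protocol is lab-specific.

## Respiration–COM coupling

Per movement cycle and axis, both signals are linearly detrended (cycles
contain large monotone COM excursions that would otherwise dominate),
standardized, and cross-correlated over lags |τ| ≤ 2 s (about one breath
period at slow rates). The headline statistic is `ccf = max_τ |r(τ)|` —
robust to the unknown phase relation between breathing and sway — with the
signed value, the lag, and the zero-lag correlation exported alongside for
sensitivity analysis, since the literature's choice is often unstated.
Ties in |r| (periodic signals match again half a period away) break toward
the smallest |lag|. Per-trial coupling is the mean over cycles.

## Group statistics

Per outcome: Shapiro–Wilk on both groups at α = 0.05 routes to a
pooled-variance independent t-test (the classical "independent samples
t-test"; Welch available behind a flag) or a Mann–Whitney U test. Exact
Mann–Whitney p-values (full null enumeration) are used when n₁·n₂ ≤ 64
without ties; otherwise the normal approximation with tie and continuity
corrections. Effect sizes: Hedges' g
(`s_p` with (n−1) weights, `J = 1 − 3/(4N−9)`, SE
`√((N)/(n₁n₂) + g²/(2N))`, CI `g ± 1.96·SE`; a noncentral-t CI is available
behind a flag) or rank-biserial `r = 2U/(n₁n₂) − 1` with a seeded 2000-
resample percentile bootstrap CI (no closed form is in common use).
q-values are Benjamini–Hochberg within an outcome *family* (movement ×
outcome category); the family structure is a declared choice, since
multiple defensible partitions exist. Significance is q < 0.05.
Descriptives follow the route: mean ± SD for t-routed outcomes, median
(IQR) otherwise.

The sample-size operation iterates per-group n upward until two-sided
noncentral-t power (noncentrality `d·√(n/2)`) reaches the target; at
d = 0.9, α = 0.05, power = 0.8 it returns 21 per group (42 total), and it
is cross-checked against `statsmodels`' power solver in the suite.

## Synthetic data: what it emulates, and what it does not

The generator is the package's validation substrate, a pure function of
(config, seed). Defaults describe one older-adult-like condition: 30 s
trials, 100 Hz kinematics, 1000 Hz plate/EMG; breathing at 15 breaths/min
with Ti/Te = 0.67 and 0.8 L tidal volume split (0.25, 0.45, 0.30) across
compartments (lower-thoracic dominant, as in diaphragmatic breathing);
centimetre-scale sway at ~0.1–0.2 Hz; three 10 s movement cycles with
hinge oscillations of 15–30° amplitude; 0.5 mm marker jitter (typical
optical residual), 0.5 mm COP noise, 0.01 mV EMG noise.

Key constructions:

* **Trunk**: 4 rings on an elliptic cylinder whose per-ring scale factors
  follow a raised-cosine breathing waveform (piecewise in Ti and Te, so
  timing asymmetry is explicit). Ring amplitudes are solved ring-by-ring in
  closed form (each band's excursion condition is a quadratic) so that band
  excursions hit the configured compartment weights exactly; band volumes
  follow the prismatoid formula `hA(s₀² + s₀s₁ + s₁²)/3` analytically, so
  volumetry is tested against closed form, never against itself.
* **Body**: articulated 14-segment stick body with marker triads on the
  lower limbs; joint angles are generated through the same Cardan
  convention the pipeline decomposes, making programmed ROM exactly
  recoverable. The root translation is solved so the segment-model COM
  equals the programmed target: `COM_X = (1−κ)·sway + κ·breathing drive`
  with κ ∈ [0, 1] — the dial the coupling statistic is validated against.
* **Plate/EMG**: `F_z = m(g + z̈_COM)`; moments are the COP equations run
  backwards from a COP tracking the COM projection, so COP inversion is an
  exact round trip at zero noise. EMG channels are 20–450 Hz noise
  carriers amplitude-modulated by raised-cosine bursts phase-locked to the
  movement cycles.
* **Cohort**: participant-level outcomes drawn normal (tidal volume
  log-normal, so both Shapiro–Wilk routes are exercised), with additive
  expert-group shifts programmed per outcome.

What passing recovery tests shows: the mesh, segmentation, angle, COP and
coupling code paths are correct and the estimators' noise behaviour is
understood at realistic jitter. What it does not show: robustness to soft-
tissue artefact, marker mislabeling, non-quasi-periodic breathing (apnea,
sighs, talking), stepping transients on the plates, or EMG crosstalk —
none of which the generator emulates. Conclusions about real cohorts still
require the usual lab QC.

## Problem sizes

The validation studies use 30 s trials (10 seeds) for parameter recovery,
a 5 × 10 κ-grid of 30 s single-cycle trials for the coupling sweep, 2000
simulated outcomes for the type-I-error check, and 21 + 21 participants for
the battery demonstrations — sizes chosen to make each check's sampling
noise small relative to its tolerance while keeping the full suite fast.

## Known limitations

* Mesh volume is a marker-shell volume; absolute values are not lung
  volumes, and no spirometric calibration is attempted.
* The exact marker topology of published 32-marker chest models varies by
  lab; the grid layout is fully configurable YAML for that reason, and the
  default rows/columns are a reasonable reconstruction, not a replica.
* Leg-role labels (leading/trailing/supporting) must come from the event
  table; the package does not infer them from kinematics.
* The Mann–Whitney bootstrap CI is percentile-based; coverage can dip for
  extreme effect sizes at small n.
* `synchronize` assumes hardware-synchronized streams sharing t = 0; it
  aligns time bases but does not estimate inter-stream offsets.
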