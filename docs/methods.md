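# Methods

## Physical model

A person moving in the static stray field of an MRI magnet is treated as an
extended non-ferromagnetic conductor. In the magnet's rest frame the induced
electric field in the moving body is the sum of the Lorentz electromotive
field **v** × **B** and the reaction electrostatic field from the charge
redistribution it drives. The reaction field opposes the electromotive
field, so neglecting it — as this package does — overestimates the net
induced field; every compliance verdict is therefore precautionary.
Physiological internal motion (blood flow etc.) is ignored. The
conversion-factor estimator Eᵢ = C·dB/dt used in ICNIRP guidance is a much
coarser surrogate; it is implemented (`exposure.icnirp_estimate`,
default C = 0.2 m, configurable) strictly for side-by-side comparison and
never enters a verdict.

### Stray field

The field outside the housing of a closed-bore magnet is modelled as a
single point dipole:

    B(r) = (mu0 / 4 pi) * [3 (m . rhat) rhat - m] / |r|^3

* `moment_magnitude` m — default 1.06×10⁶ A·m², the preliminary estimate
  for a 3.0 T closed-bore machine;
* `position` — (x0+Δx, y0+Δy, h); h = 1.0 m above the floor by default;
* `moment_axis` — unit vector; the magnet's architecture is unknown, so the
  default is horizontal along the bore axis (+y of the room frame),
  configurable.

Only the planar offsets (Δx, Δy) are treated as unknowns in the default
fit, with m and h fixed at the preliminaries; `refine_moment=True` adds the
moment magnitude as a third parameter. The fit minimises the sum of squared
(predicted − measured) |B| with Levenberg–Marquardt started at (0, 0)
(tolerances 1e-14); if that start stalls at high cost — possible when the
true dipole sits next to or inside the grid, where the objective is
multimodal — the best point of a coarse 13×13 grid over [−1.2, 1.2]² m
seeds a second run and the lower-cost solution wins. Fit quality is
reported as the Pearson correlation of predicted vs measured moduli
(delegated to `scipy.stats.pearsonr`).

A field map is |B| sampled on a planar grid replicated at three heights
(0.72, 1.19, 1.56 m). The exact planar arrangement of the original survey
is not recoverable, so the shipped default (`data/grid_layout.yaml`) is a
10×7 rectangular layout of 70 points that preserves the survey's two mesh
steps: 0.20 m close to the bore axis and couch side, 0.40 m elsewhere —
210 positions in total. Any other layout can be supplied as YAML.

### Exposure metric

For each frame t and each assessed point i,

    E[t, i] = | v_i(t) x B(p_i(t)) |   [V/m]

with B evaluated from the dipole model at the point's instantaneous
position (the model is continuous; no static room-map lookup). The
whole-body peak series is the per-frame max over all 23 points; the head
peak series the max over the 5 head points. Verdicts: health pass iff the
whole-body task peak is strictly below 1.1 V/m; sensory pass iff the head
task peak is strictly below 0.7/f V/m ("did not exceed" reads as a strict
comparison; margins are reported signed). Only these two printed rules are
implemented, not the Directive's full frequency-banded ELV table.

The motion-related frequency f is the spectral centroid of the
mean-removed, untapered periodogram (frequency resolution 1/T_task) of the
head peak-exposure series, over strictly positive frequencies up to
Nyquist. The choice of signal is configurable (any series can be passed);
the head exposure pulse is the default because the frequency adjusts the
sensory ELV applied to that same pulse.

## Body points and kinematics

The combined full-body protocol has 47 reflective markers; 6 of them
(medial femoral epicondyles, medial malleoli, medial humeral epicondyles)
are anatomical-calibration markers present only in a 1 s static double-leg
stance trial and excluded from dynamic processing. Eleven segments (head,
trunk, pelvis, thighs, tibias, feet, hands) each carry a cluster of ≥ 3
markers; the segment centroid is the per-frame arithmetic mean of its
cluster. Exposure is assessed at 23 points: the 11 centroids plus 12
individual markers (4 head, 4 trunk, 4 pelvis). The head subset used for
the sensory ELV is the head centroid plus the 4 head markers. The head
"centroid" is the mean of the four head markers — they are the head
cluster. No joint-centre regression or inverse kinematics is performed;
the 23 points need only marker positions.

Processing of a 100 Hz recording:

1. gaps (NaN runs) ≤ 10 frames are linearly interpolated, longer gaps are
   an error — laboratory-grade capture rarely drops more;
2. smoothing: 4th-order Butterworth low-pass at 6 Hz applied
   forward–backward (`sosfiltfilt`, zero phase). The original processing
   used Woltring's generalised cross-validated quintic spline; a smoothing
   spline whose penalty is set from the noise variance estimated via second
   differences is available as `method="spline"`. The 6 Hz band retains all
   gait-frequency content (stride rates here are ≤ 2.2 Hz);
3. velocities by central differences, first-order one-sided at the
   endpoints (recordings start and end at the room door, far from the
   magnet, so endpoint error is immaterial). The truncation error of
   central differences at 100 Hz is ω³/(6·10⁴) per unit amplitude — about
   4×10⁻³ m/s for a 1 Hz unit sinusoid.

## Synthetic study conditions

The generators reproduce the study's measurement conditions so the whole
chain is testable without the original recordings.

**Field maps** — |B| × (1 + ε), ε ~ N(0, σ²) with σ = 2% by default
(multiplicative because Hall-probe error scales with the reading), clipped
to keep readings positive, seeded.

**Operators** — three profiles: a 1.89 m / 115 kg male radiographer
(MRIR1), a 1.50 m / 49 kg female radiographer (MRIR2), a 1.72 m / 61 kg
male cleaner (MRIC). Segment geometry scales with stature.

**Room** — 4 × 6 m, right-handed frame, z up, origin at the map corner
nearest Door A; doors A (0.6, 0), B (3.4, 0), C (0, 3); magnet isocenter
at (2.0, 5.0), dipole height 1.0 m; bore axis +y. Scripted waypoints must
keep every body point at least 0.7 m from the dipole position (checked on
the realised markers; violation raises `ScriptError`).

**Task scripts** — N1–N3/E1–E3 (enter, reach the control panel or bore,
leave by door A/B/C), N4 (place the head coil at the couch), N5/N6 (bend
next to the bore), E4 (emergency couch extraction), C1/C2 (cleaner
sweeping/mopping serpentine). Walking speed follows a smoothstep envelope
of distance-to-magnet between v_near (0.3 m/s at ≤ 1.3 m) and v_far
(≥ 3 m): 1.5 m/s for normal radiographer tasks, 1.7 m/s for emergencies,
0.8 m/s for the cleaner — producing the U-shaped speed profile (fast at the
doors, slowest at nearest approach).

**Limb model** — feet and hands oscillate about the pelvis with gait phase
φ, dφ/dt = 2π f_stride, f_stride = min(0.9·v + 0.6, 2.2) Hz. Swing
amplitudes are set so the peak extra speed is min(g·v, 0.93·cap − v) with
gains g = 1.8 (feet) and 1.1 (hands): foot speeds approach but respect
5 m/s at brisk walking, hands 3.5 m/s. The body heading slews at ≤ 2 rad/s
and the head segment follows a slower 1 rad/s heading frame (heads
stabilise in space during locomotion), which keeps head-marker speeds below
2 m/s for radiographers and 1 m/s for the cleaner through the full
pipeline. Bending lowers the head to 0.92 m over a 3 s cosine ramp
(descent < 1.2 m/s). Every marker gets seeded Gaussian noise, SD 2 mm.
These are fixture properties chosen to reproduce the reported speed
envelopes — not a validated gait model: no ground contact, no skin-motion
artifact, no marker occlusion beyond short gaps, sinusoidal rather than
ballistic swing. Passing tests therefore demonstrate the pipeline's
correctness under realistic magnitudes and spectra, not claims about human
biomechanics.

## Numerical choices and degenerate inputs

* Field evaluation at the dipole position raises `SingularFieldError`
  (guard |r| < 1e-12 m).
* Pearson correlation requires length ≥ 2 and nonzero variance in both
  series.
* `smooth` needs ≥ 7 frames; `filtfilt` padding is capped at n − 1 frames.
* The spectral centroid needs ≥ 16 samples and nonzero power after mean
  removal.
* Grid generation orders positions row-major by planar index, heights
  ascending; frames and records are 0-indexed.
* Fits and generators accept any seed; all randomness flows through
  `numpy.random.default_rng`, and the CLI derives per-trial seeds
  deterministically from the base seed, recorded in the run manifest.

## Problem sizes

Default analysis sizes: 210-record maps; task recordings of 10–21 s
(1000–2100 frames) at 100 Hz with 41 dynamic markers; 20-seed fit-recovery
ensembles; 10-seed per-task compliance sweeps. These match the scale of the
original study (210 field measures, task executions of tens of seconds)
while keeping a full test run under a minute.

## Known limitations

* A single point dipole cannot represent shielding or soft-iron effects;
  multi-dipole or harmonic-expansion models are out of scope.
* The reaction electrostatic field and tissue-level dosimetry are not
  modelled; results are upper bounds on the induced field.
* C3D input requires the optional `ezc3d` dependency; TRC and the internal
  CSV dialect are supported natively.
* The exact planar geometry of the original 70-point survey and the exact
  door-to-panel paths are not published; both are configurable defaults
  here, so fitted offsets and exposure traces are comparable in magnitude,
  not point-for-point.
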