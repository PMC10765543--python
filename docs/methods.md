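# Methods

This note documents the models, parameter choices and numerical decisions
behind `sdrmap`, and what the synthetic study arms can and cannot show about
real recordings.

## Lattice model

The mapping array is a lattice of plunge needles with four unipolar
electrodes each (4 mm apart along the needle; ~1 cm between needles), spread
over the RV free wall, LV free wall and septum on up to six base-to-apex
levels. The published description of the preparation gives the totals
(56 needles, 224 electrodes, six levels) but not per-wall counts, so the
default allocation is a package choice: LV 6 levels × 4 columns (24), RV
5 levels × 4 columns (20), septum 6 levels × 2 columns (12). Any other
allocation can be supplied as a geometry JSON; all statistics depend only on
adjacency.

Adjacency conventions, which are genuinely open choices:

- The free walls are circumferential rings, so horizontal adjacency wraps
  within the RV and LV; the septum is a bounded sheet and never wraps. A
  two-column ring is treated as a two-edge ring when *enumerating* pairs;
  dispersion units are deduplicated by their unordered needle set, so no
  unit is ever counted twice.
- Squares are 2×2 blocks (levels l, l+1 × columns c, c+1 with wrap); no unit
  crosses a wall boundary, because inter-wall distances are not lattice
  edges.
- `depth_index` 0 is epicardial (needles enter from outside); this affects
  labeling only.

## Dispersion statistics

A unit's value is max RT − min RT over its accepted electrodes; the
per-orientation SDR is the unweighted mean over units. With missing data a
needle contributes only when ≥ 2 of its 4 electrodes survived QC, and a unit
is kept only when every member needle contributes (≥ 4 electrodes for pair
units, ≥ 8 for cubic); below that the unit is dropped, never imputed, which
avoids imputation bias at the cost of fewer units. An orientation with no
eligible units reports an explicit empty result rather than zero. SDR is
computed on uncorrected RT at the block's fixed paced cycle length; the polar
maps can optionally show Van de Water-corrected RTc, which at a fixed RR is a
constant shift and provably leaves every dispersion value and ΔRT annotation
unchanged. dRT is the difference of wall means (LV − RV) over accepted
electrodes, septum excluded; the alternative (mean of paired differences) is
not used because needles are not paired across ventricles.

Whether the original analysis excluded single channels or whole needles is
ambiguous; both modes exist (`qc_mode="channel"` default, `"needle"` drops a
needle when ≥ 2 of its channels fail).

## Synthetic electrograms

The generator's job is exact, machine-readable truth, not visual realism.
A clean channel is a sum of logistic sigmoids: a biphasic R/S complex whose
steepest negative slope is analytically at AT (R amplitude 2 mV, S 5 mV,
2 ms width, with a slower 8 ms recovery returning the ST baseline to zero),
and a 2 mV rising T sigmoid of width 15 ms whose steepest positive slope is
analytically at RT. Neighbouring deflections perturb the extrema by well
under one sample at 2048 Hz. Corruptions: injury current adds a smooth
ST–TQ baseline step of `injury_fraction` × T amplitude; flat-T scales the T
wave to 2 %; noisy adds 0.6 mV RMS white noise; cavity replaces the trace
with a 0.4 mV monophasic QS and vestigial T. The classes are constructed to
be separable — QC sensitivity/specificity tests certify the decision rules
on these constructions, not performance on borderline clinical traces.

Repolarization fields follow a linear restitution law per wall,
RT = α_wall + β_wall·RR, with defaults β_LV = 0.10, β_RV = 0.04 ms/ms
(septum midway), over the simulated 600–1200 ms RR range; four rate points
cannot constrain more than a line, and linearity gives closed-form checks
(e.g. raising RR by 400 ms widens the LV−RV difference by exactly
0.06 × 400 = 24 ms). Apicobasal and transmural gradients are *centered*
within each wall so wall means stay at α + β·RR regardless of gradient
settings. Extreme noise tails are clamped to RT ≥ AT + 120 ms — a
physiological floor, since repolarization cannot precede activation.
Activation times follow a paced-RVA template (apex earliest; wall means
RV ≈ 40, LV ≈ 60, septum ≈ 50 ms, SD 5 ms).

### Study-arm presets and the dispersion inversion

Each protocol timepoint (EB, pre-TdP, RVA100, RVA80, RVA60, plus a
retrospective RVA60 arm) is a preset fixing RR, QT, wall AT/RT means and a
target mean cubic dispersion, taken from the serial group means of the
emulated experiments. No source states a per-electrode noise SD, so it is
obtained by inversion: deterministic gradients are pinned to a small fraction
of the cubic target (5 % per level apicobasal, 3 % per depth transmural, so
noise dominates), and the noise SD is solved by Brent bisection on the
Monte-Carlo expected cubic dispersion (24 internal seeds, 0.01 ms tolerance).
The bracket [0, target] always contains the root because the range of 16
i.i.d. normals grows like ~3.5 σ. Realized cubic dispersion lands within a
few percent of the target; the other three orientations follow from the
common noise field rather than being matched independently, so their levels
are internally consistent but not tuned to any external value.

## Fiducial detection

AT is the argmin of the first difference of the signal after a 5 ms moving
average, within the QRS window ([0, 150] ms after the stimulus by default);
a three-point parabolic interpolation gives sub-sample resolution. The
shallow T-wave upslope needs a matched estimator: within the T window
((150, 0.9·RR] ms by default) the derivative is a central difference over a
50 ms span — of the order of the T upslope duration — further smoothed with
a 70 ms moving average. Both kernels are symmetric, so the extremum of a
symmetric upslope is not displaced. Because the heavily smoothed
QRS-recovery upslope can leak past the nominal T-window start, the T search
never begins earlier than AT + 120 ms (the same refractory floor the
generator enforces). With these defaults the detector recovers AT within
1 ms RMSE and RT within 2 ms RMSE on clean channels at 20 dB SNR; all widths
are configurable, and wider T kernels trade robustness against QRS leakage.

Channel QC metrics: injury = |median(ST) − median(TQ)| / peak-to-peak T
amplitude, with ST sampled 80–120 ms after the detected AT and TQ in the
last 100 ms before QRS onset (the 80 % rejection ratio is the protocol's;
the segment placement is an operationalization); flat-T = T-window
peak-to-peak below 0.15 mV; noise = median absolute sample-to-sample
difference over peak-to-peak amplitude above 0.01; cavity = negative
excursion fraction of the QRS above 0.9 with QRS amplitude below 1.5 mV.
Checks run in the order noise → cavity → flat-T → injury (the injury ratio
is meaningless on a flat T), and every channel always receives a label.

## Rhythm model

Beat streams are annotation-level: strictly periodic paced beats at
60000/rate ms, isolated ectopy as an independent Bernoulli draw per paced
slot (coupled at 55 % of the cycle, so singles never form consecutive runs),
and scripted episodes that suppress pacing capture and lay down a run of
consecutive ectopic beats. "Twisting" is surrogate: the morphology index
alternates in sign within polymorphic runs and holds constant in monomorphic
ones — an operationalization that gives the polymorphy criterion something
objective, not a claim about how twisting is adjudicated clinically.
Episodes longer than 10 s must script ≥ 1 defibrillation; defibrillation
events are attributed to the episode they fall in or the nearest episode that
ended within the preceding 5 s. A self-terminating run of ≥ 50 beats would
collide with the defibrillation score codes; the score is capped at 49 with
a warning. The severity ordering for "most severe episode per block" (any
defibrillated > any self-terminating, then defibrillation count, then beat
count) is implied by the score construction but is an assumption.

The default protocol is RVA50 for 6 min carrying the proarrhythmic challenge
(ectopy hazard 0.87 per slot ≈ 87 ectopic beats in the 2 min before the TdP;
one sustained 12 s TdP with one cardioversion at t = 300 s), then 2 min each
of RVA100/80/60 with hazards 0.02/0.05/0.28 and a 25 % per-block TdP
recurrence probability at the two slower rates, drawn reproducibly from the
run seed.

## Surface lead and intervals

The lead-II surrogate renders each beat as a piecewise-linear R/S complex
with a sharp onset at the beat time and a half-sine T wave ending exactly
QT later; it is noiseless, so interval error is purely algorithmic (QRS
onsets by R-peak walk-back, T end by last supra-threshold sample; measured
QT is within ~2 ms of truth). RR and QT are averaged over five consecutive
beats and QTc attached via the Van de Water correction (coefficient
0.087 ms/ms around RR = 1000 ms). Tables round half-up to 1 ms; full
precision is kept internally.

## Pipeline scale and determinism

Per timepoint the pipeline synthesizes one analysis beat window per channel
(224 channels × one cycle at 2048 Hz) rather than continuous multi-minute
recordings, and the surface lead only as six-beat segments; rhythm streams
stay annotation-level. These sizes keep a full run around a second while
exercising every analysis path at the full channel count. All randomness
derives from one master seed through named seed-sequence children, so a
fixed config yields byte-identical summary tables; a `synthesize_signals=False`
mode analyses truth fields directly (skipping waveform synthesis and
detection) for multi-seed calibration studies.

## Limitations

The generator contains no biophysics: no ion-channel or reaction–diffusion
model, no dofetilide pharmacokinetics, no mechanistic link from dispersion to
ectopy — arrhythmia incidence is scripted, not emergent, so passing tests
certify the *analysis* (detection, rejection rules, unit statistics, scoring
arithmetic, curve fits), not any claim that HRP would reduce dispersion in a
new animal. Short-term variability of repolarization is out of scope, as is
inferential statistics across animals (descriptive summaries only), TdP
origin localization, 3-D anatomical reconstruction, and EDF export (signals
interchange as wide CSV).
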