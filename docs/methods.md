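# Methods

This note documents the models inside `pwvest`: what is simulated, which
assumptions are made, what the tunable parameters mean, and where the
design was genuinely open.

## 1. Arterial-tree model

The simulator is a reduced systemic arterial tree with 13 elastic segments:
the aorta in five pieces (ascending, two arch pieces flanking the carotid
origin, thoracic, abdominal), the left iliac and femoral arteries, the left
common carotid, the left subclavian/brachial/radial chain, and two lumped
side branches (right-side brachiocephalic circulation, visceral bed). It is
the smallest topology that contains the five clinical measurement sites
(aortic root, left carotid, brachial, radial, femoral) with distinct
carotid→femoral and carotid→radial transmission paths.

Each segment is a uniform lossy transmission line characterized by length
`L` [m], lumen area `A` [m²] and area compliance `C_A` [m²/Pa]; the pulse
wave speed is `c = √(A/(ρ·C_A))` and the characteristic impedance
`Z_c = ρc/A`, with blood density ρ = 1050 kg/m³. Per unit length the line
has inertance `ρ/A`, Poiseuille resistance `8πμ/A²`, and compliance `C_A`
multiplied by a viscoelastic wall factor `(1 − i·a)²`, giving the
propagation constant `γ = √(z·y)`. Two loss parameters:

* `wall_damping a` (default **0.15**, dimensionless): each harmonic decays
  by `exp(−a·ω·x/c)` at unchanged phase velocity. This mimics viscoelastic
  wall dissipation. Without it, a 13-segment tree exhibits strong intra-beat
  ringing: the original, much finer discretizations of the arterial tree
  obtain smooth waveforms from gradual tapering and wall viscoelasticity
  that a reduced topology cannot provide.
* `viscosity μ` (default **0.02 Pa·s**): an *effective* viscosity, about
  five times the physical value of blood, absorbing the omitted
  Womersley-profile and three-dimensional losses. Its main role is to damp
  slow reflected components in the small distal vessels, which otherwise
  corrupt the diastolic baseline that the foot-detection algorithm relies
  on.

Terminal beds are two-element Windkessels `Z_T(ω) = R/(1 + iωRC)`; the
total peripheral resistance is split over the five beds by regional flow
fractions (visceral 48%, leg 20%, right-side 15%, head 10%, left arm 7%),
and a lumped peripheral compliance pool (0.15 mL/mmHg at baseline) is split
the same way.

The heart is an imposed periodic inflow at the aortic root. The default
ejection wave is a two-phase half-cosine (fast rise over the first 20% of
ejection, slower fall), which reproduces the rapid acceleration of
ventricular outflow; plain half-sine and triangular shapes are available.
A half-sine onset proved too gradual for reliable tangent-method foot
detection. Ejection duration is `0.33·√T` seconds for period `T`, and the
wave integrates exactly to the prescribed stroke volume.

### Solver

The tree is solved per harmonic in the frequency domain: terminal
impedances are transformed through each line
(`Z_in = Z_c (Z_L cosh γL + Z_c sinh γL)/(Z_c cosh γL + Z_L sinh γL)`)
and combined in parallel at junctions, from the leaves to the root; the
inflow spectrum then fixes the root pressure, and forward/backward wave
amplitudes are propagated back down to evaluate pressure at arbitrary
positions. The DC harmonic is a resistive network (segment Poiseuille
resistance in series, terminal R at the leaves), which sets mean-pressure
gradients and the flow split. Defaults: 40 harmonics retained (minimum 20),
1 kHz sampling. This yields the periodic steady state directly — there is
no transient — and costs ~2 ms per subject.

Two exact limits anchor the solver: with losses off and a matched load
(`Z_L = Z_c`) the input impedance equals `Z_c = ρc/A = √(ρ/(A·C_A))` — the
water-hammer relation — identically at every frequency; and with zero wave
number the network reduces to Ohm's law. An independent time-domain
integration of the same network (inertance-compliance ladder, symplectic
Euler) agrees with the frequency-domain pressures within 5% and serves as
the cross-check in the test suite.

## 2. Virtual cohort

One subject = one random parameterization of the tree plus an inflow:

| parameter | distribution | default |
|---|---|---|
| heart rate | N(73.26, 14.9²) bpm, bounded [40, 120] | Table-level mean/SD |
| stroke volume | N(81.18, 8.03²) mL | — |
| geometry scale g | N(1, 0.02²); lengths ×g, areas ×g² | body-size variation |
| compliance scale κ | N(1, 0.25²); all C_A and terminal C | elastic-state variation |
| resistance scale | N(1, 0.14²); terminal R | vasomotor variation |
| per-segment compliance jitter | N(1, 0.02²) | local heterogeneity |
| per-segment length jitter | N(1, 0.03²) | anatomical variation |

Non-physical draws are redrawn (the count is reported). Hypertensive
subjects (default mix 50/50, configurable — the class composition of the
reference population is not published) additionally apply a
proximal-to-distal aortic stiffening gradient (compliance × 0.50 at the
ascending aorta grading to × 0.68 at the abdominal aorta), a milder uniform
peripheral stiffening (× 0.70), with subject-level severity jitter
N(1, 0.25²). Hypertension is modelled as predominantly a stiffening
phenotype; the hypertensive resistance increase is left at 1.0 by default
because mean-pressure elevation otherwise cancels the diastolic-decay
signature of compliance in brachial DBP.

Every candidate subject is solved, summarized (brachial SBP/DBP/MAP/PP,
aortic SBP/DBP/PP, tangent-method cfPWV and crPWV, analytic Z_ao and C_T,
TPR = mean aortic pressure / cardiac output), and screened: all seven
pressure quantities must lie within mean ± 2.807 SD (the 99.5% band) of the
class reference ranges (`ReferenceBPRanges`, user-configurable). The
default reference means/SDs are set to normative normotensive and clinic
hypertensive values and calibrated — together with the baseline tree —
so that the *accepted* mixed cohort reproduces the target population
summaries (brachial SBP ≈ 134.5 mmHg, MAP ≈ 94.5, Z_ao ≈ 0.056 mmHg·s/mL,
C_T ≈ 1.14 mL/mmHg, cfPWV ≈ 8.06 m/s, crPWV ≈ 10.2 m/s). Acceptance runs
at ~85%; generation of 3,818 subjects takes ~10 s on one CPU.

Calibration notes:

* Foot-to-foot transit time is the *difference of arrival times* at the two
  sites, so the common path from the heart to the carotid subtracts, while
  the conventional travel length sums the full tree path through the
  junction. The effective regional PWV is therefore systematically higher
  than any segment wave speed; the baseline speeds were chosen against this
  convention (the subtracted-length convention is available as
  `travel_length` of the sub-paths).
* The reduced damped tree does not produce brachial-over-aortic pulse
  amplification; aortic pulse pressure consequently runs ~25% above the
  reference value, with brachial pressures on target. Amplification
  requires the fine tapering and nonlinear steepening that the reduced
  linear tree deliberately omits.

## 3. Feature extraction and noise

The wave **foot** is the intersection of the tangent at the maximum
systolic upstroke slope with the horizontal line through the waveform
minimum. The slope maximum is searched on the upstroke only (minimum to
peak, unwrapped across the periodic beat boundary), on a 5-point smoothed
derivative, with sub-sample quadratic refinement. Feet are phases of a
periodic signal: if the distal foot precedes the proximal one within the
beat, one period is added. On the simulator's waveforms the detected
transits track the true arrival-time differences with r > 0.99 (residual
< 2 ms).

PWV = path length / transit time; brachial SBP/DBP/MAP are the waveform
extremes and time average; HR is taken from the known simulation period
(single-beat waveforms). The dicrotic notch is the first local pressure
minimum after the systolic peak within [0.2, 0.6]·T, with fallback to the
flow zero crossing.

**Measurement noise** multiplies every regression variable — inputs and,
by default, both targets — by an independent factor `1 + e`,
`e ~ U[−0.15, +0.15]`, drawn per subject and per variable. A −6% draw, for
example, multiplies the value by 0.94. For the classical methods, one
factor scales the whole pressure signal and another the whole flow signal
(shape preserved).

## 4. Estimators

* **Random forest**: 100 trees, `max_depth` tuned on the validation split
  over [1, 10] by the coefficient of determination; ties resolve to the
  smallest depth. Prediction is the mean of the trees.
* **Network**: one hidden layer of 16 rectified-linear units, linear
  output, Adam, batch size 10, mean-squared-error loss; features and target
  min-max scaled to [0, 1] on the training partition; the epoch count is
  chosen by early stopping on validation MSE with patience 10 (cap 300),
  restoring the best-epoch weights. Hidden width and patience are package
  choices (16 is the smallest width at which accuracy saturates on this
  generator).
* Split 60/20/20 (3,818 → exactly 2,290/764/764); the scaler is fit on the
  training partition only.
* Input configurations M1 (brSBP, brDBP, HR, cfPWV, crPWV), M2 (= M1 − HR),
  M3 (MAP, cfPWV, crPWV), M4 (cfPWV, crPWV), plus a single-input cfPWV
  baseline.
* Diagnostics: permutation importance (20 shuffles per feature on the test
  set, mean ± SD of the RMSE increase), learning curves (1–95% of the
  training set in 20 steps), and training-size sensitivity (99% down to 1%,
  fixed test set).

Classical comparators (central pressure + flow): Z_ao by P′max/Q′max
(central differences, no smoothing) and by (P@Qmax − DBP)/Qmax; C_T by the
monoexponential diastolic decay (window from notch + 10% of diastole to
end-diastole; τ/R) and by the pulse-pressure method (bisection on the C of
a two-element Windkessel, integrated with an exact exponential step to
periodic steady state — 20 beats or ΔPP < 10⁻⁶ — tolerance 10⁻⁴ mL/mmHg,
bracket [0.01, 10]). R = mean pressure / mean flow with venous pressure
neglected.

## 5. Evaluation

`nRMSE = 100·RMSE/(max−min)` of the reference variable; Bland-Altman bias ±
1.96·sample SD (n−1) of the differences; Pearson r; least-squares
prediction-on-truth line with the two-sided Wald t-test for zero slope.
nRMSE is invariant to a common affine rescaling of both series.

## 6. What the synthetic data do and do not show

The generator emulates a population of linearized, periodically beating
arterial trees with exact analytic ground truth. It does **not** contain:
nonlinear pressure-dependent compliance within the beat, ventricular-
arterial coupling (the inflow is imposed), peripheral amplification,
beat-to-beat variability, or tonometry artifacts (drift, hysteresis).
Passing tests therefore demonstrate the internal consistency of the method
chain — simulation → feature extraction → regression → agreement analysis —
under a controlled noise model, not clinical validity.

Two structural consequences are worth stating explicitly because the test
suite measures them:

* **Accuracy floor.** With per-subject ±15% uniform noise on both inputs
  and targets, the achievable test nRMSE is bounded below by the target
  noise (~4.5–6.5% of the reference range alone) plus the input-noise
  attenuation of the two informative PWV features. On this generator the
  floor is ≈9% for Z_ao and ≈7% for C_T: quadrupling the training set
  moves accuracy only to that level, and clean-data models reach r ≥ 0.97.
  Published accuracies for this estimator class that lie below such a floor
  are consistent with noise applied per *variable* (one factor per column,
  which leaves correlations and learnable structure intact) rather than per
  subject; this package implements the stricter per-subject model.
* **Feature importances.** In this reduced tree the PWVs dominate the
  learned predictors and brachial DBP is a weak feature (|r| ≈ 0.2 with the
  targets): the class-level stiffening acts jointly on pulse pressure and
  decay rate, so DBP retains little independent compliance information.
  Richer models with stronger BP-compliance coupling report brachial DBP as
  the dominant feature; the input-configuration ordering M1 ≥ M2 ≥ M3 ≥ M4
  and the minimal importance of heart rate reproduce here, the DBP
  dominance does not.

## 7. Numerical choices and degenerate inputs

* Harmonic truncation at 40 harmonics (spectra of the smooth inflow decay
  fast); sampling 1 kHz; both configurable.
* Foot detection refuses waveforms without a positive upstroke slope; PWV
  computation refuses zero/negative transit after unwrapping.
* The solver raises a subject-labelled error on non-positive pressures
  (extreme parameter draws); the cohort generator counts these as
  rejections and aborts if overall acceptance falls below 1%.
* Scalers refuse zero-range features; the network refuses a constant
  training target; evaluation reports are omitted (None) when the test
  target is degenerate.
* All randomness flows from explicit integer seeds (cohort, noise, split,
  model, permutation); the forest pipeline is reproducible bit-for-bit.
* Problem sizes in the test suite: unit tests run on tubes, closed-form
  waveforms and cohorts of 60–120 subjects; the study-level checks run one
  3,818-subject cohort and the M1 model grid, ~3 minutes total on one CPU.
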