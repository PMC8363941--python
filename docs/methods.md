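# Methods

This note documents the models, numerical choices and limitations of the
package: what the synthetic generator emulates, how each analysis stage is
defined, and what passing tests do and do not establish about real data.

## Synthetic data generator

### Design

`design.generate_design` produces a balanced table over the four
conditions (*what+when*, *when*, *what*, *random*); per condition,
`n_per_condition` trials split 50/50 on target orientation (horizontal =
0°, vertical = 90°) crossed with 50/50 on target spatial frequency
(60 vs 20 cycles/degree; entrainers fixed at 40 cpd), hence the
divisible-by-4 precondition. Rotation steps are drawn per trial from
{±15°, ±30°}. Orientation-predictable sequences start at
`target − 4·step` so that the four entrainers extrapolate exactly to the
target; shuffled sequences permute those same four angles, rejecting the
sorted order so the sequence is never accidentally predictable.

Timing: every stimulus lasts 200 ms; fixed gaps are 200/200/200/600 ms;
jittered gaps are uniform on 70–330 ms (entrainers) and 370–850 ms
(target), quantised to 1 ms. The quantisation mirrors a presentation
clock, keeps stimulus onsets on exact samples of a 1 kHz recording (so
stimulus-locked epochs align bit-exactly across jittered trials), and
leaves the mean gap at 200 ms. The fixation period before E1 is 500 ms —
a value the design needed but that only shifts the time axis.

### Sensors and forward model

The helmet is a deterministic Fibonacci lattice of sites on a spherical
cap (radius 102 mm, half-angle 2.1 rad) around a 90 mm head sphere; each
site carries a radial magnetometer and two orthogonal planar gradiometers
(16.8 mm baseline, evaluated as a two-point finite difference of the
radial field projection). Only the topology of the array matters for the
statistics, not the exact helmet geometry. Site adjacency connects sites
closer than 4 cm at the 102-site density (mean degree ≈ 5); reduced
arrays used in tests scale the radius to preserve that degree, since the
≥2-neighbour cluster rule is meaningless on a disconnected graph.

Fields are computed with the analytic current-dipole-in-a-sphere solution
(Sarvas). Two properties anchor the tests: a radial dipole produces no
external field, and the radial field component equals the free-space
dipole term. The same forward code serves the simulator and the
beamformer — an inverse crime we accept deliberately, because the tests
probe the analysis chain, not forward-model mismatch.

### Effect structure

Each stimulus adds a Gaussian-windowed waveform (peak 100 ms after onset,
SD 15 ms) radiating from an occipital dipole at (0, −65, 5) mm with
moment `base_amplitude` = 50 nAm. In orientation-predictable conditions
the moment follows `1 − (k−1)·s` across entrainers with `s = 0.15`
(so E4/E1 = 0.55), times an extra factor `1 − 0.15` at E4 when timing is
jittered — expectation suppression, strengthened by temporal uncertainty.
The suppression acts multiplicatively so the two fractions compose
without ever crossing zero.

Orientation information is a second, nearby dipole whose moment sign
follows the target class and whose magnitude is
`ρ_k · base_amplitude`, with ρ = (0.01, 0.02, 0.05, 0.08) across
entrainers, 0.12 at the target — injected **only** when orientation is
predictable, so decodable information grows across entrainers exactly in
the conditions where the design permits expectations. A third dipole
carries the spatial-frequency class at the target in all conditions
(0.2·base), since the frequency judgement is the task everywhere. The ρ
schedule was chosen so that a small cohort (8 participants, 40
trials/condition) still shows the growth of decodable information across
entrainers while early entrainers stay near chance; because accuracy of
pseudo-trial-averaged SVM decoding is a steep function of pattern SNR,
full-scale runs (160 trials, bins of 10) saturate late entrainers above
the 60–80 % range a real study reports. No single schedule places both
scales mid-range; we prioritised the scale at which the package's own
studies run.

### Noise

Sensor noise is Gaussian with stationary SD 200 fT (magnetometers;
gradiometers scaled ×20 to the T/m range), spatially correlated with
`0.8·exp(−d/3 cm) + 0.2·I` across channels (the 20 % nugget keeps the
covariance full-rank even for co-located channels) and AR(1) in time with
coefficient 0.95 at 1 kHz (≈ 20 ms correlation time). Noise is generated
in trial chunks to bound memory. There is **no between-participant
variability**: participants differ only in design randomisation and noise
seed. Consequently group-level error terms are purely measurement noise,
and even tiny injected effects become statistically significant with
enough trials — see the ANOVA remarks below.

What the generator does *not* emulate: eye/cardiac artifacts, head
movement, 1/f spectra, between-subject anatomy or amplitude variability,
behavioural responses. Passing tests therefore validate the *analysis
machinery* (calibration, recovery, contracts), not robustness to real
artifacts — which the real-data preprocessing steps (tSSS, ICA) exist to
handle and which are out of scope here.

## ERF analysis

Continuous per-trial recordings (−400 ms pre-fixation to +400 ms
post-target) are band-passed 0.5–45 Hz with a 4th-order zero-phase
Butterworth (filter family/order are our choice; zero-phase doubles the
effective order). A single per-trial baseline — the mean over the 400 ms
before fixation — is subtracted from the whole trial, so all five
stimulus-locked epochs of a trial share one baseline. Epoch windows:
−50..270 ms for E1–E4 (270 ms is the shortest jittered SOA, so windows
never contain the next stimulus), −50..600 ms for E4 where the long
target gap allows, −400..550 ms for the target.

Planar pairs combine as the Euclidean norm per time point; the result is
nonnegative and rotation-invariant within a pair. Amplitude readout
averages the five combined channels with the strongest localizer response
(peak in 85–135 ms; ties broken lexicographically) and takes the window
**peak** by default (`mean` is available).

Note that the combined-planar norm is noise-biased (Rician): with 40-trial
averages the bias is common to all conditions and cancels in paired
contrasts.

## Statistics

### Repeated-measures ANOVA

For the balanced participant × 4 × 2 × 2 array, each within-subject
effect is the orthogonal projection onto its contrast subspace, tested
against its own effect-by-participant interaction; for a complete
balanced design this equals the Type III decomposition. The
implementation uses marginal-mean centering; the test suite checks it to
1e-8 against an independent orthonormal-Kronecker-basis projection oracle
and against `statsmodels` AnovaRM.

Because the generator injects deterministic effects, the qualitative
ANOVA signature is expressed in *relative* F magnitudes: entrainer, what
and entrainer×what are orders of magnitude larger than the when main
effect (which stems only from the extra E4 suppression and is ~0.1 % of
the what effect). With real between-subject variance the small effects
would be n.s.; at our noise-only error terms they can cross p < 0.05, so
the acceptance checks compare magnitudes rather than insisting on
non-significance.

### Cluster-based permutation tests

Paired t-maps over (combined-gradiometer, time) cells in the 0–270 ms
window are thresholded at the t quantile of the cluster-forming alpha
(default two-tailed 0.01; the quantile itself is configurable). Cells
lacking ≥ 2 supra-threshold spatial neighbours at the same time point are
pruned in a single pass, then connected components are formed (spatial
adjacency at equal time, temporal adjacency within a sensor); the cluster
statistic is the summed t. The null flips condition labels within
participants — for paired data equivalently the sign of the difference —
and records the maximum cluster mass; the permuted t-map is computed from
the permuted mean alone since the sum of squares is sign-invariant, which
makes the null fully vectorised. p = (r+1)/(N+1), so p is never zero and
the observed labeling is effectively a member of its own null.

For cohorts of ≤ 12 participants the pipeline replaces Monte-Carlo
sampling by **exact enumeration** of all 2ⁿ sign patterns: with n = 8 the
attainable p floor is 2/256 ≈ 0.0078 (two-tailed; both the identity and
the global flip reproduce the observed |mass|), safely below the 0.01
reporting level, whereas a 1000-draw Monte-Carlo estimate fluctuates
around that floor and makes 0.01-level calls unstable. Enumeration
comparisons use a relative tolerance (1e-9) so the identity relabeling is
always counted despite floating-point round-off.

The four pairwise comparisons follow the study logic: *when* vs
*what+when* and *random* vs *what* (suppression under fixed/jittered
timing, 0–270 ms, reported at p < 0.01), *what+when* vs *what* and *when*
vs *random* (temporal-predictability contrasts, restricted to the
75–135 ms evoked peak, reported at p < 0.05).

Decoding accuracies are tested with the one-tailed sign-flip variant over
time only (cluster-defining p < 0.05, cluster-alpha 0.01).

Both tests match exhaustive enumeration on small problems and control the
family-wise type-I error within binomial tolerance over 200 null
simulations (part of the test suite).

## Source analysis

The head sphere is fitted to the sensor sites by linear least squares;
the source grid is a regular lattice (default 5 mm; coarser in reduced
runs) of points strictly inside the sphere. Per point, the lead fields of
three orthogonal unit dipoles are reduced to the first two principal
components — in an ideal sphere the quasi-radial component is silent, and
the tests verify the discarded component carries < 0.1 % of the power.

The data covariance pools all trials and samples of the whole trial
(pre-fixation to post-target) with 5 % diagonal loading (our choice; the
data are rank-reduced and some loading is standard). Magnetometers and
gradiometers are combined after scaling each channel type by the inverse
square root of its mean covariance diagonal.

LCMV filters satisfy the unit-gain constraint `W L = I₂` to 1e-8. For
mapping, each filter row is additionally rescaled to unit noise gain
(Borgiotti–Kaplan): without this, the weak lead fields of deep grid
points inflate filter gain and every map peaks at the centre of the head.
The map value is the RMS of the two orientation components over the
85–125 ms window (`max` available); the resulting maps are unit-free and
invariant under consistent rescaling of data and covariance. Local maxima
use the 26-neighbourhood convention. Condition comparisons extract the
peak within a small sphere (≥ 5 mm, at least one grid step) around the
grand-average map's strongest local maximum and run paired t-tests.
Coordinates are reported in the head-sphere frame (occiput toward −y);
no anatomical normalisation is attempted.

## Decoding

Labels derive from the **target** of each trial (horizontal/vertical, or
high/low spatial frequency), inherited by every stimulus epoch of that
trial. Epochs are resampled to 200 Hz (polyphase, anti-aliased,
line-padded edges). Per cross-validation repeat, trials are shuffled
within class and averaged into disjoint pseudo-trials (default bins of
10; remainders dropped); whitening uses the Ledoit–Wolf-shrunk
within-class residual covariance of the training partition pooled over
time points (the per-time-resolved variant averaged over time), applied
to training and test data — the test partition never touches the
estimator. A linear SVM (squared hinge, L2, C = 1) is trained per time
point under stratified k-fold CV; accuracy is averaged over folds and
repeats. Each repeat draws one fresh pseudo-trial ordering — with 25
repeats this approximates the many-orderings scheme at bounded cost; the
number of orderings is a parameter.

Chance is 0.5 by design balance. At small cohort/trial counts the
pseudo-trial resampling correlates accuracies across repeats, so
single-dataset means scatter ±0.05 around chance; chance contracts are
therefore asserted on means over datasets.

## Pipeline

`pipeline.run_study` chains the stages for a cohort: per participant it
simulates the main and localizer blocks, preprocesses, extracts peak
amplitudes and combined evokeds, then runs the ANOVA, the four cluster
comparisons per stimulus, the E4 source contrast and the decoding tests,
and serialises everything (with config hash and all derived seeds) into a
JSON report. Participant seeds derive from the study seed
(`seed·10007 + offset + p`, kept below 2³¹); identical configs give
byte-identical reports. A full-scale cohort (16 participants, 160
trials/condition, 102 sites) needs ~7 GB per participant of transient
recordings; the packaged drivers and tests run reduced cohorts
(8 participants, 40 trials/condition, 24–30 sites) that preserve every
qualitative feature of the analysis. Trials with simulated response times
above 1.5 s would be excluded if behaviour were simulated; behaviour is
not simulated, so the filter exists as a documented no-op hook.

## Known limitations

* Inverse crime: simulator and beamformer share the forward model, so
  localisation accuracy on synthetic data overstates real-world accuracy.
* No between-participant variance: group statistics are exactly
  calibrated under the null but overpowered for injected effects.
* The single-sphere model and spherical-cap lattice are idealisations;
  channel naming follows the triple-sensor convention but the geometry is
  not a real helmet's.
* Non-causal (zero-phase) filtering smears sharp responses slightly
  backward in time; at high pattern SNR this can lift pre-stimulus
  decoding above chance, one reason the injected pattern strengths are
  kept modest.
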