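# Methods

## Model

Pupil size responses to conditioned stimuli are modelled as the output of a
linear time-invariant (LTI) system receiving impulse inputs at stimulus
onsets. The system's impulse response is described phenomenologically — not
biophysically — by a scaled, shifted gamma probability density with four
parameters: shape `k` (dimensionless), scale `θ` (s), amplitude scaling `c`
(the time integral of the response, z-units·s) and onset latency `t0` (s).
The function is identically zero before `t0`, peaks at `t0 + (k−1)θ` for
`k > 1`, and must return to baseline within the 10-s window on which all
estimation and scoring operates (`RF_WINDOW_S`).

The canonical registry (`data/canonical_rf.yaml`) holds one parameter set
per development/validation experiment, a pooled set (`combined`,
recommended for new studies with ~4-s CS and 3.5-s CS/US interval), and a
set for the response to the aversive US itself. One printed-unit caveat: θ
is used as the gamma *scale* in seconds. The rate reading (scale = 1/θ)
would put the development-set peak near 10 s, inconsistent with the
waveform the parameters describe, whereas the scale reading puts it at
~3.2 s.

The US set's `t0 = 3.76 s` is referenced to CS onset under a 3.5-s CS/US
interval. Whenever US (or US-omission) regressors are placed at US times —
the only construction that generalises to other CS/US intervals —
`us_params_relative_to_us` re-references the latency to US onset (0.26 s).

## GLM inversion

For each session, every modelled event class contributes one regressor per
basis component: the discrete convolution of a unit impulse train at the
class's onsets with the sampled kernel, truncated at the session end.
Variants:

- `cs_only` (3 columns): CS+US− and CS− onsets with the canonical kernel.
  Reinforced trials stay unmodelled so the US response cannot bias the
  CS+/CS− contrast; their samples remain in `Y` as unmodelled variance.
- `cs_plus_derivative` (5 columns): adds the *analytical* temporal
  derivative of the kernel as a second component. The analytic form keeps
  the basis grid-independent; no orthogonalisation is applied, since
  amplitude reconstruction by excursion absorbs shared variance
  symmetrically.
- `extended_us` (6 columns): all CS+ onsets, all CS− onsets, US+
  deliveries, US omissions in CS+US− trials, and "omissions" at the same
  latency in CS− trials, the last three with the US kernel.

One GLM is fitted per participant with sessions concatenated and one
intercept column per session — z-scoring is per session, so per-session
intercepts absorb level differences. Rows whose samples are flagged invalid
are removed before the least-squares solve (minimum-norm `lstsq`,
equivalent to pseudoinverse estimation); rank deficiency raises rather than
silently regularising. Amplitudes: the condition's beta for one-component
bases; for multi-component bases the reconstruction `Σ βᵢ·basisᵢ` is
summarised by its maximal signed excursion. Note the two conventions differ
in scale (multiplier of the kernel vs z-units of the reconstructed peak);
only within-convention comparisons are meaningful.

## Preprocessing

Samples are missing when |gaze| exceeds 5° visual angle in either direction
or the pupil sample is absent (NaN or zero). All causes are pooled; blink
detection is not re-implemented. Missing spans are linearly interpolated
only to keep the series continuous (baseline lookups, segment extraction);
they stay flagged and never enter model inversion or scoring. z-scoring
statistics are computed on valid samples only. No temporal filtering is
applied anywhere. The 35% exclusion criterion is evaluated per participant
by pooling sessions (`participant_missing_fraction`), with the per-session
fraction also reported; eye selection takes the eye with strictly fewer
invalid samples, ties to the left. Decimation takes every n-th sample and
marks a decimated sample invalid if any source sample in its bin was
invalid. Segments overrunning the session end are padded with invalid NaNs
so trial counts are preserved.

## Classical scoring

Signed peak is the maximal *absolute* excursion with sign retained, for
consistency with the GLM amplitude rule; signed AUC is the trapezoidal
integral over valid samples within the window. Both default to the 10-s
window so the model-based approach gains no advantage from a longer data
window; a CS-duration window is available via the `window` argument. Trial
segments are baseline-corrected at CS onset before scoring (trial-level
analogue of grand-mean baseline correction; removes slow drift). Whether to
baseline-correct is exposed on `extract_segments` since the trial-level
choice is a convention. Reinforced trials are excluded from classical CS
scoring by default.

## Predictive validity

Each method is summarised per participant by one CS+ and one CS− value. The
second-level regression uses the CS-type indicator (1/0) as dependent
variable and the estimates plus one dummy per participant as regressors;
the indicator coding is immaterial because an affine recoding rescales
every method's RSS by the same factor, leaving ΔAIC unchanged (this
invariance is tested). `AIC = n·log(RSS/n) + 2(r+1)` with `r` counted as
participants + 1; since n and r are identical across methods, ΔAIC equals
`n·log(RSS₁/RSS₂)` exactly. |ΔAIC| > 3 is labelled decisive. A perfectly
separating method hits the RSS floor (1e-12) and is flagged degenerate
instead of producing −∞. The paired t and `d = t/√n` are reported from the
same data.

## Input estimation

The fitted first-level response functions can also be read as the output of
the common final pupillary pathway. Given a luminance response kernel for
that pathway, `estimate_input` fits a gamma-shaped input whose convolution
with the kernel reproduces an observed difference waveform (the z-scored
grand-mean difference is the intended input). The input amplitude is
constrained non-negative by default (`allow_negative` lifts this). The
packaged default kernel is a **synthetic stand-in** — a gamma kernel
peaking at 1.1 s, matching the reported initial dilation latency — because
no empirically estimated final-pathway kernel ships with the package; its
provenance string travels with every result, and real-data analyses should
substitute a measured kernel. For any causal, non-negative kernel the
fitted input's peak precedes the output's peak, which is enforced by test.

## Optimisation

Response-function and input fits minimise the residual sum of squares with
a Nelder-Mead simplex over `(log k, log θ, c, t0)` (log c when the input is
constrained non-negative), with `t0` clipped at zero — the transform keeps
the simplex in the valid domain without explicit constraints. Because the
gamma fit has local minima, eight deterministic restarts are used: `k ∈ {2,
5, 10, 20}` × `t0 ∈ {0, 1 s}`, with θ chosen so the mode lands on the
series' absolute peak and c from the series' area (the input fit uses an
analogous grid shifted by the kernel's peak latency). The lowest-RSS
solution is kept; tolerances are `xatol 1e-10`, `fatol 1e-14`. An
all-(near-)zero series short-circuits to a zero-amplitude fit flagged
degenerate; total non-convergence is flagged, never silent.

`shared_variance` compares two kernels by the squared Pearson correlation
of their samples on [0, 10) s at 500 Hz (a 2-ms grid, matching the
acquisition rate). This sampled-kernel reading is one of several possible
conventions for quantifying regressor overlap; it is adopted and fixed
here. The statistic is fairly sensitive to the kernels' printed parameter
precision: perturbing the parameters within their last printed digit moves
the exp1-vs-US value across roughly 0.009–0.023.

## Synthetic data

`generate_paradigm` reproduces the development-study structure by default:
40 CS+US+, 40 CS+US−, 80 CS− trials over two sessions, 4-s CS, US at 3.5 s,
ITIs drawn from {7, 9, 11} s; a long-CS preset (20/20/40, 6.5-s CS, US at
6 s, ITIs {11, 15, 17} s) is included. Traces are built by placing
amplitude-scaled response-function templates at CS onsets (US templates at
US deliveries), adding AR(1) Gaussian noise and planting blink-like gaps.
Defaults: CS+ amplitude 1, CS− amplitude 0 (the canonical kernel already
carries the empirical difference-wave scale `c`), US amplitude 1, noise
stationary SD 0.5, AR(1) φ = 0.9, 4 blinks/min of 0.1–0.4 s, gaze noise SD
0.5° with ~1 excursion/min beyond the 5° criterion. `noise_sd` is the
*stationary* SD (innovation SD `σ√(1−φ²)`).

What the simulator does *not* emulate: inter-individual variability of true
amplitudes (all synthetic participants share the planted values, so
second-level effect sizes are much larger than in real cohorts and only
*between-method* comparisons are meaningful), habituation or learning
curves across trials, luminance confounds, gaze-dependent pupil
foreshortening, and any common-to-both-conditions CS response (whose
presence would leave the CS+/CS− contrast unchanged — tested). Passing
recovery tests therefore shows correctness of the estimation machinery
under the model's own assumptions, not robustness to model violation.

## Problem sizes

The Monte-Carlo study behind the statistical-behaviour checks runs 100
replicates of 19-participant cohorts (the development experiment's final
sample size) with full 160-trial paradigms simulated at 100 Hz — the
package's default study rate, which keeps the full study around two minutes
while leaving >1000 samples per response. Noiseless recovery checks use
reduced trial counts (their result is exact regardless of size). The
matched-generator round trip for the CS-only model uses a paradigm without
reinforced trials, since unmodelled US responses in reinforced trials are
deliberate unmodelled variance under that variant (they leak ≤1e-3 into
absolute amplitudes but cancel in the CS+/CS− contrast).

## Known limitations

- Single-trial amplitude estimation is out of scope (one amplitude per
  condition per participant).
- The packaged luminance kernel is synthetic (see Input estimation).
- OLS inversion ignores the AR(1) error structure; estimates remain
  unbiased (verified by simulation) but are not minimum-variance under
  autocorrelated noise.
- The EyeLink native formats are not parsed; inputs are plain TSV
  time/pupil/gaze tables, with a pixels→degrees utility requiring screen
  geometry.
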