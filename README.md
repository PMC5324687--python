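# pupilglm

Model-based assessment of fear learning from pupil size time series.

During discriminant fear conditioning, pupil responses to a conditioned
stimulus paired with an aversive outcome (CS+) differ from responses to an
unpaired stimulus (CS−). `pupilglm` estimates the amplitude of the central
input driving that difference by treating the pupil as a linear
time-invariant (LTI) system: the response to an event is a scaled, shifted
gamma probability density

d(t) = c · (t − t₀)^(k−1) · e^(−(t−t₀)/θ) / (θᵏ Γ(k)),  t ≥ t₀,

and a session's pupil trace is modelled as a general linear model
**Y = Xβ + ε**, where each column of X is the convolution of an event
impulse train with the response function (optionally plus its temporal
derivative) and β holds the input amplitudes. Inversion is least squares on
valid samples only, after blink/gaze artefacts are masked. The package is
aimed at psychophysiologists analysing fear-conditioning (or similar
event-related) pupillometry who want a principled, higher-powered
alternative to ad-hoc peak scoring or area-under-the-curve measures.

It provides:

- **`response_model`** — the gamma response function, a registry of canonical
  parameter sets (per experiment, pooled, and for the aversive US itself),
  analytical derivative basis, and multi-start simplex fitting.
- **`preprocessing`** — ±5° gaze criterion, missing-data masking, linear
  interpolation, per-session z-scoring, 35% exclusion rule, decimation,
  per-trial segment extraction.
- **`classical_scoring`** — signed peak and signed AUC baselines.
- **`glm`** — design construction (CS-only, CS + derivative, extended model
  with US and US-omission regressors), pseudoinverse-style inversion,
  amplitude reconstruction by maximal signed excursion.
- **`validation`** — predictive validity: second-level regression of CS type
  on estimates with subject intercepts, AIC = n·log(RSS/n) + 2(r+1), paired
  t, Cohen's d = t/√n, and ΔAIC verdicts (|ΔAIC| > 3 is decisive).
- **`input_estimation`** — gamma-shaped central input fitted through a
  luminance response kernel (packaged default is a synthetic stand-in;
  supply a measured kernel for real data).
- **`synthetic`** — paradigm schedules (e.g. 40/40/80 trials, 4-s CS, US at
  3.5 s, ITIs of 7/9/11 s) and trace simulation with AR(1) noise, blinks and
  planted ground truth.

## Worked example

Simulate eight participants of the development-style paradigm, analyse each
with the GLM and with peak scoring, and compare predictive validity:

```python
import numpy as np
import pupilglm as pg
from pupilglm.validation import SecondLevelData, validity_report
from pupilglm.classical_scoring import condition_summaries, score_segments
from pupilglm.preprocessing import extract_segments

sr = 100.0
spec = pg.exp1_paradigm()
sim = pg.SimulationSpec()          # CS+ amplitude 1, CS- 0, noise_sd 0.5, phi 0.9
basis = pg.basis_set(sim.rf, sr)

rng = np.random.default_rng(7)
glm_plus, glm_minus, peak_plus, peak_minus = [], [], [], []
for participant in range(8):
    paradigm = pg.generate_paradigm(spec, rng)
    sessions, truth = pg.simulate_participant(paradigm, sim, sr, rng)
    res = pg.fit_participant(sessions, basis, "cs_only")
    glm_plus.append(res.amplitudes["CSpUSm"]); glm_minus.append(res.amplitudes["CSm"])
    peaks = [condition_summaries(score_segments(extract_segments(tr, ev), "peak"))
             for tr, ev in sessions]
    peak_plus.append(np.mean([p["CSpUSm"] for p in peaks]))
    peak_minus.append(np.mean([p["CSm"] for p in peaks]))

ids = np.arange(8)
reports = [
    validity_report(SecondLevelData(ids, np.array(glm_plus), np.array(glm_minus)), "glm"),
    validity_report(SecondLevelData(ids, np.array(peak_plus), np.array(peak_minus)), "peak"),
]
print(pg.compare_methods(reports, reference="peak").to_string(index=False))
for r in reports:
    print(f"{r.method}: t({r.df}) = {r.t_statistic:.2f}, p = {r.p_value:.2g}, d = {r.cohens_d:.2f}")
```

Output:

```
method         aic  delta_aic    verdict favours
   glm -103.902423 -62.298712   decisive  method
  peak  -41.603711   0.000000 indecisive neither
glm: t(7) = 63.49, p = 6.3e-11, d = 22.45
peak: t(7) = 8.68, p = 5.4e-05, d = 3.07
```

The GLM's amplitude estimates separate CS+ from CS− with a much lower AIC
than peak scoring (ΔAIC = −62, far past the decisive threshold of ±3): the
model-based estimates are less noisy because they pool every sample of the
10-s response rather than a single extremum. The absolute effect sizes are
inflated relative to real cohorts because simulated participants share
identical true amplitudes (see `docs/methods.md`).

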