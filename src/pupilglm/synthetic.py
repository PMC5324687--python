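"""Paradigm schedules and simulated pupil traces for offline testing.

The generator mirrors the forward model the analysis assumes: each trial
adds a condition-amplitude-scaled copy of the CS response function at CS
onset (plus a US response function at US delivery on reinforced trials) and
the trace is corrupted with AR(1) Gaussian noise and blink-like missing
gaps.  Planted ground-truth amplitudes are returned alongside, so parameter
recovery can be checked black-box.

Two output levels are provided: :func:`simulate_session` yields a
model-space :class:`~pupilglm.preprocessing.CleanTrace` (z-unit signal,
validity mask), which is what recovery studies operate on;
:func:`simulate_trace` additionally wraps the signal into raw device units
with gaze channels for exercising the preprocessing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .glm import EventTable
from .preprocessing import CleanTrace, RawTrace
from .response_model import (
    GammaParams,
    canonical_params,
    evaluate_rf,
    us_params_relative_to_us,
)

__all__ = [
    "ParadigmSpec",
    "SimulationSpec",
    "Paradigm",
    "exp1_paradigm",
    "exp5_paradigm",
    "generate_paradigm",
    "simulate_session",
    "simulate_trace",
    "simulate_participant",
]

#: Post-event tail (s) appended after the last trial onset of a session.
SESSION_TAIL_S = 15.0


@dataclass(frozen=True)
class ParadigmSpec:
    """Trial counts and timing of a delay fear-conditioning paradigm."""

    n_cspusp: int = 40
    n_cspusm: int = 40
    n_csm: int = 80
    cs_duration: float = 4.0
    cs_us_interval: float = 3.5
    iti_choices: tuple[float, ...] = (7.0, 9.0, 11.0)
    sessions: int = 2
    lead_in: float = 2.0

    def __post_init__(self) -> None:
        if min(self.n_cspusp, self.n_cspusm, self.n_csm) < 0:
            raise ValueError("trial counts must be >= 0")
        if not self.cs_us_interval < self.cs_duration:
            raise ValueError("CS/US interval must be shorter than CS duration")
        if not self.iti_choices:
            raise ValueError("iti_choices must be nonempty")
        if self.sessions < 1:
            raise ValueError("need at least one session")


def exp1_paradigm() -> ParadigmSpec:
    """Auditory short-CS paradigm: 40/40/80 trials, 4-s CS, US at 3.5 s."""
    return ParadigmSpec()


def exp5_paradigm() -> ParadigmSpec:
    """Long-CS paradigm: 20/20/40 trials, 6.5-s CS, US at 6 s, longer ITIs."""
    return ParadigmSpec(
        n_cspusp=20, n_cspusm=20, n_csm=40,
        cs_duration=6.5, cs_us_interval=6.0,
        iti_choices=(11.0, 15.0, 17.0),
    )


@dataclass(frozen=True)
class Paradigm:
    """Randomised schedule: one event table and duration per session."""

    sessions: tuple[EventTable, ...]
    durations: tuple[float, ...]
    spec: ParadigmSpec

    @property
    def n_trials(self) -> int:
        return sum(len(ev) for ev in self.sessions)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def generate_paradigm(spec: ParadigmSpec, seed=0) -> Paradigm:
    """Randomise trial order and draw ITIs; deterministic given the seed.

    Trials are shuffled globally, split evenly across sessions, and spaced
    by CS duration plus an ITI drawn uniformly from ``iti_choices``.
    """
    rng = _as_rng(seed)
    labels = (
        ["CSpUSp"] * spec.n_cspusp
        + ["CSpUSm"] * spec.n_cspusm
        + ["CSm"] * spec.n_csm
    )
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    chunks = np.array_split(labels, spec.sessions)
    sessions, durations = [], []
    for chunk in chunks:
        onsets = []
        t = spec.lead_in
        for _ in chunk:
            onsets.append(t)
            t += spec.cs_duration + rng.choice(spec.iti_choices)
        ev = EventTable(
            onsets=np.array(onsets),
            conditions=chunk,
            include=np.ones(len(chunk), dtype=bool),
            cs_us_interval=spec.cs_us_interval,
        )
        sessions.append(ev)
        durations.append((onsets[-1] if onsets else spec.lead_in) + SESSION_TAIL_S)
    return Paradigm(sessions=tuple(sessions), durations=tuple(durations), spec=spec)


@dataclass(frozen=True)
class SimulationSpec:
    """Generative settings for simulated pupil traces.

    Amplitudes are multipliers on the response functions (z-units relative
    to the kernels' own scaling); ``noise_sd`` is the stationary standard
    deviation of the AR(1) noise with lag-one coefficient ``noise_ar1``;
    blinks arrive at ``missing_rate`` events per minute with durations drawn
    uniformly from ``missing_duration`` (s).
    """

    cs_plus_amplitude: float = 1.0
    cs_minus_amplitude: float = 0.0
    us_amplitude: float = 1.0
    rf: GammaParams = field(default_factory=lambda: canonical_params("exp1"))
    us_rf: GammaParams | None = None
    noise_sd: float = 0.5
    noise_ar1: float = 0.9
    missing_rate: float = 4.0
    missing_duration: tuple[float, float] = (0.1, 0.4)
    gaze_sd_deg: float = 0.5
    excursion_rate: float = 1.0
    excursion_duration: tuple[float, float] = (0.2, 0.5)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.noise_ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in [0, 1)")

    def resolved_us_rf(self, cs_us_interval: float) -> GammaParams:
        """US kernel referenced to US onset for the given CS/US interval."""
        if self.us_rf is not None:
            return self.us_rf
        return us_params_relative_to_us(canonical_params("us"))

    def ground_truth(self) -> dict:
        return {
            "cs_plus_amplitude": self.cs_plus_amplitude,
            "cs_minus_amplitude": self.cs_minus_amplitude,
            "us_amplitude": self.us_amplitude,
            "contrast": self.cs_plus_amplitude - self.cs_minus_amplitude,
            "rf": self.rf.as_dict(),
            "noise_sd": self.noise_sd,
            "noise_ar1": self.noise_ar1,
        }


def _add_template(signal: np.ndarray, template: np.ndarray, onset: float,
                  sampling_rate: float, amplitude: float) -> None:
    idx = int(round(onset * sampling_rate))
    if idx >= signal.size or amplitude == 0.0:
        return
    stop = min(idx + template.size, signal.size)
    signal[idx:stop] += amplitude * template[: stop - idx]


def _deterministic_signal(
    events: EventTable, duration: float, sim: SimulationSpec, sampling_rate: float
) -> np.ndarray:
    n = int(round(duration * sampling_rate))
    t_rf = np.arange(int(10.0 * sampling_rate)) / sampling_rate
    cs_template = evaluate_rf(sim.rf, t_rf)
    us_template = evaluate_rf(sim.resolved_us_rf(events.cs_us_interval), t_rf)
    signal = np.zeros(n)
    for onset, cond in zip(events.onsets, events.conditions):
        amp = (
            sim.cs_minus_amplitude if cond == "CSm" else sim.cs_plus_amplitude
        )
        _add_template(signal, cs_template, onset, sampling_rate, amp)
        if cond == "CSpUSp":
            _add_template(
                signal, us_template, onset + events.cs_us_interval,
                sampling_rate, sim.us_amplitude,
            )
    return signal


def _ar1_noise(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0.0:
        return np.zeros(n)
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, innov_sd, size=n)
    e[0] = rng.normal(0.0, sd)  # start at stationarity
    return lfilter([1.0], [1.0, -phi], e)


def _gap_mask(n: int, sampling_rate: float, rate_per_min: float,
              duration_range: tuple[float, float],
              rng: np.random.Generator) -> np.ndarray:
    """True where a planted gap (blink or excursion) covers the sample."""
    mask = np.zeros(n, dtype=bool)
    minutes = n / sampling_rate / 60.0
    for _ in range(rng.poisson(rate_per_min * minutes)):
        start = rng.uniform(0.0, n / sampling_rate)
        dur = rng.uniform(*duration_range)
        i0 = int(start * sampling_rate)
        i1 = min(int((start + dur) * sampling_rate), n)
        mask[i0:i1] = True
    return mask


def simulate_session(
    events: EventTable,
    duration: float,
    sim: SimulationSpec,
    sampling_rate: float = 500.0,
    seed=0,
) -> tuple[CleanTrace, dict]:
    """Model-space simulated session: z-unit signal + AR(1) noise + gaps."""
    rng = _as_rng(seed)
    signal = _deterministic_signal(events, duration, sim, sampling_rate)
    n = signal.size
    signal = signal + _ar1_noise(n, sim.noise_sd, sim.noise_ar1, rng)
    blinks = _gap_mask(n, sampling_rate, sim.missing_rate,
                       sim.missing_duration, rng)
    trace = CleanTrace(
        pupil_z=signal, valid=~blinks, sampling_rate=sampling_rate,
        session_id="sim",
    )
    return trace, sim.ground_truth()


#: Device-unit conversion used for raw simulated traces.
DEVICE_OFFSET = 4000.0
DEVICE_GAIN = 600.0


def simulate_trace(
    events: EventTable,
    duration: float,
    sim: SimulationSpec,
    sampling_rate: float = 500.0,
    seed=0,
) -> tuple[RawTrace, RawTrace, dict]:
    """Raw left/right eye traces in device units with gaze channels.

    Both eyes share the deterministic response but carry independent noise,
    blinks (pupil set to NaN) and occasional gaze excursions beyond the
    5-degree fixation criterion.
    """
    rng = _as_rng(seed)
    signal = _deterministic_signal(events, duration, sim, sampling_rate)
    n = signal.size
    time = np.arange(n) / sampling_rate
    traces = []
    for eye in ("left", "right"):
        noisy = signal + _ar1_noise(n, sim.noise_sd, sim.noise_ar1, rng)
        pupil = DEVICE_OFFSET + DEVICE_GAIN * noisy
        blinks = _gap_mask(n, sampling_rate, sim.missing_rate,
                           sim.missing_duration, rng)
        pupil[blinks] = np.nan
        gaze_x = rng.normal(0.0, sim.gaze_sd_deg, size=n)
        gaze_y = rng.normal(0.0, sim.gaze_sd_deg, size=n)
        excursions = _gap_mask(n, sampling_rate, sim.excursion_rate,
                               sim.excursion_duration, rng)
        gaze_x[excursions] += rng.choice([-8.0, 8.0])
        traces.append(
            RawTrace(time=time, pupil=pupil, gaze_x=gaze_x, gaze_y=gaze_y,
                     sampling_rate=sampling_rate, eye=eye, session_id="sim")
        )
    return traces[0], traces[1], sim.ground_truth()


def simulate_participant(
    paradigm: Paradigm,
    sim: SimulationSpec,
    sampling_rate: float = 500.0,
    seed=0,
) -> tuple[list[tuple[CleanTrace, EventTable]], dict]:
    """Model-space sessions for one participant under a shared paradigm spec."""
    rng = _as_rng(seed)
    sessions = []
    truth = sim.ground_truth()
    for ev, dur in zip(paradigm.sessions, paradigm.durations):
        trace, _ = simulate_session(ev, dur, sim, sampling_rate, rng)
        sessions.append((trace, ev))
    return sessions, truth
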