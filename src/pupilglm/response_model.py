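"""Gamma-form impulse response functions of the pupillary system.

Fear-conditioned pupil size responses are modelled as the output of a linear
time-invariant (LTI) system receiving impulse inputs at stimulus onsets.  Such
a system is fully characterised by its impulse response function, which is
described phenomenologically by a scaled, shifted gamma probability density

    d(t) = c * (t - t0)^(k-1) * exp(-(t - t0)/theta) / (theta^k * Gamma(k))

for t >= t0 and 0 before onset.  ``k`` (shape) and ``theta`` (scale, seconds)
set the waveform, ``t0`` (seconds) the onset latency, and ``c`` the time
integral of the response in z-units x seconds.  The function is not meant to
reflect biophysics; it is an analytical description of the empirical
difference wave between reinforced-context CS+ and CS- trials.

A registry of canonical parameter sets is shipped with the package: one per
development/validation experiment (``exp1`` ... ``exp4``), one pooled over the
four experiments with identical timing (``combined``), and one for the
response to the aversive US itself (``us``; its onset latency is referenced to
CS onset under a 3.5-s CS/US interval, see :func:`us_params_relative_to_us`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from importlib import resources
from typing import Sequence

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = [
    "GammaParams",
    "BasisSet",
    "RFFit",
    "evaluate_rf",
    "evaluate_rf_derivative",
    "basis_set",
    "canonical_params",
    "canonical_names",
    "us_params_relative_to_us",
    "fit_rf",
    "shared_variance",
]

#: Window (s) over which response functions are evaluated, fitted and
#: truncated into basis components.  The response must return to baseline
#: within this window for the finite LTI system to be well posed.
RF_WINDOW_S = 10.0


@dataclass(frozen=True)
class GammaParams:
    """Parameters of one gamma-form response function.

    k: shape (dimensionless, > 0); theta: scale (s, > 0); c: amplitude
    scaling (z-units x s, the time integral of the response); t0: onset
    latency (s, >= 0).
    """

    k: float
    theta: float
    c: float
    t0: float

    def __post_init__(self) -> None:
        vals = (self.k, self.theta, self.c, self.t0)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"non-finite response-function parameters: {vals}")
        if self.k <= 0 or self.theta <= 0:
            raise ValueError(
                f"shape and scale must be positive, got k={self.k}, theta={self.theta}"
            )
        if self.t0 < 0:
            raise ValueError(f"onset latency must be >= 0, got t0={self.t0}")

    @property
    def mode(self) -> float:
        """Time of the response peak: t0 + (k - 1) * theta for k > 1."""
        if self.k <= 1:
            return self.t0
        return self.t0 + (self.k - 1.0) * self.theta

    def replace(self, **kwargs) -> "GammaParams":
        return replace(self, **kwargs)

    def as_dict(self) -> dict:
        return {"k": self.k, "theta": self.theta, "c": self.c, "t0": self.t0}


@dataclass(frozen=True)
class BasisSet:
    """Sampled basis time courses used to build GLM regressors.

    The first component is the canonical response function; the optional
    second component is its analytical time derivative.  All components share
    length ``floor(duration * sampling_rate)``.
    """

    components: np.ndarray  # (n_components, n_samples)
    sampling_rate: float
    duration: float
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        n = int(np.floor(self.duration * self.sampling_rate))
        if self.components.ndim != 2 or self.components.shape[1] != n:
            raise ValueError(
                f"components must be (m, {n}), got {self.components.shape}"
            )
        if len(self.labels) != self.components.shape[0]:
            raise ValueError("one label per component required")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def evaluate_rf(params: GammaParams, time_grid) -> np.ndarray:
    """Evaluate the response function on ``time_grid`` (seconds).

    Returns ``c * gammapdf(t - t0; k, theta)`` elementwise; exactly zero for
    t < t0.  The grid must be nondecreasing.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size > 1 and np.any(np.diff(t) < 0):
        raise ValueError("time_grid must be nondecreasing")
    return params.c * stats.gamma.pdf(t - params.t0, a=params.k, scale=params.theta)


def evaluate_rf_derivative(params: GammaParams, time_grid) -> np.ndarray:
    """Analytical time derivative of the response function.

    d/dt [c * f(t - t0)] = c * f(t - t0) * ((k - 1)/(t - t0) - 1/theta)
    for t > t0, and 0 for t <= t0.  Computed analytically rather than by
    finite differences so the basis is grid-independent.
    """
    t = np.asarray(time_grid, dtype=float)
    dt = t - params.t0
    f = evaluate_rf(params, t)
    out = np.zeros_like(f)
    pos = dt > 0
    out[pos] = f[pos] * ((params.k - 1.0) / dt[pos] - 1.0 / params.theta)
    return out


def basis_set(
    params: GammaParams,
    sampling_rate: float,
    duration: float = RF_WINDOW_S,
    include_derivative: bool = False,
) -> BasisSet:
    """Sample the response function (and optionally its derivative) into a basis."""
    n = int(np.floor(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    comps = [evaluate_rf(params, t)]
    labels = ["canonical"]
    if include_derivative:
        comps.append(evaluate_rf_derivative(params, t))
        labels.append("derivative")
    return BasisSet(
        components=np.vstack(comps),
        sampling_rate=sampling_rate,
        duration=duration,
        labels=tuple(labels),
    )


def _load_registry() -> dict[str, GammaParams]:
    text = resources.files("pupilglm.data").joinpath("canonical_rf.yaml").read_text()
    raw = yaml.safe_load(text)
    return {
        name: GammaParams(d["k"], d["theta"], d["c"], d["t0"])
        for name, d in raw.items()
    }


_REGISTRY: dict[str, GammaParams] | None = None


def canonical_names() -> tuple[str, ...]:
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    return tuple(_REGISTRY)


def canonical_params(name: str) -> GammaParams:
    """Return a canonical response-function parameter set by name.

    Valid names: ``exp1``..``exp4`` (per-experiment fits of the CS+/CS-
    difference wave), ``combined`` (pooled over the four same-timing
    experiments), ``us`` (response to the US itself; t0 referenced to CS
    onset under a 3.5-s CS/US interval).
    """
    global _REGISTRY
    if _REGISTRY is None:
        _REGISTRY = _load_registry()
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown response function {name!r}; valid names: "
            f"{', '.join(sorted(_REGISTRY))}"
        ) from None


#: CS/US interval (s) under which the canonical US response function's onset
#: latency was defined relative to CS onset.
US_RF_CS_REFERENCE_S = 3.5


def us_params_relative_to_us(
    params: GammaParams | None = None,
    cs_us_interval: float = US_RF_CS_REFERENCE_S,
) -> GammaParams:
    """Re-reference the US response function's onset latency to US onset.

    The canonical ``us`` set prints t0 relative to CS onset for a 3.5-s CS/US
    interval; placing regressor impulses at US (or US-omission) times instead
    requires the latency measured from the US itself (0.26 s for the
    canonical set).  This keeps the US kernel valid for paradigms with other
    CS/US intervals.
    """
    if params is None:
        params = canonical_params("us")
    t0 = params.t0 - cs_us_interval
    if t0 < 0:
        raise ValueError(
            f"t0={params.t0} precedes the US onset for interval {cs_us_interval}"
        )
    return params.replace(t0=t0)


@dataclass(frozen=True)
class RFFit:
    """Result of fitting a gamma response function to a sampled waveform."""

    params: GammaParams
    rss: float
    converged: bool
    degenerate: bool
    n_starts: int


def _rf_objective(x: np.ndarray, t: np.ndarray, y: np.ndarray) -> float:
    k = np.exp(x[0])
    theta = np.exp(x[1])
    c = x[2]
    t0 = max(x[3], 0.0)
    pred = c * stats.gamma.pdf(t - t0, a=k, scale=theta)
    r = pred - y
    return float(r @ r)


def _default_starts(t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid: the gamma fit has local minima.

    k over a fixed grid, theta matched so the mode lands on the series'
    absolute peak, c from the series' area, t0 in {0, 1} s.
    """
    i_peak = int(np.argmax(np.abs(y)))
    t_peak = t[i_peak]
    area = float(np.trapezoid(y, t))
    if area == 0.0:
        area = float(y[i_peak]) or 1.0
    starts = []
    for k0 in (2.0, 5.0, 10.0, 20.0):
        for t00 in (0.0, 1.0):
            theta0 = max((t_peak - t00) / (k0 - 1.0), 1e-3)
            starts.append(np.array([np.log(k0), np.log(theta0), area, t00]))
    return starts


def fit_rf(
    mean_diff: Sequence[float],
    sampling_rate: float,
    init: GammaParams | None = None,
    max_iter: int = 4000,
) -> RFFit:
    """Fit gamma response-function parameters to a sampled waveform.

    Ordinary least squares via a Nelder-Mead simplex search, restarted from a
    deterministic grid of initialisations (plus ``init`` if given) with the
    lowest-RSS solution retained.  The simplex runs over (log k, log theta,
    c, t0) with t0 clipped at 0, which keeps it inside the valid domain.

    An all-(near-)zero input returns a zero-amplitude fit flagged
    ``degenerate``; failure of every restart to converge is flagged via
    ``converged=False`` rather than raised.
    """
    y = np.asarray(mean_diff, dtype=float)
    if y.ndim != 1:
        raise ValueError("mean_diff must be one-dimensional")
    if y.size < int(2 * sampling_rate):
        raise ValueError("need at least 2 s of samples to fit a response function")
    if not np.all(np.isfinite(y)):
        raise ValueError("mean_diff contains non-finite values")
    t = np.arange(y.size) / sampling_rate

    if float(np.max(np.abs(y))) < 1e-12:
        params = GammaParams(k=2.0, theta=1.0, c=0.0, t0=0.0)
        return RFFit(params=params, rss=float(y @ y), converged=True,
                     degenerate=True, n_starts=0)

    starts = _default_starts(t, y)
    if init is not None:
        starts.append(
            np.array([np.log(init.k), np.log(init.theta), init.c, init.t0])
        )

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            _rf_objective,
            x0,
            args=(t, y),
            method="Nelder-Mead",
            options={
                "maxiter": max_iter,
                "maxfev": max_iter,
                "xatol": 1e-10,
                "fatol": 1e-14,
            },
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    k, theta = np.exp(best.x[0]), np.exp(best.x[1])
    params = GammaParams(k=float(k), theta=float(theta),
                         c=float(best.x[2]), t0=float(max(best.x[3], 0.0)))
    return RFFit(params=params, rss=float(best.fun), converged=any_converged,
                 degenerate=False, n_starts=len(starts))


def shared_variance(
    a: GammaParams,
    b: GammaParams,
    duration: float = RF_WINDOW_S,
    sampling_rate: float = 500.0,
) -> float:
    """Squared Pearson correlation of two response functions on a common grid.

    Both functions are sampled on [0, duration) at ``sampling_rate`` (default
    2-ms grid, matching a 500-Hz acquisition).  Quantifies how separable two
    regressors built from these kernels are; a small value means their input
    amplitudes can be estimated independently in one GLM.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(np.floor(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    ya = evaluate_rf(a, t)
    yb = evaluate_rf(b, t)
    if np.std(ya) == 0.0 or np.std(yb) == 0.0:
        raise ValueError("zero-variance response function on the grid; "
                         "correlation undefined")
    r = float(np.corrcoef(ya, yb)[0, 1])
    return r * r


def params_to_json(params: GammaParams) -> str:
    return json.dumps(params.as_dict(), indent=2)


def params_from_json(text: str) -> GammaParams:
    d = json.loads(text)
    return GammaParams(d["k"], d["theta"], d["c"], d["t0"])
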