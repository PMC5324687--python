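"""Estimate central inputs into the pupillary pathway.

Cognitively driven pupil responses are assumed to pass through the same
final (neural and muscular) pathway as luminance-driven responses.  Given a
luminance response function for that pathway, the time course of the central
input eliciting an observed waveform (e.g. the CS+US- minus CS- grand-mean
difference) can be estimated by fitting a gamma-shaped input whose
convolution with the luminance kernel reproduces the waveform.  The fitted
input for an aversive-stimulus response is expected to be steep and
immediate, while the input for the anticipatory CS+ response is shallower
and peaks later — and, for any causal non-negative kernel, the input's peak
precedes the predicted output's peak.

The packaged default kernel is a SYNTHETIC stand-in (a gamma kernel peaking
near the empirically reported ~1.1-s initial dilation latency); for
real-data use, supply an empirically derived luminance response function.
Every result carries the kernel's provenance string so outputs remain
traceable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy import optimize
from scipy.signal import fftconvolve

from .response_model import GammaParams, evaluate_rf

__all__ = [
    "LuminanceRF",
    "InputFit",
    "default_luminance_rf",
    "estimate_input",
]


@dataclass(frozen=True)
class LuminanceRF:
    """Sampled pupillary response kernel to luminance/final-pathway inputs."""

    kernel: np.ndarray
    sampling_rate: float
    provenance: str
    params: GammaParams | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "kernel", np.asarray(self.kernel, dtype=float))
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel contains non-finite values")
        if self.kernel.size / self.sampling_rate > 10.0 + 1e-9:
            raise ValueError("kernel longer than the 10-s response window")
        if not self.provenance:
            raise ValueError("a provenance note is mandatory for the kernel")

    @classmethod
    def from_params(
        cls,
        params: GammaParams,
        sampling_rate: float,
        provenance: str,
        duration: float = 10.0,
    ) -> "LuminanceRF":
        t = np.arange(int(np.floor(duration * sampling_rate))) / sampling_rate
        return cls(
            kernel=evaluate_rf(params, t),
            sampling_rate=sampling_rate,
            provenance=provenance,
            params=params,
        )

    @classmethod
    def from_json(cls, path, sampling_rate: float) -> "LuminanceRF":
        with open(path) as fh:
            d = json.load(fh)
        return cls.from_params(
            GammaParams(d["k"], d["theta"], d["c"], d["t0"]),
            sampling_rate=sampling_rate,
            provenance=d["provenance"],
        )


def default_luminance_rf(sampling_rate: float = 500.0) -> LuminanceRF:
    """Packaged default kernel — a synthetic stand-in, see module docstring."""
    text = (
        resources.files("pupilglm.data")
        .joinpath("luminance_rf_synthetic.json")
        .read_text()
    )
    d = json.loads(text)
    return LuminanceRF.from_params(
        GammaParams(d["k"], d["theta"], d["c"], d["t0"]),
        sampling_rate=sampling_rate,
        provenance=d["provenance"],
    )


@dataclass(frozen=True)
class InputFit:
    params: GammaParams
    rss: float
    converged: bool
    degenerate: bool
    kernel_provenance: str


def _predict(kernel: np.ndarray, input_wave: np.ndarray, dt: float, n: int) -> np.ndarray:
    # discrete approximation of the continuous convolution (x dt)
    return fftconvolve(kernel, input_wave)[:n] * dt


def _input_objective(x, t, y, kernel, dt, allow_negative):
    k = np.exp(x[0])
    theta = np.exp(x[1])
    c = x[2] if allow_negative else np.exp(x[2])
    t0 = max(x[3], 0.0)
    try:
        g = evaluate_rf(GammaParams(k, theta, c, t0), t)
    except (ValueError, OverflowError):
        return np.inf
    if not np.all(np.isfinite(g)):
        return np.inf
    r = _predict(kernel, g, dt, y.size) - y
    return float(r @ r)


def estimate_input(
    observed_diff,
    sampling_rate: float,
    kernel: LuminanceRF | None = None,
    allow_negative: bool = False,
    max_iter: int = 4000,
) -> InputFit:
    """Fit a gamma-shaped input through the luminance kernel to a waveform.

    Minimises the squared error between kernel * input (convolution) and the
    observed waveform via the same deterministic multi-start Nelder-Mead
    scheme as the response-function fit.  The input amplitude is constrained
    non-negative by default (fitted fear-conditioning inputs are dilatory);
    pass ``allow_negative=True`` to lift that.
    """
    y = np.asarray(observed_diff, dtype=float)
    if y.ndim != 1:
        raise ValueError("observed_diff must be one-dimensional")
    if not np.all(np.isfinite(y)):
        raise ValueError("observed_diff contains non-finite values")
    if kernel is None:
        kernel = default_luminance_rf(sampling_rate)
    if abs(kernel.sampling_rate - sampling_rate) > 1e-9:
        raise ValueError("waveform and kernel must share the sampling rate")
    if y.size < kernel.kernel.size:
        raise ValueError("waveform must be at least as long as the kernel")
    if float(np.max(np.abs(kernel.kernel))) == 0.0:
        raise ValueError("zero kernel")

    dt = 1.0 / sampling_rate
    t = np.arange(y.size) * dt

    if float(np.max(np.abs(y))) < 1e-12:
        return InputFit(
            params=GammaParams(2.0, 1.0, 0.0, 0.0),
            rss=float(y @ y), converged=True, degenerate=True,
            kernel_provenance=kernel.provenance,
        )

    # input peak precedes the output peak by roughly the kernel's peak latency
    t_out = t[int(np.argmax(np.abs(y)))]
    t_kern = np.argmax(np.abs(kernel.kernel)) * dt
    t_in = max(t_out - t_kern, 0.1)
    area = abs(float(np.trapezoid(y, t))) / max(float(np.sum(kernel.kernel) * dt), 1e-6)
    area = max(area, 1e-6)
    starts = []
    for k0 in (1.5, 3.0, 6.0):
        for t00 in (0.0, t_in / 2.0):
            theta0 = max((t_in - t00) / max(k0 - 1.0, 0.5), 1e-3)
            c0 = area if allow_negative else np.log(area)
            starts.append(np.array([np.log(k0), np.log(theta0), c0, t00]))

    best = None
    any_converged = False
    for x0 in starts:
        res = optimize.minimize(
            _input_objective, x0, args=(t, y, kernel.kernel, dt, allow_negative),
            method="Nelder-Mead",
            options={"maxiter": max_iter, "maxfev": max_iter,
                     "xatol": 1e-10, "fatol": 1e-14},
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    c = best.x[2] if allow_negative else float(np.exp(best.x[2]))
    params = GammaParams(
        k=float(np.exp(best.x[0])), theta=float(np.exp(best.x[1])),
        c=float(c), t0=float(max(best.x[3], 0.0)),
    )
    return InputFit(
        params=params, rss=float(best.fun), converged=any_converged,
        degenerate=False, kernel_provenance=kernel.provenance,
    )
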