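"""Raw eye-tracker traces to z-scored, validity-masked session time series.

Samples are treated as missing when the gaze deviates more than a threshold
(default +-5 degrees visual angle) from screen centre in either direction, or
when the pupil sample is absent (NaN or zero, as emitted by video trackers
during blinks).  All causes of missingness are pooled.  Missing spans are
linearly interpolated only to keep the series continuous for normalisation
and segment extraction; they stay flagged invalid and are excluded before
model inversion.  The pupil series is z-scored within each session using
valid samples only.  The time series is never temporally filtered.

A participant whose pooled missing fraction exceeds 35% is flagged for
exclusion from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RawTrace",
    "CleanTrace",
    "ScreenGeometry",
    "pixels_to_degrees",
    "preprocess_trace",
    "participant_missing_fraction",
    "downsample",
    "Segments",
    "extract_segments",
]

#: Gaze eccentricity (degrees visual angle) beyond which a sample is missing.
GAZE_THRESHOLD_DEG = 5.0
#: Missing-data fraction above which a participant is excluded.
EXCLUSION_MISSING_FRACTION = 0.35


@dataclass
class RawTrace:
    """One eye's raw recording for one session.

    time (s), pupil (device units; NaN/0 = missing), gaze_x/gaze_y (degrees
    visual angle from screen centre).
    """

    time: np.ndarray
    pupil: np.ndarray
    gaze_x: np.ndarray
    gaze_y: np.ndarray
    sampling_rate: float
    eye: str = "left"
    session_id: str = "session1"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pupil = np.asarray(self.pupil, dtype=float)
        self.gaze_x = np.asarray(self.gaze_x, dtype=float)
        self.gaze_y = np.asarray(self.gaze_y, dtype=float)
        n = self.time.size
        if not (self.pupil.size == self.gaze_x.size == self.gaze_y.size == n):
            raise ValueError("time, pupil and gaze channels must share length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            nominal = 1.0 / self.sampling_rate
            if np.any(np.abs(dt - nominal) > 0.01 * nominal):
                raise ValueError(
                    "sampling interval deviates more than 1% from nominal rate"
                )

    @classmethod
    def from_tsv(cls, path, sampling_rate: float, eye: str = "left",
                 session_id: str = "session1") -> "RawTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(
            time=df["time_s"].to_numpy(),
            pupil=df["pupil"].to_numpy(),
            gaze_x=df["gaze_x_deg"].to_numpy(),
            gaze_y=df["gaze_y_deg"].to_numpy(),
            sampling_rate=sampling_rate,
            eye=eye,
            session_id=session_id,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"time_s": self.time, "pupil": self.pupil,
             "gaze_x_deg": self.gaze_x, "gaze_y_deg": self.gaze_y}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class CleanTrace:
    """z-scored pupil series with validity mask for one session."""

    pupil_z: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    session_id: str = "session1"
    eye: str = "left"
    excluded: bool = False

    def __post_init__(self) -> None:
        self.pupil_z = np.asarray(self.pupil_z, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.pupil_z.size != self.valid.size:
            raise ValueError("pupil_z and valid must share length")

    @property
    def n_samples(self) -> int:
        return self.pupil_z.size

    @property
    def missing_fraction(self) -> float:
        return 1.0 - self.valid.sum() / self.valid.size

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"pupil_z": self.pupil_z, "valid": self.valid.astype(int)}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sampling_rate: float,
                 session_id: str = "session1") -> "CleanTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(pupil_z=df["pupil_z"].to_numpy(),
                   valid=df["valid"].to_numpy().astype(bool),
                   sampling_rate=sampling_rate, session_id=session_id)


@dataclass(frozen=True)
class ScreenGeometry:
    """Screen geometry for converting gaze pixels to degrees visual angle."""

    width_px: float
    height_px: float
    width_mm: float
    height_mm: float
    distance_mm: float


def pixels_to_degrees(x_px, y_px, geometry: ScreenGeometry):
    """Convert gaze pixel coordinates to degrees from screen centre."""
    x_mm = (np.asarray(x_px, float) - geometry.width_px / 2.0) * (
        geometry.width_mm / geometry.width_px
    )
    y_mm = (np.asarray(y_px, float) - geometry.height_px / 2.0) * (
        geometry.height_mm / geometry.height_px
    )
    x_deg = np.degrees(np.arctan2(x_mm, geometry.distance_mm))
    y_deg = np.degrees(np.arctan2(y_mm, geometry.distance_mm))
    return x_deg, y_deg


def _invalid_mask(trace: RawTrace, gaze_threshold: float) -> np.ndarray:
    pupil_missing = ~np.isfinite(trace.pupil) | (trace.pupil == 0.0)
    gaze_bad = (
        ~np.isfinite(trace.gaze_x)
        | ~np.isfinite(trace.gaze_y)
        | (np.abs(trace.gaze_x) > gaze_threshold)
        | (np.abs(trace.gaze_y) > gaze_threshold)
    )
    return pupil_missing | gaze_bad


def _interpolate_invalid(x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    idx = np.arange(x.size)
    out = x.copy()
    out[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
    return out


def preprocess_trace(
    left: RawTrace,
    right: RawTrace | None = None,
    gaze_threshold: float = GAZE_THRESHOLD_DEG,
    exclusion_threshold: float = EXCLUSION_MISSING_FRACTION,
) -> CleanTrace:
    """Select an eye, mask missing samples, interpolate and z-score a session.

    The eye with the strictly smaller invalid-sample count is analysed (ties
    go to the left eye).  Invalid spans are linearly interpolated for
    continuity but remain flagged invalid.  z-scoring statistics use valid
    samples only.  ``excluded`` is set when the session's missing fraction
    exceeds ``exclusion_threshold``; participant-level pooling across
    sessions is done by :func:`participant_missing_fraction`.
    """
    candidates = [left] if right is None else [left, right]
    masks = [_invalid_mask(tr, gaze_threshold) for tr in candidates]
    best = int(np.argmin([m.sum() for m in masks]))  # argmin tie -> first (left)
    trace, invalid = candidates[best], masks[best]
    valid = ~invalid
    if not valid.any():
        raise ValueError(
            f"session {trace.session_id}: every sample is invalid"
        )
    mu = trace.pupil[valid].mean()
    sd = trace.pupil[valid].std()
    if sd == 0.0:
        raise ValueError(
            f"session {trace.session_id}: zero variance over valid samples"
        )
    filled = _interpolate_invalid(trace.pupil, valid)
    z = (filled - mu) / sd
    clean = CleanTrace(
        pupil_z=z,
        valid=valid,
        sampling_rate=trace.sampling_rate,
        session_id=trace.session_id,
        eye=trace.eye,
    )
    clean.excluded = clean.missing_fraction > exclusion_threshold
    return clean


def participant_missing_fraction(traces: list[CleanTrace]) -> float:
    """Pooled missing fraction across a participant's sessions."""
    total = sum(t.n_samples for t in traces)
    missing = sum(int((~t.valid).sum()) for t in traces)
    return missing / total


def downsample(trace: CleanTrace, target_rate: float) -> CleanTrace:
    """Decimate a clean trace to an integer-divisor target rate.

    Takes every (source/target)-th sample; a decimated sample is invalid if
    any source sample in its bin is invalid, so interpolated values never
    gain validity.  No anti-alias filtering is applied, consistent with the
    unfiltered analysis pipeline.
    """
    ratio = trace.sampling_rate / target_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError(
            f"source rate {trace.sampling_rate} is not an integer multiple "
            f"of target rate {target_rate}"
        )
    if factor == 1:
        return CleanTrace(
            pupil_z=trace.pupil_z.copy(), valid=trace.valid.copy(),
            sampling_rate=trace.sampling_rate, session_id=trace.session_id,
            eye=trace.eye, excluded=trace.excluded,
        )
    n_out = int(np.ceil(trace.n_samples / factor))
    z = trace.pupil_z[::factor]
    pad = n_out * factor - trace.n_samples
    v = trace.valid
    if pad:
        v = np.concatenate([v, np.ones(pad, dtype=bool)])
    valid = v.reshape(n_out, factor).all(axis=1)
    return CleanTrace(
        pupil_z=z, valid=valid, sampling_rate=target_rate,
        session_id=trace.session_id, eye=trace.eye, excluded=trace.excluded,
    )


@dataclass
class Segments:
    """Per-trial 10-s segments with validity masks.

    values: (n_trials, n_samples); invalid samples hold interpolated (or
    padded NaN) values and are flagged in ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray
    conditions: np.ndarray
    include: np.ndarray
    sampling_rate: float
    duration: float
    baseline_corrected: bool
    trial_ids: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.values.shape[0])

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    def condition_mean(self, condition: str, included_only: bool = True) -> np.ndarray:
        """Mean time course over (included) trials of one condition.

        Invalid samples are dropped per-timepoint before averaging.
        """
        sel = self.conditions == condition
        if included_only:
            sel &= self.include
        if not sel.any():
            raise ValueError(f"no trials in condition {condition!r}")
        vals = np.where(self.valid[sel], self.values[sel], np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(vals, axis=0)


def extract_segments(
    trace: CleanTrace,
    events,
    duration: float = 10.0,
    baseline_correct: bool = True,
) -> Segments:
    """Cut per-trial segments of ``duration`` seconds starting at each onset.

    Segment i starts at the sample nearest onset i and has
    floor(duration * rate) samples.  Segments overrunning the session end are
    padded with NaN samples flagged invalid, preserving trial counts.  With
    ``baseline_correct``, the segment's first sample value is subtracted from
    the whole segment.
    """
    sr = trace.sampling_rate
    n_seg = int(np.floor(duration * sr))
    n = trace.n_samples
    values = np.full((len(events.onsets), n_seg), np.nan)
    valid = np.zeros((len(events.onsets), n_seg), dtype=bool)
    for i, onset in enumerate(events.onsets):
        start = int(round(onset * sr))
        if start < 0 or start >= n:
            raise IndexError(
                f"trial {i} onset {onset} s falls outside the trace"
            )
        stop = min(start + n_seg, n)
        m = stop - start
        values[i, :m] = trace.pupil_z[start:stop]
        valid[i, :m] = trace.valid[start:stop]
        if baseline_correct:
            values[i, :m] -= values[i, 0]
    return Segments(
        values=values,
        valid=valid,
        conditions=np.asarray(events.conditions),
        include=np.asarray(events.include, dtype=bool),
        sampling_rate=sr,
        duration=duration,
        baseline_corrected=baseline_correct,
    )
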