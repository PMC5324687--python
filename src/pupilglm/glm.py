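"""GLM inversion of pupil time series: Y = X beta + epsilon.

The design matrix X contains, per modelled event class, the discrete
convolution of a unit-impulse train at that class's onsets with a response
basis component, plus intercept column(s).  Inversion is minimum-norm least
squares on valid samples only (missing-data rows are removed first), the
direct analogue of pseudoinverse estimation.  Per-condition response
amplitudes are the corresponding betas for a one-component basis, or the
maximal signed excursion of the reconstructed response (sum of beta-weighted
components) for multi-component bases.

Model variants
--------------
cs_only             CS+US- and CS- onsets, canonical basis (3 columns
                    including intercept).  Reinforced trials are left
                    unmodelled so the US response cannot bias the contrast.
cs_plus_derivative  as above with the analytical derivative as a second
                    basis component per class (5 columns).
extended_us         one regressor each for all CS+ onsets, all CS- onsets,
                    US+ deliveries, US omissions in CS+US- trials and
                    "omissions" at the corresponding latency in CS- trials
                    (6 columns).  US-class impulses sit at (would-be) US
                    times and are convolved with the US kernel re-referenced
                    to US onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocessing import CleanTrace
from .response_model import BasisSet

__all__ = [
    "EventTable",
    "DesignMatrix",
    "GLMResult",
    "build_design",
    "invert_glm",
    "reconstruct_amplitudes",
    "fit_participant",
    "VARIANTS",
]

CONDITIONS = ("CSpUSp", "CSpUSm", "CSm")
VARIANTS = ("cs_only", "cs_plus_derivative", "extended_us")


@dataclass
class EventTable:
    """Trial onsets with condition labels and inclusion flags for one session."""

    onsets: np.ndarray
    conditions: np.ndarray
    include: np.ndarray
    cs_us_interval: float = 3.5

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=object)
        self.include = np.asarray(self.include, dtype=bool)
        if not (self.onsets.size == self.conditions.size == self.include.size):
            raise ValueError("onsets, conditions, include must share length")
        if self.onsets.size > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        bad = set(self.conditions) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")

    def __len__(self) -> int:
        return self.onsets.size

    @property
    def us_onsets(self) -> np.ndarray:
        """US delivery times for reinforced trials (NaN elsewhere)."""
        return np.where(
            self.conditions == "CSpUSp",
            self.onsets + self.cs_us_interval,
            np.nan,
        )

    def onsets_for(self, conditions, included_only: bool = True) -> np.ndarray:
        sel = np.isin(self.conditions, list(conditions))
        if included_only:
            sel &= self.include
        return self.onsets[sel]

    @classmethod
    def from_tsv(cls, path, cs_us_interval: float = 3.5) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        return cls(
            onsets=df["onset_s"].to_numpy(),
            conditions=df["condition"].to_numpy(),
            include=df["include"].to_numpy().astype(bool),
            cs_us_interval=cs_us_interval,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "onset_s": self.onsets,
                "condition": self.conditions,
                "include": self.include.astype(int),
            }
        ).to_csv(path, sep="\t", index=False)


@dataclass
class DesignMatrix:
    X: np.ndarray
    labels: tuple[str, ...]
    sampling_rate: float
    valid_rows: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape[1] != len(self.labels):
            raise ValueError("one label per column required")
        if self.valid_rows.size != self.X.shape[0]:
            raise ValueError("valid_rows must match row count")

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class GLMResult:
    betas: np.ndarray
    labels: tuple[str, ...]
    model_variant: str
    residual_variance: float
    n_valid: int
    amplitudes: dict | None = None

    def beta(self, label: str) -> float:
        return float(self.betas[self.labels.index(label)])


def _impulse_column(
    onsets: np.ndarray, kernel: np.ndarray, n_samples: int, sampling_rate: float
) -> np.ndarray:
    # direct template placement: exact impulse-train convolution, truncated
    col = np.zeros(n_samples)
    for onset in onsets:
        idx = int(round(onset * sampling_rate))
        if 0 <= idx < n_samples:
            stop = min(idx + kernel.size, n_samples)
            col[idx:stop] += kernel[: stop - idx]
    return col


def _event_classes(events: EventTable, variant: str) -> list[tuple[str, np.ndarray, str]]:
    """(label, onsets, kernel-group) per regressor class of a variant."""
    if variant in ("cs_only", "cs_plus_derivative"):
        return [
            ("CSpUSm", events.onsets_for(["CSpUSm"]), "cs"),
            ("CSm", events.onsets_for(["CSm"]), "cs"),
        ]
    if variant == "extended_us":
        usp = events.us_onsets[
            (events.conditions == "CSpUSp") & events.include
        ]
        return [
            ("CSp", events.onsets_for(["CSpUSp", "CSpUSm"]), "cs"),
            ("CSm", events.onsets_for(["CSm"]), "cs"),
            ("USp", usp, "us"),
            ("USm_CSpUSm",
             events.onsets_for(["CSpUSm"]) + events.cs_us_interval, "us"),
            ("USm_CSm",
             events.onsets_for(["CSm"]) + events.cs_us_interval, "us"),
        ]
    raise ValueError(f"unknown model variant {variant!r}; valid: {VARIANTS}")


def build_design(
    events: EventTable,
    basis: BasisSet,
    n_samples: int,
    variant: str = "cs_only",
    us_basis: BasisSet | None = None,
    intercept: bool = True,
) -> DesignMatrix:
    """Convolve event impulse trains with basis components into a design.

    ``basis`` carries the CS kernel(s); ``extended_us`` additionally needs
    ``us_basis`` (single-component US kernel referenced to US onset, see
    :func:`pupilglm.response_model.us_params_relative_to_us`).  Excluded
    trials contribute no impulse; convolution tails beyond the session end
    are truncated.
    """
    if variant == "cs_only" and basis.n_components != 1:
        raise ValueError("cs_only requires a single-component basis")
    if variant == "cs_plus_derivative" and basis.n_components != 2:
        raise ValueError("cs_plus_derivative requires canonical + derivative basis")
    if variant == "extended_us":
        if basis.n_components != 1:
            raise ValueError("extended_us uses a single-component CS basis")
        if us_basis is None or us_basis.n_components != 1:
            raise ValueError("extended_us requires a single-component us_basis")

    sr = basis.sampling_rate
    cols, labels = [], []
    for label, onsets, group in _event_classes(events, variant):
        if onsets.size == 0:
            raise ValueError(
                f"variant {variant!r} requires events of class {label!r}, none present"
            )
        kernels = basis if group == "cs" else us_basis
        for comp, comp_label in zip(kernels.components, kernels.labels):
            cols.append(_impulse_column(onsets, comp, n_samples, sr))
            labels.append(
                label if kernels.n_components == 1 else f"{label}:{comp_label}"
            )
    if intercept:
        cols.append(np.ones(n_samples))
        labels.append("intercept")
    return DesignMatrix(
        X=np.column_stack(cols),
        labels=tuple(labels),
        sampling_rate=sr,
        valid_rows=np.ones(n_samples, dtype=bool),
    )


def invert_glm(trace: CleanTrace, design: DesignMatrix,
               variant: str = "cs_only") -> GLMResult:
    """Least-squares inversion on valid rows only.

    Minimum-norm solution (numpy lstsq, equivalent to pseudoinverse
    estimation); rank deficiency on the valid rows raises, as does having
    fewer valid rows than columns.
    """
    if trace.n_samples != design.X.shape[0]:
        raise ValueError("trace length and design rows differ")
    rows = trace.valid & design.valid_rows
    n_valid = int(rows.sum())
    if n_valid <= design.n_columns:
        raise ValueError(
            f"only {n_valid} valid samples for {design.n_columns} columns"
        )
    Xv = design.X[rows]
    yv = trace.pupil_z[rows]
    if np.linalg.matrix_rank(Xv) < design.n_columns:
        raise np.linalg.LinAlgError(
            "design matrix is rank deficient on valid rows"
        )
    betas, _, _, _ = np.linalg.lstsq(Xv, yv, rcond=None)
    resid = yv - Xv @ betas
    dof = n_valid - design.n_columns
    return GLMResult(
        betas=betas,
        labels=design.labels,
        model_variant=variant,
        residual_variance=float(resid @ resid) / dof,
        n_valid=n_valid,
    )


def reconstruct_amplitudes(result: GLMResult, basis: BasisSet) -> dict[str, float]:
    """Per-condition response amplitude from fitted betas.

    One-component basis: the amplitude is the condition's beta itself.
    Multi-component basis: the estimated response is reconstructed as the
    beta-weighted sum of components and summarised by its maximal signed
    excursion, collapsing the first level into one parameter per condition.
    """
    conditions: dict[str, dict[str, float]] = {}
    for label, b in zip(result.labels, result.betas):
        if label == "intercept" or label.startswith("intercept"):
            continue
        cond, _, comp = label.partition(":")
        conditions.setdefault(cond, {})[comp or "canonical"] = float(b)
    out: dict[str, float] = {}
    for cond, comps in conditions.items():
        if basis.n_components == 1:
            out[cond] = next(iter(comps.values()))
        else:
            for lab in basis.labels:
                if lab not in comps:
                    raise ValueError(
                        f"missing beta for component {lab!r} of condition {cond!r}"
                    )
            recon = sum(
                comps[lab] * comp
                for lab, comp in zip(basis.labels, basis.components)
            )
            out[cond] = float(recon[np.argmax(np.abs(recon))])
    return out


def fit_participant(
    sessions: list[tuple[CleanTrace, EventTable]],
    basis: BasisSet,
    variant: str = "cs_only",
    us_basis: BasisSet | None = None,
) -> GLMResult:
    """One GLM per participant: sessions concatenated, shared condition betas,
    one intercept column per session (z-scoring is per session, so
    session-specific intercepts absorb level differences)."""
    if not sessions:
        raise ValueError("no sessions provided")
    designs = [
        build_design(ev, basis, tr.n_samples, variant, us_basis, intercept=False)
        for tr, ev in sessions
    ]
    labels = designs[0].labels
    for d in designs[1:]:
        if d.labels != labels:
            raise ValueError("sessions yield inconsistent regressor sets")
    cond_block = np.vstack([d.X for d in designs])
    n_total = cond_block.shape[0]
    icepts = np.zeros((n_total, len(sessions)))
    start = 0
    icept_labels = []
    for j, (tr, _) in enumerate(sessions):
        icepts[start:start + tr.n_samples, j] = 1.0
        start += tr.n_samples
        icept_labels.append(f"intercept:{tr.session_id or j}")
    design = DesignMatrix(
        X=np.hstack([cond_block, icepts]),
        labels=tuple(labels) + tuple(icept_labels),
        sampling_rate=basis.sampling_rate,
        valid_rows=np.ones(n_total, dtype=bool),
    )
    concat = CleanTrace(
        pupil_z=np.concatenate([tr.pupil_z for tr, _ in sessions]),
        valid=np.concatenate([tr.valid for tr, _ in sessions]),
        sampling_rate=sessions[0][0].sampling_rate,
        session_id="concatenated",
    )
    result = invert_glm(concat, design, variant)
    result.amplitudes = reconstruct_amplitudes(result, basis)
    return result
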