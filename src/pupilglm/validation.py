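"""Predictive-validity framework for comparing quantification methods.

Each method delivers one CS+ and one CS- estimate per participant.  Its
validity is how well these estimates discriminate the known trial types,
quantified by an ordinary least-squares regression in which the CS-type
indicator (CS+ = 1, CS- = 0) is the dependent variable and the estimates the
independent variable, complemented by subject-specific intercepts.  The
residual sum of squares maps to

    AIC = n log(RSS / n) + 2 (r + 1)

with n observations (two per participant) and r regressors (participants + 1:
the subject intercepts plus one slope).  n and r are identical across
methods, so AIC differences reduce to n log(RSS1 / RSS2) — differences in
negative log likelihood.  |dAIC| > 3 is treated as decisive (the inferior
model's posterior probability is below e^-3, about .05).  The same data admit
a paired t test across participants, reported with the paired effect size
d = t / sqrt(n_participants).

The 1/0 indicator coding is immaterial: any affine recoding a*y + b changes
every method's RSS by the factor a^2, so AIC differences are invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "SecondLevelData",
    "ValidityReport",
    "predictive_validity",
    "paired_t_and_d",
    "validity_report",
    "compare_methods",
    "aic_from_rss",
    "cohens_d_from_t",
    "p_from_t",
    "DECISIVE_DELTA_AIC",
    "RSS_FLOOR",
]

DECISIVE_DELTA_AIC = 3.0
RSS_FLOOR = 1e-12


@dataclass
class SecondLevelData:
    """Per-participant (CS+, CS-) estimate pairs from one method."""

    participants: np.ndarray
    cs_plus: np.ndarray
    cs_minus: np.ndarray

    def __post_init__(self) -> None:
        self.participants = np.asarray(self.participants)
        self.cs_plus = np.asarray(self.cs_plus, dtype=float)
        self.cs_minus = np.asarray(self.cs_minus, dtype=float)
        if not (self.participants.size == self.cs_plus.size == self.cs_minus.size):
            raise ValueError("one CS+ and one CS- value per participant required")
        if np.unique(self.participants).size != self.participants.size:
            raise ValueError("duplicate participant ids")
        if not (np.all(np.isfinite(self.cs_plus)) and np.all(np.isfinite(self.cs_minus))):
            raise ValueError("absent (non-finite) estimates are not allowed")

    @property
    def n_participants(self) -> int:
        return self.participants.size


@dataclass
class ValidityReport:
    method: str
    rss: float
    n_obs: int
    n_regressors: int
    aic: float
    t_statistic: float
    df: int
    p_value: float
    cohens_d: float
    degenerate: bool = False


def aic_from_rss(rss: float, n_obs: int, n_regressors: int) -> float:
    """AIC = n log(RSS/n) + 2 (r + 1)."""
    return n_obs * np.log(rss / n_obs) + 2.0 * (n_regressors + 1)


def predictive_validity(data: SecondLevelData) -> tuple[float, float, bool]:
    """Second-level OLS of CS type on estimates; returns (RSS, AIC, degenerate).

    Design: one estimates column plus one dummy per participant (the dummies
    span the intercept).  RSS below the numerical floor marks a degenerate,
    perfectly separating fit; the RSS is floored rather than letting the AIC
    run to -inf.
    """
    P = data.n_participants
    if P < 2:
        raise ValueError("need at least 2 participants")
    estimates = np.concatenate([data.cs_plus, data.cs_minus])
    if np.ptp(estimates) == 0.0:
        raise ValueError("all estimates identical; validity regression undefined")
    y = np.concatenate([np.ones(P), np.zeros(P)])
    dummies = np.vstack([np.eye(P), np.eye(P)])
    X = np.column_stack([estimates, dummies])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("collinear second-level design")
    fit = sm.OLS(y, X).fit()
    rss = float(fit.ssr)
    degenerate = rss < RSS_FLOOR
    if degenerate:
        rss = RSS_FLOOR
    n_obs = 2 * P
    r = P + 1
    return rss, float(aic_from_rss(rss, n_obs, r)), degenerate


def paired_t_and_d(data: SecondLevelData) -> tuple[float, int, float, float]:
    """Two-sided paired t of CS+ vs CS- values; d = t / sqrt(participants)."""
    diffs = data.cs_plus - data.cs_minus
    if data.n_participants < 2:
        raise ValueError("need at least 2 participants")
    if np.std(diffs, ddof=1) == 0.0:
        raise ValueError("zero variance of paired differences; t undefined")
    res = stats.ttest_rel(data.cs_plus, data.cs_minus)
    t = float(res.statistic)
    df = data.n_participants - 1
    return t, df, float(res.pvalue), cohens_d_from_t(t, data.n_participants)


def cohens_d_from_t(t: float, n_participants: int) -> float:
    """Paired-design effect size d = t / sqrt(n)."""
    return t / np.sqrt(n_participants)


def p_from_t(t: float, df: int) -> float:
    """Two-sided p for a t statistic."""
    return float(2.0 * stats.t.sf(abs(t), df))


def validity_report(data: SecondLevelData, method: str) -> ValidityReport:
    rss, aic, degenerate = predictive_validity(data)
    t, df, p, d = paired_t_and_d(data)
    return ValidityReport(
        method=method, rss=rss, n_obs=2 * data.n_participants,
        n_regressors=data.n_participants + 1, aic=aic,
        t_statistic=t, df=df, p_value=p, cohens_d=d, degenerate=degenerate,
    )


def compare_methods(
    reports: list[ValidityReport], reference: str
) -> pd.DataFrame:
    """dAIC of every method against a reference, with decisiveness verdicts.

    dAIC = AIC(method) - AIC(reference); negative favours the method.
    Comparability requires identical n and r across reports (guaranteed when
    all methods are evaluated on the same participants).
    """
    by_name = {r.method: r for r in reports}
    if reference not in by_name:
        raise KeyError(f"reference method {reference!r} not among reports")
    ref = by_name[reference]
    for r in reports:
        if r.n_obs != ref.n_obs or r.n_regressors != ref.n_regressors:
            raise ValueError(
                f"method {r.method!r} has n={r.n_obs}, r={r.n_regressors}; "
                f"reference has n={ref.n_obs}, r={ref.n_regressors} — "
                "AIC values are not comparable"
            )
    rows = []
    for r in reports:
        delta = r.aic - ref.aic
        rows.append(
            {
                "method": r.method,
                "aic": r.aic,
                "delta_aic": delta,
                "verdict": "decisive" if abs(delta) > DECISIVE_DELTA_AIC
                else "indecisive",
                "favours": (
                    "method" if delta < 0 else
                    "reference" if delta > 0 else "neither"
                ),
            }
        )
    return pd.DataFrame(rows)
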