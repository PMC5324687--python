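"""Classical trial-wise quantification: signed peak and signed AUC.

These are the baseline methods the model-based approach is compared against.
Both operate on baseline-corrected per-trial segments within a scoring window
after CS onset (default 10 s, the same window the response function is
defined on; a window of CS duration can be passed instead).  "Signed peak" is
the maximal absolute excursion with its sign retained — consistent with the
amplitude rule used for reconstructed model responses — and "signed AUC" is
the trapezoidal time integral over valid samples.  Per-condition,
per-participant means over included trials summarise the scores; reinforced
(CS+US+) trials are excluded from classical CS scoring by default so the US
response cannot contaminate the CS+/CS- contrast.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocessing import Segments

__all__ = ["peak_score", "auc_score", "score_segments", "condition_summaries"]


def peak_score(values, valid, sampling_rate: float, window: float = 10.0) -> float:
    """Signed maximal excursion within the window; NaN if no valid sample."""
    values = np.asarray(values, float)
    valid = np.asarray(valid, bool)
    n_win = int(np.floor(window * sampling_rate))
    v = values[:n_win]
    m = valid[:n_win] & np.isfinite(v)
    if not m.any():
        return float("nan")
    sel = v[m]
    return float(sel[np.argmax(np.abs(sel))])


def auc_score(values, valid, sampling_rate: float, window: float = 10.0) -> float:
    """Signed trapezoidal area (z x s) over valid samples within the window.

    Integrates over the valid samples' actual times, so isolated invalid
    samples bridge linearly; NaN if fewer than two valid samples.
    """
    values = np.asarray(values, float)
    valid = np.asarray(valid, bool)
    n_win = int(np.floor(window * sampling_rate))
    v = values[:n_win]
    m = valid[:n_win] & np.isfinite(v)
    if m.sum() < 2:
        return float("nan")
    t = np.nonzero(m)[0] / sampling_rate
    return float(np.trapezoid(v[m], t))


def score_segments(
    segments: Segments, method: str, window: float = 10.0
) -> pd.DataFrame:
    """Score every trial of a segment set with one method.

    Returns a tidy frame: trial_id, condition, include, method, window_s,
    value (NaN = absent score).
    """
    if method not in ("peak", "auc"):
        raise ValueError(f"unknown scoring method {method!r}")
    fn = peak_score if method == "peak" else auc_score
    rows = []
    for i in range(segments.n_trials):
        rows.append(
            {
                "trial_id": int(segments.trial_ids[i]),
                "condition": segments.conditions[i],
                "include": bool(segments.include[i]),
                "method": method,
                "window_s": window,
                "value": fn(
                    segments.values[i], segments.valid[i],
                    segments.sampling_rate, window,
                ),
            }
        )
    return pd.DataFrame(rows)


def condition_summaries(
    scores: pd.DataFrame, exclude_reinforced: bool = True
) -> pd.Series:
    """Per-condition mean over included, non-absent trials.

    CS+US+ trials are dropped by default (classical CS scoring uses
    unreinforced trials only).  An empty condition raises, naming it.
    """
    df = scores[scores["include"] & scores["value"].notna()]
    if exclude_reinforced:
        df = df[df["condition"] != "CSpUSp"]
    if df.empty:
        raise ValueError("no scoreable trials remain after exclusions")
    means = df.groupby("condition")["value"].mean()
    wanted = set(df["condition"].unique())
    missing = wanted - set(means.index)
    if missing:
        raise ValueError(f"empty condition(s): {sorted(missing)}")
    return means
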