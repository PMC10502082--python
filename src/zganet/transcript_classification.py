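"""Switch detection and per-mutant regulation status for zygotic transcripts.

A transcript is called zygotically expressed (switch UP) when a two-level
step function fits its wild-type time course significantly better than a
constant, subject to an expression floor.  Against each mutant a transcript
is then labelled DOWN (at least two-fold lower with t-test p < 0.05 at one
or more timepoints at or after the switch), UP (two-fold higher at any
timepoint), U (both, at different timepoints) or SAME.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TIMEPOINTS",
    "SwitchCall",
    "RegulationStatus",
    "detect_switch",
    "regulation_status",
    "normalize_expression_matrix",
    "peak_time_summary",
]

#: the eight sampled timepoints of the study window (hpf)
TIMEPOINTS = (2.5, 3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0)


@dataclass
class SwitchCall:
    direction: str  # UP | DOWN | NONE
    switch_time: float | None  # first timepoint of the high segment
    p_value: float
    max_expression: float


@dataclass
class RegulationStatus:
    gene: str
    mutant: str
    status: str  # DOWN | UP | SAME | U


def _as_replicate_matrix(values) -> np.ndarray:
    """Coerce input to a (replicates, timepoints) array."""
    a = np.asarray(values, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.ndim != 2:
        raise ValueError("expected a 1-D series or (replicates, timepoints) matrix")
    return a


def detect_switch(
    values,
    timepoints=TIMEPOINTS,
    expr_threshold: float = 100.0,
    p_threshold: float = 0.15,
) -> SwitchCall:
    """Step-function switch detection on one gene's replicate time courses.

    For every split between consecutive timepoints a two-level step model is
    fitted by least squares across replicates; the best split (smallest
    residual sum of squares) is tested against the constant model with an
    F-test.  The call is NONE when the maximal expression does not exceed
    ``expr_threshold`` or the step p-value is not below ``p_threshold``.
    """
    t = np.asarray(timepoints, dtype=float)
    if t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing with >= 2 points")
    Y = _as_replicate_matrix(values)
    if Y.shape[1] != t.size:
        raise ValueError("values and timepoints are not aligned")
    flat = Y.ravel()
    n = flat.size
    max_expr = float(np.max(Y))

    grand = float(np.mean(flat))
    rss0 = float(np.sum((flat - grand) ** 2))
    if rss0 == 0.0:
        return SwitchCall("NONE", None, 1.0, max_expr)

    best = None  # (rss1, split)
    for split in range(1, t.size):
        early = Y[:, :split]
        late = Y[:, split:]
        rss1 = float(np.sum((early - early.mean()) ** 2) + np.sum((late - late.mean()) ** 2))
        if best is None or rss1 < best[0]:
            best = (rss1, split)
    rss1, split = best
    df2 = n - 2
    if rss1 <= 0:
        p = 0.0
    else:
        F = (rss0 - rss1) / (rss1 / df2)
        p = float(stats.f.sf(F, 1, df2))
    early_mean = float(Y[:, :split].mean())
    late_mean = float(Y[:, split:].mean())
    direction = "UP" if late_mean > early_mean else "DOWN"
    if max_expr <= expr_threshold or p >= p_threshold:
        return SwitchCall("NONE", None, p, max_expr)
    # first timepoint of the high segment
    switch_time = float(t[split]) if direction == "UP" else float(t[0])
    return SwitchCall(direction, switch_time, p, max_expr)


def regulation_status(
    gene: str,
    mutant: str,
    wt_values,
    mut_values,
    switch: SwitchCall,
    timepoints=TIMEPOINTS,
    fold: float = 2.0,
    p_threshold: float = 0.05,
) -> RegulationStatus:
    """Per-mutant DOWN/UP/SAME/U label for one zygotic transcript.

    DOWN needs a timepoint at or after the switch-UP time where the mutant is
    at least ``fold`` lower than wild type with Welch t-test p < 0.05; UP
    needs a two-fold-higher timepoint anywhere in the curve; a transcript
    satisfying both is undefined (U).
    """
    t = np.asarray(timepoints, dtype=float)
    W = _as_replicate_matrix(wt_values)
    M = _as_replicate_matrix(mut_values)
    if W.shape[1] != t.size or M.shape[1] != t.size:
        raise ValueError("values and timepoints are not aligned")
    switch_time = switch.switch_time if switch.switch_time is not None else t[0]

    down = up = False
    for k in range(t.size):
        w = W[:, k][np.isfinite(W[:, k])]
        m = M[:, k][np.isfinite(M[:, k])]
        if w.size < 2 or m.size < 2:
            continue  # timepoint without enough replicates: skipped
        mw, mm = float(np.mean(w)), float(np.mean(m))
        if mw <= 0 and mm <= 0:
            continue
        if np.allclose(w, w[0]) and np.allclose(m, m[0]) and np.isclose(w[0], m[0]):
            continue
        p = float(stats.ttest_ind(w, m, equal_var=False).pvalue)
        if t[k] >= switch_time - 1e-9 and mm <= mw / fold and p < p_threshold:
            down = True
        if mm >= fold * mw and p < p_threshold:
            up = True
    if down and up:
        status = "U"
    elif down:
        status = "DOWN"
    elif up:
        status = "UP"
    else:
        status = "SAME"
    return RegulationStatus(gene, mutant, status)


def normalize_expression_matrix(panel: pd.DataFrame) -> pd.DataFrame:
    """Expression/max normalization of a wide panel (genes x columns).

    Each gene row is divided by its maximum over the full time curve in all
    genotypes (all columns); all-zero genes stay zero and are flagged in the
    ``all_zero`` attribute of the returned frame.
    """
    values = panel.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("expression values must be non-negative")
    maxima = values.max(axis=1)
    flagged = maxima <= 0
    safe = np.where(flagged, 1.0, maxima)
    out = pd.DataFrame(values / safe[:, None], index=panel.index, columns=panel.columns)
    out.attrs["all_zero"] = list(panel.index[flagged])
    return out


def peak_time_summary(statuses: pd.Series, peak_times: pd.Series) -> pd.DataFrame:
    """Median developmental peak-expression time per regulation-status group.

    ``statuses`` maps gene -> status label; ``peak_times`` maps gene -> time
    of maximal expression in normal development (hpf, external annotation).
    Genes lacking an annotation are dropped; empty groups get a NaN median.
    """
    df = pd.DataFrame({"status": statuses, "peak_time": peak_times}).dropna(subset=["status"])
    rows = []
    for status, grp in df.groupby("status", sort=True):
        times = grp["peak_time"].dropna()
        rows.append(
            {
                "status": status,
                "n": int(len(grp)),
                "n_annotated": int(times.size),
                "median_peak_time": float(np.median(times)) if times.size else np.nan,
            }
        )
    return pd.DataFrame(rows)
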