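"""Visual motor response (VMR) quantification.

Zebrafish larvae respond to abrupt light onset and offset with a brief burst
of locomotor activity.  Traces are recorded per larva at 1 Hz (activity
integrated into 1-second bins) over a protocol of a settling period followed
by alternating light ON/OFF phases.  For each light transition after
settling, the response peak is the maximal 1-second bin within a window
after the transition, and the baseline is the mean activity in a window
before it; per-larva ON and OFF peaks are the means over that transition
type's repeats, and normalized peaks (fold increase over baseline) are the
means of per-transition peak/baseline ratios.  Group contrasts use the
Wilcoxon rank-sum test (exact for small tie-free samples) with Bonferroni
correction, or Welch's unequal-variance t-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

ON, OFF = "ON", "OFF"


@dataclass
class Protocol:
    settle_s: int
    phase_s: int
    n_cycles: int  # ON/OFF pairs after settling

    @property
    def total_s(self) -> int:
        return self.settle_s + 2 * self.phase_s * self.n_cycles


@dataclass
class ActivityTrace:
    """One larva's 1 Hz activity trace with its light-state channel."""

    larva_id: str
    treatment: str
    activity: np.ndarray
    light_state: np.ndarray  # "ON"/"OFF" per second
    protocol: Protocol

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        self.light_state = np.asarray(self.light_state, dtype=object)
        if len(self.activity) != len(self.light_state):
            raise ValueError(f"{self.larva_id}: activity/light length mismatch")
        if np.any(self.activity < 0):
            raise ValueError(f"{self.larva_id}: negative activity")
        if len(self.activity) < self.protocol.total_s:
            raise ValueError(
                f"{self.larva_id}: trace shorter than settle + phases "
                f"({len(self.activity)} < {self.protocol.total_s})")


@dataclass
class VMRSummary:
    larva_id: str
    treatment: str
    on_peak: float
    off_peak: float
    base_pre_on: float
    base_pre_off: float
    norm_on: float   # NaN when every pre-ON baseline was zero
    norm_off: float


def bin_activity(
    timestamps: Sequence[float],
    values: Sequence[float],
    light_states: Optional[Sequence[str]] = None,
    *,
    bin_s: float = 1.0,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Integrate sub-second activity samples into 1-second bins.

    ``activity[t]`` is the sum of raw values with timestamp in [t, t+1);
    the light state of a bin is the majority state among its samples.
    Total activity is conserved.  Raises on negative or decreasing
    timestamps.
    """
    ts = np.asarray(timestamps, dtype=float)
    vals = np.asarray(values, dtype=float)
    if ts.size and ts[0] < 0:
        raise ValueError("negative timestamps")
    if np.any(np.diff(ts) < 0):
        raise ValueError("timestamps must be nondecreasing")
    n_bins = int(math.floor(ts[-1] / bin_s)) + 1 if ts.size else 0
    idx = np.minimum((ts / bin_s).astype(int), n_bins - 1)
    activity = np.bincount(idx, weights=vals, minlength=n_bins)
    light = None
    if light_states is not None:
        states = np.asarray(light_states, dtype=object)
        light = np.empty(n_bins, dtype=object)
        for b in range(n_bins):
            members = states[idx == b]
            if members.size == 0:
                light[b] = light[b - 1] if b else OFF
            else:
                on_votes = int(np.sum(members == ON))
                light[b] = ON if on_votes * 2 > members.size else OFF
    return activity, light


def _transitions(light_state: np.ndarray, after: int) -> list[tuple[int, str]]:
    """(second, new_state) for each light switch at or after ``after``."""
    out = []
    for t in range(1, len(light_state)):
        if light_state[t] != light_state[t - 1] and t >= after:
            out.append((t, str(light_state[t])))
    return out


def vmr_peaks(
    trace: ActivityTrace,
    *,
    peak_window_s: int = 30,
    base_window_s: int = 30,
    peak_mode: str = "max",
) -> VMRSummary:
    """Extract per-larva ON/OFF peaks and baseline-normalized responses.

    Per transition: peak = max (or mean, per ``peak_mode``) 1-second bin in
    the ``peak_window_s`` after it; baseline = mean over ``base_window_s``
    before it.  ON/OFF peaks are averaged over that type's duplicate
    transitions; normalized values average the per-transition
    peak/baseline ratios, skipping transitions with a zero baseline (an
    immobile larva cannot define a fold change) — all-zero baselines yield
    NaN, excluded downstream from group tests.
    """
    trans = _transitions(trace.light_state, trace.protocol.settle_s)
    if not trans:
        raise ValueError(f"{trace.larva_id}: no light transitions after settling")
    peaks: dict[str, list[float]] = {ON: [], OFF: []}
    bases: dict[str, list[float]] = {ON: [], OFF: []}
    ratios: dict[str, list[float]] = {ON: [], OFF: []}
    for t, state in trans:
        window = trace.activity[t:t + peak_window_s]
        peak = float(window.max() if peak_mode == "max" else window.mean())
        base = float(trace.activity[max(0, t - base_window_s):t].mean())
        peaks[state].append(peak)
        bases[state].append(base)
        if base > 0:
            ratios[state].append(peak / base)

    def mean_or_nan(xs: list[float]) -> float:
        return float(np.mean(xs)) if xs else float("nan")

    return VMRSummary(
        larva_id=trace.larva_id, treatment=trace.treatment,
        on_peak=mean_or_nan(peaks[ON]), off_peak=mean_or_nan(peaks[OFF]),
        base_pre_on=mean_or_nan(bases[ON]), base_pre_off=mean_or_nan(bases[OFF]),
        norm_on=mean_or_nan(ratios[ON]), norm_off=mean_or_nan(ratios[OFF]),
    )


def summaries_to_frame(summaries: Sequence[VMRSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in summaries])


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact null distribution when the combined sample is tie-free and of
    size <= 20; normal approximation with tie correction otherwise.
    Returns (U statistic, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    combined = np.concatenate([a, b])
    exact = combined.size <= 20 and np.unique(combined).size == combined.size
    res = stats.mannwhitneyu(a, b, alternative="two-sided",
                             method="exact" if exact else "asymptotic")
    return float(res.statistic), float(res.pvalue)


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Independent two-sample t-test with unequal variances (Welch)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t requires >= 2 observations per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def group_compare(
    treatment: pd.DataFrame,
    control: pd.DataFrame,
    metrics: Sequence[str] = ("norm_on", "norm_off"),
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Compare treatment vs control summaries metric by metric.

    NaN metric values (undefined normalizations) are dropped per group with
    the dropped count reported.  Two-sided p-values are Bonferroni-adjusted
    across the metrics in this report.
    """
    if method not in ("wilcoxon", "welch_t"):
        raise ValueError(f"unknown method {method!r}")
    if not len(treatment) or not len(control):
        raise ValueError("both groups must be nonempty")
    rows = []
    for metric in metrics:
        a = treatment[metric].to_numpy(dtype=float)
        b = control[metric].to_numpy(dtype=float)
        a_clean, b_clean = a[~np.isnan(a)], b[~np.isnan(b)]
        stat, p = (rank_sum_test(a_clean, b_clean) if method == "wilcoxon"
                   else welch_t_test(a_clean, b_clean))
        delta = float(np.mean(a_clean) - np.mean(b_clean))
        rows.append({
            "metric": metric, "method": method,
            "n_treatment": a_clean.size, "n_control": b_clean.size,
            "n_dropped": int(np.isnan(a).sum() + np.isnan(b).sum()),
            "mean_treatment": float(np.mean(a_clean)),
            "mean_control": float(np.mean(b_clean)),
            "delta": delta,
            "direction": "increase" if delta > 0 else ("decrease" if delta < 0 else "none"),
            "statistic": stat, "p": p,
        })
    report = pd.DataFrame(rows)
    m = len(report)
    report["p_bonferroni"] = np.minimum(1.0, report["p"] * m)
    return report


def recovery_compare(
    pre: pd.DataFrame,
    post_washout: pd.DataFrame,
    metrics: Sequence[str] = ("norm_on", "norm_off"),
    method: str = "wilcoxon",
) -> pd.DataFrame:
    """Pre-treatment vs post-washout comparison (unpaired).

    Same statistics as ``group_compare`` with ``post_washout`` in the
    treatment slot, so ``direction`` reports the change after washout.
    """
    if not len(post_washout):
        raise ValueError("post-washout group is empty")
    return group_compare(post_washout, pre, metrics=metrics, method=method)
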