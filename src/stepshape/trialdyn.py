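"""Trial-to-trial dynamics of the peak-height configuration.

Works on the sequence of (hip, knee) flexion angles at peak foot height
across a practice block or condition, plus the movement outcome (peak heel
height).  Three questions are answered:

1. *Where does the mean configuration break?*  Binary segmentation per
   execution variable with a maximal Welch-t statistic over candidate
   splits, whose significance is assessed by a permutation test (so the
   null false-positive rate is controlled at alpha despite the maximisation
   over split points).  Per-variable alpha is Bonferroni-corrected so the
   family-wise rate over execution variables stays at alpha.
2. *What happens between breaks?*  Each segment is labelled maintenance
   (no trial-to-trial trend in execution variables or outcome), covariation
   (execution trends with a stable outcome) or change (execution trends
   that alter the outcome), via OLS slope t-tests against movement index.
3. *Are breaks jumps?*  A discontinuity is a jump when the mean of at
   least one execution variable differs across the adjacent segments
   (Welch test at alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TrialSeries",
    "SegmentLabel",
    "JumpEvent",
    "detect_discontinuities",
    "classify_segments",
    "classify_jumps",
]


@dataclass
class TrialSeries:
    """Execution variables and outcome over one movement sequence."""

    exec_vars: np.ndarray  # movements x k (hip_deg, knee_deg at peak)
    outcome: np.ndarray    # movements (peak heel height, m)

    def __post_init__(self) -> None:
        self.exec_vars = np.atleast_2d(np.asarray(self.exec_vars, dtype=float))
        if self.exec_vars.shape[0] == 1 and self.exec_vars.shape[1] > 2:
            self.exec_vars = self.exec_vars.T
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.exec_vars.shape[0] != self.outcome.shape[0]:
            raise ValueError("exec_vars and outcome must have one row per movement")

    @property
    def n(self) -> int:
        return self.outcome.shape[0]


@dataclass
class SegmentLabel:
    start: int  # 1-based movement index, inclusive
    end: int    # inclusive
    label: str  # maintenance | covariation | change
    slopes: dict
    p_values: dict


@dataclass
class JumpEvent:
    at: int          # 1-based index of the first movement after the discontinuity
    is_jump: bool
    mean_shift: np.ndarray  # per execution variable
    p_values: np.ndarray


def _max_welch_batch(X: np.ndarray, min_segment: int) -> tuple[np.ndarray, np.ndarray]:
    """Maximal |Welch t| over all splits leaving >= min_segment on each side.

    ``X`` is (batch, n); returns (max statistic, split index) per row.  A
    zero-variance comparison gives t = 0 when the means agree and +inf
    otherwise.
    """
    n = X.shape[1]
    ks = np.arange(min_segment, n - min_segment + 1)
    c1 = np.cumsum(X, axis=1)
    c2 = np.cumsum(X * X, axis=1)
    s1a, s2a = c1[:, ks - 1], c2[:, ks - 1]
    s1b, s2b = c1[:, -1:] - s1a, c2[:, -1:] - s2a
    na, nb = ks.astype(float), float(n) - ks
    ma, mb = s1a / na, s1b / nb
    va = np.maximum(s2a - s1a * s1a / na, 0.0) / (na - 1)
    vb = np.maximum(s2b - s1b * s1b / nb, 0.0) / (nb - 1)
    denom = np.sqrt(va / na + vb / nb)
    diff = np.abs(ma - mb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, np.where(diff > 1e-12, np.inf, 0.0))
    best = np.argmax(t, axis=1)
    rows = np.arange(X.shape[0])
    return t[rows, best], ks[best]


def _max_welch_stat(x: np.ndarray, min_segment: int) -> tuple[float, int]:
    t, k = _max_welch_batch(x[None, :], min_segment)
    return float(t[0]), int(k[0])


def _perm_pvalue(x: np.ndarray, observed: float, min_segment: int,
                 n_perm: int, rng: np.random.Generator) -> float:
    perms = rng.permuted(np.broadcast_to(x, (n_perm, x.shape[0])).copy(), axis=1)
    t, _ = _max_welch_batch(perms, min_segment)
    return (1 + int((t >= observed).sum())) / (n_perm + 1)


def _binary_segment(x: np.ndarray, offset: int, alpha: float, min_segment: int,
                    n_perm: int, rng: np.random.Generator, out: list[int]) -> None:
    if x.shape[0] < 2 * min_segment:
        return
    t_obs, k = _max_welch_stat(x, min_segment)
    if not np.isfinite(t_obs) and t_obs > 0:
        p = 0.0
    else:
        p = _perm_pvalue(x, t_obs, min_segment, n_perm, rng)
    if p < alpha:
        out.append(offset + k)
        _binary_segment(x[:k], offset, alpha, min_segment, n_perm, rng, out)
        _binary_segment(x[k:], offset + k, alpha, min_segment, n_perm, rng, out)


def detect_discontinuities(
    series: TrialSeries,
    alpha: float = 0.05,
    min_segment: int = 5,
    n_perm: int = 199,
    rng: np.random.Generator | int | None = 0,
) -> list[int]:
    """Changepoints of the execution-variable means.

    Returns sorted 1-based indices of the first movement of each new
    segment.  Indices found independently in different variables within one
    movement of each other are merged (the earlier one is kept).
    """
    if series.n < 2 * min_segment:
        raise ValueError("series shorter than two minimum segments")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    a_var = alpha / series.exec_vars.shape[1]  # Bonferroni across variables
    found: list[int] = []
    for j in range(series.exec_vars.shape[1]):
        per_var: list[int] = []
        _binary_segment(series.exec_vars[:, j], 0, a_var, min_segment, n_perm, rng, per_var)
        found.extend(per_var)
    merged: list[int] = []
    for k in sorted(found):
        if not merged or k - merged[-1] > 1:
            merged.append(k)
    return [k + 1 for k in merged]  # 1-based movement index of segment start


def _slope_test(y: np.ndarray) -> tuple[float, float]:
    """OLS slope of y on movement index and its two-sided p-value."""
    n = y.shape[0]
    if n < 3 or np.ptp(y) == 0:
        return 0.0, 1.0
    res = stats.linregress(np.arange(n), y)
    p = res.pvalue if np.isfinite(res.pvalue) else 1.0
    return float(res.slope), float(p)


def _segment_bounds(n: int, indices: list[int]) -> list[tuple[int, int]]:
    """Segments as 0-based half-open (a, b) from 1-based new-segment starts."""
    starts = [0] + [i - 1 for i in indices] + [n]
    return list(zip(starts[:-1], starts[1:]))


def classify_segments(series: TrialSeries, indices: list[int],
                      alpha: float = 0.05) -> list[SegmentLabel]:
    """Maintenance / covariation / change label per inter-discontinuity segment."""
    labels: list[SegmentLabel] = []
    names = [f"x{j}" for j in range(series.exec_vars.shape[1])]
    for a, b in _segment_bounds(series.n, indices):
        if b - a < 3:
            warnings.warn(f"segment {a + 1}-{b} shorter than 3 movements; labelled maintenance")
            labels.append(SegmentLabel(a + 1, b, "maintenance", {}, {}))
            continue
        slopes, pvals = {}, {}
        for j, name in enumerate(names):
            slopes[name], pvals[name] = _slope_test(series.exec_vars[a:b, j])
        slopes["outcome"], pvals["outcome"] = _slope_test(series.outcome[a:b])
        exec_trend = any(pvals[n_] < alpha for n_ in names)
        out_trend = pvals["outcome"] < alpha
        if not exec_trend and not out_trend:
            label = "maintenance"
        elif exec_trend and not out_trend:
            label = "covariation"
        elif exec_trend and out_trend:
            label = "change"
        else:  # outcome drifts without any execution trend: no exec change to report
            label = "maintenance"
        labels.append(SegmentLabel(a + 1, b, label, slopes, pvals))
    return labels


def classify_jumps(series: TrialSeries, indices: list[int],
                   alpha: float = 0.05) -> list[JumpEvent]:
    """Jump / no-jump label for each discontinuity.

    A jump means the mean of at least one execution variable differs
    between the adjacent segments (Welch t-test at alpha).
    """
    bounds = _segment_bounds(series.n, indices)
    events: list[JumpEvent] = []
    for seg_idx, k in enumerate(indices):
        a0, b0 = bounds[seg_idx]
        a1, b1 = bounds[seg_idx + 1]
        shifts = np.empty(series.exec_vars.shape[1])
        ps = np.empty(series.exec_vars.shape[1])
        for j in range(series.exec_vars.shape[1]):
            before = series.exec_vars[a0:b0, j]
            after = series.exec_vars[a1:b1, j]
            shifts[j] = after.mean() - before.mean()
            if before.size < 2 or after.size < 2:
                ps[j] = 1.0
            else:
                ps[j] = stats.ttest_ind(before, after, equal_var=False).pvalue
                if not np.isfinite(ps[j]):
                    ps[j] = 0.0 if shifts[j] != 0 else 1.0
        events.append(JumpEvent(at=k, is_jump=bool((ps < alpha).any()),
                                mean_shift=shifts, p_values=ps))
    return events


def jump_rates(events_per_block: list[list[JumpEvent]]) -> dict:
    """Per-block and per-discontinuity jump rates over a set of blocks."""
    n_blocks = len(events_per_block)
    blocks_with_jump = sum(any(e.is_jump for e in evs) for evs in events_per_block)
    all_events = [e for evs in events_per_block for e in evs]
    return {
        "block_rate": blocks_with_jump / n_blocks if n_blocks else 0.0,
        "event_rate": (sum(e.is_jump for e in all_events) / len(all_events))
        if all_events else 0.0,
        "n_blocks": n_blocks,
        "n_events": len(all_events),
    }
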