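"""Maze behavioral scoring, morphometry formulas and group comparison.

Scoring definitions
-------------------
Radial-arm maze: an entry is an *error* when its arm was visited earlier
in the same session; the error percentage is errors over total entries.
Y-maze: an *alternation* is a window of three consecutive entries into
three distinct arms (overlapping windows); the alternation percentage
divides by the maximum possible number of alternations, entries minus
two.  DNMTP: the correct-choice percentage for a day is excluded when
the mouse failed five or all six forced trials.

Consecutive duplicate arm labels are collapsed on ingest: an entry
requires leaving and re-entering an arm, and the alternation definition
presumes transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError

#: sentinel for undefined latencies / percentages
UNDEFINED = float("nan")


@dataclass
class EntrySequence:
    """Timestamped, ordered arm entries for one session."""

    arms: list
    times: list[float]
    duration: float = 300.0
    session_id: str = ""

    def __post_init__(self) -> None:
        if len(self.arms) != len(self.times):
            raise ValidationError("arms and times differ in length")
        t = np.asarray(self.times, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0)):
            raise ValidationError("entry timestamps must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.duration):
            raise ValidationError("timestamps outside [0, session duration]")
        for a, b in zip(self.arms, self.arms[1:]):
            if a == b:
                raise ValidationError(
                    "consecutive identical arms; use from_raw to collapse"
                )
        self.times = list(map(float, t))

    @classmethod
    def from_raw(
        cls, arms, times, duration: float = 300.0, session_id: str = ""
    ) -> "EntrySequence":
        """Build from a raw log, collapsing consecutive duplicate arms."""
        kept_arms, kept_times = [], []
        for a, t in zip(arms, times):
            if kept_arms and kept_arms[-1] == a:
                continue
            kept_arms.append(a)
            kept_times.append(float(t))
        return cls(kept_arms, kept_times, duration, session_id)

    @property
    def n_entries(self) -> int:
        return len(self.arms)


def score_radial_arm(entries: EntrySequence) -> dict:
    """Radial-arm maze working-memory scores for one session."""
    arms, times = entries.arms, entries.times
    n = len(arms)
    visited: set = set()
    errors = 0
    first_error_index: int | None = None
    for i, arm in enumerate(arms):
        if arm in visited:
            errors += 1
            if first_error_index is None:
                first_error_index = i
        visited.add(arm)
    return {
        "total_entries": n,
        "latency_first_entry": times[0] if n else UNDEFINED,
        "entries_before_first_error": (
            first_error_index if first_error_index is not None else n
        ),
        "latency_first_error": (
            times[first_error_index]
            if first_error_index is not None
            else UNDEFINED
        ),
        "n_errors": errors,
        "pct_errors": (100.0 * errors / n) if n else UNDEFINED,
    }


def score_y_maze(entries: EntrySequence) -> dict:
    """Spontaneous alternation scores; undefined with fewer than 3 entries."""
    arms = entries.arms
    if len(set(arms)) > 3:
        raise ValidationError(
            f"Y-maze expects at most 3 arm labels, got {sorted(set(arms))!r}"
        )
    n = len(arms)
    alternations = sum(
        1 for i in range(n - 2) if len({arms[i], arms[i + 1], arms[i + 2]}) == 3
    )
    return {
        "total_entries": n,
        "latency_first_entry": entries.times[0] if n else UNDEFINED,
        "n_alternations": alternations,
        "pct_alternation": (
            100.0 * alternations / (n - 2) if n >= 3 else UNDEFINED
        ),
    }


def score_dnmtp(days: pd.DataFrame, max_failed_forced: int = 5) -> pd.DataFrame:
    """Per mouse per day correct-choice percentage with the exclusion rule.

    ``days`` is a long table with columns (mouse, day, trial_type,
    outcome): forced trials have outcome completed/failed, choice trials
    correct/incorrect.  A day is excluded (percentage undefined) when
    the number of failed forced trials reaches ``max_failed_forced``.
    """
    rows = []
    for (mouse, day), sub in days.groupby(["mouse", "day"], sort=True):
        forced = sub[sub["trial_type"] == "forced"]
        choice = sub[sub["trial_type"] == "choice"]
        if len(forced) > 6 or len(choice) > 6:
            raise ValidationError(
                f"mouse {mouse!r} day {day!r}: more than six forced or "
                "choice trials"
            )
        failed = int((forced["outcome"] == "failed").sum())
        correct = int((choice["outcome"] == "correct").sum())
        excluded = failed >= max_failed_forced
        reason = "failed_forced" if excluded else ""
        if not excluded and len(choice) == 0:
            excluded = True
            reason = "no_choice_trials"
            warnings.warn(
                f"mouse {mouse!r} day {day!r}: no choice trials on a "
                "non-excluded day",
                stacklevel=2,
            )
        rows.append(
            {
                "mouse": mouse,
                "day": day,
                "n_forced_failed": failed,
                "n_choice": len(choice),
                "n_correct": correct,
                "pct_correct": (
                    UNDEFINED if excluded else 100.0 * correct / len(choice)
                ),
                "excluded": excluded,
                "exclusion_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def intensity_ratio(signal: float, shaft: float, background: float) -> float:
    """Background-subtracted synaptic enrichment ratio.

    ``(signal - background) / (shaft - background)`` where ``signal`` is
    the bouton (or postsynaptic) intensity and ``shaft`` the axonal (or
    dendritic) intensity.
    """
    if shaft <= background:
        raise ValidationError(
            "shaft intensity must exceed background for a defined ratio"
        )
    return (signal - background) / (shaft - background)


def normalize_vesicle_positions(distances) -> np.ndarray:
    """Normalize vesicle distances from the active zone to [0, 1].

    Each distance is divided by the terminal's maximum distance, so 0 is
    closest to the active zone and 1 is the farthest vesicle.  All-zero
    input maps to all zeros by convention.
    """
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        raise ValidationError("empty distance list")
    if np.any(d < 0):
        raise ValidationError("distances must be non-negative")
    m = d.max()
    if m == 0:
        warnings.warn("all distances zero; returning zeros", stacklevel=2)
        return np.zeros_like(d)
    return d / m


def _passes_normality(x: np.ndarray, alpha: float) -> bool:
    if np.ptp(x) == 0:
        return False  # constant data: normality undefined, use nonparametric
    return stats.shapiro(x).pvalue > alpha


def compare_groups(
    a,
    b,
    mode: str = "behavior",
    alpha_normality: float = 0.05,
    welch: bool = False,
) -> dict:
    """Normality-gated two-group comparison.

    Shapiro-Wilk is run on each group at ``alpha_normality``; when both
    pass, a two-tailed unpaired t-test is used (classical pooled by
    default, Welch with ``welch=True``).  Otherwise the nonparametric
    branch is Mann-Whitney for behavioral data (``mode="behavior"``) or
    two-sample Kolmogorov-Smirnov for morphometry (``mode="em"``).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValidationError("compare_groups requires >= 3 values per group")
    if mode not in ("behavior", "em"):
        raise ValidationError("mode must be 'behavior' or 'em'")
    normal_a = _passes_normality(a, alpha_normality)
    normal_b = _passes_normality(b, alpha_normality)
    if np.ptp(np.concatenate([a, b])) == 0:
        # both groups one identical constant: no evidence of any difference
        return {
            "test_used": "mannwhitney" if mode == "behavior" else "ks",
            "statistic": 0.0,
            "p": 1.0,
            "normal_a": normal_a,
            "normal_b": normal_b,
        }
    if normal_a and normal_b:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test_used = "welch_t" if welch else "student_t"
    elif mode == "behavior":
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        test_used = "mannwhitney"
    else:
        res = stats.ks_2samp(a, b)
        test_used = "ks"
    return {
        "test_used": test_used,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "normal_a": normal_a,
        "normal_b": normal_b,
    }


def rout_outliers(values, max_fdr: float = 0.01) -> np.ndarray:
    """Robust outlier detection at a maximum desired FDR (inlier mask).

    One-sample robust fit: location is the median; scale is the robust
    standard deviation of residuals estimated as the 68.27th percentile
    of absolute residuals.  Each point's residual t-score is converted
    to a two-tailed p-value (t distribution, n - 1 df) and outliers are
    the points rejected by a Benjamini-Hochberg step-up at ``max_fdr``.
    Fewer than 5 points: nothing is flagged.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 5:
        warnings.warn("fewer than 5 values; no outlier detection", stacklevel=2)
        return np.ones(n, dtype=bool)
    resid = np.abs(v - np.median(v))
    rsdr = np.percentile(resid, 68.27)
    if rsdr == 0:
        return resid == 0
    t = resid / rsdr
    p = 2.0 * stats.t.sf(t, df=n - 1)
    order = np.argsort(p)
    thresholds = max_fdr * (np.arange(1, n + 1)) / n
    sorted_p = p[order]
    passing = np.nonzero(sorted_p <= thresholds)[0]
    rejected = np.zeros(n, dtype=bool)
    if passing.size:
        k = passing.max()
        rejected[order[: k + 1]] = True
    return ~rejected
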