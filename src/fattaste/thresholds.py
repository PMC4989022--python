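"""Detection-threshold estimation and sensitivity grouping from staircase logs.

A trial log is first collapsed into per-level tallies (sets presented,
correct answers).  Each visited level is then classified:

* ``true_positive`` — correct answers significantly above the 1-in-3
  guessing rate (exact binomial tail at ``alpha``, the default rule), or,
  under the simpler ``fraction`` rule, a percent correct above 100/3;
* ``false_positive`` — some correct answers, but not enough to beat
  guessing; such levels are ignored as threshold anchors;
* ``incorrect`` — no correct answer at that level.

The detection threshold is the geometric mean of the lowest true-positive
concentration and the highest concentration below it answered incorrectly
(incorrect or false-positive).  Runs with no qualifying anchor at one end
are censored and imputed half a log step beyond the ladder, so that every
participant can still be placed into a sensitivity group.

Sensitivity groups split the ladder's decimal-log span into three equal
parts.  Cut points are computed on the %w/v scale; because published
boundaries are conventionally displayed at two significant figures in %w/v
before conversion to mM, the grouping also reports these display-convention
values (e.g. 0.041 %w/v -> 1.45 mM and 0.19 %w/v -> 6.73 mM on the
nine-level ladder).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .concentrations import DilutionSeries, pct_to_mM
from .staircase import TrialLog

__all__ = [
    "LevelTally",
    "ThresholdResult",
    "SensitivityGrouping",
    "tally_levels",
    "classify_level",
    "classify_levels",
    "estimate_threshold",
    "threshold_from_log",
    "group_cuts",
    "assign_groups",
    "quartile_groups",
]

GUESS_RATE_3AFC = 1.0 / 3.0


@dataclass
class LevelTally:
    """Aggregate of all triads presented at one ladder level."""

    level_index: int
    n_presented: int
    n_correct: int
    classification: str = "unvisited"

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_presented:
            raise ValueError("need 0 <= n_correct <= n_presented")

    @property
    def pct_correct(self) -> float:
        if self.n_presented == 0:
            return math.nan
        return 100.0 * self.n_correct / self.n_presented

    @property
    def chance_tail(self) -> float:
        """P(X >= n_correct) for X ~ Binomial(n_presented, 1/3)."""
        return float(stats.binom.sf(self.n_correct - 1, self.n_presented, GUESS_RATE_3AFC))


@dataclass
class ThresholdResult:
    participant_id: str
    threshold_mM: float
    lowest_TP_index: int | None
    highest_incorrect_index: int | None
    censored: str = "none"  # none | low | high
    rule: str = "tail"

    @property
    def log10_mM(self) -> float:
        return math.log10(self.threshold_mM)


@dataclass
class SensitivityGrouping:
    """Equal-log-thirds sensitivity grouping of a cohort.

    ``low_cut_mM``/``high_cut_mM`` are the exact cut points used for
    assignment; ``display_low_cut_mM``/``display_high_cut_mM`` follow the
    reporting convention (cuts rounded to two significant figures in %w/v
    before unit conversion).
    """

    low_cut_mM: float
    high_cut_mM: float
    display_low_cut_mM: float
    display_high_cut_mM: float
    low_cut_pct: float
    high_cut_pct: float
    labels: dict[str, str] = field(default_factory=dict)


def tally_levels(log: TrialLog) -> list[LevelTally]:
    """Per-level tallies for every level visited in a trial log."""
    if not log.trials:
        raise ValueError("cannot tally an empty trial log")
    counts: dict[int, list[int]] = {}
    for t in log.trials:
        n, k = counts.setdefault(t.level_index, [0, 0])
        counts[t.level_index][0] = n + 1
        counts[t.level_index][1] = k + int(t.correct)
    return [
        LevelTally(level_index=idx, n_presented=n, n_correct=k)
        for idx, (n, k) in sorted(counts.items())
    ]


def classify_level(tally: LevelTally, rule: str = "tail", alpha: float = 0.05) -> str:
    """Classify one visited level as true/false positive or incorrect.

    ``tail``: true positive when the exact binomial tail probability of the
    observed correct count under guessing (p = 1/3) is at most ``alpha``.
    ``fraction``: true positive when percent correct exceeds the chance
    percentage 100/3.
    """
    if tally.n_presented == 0:
        return "unvisited"
    if tally.n_correct == 0:
        return "incorrect"
    if rule == "tail":
        return "true_positive" if tally.chance_tail <= alpha else "false_positive"
    if rule == "fraction":
        return "true_positive" if tally.pct_correct > 100.0 / 3.0 else "false_positive"
    raise ValueError(f"unknown classification rule {rule!r}")


def classify_levels(
    tallies: list[LevelTally], rule: str = "tail", alpha: float = 0.05
) -> list[LevelTally]:
    """Classify every tally in place; returns the same list for chaining."""
    for t in tallies:
        t.classification = classify_level(t, rule=rule, alpha=alpha)
    return tallies


def estimate_threshold(
    tallies: list[LevelTally],
    series: DilutionSeries,
    participant_id: str = "obs",
    rule: str = "tail",
    *,
    incorrect_scope: str = "below_tp",
) -> ThresholdResult:
    """Geometric-mean detection threshold from classified level tallies.

    The estimate is sqrt(c_TP * c_inc) where c_TP is the lowest
    true-positive concentration and c_inc the highest concentration below it
    classified incorrect or false positive.  Censoring:

    * no incorrect level below the lowest true positive -> ``censored='low'``
      with the threshold imputed half a log step below the ladder bottom;
    * no true positive anywhere -> ``censored='high'`` with the threshold
      imputed half a log step above the ladder top.

    ``incorrect_scope='global'`` instead anchors on the highest
    incorrect/false-positive level anywhere in the run and the lowest true
    positive above it (a stricter reading that does not ignore false
    positives above the threshold).
    """
    visited = [t for t in tallies if t.n_presented > 0]
    if not visited:
        raise ValueError("no visited levels to estimate a threshold from")
    if any(t.classification == "unvisited" for t in visited):
        raise ValueError("tallies must be classified before estimation")
    if incorrect_scope not in ("below_tp", "global"):
        raise ValueError(f"unknown incorrect_scope {incorrect_scope!r}")

    tp_indices = [t.level_index for t in visited if t.classification == "true_positive"]
    miss_indices = [
        t.level_index
        for t in visited
        if t.classification in ("incorrect", "false_positive")
    ]
    half_step = 10.0 ** (series.log_step / 2.0)

    if incorrect_scope == "global" and miss_indices:
        highest_miss = max(miss_indices)
        tp_indices = [i for i in tp_indices if i > highest_miss]

    if not tp_indices:
        top = float(series.mM[-1])
        return ThresholdResult(
            participant_id=participant_id,
            threshold_mM=top * half_step,
            lowest_TP_index=None,
            highest_incorrect_index=max(miss_indices) if miss_indices else None,
            censored="high",
            rule=rule,
        )
    lowest_tp = min(tp_indices)
    below = [i for i in miss_indices if i < lowest_tp]
    if not below:
        bottom = float(series.mM[0])
        return ThresholdResult(
            participant_id=participant_id,
            threshold_mM=bottom / half_step,
            lowest_TP_index=lowest_tp,
            highest_incorrect_index=None,
            censored="low",
            rule=rule,
        )
    highest_inc = max(below)
    thr = math.sqrt(float(series.mM[lowest_tp]) * float(series.mM[highest_inc]))
    return ThresholdResult(
        participant_id=participant_id,
        threshold_mM=thr,
        lowest_TP_index=lowest_tp,
        highest_incorrect_index=highest_inc,
        censored="none",
        rule=rule,
    )


def threshold_from_log(
    log: TrialLog,
    series: DilutionSeries,
    rule: str = "tail",
    alpha: float = 0.05,
    **kwargs,
) -> ThresholdResult:
    """Convenience: tally, classify and estimate in one call."""
    tallies = classify_levels(tally_levels(log), rule=rule, alpha=alpha)
    return estimate_threshold(
        tallies, series, participant_id=log.participant_id, rule=rule, **kwargs
    )


def _round_sig(x: float, sig: int) -> float:
    if x <= 0:
        raise ValueError("positive value required")
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def group_cuts(series: DilutionSeries, display_sig_figs: int = 2) -> SensitivityGrouping:
    """Equal log-thirds cut points of a ladder, in %w/v and mM.

    The two cuts sit at one third and two thirds of the decimal-log span of
    the ladder, computed on the %w/v scale and converted to mM with the
    series' molar mass.  Display values round the %w/v cut to
    ``display_sig_figs`` significant figures before conversion, matching how
    such boundaries are conventionally printed.
    """
    bottom_pct = float(series.pct_wv[0])
    top_pct = float(series.pct_wv[-1])
    span = math.log10(top_pct / bottom_pct)
    if span <= 0:
        raise ValueError("degenerate series: top must exceed bottom")
    low_pct = 10.0 ** (math.log10(bottom_pct) + span / 3.0)
    high_pct = 10.0 ** (math.log10(bottom_pct) + 2.0 * span / 3.0)
    return SensitivityGrouping(
        low_cut_mM=pct_to_mM(low_pct, series.molar_mass),
        high_cut_mM=pct_to_mM(high_pct, series.molar_mass),
        display_low_cut_mM=pct_to_mM(_round_sig(low_pct, display_sig_figs), series.molar_mass),
        display_high_cut_mM=pct_to_mM(_round_sig(high_pct, display_sig_figs), series.molar_mass),
        low_cut_pct=low_pct,
        high_cut_pct=high_pct,
    )


def assign_groups(
    thresholds: list[ThresholdResult], series: DilutionSeries
) -> SensitivityGrouping:
    """Label each participant high/medium/low sensitivity by equal log thirds.

    Thresholds below the lower cut are *high* sensitivity (they detect dilute
    stimuli), above the upper cut *low* sensitivity, otherwise *medium*.
    Censored thresholds participate at their imputed values.
    """
    if not thresholds:
        raise ValueError("no thresholds to group")
    grouping = group_cuts(series)
    for res in thresholds:
        if res.threshold_mM < grouping.low_cut_mM:
            label = "high"
        elif res.threshold_mM > grouping.high_cut_mM:
            label = "low"
        else:
            label = "medium"
        grouping.labels[res.participant_id] = label
    return grouping


def quartile_groups(thresholds: list[ThresholdResult]) -> dict[str, str]:
    """Alternative quartile-based grouping (unstable for small cohorts).

    Bottom quartile of thresholds -> high sensitivity, top quartile -> low,
    the middle half -> medium.  Provided for comparison only; equal
    log-thirds grouping is the primary method.
    """
    if not thresholds:
        raise ValueError("no thresholds to group")
    vals = np.array([t.threshold_mM for t in thresholds])
    q1, q3 = np.percentile(vals, [25, 75])
    out = {}
    for t in thresholds:
        if t.threshold_mM <= q1:
            out[t.participant_id] = "high"
        elif t.threshold_mM >= q3:
            out[t.participant_id] = "low"
        else:
            out[t.participant_id] = "medium"
    return out
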