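"""Summary and inference for gLMS fat-intensity ratings.

Ratings live in long format: one row per (participant, modality condition,
fat level) with a score on the generalised labelled magnitude scale
(0 = "no sensation" to 100 = "strongest imaginable sensation of any kind").
The modality conditions encode which sensory cues were available: ``taste``
(mouthfeel and odour both masked), ``taste_odour`` (mouthfeel masked),
``taste_mouthfeel`` (nose clip), ``overall`` (no masking).

Inference is the field-standard repeated-measures ANOVA with the
Greenhouse–Geisser sphericity correction always applied (conservative; a
separate sphericity pre-test is deliberately omitted), plus
Bonferroni-adjusted paired comparisons.  When a between-subjects factor
(e.g. sensitivity group) is supplied, a mixed-design ANOVA with one within
factor is fitted.  Participants with incomplete within-subject cells are
excluded listwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "MODALITIES",
    "AnovaResult",
    "cell_summary",
    "rm_anova",
    "bonferroni_pairwise",
]

MODALITIES = ("taste", "taste_odour", "taste_mouthfeel", "overall")

#: canonical column names for rating records
PARTICIPANT, MODALITY, FAT_LEVEL, SCORE = "participant_id", "modality", "fat_level", "score"


@dataclass(frozen=True)
class AnovaResult:
    """One effect line of a (mixed) repeated-measures ANOVA.

    ``df_num``/``df_den`` are Greenhouse–Geisser corrected whenever an
    epsilon applies to the effect (within-subject effects with 3+ levels);
    ``epsilon`` is None for between-subject effects.
    """

    effect: str
    F: float
    df_num: float
    df_den: float
    epsilon: float | None
    p: float


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    required = {PARTICIPANT, MODALITY, FAT_LEVEL, SCORE}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"rating records missing columns: {sorted(missing)}")
    bad = records[(records[SCORE] < 0) | (records[SCORE] > 100)]
    if len(bad):
        raise ValueError(f"{len(bad)} scores outside the 0-100 gLMS range")
    return records


def cell_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SEM per (modality, fat level) cell.

    Returns columns n, mean, sem; ``sem`` is NaN for cells with fewer than
    two observations (flagged via ``sem_defined``).
    """
    records = _validate(records)
    if records.empty:
        raise ValueError("no rating records")
    out = (
        records.groupby([MODALITY, FAT_LEVEL])[SCORE]
        .agg(n="count", mean="mean", sem=lambda s: s.sem())
        .reset_index()
    )
    out["sem_defined"] = out["n"] >= 2
    return out


def _complete_cases(records: pd.DataFrame, within: list[str]) -> pd.DataFrame:
    """Listwise-delete participants missing any within-subject cell."""
    n_cells = int(np.prod([records[w].nunique() for w in within]))
    counts = records.groupby(PARTICIPANT).apply(
        lambda g: g.drop_duplicates(subset=within).shape[0], include_groups=False
    )
    keep = counts[counts == n_cells].index
    dropped = set(records[PARTICIPANT]) - set(keep)
    if dropped:
        import warnings

        warnings.warn(
            f"excluding {len(dropped)} participant(s) with incomplete cells: "
            f"{sorted(dropped)[:5]}...",
            stacklevel=3,
        )
    return records[records[PARTICIPANT].isin(keep)]


def rm_anova(
    records: pd.DataFrame,
    within: str | list[str] = (FAT_LEVEL, MODALITY),
    between: str | None = None,
) -> list[AnovaResult]:
    """Repeated-measures (or mixed-design) ANOVA on rating scores.

    ``within`` names one or two within-subject factors.  With ``between``
    set (e.g. a sensitivity-group column), a mixed ANOVA with a single
    within factor is fitted instead, including the between-subjects main
    effect and the interaction.

    Greenhouse–Geisser correction is always applied to within effects; the
    reported p values and degrees of freedom are the corrected ones.
    """
    within = [within] if isinstance(within, str) else list(within)
    records = _validate(records)
    records = _complete_cases(records, within)
    if between is not None:
        if len(within) != 1:
            raise ValueError("mixed design supports exactly one within factor")
        aov = pg.mixed_anova(
            data=records,
            dv=SCORE,
            within=within[0],
            subject=PARTICIPANT,
            between=between,
            correction=True,
        )
        return _collect(aov, df_cols=("DF1", "DF2"))
    if len(within) == 1:
        aov = pg.rm_anova(
            data=records,
            dv=SCORE,
            within=within[0],
            subject=PARTICIPANT,
            correction=True,
            detailed=True,
        )
        # one-way layout reports the error row separately
        err_df = float(aov.loc[aov["Source"] == "Error", "DF"].iloc[0])
        aov = aov[aov["Source"] != "Error"].copy()
        aov["ddof1"], aov["ddof2"] = aov["DF"], err_df
        return _collect(aov, df_cols=("ddof1", "ddof2"))
    if len(within) == 2:
        aov = pg.rm_anova(
            data=records,
            dv=SCORE,
            within=within,
            subject=PARTICIPANT,
            correction=True,
            detailed=True,
        )
        return _collect(aov, df_cols=("ddof1", "ddof2"))
    raise ValueError("within must name one or two factors")


def _collect(aov: pd.DataFrame, df_cols: tuple[str, str]) -> list[AnovaResult]:
    results = []
    for _, row in aov.iterrows():
        eps = row.get("eps", math.nan)
        eps = None if (eps is None or (isinstance(eps, float) and math.isnan(eps))) else float(eps)
        p = row.get("p_GG_corr", math.nan)
        if isinstance(p, float) and math.isnan(p):
            p = row["p_unc"]
        d1, d2 = float(row[df_cols[0]]), float(row[df_cols[1]])
        if eps is not None:
            d1, d2 = eps * d1, eps * d2
        results.append(
            AnovaResult(
                effect=str(row["Source"]),
                F=float(row["F"]),
                df_num=d1,
                df_den=d2,
                epsilon=eps,
                p=float(p),
            )
        )
    return results


def bonferroni_pairwise(
    records: pd.DataFrame,
    factor: str = FAT_LEVEL,
    modality: str | None = None,
) -> pd.DataFrame:
    """Paired t comparisons between factor levels, Bonferroni adjusted.

    Filters to one modality condition when given, pivots to a participant ×
    level table (listwise-complete), and compares every pair of levels with
    a paired t test; p values are multiplied by the number of comparisons
    and capped at 1.  Pairs with zero difference everywhere get p = 1.
    """
    records = _validate(records)
    if modality is not None:
        records = records[records[MODALITY] == modality]
    wide = records.pivot_table(index=PARTICIPANT, columns=factor, values=SCORE)
    wide = wide.dropna(axis=0)
    levels = list(wide.columns)
    pairs = list(itertools.combinations(levels, 2))
    if not pairs:
        return pd.DataFrame(
            columns=["level_a", "level_b", "n", "mean_diff", "t", "p_unc", "p_bonf"]
        )
    m = len(pairs)
    rows = []
    for a, b in pairs:
        diff = wide[a] - wide[b]
        n = len(diff)
        if np.allclose(diff, 0.0):
            t_stat, p_unc = 0.0, 1.0
        else:
            t_stat, p_unc = stats.ttest_rel(wide[a], wide[b])
        rows.append(
            {
                "level_a": a,
                "level_b": b,
                "n": n,
                "mean_diff": float(diff.mean()),
                "t": float(t_stat),
                "p_unc": float(p_unc),
                "p_bonf": min(float(p_unc) * m, 1.0),
            }
        )
    return pd.DataFrame(rows)
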