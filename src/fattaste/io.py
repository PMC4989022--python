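"""Delimited-text formats for every table the toolkit reads or writes.

All files are UTF-8 comma-separated with a mandatory header row.  Schemas:

* trial logs — participant_id, trial_index, level_index, correct (0/1),
  terminated_by; one row per 3-AFC set;
* panel tallies — pair_label, n_total, n_correct, guess_rate;
* rating tables — participant_id, modality, fat_level, score;
* threshold reports — participant_id, threshold_mM, threshold_pctwv,
  censored, lowest_TP_level, highest_incorrect_level, rule, group
  (levels are displayed 1-based; empty when censoring removed the anchor);
* series export — level_index, mM, pct_wv.

Schema violations raise :class:`SchemaError` naming file, line and column.
Write/read round-trips are identity on valid files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .concentrations import DilutionSeries
from .staircase import TrialLog, TrialRecord, count_reversals
from .thresholds import ThresholdResult

__all__ = [
    "SchemaError",
    "write_trial_logs",
    "read_trial_logs",
    "write_panel",
    "read_panel",
    "write_ratings",
    "read_ratings",
    "write_threshold_report",
    "read_threshold_report",
    "write_series",
    "read_series",
]


class SchemaError(ValueError):
    """A delimited file violated its declared schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")


def _check(df: pd.DataFrame, column: str, ok: pd.Series, path: Path, expect: str) -> None:
    bad = df.index[~ok]
    if len(bad):
        # +2: header row plus 1-based numbering
        line = int(bad[0]) + 2
        raise SchemaError(
            f"{path}, line {line}, column '{column}': expected {expect}, "
            f"got {df.loc[bad[0], column]!r}"
        )


# ---------------------------------------------------------------- trial logs

def write_trial_logs(logs: list[TrialLog], path: str | Path) -> None:
    rows = [
        {
            "participant_id": log.participant_id,
            "trial_index": t.trial_index,
            "level_index": t.level_index,
            "correct": int(t.correct),
            "terminated_by": log.terminated_by or "",
        }
        for log in logs
        for t in log.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trial_logs(path: str | Path) -> list[TrialLog]:
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(
        df, ["participant_id", "trial_index", "level_index", "correct"], path
    )
    for col in ("trial_index", "level_index", "correct"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        _check(df, col, numeric.notna() & (numeric == numeric.round()), path, "an integer")
        df[col] = numeric.astype(int)
    _check(df, "correct", df["correct"].isin([0, 1]), path, "0 or 1")
    _check(df, "level_index", df["level_index"] >= 0, path, "a nonnegative level index")
    logs = []
    for pid, g in df.groupby("participant_id", sort=False):
        g = g.sort_values("trial_index")
        trials = [
            TrialRecord(int(r.trial_index), int(r.level_index), bool(r.correct))
            for r in g.itertuples(index=False)
        ]
        term = None
        if "terminated_by" in g.columns:
            vals = g["terminated_by"].dropna().unique()
            term = str(vals[0]) if len(vals) and str(vals[0]) else None
        logs.append(
            TrialLog(
                participant_id=str(pid),
                trials=trials,
                reversals=count_reversals([t.correct for t in trials]),
                terminated_by=term,
            )
        )
    return logs


# --------------------------------------------------------------- 2-AFC panel

def write_panel(pairs, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "pair_label": p.pair_label,
                "n_total": p.n_total,
                "n_correct": p.n_correct,
                "guess_rate": p.guess_rate,
            }
            for p in pairs
        ]
    ).to_csv(path, index=False)


def read_panel(path: str | Path):
    from .discrimination import PairDiscrimination

    path = Path(path)
    df = pd.read_csv(path, dtype={"pair_label": str})
    _require_columns(df, ["pair_label", "n_total", "n_correct", "guess_rate"], path)
    for col in ("n_total", "n_correct"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        _check(df, col, numeric.notna() & (numeric >= 0), path, "a nonnegative integer")
        df[col] = numeric.astype(int)
    _check(df, "n_correct", df["n_correct"] <= df["n_total"], path, "n_correct <= n_total")
    return [
        PairDiscrimination(
            pair_label=str(r.pair_label),
            n_total=int(r.n_total),
            n_correct=int(r.n_correct),
            guess_rate=float(r.guess_rate),
        )
        for r in df.itertuples(index=False)
    ]


# ------------------------------------------------------------------- ratings

def write_ratings(records: pd.DataFrame, path: str | Path) -> None:
    cols = ["participant_id", "modality", "fat_level", "score"]
    records[cols + [c for c in records.columns if c not in cols]].to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str, "modality": str})
    _require_columns(df, ["participant_id", "modality", "fat_level", "score"], path)
    score = pd.to_numeric(df["score"], errors="coerce")
    _check(df, "score", score.notna() & (score >= 0) & (score <= 100), path, "a score in [0, 100]")
    df["score"] = score
    df["fat_level"] = pd.to_numeric(df["fat_level"])
    return df


# ---------------------------------------------------------- threshold report

def write_threshold_report(
    results: list[ThresholdResult],
    series: DilutionSeries,
    path: str | Path,
    groups: dict[str, str] | None = None,
) -> None:
    """Threshold report with 1-based level displays and optional groups."""
    rows = []
    for r in results:
        rows.append(
            {
                "participant_id": r.participant_id,
                "threshold_mM": r.threshold_mM,
                "threshold_pctwv": r.threshold_mM * series.molar_mass / 10000.0,
                "censored": r.censored,
                "lowest_TP_level": "" if r.lowest_TP_index is None else r.lowest_TP_index + 1,
                "highest_incorrect_level": ""
                if r.highest_incorrect_index is None
                else r.highest_incorrect_index + 1,
                "rule": r.rule,
                "group": (groups or {}).get(r.participant_id, ""),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_threshold_report(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    _require_columns(df, ["participant_id", "threshold_mM", "censored"], path)
    thr = pd.to_numeric(df["threshold_mM"], errors="coerce")
    _check(df, "threshold_mM", thr.notna() & (thr > 0), path, "a positive concentration")
    return df


# -------------------------------------------------------------------- series

def write_series(series: DilutionSeries, path: str | Path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path: str | Path, molar_mass: float | None = None) -> DilutionSeries:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["level_index", "mM"], path)
    mM = pd.to_numeric(df["mM"], errors="coerce")
    _check(df, "mM", mM.notna() & (mM > 0), path, "a positive concentration")
    mM = mM.to_numpy()
    step = float(np.round(np.mean(np.diff(np.log10(mM))), 12))
    kwargs = {} if molar_mass is None else {"molar_mass": molar_mass}
    if molar_mass is None and "pct_wv" in df.columns:
        kwargs["molar_mass"] = float(df["pct_wv"].iloc[0] * 10000.0 / mM[0])
    return DilutionSeries(mM=mM, log_step=step, **kwargs)
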