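"""Trial-level data model, delimited-file I/O, and screening/filtering rules.

A trial table holds one row per hybrid-search trial: participant, memory set
size (MSS), visual set size (VSS), scene-context flag, target-presence flag,
the response ("present"/"absent", or "none" for a 7 s timeout), the response
time in seconds, and correctness.  Filters record provenance (which rule
removed how many rows) so exclusion tallies stay traceable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TrialRecord",
    "TrialTable",
    "CsvDialect",
    "TrialValidationError",
    "read_trials",
    "write_trials",
    "filter_for_rt_analysis",
    "exclude_low_accuracy_participants",
    "screen_stimuli",
]

SET_SIZES = (1, 2, 4, 8)
RESPONSES = ("present", "absent", "none")
T_DEADLINE = 7.0

COLUMNS = [
    "participant_id",
    "trial_index",
    "stimulus_id",
    "mss",
    "vss",
    "context_present",
    "target_present",
    "response",
    "rt",
    "correct",
]


class TrialValidationError(ValueError):
    """Raised when rows violate the trial-record invariants.

    Carries ``errors``: a list of (line_number, message) pairs.
    """

    def __init__(self, errors):
        self.errors = list(errors)
        lines = "; ".join(f"line {ln}: {msg}" for ln, msg in self.errors[:10])
        more = "" if len(self.errors) <= 10 else f" (+{len(self.errors) - 10} more)"
        super().__init__(f"{len(self.errors)} invalid trial rows: {lines}{more}")


@dataclass(frozen=True)
class TrialRecord:
    """A single hybrid-search trial."""

    participant_id: str
    trial_index: int
    stimulus_id: str
    mss: int
    vss: int
    context_present: bool
    target_present: bool
    response: str  # "present" | "absent" | "none"
    rt: float | None  # seconds; None when response == "none"
    correct: bool | None  # None when response == "none"

    def validate(self) -> list[str]:
        problems = []
        if self.mss not in SET_SIZES:
            problems.append(f"mss must be one of {SET_SIZES}, got {self.mss}")
        if self.vss not in SET_SIZES:
            problems.append(f"vss must be one of {SET_SIZES}, got {self.vss}")
        if self.trial_index < 0:
            problems.append(f"trial_index must be >= 0, got {self.trial_index}")
        if self.response not in RESPONSES:
            problems.append(f"response must be one of {RESPONSES}, got {self.response!r}")
        if self.response == "none":
            if self.rt is not None and not math.isnan(self.rt):
                problems.append("rt must be missing when response is 'none'")
        else:
            if self.rt is None or math.isnan(self.rt):
                problems.append("rt is mandatory for answered trials")
            elif not (0 < self.rt <= T_DEADLINE):
                problems.append(f"rt must lie in (0, {T_DEADLINE}] s, got {self.rt}")
            expected = (self.response == "present") != (not self.target_present)
            if self.correct is None:
                problems.append("correct is mandatory for answered trials")
            elif bool(self.correct) != expected:
                problems.append(
                    f"correct={self.correct} inconsistent with response="
                    f"{self.response!r}, target_present={self.target_present}"
                )
        return problems


@dataclass
class TrialTable:
    """Ordered trial collection with filter provenance.

    ``data`` is a pandas DataFrame with the canonical columns; ``provenance``
    is a list of dicts, one per filter applied, each recording the rule and
    the number of rows removed.
    """

    data: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "TrialTable":
        df = df.loc[:, COLUMNS].reset_index(drop=True)
        table = cls(data=df)
        if validate:
            errors = _validate_frame(df)
            if errors:
                raise TrialValidationError(errors)
        return table

    def records(self):
        for row in self.data.itertuples(index=False):
            yield TrialRecord(
                participant_id=str(row.participant_id),
                trial_index=int(row.trial_index),
                stimulus_id=str(row.stimulus_id),
                mss=int(row.mss),
                vss=int(row.vss),
                context_present=bool(row.context_present),
                target_present=bool(row.target_present),
                response=str(row.response),
                rt=None if pd.isna(row.rt) else float(row.rt),
                correct=None if pd.isna(row.correct) else bool(row.correct),
            )

    def with_filter(self, df: pd.DataFrame, note: dict) -> "TrialTable":
        removed = len(self.data) - len(df)
        note = dict(note, rows_before=len(self.data), rows_after=len(df), removed=removed)
        return TrialTable(data=df.reset_index(drop=True), provenance=self.provenance + [note])

    def write_provenance(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.provenance, fh, indent=2)


@dataclass(frozen=True)
class CsvDialect:
    """How a delimited trial file maps onto the canonical columns."""

    delimiter: str = ","
    encoding: str = "utf-8"
    rt_unit: str = "s"  # "s" or "ms"; ms values are converted on read
    column_map: dict = field(default_factory=dict)  # file column -> canonical


_TRUE = {"1", "true", "True", "TRUE", True, 1, 1.0}
_FALSE = {"0", "false", "False", "FALSE", False, 0, 0.0}


def _parse_bool(value, line, col, errors):
    if value in _TRUE:
        return True
    if value in _FALSE:
        return False
    errors.append((line, f"column {col!r}: cannot parse boolean from {value!r}"))
    return None


def _validate_frame(df: pd.DataFrame, line_offset: int = 0) -> list:
    errors = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = TrialRecord(
            participant_id=str(row.participant_id),
            trial_index=int(row.trial_index),
            stimulus_id=str(row.stimulus_id),
            mss=int(row.mss),
            vss=int(row.vss),
            context_present=bool(row.context_present),
            target_present=bool(row.target_present),
            response=str(row.response),
            rt=None if pd.isna(row.rt) else float(row.rt),
            correct=None if pd.isna(row.correct) else bool(row.correct),
        )
        for msg in rec.validate():
            errors.append((i + line_offset, msg))
    return errors


def read_trials(path, dialect: CsvDialect | None = None) -> TrialTable:
    """Read a delimited trial file into a validated :class:`TrialTable`.

    Raises a hard error naming any missing mandatory column; row-level
    problems (unparseable RT, invariant violations) are collected and raised
    together as :class:`TrialValidationError` with data line numbers
    (header = line 1, first data row = line 2).
    """
    dialect = dialect or CsvDialect()
    raw = pd.read_csv(
        path,
        sep=dialect.delimiter,
        encoding=dialect.encoding,
        dtype=str,
        keep_default_na=False,
    )
    if dialect.column_map:
        raw = raw.rename(columns=dialect.column_map)
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    errors: list = []
    n = len(raw)
    out = pd.DataFrame(index=range(n), columns=COLUMNS, dtype=object)
    missing_tokens = {"", "NA", "na", "NaN", "nan", "None"}
    for i in range(n):
        line = i + 2  # header occupies line 1
        row = raw.iloc[i]
        out.at[i, "participant_id"] = row["participant_id"]
        out.at[i, "stimulus_id"] = row["stimulus_id"]
        for col in ("trial_index", "mss", "vss"):
            try:
                out.at[i, col] = int(row[col])
            except (TypeError, ValueError):
                errors.append((line, f"column {col!r}: cannot parse integer from {row[col]!r}"))
        for col in ("context_present", "target_present"):
            out.at[i, col] = _parse_bool(row[col], line, col, errors)
        out.at[i, "response"] = row["response"].strip().lower()
        rt_raw = str(row["rt"]).strip()
        if rt_raw in missing_tokens:
            out.at[i, "rt"] = np.nan
        else:
            try:
                rt = float(rt_raw)
                out.at[i, "rt"] = rt / 1000.0 if dialect.rt_unit == "ms" else rt
            except ValueError:
                errors.append((line, f"column 'rt': cannot parse {rt_raw!r}"))
        corr_raw = str(row["correct"]).strip()
        if corr_raw in missing_tokens:
            out.at[i, "correct"] = np.nan
        else:
            out.at[i, "correct"] = _parse_bool(corr_raw, line, "correct", errors)
    if errors:
        raise TrialValidationError(errors)

    out = out.astype(
        {
            "trial_index": int,
            "mss": int,
            "vss": int,
            "context_present": bool,
            "target_present": bool,
            "rt": float,
        }
    )
    errors = _validate_frame(out, line_offset=2)
    if errors:
        raise TrialValidationError(errors)
    table = TrialTable(data=out.reset_index(drop=True))
    table.provenance.append({"rule": "read", "path": str(path), "rows": len(out)})
    return table


def write_trials(table: TrialTable, path, provenance_sidecar: bool = True) -> None:
    """Write the canonical trial CSV plus a JSON provenance sidecar."""
    df = table.data.copy()
    df["context_present"] = df["context_present"].astype(int)
    df["target_present"] = df["target_present"].astype(int)
    df["correct"] = df["correct"].map(lambda v: "" if pd.isna(v) else int(bool(v)))
    df.to_csv(path, index=False, float_format="%.6f")
    if provenance_sidecar:
        table.write_provenance(str(path) + ".provenance.json")


# ---------------------------------------------------------------------------
# filtering rules
# ---------------------------------------------------------------------------

def filter_for_rt_analysis(trials: TrialTable) -> TrialTable:
    """Keep answered, correct trials for RT analysis.

    Timeouts (no answer within the 7 s deadline) and incorrect trials are
    removed; very short responses (< 200 ms) are deliberately retained.
    Idempotent; warns (does not fail) when nothing survives.
    """
    df = trials.data
    answered = df["response"] != "none"
    n_timeout = int((~answered).sum())
    correct = df["correct"].eq(True)  # missing (timeout) counts as not correct
    n_incorrect = int((answered & ~correct).sum())
    kept = df[answered & correct]
    if len(kept) == 0:
        logger.warning("filter_for_rt_analysis removed every trial")
    return trials.with_filter(
        kept, {"rule": "rt_analysis", "timeouts": n_timeout, "incorrect": n_incorrect}
    )


def exclude_low_accuracy_participants(trials: TrialTable, k: float = 3.0):
    """Drop participants whose overall accuracy falls k SDs below the mean.

    Accuracy is computed on the raw table (timeouts count as not correct);
    the mean and SD are taken over participants.  When the SD is zero nobody
    is excluded.  Returns (filtered table, sorted excluded participant ids).
    """
    df = trials.data
    participants = df["participant_id"].unique()
    if len(participants) < 2:
        raise ValueError("need at least 2 participants to estimate an accuracy SD")
    acc = (
        df.assign(_c=df["correct"].eq(True).astype(float))
        .groupby("participant_id")["_c"]
        .mean()
    )
    mean, sd = float(acc.mean()), float(acc.std(ddof=1))
    if sd == 0:
        excluded: list = []
    else:
        cutoff = mean - k * sd
        excluded = sorted(acc.index[acc < cutoff])
    kept = df[~df["participant_id"].isin(excluded)]
    table = trials.with_filter(
        kept,
        {
            "rule": "low_accuracy_participants",
            "k": k,
            "mean_accuracy": mean,
            "sd_accuracy": sd,
            "excluded": list(map(str, excluded)),
        },
    )
    return table, list(excluded)


def screen_stimuli(trials: TrialTable, f_threshold: float = 20.0, alpha: float = 0.05):
    """Flag one outlier stimulus per condition cell via one-way ANOVA + Tukey.

    Within each {context, MSS, VSS, target} cell, a one-way ANOVA of
    correct-trial RT on stimulus id is run.  If F > ``f_threshold`` with
    p < ``alpha``, Tukey's HSD (same alpha) identifies deviant stimuli and
    the single stimulus whose mean RT differs most from the mean of the
    remaining stimuli is discarded — at most one per cell, to preserve the
    design balance.  Cells with fewer than two stimuli (or stimuli with
    fewer than two RTs) are skipped with a log entry.

    Returns (filtered table, sorted discarded stimulus ids).
    """
    df = trials.data
    usable = df[(df["response"] != "none") & df["correct"].eq(True)]
    discarded: list = []
    for cell, sub in usable.groupby(
        ["context_present", "mss", "vss", "target_present"], sort=True
    ):
        counts = sub.groupby("stimulus_id")["rt"].count()
        good = counts.index[counts >= 2]
        if len(good) < 2:
            logger.info("screen_stimuli: cell %s skipped (fewer than 2 usable stimuli)", cell)
            continue
        groups = [sub.loc[sub["stimulus_id"] == s, "rt"].to_numpy() for s in good]
        f_stat, p_val = stats.f_oneway(*groups)
        if not (f_stat > f_threshold and p_val < alpha):
            continue
        tukey = stats.tukey_hsd(*groups)
        sig = np.any(tukey.pvalue + np.eye(len(good)) < alpha, axis=1)
        if not np.any(sig):
            continue
        means = np.array([g.mean() for g in groups])
        sizes = np.array([g.size for g in groups])
        total, total_n = means @ sizes, sizes.sum()
        # |own mean - mean of all other stimuli|, restricted to Tukey-flagged
        # ones; exact ties (e.g. a two-stimulus cell) break toward the slower
        # stimulus, since screening hunts abnormally slow images
        others_mean = (total - means * sizes) / (total_n - sizes)
        dev = np.round(np.abs(means - others_mean), 9)
        dev[~sig] = -np.inf
        worst = good[int(np.lexsort((means, dev))[-1])]
        discarded.append(str(worst))
        logger.info(
            "screen_stimuli: cell %s discards stimulus %s (F=%.1f, p=%.2g)",
            cell,
            worst,
            f_stat,
            p_val,
        )
    kept = df[~df["stimulus_id"].isin(discarded)]
    table = trials.with_filter(
        kept,
        {
            "rule": "stimulus_screen",
            "f_threshold": f_threshold,
            "alpha": alpha,
            "discarded": sorted(discarded),
        },
    )
    return table, sorted(discarded)
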