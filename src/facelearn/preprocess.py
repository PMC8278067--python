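"""Scoring, exclusion rules and descriptive summaries for trial-level records.

Exclusion rules: responses faster than the physiologically possible cutoff
(neutral hold + minimal mimicry latency = 626 ms) are non-compliance, RTs
above 5 s are outliers, and trials without a detectable response are removed.
Boundary semantics are strict (< fast cutoff, > slow cutoff); trials exactly
at a cutoff are retained.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterReport",
    "rt_cutoff_ms",
    "filter_trials",
    "add_condition_trial_number",
    "summarize_behaviour",
    "learning_curves",
    "reversal_early_late",
]

FAST_CUTOFF_MS = 626.0
SLOW_CUTOFF_MS = 5000.0

#: columns the tidy record frame must carry
RECORD_COLUMNS = [
    "participant_id",
    "trial_index",
    "block",
    "interactant",
    "target_expression",
    "condition",
    "correct_response",
    "response",
    "rt_ms",
    "shock",
    "correct",
]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_fast_excluded: int
    n_slow_excluded: int
    n_no_response_excluded: int
    n_retained: int

    def __post_init__(self) -> None:
        excluded = (
            self.n_fast_excluded + self.n_slow_excluded + self.n_no_response_excluded
        )
        if self.n_retained != self.n_input - excluded:
            raise ValueError("filter report counts do not partition the input")
        if min(asdict(self).values()) < 0:
            raise ValueError("filter report counts must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def rt_cutoff_ms(
    neutral_hold_ms: float = 500.0, min_mimicry_latency_ms: float = 126.0
) -> float:
    """Fastest physiologically possible RT: stimulus neutral-hold duration
    plus the minimal observable mimicry latency."""
    if neutral_hold_ms < 0 or min_mimicry_latency_ms < 0:
        raise ValueError("durations must be non-negative")
    return neutral_hold_ms + min_mimicry_latency_ms


def validate_records(records: pd.DataFrame) -> None:
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"record frame is missing columns: {missing}")


def filter_trials(
    records: pd.DataFrame,
    fast_cutoff_ms: float = FAST_CUTOFF_MS,
    slow_cutoff_ms: float = SLOW_CUTOFF_MS,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the exclusion rules; reasons checked fast -> slow -> no-response.

    A trial with no response has undefined rt_ms (NaN) and can only fall in
    the no-response bin.  Returns the retained records (original order) and a
    report partitioning the exclusions.
    """
    validate_records(records)
    rt = records["rt_ms"].to_numpy(dtype=float)
    no_resp = records["response"].isna().to_numpy() | np.isnan(rt)
    fast = ~no_resp & (rt < fast_cutoff_ms)
    slow = ~no_resp & ~fast & (rt > slow_cutoff_ms)
    drop = fast | slow | no_resp
    report = FilterReport(
        n_input=len(records),
        n_fast_excluded=int(fast.sum()),
        n_slow_excluded=int(slow.sum()),
        n_no_response_excluded=int(no_resp.sum()),
        n_retained=int((~drop).sum()),
    )
    return records.loc[~drop].copy(), report


def add_condition_trial_number(records: pd.DataFrame) -> pd.DataFrame:
    """Add ``cond_trial``: 1-based position within each participant's
    (block, interactant, target_expression) clip condition, in trial order,
    and ``cond_trial_overall`` running 1..24 across both blocks."""
    out = records.sort_values(["participant_id", "trial_index"]).copy()
    out["cond_trial"] = (
        out.groupby(
            ["participant_id", "block", "interactant", "target_expression"],
            observed=True,
        ).cumcount()
        + 1
    )
    reps = int(out["cond_trial"].max()) if len(out) else 0
    out["cond_trial_overall"] = out["cond_trial"] + (out["block"] - 1) * reps
    return out


def summarize_behaviour(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell summary over {congruent, incongruent} x {smile, frown}.

    Returns mean CR, mean RT (ms), standard errors and n per cell; empty
    cells appear with n = 0 and NaN statistics (unavailable, not zero).
    """
    validate_records(records)
    cells = pd.MultiIndex.from_product(
        [["congruent", "incongruent"], ["smile", "frown"]],
        names=["condition", "target_expression"],
    )
    grouped = records.groupby(["condition", "target_expression"], observed=True)
    summary = grouped.agg(
        mean_cr=("correct", "mean"),
        sem_cr=("correct", "sem"),
        mean_rt_ms=("rt_ms", "mean"),
        sem_rt_ms=("rt_ms", "sem"),
        n=("correct", "size"),
    ).reindex(cells)
    summary["n"] = summary["n"].fillna(0).astype(int)
    return summary.reset_index()


def learning_curves(records: pd.DataFrame) -> pd.DataFrame:
    """Mean CR per congruency condition and per-condition trial number."""
    rec = records
    if "cond_trial" not in rec.columns:
        rec = add_condition_trial_number(rec)
    per_subject = (
        rec.groupby(
            ["condition", "block", "cond_trial", "participant_id"], observed=True
        )["correct"]
        .mean()
        .reset_index()
    )
    curves = (
        per_subject.groupby(["condition", "block", "cond_trial"], observed=True)["correct"]
        .agg(mean_cr="mean", sem_cr="sem", n_participants="size")
        .reset_index()
    )
    return curves


def _paired_t(block1: pd.Series, block2: pd.Series) -> dict:
    """Paired two-sided t-test across participants (block1 vs block2)."""
    paired = pd.concat([block1, block2], axis=1, keys=["b1", "b2"]).dropna()
    n = len(paired)
    diff = paired["b1"] - paired["b2"]
    out = {
        "mean_block1": float(paired["b1"].mean()) if n else float("nan"),
        "mean_block2": float(paired["b2"].mean()) if n else float("nan"),
        "mean_diff": float(diff.mean()) if n else float("nan"),
        "n_pairs": n,
        "n_dropped": int(max(len(block1.index.union(block2.index)) - n, 0)),
        "zero_variance": False,
    }
    if n < 2:
        out.update(t=float("nan"), df=max(n - 1, 0), p=float("nan"))
        return out
    if np.allclose(diff.std(ddof=1), 0.0):
        # degenerate paired test: all differences identical
        out["zero_variance"] = True
        out.update(
            t=0.0 if np.allclose(diff.mean(), 0) else float("inf"),
            df=n - 1,
            p=1.0 if np.allclose(diff.mean(), 0) else 0.0,
        )
        return out
    t, p = stats.ttest_rel(paired["b1"], paired["b2"])
    out.update(t=float(t), df=n - 1, p=float(p))
    return out


def reversal_early_late(records: pd.DataFrame, window: int = 3) -> pd.DataFrame:
    """Compare CR on the first/last ``window`` per-condition trials of block 1
    against the same trials of block 2, separately per congruency condition.

    Returns one row per (condition, window position) with per-block means and
    a paired t-test across participants.
    """
    rec = records
    if "cond_trial" not in rec.columns:
        rec = add_condition_trial_number(rec)
    reps = int(rec["cond_trial"].max())
    rows = []
    for condition in ("congruent", "incongruent"):
        sub = rec[rec["condition"] == condition]
        for which, mask in (
            ("first", sub["cond_trial"] <= window),
            ("last", sub["cond_trial"] > reps - window),
        ):
            win = sub[mask]
            per_subj = win.groupby(["participant_id", "block"], observed=True)[
                "correct"
            ].mean().unstack("block")
            b1 = per_subj[1] if 1 in per_subj.columns else pd.Series(dtype=float)
            b2 = per_subj[2] if 2 in per_subj.columns else pd.Series(dtype=float)
            res = _paired_t(b1, b2)
            rows.append({"condition": condition, "window": which, **res})
    return pd.DataFrame(rows)
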