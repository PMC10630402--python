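"""Scoring of the one-back social attention task.

Participants view blocks of composite face/house images and judge each image
"same" or "different" relative to the immediately preceding image, while
attending either to faces or to houses.  Performance per condition is
summarised as the signal-detection sensitivity d' with the log-linear
correction, which keeps d' finite at perfect or empty hit/false-alarm
counts:

    d' = Phi^-1((hits + 0.5) / (n_signal + 1))
       - Phi^-1((false_alarms + 0.5) / (n_noise + 1))

Scoring conventions (the task itself does not force them):

* The first image of each block has no predecessor, so it generates no
  scorable one-back trial and is excluded.
* A missing / "none" response can neither hit nor false-alarm, since both
  are defined through responding "same"; it is scored like "different".
* The correction is applied unconditionally so that d' is monotone in the
  counts across participants, not only at extreme proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

CONDITIONS = ("attend_faces", "attend_houses")

#: Required columns of a trial table.
TRIAL_COLUMNS = ("block", "condition", "truth", "response")


@dataclass(frozen=True)
class PerformanceCounts:
    """Hit/false-alarm summary of one condition of a one-back run."""

    hits: int
    false_alarms: int
    n_signal: int
    n_noise: int
    d_prime: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.hits <= self.n_signal:
            raise ValueError(f"hits={self.hits} outside [0, n_signal={self.n_signal}]")
        if not 0 <= self.false_alarms <= self.n_noise:
            raise ValueError(
                f"false_alarms={self.false_alarms} outside [0, n_noise={self.n_noise}]"
            )

    def with_dprime(self) -> "PerformanceCounts":
        return PerformanceCounts(
            self.hits,
            self.false_alarms,
            self.n_signal,
            self.n_noise,
            dprime_loglinear(self.hits, self.false_alarms, self.n_signal, self.n_noise),
        )


def dprime_loglinear(
    hits: int, false_alarms: int, n_signal: int, n_noise: int
) -> float:
    """Log-linear-corrected d'.

    Adds 0.5 to both counts and 1 to both trial totals before the z
    transform, so the result is finite for every admissible count tuple.
    """
    if n_signal < 1 or n_noise < 1:
        raise ValueError("n_signal and n_noise must be >= 1")
    if not 0 <= hits <= n_signal:
        raise ValueError(f"hits={hits} outside [0, {n_signal}]")
    if not 0 <= false_alarms <= n_noise:
        raise ValueError(f"false_alarms={false_alarms} outside [0, {n_noise}]")
    hit_rate = (hits + 0.5) / (n_signal + 1)
    fa_rate = (false_alarms + 0.5) / (n_noise + 1)
    return float(norm.ppf(hit_rate) - norm.ppf(fa_rate))


def _scorable(trials: pd.DataFrame) -> pd.DataFrame:
    """Drop the first image of each block (no one-back judgment exists)."""
    if "scorable" in trials.columns:
        return trials[trials["scorable"].astype(bool)]
    first = trials.groupby("block").cumcount() == 0
    return trials[~first]


def score_oneback(trials: pd.DataFrame, condition: str) -> PerformanceCounts:
    """Count hits and false alarms for one condition of a trial table.

    A hit is responding "same" on a "same" trial; a false alarm is
    responding "same" on a "different" trial, both over scorable trials
    only.  Returns counts without d'; chain ``.with_dprime()`` to add it.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial table missing columns: {missing}")
    available = sorted(trials["condition"].unique())
    if condition not in available:
        raise ValueError(f"condition {condition!r} not present; available: {available}")
    sub = _scorable(trials)
    sub = sub[sub["condition"] == condition]
    same_truth = sub["truth"] == "same"
    same_resp = sub["response"] == "same"
    return PerformanceCounts(
        hits=int((same_truth & same_resp).sum()),
        false_alarms=int((~same_truth & same_resp).sum()),
        n_signal=int(same_truth.sum()),
        n_noise=int((~same_truth).sum()),
    )


def score_subjects(
    trials: pd.DataFrame, conditions: tuple[str, ...] = CONDITIONS
) -> pd.DataFrame:
    """Score a multi-subject trial log into a per-subject performance table.

    Expects a ``subject`` column in addition to the trial columns; returns
    one row per subject x condition with counts and log-linear d'.
    """
    if "subject" not in trials.columns:
        raise ValueError("trial table missing 'subject' column")
    rows = []
    for subject, sub in trials.groupby("subject", sort=True):
        present = set(sub["condition"])
        for cond in conditions:
            if cond not in present:
                continue
            counts = score_oneback(sub, cond).with_dprime()
            rows.append(
                {
                    "subject": subject,
                    "condition": cond,
                    "hits": counts.hits,
                    "false_alarms": counts.false_alarms,
                    "n_signal": counts.n_signal,
                    "n_noise": counts.n_noise,
                    "d_prime": counts.d_prime,
                }
            )
    return pd.DataFrame(rows)
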