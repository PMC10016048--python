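"""Go/NoGo task scoring: response gating, trial outcomes, d', mean Go RT.

Scoring follows standard signal-detection practice for a Go/NoGo design:
hits and misses on Go trials, correct rejections and false alarms on NoGo
trials, with the sensitivity index d' = z(HR) - z(FAR).  Responses earlier
than 183 ms after stimulus onset are treated as delayed responses to the
previous trial and discarded before scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import EmptySampleError, InvalidConfigError, OrderingError

__all__ = [
    "filter_responses",
    "classify_trials",
    "compute_dprime",
    "mean_go_rt",
    "summarize_participant",
    "BehavioralSummary",
]

MIN_RT_MS = 183.0  # responses accepted strictly after this latency


@dataclass
class BehavioralSummary:
    participant_id: str
    motor_condition: str
    n_hits: int
    n_misses: int
    n_cr: int
    n_fa: int
    hit_rate: float
    fa_rate: float
    dprime: float
    mean_go_rt_ms: float


def filter_responses(trials: pd.DataFrame, min_rt_ms: float = MIN_RT_MS) -> pd.DataFrame:
    """Drop responses at or before ``min_rt_ms`` post-stimulus-onset.

    A too-early response is a delayed response to the previous trial: the
    trial keeps all its fields but becomes a non-response trial.  The cutoff
    is exclusive -- only latencies strictly greater than ``min_rt_ms`` are
    accepted.
    """
    if min_rt_ms <= 0:
        raise InvalidConfigError("min_rt_ms must be positive")
    out = trials.copy()
    early = out["response_ms"].notna() & (out["response_ms"] <= min_rt_ms)
    out.loc[early, "response_ms"] = np.nan
    return out


def classify_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Label each trial hit/miss/correct_rejection/false_alarm.

    Adds ``outcome`` and ``preceded_by_hit`` columns; the latter is true iff
    the immediately preceding trial of the same block is a hit, which defines
    the epoch-eligible subset of correct rejections and false alarms (the
    inhibitory component is only guaranteed when the previous image drew a
    response).
    """
    for _, block in trials.groupby("block", sort=False):
        idx = block["trial_idx"].to_numpy()
        if len(idx) > 1 and not (np.diff(idx) > 0).all():
            raise OrderingError("trial_idx must be strictly increasing within block")
    out = trials.copy()
    responded = out["response_ms"].notna()
    is_go = out["trial_type"] == "go"
    outcome = np.where(
        is_go,
        np.where(responded, "hit", "miss"),
        np.where(responded, "false_alarm", "correct_rejection"),
    )
    out["outcome"] = outcome
    prev_hit = pd.Series(outcome == "hit", index=out.index).groupby(out["block"]).shift(
        1, fill_value=False
    )
    out["preceded_by_hit"] = prev_hit.to_numpy()
    return out


def _adjusted_rate(rate: float, n: int) -> float:
    """Rate with a log-linear correction applied only at the 0/1 boundaries."""
    if rate == 0.0 or rate == 1.0:
        return (rate * n + 0.5) / (n + 1.0)
    return rate


def compute_dprime(hit_rate: float, fa_rate: float, n_go: int, n_nogo: int) -> float:
    """Sensitivity index d' = z(HR) - z(FAR), finite at boundary rates.

    Boundary rates (0 or 1) are replaced by the log-linear corrected rate
    (k + 0.5)/(n + 1) so the normal quantile stays finite.  Antisymmetric
    under swapping HR and FAR.
    """
    if n_go <= 0 or n_nogo <= 0:
        raise EmptySampleError("d' undefined without Go and NoGo trials")
    for name, r in [("hit_rate", hit_rate), ("fa_rate", fa_rate)]:
        if not 0.0 <= r <= 1.0:
            raise InvalidConfigError(f"{name} must lie in [0, 1]")
    hr = _adjusted_rate(hit_rate, n_go)
    far = _adjusted_rate(fa_rate, n_nogo)
    return float(norm.ppf(hr) - norm.ppf(far))


def mean_go_rt(trials: pd.DataFrame) -> float:
    """Arithmetic mean latency over hits, ms (input already response-gated)."""
    labeled = trials if "outcome" in trials else classify_trials(trials)
    rts = labeled.loc[labeled["outcome"] == "hit", "response_ms"]
    if len(rts) == 0:
        raise EmptySampleError("no hits: mean Go RT undefined")
    return float(rts.mean())


def summarize_participant(
    trials: pd.DataFrame,
    participant_id: str = "",
    min_rt_ms: float = MIN_RT_MS,
) -> list[BehavioralSummary]:
    """Score one participant's event table, pooled per motor condition.

    Rates are pooled across all blocks of a motor condition (not averaged
    per block), matching one d' per participant x condition.
    """
    summaries = []
    for cond, sub in trials.groupby("motor_condition", sort=True):
        labeled = classify_trials(filter_responses(sub, min_rt_ms))
        counts = labeled["outcome"].value_counts()
        n_hits = int(counts.get("hit", 0))
        n_misses = int(counts.get("miss", 0))
        n_cr = int(counts.get("correct_rejection", 0))
        n_fa = int(counts.get("false_alarm", 0))
        n_go, n_nogo = n_hits + n_misses, n_cr + n_fa
        if n_go == 0 or n_nogo == 0:
            raise EmptySampleError(f"{participant_id}/{cond}: missing Go or NoGo trials")
        hr, far = n_hits / n_go, n_fa / n_nogo
        summaries.append(
            BehavioralSummary(
                participant_id=participant_id,
                motor_condition=str(cond),
                n_hits=n_hits,
                n_misses=n_misses,
                n_cr=n_cr,
                n_fa=n_fa,
                hit_rate=hr,
                fa_rate=far,
                dprime=compute_dprime(hr, far, n_go, n_nogo),
                mean_go_rt_ms=mean_go_rt(labeled),
            )
        )
    return summaries
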