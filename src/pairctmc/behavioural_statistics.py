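"""Temperament scores, initiation-sequence tests and descriptive summaries.

A fish's temperament is the ratio of its leave-cover intensity to its
return-to-cover intensity in the two-state individual model; higher scores
mean bolder behaviour, and the ratio is invariant to the time unit.

Leadership sequences are analysed on the ordered initiator labels of a
pair's initiation events: a Wald-Wolfowitz runs test (negative z = fewer
runs than expected, i.e. clumping of consecutive initiations by the same
fish) and, across pairs, an exact binomial sign test on the number of pairs
with negative z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .ctmc_inference import SECONDS_PER_MINUTE, mle_closed_form
from .event_encoding import (
    SessionLog,
    Trajectory,
    encode_individual,
    encode_pair,
    initiation_sequence,
    trip_position_changes,
)
from .state_space import BOLD, RETURN, SHY, individual_scheme

__all__ = [
    "TemperamentScore",
    "UndefinedScoreError",
    "UndefinedRunsError",
    "temperament_score",
    "temperament_from_log",
    "runs_z_score",
    "sign_binomial_test",
    "descriptives",
    "initiation_runs_by_pair",
]


class UndefinedScoreError(ValueError):
    """Temperament score undefined (zero exposure to one of the states)."""


class UndefinedRunsError(ValueError):
    """Runs test undefined for a single-label sequence."""


@dataclass(frozen=True)
class TemperamentScore:
    """Leave and return intensities of one fish and their ratio."""

    fish_id: str
    leave_rate: float
    return_rate: float

    @property
    def score(self) -> float:
        return self.leave_rate / self.return_rate


def temperament_score(traj: Trajectory, fish_id: str = "",
                      time_unit: float = 1.0) -> TemperamentScore:
    """Temperament score from a two-state trajectory.

    Rates are the closed-form MLEs (events / exposure) of the two-state
    chain; the score is their ratio (time-unit free).
    """
    if traj.space_name != "individual":
        raise ValueError("expected a two-state individual trajectory")
    import warnings
    with warnings.catch_warnings():
        # zero-exposure classes surface as UndefinedScoreError below
        warnings.simplefilter("ignore")
        fit = mle_closed_form([traj], individual_scheme(), time_unit=time_unit)
    if fit.non_estimable or fit.exposure["leave"] <= 0 or fit.exposure["return"] <= 0 \
            or fit.rates["return"] == 0:
        raise UndefinedScoreError(
            f"zero exposure or zero return rate for fish {fish_id!r}")
    return TemperamentScore(fish_id, fit.rates["leave"], fit.rates["return"])


def temperament_from_log(log: SessionLog, fish: str,
                         time_unit: float = SECONDS_PER_MINUTE) -> TemperamentScore:
    """Per-minute temperament rates of one fish from a raw session log."""
    traj = encode_individual(log, fish)
    return temperament_score(traj, fish_id=f"{log.pair_id}:{fish}",
                             time_unit=time_unit)


def runs_z_score(seq: Sequence) -> float:
    """Wald-Wolfowitz runs z for a binary sequence.

    ``z = (R - mu) / sigma`` with ``R`` the observed number of runs,
    ``mu = 2 n1 n2 / N + 1`` and
    ``sigma^2 = 2 n1 n2 (2 n1 n2 - N) / (N^2 (N - 1))``.
    Negative z means fewer runs than expected under exchangeability, i.e.
    clumping of identical labels.
    """
    seq = list(seq)
    labels = sorted(set(seq), key=str)
    if len(labels) < 2:
        raise UndefinedRunsError("runs test needs both labels present")
    if len(labels) > 2:
        raise ValueError("runs test is defined for binary sequences")
    n1 = seq.count(labels[0])
    n2 = len(seq) - n1
    N = n1 + n2
    R = 1 + sum(a != b for a, b in zip(seq, seq[1:]))
    mu = 2.0 * n1 * n2 / N + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - N) / (N * N * (N - 1.0))
    return float((R - mu) / math.sqrt(var))


def sign_binomial_test(k: int, n: int) -> float:
    """Exact two-sided binomial test at null proportion 1/2.

    Doubled smaller-tail probability, capped at 1.
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n and n >= 1")
    lower = sp_stats.binom.cdf(k, n, 0.5)
    upper = sp_stats.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


def initiation_runs_by_pair(logs: Sequence[SessionLog],
                            include_failed: bool = True) -> pd.DataFrame:
    """Per-pair runs z on the sequence of initiator labels.

    Initiation events of each pair's transparent sessions are concatenated
    in session order; unresolved final trips are dropped.  Pairs whose
    sequence contains only one label get ``z = NaN``.  ``include_failed``
    keeps failed initiations in the sequence (the default reading of an
    initiation event: any first departure from a both-covered pair).
    """
    rows = []
    by_pair: dict[str, list[SessionLog]] = {}
    for log in logs:
        if log.partition == "transparent":
            by_pair.setdefault(str(log.pair_id), []).append(log)
    for pid in sorted(by_pair):
        labels = []
        for log in sorted(by_pair[pid], key=lambda l: str(l.session_id)):
            for rec in initiation_sequence(encode_pair(log)):
                if rec.success is None:
                    continue
                if rec.success or include_failed:
                    labels.append(rec.initiator)
        try:
            z = runs_z_score(labels)
        except (UndefinedRunsError, ValueError):
            z = float("nan")
        rows.append({"pair_id": pid, "n_initiations": len(labels), "runs_z": z})
    return pd.DataFrame(rows)


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) == 0:
        return float("nan"), float("nan")
    se = float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else float("nan")
    return float(x.mean()), se


def descriptives(logs: Sequence[SessionLog]) -> dict:
    """Descriptive summaries of transparent-partition sessions.

    Returns a dict with:

    * ``per_fish``: completed trips per hour for every fish (a completed
      trip is a leave followed by its return), with mean and SE across fish;
    * ``per_pair``: initiation counts and success proportions by fish, and
      the per-joint-trip position-change counts;
    * ``position_changes``: pooled mean and SE (per joint trip) plus range.
    """
    logs = [l for l in logs if l.partition == "transparent"]
    if not logs:
        raise ValueError("no transparent-partition sessions")
    fish_rows = []
    pair_rows = []
    changes_all: list[int] = []
    by_pair: dict[str, list[SessionLog]] = {}
    for log in logs:
        by_pair.setdefault(str(log.pair_id), []).append(log)
    for pid in sorted(by_pair):
        hours = {BOLD: 0.0, SHY: 0.0}
        trips = {BOLD: 0, SHY: 0}
        init_counts = {BOLD: 0, SHY: 0}
        succ_counts = {BOLD: 0, SHY: 0}
        changes: list[int] = []
        for log in by_pair[pid]:
            for fish in (BOLD, SHY):
                hours[fish] += log.duration_s / 3600.0
                trips[fish] += sum(1 for e in log.events_of(fish)
                                   if e.action == RETURN)
            traj = encode_pair(log)
            for rec in initiation_sequence(traj):
                if rec.success is None:
                    continue
                init_counts[rec.initiator] += 1
                if rec.success:
                    succ_counts[rec.initiator] += 1
            changes.extend(trip_position_changes(traj))
        for fish in (BOLD, SHY):
            fish_rows.append({
                "pair_id": pid, "fish": fish,
                "trips_per_hour": trips[fish] / hours[fish] if hours[fish] else np.nan,
            })
        pair_rows.append({
            "pair_id": pid,
            "initiations_bold": init_counts[BOLD],
            "initiations_shy": init_counts[SHY],
            "initiation_share_bold": (init_counts[BOLD] /
                                      (init_counts[BOLD] + init_counts[SHY])
                                      if init_counts[BOLD] + init_counts[SHY] else np.nan),
            "success_prop_bold": (succ_counts[BOLD] / init_counts[BOLD]
                                  if init_counts[BOLD] else np.nan),
            "success_prop_shy": (succ_counts[SHY] / init_counts[SHY]
                                 if init_counts[SHY] else np.nan),
            "mean_position_changes": float(np.mean(changes)) if changes else np.nan,
            "n_joint_trips": len(changes),
        })
        changes_all.extend(changes)
    per_fish = pd.DataFrame(fish_rows)
    per_pair = pd.DataFrame(pair_rows)
    tph_mean, tph_se = _mean_se(per_fish["trips_per_hour"].to_numpy())
    ch_mean, ch_se = _mean_se(np.array(changes_all, dtype=float))
    return {
        "per_fish": per_fish,
        "per_pair": per_pair,
        "trips_per_hour_mean": tph_mean,
        "trips_per_hour_se": tph_se,
        "position_changes": {
            "mean": ch_mean,
            "se": ch_se,
            "min": int(min(changes_all)) if changes_all else None,
            "max": int(max(changes_all)) if changes_all else None,
            "n": len(changes_all),
        },
    }
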