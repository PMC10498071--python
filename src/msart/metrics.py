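"""Scoring of session logs into mind-wandering measures.

Measures:

* error rates — no-go commissions / no-go count, go omissions / go count
  (b-corrected errors still count: correction affects only the mode
  machine);
* mean RT and RT coefficient of variation over the 4 go trials preceding
  each no-go stimulus, after three exclusion rules (sets anchored at the
  first two no-gos of the session; sets with fewer than 4 intervening go
  trials since the previous no-go; sets containing an omitted go);
* d' = Z(hit rate) - Z(false-alarm rate), with hits = correct no-go
  withholds and false alarms = go omissions, extreme proportions nudged by
  1/(2N);
* deepest mode reached and its mild (1-3) / moderate (4-6) / severe (7-9)
  classification, plus maximal runs of consecutive no-go commissions;
* the same battery per 5-minute time window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _sps

from msart.engine import SessionLog, TrialRecord

MW_CLASSES = ("mild", "moderate", "severe")


@dataclass
class MetricsSummary:
    nogo_error_rate: Optional[float]
    go_error_rate: Optional[float]
    mean_rt: Optional[float]
    rt_cv: Optional[float]
    d_prime: Optional[float]
    deepest_mode: int
    mw_class: str
    max_consecutive_errors: int
    n_retained_rt_sets: int

    def to_dict(self) -> dict:
        return {
            "nogo_error_rate": self.nogo_error_rate,
            "go_error_rate": self.go_error_rate,
            "mean_rt": self.mean_rt,
            "rt_cv": self.rt_cv,
            "d_prime": self.d_prime,
            "deepest_mode": self.deepest_mode,
            "mw_class": self.mw_class,
            "max_consecutive_errors": self.max_consecutive_errors,
            "n_retained_rt_sets": self.n_retained_rt_sets,
        }


@dataclass
class WindowSummary:
    window_index: int
    n_trials: int
    nogo_error_rate: Optional[float]
    go_error_rate: Optional[float]
    mean_rt: Optional[float]
    rt_cv: Optional[float]
    d_prime: Optional[float]

    def to_dict(self) -> dict:
        return {
            "window_index": self.window_index,
            "n_trials": self.n_trials,
            "nogo_error_rate": self.nogo_error_rate,
            "go_error_rate": self.go_error_rate,
            "mean_rt": self.mean_rt,
            "rt_cv": self.rt_cv,
            "d_prime": self.d_prime,
        }


def error_rates(log: SessionLog) -> tuple[Optional[float], Optional[float]]:
    """(no-go error rate, go error rate); a rate is None when its trial
    class is absent from the log, never 0 by fiat."""
    return _error_rates_trials(log.trials)


def _error_rates_trials(trials: Sequence[TrialRecord]) -> tuple[Optional[float], Optional[float]]:
    n_nogo = sum(t.stim_class == "nogo" for t in trials)
    n_go = sum(t.stim_class == "go" for t in trials)
    commissions = sum(t.outcome == "nogo_commission" for t in trials)
    omissions = sum(t.outcome == "go_omission" for t in trials)
    nogo_rate = commissions / n_nogo if n_nogo else None
    go_rate = omissions / n_go if n_go else None
    return nogo_rate, go_rate


def extract_pre_nogo_sets(log: SessionLog, with_anchors: bool = False):
    """Candidate 4-RT sets, one per no-go stimulus: the RTs of the 4 go
    trials immediately preceding it.

    A candidate is dropped when (a) its anchor is the session's 1st or 2nd
    no-go, (b) fewer than 4 go trials separate the anchor from the previous
    no-go (or the session start), or (c) any of its 4 go trials carries no
    RT (an omission cannot be imputed).

    With ``with_anchors=True`` returns ``(sets, anchor_trials)`` so callers
    can bin sets by the anchor's onset.
    """
    trials = log.trials
    sets: list[list[float]] = []
    anchors: list[TrialRecord] = []
    nogo_seen = 0
    go_since_nogo: list[TrialRecord] = []
    for t in trials:
        if t.stim_class == "go":
            go_since_nogo.append(t)
            continue
        nogo_seen += 1
        candidate = go_since_nogo[-4:]
        ok = (
            nogo_seen > 2
            and len(go_since_nogo) >= 4
            and all(g.rt_ms is not None for g in candidate)
        )
        if ok:
            sets.append([float(g.rt_ms) for g in candidate])  # type: ignore[arg-type]
            anchors.append(t)
        go_since_nogo = []
    if with_anchors:
        return sets, anchors
    return sets


def mean_rt_and_cv(
    sets: Sequence[Sequence[float]], aggregation: str = "per_set"
) -> tuple[Optional[float], Optional[float]]:
    """Mean RT and RT CV (sample SD / mean) over the retained 4-RT sets.

    ``per_set`` (default): compute each set's mean and CV, then average
    across sets — the 4-RT set is the unit of analysis.  ``pooled``: pool
    every retained RT and compute one mean and one CV.
    """
    if not sets:
        return None, None
    if aggregation == "per_set":
        means = [float(np.mean(s)) for s in sets]
        cvs = [float(np.std(s, ddof=1) / np.mean(s)) for s in sets]
        return float(np.mean(means)), float(np.mean(cvs))
    if aggregation == "pooled":
        allrt = np.concatenate([np.asarray(s, dtype=float) for s in sets])
        m = float(allrt.mean())
        return m, float(allrt.std(ddof=1) / m)
    raise ValueError(f"unknown aggregation {aggregation!r}")


def _corrected_z(p: float, n: int) -> float:
    if p <= 0.0:
        p = 1.0 / (2 * n)
    elif p >= 1.0:
        p = 1.0 - 1.0 / (2 * n)
    return float(_sps.norm.ppf(p))


def d_prime(log: SessionLog) -> Optional[float]:
    """Signal-detection sensitivity: Z(hit) - Z(false alarm), hits being
    correct no-go withholds and false alarms go omissions.  Proportions of
    exactly 0 or 1 are replaced by 1/(2N) and 1 - 1/(2N)."""
    return _d_prime_trials(log.trials)


def _d_prime_trials(trials: Sequence[TrialRecord]) -> Optional[float]:
    n_nogo = sum(t.stim_class == "nogo" for t in trials)
    n_go = sum(t.stim_class == "go" for t in trials)
    if n_nogo == 0 or n_go == 0:
        return None
    hit = sum(t.outcome == "nogo_correct" for t in trials) / n_nogo
    fa = sum(t.outcome == "go_omission" for t in trials) / n_go
    return _corrected_z(hit, n_nogo) - _corrected_z(fa, n_go)


def classify_mw(deepest_mode: int) -> str:
    """Mild for modes 1-3, moderate for 4-6, severe for 7-9."""
    if not 1 <= deepest_mode <= 9:
        raise ValueError("deepest_mode must be in 1..9")
    return MW_CLASSES[(deepest_mode - 1) // 3]


def consecutive_runs(log: SessionLog) -> list[int]:
    """Lengths of maximal runs of no-go commissions, each run terminated by
    a correct no-go withhold or an effective "b" correction (the corrected
    commission still counts inside its run)."""
    runs: list[int] = []
    current = 0
    for t in log.trials:
        if t.outcome == "nogo_commission":
            current += 1
            if t.corrected:
                runs.append(current)
                current = 0
        elif t.outcome == "nogo_correct":
            if current:
                runs.append(current)
            current = 0
        elif t.outcome == "go_omission" and t.corrected and current:
            runs.append(current)
            current = 0
    if current:
        runs.append(current)
    return runs


def deepest_mode_and_class(log: SessionLog) -> tuple[int, str, int]:
    """(deepest mode, mind-wandering class, longest commission run).

    Deepest mode is the maximum mode at which a stimulus was presented."""
    if not log.trials:
        raise ValueError("empty log")
    deepest = max(t.mode_at_onset for t in log.trials)
    runs = consecutive_runs(log)
    return deepest, classify_mw(deepest), max(runs) if runs else 0


def score_session(log: SessionLog, aggregation: str = "per_set") -> MetricsSummary:
    """Full per-session scoring battery."""
    nogo_rate, go_rate = error_rates(log)
    sets = extract_pre_nogo_sets(log)
    mean_rt, rt_cv = mean_rt_and_cv(sets, aggregation=aggregation)
    dp = d_prime(log)
    deepest, mw_class, max_run = deepest_mode_and_class(log)
    return MetricsSummary(
        nogo_error_rate=nogo_rate,
        go_error_rate=go_rate,
        mean_rt=mean_rt,
        rt_cv=rt_cv,
        d_prime=dp,
        deepest_mode=deepest,
        mw_class=mw_class,
        max_consecutive_errors=max_run,
        n_retained_rt_sets=len(sets),
    )


def window_metrics(
    log: SessionLog, window_s: float = 300.0, aggregation: str = "per_set"
) -> list[WindowSummary]:
    """Per-window scoring over half-open [300*(k-1), 300*k) s bins.

    The number of windows is session_duration / 300 rounded up (six for the
    default 30-min session).  Pre-no-go RT sets are assigned to the window
    of their anchoring no-go stimulus; empty windows report absent metrics.
    """
    n_windows = max(1, math.ceil(log.config.session_duration / window_s))
    by_window: list[list[TrialRecord]] = [[] for _ in range(n_windows)]
    for t in log.trials:
        k = int(t.onset // window_s)
        if 0 <= k < n_windows:
            by_window[k].append(t)

    sets, anchors = extract_pre_nogo_sets(log, with_anchors=True)
    sets_by_window: list[list[list[float]]] = [[] for _ in range(n_windows)]
    for s, a in zip(sets, anchors):
        k = int(a.onset // window_s)
        if 0 <= k < n_windows:
            sets_by_window[k].append(s)

    out: list[WindowSummary] = []
    for k in range(n_windows):
        trials = by_window[k]
        if not trials:
            out.append(WindowSummary(k + 1, 0, None, None, None, None, None))
            continue
        nogo_rate, go_rate = _error_rates_trials(trials)
        mean_rt, rt_cv = mean_rt_and_cv(sets_by_window[k], aggregation=aggregation)
        out.append(
            WindowSummary(
                window_index=k + 1,
                n_trials=len(trials),
                nogo_error_rate=nogo_rate,
                go_error_rate=go_rate,
                mean_rt=mean_rt,
                rt_cv=rt_cv,
                d_prime=_d_prime_trials(trials),
            )
        )
    return out
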