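"""Generative synthetic participants for the adaptive go/no-go task.

The central model is a two-state Markov chain over trials: attention is
either *on-task* or *off-task* (mind-wandering), with per-trial transition
probabilities.  Conditional on the attention state, the responder commits
no-go errors and omits go responses with state-specific probabilities, and
draws go reaction times from a lognormal whose mean and coefficient of
variation are state-specific.  Off-task responding is faster and more
variable and commits far more no-go errors — the behavioural signature the
task's metrics are designed to pick up.  A scalar ``severity`` knob tilts
the chain toward the off-task state without touching the conditional
response parameters.

All responder parameters are constructs of this simulator; they are not
estimates from any human dataset.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Optional, Protocol

import numpy as np

# Ceiling/floor used by the severity tilt of the attention chain.
_P_OFF_CEIL = 0.50
_P_ON_FLOOR = 0.02


@dataclass(frozen=True)
class ResponderParams:
    """Parameters of the simulated participant's latent attention process.

    ``p_off`` / ``p_on`` are the baseline (severity = 0) per-trial
    transition probabilities on-task -> off-task and back.  ``severity`` in
    [0, 1] interpolates ``p_off`` up toward 0.5 and ``p_on`` down toward
    0.02, so higher severity means entering mind-wandering more often and
    staying in it longer.  RT means are in ms; CVs are unitless.  The
    construction enforces the orderings that define the phenomenon:
    off-task responding is faster (``rt_mean_off < rt_mean_on``), more
    variable (``rt_cv_off > rt_cv_on``), and more error-prone
    (``commit_off > commit_on``, ``omit_off > omit_on``).
    """

    p_off: float = 0.02
    p_on: float = 0.40
    commit_on: float = 0.10
    commit_off: float = 0.78
    omit_on: float = 0.02
    omit_off: float = 0.15
    rt_mean_on: float = 335.0
    rt_mean_off: float = 300.0
    rt_cv_on: float = 0.15
    rt_cv_off: float = 0.24
    p_correct_b: float = 0.5
    severity: float = 0.5

    def __post_init__(self) -> None:
        for name in ("p_off", "p_on", "commit_on", "commit_off", "omit_on",
                     "omit_off", "p_correct_b", "severity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rt_mean_on <= 0 or self.rt_mean_off <= 0:
            raise ValueError("RT means must be positive")
        if self.rt_mean_off >= self.rt_mean_on:
            raise ValueError("rt_mean_off must be below rt_mean_on")
        if self.rt_cv_off <= self.rt_cv_on:
            raise ValueError("rt_cv_off must exceed rt_cv_on")
        if self.commit_off <= self.commit_on:
            raise ValueError("commit_off must exceed commit_on")
        if self.omit_off <= self.omit_on:
            raise ValueError("omit_off must exceed omit_on")

    @property
    def effective_p_off(self) -> float:
        return self.p_off + self.severity * (_P_OFF_CEIL - self.p_off)

    @property
    def effective_p_on(self) -> float:
        return self.p_on - self.severity * (self.p_on - _P_ON_FLOOR)

    @property
    def stationary_off(self) -> float:
        """Stationary probability of the off-task state."""
        po, pn = self.effective_p_off, self.effective_p_on
        if po + pn == 0:
            return 0.0
        return po / (po + pn)

    def replace(self, **kw) -> "ResponderParams":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ResponderParams":
        return cls(**d)


#: Preset severity levels loosely matching the three mind-wandering bands.
PRESETS: dict[str, ResponderParams] = {
    "mild": ResponderParams(severity=0.02),
    "moderate": ResponderParams(severity=0.25),
    "severe": ResponderParams(severity=0.75),
}


class ResponderPolicy(Protocol):
    """Contract the session runner expects.

    ``respond`` is called once per stimulus and returns ``("press", rt_ms)``
    or ``("withhold", None)``.  ``post_trial`` is called after an error
    outcome and returns True when the responder presses the "b" correction
    key before the next stimulus.
    """

    def respond(self, digit: int, is_nogo: bool, rng: np.random.Generator) -> tuple[str, Optional[float]]: ...
    def post_trial(self, outcome: str, rng: np.random.Generator) -> bool: ...
    def metadata(self) -> dict: ...


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    # mean/CV -> (mu, sigma) of the underlying normal
    sigma2 = math.log1p(cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


class MarkovResponder:
    """Two-state Markov attention responder (the default synthetic
    participant).  The attention chain advances once per trial *before* the
    response is generated; "b" is pressed only after an error committed
    while on-task, with probability ``p_correct_b``."""

    def __init__(self, params: ResponderParams | None = None):
        self.params = params if params is not None else ResponderParams()
        self.attention = "on_task"
        self._mu_on, self._sd_on = _lognormal_params(self.params.rt_mean_on, self.params.rt_cv_on)
        self._mu_off, self._sd_off = _lognormal_params(self.params.rt_mean_off, self.params.rt_cv_off)

    def respond(self, digit: int, is_nogo: bool, rng: np.random.Generator) -> tuple[str, Optional[float]]:
        p = self.params
        if self.attention == "on_task":
            if rng.random() < p.effective_p_off:
                self.attention = "off_task"
        else:
            if rng.random() < p.effective_p_on:
                self.attention = "on_task"

        on = self.attention == "on_task"
        if is_nogo:
            if rng.random() < (p.commit_on if on else p.commit_off):
                return "press", self._draw_rt(rng, on)
            return "withhold", None
        if rng.random() < (p.omit_on if on else p.omit_off):
            return "withhold", None
        return "press", self._draw_rt(rng, on)

    def _draw_rt(self, rng: np.random.Generator, on: bool) -> float:
        mu, sd = (self._mu_on, self._sd_on) if on else (self._mu_off, self._sd_off)
        return float(rng.lognormal(mu, sd))

    def post_trial(self, outcome: str, rng: np.random.Generator) -> bool:
        if self.attention != "on_task":
            return False
        return bool(rng.random() < self.params.p_correct_b)

    def metadata(self) -> dict:
        return {"kind": "markov", "params": self.params.to_dict()}


class PerfectResponder:
    """Withholds every no-go, presses every go at a fixed RT; never errs."""

    def __init__(self, rt_ms: float = 300.0):
        self.rt_ms = rt_ms

    def respond(self, digit: int, is_nogo: bool, rng: np.random.Generator) -> tuple[str, Optional[float]]:
        if is_nogo:
            return "withhold", None
        return "press", self.rt_ms

    def post_trial(self, outcome: str, rng: np.random.Generator) -> bool:
        return False

    def metadata(self) -> dict:
        return {"kind": "perfect", "rt_ms": self.rt_ms}


class AlwaysPressResponder:
    """Presses on every stimulus and never corrects: the worst case that
    drives the mode machine monotonically to 9."""

    def __init__(self, rt_ms: float = 300.0):
        self.rt_ms = rt_ms

    def respond(self, digit: int, is_nogo: bool, rng: np.random.Generator) -> tuple[str, Optional[float]]:
        return "press", self.rt_ms

    def post_trial(self, outcome: str, rng: np.random.Generator) -> bool:
        return False

    def metadata(self) -> dict:
        return {"kind": "always_press", "rt_ms": self.rt_ms}


class ScriptedNogoResponder:
    """Commits on the first ``n_commissions`` no-go stimuli, withholds every
    later one; presses every go.  Reproduces the worked escalation example
    (5 consecutive commissions, then a correct withhold, lands the session
    at deepest mode 6)."""

    def __init__(self, n_commissions: int, rt_ms: float = 300.0):
        self.n_commissions = n_commissions
        self.rt_ms = rt_ms
        self._seen_nogo = 0

    def respond(self, digit: int, is_nogo: bool, rng: np.random.Generator) -> tuple[str, Optional[float]]:
        if is_nogo:
            self._seen_nogo += 1
            if self._seen_nogo <= self.n_commissions:
                return "press", self.rt_ms
            return "withhold", None
        return "press", self.rt_ms

    def post_trial(self, outcome: str, rng: np.random.Generator) -> bool:
        return False

    def metadata(self) -> dict:
        return {"kind": "scripted_nogo", "n_commissions": self.n_commissions}


def severity_sweep(
    levels: list[float],
    config=None,
    n_reps: int = 1,
    seed: int = 0,
    params: ResponderParams | None = None,
):
    """Simulate and score ``n_reps`` sessions at each severity level.

    Returns a pandas DataFrame with one row per (severity, rep) carrying the
    scored session summary.  Fully reproducible from ``seed``: each cell
    gets its own session seed derived from (seed, level index, rep).
    """
    import dataclasses as _dc

    import pandas as pd

    from msart.engine import SessionConfig, run_session
    from msart.metrics import score_session

    if not levels:
        raise ValueError("levels must be nonempty")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = config if config is not None else SessionConfig()
    base = params if params is not None else ResponderParams()

    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(levels) * n_reps) >> 1  # keep below 2**31
    k = 0
    for level in levels:
        p = base.replace(severity=float(level))
        for rep in range(n_reps):
            run_cfg = _dc.replace(cfg, rng_seed=int(child_seeds[k]))
            k += 1
            log = run_session(run_cfg, MarkovResponder(p))
            summary = score_session(log)
            row = {"severity": float(level), "rep": rep, "seed": run_cfg.rng_seed}
            row.update(summary.to_dict())
            rows.append(row)
    return pd.DataFrame(rows)
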