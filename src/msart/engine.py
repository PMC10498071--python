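"""Discrete-event runner for the adaptive go/no-go (mSART) paradigm.

A session is a timed sequence of trials.  Each trial shows a fixation cross
for a jittered 900-1200 ms, then a digit 1-9 for 500 ms.  Digit 3 is the
no-go stimulus; every other digit requires a "j" press.  The task holds a
difficulty *mode* in 1..9; the mode fixes the probability that the next
stimulus is a no-go (1/9, 1/9, 2/9, ..., 8/9).  A no-go commission error
advances the mode by one (capped at 9); a correct no-go withhold, or a "b"
correction press immediately after an error, resets the mode to 1.  The
deepest mode at which a stimulus was actually presented is the session's
mind-wandering depth score.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from fractions import Fraction
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    import pandas as pd

    from msart.responder import ResponderPolicy

DEFAULT_MODE_PROBS: tuple[Fraction, ...] = (
    Fraction(1, 9),
    Fraction(1, 9),
    Fraction(2, 9),
    Fraction(3, 9),
    Fraction(4, 9),
    Fraction(5, 9),
    Fraction(6, 9),
    Fraction(7, 9),
    Fraction(8, 9),
)

GO_DIGITS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 8, 9)
NOGO_DIGIT: int = 3

MODE_EVENTS = ("nogo_commission", "nogo_correct", "b_press")
OUTCOMES = ("go_correct", "go_omission", "nogo_correct", "nogo_commission")


@dataclass(frozen=True)
class SessionConfig:
    """All paradigm constants for one session.

    Parameters
    ----------
    session_duration
        Session length in seconds; the clock stops admitting new trials once
        the next stimulus onset would reach it.  Default 1800 s (30 min).
    fixation_range
        Inclusive bounds, in ms, of the uniform fixation-cross jitter.
    stimulus_duration
        Stimulus display time in ms.
    response_deadline
        Time in ms from stimulus onset within which a press is registered.
        ``None`` means onset-to-onset: the window closes at the next
        stimulus onset.
    mode_probs
        No-go probability per mode, strictly nondecreasing; the default is
        the nine-mode table (1/9, 1/9, 2/9, ..., 8/9).
    deepest
        ``"presented"``: the deepest-mode score counts only modes at which a
        stimulus was presented, so a "b" correction before the next stimulus
        annuls the escalation.  ``"entered"``: every mode entered counts.
    """

    session_duration: float = 1800.0
    fixation_range: tuple[int, int] = (900, 1200)
    stimulus_duration: int = 500
    response_deadline: Optional[int] = None
    mode_probs: tuple[Fraction, ...] = DEFAULT_MODE_PROBS
    go_digits: tuple[int, ...] = GO_DIGITS
    nogo_digit: int = NOGO_DIGIT
    practice_n_trials: int = 18
    practice_n_nogo: int = 2
    rng_seed: int = 0
    deepest: str = "presented"

    def __post_init__(self) -> None:
        if self.session_duration <= 0:
            raise ValueError("session_duration must be positive")
        lo, hi = self.fixation_range
        if not (0 < lo <= hi):
            raise ValueError("fixation_range must satisfy 0 < lo <= hi")
        probs = tuple(Fraction(p) if not isinstance(p, Fraction) else p for p in self.mode_probs)
        if len(probs) != 9:
            raise ValueError("mode_probs must have exactly 9 entries")
        if any(not (0 < p < 1) for p in probs):
            raise ValueError("mode_probs must lie strictly in (0, 1)")
        if any(b < a for a, b in zip(probs, probs[1:])):
            raise ValueError("mode_probs must be nondecreasing")
        object.__setattr__(self, "mode_probs", probs)
        if self.nogo_digit in self.go_digits:
            raise ValueError("nogo_digit must not be a go digit")
        if self.practice_n_nogo > self.practice_n_trials:
            raise ValueError("practice_n_nogo cannot exceed practice_n_trials")
        if self.practice_n_trials < 0 or self.practice_n_nogo < 0:
            raise ValueError("practice counts must be nonnegative")
        if self.deepest not in ("presented", "entered"):
            raise ValueError("deepest must be 'presented' or 'entered'")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mode_probs"] = [str(p) for p in self.mode_probs]
        d["fixation_range"] = list(self.fixation_range)
        d["go_digits"] = list(self.go_digits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if "mode_probs" in d:
            d["mode_probs"] = tuple(Fraction(p) for p in d["mode_probs"])
        if "fixation_range" in d:
            d["fixation_range"] = tuple(d["fixation_range"])
        if "go_digits" in d:
            d["go_digits"] = tuple(d["go_digits"])
        return cls(**d)


@dataclass
class ModeState:
    """Mode-machine state: current mode, consecutive no-go commissions, and
    the deepest mode credited so far."""

    mode: int = 1
    consecutive_errors: int = 0
    deepest_mode: int = 1

    def __post_init__(self) -> None:
        if not 1 <= self.mode <= 9:
            raise ValueError("mode must be in 1..9")
        if self.consecutive_errors < 0:
            raise ValueError("consecutive_errors must be nonnegative")
        if not 1 <= self.deepest_mode <= 9:
            raise ValueError("deepest_mode must be in 1..9")


def next_mode(state: ModeState, event: str) -> ModeState:
    """Apply one mode-machine event and return the new state.

    ``nogo_commission`` advances the mode (capped at 9) and increments the
    consecutive-error count.  ``nogo_correct`` and ``b_press`` both reset to
    mode 1 and zero the count.  ``deepest_mode`` is *not* touched here: the
    runner credits it only when a stimulus is presented at a mode (or on
    entry, under the ``entered`` convention), so that a "b" correction can
    annul a pending escalation.
    """
    if event == "nogo_commission":
        return ModeState(min(state.mode + 1, 9), state.consecutive_errors + 1, state.deepest_mode)
    if event in ("nogo_correct", "b_press"):
        return ModeState(1, 0, state.deepest_mode)
    raise ValueError(f"unknown mode event: {event!r}")


def sample_stimulus(mode: int, rng: np.random.Generator, config: SessionConfig | None = None) -> tuple[int, str]:
    """Draw one stimulus at the given mode.

    Returns ``(digit, stim_class)`` where the digit is the no-go digit with
    the mode's no-go probability, else a uniformly chosen go digit.
    """
    cfg = config if config is not None else SessionConfig()
    if not 1 <= mode <= len(cfg.mode_probs):
        raise ValueError(f"mode {mode} outside the mode table")
    p = float(cfg.mode_probs[mode - 1])
    if rng.random() < p:
        return cfg.nogo_digit, "nogo"
    return int(rng.choice(cfg.go_digits)), "go"


@dataclass
class TrialRecord:
    index: int                     # 1-based
    onset: float                   # seconds from session start
    fixation_ms: int
    digit: int
    stim_class: str                # go | nogo
    mode_at_onset: int
    response: str                  # press | withhold
    rt_ms: Optional[float]
    outcome: str                   # go_correct | go_omission | nogo_correct | nogo_commission
    corrected: bool = False

    def __post_init__(self) -> None:
        if (self.response == "press") != (self.rt_ms is not None):
            raise ValueError(f"trial {self.index}: rt_ms present iff response is press")
        if self.outcome not in OUTCOMES:
            raise ValueError(f"trial {self.index}: unknown outcome {self.outcome!r}")
        expected = _adjudicate(self.stim_class, self.response)
        if self.outcome != expected:
            raise ValueError(
                f"trial {self.index}: outcome {self.outcome!r} inconsistent with "
                f"({self.stim_class}, {self.response})"
            )
        if self.corrected and self.outcome not in ("nogo_commission", "go_omission"):
            raise ValueError(f"trial {self.index}: only errors can be b-corrected")


def _adjudicate(stim_class: str, response: str) -> str:
    if stim_class == "go":
        return "go_correct" if response == "press" else "go_omission"
    return "nogo_commission" if response == "press" else "nogo_correct"


@dataclass
class SessionLog:
    """One session's configuration snapshot, ordered trials, responder
    metadata and terminal mode state."""

    config: SessionConfig
    trials: list[TrialRecord] = field(default_factory=list)
    responder_meta: dict = field(default_factory=dict)
    terminal_state: ModeState = field(default_factory=ModeState)
    practice: bool = False

    def __post_init__(self) -> None:
        onsets = [t.onset for t in self.trials]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("trial onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> "pd.DataFrame":
        import pandas as pd

        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "onset_s": [t.onset for t in self.trials],
                "fixation_ms": [t.fixation_ms for t in self.trials],
                "digit": [t.digit for t in self.trials],
                "stim_class": [t.stim_class for t in self.trials],
                "mode": [t.mode_at_onset for t in self.trials],
                "response": [t.response for t in self.trials],
                "rt_ms": [t.rt_ms for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "corrected": [t.corrected for t in self.trials],
            }
        )


def run_session(config: SessionConfig, responder: "ResponderPolicy") -> SessionLog:
    """Run one full session and return its log.

    The clock advances as fixation + stimulus; a new trial starts only if
    its stimulus onset falls strictly before ``session_duration``.  All
    randomness derives from ``config.rng_seed`` through four independent
    substreams (fixation jitter, stimulus class, go digit, responder), so a
    given (config, responder-parameters, seed) triple reproduces the log
    exactly.
    """
    root = np.random.default_rng(config.rng_seed)
    jitter_rng, class_rng, digit_rng, resp_rng = root.spawn(4)

    state = ModeState()
    trials: list[TrialRecord] = []
    clock = 0.0
    lo, hi = config.fixation_range
    index = 0

    while True:
        fixation = int(jitter_rng.integers(lo, hi + 1))
        onset = clock + fixation / 1000.0
        if onset >= config.session_duration:
            break
        index += 1

        mode_at_onset = state.mode
        p_nogo = float(config.mode_probs[mode_at_onset - 1])
        if class_rng.random() < p_nogo:
            digit, stim_class = config.nogo_digit, "nogo"
        else:
            digit, stim_class = int(digit_rng.choice(config.go_digits)), "go"

        # a stimulus was presented at this mode: credit depth
        state.deepest_mode = max(state.deepest_mode, mode_at_onset)

        action, rt_ms = responder.respond(digit, stim_class == "nogo", resp_rng)
        deadline = config.response_deadline
        if action == "press" and deadline is not None and rt_ms is not None and rt_ms >= deadline:
            action, rt_ms = "withhold", None  # press after window closed
        response = "press" if action == "press" else "withhold"
        outcome = _adjudicate(stim_class, response)

        if outcome == "nogo_correct":
            state = next_mode(state, "nogo_correct")
        elif outcome == "nogo_commission":
            state = next_mode(state, "nogo_commission")
            if config.deepest == "entered":
                state.deepest_mode = max(state.deepest_mode, state.mode)

        corrected = False
        if outcome in ("nogo_commission", "go_omission"):
            if responder.post_trial(outcome, resp_rng):
                state = next_mode(state, "b_press")
                corrected = True

        trials.append(
            TrialRecord(
                index=index,
                onset=round(onset, 4),
                fixation_ms=fixation,
                digit=digit,
                stim_class=stim_class,
                mode_at_onset=mode_at_onset,
                response=response,
                rt_ms=None if rt_ms is None else round(float(rt_ms), 3),
                outcome=outcome,
                corrected=corrected,
            )
        )
        clock = onset + config.stimulus_duration / 1000.0

    return SessionLog(
        config=config,
        trials=trials,
        responder_meta=responder.metadata(),
        terminal_state=state,
    )


def make_practice_block(
    config: SessionConfig,
    rng: np.random.Generator,
    responder: Optional["ResponderPolicy"] = None,
) -> SessionLog:
    """Generate the practice block: a fixed trial count with a fixed number
    of no-go stimuli at random positions, no mode escalation (all trials
    labelled mode 1).

    If no responder is given, a perfect one (press every go, withhold every
    no-go) stands in; practice responses are never scored.
    """
    from msart.responder import PerfectResponder

    if config.practice_n_nogo > config.practice_n_trials:
        raise ValueError("practice_n_nogo cannot exceed practice_n_trials")
    resp = responder if responder is not None else PerfectResponder()

    n = config.practice_n_trials
    nogo_positions = set(rng.choice(n, size=config.practice_n_nogo, replace=False).tolist()) if n else set()
    lo, hi = config.fixation_range
    trials: list[TrialRecord] = []
    clock = 0.0
    for i in range(n):
        fixation = int(rng.integers(lo, hi + 1))
        onset = clock + fixation / 1000.0
        if i in nogo_positions:
            digit, stim_class = config.nogo_digit, "nogo"
        else:
            digit, stim_class = int(rng.choice(config.go_digits)), "go"
        action, rt_ms = resp.respond(digit, stim_class == "nogo", rng)
        response = "press" if action == "press" else "withhold"
        trials.append(
            TrialRecord(
                index=i + 1,
                onset=round(onset, 4),
                fixation_ms=fixation,
                digit=digit,
                stim_class=stim_class,
                mode_at_onset=1,
                response=response,
                rt_ms=None if rt_ms is None else round(float(rt_ms), 3),
                outcome=_adjudicate(stim_class, response),
            )
        )
        clock = onset + config.stimulus_duration / 1000.0

    return SessionLog(config=config, trials=trials, responder_meta=resp.metadata(), practice=True)


def build_log_from_sequence(
    outcomes: Sequence[str],
    rts: Optional[Sequence[Optional[float]]] = None,
    config: Optional[SessionConfig] = None,
    corrected: Optional[Sequence[bool]] = None,
) -> SessionLog:
    """Construct a SessionLog from a scripted outcome sequence, running the
    mode machine over it.  Convenience for tests, fixtures and worked
    examples; onsets are spaced on a fixed 1.5 s grid.

    ``outcomes`` entries are the four outcome labels; RTs default to 300 ms
    for presses.
    """
    cfg = config if config is not None else SessionConfig()
    state = ModeState()
    trials: list[TrialRecord] = []
    for i, out in enumerate(outcomes):
        stim_class = "go" if out.startswith("go") else "nogo"
        response = "press" if out in ("go_correct", "nogo_commission") else "withhold"
        rt = None
        if response == "press":
            rt = 300.0 if rts is None or rts[i] is None else float(rts[i])
        mode_at_onset = state.mode
        state.deepest_mode = max(state.deepest_mode, mode_at_onset)
        if out == "nogo_correct":
            state = next_mode(state, "nogo_correct")
        elif out == "nogo_commission":
            state = next_mode(state, "nogo_commission")
        is_corr = bool(corrected[i]) if corrected is not None else False
        if is_corr:
            state = next_mode(state, "b_press")
        trials.append(
            TrialRecord(
                index=i + 1,
                onset=round(0.9 + 1.5 * i, 4),
                fixation_ms=900,
                digit=cfg.nogo_digit if stim_class == "nogo" else cfg.go_digits[0],
                stim_class=stim_class,
                mode_at_onset=mode_at_onset,
                response=response,
                rt_ms=rt,
                outcome=out,
                corrected=is_corr,
            )
        )
    return SessionLog(config=cfg, trials=trials, terminal_state=state, responder_meta={"kind": "scripted"})
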