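"""Horse-race simulation of the stop/change-signal task.

The task: on every trial a left/right "Go" arrow instructs a speeded button
press.  On half of the trials a second cue (the stop/change signal) follows
after a stimulus onset asynchrony (SOA) and instructs the subject either to
withhold the press (stop mode) or to press the opposite button instead
(change mode).  Behavior is modelled as a race between an ex-Gaussian "go"
process and a stop process of duration SSRT: whichever finishes first
determines the trial outcome.  The SOA is driven by two independent
one-up/one-down staircase threads (+step after a successful stop/change,
-step after a failure, floored at zero) which together track the SOA at
which stopping succeeds on 50% of signal trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

__all__ = [
    "TaskConfig",
    "RaceParams",
    "TrialRecord",
    "SessionBehavior",
    "complexity_level",
    "update_staircase",
    "simulate_behavior_session",
]

SignalStimulus = Literal["bar", "arrow"]
ResponseMode = Literal["stop", "change"]
Outcome = Literal["go_correct", "signal_success", "signal_fail", "unclassified"]


@dataclass(frozen=True)
class TaskConfig:
    """Design of one session (a single task variant, several blocks).

    Defaults follow the study design: two ~4-minute blocks of 78 trials
    (~155 presented trials per session), signal probability 0.5, fixation
    1.3-1.5 s (uniform), a 0.2 s blank pause, staircase threads starting
    at 0 and 0.300 s with 0.050 s steps asymptoting at zero.
    """

    n_trials_per_block: int = 78
    n_blocks: int = 2
    signal_probability: float = 0.5
    fixation_range: tuple[float, float] = (1.3, 1.5)
    pause: float = 0.2
    staircase_starts: tuple[float, float] = (0.0, 0.300)
    staircase_step: float = 0.050
    soa_floor: float = 0.0
    signal_stimulus: SignalStimulus = "bar"
    response_mode: ResponseMode = "stop"
    #: go stimulus display / response window; also paces the trial clock
    response_window: float = 1.0
    #: silence between blocks on the session clock
    block_gap: float = 10.0

    def __post_init__(self) -> None:
        if not 0.0 < self.signal_probability < 1.0:
            raise ValueError("signal_probability must be in (0, 1)")
        if self.staircase_step <= 0:
            raise ValueError("staircase_step must be positive")
        if self.fixation_range[0] > self.fixation_range[1]:
            raise ValueError("fixation_range must be ordered (lo, hi)")
        if self.soa_floor < 0:
            raise ValueError("soa_floor must be non-negative")
        if self.signal_stimulus not in ("bar", "arrow"):
            raise ValueError(f"unknown signal stimulus {self.signal_stimulus!r}")
        if self.response_mode not in ("stop", "change"):
            raise ValueError(f"unknown response mode {self.response_mode!r}")

    @property
    def condition(self) -> tuple[SignalStimulus, ResponseMode]:
        return (self.signal_stimulus, self.response_mode)

    @property
    def complexity(self) -> int:
        return complexity_level(self.signal_stimulus, self.response_mode)


def complexity_level(signal_stimulus: SignalStimulus, response_mode: ResponseMode) -> int:
    """Contextual complexity of a task variant: the minimal number of
    informative cue elements that must be combined to act correctly.

    A bar cue unambiguously means "stop" (1 element), but in change mode
    the direction of the change must be inferred from the preceding go
    arrow (2 elements).  An arrow cue gives the change direction directly
    (1 element), but as a stop instruction it must be combined with the go
    arrow's direction (2 elements).  The complexity manipulation therefore
    reverses between stop and change modes.
    """
    if response_mode == "stop":
        return 1 if signal_stimulus == "bar" else 2
    return 1 if signal_stimulus == "arrow" else 2


@dataclass(frozen=True)
class RaceParams:
    """Parameters of the go/stop race.

    The go-process finish time is ex-Gaussian (normal(go_mu, go_sigma) +
    exponential(go_tau)), optionally drifting upward linearly with trial
    index; the stop-process duration is ``ssrt_true`` with optional
    Gaussian trial-to-trial jitter ``ssrt_sd``.  In change mode the
    remapped press lands ``change_extra`` seconds after the stop process
    wins.  ``complexity_effect`` is added to go_mu in contextually complex
    task variants; ``lapse_prob`` trials become unclassifiable errors.
    """

    go_mu: float = 0.35
    go_sigma: float = 0.05
    go_tau: float = 0.15
    ssrt_true: float = 0.20
    ssrt_sd: float = 0.0
    drift_slope: float = 0.0
    change_extra: float = 0.25
    lapse_prob: float = 0.0
    complexity_effect: float = 0.03

    def __post_init__(self) -> None:
        if self.go_sigma < 0:
            raise ValueError("go_sigma must be >= 0")
        if self.ssrt_true <= 0:
            raise ValueError("ssrt_true must be positive")
        if not 0.0 <= self.lapse_prob < 1.0:
            raise ValueError("lapse_prob must be in [0, 1)")


@dataclass
class TrialRecord:
    """One simulated (or logged) trial."""

    index: int
    block: int
    go_direction: Literal["L", "R"]
    is_signal_trial: bool
    outcome: Outcome
    soa: Optional[float] = None
    staircase_thread: Optional[int] = None
    rt: Optional[float] = None
    press_direction: Optional[str] = None  # "L", "R", or "LR" for double press
    onset_fixation: float = 0.0
    onset_go: float = 0.0
    onset_signal: Optional[float] = None
    onset_press: Optional[float] = None
    #: latent go-process finish time (ground truth; None for lapse trials)
    go_finish: Optional[float] = None
    #: latent stop-process duration on signal trials (ground truth)
    stop_duration: Optional[float] = None


@dataclass
class SessionBehavior:
    """An ordered list of trials plus the configuration that produced them."""

    trials: list[TrialRecord]
    config: TaskConfig
    params: Optional[RaceParams] = None
    subject_id: str = "sim"
    session_id: str = "0"
    block_bounds: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = [t.index for t in self.trials]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("trial indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.trials)

    def signal_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.is_signal_trial]

    def to_frame(self):
        """Tabular view of the session (one row per trial)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "index": [t.index for t in self.trials],
                "block": [t.block for t in self.trials],
                "go_direction": [t.go_direction for t in self.trials],
                "is_signal_trial": [t.is_signal_trial for t in self.trials],
                "outcome": [t.outcome for t in self.trials],
                "soa": [t.soa for t in self.trials],
                "rt": [t.rt for t in self.trials],
                "press_direction": [t.press_direction for t in self.trials],
                "onset_go": [t.onset_go for t in self.trials],
            }
        )


def update_staircase(soa: float, outcome: str, step: float, floor: float = 0.0) -> float:
    """One-up/one-down SOA update: +step after a success, -step after a
    failure, never below ``floor``."""
    if step <= 0:
        raise ValueError("step must be positive")
    if soa < floor:
        raise ValueError(f"soa {soa} below floor {floor}")
    if outcome == "success":
        return soa + step
    if outcome == "fail":
        return max(soa - step, floor)
    raise ValueError(f"outcome must be 'success' or 'fail', got {outcome!r}")


def _other(direction: str) -> str:
    return "R" if direction == "L" else "L"


def simulate_behavior_session(
    config: TaskConfig,
    params: RaceParams,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
    session_id: str = "0",
) -> SessionBehavior:
    """Simulate one session of the stop/change-signal task.

    Signal trials are assigned per block (exactly the requested fraction,
    in random order).  Each signal trial draws one of the two staircase
    threads uniformly and updates only that thread; thread state persists
    across blocks.  The trial outcome is decided by the race: the stop
    process wins iff the go finish time exceeds SOA + stop duration.
    Lapses become unclassifiable errors (wrong-direction presses) and, on
    signal trials, update the staircase as failures (a press occurred).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    threads = list(config.staircase_starts)
    mu = params.go_mu + (params.complexity_effect if config.complexity == 2 else 0.0)

    trials: list[TrialRecord] = []
    block_bounds: list[tuple[float, float]] = []
    clock = 0.0
    index = 0
    for block in range(config.n_blocks):
        block_start = clock
        n = config.n_trials_per_block
        n_signal = int(round(config.signal_probability * n))
        is_signal = np.zeros(n, dtype=bool)
        is_signal[:n_signal] = True
        rng.shuffle(is_signal)
        for k in range(n):
            fix_dur = rng.uniform(*config.fixation_range)
            onset_fix = clock
            onset_go = onset_fix + fix_dur + config.pause
            go_dir = "L" if rng.random() < 0.5 else "R"
            T = rng.normal(mu, params.go_sigma) + rng.exponential(params.go_tau)
            T += params.drift_slope * index
            T = max(T, 1e-3)
            lapse = rng.random() < params.lapse_prob

            rec = TrialRecord(
                index=index,
                block=block,
                go_direction=go_dir,
                is_signal_trial=bool(is_signal[k]),
                outcome="unclassified",
                onset_fixation=onset_fix,
                onset_go=onset_go,
                go_finish=T,
            )

            if not is_signal[k]:
                if lapse:
                    rec.press_direction = _other(go_dir)
                    rec.rt = T
                    rec.outcome = "unclassified"
                else:
                    rec.press_direction = go_dir
                    rec.rt = T
                    rec.outcome = "go_correct"
                rec.onset_press = onset_go + T
            else:
                thread = int(rng.integers(2))
                soa = threads[thread]
                D = params.ssrt_true
                if params.ssrt_sd > 0:
                    D = max(rng.normal(params.ssrt_true, params.ssrt_sd), 1e-3)
                rec.soa = soa
                rec.staircase_thread = thread
                rec.onset_signal = onset_go + soa
                rec.stop_duration = D
                stop_wins = T > soa + D
                if lapse:
                    # unclassifiable error: double press at the go finish
                    rec.press_direction = "LR"
                    rec.rt = T
                    rec.onset_press = onset_go + T
                    rec.outcome = "unclassified"
                    staircase_result = "fail"
                elif config.response_mode == "stop":
                    if stop_wins:
                        rec.outcome = "signal_success"
                        staircase_result = "success"
                    else:
                        rec.outcome = "signal_fail"
                        rec.press_direction = go_dir
                        rec.rt = T
                        rec.onset_press = onset_go + T
                        staircase_result = "fail"
                else:  # change mode: a second, opposite press follows the stop win
                    if stop_wins:
                        rec.outcome = "signal_success"
                        change_rt = soa + D + params.change_extra
                        rec.press_direction = _other(go_dir)
                        rec.rt = change_rt
                        rec.onset_press = onset_go + change_rt
                        staircase_result = "success"
                    else:
                        rec.outcome = "signal_fail"
                        rec.press_direction = go_dir
                        rec.rt = T
                        rec.onset_press = onset_go + T
                        staircase_result = "fail"
                threads[thread] = update_staircase(
                    soa, staircase_result, config.staircase_step, config.soa_floor
                )

            trials.append(rec)
            press_end = rec.onset_press if rec.onset_press is not None else onset_go
            clock = max(onset_go + config.response_window, press_end + 0.05)
            index += 1
        block_bounds.append((block_start, clock))
        clock += config.block_gap

    return SessionBehavior(
        trials=trials,
        config=config,
        params=params,
        subject_id=subject_id,
        session_id=session_id,
        block_bounds=block_bounds,
    )
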