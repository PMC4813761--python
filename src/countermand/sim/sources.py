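"""Source-level oscillatory activity with known, event-locked effects.

Each simulated cortical source is a 1/f-like background plus band-limited
components whose envelopes are locked to task events:

* a theta/alpha (2-12 Hz) burst at the stop/change signal;
* sustained gamma (>= 55 Hz) from trial onset whose amplitude scales with
  the contextual complexity of the task variant;
* a post-signal beta (15-25 Hz) component whose amplitude depends on the
  success of the trial and the response mode;
* a motor beta desynchronization (envelope dip of the baseline beta
  rhythm) around button presses.

Every band-limited carrier has unit RMS before the envelope is applied,
so injected amplitudes are directly the expected band-RMS increments:
scaling an amplitude by k scales the corresponding triggered band-RMS
increment by k (up to the quadrature sum with the background).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .race import SessionBehavior, complexity_level

__all__ = [
    "BandBurst",
    "SourceRecipe",
    "SourceEffectConfig",
    "SourceBlock",
    "simulate_source_signals",
    "events_table",
]

ANALYSIS_BAND = (2.5, 90.0)

THETA_ALPHA = (2.0, 12.0)
BETA = (15.0, 25.0)
GAMMA = (55.0, 75.0)


def _check_band(band: tuple[float, float]) -> tuple[float, float]:
    lo, hi = band
    if not (ANALYSIS_BAND[0] <= lo < hi <= ANALYSIS_BAND[1]):
        raise ValueError(f"band {band} outside the {ANALYSIS_BAND} Hz analysis range")
    return (float(lo), float(hi))


@dataclass(frozen=True)
class BandBurst:
    """A band-limited component locked to an event type.

    ``lock`` names the event ('signal', 'go', 'fixation', 'press');
    the Hanning envelope starts ``offset`` seconds after each event and
    lasts ``duration`` seconds with peak amplitude ``amplitude``.
    """

    band: tuple[float, float]
    amplitude: float
    lock: str = "signal"
    duration: float = 0.4
    offset: float = 0.0

    def __post_init__(self) -> None:
        _check_band(self.band)
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


@dataclass(frozen=True)
class SourceRecipe:
    """Effect recipe for one simulated source."""

    name: str
    #: continuous background rhythms: (band, RMS amplitude)
    base_bands: tuple[tuple[tuple[float, float], float], ...] = ()
    #: 1/f-like broadband background RMS
    background: float = 1.0
    #: signal-locked theta/alpha burst amplitude (band 2-12 Hz)
    theta_alpha_burst: float = 0.0
    theta_alpha_duration: float = 0.4
    #: gamma amplitude per unit of complexity, sustained over the trial
    gamma_complexity: float = 0.0
    gamma_band: tuple[float, float] = GAMMA
    #: post-signal beta amplitude keyed by (success, response_mode)
    beta_post: dict = field(default_factory=dict)
    beta_post_offset: float = 0.3
    beta_post_duration: float = 0.6
    #: fractional envelope dip of base beta rhythms around presses
    motor_beta_desync: float = 0.0
    extra_bursts: tuple[BandBurst, ...] = ()

    def __post_init__(self) -> None:
        for band, amp in self.base_bands:
            _check_band(band)
            if amp < 0:
                raise ValueError("base amplitude must be >= 0")
        _check_band(self.gamma_band)
        for amp in (self.theta_alpha_burst, self.gamma_complexity):
            if amp < 0:
                raise ValueError("amplitudes must be >= 0")


@dataclass(frozen=True)
class SourceEffectConfig:
    recipes: tuple[SourceRecipe, ...]

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.recipes]


@dataclass
class SourceBlock:
    """Simulated source traces for one recording block."""

    data: np.ndarray  # (n_sources, n_samples)
    sfreq: float
    t0: float  # block start on the session clock
    names: list[str]
    events: pd.DataFrame
    #: per-source dict of (effect name -> envelope trace), ground truth
    envelopes: list[dict]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


def events_table(session: SessionBehavior, block: Optional[int] = None) -> pd.DataFrame:
    """Flat event list (onset on the session clock) for a session or block."""
    rows = []
    for t in session.trials:
        if block is not None and t.block != block:
            continue
        meta = dict(
            trial_index=t.index,
            outcome=t.outcome,
            soa=t.soa if t.soa is not None else np.nan,
            rt=t.rt if t.rt is not None else np.nan,
        )
        rows.append(dict(onset=t.onset_fixation, duration=0.0, event_type="fixation", **meta))
        rows.append(dict(onset=t.onset_go, duration=0.0, event_type="go", **meta))
        if t.onset_signal is not None:
            rows.append(dict(onset=t.onset_signal, duration=0.0, event_type="signal", **meta))
        if t.onset_press is not None and t.press_direction is not None:
            d = t.press_direction if len(t.press_direction) == 1 else "L"
            rows.append(
                dict(onset=t.onset_press, duration=0.0, event_type=f"press_{d}", **meta)
            )
    df = pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)
    df["condition"] = "{}_{}".format(*session.config.condition)
    return df


def _band_noise(rng: np.random.Generator, n: int, sfreq: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to ``band`` (boxcar in frequency)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[~mask] = 0.0
    x = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, sfreq: float) -> np.ndarray:
    """Unit-RMS 1/f-amplitude noise, flat below 1 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    scale = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= scale
    x = np.fft.irfft(spec, n)
    return x / np.sqrt(np.mean(x**2))


def _hann_envelope(n: int, sfreq: float, onsets_amps, duration: float, t0: float) -> np.ndarray:
    env = np.zeros(n)
    L = max(int(round(duration * sfreq)), 2)
    win = np.hanning(L)
    for onset, amp in onsets_amps:
        s = int(round((onset - t0) * sfreq))
        if s >= n or s + L <= 0:
            continue
        a, b = max(s, 0), min(s + L, n)
        env[a:b] = np.maximum(env[a:b], amp * win[a - s : b - s])
    return env


def simulate_source_signals(
    session: SessionBehavior,
    effects: SourceEffectConfig,
    sfreq: float,
    seed: int | np.random.Generator = 0,
    block: int = 0,
) -> SourceBlock:
    """Simulate all sources for one block of a session.

    The returned traces are background + sum of enveloped unit-RMS
    band-limited carriers; the exact envelopes are returned as ground
    truth so downstream estimates can be checked against the injection.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t0, t1 = session.block_bounds[block]
    # trailing margin lets post-signal components of the last trial play out
    n = int(round((t1 - t0 + 2.0) * sfreq))
    ev = events_table(session, block=block)
    mode = session.config.response_mode
    complexity = complexity_level(*session.config.condition)

    trials = [t for t in session.trials if t.block == block]
    signal_onsets = [(t.onset_signal, 1.0) for t in trials if t.onset_signal is not None]
    press_onsets = [(t.onset_press, 1.0) for t in trials if t.onset_press is not None]
    trial_spans = [(t.onset_fixation, t.onset_go) for t in trials]

    data = np.empty((len(effects.recipes), n))
    env_truth: list[dict] = []
    for s, rec in enumerate(effects.recipes):
        x = rec.background * _pink_noise(rng, n, sfreq)
        envs: dict[str, np.ndarray] = {}

        for band, amp in rec.base_bands:
            env = np.full(n, amp)
            if rec.motor_beta_desync > 0 and BETA[0] <= band[0] and band[1] <= BETA[1]:
                dip = _hann_envelope(n, sfreq, press_onsets, 0.8, t0 - 0.4)
                env = env * (1.0 - rec.motor_beta_desync * np.clip(dip, 0, 1))
                envs["motor_beta"] = env.copy()
            x += env * _band_noise(rng, n, sfreq, band)

        if rec.theta_alpha_burst > 0 and signal_onsets:
            env = _hann_envelope(
                n, sfreq, [(o, rec.theta_alpha_burst) for o, _ in signal_onsets],
                rec.theta_alpha_duration, t0,
            )
            x += env * _band_noise(rng, n, sfreq, THETA_ALPHA)
            envs["theta_alpha"] = env

        if rec.gamma_complexity > 0 and trial_spans:
            amp = rec.gamma_complexity * complexity
            # sustained from trial onset through the go period; short enough
            # to keep clear inter-trial dips, otherwise the effect would be
            # a block-wide DC offset that drift removal cancels
            spans = [(a, amp) for a, _ in trial_spans]
            env = _hann_envelope(n, sfreq, spans, 1.6, t0)
            x += env * _band_noise(rng, n, sfreq, rec.gamma_band)
            envs["gamma_complexity"] = env

        if rec.beta_post:
            onsets = []
            for t in trials:
                if t.onset_signal is None:
                    continue
                success = t.outcome == "signal_success"
                amp = rec.beta_post.get((success, mode), 0.0)
                if amp > 0:
                    onsets.append((t.onset_signal + rec.beta_post_offset, amp))
            if onsets:
                env = _hann_envelope(n, sfreq, onsets, rec.beta_post_duration, t0)
                x += env * _band_noise(rng, n, sfreq, BETA)
                envs["beta_post"] = env

        for burst in rec.extra_bursts:
            locks = {
                "signal": signal_onsets,
                "press": press_onsets,
                "go": [(t.onset_go, 1.0) for t in trials],
                "fixation": [(t.onset_fixation, 1.0) for t in trials],
            }[burst.lock]
            onsets = [(o + burst.offset, burst.amplitude) for o, _ in locks]
            env = _hann_envelope(n, sfreq, onsets, burst.duration, t0)
            x += env * _band_noise(rng, n, sfreq, burst.band)
            envs[f"burst_{burst.lock}_{burst.band[0]:g}"] = env

        data[s] = x
        env_truth.append(envs)

    return SourceBlock(
        data=data,
        sfreq=sfreq,
        t0=t0,
        names=effects.names,
        events=ev,
        envelopes=env_truth,
    )
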