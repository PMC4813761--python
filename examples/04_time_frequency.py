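"""Multitaper RMS time-frequency decomposition of a simulated source.

Simulates a source with a stop-signal-locked theta/alpha burst, runs the
multitaper decomposition (0.4 s windows, 0.05 s steps, piecewise
bandwidth rule), and prints the signal-triggered band amplitude around
the stop/change signal against the pre-signal baseline.
"""

import numpy as np

from countermand import (
    RaceParams,
    SourceEffectConfig,
    SourceRecipe,
    TaskConfig,
    TfConfig,
    simulate_behavior_session,
    simulate_source_signals,
    multitaper_rms,
)
from countermand.beamformer import SourceTimeSeries

SFREQ = 160.0
session = simulate_behavior_session(
    TaskConfig(n_trials_per_block=150, n_blocks=1), RaceParams(), seed=3
)
effects = SourceEffectConfig(
    recipes=(SourceRecipe(name="frontal", theta_alpha_burst=1.2),)
)
block = simulate_source_signals(session, effects, SFREQ, seed=5)

ts = SourceTimeSeries(values=block.data[0], sfreq=SFREQ, t0=block.t0)
tf = multitaper_rms(ts, TfConfig(freqs=(5.0, 7.5, 10.0, 20.0, 40.0, 60.0)))
theta = tf.values[:3].mean(axis=0)

onsets = np.array([t.onset_signal for t in session.trials if t.onset_signal is not None])
lags = np.arange(-8, 13) * 0.05
trig = np.array([np.interp(onsets + l, tf.times, theta).mean() for l in lags])
baseline = trig[lags < -0.2].mean()
print(f"{len(onsets)} stop/change signals; theta/alpha bins 5-10 Hz")
print("lag (s) -> triggered theta/alpha RMS amplitude:")
for l, v in zip(lags[::2], trig[::2]):
    print(f"  {l:+.2f}  {v:.2f}")
print(f"baseline {baseline:.2f}; peak {trig.max():.2f} at "
      f"{lags[np.argmax(trig)]:+.2f} s -> the injected burst appears as a "
      "transient amplitude rise locked to the signal")
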