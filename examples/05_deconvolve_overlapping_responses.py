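"""Disambiguate overlapping induced responses with the convolution GLM.

Two event types follow each other by ~0.3 s (like a go cue and a
stop/change signal), each injecting a known amplitude response.  The
naive event-triggered average of type A is contaminated by type B;
regressing the continuous amplitude on both event trains convolved with
a Fourier basis separates them.
"""

import numpy as np
import pandas as pd

from countermand import (
    TimeFrequencyImage,
    build_design,
    fit_tf_glm,
    fourier_basis,
    reconstruct_induced,
)

STEP = 0.05
rng = np.random.default_rng(4)
basis = fourier_basis(order=6)
times = np.arange(0, 240, STEP)

resp_a = np.exp(-0.5 * ((basis.taus - 0.25) / 0.12) ** 2)
resp_b = 0.8 * np.exp(-0.5 * ((basis.taus - 0.5) / 0.2) ** 2)
on_a = np.arange(3.0, 234.0, 3.0) + rng.uniform(-0.3, 0.3, 77)
on_b = on_a + 0.3 + rng.uniform(-0.1, 0.1, 77)
on_b = on_b[rng.random(77) < 0.8]

y = np.zeros(len(times))
for resp, onsets in ((resp_a, on_a), (resp_b, on_b)):
    for o in onsets:
        s = int(round(o / STEP)) - 10
        lo, hi = max(s, 0), min(s + len(resp), len(times))
        y[lo:hi] += resp[lo - s : hi - s]
y += 0.15 * rng.standard_normal(len(y))

ev = pd.concat(
    [
        pd.DataFrame({"onset": on_a, "event_type": "go"}),
        pd.DataFrame({"onset": on_b, "event_type": "signal"}),
    ]
)
design = build_design(ev, basis, times, event_types=["go", "signal"])
fit = fit_tf_glm(
    TimeFrequencyImage(times=times, freqs=np.array([10.0]), values=y[None, :]),
    design,
    highpass=None,
)
rec_a = reconstruct_induced(fit, "go").values[0]

# naive triggered average for comparison
ta = np.zeros(len(basis.taus))
for o in on_a:
    idx = int(round(o / STEP)) + np.round(basis.taus / STEP).astype(int)
    ta += y[idx]
ta /= len(on_a)

rmse_glm = np.sqrt(np.mean((rec_a - resp_a) ** 2))
rmse_ta = np.sqrt(np.mean((ta - resp_a) ** 2))
print(f"{len(on_a)} 'go' events, {len(on_b)} 'signal' events ~0.3 s later")
print(f"RMSE of the type-A response estimate vs injected truth:")
print(f"  triggered average : {rmse_ta:.3f}  (contaminated by the overlap)")
print(f"  convolution GLM   : {rmse_glm:.3f}")
print("the deconvolution removes the systematic bleed-through of the "
      "second response into the first")
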