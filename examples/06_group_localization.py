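"""Full pipeline: localize injected effects across simulated subjects.

Runs a scaled-down synthetic study (6 subjects, all four task variants):
simulate behavior + sources + sensors, beamform, time-frequency
decompose, deconvolve, then test per source with the sign-flip
maximum-statistic FWE procedure.  The theta/alpha burst is injected at
the two frontal sources and the complexity-scaled gamma only at the
medial-frontal one; the motor source carries neither.
"""

import numpy as np

from countermand import StudyConfig, run_study

cfg = StudyConfig(n_subjects=6, n_trials_per_block=60, n_perm=400)
res = run_study(cfg, seed=11)
freqs = res["freqs"]
gamma = freqs >= 55
theta = freqs <= 12

print("complexity (stimulus x response) contrast, gamma band:")
for name, sm in res["stats"]["complexity"].items():
    sig = (sm.mask_increase | sm.mask_decrease)[gamma].any()
    print(f"  {name:7s} peak |t| {np.abs(sm.t_image[gamma]).max():5.2f} "
          f"threshold {sm.threshold:5.2f} -> {'SIGNIFICANT' if sig else 'n.s.'}")

print("mean stop/change-locked response, theta/alpha band:")
for name, sm in res["stats"]["stop_mean"].items():
    sig = sm.mask_increase[theta].any()
    print(f"  {name:7s} peak t {sm.t_image[theta].max():5.2f} "
          f"threshold {sm.threshold:5.2f} -> {'SIGNIFICANT' if sig else 'n.s.'}")

print("expected: gamma only at preSMA, theta/alpha at rIFG and preSMA, "
      "nothing at M1")
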