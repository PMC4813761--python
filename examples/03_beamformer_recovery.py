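"""Recover three simulated cortical sources with the LCMV beamformer.

Three band-limited sources at different locations are mixed into a
28-channel spherical sensor array with noise; the beamformer is built
from the block covariance with max-power orientations.  Printed are the
correlations between each extracted series and each true source, and the
filter-similarity diagnostic.
"""

import numpy as np

from countermand import (
    build_spherical_leadfield,
    compute_covariance,
    extract_sources,
    filter_similarity,
    lcmv_filter,
    project_to_sensors,
    sensor_array,
)
from countermand.sim.sources import _band_noise

rng = np.random.default_rng(0)
chans = sensor_array(28, radius=0.12, coverage=1.2)
srcs = np.array([[0.05, 0.02, 0.02], [-0.04, 0.04, 0.0], [0.0, -0.05, 0.04]])
lf = build_spherical_leadfield(chans, srcs, center=np.zeros(3))

sfreq = 160.0
bands = [(4, 8), (10, 20), (30, 45)]
X = np.stack([_band_noise(rng, int(60 * sfreq), sfreq, b) for b in bands])
U = []
for s in range(3):
    radial = srcs[s] / np.linalg.norm(srcs[s])
    t = np.cross(radial, [0.0, 0.0, 1.0])
    U.append(t / np.linalg.norm(t))

rec = project_to_sensors(X, np.stack(U), lf, noise_sd=0.05, seed=rng, sfreq=sfreq)
cov = compute_covariance(rec)
filters = [lcmv_filter(lf.source_gain(s), cov, label=f"src{s}") for s in range(3)]
series = extract_sources(rec, filters)

print("correlation |extracted_i x true_j| (diagonal should be ~1):")
for i in range(3):
    row = [abs(np.corrcoef(series[i].values, X[j])[0, 1]) for j in range(3)]
    print("  " + "  ".join(f"{v:.3f}" for v in row))
for f in filters:
    print(f"unit gain w'l for {f.label}: {f.weights @ f.oriented_gain:.12f}")
r2 = filter_similarity(filters)
print(f"max off-diagonal filter r^2: {np.max(r2[~np.eye(3, dtype=bool)]):.3f} "
      "(small values mean the sources are instrumentally separable)")
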