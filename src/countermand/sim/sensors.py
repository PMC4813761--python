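"""Projection of simulated sources to a sensor array.

Mixing is linear and instantaneous (the assumption the beamformer relies
on): data = sum_s (L_s . u_s) x_s(t) + white sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .forward import LeadField
from .sources import SourceBlock

__all__ = ["SensorRecording", "project_to_sensors"]


@dataclass
class SensorRecording:
    """Multichannel recording: channels x samples plus event metadata."""

    data: np.ndarray
    sfreq: float
    channel_names: list[str]
    channel_positions: Optional[np.ndarray] = None
    events: Optional[pd.DataFrame] = None
    t0: float = 0.0
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sfreq


def project_to_sensors(
    sources: SourceBlock | np.ndarray,
    orientations: np.ndarray,
    leadfield: LeadField,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    sfreq: Optional[float] = None,
) -> SensorRecording:
    """Mix source traces through the lead field and add white sensor noise.

    ``orientations`` is one unit 3-vector per source (normalized here for
    safety).  Accepts either a SourceBlock (events and ground truth are
    carried through) or a bare (n_sources, n_samples) array with ``sfreq``.
    """
    if isinstance(sources, SourceBlock):
        X = sources.data
        sfreq = sources.sfreq
        events = sources.events
        t0 = sources.t0
        truth = {"source_data": X, "envelopes": sources.envelopes, "names": sources.names}
    else:
        X = np.atleast_2d(np.asarray(sources, dtype=float))
        if sfreq is None:
            raise ValueError("sfreq is required for bare source arrays")
        events, t0, truth = None, 0.0, {"source_data": X}

    orientations = np.atleast_2d(np.asarray(orientations, dtype=float))
    if orientations.shape != (X.shape[0], 3):
        raise ValueError("need one 3-vector orientation per source")
    if X.shape[0] != leadfield.n_sources:
        raise ValueError(
            f"{X.shape[0]} source traces vs {leadfield.n_sources} lead-field sources"
        )
    norms = np.linalg.norm(orientations, axis=1, keepdims=True)
    orientations = orientations / norms

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_ch = leadfield.n_channels
    data = np.zeros((n_ch, X.shape[1]))
    for s in range(X.shape[0]):
        g = leadfield.source_gain(s) @ orientations[s]  # (n_channels,)
        data += np.outer(g, X[s])
    if noise_sd > 0:
        data += noise_sd * rng.standard_normal(data.shape)

    truth["orientations"] = orientations
    return SensorRecording(
        data=data,
        sfreq=float(sfreq),
        channel_names=[f"CH{i:03d}" for i in range(n_ch)],
        channel_positions=leadfield.channel_positions,
        events=events,
        t0=t0,
        ground_truth=truth,
    )
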