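"""Analytic single-sphere MEG forward model.

Sensors are radial magnetometers on a sphere around the head center; the
field of a current dipole in a homogeneous conducting sphere is given by
the closed-form conducting-sphere solution, in which volume currents
contribute nothing to the radial field component and radially oriented
dipoles are magnetically silent.  Units are arbitrary but internally
consistent (the physical mu0/4pi prefactor is dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LeadField", "build_spherical_leadfield", "sensor_array", "DegenerateGeometryError"]


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class LeadField:
    """Gain of three orthogonal unit dipoles per source at every channel.

    gains has shape (n_sources, n_channels, 3): column j is the sensor
    pattern of a unit dipole along axis j.
    """

    gains: np.ndarray
    channel_positions: np.ndarray
    source_positions: np.ndarray
    center: np.ndarray

    @property
    def n_sources(self) -> int:
        return self.gains.shape[0]

    @property
    def n_channels(self) -> int:
        return self.gains.shape[1]

    def source_gain(self, s: int) -> np.ndarray:
        """(n_channels, 3) gain matrix of source s."""
        return self.gains[s]


def _sarvas_field(r: np.ndarray, r0: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Magnetic field of dipole q at r0 inside a conducting sphere centered
    at the origin, evaluated at sensor positions r (n, 3)."""
    a_vec = r - r0[None, :]
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    ar = np.einsum("ij,ij->i", a_vec, r)
    F = a * (R * a + R**2 - r @ r0)
    gradF = (
        (a**2 / R + ar / a + 2 * a + 2 * R)[:, None] * r
        - (a + 2 * R + ar / a)[:, None] * r0[None, :]
    )
    qxr0 = np.cross(q, r0)
    B = (F[:, None] * qxr0[None, :] - (r @ qxr0)[:, None] * gradF) / (F**2)[:, None]
    return B


def build_spherical_leadfield(
    channel_positions: np.ndarray,
    source_positions: np.ndarray,
    center: np.ndarray | None = None,
) -> LeadField:
    """Lead field for radial magnetometers around a conducting sphere.

    The sphere center defaults to the sensor centroid; sensors measure the
    radial field component.  Sources must lie strictly inside the sensor
    shell and away from the center (a dipole at the center has no
    tangential lever arm and is fully silent).
    """
    chans = np.asarray(channel_positions, dtype=float)
    srcs = np.atleast_2d(np.asarray(source_positions, dtype=float))
    if not (np.isfinite(chans).all() and np.isfinite(srcs).all()):
        raise ValueError("positions must be finite")
    if center is None:
        center = chans.mean(axis=0)
    center = np.asarray(center, dtype=float)
    r = chans - center
    radii = np.linalg.norm(r, axis=1)
    normal = r / radii[:, None]

    gains = np.empty((len(srcs), len(chans), 3))
    for s, pos in enumerate(srcs):
        r0 = pos - center
        if np.linalg.norm(r0) < 1e-9 * radii.mean():
            raise DegenerateGeometryError("source at sphere center is silent")
        if np.linalg.norm(r0) >= radii.min():
            raise DegenerateGeometryError("source outside the sensor shell")
        for j in range(3):
            q = np.zeros(3)
            q[j] = 1.0
            B = _sarvas_field(r, r0, q)
            gains[s, :, j] = np.einsum("ij,ij->i", B, normal)
    return LeadField(
        gains=gains,
        channel_positions=chans,
        source_positions=srcs,
        center=center,
    )


def sensor_array(n_channels: int, radius: float = 0.12, coverage: float = 0.7) -> np.ndarray:
    """Helmet-like sensor positions: a Fibonacci spiral over the upper
    portion of a sphere of the given radius (coverage = fraction of the
    z-axis cap covered, 1.0 = full sphere)."""
    i = np.arange(n_channels)
    golden = (1 + 5**0.5) / 2
    z = 1.0 - coverage * (i + 0.5) / n_channels  # from pole downward
    theta = 2 * np.pi * i / golden
    rho = np.sqrt(1 - z**2)
    pts = np.stack([rho * np.cos(theta), rho * np.sin(theta), z], axis=1)
    return radius * pts
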