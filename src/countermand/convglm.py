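"""Convolution GLM for overlapping induced responses.

Event-locked changes in frequency-specific RMS amplitude are estimated by
regressing the continuous amplitude time course on event trains convolved
with a Fourier basis spanning -0.5 to +1.5 s around each event.  With
isolated events this reduces to triggered averaging; with overlapping
events the joint regression disambiguates the per-event-type responses.
Slow drifts are removed from data and design alike by projecting out a
discrete-cosine subspace below 0.25 Hz, which keeps the regression
symmetric between the two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectral import TimeFrequencyImage

__all__ = [
    "BasisSet",
    "DesignMatrix",
    "GlmResult",
    "InducedResponse",
    "fourier_basis",
    "build_design",
    "highpass_below",
    "fit_tf_glm",
    "reconstruct_induced",
]

PERISTIMULUS_WINDOW = (-0.5, 1.5)
DEFAULT_ORDER = 11
HIGHPASS_CUTOFF = 0.25


@dataclass
class BasisSet:
    """Constant + R sine/cosine pairs on the peristimulus grid.

    The harmonics have period N*step (the grid treated as one full cycle),
    which makes the columns exactly orthogonal on the N-point grid.
    """

    taus: np.ndarray  # peristimulus times of the grid
    matrix: np.ndarray  # (N, 2R+1)
    order: int
    step: float
    window: tuple[float, float]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def fourier_basis(
    window: tuple[float, float] = PERISTIMULUS_WINDOW,
    order: int = DEFAULT_ORDER,
    step: float = 0.05,
) -> BasisSet:
    lo, hi = window
    if order < 1:
        raise ValueError("order must be >= 1")
    n_float = (hi - lo) / step
    if abs(n_float - round(n_float)) > 1e-9:
        raise ValueError("window length must be an integer number of steps")
    N = int(round(n_float)) + 1
    if 2 * order + 1 > N:
        raise ValueError(
            f"order {order} needs {2 * order + 1} columns but the grid has only {N} points"
        )
    taus = lo + step * np.arange(N)
    n = np.arange(N)
    cols = [np.ones(N)]
    for k in range(1, order + 1):
        ang = 2.0 * np.pi * k * n / N
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    return BasisSet(
        taus=taus, matrix=np.stack(cols, axis=1), order=order, step=step, window=(lo, hi)
    )


@dataclass
class DesignMatrix:
    X: np.ndarray  # (n_times, n_columns)
    column_labels: list[tuple[str, int]]  # (regressor name, basis index)
    tf_times: np.ndarray
    basis: BasisSet
    dropped_events: int = 0
    empty_regressors: list[str] = field(default_factory=list)

    def columns_of(self, name: str) -> np.ndarray:
        idx = [i for i, (n, _) in enumerate(self.column_labels) if n == name]
        if not idx:
            raise KeyError(f"no regressor named {name!r}")
        return np.asarray(idx)

    @property
    def regressor_names(self) -> list[str]:
        seen: list[str] = []
        for n, _ in self.column_labels:
            if n not in seen:
                seen.append(n)
        return seen


def build_design(
    events: pd.DataFrame,
    basis: BasisSet,
    tf_times: np.ndarray,
    event_types: Optional[Sequence[str]] = None,
    modulators: Optional[dict[str, str]] = None,
) -> DesignMatrix:
    """Convolve per-event-type impulse trains with the basis.

    ``events`` needs columns onset and event_type (plus any modulator
    columns).  Each event is snapped to the nearest TF sample; its basis,
    shifted to that sample, is added to the event type's column block.
    ``modulators`` maps event_type -> column name: an extra block is added
    whose impulses are weighted by the mean-centered modulator value, so
    the unmodulated block keeps the mean response.
    """
    tf_times = np.asarray(tf_times, dtype=float)
    dt = float(np.median(np.diff(tf_times)))
    if abs(dt - basis.step) > 1e-9:
        raise ValueError("TF time step must match the basis step")
    n_t = len(tf_times)
    if event_types is None:
        event_types = list(pd.unique(events["event_type"]))
    modulators = modulators or {}

    labels: list[tuple[str, int]] = []
    blocks: list[np.ndarray] = []
    offset0 = int(round(basis.window[0] / basis.step))
    dropped = 0
    empty: list[str] = []

    def convolve(onsets: np.ndarray, weights: np.ndarray) -> np.ndarray:
        nonlocal dropped
        block = np.zeros((n_t, basis.n_columns))
        samp = np.round((onsets - tf_times[0]) / dt).astype(int)
        inside = (samp >= 0) & (samp < n_t)
        dropped += int((~inside).sum())
        for s, wgt in zip(samp[inside], weights[inside]):
            a = s + offset0
            b = a + len(basis.taus)
            ba, bb = max(a, 0), min(b, n_t)
            if bb <= ba:
                continue
            block[ba:bb] += wgt * basis.matrix[ba - a : bb - a]
        return block

    for et in event_types:
        sel = events[events["event_type"] == et]
        onsets = sel["onset"].to_numpy(dtype=float)
        block = convolve(onsets, np.ones(len(onsets)))
        if len(onsets) == 0:
            empty.append(et)
        blocks.append(block)
        labels.extend((et, k) for k in range(basis.n_columns))
        if et in modulators:
            col = modulators[et]
            vals = sel[col].to_numpy(dtype=float)
            if not np.isfinite(vals).all():
                raise ValueError(f"modulator {col!r} has non-finite values")
            centered = vals - vals.mean() if len(vals) else vals
            blocks.append(convolve(onsets, centered))
            labels.extend((f"{et}*{col}", k) for k in range(basis.n_columns))

    if dropped:
        warnings.warn(f"dropped {dropped} events outside the TF span", stacklevel=2)
    X = np.concatenate(blocks, axis=1) if blocks else np.zeros((n_t, 0))
    return DesignMatrix(
        X=X,
        column_labels=labels,
        tf_times=tf_times,
        basis=basis,
        dropped_events=dropped,
        empty_regressors=empty,
    )


def _dct_subspace(n: int, dt: float, cutoff: float) -> Optional[np.ndarray]:
    """Orthonormal DCT-II columns with frequency below ``cutoff`` Hz."""
    # DCT-II basis function k has frequency k / (2 n dt)
    k_max = int(np.floor(2.0 * n * dt * cutoff))
    if n * dt < 1.0 / cutoff:
        return None
    ks = np.arange(0, k_max + 1)
    grid = np.arange(n)
    cols = np.cos(np.pi * ks[None, :] * (grid[:, None] + 0.5) / n)
    cols /= np.linalg.norm(cols, axis=0)
    return cols


def highpass_below(arr: np.ndarray, dt: float = 0.05, cutoff: float = HIGHPASS_CUTOFF) -> np.ndarray:
    """Remove components below ``cutoff`` Hz by projecting out a low-order
    discrete-cosine subspace along the first axis.  Blocks shorter than
    one cutoff period are returned unchanged with a warning."""
    arr = np.asarray(arr, dtype=float)
    x = arr[:, None] if arr.ndim == 1 else arr
    D = _dct_subspace(x.shape[0], dt, cutoff)
    if D is None:
        warnings.warn("block shorter than one cutoff period; high-pass skipped", stacklevel=2)
        return arr
    out = x - D @ (D.T @ x)
    return out[:, 0] if arr.ndim == 1 else out


@dataclass
class GlmResult:
    coefficients: np.ndarray  # (n_columns, n_freqs)
    column_labels: list[tuple[str, int]]
    freqs: np.ndarray
    basis: BasisSet
    rank: int
    n_columns: int

    @property
    def rank_deficient(self) -> bool:
        return self.rank < self.n_columns


def fit_tf_glm(
    tf: TimeFrequencyImage,
    design: DesignMatrix,
    highpass: Optional[float] = HIGHPASS_CUTOFF,
) -> GlmResult:
    """Mass-univariate OLS of the TF image on the convolution design.

    Frequencies are fitted independently with a shared design.  When
    ``highpass`` is set, the identical DCT projector is applied to the
    data rows and the design columns first.  A rank-deficient design
    falls back to the minimum-norm (pseudo-inverse) solution with a
    warning.
    """
    Y = tf.values.T  # (n_times, n_freqs)
    if Y.shape[0] != design.X.shape[0]:
        raise ValueError("TF image and design have different numbers of time samples")
    X = design.X
    if highpass is not None:
        dt = design.basis.step
        X = highpass_below(X, dt=dt, cutoff=highpass)
        Y = highpass_below(Y, dt=dt, cutoff=highpass)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn(
            f"design rank {rank} < {X.shape[1]} columns; minimum-norm solution returned",
            stacklevel=2,
        )
    return GlmResult(
        coefficients=beta,
        column_labels=design.column_labels,
        freqs=np.asarray(tf.freqs),
        basis=design.basis,
        rank=int(rank),
        n_columns=X.shape[1],
    )


@dataclass
class InducedResponse:
    """Peristimulus reconstruction for one event type: freqs x tau grid."""

    taus: np.ndarray
    freqs: np.ndarray
    values: np.ndarray  # (n_freqs, n_taus)
    event_type: str
    condition: str = ""


def reconstruct_induced(result: GlmResult, event_type: str) -> InducedResponse:
    """response(tau, f) = sum_k basis_k(tau) * beta[f, (event_type, k)]."""
    idx = [i for i, (n, _) in enumerate(result.column_labels) if n == event_type]
    if not idx:
        raise KeyError(f"event type {event_type!r} not in the design")
    beta = result.coefficients[idx]  # (2R+1, n_freqs)
    values = (result.basis.matrix @ beta).T
    return InducedResponse(
        taus=result.basis.taus,
        freqs=result.freqs,
        values=values,
        event_type=event_type,
    )
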