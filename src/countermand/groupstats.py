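"""Group-level statistics on induced time-frequency responses.

Condition contrasts are formed per subject as weighted sums of induced
responses; familywise error over the time-frequency image is controlled
with a sign-flip maximum-statistic permutation test on the one-sample t
image, which is exact under per-subject sign symmetry of the null and
makes no smoothness assumptions.  Band summaries (theta/alpha 2-12 Hz,
beta 15-25 Hz) and the peak rate of rise of the theta/alpha course feed
the SSRT-by-source analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .behavior import StatResult
from .convglm import InducedResponse

__all__ = [
    "StatMap",
    "BandCourse",
    "tf_contrast",
    "permutation_fwe",
    "band_course",
    "peak_rate_of_rise",
    "rate_by_ssrt_anova",
    "THETA_ALPHA_BAND",
    "BETA_BAND",
]

THETA_ALPHA_BAND = (2.0, 12.0)
BETA_BAND = (15.0, 25.0)

COMPLEXITY_WEIGHTS = {
    ("bar", "stop"): 1.0,
    ("arrow", "stop"): -1.0,
    ("bar", "change"): -1.0,
    ("arrow", "change"): 1.0,
}


@dataclass
class StatMap:
    t_image: np.ndarray
    threshold: float
    mask_increase: np.ndarray
    mask_decrease: np.ndarray
    alpha: float
    n_permutations: int
    taus: Optional[np.ndarray] = None
    freqs: Optional[np.ndarray] = None

    @property
    def any_significant(self) -> bool:
        return bool(self.mask_increase.any() or self.mask_decrease.any())


@dataclass
class BandCourse:
    band: tuple[float, float]
    times: np.ndarray
    values: np.ndarray
    source: str = ""
    condition: str = ""


def tf_contrast(
    responses: Mapping, weights: Mapping, normalize: bool = False
) -> np.ndarray:
    """Weighted sum of one subject's condition images.

    ``responses`` maps condition key -> InducedResponse (or array);
    ``weights`` maps the same keys to contrast weights.  Weights that sum
    to zero cancel any condition-independent component exactly.
    """
    missing = [k for k in weights if k not in responses]
    if missing:
        raise ValueError(f"missing conditions for contrast: {missing}")
    acc = None
    wsum = 0.0
    for k, w in weights.items():
        r = responses[k]
        img = r.values if isinstance(r, InducedResponse) else np.asarray(r, dtype=float)
        acc = w * img if acc is None else acc + w * img
        wsum += abs(w)
    if normalize and wsum > 0:
        acc = acc / wsum
    return acc


def one_sample_t(images: np.ndarray) -> np.ndarray:
    """t image across the subject axis (axis 0)."""
    n = images.shape[0]
    mean = images.mean(axis=0)
    sd = images.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def permutation_fwe(
    contrast_images: Sequence[np.ndarray] | np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
    taus: Optional[np.ndarray] = None,
    freqs: Optional[np.ndarray] = None,
) -> StatMap:
    """Sign-flip max-|t| permutation threshold over the whole image.

    The observed one-sample t image is compared against the (1 - alpha)
    quantile of the maximum absolute t over ``n_perm`` random per-subject
    sign flips; two-tailed masks of significant increases and decreases
    are returned.
    """
    X = np.stack([np.asarray(im, dtype=float) for im in contrast_images])
    n_sub = X.shape[0]
    if n_sub < 5:
        raise ValueError("need at least 5 subjects for a stable permutation null")
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable tail estimate")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")

    flat = X.reshape(n_sub, -1)
    t_obs = one_sample_t(flat)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n_sub))
    # under sign flipping the per-subject squares are unchanged, so the
    # flipped t image only needs the flipped means
    sq = np.sum(flat**2, axis=0)
    means = (signs @ flat) / n_sub
    var = (sq[None, :] - n_sub * means**2) / (n_sub - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = means / np.sqrt(var / n_sub)
    t_perm = np.where(np.isfinite(t_perm), t_perm, 0.0)
    max_t = np.max(np.abs(t_perm), axis=1)
    if alpha >= 1.0:
        threshold = 0.0
    else:
        threshold = float(np.quantile(max_t, 1.0 - alpha))

    t_img = t_obs.reshape(X.shape[1:])
    return StatMap(
        t_image=t_img,
        threshold=threshold,
        mask_increase=t_img >= threshold,
        mask_decrease=t_img <= -threshold,
        alpha=alpha,
        n_permutations=n_perm,
        taus=taus,
        freqs=freqs,
    )


def band_course(resp: InducedResponse, band: tuple[float, float]) -> BandCourse:
    """Mean over the band's frequency rows at each peristimulus time."""
    freqs = np.asarray(resp.freqs, dtype=float)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError(f"band {band} contains none of the analyzed frequencies")
    return BandCourse(
        band=band,
        times=np.asarray(resp.taus),
        values=resp.values[sel].mean(axis=0),
        source=getattr(resp, "condition", ""),
    )


def peak_rate_of_rise(
    course: BandCourse | Sequence[BandCourse],
    window: tuple[float, float] = (-0.2, 0.5),
) -> float:
    """Maximum centered first difference (amplitude/s) within ``window``.

    When several courses are given (e.g., successful and unsuccessful
    trials), they are averaged first.
    """
    if not isinstance(course, BandCourse):
        courses = list(course)
        values = np.mean([c.values for c in courses], axis=0)
        times = courses[0].times
    else:
        values, times = course.values, course.times
    if window[0] < times[0] or window[1] > times[-1]:
        raise ValueError(f"window {window} outside the course span")
    dt = float(np.median(np.diff(times)))
    deriv = np.gradient(values, dt)
    sel = (times >= window[0]) & (times <= window[1])
    return float(np.max(deriv[sel]))


def median_split(ssrts: Sequence[float]) -> np.ndarray:
    """Short/long grouping relative to the across-session mean SSRT."""
    s = np.asarray(ssrts, dtype=float)
    return np.where(s <= s.mean(), "short", "long")


def rate_by_ssrt_anova(
    rates: pd.DataFrame,
    n_perm: int = 2000,
    seed: int | np.random.Generator = 0,
    posthoc_alpha: float = 0.05,
) -> dict[str, StatResult]:
    """Source x SSRT-group permutation ANOVA on peak rates of rise.

    ``rates`` needs columns session, source, rate, ssrt_group ('short' or
    'long'; one label per session).  Group labels are permuted across
    sessions (the exchangeable unit); F statistics from the two-factor
    cell-mean decomposition are referenced to their permutation nulls.
    Post hoc per-source group contrasts run only when the interaction is
    significant at ``posthoc_alpha``.
    """
    needed = {"session", "source", "rate", "ssrt_group"}
    if not needed.issubset(rates.columns):
        raise ValueError(f"rates needs columns {sorted(needed)}")
    sources = sorted(rates["source"].unique())
    sessions = sorted(rates["session"].unique())
    groups = rates.groupby("session")["ssrt_group"].first()
    if len(set(groups)) < 2:
        raise ValueError("need both short and long SSRT groups")

    wide = rates.pivot_table(index="session", columns="source", values="rate").loc[sessions]
    Y = wide.to_numpy(dtype=float)  # (n_sessions, n_sources)
    g = (groups.loc[sessions] == "long").to_numpy()

    def f_stats(labels: np.ndarray) -> tuple[float, float, float]:
        a, b = Y[labels], Y[~labels]
        if len(a) == 0 or len(b) == 0:
            return 0.0, 0.0, 0.0
        grand = Y.mean()
        ss_group = Y.shape[1] * (
            len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
        )
        col_means = Y.mean(axis=0)
        ss_source = len(Y) * np.sum((col_means - grand) ** 2)
        cell_a, cell_b = a.mean(axis=0), b.mean(axis=0)
        pred_a = a.mean() + col_means - grand
        pred_b = b.mean() + col_means - grand
        ss_inter = len(a) * np.sum((cell_a - pred_a) ** 2) + len(b) * np.sum(
            (cell_b - pred_b) ** 2
        )
        resid = np.concatenate([a - cell_a, b - cell_b])
        ss_err = float(np.sum(resid**2))
        df_err = max((len(Y) - 2) * Y.shape[1], 1)
        ms_err = ss_err / df_err if ss_err > 0 else 1e-12
        k = Y.shape[1]
        return (
            ss_group / 1.0 / ms_err,
            ss_source / (k - 1) / ms_err if k > 1 else 0.0,
            ss_inter / (k - 1) / ms_err if k > 1 else 0.0,
        )

    F_obs = f_stats(g)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = np.zeros(3)
    for _ in range(n_perm):
        perm = rng.permutation(g)
        F_p = f_stats(perm)
        counts += np.array([F_p[i] >= F_obs[i] - 1e-15 for i in range(3)], dtype=float)
    pvals = (counts + 1) / (n_perm + 1)

    out = {
        "ssrt_group": StatResult("SSRT group", float(Y[g].mean() - Y[~g].mean()), F_obs[0], pvals[0], n_perm),
        "source": StatResult("source", float(np.ptp(Y.mean(axis=0))), F_obs[1], pvals[1], n_perm),
        "interaction": StatResult("source x SSRT group", float("nan"), F_obs[2], pvals[2], n_perm),
    }

    if pvals[2] < posthoc_alpha:
        for j, src in enumerate(sources):
            y = Y[:, j]
            diff = float(y[g].mean() - y[~g].mean())
            null = np.empty(n_perm)
            for i in range(n_perm):
                perm = rng.permutation(g)
                null[i] = y[perm].mean() - y[~perm].mean()
            p = float((np.sum(np.abs(null) >= abs(diff) - 1e-15) + 1) / (n_perm + 1))
            out[f"posthoc_{src}"] = StatResult(f"group effect at {src}", diff, diff, p, n_perm)
    return out
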