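"""Behavioral analysis of stop/change-signal sessions.

Covers trial classification, the three session-screening rules (race-model
SOA ordering, fail fraction >= 0.28, inhibition-function deviance <= 7.5),
three SSRT estimators (average-difference, integration, and the Bayesian
inhibition-function midpoint with RT-drift correction), drift-corrected
post-signal slowing, and the contextual-complexity interaction contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import LSQUnivariateSpline

from .sim.race import SessionBehavior, TrialRecord

__all__ = [
    "ClassifiedTrials",
    "ScreeningReport",
    "DriftModel",
    "InhibitionFit",
    "SsrtEstimates",
    "StatResult",
    "classify_trials",
    "screen_session",
    "screen_values",
    "median_go_rt",
    "ssrt_average_difference",
    "ssrt_integration",
    "estimate_rt_drift",
    "fit_inhibition_function",
    "fit_psychometric",
    "estimate_ssrt",
    "corrected_post_signal_rt",
    "complexity_contrast",
    "session_medians",
]

FAIL_FRACTION_THRESHOLD = 0.28
DEVIANCE_THRESHOLD = 7.5


class InsufficientDataError(ValueError):
    """Raised when a session does not contain enough trials for an estimate."""


class DegeneratePerformanceError(ValueError):
    """Raised when the stopping performance is 0% or 100% (no information)."""


def _classify_one(t: TrialRecord, response_mode: str) -> str:
    """Trial class from the recorded presses (never from the simulator's
    outcome field): wrong-direction presses, double presses, and omitted
    go responses are unclassified errors."""
    press = t.press_direction
    if not t.is_signal_trial:
        return "go_only" if press == t.go_direction else "unclassified"
    if response_mode == "stop":
        if press is None:
            return "signal_success"
        if press == t.go_direction:
            return "signal_fail"
        return "unclassified"
    # change mode: the remapped (opposite) press is the success
    if press == t.go_direction:
        return "signal_fail"
    if press is not None and len(press) == 1:
        return "signal_success"
    return "unclassified"


@dataclass
class ClassifiedTrials:
    """Per-trial classes for one session plus the class counts and fractions."""

    session: SessionBehavior
    labels: list[str]
    counts: dict[str, int]
    presented_count: int
    change_fraction: Optional[float]
    fail_fraction: Optional[float]

    @property
    def classified_count(self) -> int:
        return self.presented_count - self.counts["unclassified"]

    def trials_of(self, label: str) -> list[TrialRecord]:
        return [t for t, c in zip(self.session.trials, self.labels) if c == label]

    def go_rts(self) -> np.ndarray:
        return np.array([t.rt for t in self.trials_of("go_only")], dtype=float)

    def go_indices(self) -> np.ndarray:
        return np.array([t.index for t in self.trials_of("go_only")], dtype=int)

    def signal_soas(self) -> np.ndarray:
        """SOAs of every presented signal trial (classified or not)."""
        return np.array(
            [t.soa for t in self.session.trials if t.is_signal_trial], dtype=float
        )

    def signal_table(self) -> pd.DataFrame:
        """Classified signal trials: index, soa, success flag."""
        rows = [
            (t.index, t.soa, lab == "signal_success")
            for t, lab in zip(self.session.trials, self.labels)
            if lab in ("signal_success", "signal_fail")
        ]
        return pd.DataFrame(rows, columns=["index", "soa", "success"])


def classify_trials(session: SessionBehavior) -> ClassifiedTrials:
    if len(session.trials) == 0:
        raise InsufficientDataError("empty session")
    mode = session.config.response_mode
    labels = [_classify_one(t, mode) for t in session.trials]
    counts = {
        k: labels.count(k)
        for k in ("go_only", "signal_success", "signal_fail", "unclassified")
    }
    presented = len(labels)
    classified = presented - counts["unclassified"]
    n_signal = sum(t.is_signal_trial for t in session.trials)
    n_signal_classified = counts["signal_success"] + counts["signal_fail"]
    change_fraction = n_signal_classified / classified if classified else None
    fail_fraction = counts["signal_fail"] / n_signal if n_signal else None
    return ClassifiedTrials(
        session=session,
        labels=labels,
        counts=counts,
        presented_count=presented,
        change_fraction=change_fraction,
        fail_fraction=fail_fraction,
    )


def session_medians(ct: ClassifiedTrials, trim: int = 15) -> dict[str, Optional[float]]:
    """Median RT / SOA summaries used by screening and the Table-2 roster."""

    def med(vals: Sequence[float]) -> Optional[float]:
        return float(np.median(vals)) if len(vals) else None

    succ = ct.trials_of("signal_success")
    fail = ct.trials_of("signal_fail")
    try:
        go_rt = median_go_rt(ct, trim=trim)
    except InsufficientDataError:
        go_rt = med([t.rt for t in ct.trials_of("go_only")])
    return {
        "go_rt": go_rt,
        "fail_rt": med([t.rt for t in fail]),
        "success_rt": med([t.rt for t in succ if t.rt is not None]),
        "fail_soa": med([t.soa for t in fail]),
        "success_soa": med([t.soa for t in succ]),
    }


@dataclass
class ScreeningReport:
    """Outcome of the three exclusion rules.

    The deviance rule is only evaluated when both earlier rules pass
    (sessions rejected on behavioral grounds never get a psychometric fit).
    """

    rule_soa_ordering: bool
    rule_fail_fraction: bool
    rule_deviance: Optional[bool]  # None = not evaluated
    retained: bool


def screen_values(
    fail_fraction: Optional[float],
    success_soa: Optional[float],
    fail_soa: Optional[float],
    deviance: Optional[float] = None,
) -> ScreeningReport:
    """Apply the three session-exclusion rules to summary values.

    1. race-model ordering: median success SOA must not exceed median fail SOA;
    2. fail fraction must be >= 0.28;
    3. inhibition-function deviance must be <= 7.5 (evaluated only if 1-2 pass).

    Missing values (no trials in a class) conservatively fail rule 1.
    """
    rule_soa = (
        success_soa is not None
        and fail_soa is not None
        and not (success_soa > fail_soa)
    )
    rule_ff = fail_fraction is not None and fail_fraction >= FAIL_FRACTION_THRESHOLD
    rule_dev: Optional[bool] = None
    if rule_soa and rule_ff and deviance is not None and np.isfinite(deviance):
        rule_dev = not (deviance > DEVIANCE_THRESHOLD)
    retained = rule_soa and rule_ff and rule_dev is not False
    return ScreeningReport(
        rule_soa_ordering=rule_soa,
        rule_fail_fraction=rule_ff,
        rule_deviance=rule_dev,
        retained=retained,
    )


def screen_session(
    ct: ClassifiedTrials,
    medians: Optional[dict] = None,
    fit: Optional["InhibitionFit"] = None,
    deviance: Optional[float] = None,
) -> ScreeningReport:
    """Session-level wrapper around :func:`screen_values`."""
    medians = medians if medians is not None else session_medians(ct)
    if deviance is None and fit is not None:
        deviance = fit.deviance
    return screen_values(
        fail_fraction=ct.fail_fraction,
        success_soa=medians.get("success_soa"),
        fail_soa=medians.get("fail_soa"),
        deviance=deviance,
    )


def median_go_rt(ct: ClassifiedTrials, trim: int = 15) -> float:
    """Median go-only RT after dropping the first and last ``trim`` trials
    of the session (a partial guard against RT drift)."""
    n = ct.presented_count
    lo, hi = trim, n - trim
    rts = [
        t.rt
        for t, lab in zip(ct.session.trials, ct.labels)
        if lab == "go_only" and lo <= t.index < hi
    ]
    if len(rts) < 5:
        raise InsufficientDataError(
            f"only {len(rts)} go trials remain after trimming {trim} from each end"
        )
    return float(np.median(rts))


def ssrt_average_difference(ct: ClassifiedTrials) -> float:
    """Average-difference (mean) method: mean go-only RT minus the mean SOA
    over all presented signal trials."""
    rts = ct.go_rts()
    soas = ct.signal_soas()
    if len(rts) == 0 or len(soas) == 0:
        raise InsufficientDataError("need at least one go trial and one signal trial")
    return float(rts.mean() - soas.mean())


def ssrt_integration(ct: ClassifiedTrials) -> float:
    """Integration method: the p-th go-RT quantile minus the mean SOA, where
    p is the overall probability of responding on a signal trial (the fail
    fraction).  Quantile convention: sorted go RT at 1-based index
    ceil(p * n)."""
    rts = np.sort(ct.go_rts())
    soas = ct.signal_soas()
    if len(rts) == 0 or len(soas) == 0:
        raise InsufficientDataError("need at least one go trial and one signal trial")
    p = ct.fail_fraction
    if p is None or p <= 0.0 or p >= 1.0:
        raise DegeneratePerformanceError(
            f"fail fraction {p} carries no quantile information"
        )
    q = rts[int(math.ceil(p * len(rts))) - 1]
    return float(q - soas.mean())


@dataclass
class SsrtEstimates:
    ssrt_avgdiff: float
    ssrt_integration: float
    ssrt_mcmc: Optional[float] = None

    @property
    def ssrt_av(self) -> float:
        return 0.5 * (self.ssrt_avgdiff + self.ssrt_integration)


def estimate_ssrt(ct: ClassifiedTrials) -> SsrtEstimates:
    """The two traditional estimators (their mean is SSRTav)."""
    return SsrtEstimates(
        ssrt_avgdiff=ssrt_average_difference(ct),
        ssrt_integration=ssrt_integration(ct),
    )


# --------------------------------------------------------------------------
# RT drift
# --------------------------------------------------------------------------

@dataclass
class DriftModel:
    """Running central tendency of the go RT as a function of trial index.

    The smooth component is a low-order cubic regression spline with
    interior knots every ~75 go trials (linear fit when fewer than
    ``linear_fallback`` points); the small knot budget keeps the curve
    from tracking the heavy right tail of ex-Gaussian RT noise, which a
    GCV-tuned smoothing spline does badly here.  The prediction adds the
    median of the fit residuals so that the curve tracks the running
    *median* go RT: session summaries are medians, and with a constant
    stop duration the inhibition-function midpoint on median-corrected
    SOA equals the stop duration exactly.
    """

    _predict_mean: object
    median_offset: float
    residual_scale: float
    kind: str  # "spline" or "linear"
    index_range: tuple[int, int]

    def predict(self, indices) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self._predict_mean(idx), dtype=float) + self.median_offset

    def average_slope(self) -> float:
        lo, hi = self.index_range
        if hi == lo:
            return 0.0
        p = self.predict([lo, hi])
        return float((p[1] - p[0]) / (hi - lo))


def estimate_rt_drift(ct: ClassifiedTrials, linear_fallback: int = 30) -> DriftModel:
    idx = ct.go_indices().astype(float)
    rts = ct.go_rts()
    if len(idx) < 10:
        raise InsufficientDataError("need at least 10 go trials to estimate drift")
    order = np.argsort(idx)
    idx, rts = idx[order], rts[order]
    coef = np.polyfit(idx, rts, 1)

    def predict_linear(x, _c=coef):
        return np.polyval(_c, x)

    predict, kind = predict_linear, "linear"
    if len(idx) >= linear_fallback:
        # cubic regression spline with a deliberately small knot budget,
        # kept only if BIC prefers it over the linear fit
        n_interior = max(len(idx) // 75 - 1, 0)
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        knots = np.quantile(idx, qs) if n_interior else np.array([])
        spl = LSQUnivariateSpline(idx, rts, t=knots, k=3)

        def predict_spline(x, _spl=spl, lo=idx[0], hi=idx[-1]):
            return _spl(np.clip(x, lo, hi))

        n = len(idx)
        k_spline = 4 + len(knots)
        bic_lin = n * np.log(np.mean((rts - predict_linear(idx)) ** 2)) + 2 * np.log(n)
        bic_spl = n * np.log(np.mean((rts - predict_spline(idx)) ** 2)) + k_spline * np.log(n)
        if bic_spl < bic_lin:
            predict, kind = predict_spline, "spline"
    resid = rts - predict(idx)
    full_range = (int(ct.session.trials[0].index), int(ct.session.trials[-1].index))
    return DriftModel(
        _predict_mean=predict,
        median_offset=float(np.median(resid)),
        residual_scale=float(np.std(resid)),
        kind=kind,
        index_range=full_range,
    )


# --------------------------------------------------------------------------
# Bayesian inhibition function
# --------------------------------------------------------------------------

@dataclass
class InhibitionFit:
    """Posterior summary of the psychometric (inhibition) function.

    The predictor is z = predicted go RT - SOA, so the midpoint ``alpha``
    is the SSRT estimate.  ``deviance`` is the binomial goodness-of-fit
    statistic 2*(LL_saturated - LL_model) over decile bins of z.
    """

    alpha: float
    beta: float
    lapse: float
    samples: dict[str, np.ndarray]
    deviance: float
    prior_center: float
    rhat: float
    converged: bool
    z: np.ndarray = field(repr=False, default=None)
    success: np.ndarray = field(repr=False, default=None)

    def predict(self, z) -> np.ndarray:
        return _psychometric(np.asarray(z, float), self.alpha, self.beta, self.lapse)


def _psychometric(z, alpha, beta, lam):
    return lam / 2.0 + (1.0 - lam) / (1.0 + np.exp(-beta * (z - alpha)))


_BETA_BOUNDS = (1.0, 500.0)
_LAPSE_MAX = 0.1
_ALPHA_PRIOR_SD = 0.05


def _log_posterior(alpha, log_beta, lam, z, y, prior_center):
    """Vectorized over chains: alpha/log_beta/lam are arrays of shape (C,)."""
    lp = np.full(np.shape(alpha), -np.inf)
    ok = (
        (log_beta >= np.log(_BETA_BOUNDS[0]))
        & (log_beta <= np.log(_BETA_BOUNDS[1]))
        & (lam >= 0.0)
        & (lam <= _LAPSE_MAX)
    )
    if not np.any(ok):
        return lp
    a, lb, l0 = alpha[ok], log_beta[ok], lam[ok]
    p = _psychometric(z[None, :], a[:, None], np.exp(lb)[:, None], l0[:, None])
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    loglik = np.where(y[None, :], np.log(p), np.log1p(-p)).sum(axis=1)
    log_prior = (
        -0.5 * ((a - prior_center) / _ALPHA_PRIOR_SD) ** 2  # alpha ~ Normal
        + 18.0 * np.log1p(-l0 / 1.0)  # lambda ~ Beta(1, 19), truncated
    )  # log-beta flat on its bounds (log-uniform beta)
    lp[ok] = loglik + log_prior
    return lp


def fit_inhibition_function(
    ct: ClassifiedTrials,
    drift: Optional[DriftModel] = None,
    prior_center: Optional[float] = None,
    n_chains: int = 4,
    n_iter: int = 5000,
    proposal_scales: tuple[float, float, float] = (0.01, 0.12, 0.012),
    seed: int | np.random.Generator = 0,
) -> InhibitionFit:
    """Fit P(success | z) with random-walk Metropolis.

    z is the RT-drift-corrected SOA (predicted go RT minus SOA).  The
    sampler runs ``n_chains`` chains of ``n_iter`` iterations on
    (alpha, log beta, lambda); the first half of each chain is discarded.
    Convergence is summarized by split-R-hat on alpha; a value above 1.1
    flags the fit (``converged=False``) without raising.
    """
    tab = ct.signal_table()
    if len(tab) < 20:
        raise InsufficientDataError("need at least 20 classified signal trials")
    if drift is None:
        drift = estimate_rt_drift(ct)
    if prior_center is None:
        prior_center = estimate_ssrt(ct).ssrt_av
    z = drift.predict(tab["index"].to_numpy()) - tab["soa"].to_numpy(dtype=float)
    y = tab["success"].to_numpy(dtype=bool)
    return fit_psychometric(
        z,
        y,
        prior_center=float(prior_center),
        n_chains=n_chains,
        n_iter=n_iter,
        proposal_scales=proposal_scales,
        seed=seed,
    )


def fit_psychometric(
    z: np.ndarray,
    y: np.ndarray,
    prior_center: float,
    n_chains: int = 4,
    n_iter: int = 5000,
    proposal_scales: tuple[float, float, float] = (0.01, 0.12, 0.012),
    seed: int | np.random.Generator = 0,
) -> InhibitionFit:
    """Sampler core: fit the lapse-logistic to (z, success) pairs directly."""
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=bool)
    if len(np.unique(np.round(z, 6))) < 3:
        raise InsufficientDataError("need at least 3 distinct corrected-SOA values")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    C = n_chains
    alpha = prior_center + rng.normal(0, _ALPHA_PRIOR_SD / 2, C)
    log_beta = np.log(rng.uniform(10.0, 60.0, C))
    lam = rng.uniform(0.0, 0.05, C)
    lp = _log_posterior(alpha, log_beta, lam, z, y, prior_center)
    sa, sb, sl = proposal_scales

    keep = n_iter // 2
    trace = {k: np.empty((C, keep)) for k in ("alpha", "beta", "lapse")}
    for it in range(n_iter):
        prop_a = alpha + rng.normal(0, sa, C)
        prop_b = log_beta + rng.normal(0, sb, C)
        prop_l = lam + rng.normal(0, sl, C)
        lp_prop = _log_posterior(prop_a, prop_b, prop_l, z, y, prior_center)
        accept = np.log(rng.random(C)) < (lp_prop - lp)
        alpha = np.where(accept, prop_a, alpha)
        log_beta = np.where(accept, prop_b, log_beta)
        lam = np.where(accept, prop_l, lam)
        lp = np.where(accept, lp_prop, lp)
        if it >= n_iter - keep:
            j = it - (n_iter - keep)
            trace["alpha"][:, j] = alpha
            trace["beta"][:, j] = np.exp(log_beta)
            trace["lapse"][:, j] = lam

    rhat = _split_rhat(trace["alpha"])
    a_hat = float(trace["alpha"].mean())
    b_hat = float(trace["beta"].mean())
    l_hat = float(trace["lapse"].mean())
    dev = deviance_statistic(z, y, a_hat, b_hat, l_hat)
    return InhibitionFit(
        alpha=a_hat,
        beta=b_hat,
        lapse=l_hat,
        samples={k: v.reshape(-1) for k, v in trace.items()},
        deviance=dev,
        prior_center=float(prior_center),
        rhat=rhat,
        converged=bool(rhat <= 1.1),
        z=z,
        success=y,
    )


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat; chains is (n_chains, n_draws)."""
    C, N = chains.shape
    half = N // 2
    splits = np.concatenate([chains[:, :half], chains[:, half : 2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    W = splits.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def deviance_statistic(z, y, alpha, beta, lam, n_bins: Optional[int] = None, min_per_bin: int = 5):
    """Binned binomial deviance 2*(LL_saturated - LL_model).

    Trials are binned into quantiles of z; bins with fewer than
    ``min_per_bin`` trials are merged into their neighbor.  Invariant
    under bin relabeling, zero when the binned model matches the binned
    data.  The default bin count scales with the trial count (~12 trials
    per bin, between 4 and 10 bins) so that a correctly specified fit has
    an expected deviance of a few, matching the scale on which the
    exclusion threshold of 7.5 operates; with a fixed decile binning a
    perfect model would already exceed that threshold in roughly a third
    of ~80-trial sessions.
    """
    z = np.asarray(z, float)
    y = np.asarray(y, bool)
    if n_bins is None:
        n_bins = int(min(10, max(4, len(z) // 12)))
    edges = np.quantile(z, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        bins = [np.ones(len(z), bool)]
    else:
        which = np.clip(np.searchsorted(edges, z, side="right") - 1, 0, len(edges) - 2)
        bins = [which == b for b in range(len(edges) - 1)]
        bins = [b for b in bins if b.sum() > 0]
        # merge sparse bins forward
        merged, carry = [], np.zeros(len(z), bool)
        for b in bins:
            cur = b | carry
            if cur.sum() < min_per_bin:
                carry = cur
            else:
                merged.append(cur)
                carry = np.zeros(len(z), bool)
        if carry.any():
            if merged:
                merged[-1] = merged[-1] | carry
            else:
                merged = [carry]
        bins = merged

    dev = 0.0
    for b in bins:
        n = int(b.sum())
        k = int(y[b].sum())
        p_mod = float(np.clip(_psychometric(z[b], alpha, beta, lam).mean(), 1e-12, 1 - 1e-12))
        ll_mod = k * math.log(p_mod) + (n - k) * math.log(1 - p_mod)
        p_sat = k / n
        ll_sat = 0.0
        if 0 < k:
            ll_sat += k * math.log(p_sat)
        if k < n:
            ll_sat += (n - k) * math.log(1 - p_sat)
        dev += 2.0 * (ll_sat - ll_mod)
    return float(max(dev, 0.0))


# --------------------------------------------------------------------------
# Post-signal slowing
# --------------------------------------------------------------------------

def corrected_post_signal_rt(ct: ClassifiedTrials) -> pd.DataFrame:
    """Drift-corrected post-signal slowing rows.

    For every go-only trial preceded by one or more signal trials of a
    single uniform outcome (all successes or all failures), emit
    current go RT minus the most recent preceding go-only RT.  Runs with
    mixed or unclassified signal outcomes contribute nothing.
    """
    mode = ct.session.config.response_mode
    rows = []
    last_go_rt: Optional[float] = None
    run_outcomes: list[str] = []
    for t, lab in zip(ct.session.trials, ct.labels):
        if lab == "go_only":
            if run_outcomes and last_go_rt is not None:
                kinds = set(run_outcomes)
                if kinds == {"signal_success"}:
                    rows.append(("success", mode, t.rt - last_go_rt))
                elif kinds == {"signal_fail"}:
                    rows.append(("fail", mode, t.rt - last_go_rt))
            last_go_rt = t.rt
            run_outcomes = []
        elif lab in ("signal_success", "signal_fail"):
            run_outcomes.append(lab)
        else:  # unclassified poisons the current run
            run_outcomes.append("unclassified")
    return pd.DataFrame(rows, columns=["previous_outcome", "response_mode", "corrected_rt"])


# --------------------------------------------------------------------------
# Contextual-complexity contrast
# --------------------------------------------------------------------------

@dataclass
class StatResult:
    effect: str
    estimate: float
    statistic: float
    p_value: float
    n_permutations: int = 0


def interaction_contrast(cells: dict[tuple[str, str], float]) -> float:
    """(bar,stop) - (arrow,stop) - (bar,change) + (arrow,change).

    With complexity reversing between stop and change modes, this isolates
    the contextual-complexity effect on go RT: the contrast equals minus
    twice the per-cell complexity effect.
    """
    return (
        cells[("bar", "stop")]
        - cells[("arrow", "stop")]
        - cells[("bar", "change")]
        + cells[("arrow", "change")]
    )


def complexity_contrast(
    session_summaries: pd.DataFrame,
    value: str = "go_rt",
    n_permutations: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> StatResult:
    """Stimulus x response interaction on per-session go-RT medians.

    ``session_summaries`` must contain columns subject, stimulus
    ('bar'/'arrow'), response ('stop'/'change') and the value column, one
    row per subject x cell.  Inference is by within-subject permutation of
    the four cell labels (the interaction null), two-tailed on the mean
    subject-level contrast.
    """
    df = session_summaries
    needed = {"subject", "stimulus", "response", value}
    if not needed.issubset(df.columns):
        raise ValueError(f"summaries need columns {sorted(needed)}")
    subjects = sorted(df["subject"].unique())
    cells_by_subject = []
    for s in subjects:
        sub = df[df["subject"] == s]
        cell = {}
        for _, r in sub.iterrows():
            cell[(r["stimulus"], r["response"])] = float(r[value])
        if len(cell) < 4:
            raise InsufficientDataError(f"subject {s} is missing design cells")
        cells_by_subject.append(
            np.array(
                [
                    cell[("bar", "stop")],
                    cell[("arrow", "stop")],
                    cell[("bar", "change")],
                    cell[("arrow", "change")],
                ]
            )
        )
    X = np.stack(cells_by_subject)  # (n_subjects, 4)
    w = np.array([1.0, -1.0, -1.0, 1.0])
    per_subject = X @ w
    observed = float(per_subject.mean())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_sub = len(subjects)
    null = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = np.array([rng.permutation(4) for _ in range(n_sub)])
        null[i] = (np.take_along_axis(X, perm, axis=1) @ w).mean()
    p = float((np.sum(np.abs(null) >= abs(observed) - 1e-15) + 1) / (n_permutations + 1))
    se = per_subject.std(ddof=1) / math.sqrt(n_sub) if n_sub > 1 else np.nan
    tstat = observed / se if se and se > 0 else np.nan
    return StatResult(
        effect="stimulus x response (contextual complexity)",
        estimate=observed,
        statistic=float(tstat),
        p_value=p,
        n_permutations=n_permutations,
    )
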