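"""End-to-end orchestration: simulate, beamform, decompose, deconvolve,
and test, with deterministic seeding throughout.

A *study* is a set of simulated subjects, each performing the four task
variants (stop/change x bar/arrow).  Per subject and variant the driver
simulates behavior and source activity, projects it to sensors, rebuilds
the sources with the LCMV beamformer, computes multitaper RMS images, and
deconvolves event-locked induced responses with the convolution GLM.
Group statistics then look for the injected effects: the stop-locked
theta/alpha burst and the complexity-scaled gamma.

The module also carries the published per-session behavioral summary
table as a packaged fixture (`load_table2`) so that the screening rules
and the summary statistics can be reproduced from print.
"""

from __future__ import annotations

import importlib.resources as resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import behavior as bhv
from . import io as cio
from .beamformer import (
    compute_covariance,
    extract_sources,
    filter_similarity,
    lcmv_filter,
    robust_standardize,
)
from .convglm import build_design, fit_tf_glm, fourier_basis, reconstruct_induced
from .groupstats import COMPLEXITY_WEIGHTS, permutation_fwe, tf_contrast
from .sim.forward import build_spherical_leadfield, sensor_array
from .sim.race import RaceParams, TaskConfig, SessionBehavior, simulate_behavior_session
from .sim.sensors import project_to_sensors
from .sim.sources import SourceEffectConfig, SourceRecipe, simulate_source_signals
from .spectral import TfConfig, multitaper_rms

__all__ = [
    "StudyConfig",
    "default_effects",
    "default_geometry",
    "run_subject",
    "run_study",
    "run_pipeline",
    "load_table2",
    "summarize_retained",
    "session_summary_row",
]

VARIANTS = [("bar", "stop"), ("arrow", "stop"), ("bar", "change"), ("arrow", "change")]


def default_effects() -> SourceEffectConfig:
    """Three-source recipe mirroring the study's effect structure.

    * ``rIFG``: a stop/change-locked theta/alpha burst plus a post-signal
      beta component larger after successful stops.
    * ``preSMA``: the same theta/alpha burst plus sustained gamma whose
      amplitude scales with the contextual complexity of the variant.
    * ``M1``: a motor region with an ongoing beta rhythm that
      desynchronizes around button presses and no signal-locked effects
      (the negative control for the stop-related contrasts).
    """
    beta_post = {
        (True, "stop"): 0.8,
        (False, "stop"): 0.2,
        (True, "change"): 0.35,
        (False, "change"): 0.3,
    }
    return SourceEffectConfig(
        recipes=(
            SourceRecipe(
                name="rIFG",
                theta_alpha_burst=1.2,
                beta_post=beta_post,
            ),
            SourceRecipe(
                name="preSMA",
                theta_alpha_burst=1.0,
                gamma_complexity=0.4,
                beta_post=beta_post,
            ),
            SourceRecipe(
                name="M1",
                base_bands=(((15.0, 25.0), 0.7),),
                motor_beta_desync=0.5,
            ),
        )
    )


def default_geometry(n_channels: int = 28, radius: float = 0.12):
    """Sensor cap positions and three well-separated source positions."""
    chans = sensor_array(n_channels, radius=radius, coverage=0.8)
    srcs = np.array(
        [
            [0.055, 0.035, 0.03],   # right-frontal (rIFG analogue)
            [0.0, 0.045, 0.055],    # medial-frontal (preSMA analogue)
            [-0.04, -0.03, 0.06],   # left central (M1 analogue)
        ]
    )
    return chans, srcs


@dataclass
class StudyConfig:
    """Scale and physics of one simulated study."""

    n_subjects: int = 8
    n_trials_per_block: int = 100
    n_blocks: int = 1
    race: RaceParams = field(default_factory=RaceParams)
    effects: SourceEffectConfig = field(default_factory=default_effects)
    sfreq: float = 160.0
    n_channels: int = 28
    noise_sd: float = 1.0
    #: analyzed frequencies (Hz); a subset keeps the TF stage affordable
    freqs: tuple = (5.0, 7.5, 10.0, 17.5, 20.0, 22.5, 40.0, 57.5, 60.0, 62.5)
    basis_order: int = 6
    alpha: float = 0.05
    n_perm: int = 800

    def task(self, stimulus: str, mode: str) -> TaskConfig:
        return TaskConfig(
            n_trials_per_block=self.n_trials_per_block,
            n_blocks=self.n_blocks,
            signal_stimulus=stimulus,
            response_mode=mode,
        )

    def to_yaml(self, path) -> Path:
        """Write the scalar study settings as a YAML file (the effect
        recipes keep their in-code defaults unless overridden)."""
        import yaml

        scalars = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.__dict__.items()
            if isinstance(v, (int, float, str, tuple))
        }
        path = Path(path)
        path.write_text(yaml.safe_dump(scalars, sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path, **overrides) -> "StudyConfig":
        """Build a config from a YAML file; keyword overrides win."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "freqs" in raw:
            raw["freqs"] = tuple(raw["freqs"])
        return cls(**raw)


def _source_orientations(leadfield) -> np.ndarray:
    """Fixed tangential ground-truth orientations, one per source."""
    outs = []
    for s in range(leadfield.n_sources):
        r0 = leadfield.source_positions[s] - leadfield.center
        # any unit vector orthogonal to the radial direction is tangential
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, r0) / np.linalg.norm(r0)) > 0.9:
            ref = np.array([1.0, 0.0, 0.0])
        t = np.cross(r0, ref)
        outs.append(t / np.linalg.norm(t))
    return np.stack(outs)


def run_subject(
    cfg: StudyConfig,
    seed: int,
    subject_id: str = "S0",
    keep_sessions: bool = False,
) -> dict:
    """Simulate and fully analyze one subject (all four task variants).

    Returns per-source induced responses keyed by (stimulus, mode) and
    event type, the per-variant behavioral summaries, and the filter
    similarity diagnostics.
    """
    ss = np.random.SeedSequence(seed)
    chans, srcs = default_geometry(cfg.n_channels)
    lf = build_spherical_leadfield(chans, srcs, center=np.zeros(3))
    orientations = _source_orientations(lf)
    names = cfg.effects.names
    tf_cfg = TfConfig(freqs=cfg.freqs)
    basis = fourier_basis(order=cfg.basis_order, step=tf_cfg.step)

    responses: dict = {name: {} for name in names}
    behavior_rows = []
    sessions = {}
    rsq_max = 0.0
    for (stim, mode), child in zip(VARIANTS, ss.spawn(len(VARIANTS))):
        rngs = [np.random.default_rng(s) for s in child.spawn(3)]
        session = simulate_behavior_session(
            cfg.task(stim, mode), cfg.race, seed=rngs[0],
            subject_id=subject_id, session_id=f"{stim}_{mode}",
        )
        ct = bhv.classify_trials(session)
        try:
            drift = bhv.estimate_rt_drift(ct)
        except bhv.InsufficientDataError:
            # tiny demo sessions: fall back to a constant at the median RT
            med = float(np.median(ct.go_rts())) if len(ct.go_rts()) else 0.5
            drift = bhv.DriftModel(
                _predict_mean=lambda x, _m=med: np.full(np.shape(x), _m),
                median_offset=0.0,
                residual_scale=0.0,
                kind="constant",
                index_range=(0, max(len(session) - 1, 1)),
            )
        behavior_rows.append(session_summary_row(session, ct, mcmc=False))
        sessions[(stim, mode)] = session

        per_type_accum: dict = {name: {} for name in names}
        for block in range(cfg.n_blocks):
            src_block = simulate_source_signals(
                session, cfg.effects, cfg.sfreq, seed=rngs[1], block=block
            )
            rec = project_to_sensors(
                src_block, orientations, lf, noise_sd=cfg.noise_sd, seed=rngs[2]
            )
            cov = compute_covariance(rec)
            filters = [
                lcmv_filter(lf.source_gain(s), cov, label=names[s],
                            channel_names=rec.channel_names)
                for s in range(len(names))
            ]
            rsq = filter_similarity(filters)
            rsq_max = max(rsq_max, float(np.max(rsq[~np.eye(len(names), dtype=bool)])))
            series = extract_sources(rec, filters)
            ev = src_block.events.copy()
            # go RT drift as a parametric modulator of the go regressor
            ev["rt_pred"] = drift.predict(ev["trial_index"].to_numpy())
            ev["outcome_type"] = ev["event_type"].where(
                ev["event_type"] != "signal",
                "signal_" + ev["outcome"].map(
                    {"signal_success": "success", "signal_fail": "fail"}
                ).fillna("other"),
            )
            ev_glm = ev[ev["outcome_type"] != "signal_other"].copy()
            ev_glm["event_type"] = ev_glm["outcome_type"]
            # windows exist only fully inside the block; events snapped
            # outside that span cannot be modeled, drop them up front
            tf_t0 = src_block.t0 + 0.2
            tf_t1 = src_block.t0 + src_block.duration - 0.2
            ev_glm = ev_glm[(ev_glm["onset"] >= tf_t0 - 0.025) & (ev_glm["onset"] < tf_t1)]
            event_types = [
                "fixation", "go", "signal_success", "signal_fail", "press_L", "press_R",
            ]
            for s, ts in enumerate(series):
                std = robust_standardize(ts, segment=10.0)
                tfi = multitaper_rms(std, tf_cfg)
                design = build_design(
                    ev_glm, basis, tfi.times,
                    event_types=[e for e in event_types
                                 if (ev_glm["event_type"] == e).any()],
                    modulators={"go": "rt_pred"},
                )
                res = fit_tf_glm(tfi, design)
                for et in ("fixation", "go", "signal_success", "signal_fail"):
                    if et in design.regressor_names:
                        r = reconstruct_induced(res, et)
                        acc = per_type_accum[names[s]].setdefault(et, [])
                        acc.append(r.values)
        for s_name in names:
            for et, imgs in per_type_accum[s_name].items():
                r_mean = np.mean(imgs, axis=0)
                responses[s_name][(stim, mode, et)] = r_mean

    out = {
        "responses": responses,
        "behavior": pd.DataFrame(behavior_rows),
        "taus": basis.taus,
        "freqs": np.asarray(cfg.freqs),
        "max_filter_rsq": rsq_max,
    }
    if keep_sessions:
        out["sessions"] = sessions
    return out


def run_study(cfg: StudyConfig, seed: int) -> dict:
    """Simulate ``cfg.n_subjects`` subjects and run the group contrasts.

    Returns per-source StatMaps for (a) the stimulus x response
    (contextual complexity) interaction on the go-locked response and
    (b) the mean stop/change-signal-locked response, plus the stacked
    per-subject contrast images.
    """
    ss = np.random.SeedSequence(seed)
    subject_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(cfg.n_subjects)]
    names = cfg.effects.names
    complexity_imgs: dict = {n: [] for n in names}
    stop_imgs: dict = {n: [] for n in names}
    subjects = []
    for i, s_seed in enumerate(subject_seeds):
        sub = run_subject(cfg, s_seed, subject_id=f"S{i}")
        subjects.append(sub)
        for n in names:
            resp = sub["responses"][n]
            # the complexity "set" effect starts at trial onset, so the
            # trial-onset-locked reconstruction is the image to contrast
            cmplx = tf_contrast(
                {k: resp[(k[0], k[1], "fixation")] for k in COMPLEXITY_WEIGHTS},
                COMPLEXITY_WEIGHTS,
            )
            complexity_imgs[n].append(cmplx)
            stop_mean = np.mean(
                [
                    resp[(stim, mode, et)]
                    for (stim, mode) in VARIANTS
                    for et in ("signal_success", "signal_fail")
                    if (stim, mode, et) in resp
                ],
                axis=0,
            )
            stop_imgs[n].append(stop_mean)

    rng_perm = np.random.SeedSequence(seed).spawn(1)[0]
    perm_rng = np.random.default_rng(rng_perm)
    taus, freqs = subjects[0]["taus"], subjects[0]["freqs"]
    stats = {"complexity": {}, "stop_mean": {}}
    for n in names:
        stats["complexity"][n] = permutation_fwe(
            complexity_imgs[n], alpha=cfg.alpha, n_perm=cfg.n_perm,
            seed=perm_rng, taus=taus, freqs=freqs,
        )
        stats["stop_mean"][n] = permutation_fwe(
            stop_imgs[n], alpha=cfg.alpha, n_perm=cfg.n_perm,
            seed=perm_rng, taus=taus, freqs=freqs,
        )
    return {
        "stats": stats,
        "complexity_images": complexity_imgs,
        "stop_images": stop_imgs,
        "subjects": subjects,
        "taus": taus,
        "freqs": freqs,
    }


# --------------------------------------------------------------------------
# Behavioral summary rows (printed-table roster)
# --------------------------------------------------------------------------

def session_summary_row(
    session: SessionBehavior,
    ct: Optional[bhv.ClassifiedTrials] = None,
    mcmc: bool = True,
    mcmc_seed: int = 0,
    mcmc_iter: int = 4000,
) -> dict:
    """One summary row per session in the printed table's column roster."""
    ct = ct or bhv.classify_trials(session)
    med = bhv.session_medians(ct)
    row = {
        "subject": session.subject_id,
        "condition": "{}_{}".format(*session.config.condition),
        "presented": ct.presented_count,
        "unclassified": ct.counts["unclassified"],
        "classified": ct.classified_count,
        "change_fraction": ct.change_fraction,
        "fail_fraction": ct.fail_fraction,
        "go_rt": med["go_rt"],
        "fail_rt": med["fail_rt"],
        "success_rt": med["success_rt"],
        "fail_soa": med["fail_soa"],
        "success_soa": med["success_soa"],
    }
    try:
        est = bhv.estimate_ssrt(ct)
        row["ssrt_av"] = est.ssrt_av
    except (bhv.InsufficientDataError, bhv.DegeneratePerformanceError):
        row["ssrt_av"] = np.nan
    row["ssrt_mcmc"] = np.nan
    row["deviance"] = np.nan
    if mcmc and np.isfinite(row["ssrt_av"]):
        screen = bhv.screen_session(ct, med)
        if screen.rule_soa_ordering and screen.rule_fail_fraction:
            fit = bhv.fit_inhibition_function(
                ct, prior_center=row["ssrt_av"], n_iter=mcmc_iter, seed=mcmc_seed
            )
            row["ssrt_mcmc"] = fit.alpha
            row["deviance"] = fit.deviance
    return row


# --------------------------------------------------------------------------
# Published behavioral table fixture
# --------------------------------------------------------------------------

def load_table2(path=None) -> pd.DataFrame:
    """Load the transcribed per-session behavioral summary table."""
    if path is None:
        ref = resources.files("countermand") / "data" / "table2.tsv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    bad = df["classified"] + df["unclassified"] != df["presented"]
    if bad.any():
        raise ValueError(f"inconsistent rows at index {list(df.index[bad])}")
    return df


def summarize_retained(rows: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each numeric column over the retained sessions."""
    kept = rows[rows["rejected"] == 0]
    if len(kept) == 0:
        raise ValueError("no retained sessions to summarize")
    num = kept.select_dtypes("number").drop(columns=["subject", "condition", "rejected"], errors="ignore")
    return pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})


# --------------------------------------------------------------------------
# File-producing pipeline
# --------------------------------------------------------------------------

def run_pipeline(
    out_dir,
    cfg: Optional[StudyConfig] = None,
    seed: int = 0,
    stages: tuple = ("behavior", "meg", "stats"),
) -> Path:
    """Run the study end to end, writing artifacts and a hash manifest.

    Deterministic for a fixed seed and config: running twice into two
    directories produces identical manifests.
    """
    cfg = cfg or StudyConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    ss = np.random.SeedSequence(seed)
    behavior_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    if "behavior" in stages:
        rows = []
        for i, (stim, mode) in enumerate(VARIANTS):
            session = simulate_behavior_session(
                cfg.task(stim, mode), cfg.race, seed=behavior_seed + i,
                subject_id="S0", session_id=f"{stim}_{mode}",
            )
            p = cio.write_events_tsv(session, out / f"events_{stim}_{mode}.tsv")
            written.append(p)
            rows.append(session_summary_row(session, mcmc=False))
        p = cio.write_summary_tsv(pd.DataFrame(rows), out / "behavior_summary.tsv")
        written.append(p)

    study = None
    if "meg" in stages or "stats" in stages:
        study = run_study(cfg, seed)
        import h5py

        with h5py.File(out / "induced_responses.h5", "w") as f:
            f.create_dataset("taus", data=study["taus"], track_times=False)
            f.create_dataset("freqs", data=study["freqs"], track_times=False)
            for n in cfg.effects.names:
                f.create_dataset(
                    f"complexity/{n}",
                    data=np.stack(study["complexity_images"][n]),
                    track_times=False,
                )
                f.create_dataset(
                    f"stop/{n}",
                    data=np.stack(study["stop_images"][n]),
                    track_times=False,
                )
        written.append(out / "induced_responses.h5")

    if "stats" in stages and study is not None:
        report = {}
        for effect, per_source in study["stats"].items():
            report[effect] = {
                n: {
                    "threshold": sm.threshold,
                    "n_significant_increase": int(sm.mask_increase.sum()),
                    "n_significant_decrease": int(sm.mask_decrease.sum()),
                    "peak_t": float(np.max(np.abs(sm.t_image))),
                }
                for n, sm in per_source.items()
            }
        p = out / "group_stats.json"
        p.write_text(json.dumps(report, indent=2, sort_keys=True))
        written.append(p)

    manifest = cio.write_manifest(
        written,
        out / "manifest.json",
        meta={"seed": seed, "stages": list(stages), "n_subjects": cfg.n_subjects},
    )
    return manifest
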