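"""End-to-end analysis pipeline.

Chains conditioning → epoching → mean-reversion correction → dose-response
fitting → charge-bin statistics → (imaging) engagement and mediation, with
per-stage logging.  All randomness descends from ``config.seed``, so two
runs with the same configuration produce identical numeric outputs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .conditioning import condition_channel, detect_blinks, resample_uniform
from .config import AnalysisConfig
from .evoked import build_trial_table, reject_artifacts
from .dose import (assign_charge_bins, binwise_tests, compare_full_vs_reduced,
                   half_max_charge)
from .mediation import bootstrap_mediation, partial_residual_correlation, \
    predict_engagement_cv
from .reversion import apply_correction, extract_pseudo_trials, fit_correction
from .session import SessionRecord

logger = logging.getLogger("vnspupil")

CHANNEL_KIND_MAP = {
    "pupil": "pupil",
    "eyelid": "eyelid",
    "eye_x": "eye_position",
    "eye_y": "eye_position",
    "velocity": "velocity",
    "fluorescence": "calcium",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, session_id: str, err: Exception):
        super().__init__(f"stage {stage!r} failed for session {session_id!r}: {err}")
        self.stage = stage
        self.session_id = session_id


def condition_session(record: SessionRecord, config: AnalysisConfig) -> dict:
    """Condition every recognized channel of a session."""
    out = {}
    kw = dict(rate=config.sample_rate_hz, blink_z=config.blink_z_threshold,
              pad_s=config.interpolation_pad_s, filter_order=config.filter_order,
              cutoff_hz=config.filter_cutoff_hz, percentile=config.percentile_norm)
    if "pupil" not in record.channels:
        raise KeyError("session has no 'pupil' channel; pupillometry is mandatory")
    raw = resample_uniform(record.channels["pupil"], config.sample_rate_hz)
    pupil_blinks = detect_blinks(raw, z_threshold=config.blink_z_threshold,
                                 pad_s=config.interpolation_pad_s)
    for name, ch in record.channels.items():
        kind = CHANNEL_KIND_MAP.get(name)
        if kind is None:
            continue  # unknown channels preserved upstream, not conditioned
        blinks = pupil_blinks if kind == "eye_position" else None
        out[name] = condition_channel(ch, kind, blink_intervals=blinks, **kw)
    return out


def session_trials(record: SessionRecord, config: AnalysisConfig,
                   conditioned: dict | None = None) -> tuple[pd.DataFrame, dict, dict]:
    """Conditioned channels → artifact-flagged trial table (uncorrected)."""
    sid = record.meta.session_id
    try:
        cond = conditioned or condition_session(record, config)
    except Exception as err:
        raise PipelineError("conditioning", sid, err) from err
    win = config.window_set(record.meta.luminance_class)
    try:
        trials, epochs = build_trial_table(
            record.events, pupil=cond["pupil"], eyelid=cond.get("eyelid"),
            calcium=cond.get("fluorescence"), velocity=cond.get("velocity"),
            windows=win, walk_threshold=config.walk_threshold_cm_s,
            walk_window=config.walk_window_s)
        motion = record.meta.extra.get("motion_um")
        motion = pd.DataFrame(motion) if motion is not None else None
        trials = reject_artifacts(trials, epochs["pupil"], win,
                                  gap_fraction_limit=config.artifact_gap_fraction,
                                  motion_um=motion,
                                  motion_limit_um=config.motion_limit_um)
        trials.insert(0, "session_id", sid)
    except Exception as err:
        raise PipelineError("epoching", sid, err) from err
    return trials, epochs, cond


def correct_experiment(trials: pd.DataFrame, pseudo: pd.DataFrame,
                       columns=(("response_pupil", "baseline_pupil"),)) -> tuple[pd.DataFrame, object]:
    """Fit the pooled mean-reversion model and correct the given columns."""
    model = fit_correction(pseudo)
    for resp, base in columns:
        if resp in trials.columns:
            model.applied_to = [a for a in model.applied_to if a != resp]
            trials = apply_correction(trials, model, response_col=resp,
                                      baseline_col=base)
    return trials, model


def run_pipeline(records: list[SessionRecord], config: AnalysisConfig | None = None,
                 correct: bool = True) -> dict:
    """Run the full analysis over one or more sessions.

    Returns a report dict with the pooled corrected trial table, the
    mean-reversion model, dose-response fits (full vs reduced), charge-bin
    statistics, half-max charge bootstrap, and — when calcium responses are
    present — the cross-validated engagement vector and mediation fits.
    """
    config = config or AnalysisConfig()
    if not records:
        raise ValueError("need at least one session")
    all_trials, all_pseudo = [], []
    for rec in records:
        trials, epochs, cond = session_trials(rec, config)
        win = config.window_set(rec.meta.luminance_class)
        try:
            ps = extract_pseudo_trials(cond["pupil"], rec.events, win)
            ps.insert(0, "session_id", rec.meta.session_id)
        except Exception as err:
            raise PipelineError("pseudo_trials", rec.meta.session_id, err) from err
        all_trials.append(trials)
        all_pseudo.append(ps)
        logger.info("session %s: %d trials (%d artifact), %d pseudo",
                    rec.meta.session_id, len(trials),
                    int(trials["artifact"].sum()), len(ps))
    trials = pd.concat(all_trials, ignore_index=True)
    pseudo = pd.concat(all_pseudo, ignore_index=True)

    report: dict = {"config_seed": config.seed, "n_sessions": len(records),
                    "n_trials": len(trials)}
    model = None
    if correct and len(pseudo) >= 20:
        trials, model = correct_experiment(trials, pseudo)
    report["trials"] = trials
    report["pseudo_trials"] = pseudo
    report["reversion_model"] = model

    usable = trials.loc[~trials["artifact"]]
    if len(usable) >= 30 and usable["response_pupil"].notna().all():
        try:
            report["dose"] = compare_full_vs_reduced(usable)
            bins = assign_charge_bins(usable, n_bins=config.n_charge_bins)
            report["charge_bins"] = binwise_tests(usable, bins, mode="vs_zero",
                                                  q=config.fdr_q)
            report["half_max"] = half_max_charge(
                usable, n_boot=config.n_bootstrap, seed=config.seed)
        except Exception as err:
            raise PipelineError("dose_response", "pooled", err) from err

    if "response_calcium" in trials.columns and trials["response_calcium"].notna().any():
        try:
            med = usable
            walked = med["walked"]
            med = med.loc[~walked.fillna(False).astype(bool)].reset_index(drop=True)
            eng = predict_engagement_cv(med, folds=min(config.cv_folds, len(med)),
                                        seed=config.seed)
            fit = bootstrap_mediation(med["response_pupil"].to_numpy(),
                                      med["response_calcium"].to_numpy(),
                                      eng.values, n_boot=config.n_bootstrap,
                                      seed=config.seed)
            report["engagement"] = eng
            report["mediation"] = fit
            report["partial_correlation"] = partial_residual_correlation(
                med["response_pupil"].to_numpy(),
                med["response_calcium"].to_numpy(), eng.values)
        except Exception as err:
            raise PipelineError("mediation", "pooled", err) from err
    return report


def report_fits(report: dict) -> dict:
    """JSON-ready summary of a pipeline report."""
    out = {"n_sessions": report.get("n_sessions"), "n_trials": report.get("n_trials"),
           "seed": report.get("config_seed")}
    if report.get("reversion_model") is not None:
        out["reversion_model"] = report["reversion_model"].to_dict()
    if "dose" in report:
        out["dose_full"] = report["dose"]["full"].to_dict()
        out["dose_reduced"] = report["dose"]["reduced"].to_dict()
        out["variance_explained_difference"] = report["dose"]["difference"]
    if "half_max" in report:
        out["half_max_charge_uc"] = report["half_max"]["estimate_uc"]
        out["half_max_bootstrap_sd_uc"] = report["half_max"]["bootstrap_sd_uc"]
    if "charge_bins" in report:
        out["charge_bin_table"] = report["charge_bins"].table.to_dict(orient="list")
        out["charge_bin_edges_uc"] = report["charge_bins"].edges.tolist()
    if "mediation" in report:
        out["mediation"] = report["mediation"].to_dict()
    if "partial_correlation" in report:
        pc = report["partial_correlation"]
        out["partial_correlation"] = {"r": pc["r"], "p": pc["p"]}
    return out
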