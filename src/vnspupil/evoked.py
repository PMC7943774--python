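"""Epoching and per-train evoked-response scalars.

The evoked scalar of a trial is the mean of the conditioned signal over the
response window minus the mean over the pre-onset baseline window (windows
half-open, seconds relative to train onset).  Standard-luminance sessions
use 2.5-7.5 s vs the 5 s baseline; the dim imaging setup produces
longer-lasting pupil dilations measured over 10-30 s vs a 20 s baseline.
Calcium responses are quantified over 2.5-7.5 s vs 5 s in all sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditioning import ConditionedSignal
from .session import StimTrain


@dataclass
class EpochMatrix:
    """Trials x time array locked to train onsets."""

    data: np.ndarray          # trials x samples; NaN outside the recording
    time: np.ndarray          # seconds relative to onset
    window: tuple[float, float]
    partial: np.ndarray       # per-trial flag: epoch extends past the recording
    gaps: np.ndarray | None = None  # trials x samples, True where interpolated

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def epoch(sig: ConditionedSignal, events: list[StimTrain],
          window: tuple[float, float]) -> EpochMatrix:
    """Slice a conditioned signal around each train onset.

    Epochs reaching past the session edges are flagged ``partial`` and
    padded with NaN, never silently truncated.
    """
    n_samp = int(round((window[1] - window[0]) * sig.rate))
    rel = window[0] + np.arange(n_samp) / sig.rate
    data = np.full((len(events), n_samp), np.nan)
    gaps = np.zeros((len(events), n_samp), dtype=bool)
    partial = np.zeros(len(events), dtype=bool)
    n = sig.values.size
    for i, ev in enumerate(events):
        start = sig.index_of(ev.onset + window[0])
        stop = start + n_samp
        s0, s1 = max(start, 0), min(stop, n)
        if s0 >= s1:
            partial[i] = True
            continue
        data[i, s0 - start: s1 - start] = sig.values[s0:s1]
        gaps[i, s0 - start: s1 - start] = sig.gap_mask[s0:s1]
        if start < 0 or stop > n:
            partial[i] = True
    return EpochMatrix(data=data, time=rel, window=tuple(window),
                       partial=partial, gaps=gaps)


def _window_mean(ep: EpochMatrix, window: tuple[float, float]) -> np.ndarray:
    sel = (ep.time >= window[0]) & (ep.time < window[1])
    if not sel.any():
        raise ValueError(f"window {window} outside epoch span "
                         f"[{ep.time[0]}, {ep.time[-1]}]")
    return np.nanmean(ep.data[:, sel], axis=1)


def evoked_scalar(ep: EpochMatrix, response_window: tuple[float, float],
                  baseline_window: tuple[float, float]) -> np.ndarray:
    """Per-trial mean(response window) - mean(baseline window)."""
    for w in (response_window, baseline_window):
        if w[0] < ep.window[0] or w[1] > ep.window[1]:
            raise ValueError(f"window {w} outside epoch window {ep.window}")
    return _window_mean(ep, response_window) - _window_mean(ep, baseline_window)


def walk_metrics(velocity: ConditionedSignal | None, events: list[StimTrain],
                 threshold: float = 0.05,
                 window: tuple[float, float] = (0.0, 10.0)) -> pd.DataFrame:
    """Mean speed over the train window and the walk criterion per trial.

    ``walked`` is True when |mean speed| strictly exceeds the threshold
    (0.05 cm/s); a speed exactly at the threshold does not count as walking.
    """
    if velocity is None:
        return pd.DataFrame({"walk_speed": [np.nan] * len(events),
                             "walked": [pd.NA] * len(events),
                             "walk_missing": [True] * len(events)})
    ep = epoch(velocity, events, window)
    speed = np.nanmean(ep.data, axis=1)
    return pd.DataFrame({"walk_speed": speed,
                         "walked": np.abs(speed) > threshold,
                         "walk_missing": False})


def build_trial_table(events: list[StimTrain], *, pupil: ConditionedSignal,
                      eyelid: ConditionedSignal | None = None,
                      calcium: ConditionedSignal | None = None,
                      velocity: ConditionedSignal | None = None,
                      windows, calcium_windows=None,
                      walk_threshold: float = 0.05,
                      walk_window: tuple[float, float] = (0.0, 10.0),
                      ) -> tuple[pd.DataFrame, dict]:
    """Assemble the per-train trial table from conditioned channels.

    ``windows`` (a :class:`vnspupil.config.Windows`) applies to pupil and
    eyelid; ``calcium_windows`` (default: 2.5-7.5 s response vs 5 s
    baseline) applies to the fluorescence trace.  Returns the table and the
    epoch matrices used to build it.
    """
    rows = pd.DataFrame({
        "onset_s": [e.onset for e in events],
        "amplitude_ma": [e.amplitude for e in events],
        "width_ms": [e.width for e in events],
        "rate_hz": [e.rate for e in events],
        "charge_uc": [e.charge_per_pulse for e in events],
    })
    epochs: dict[str, EpochMatrix] = {}

    ep = epoch(pupil, events, windows.epoch)
    epochs["pupil"] = ep
    rows["baseline_pupil"] = _window_mean(ep, windows.baseline) if events else []
    rows["response_pupil"] = evoked_scalar(ep, windows.response, windows.baseline) \
        if events else []
    rows["partial_epoch"] = ep.partial

    if eyelid is not None:
        epe = epoch(eyelid, events, windows.epoch)
        epochs["eyelid"] = epe
        rows["baseline_eyelid"] = _window_mean(epe, windows.baseline) if events else []
        rows["response_eyelid"] = evoked_scalar(epe, windows.response, windows.baseline) \
            if events else []
    if calcium is not None:
        cw = calcium_windows
        if cw is None:
            from .config import Windows

            cw = Windows(epoch=windows.epoch, baseline=(-5.0, 0.0),
                         response=(2.5, 7.5), pre_span=windows.pre_span)
        epc = epoch(calcium, events, cw.epoch)
        epochs["calcium"] = epc
        rows["baseline_calcium"] = _window_mean(epc, cw.baseline) if events else []
        rows["response_calcium"] = evoked_scalar(epc, cw.response, cw.baseline) \
            if events else []
    wm = walk_metrics(velocity, events, threshold=walk_threshold, window=walk_window)
    rows = pd.concat([rows, wm], axis=1)
    return rows, epochs


def reject_artifacts(trials: pd.DataFrame, pupil_epochs: EpochMatrix,
                     windows, gap_fraction_limit: float = 0.25,
                     motion_um: pd.DataFrame | None = None,
                     motion_limit_um: float = 2.0) -> pd.DataFrame:
    """Flag unreliable trials; flags never delete rows.

    A trial is flagged when more than ``gap_fraction_limit`` of the samples
    inside its baseline+response measurement windows were interpolated (the
    pupil could not be reliably recorded), when its epoch was partial, or —
    for imaging sessions with a motion table (columns ``x_um``/``y_um``) —
    when image motion exceeded ``motion_limit_um`` in either direction.
    """
    out = trials.copy()
    sel = (((pupil_epochs.time >= windows.baseline[0]) & (pupil_epochs.time < windows.baseline[1]))
           | ((pupil_epochs.time >= windows.response[0]) & (pupil_epochs.time < windows.response[1])))
    reasons = []
    flags = np.zeros(len(out), dtype=bool)
    gap_in_windows = np.zeros(len(out))
    if pupil_epochs.gaps is not None and sel.any():
        gap_in_windows = pupil_epochs.gaps[:, sel].mean(axis=1)
    for i in range(len(out)):
        why = []
        if pupil_epochs.partial[i]:
            why.append("partial_epoch")
        if gap_in_windows[i] > gap_fraction_limit:
            why.append("pupil_gap")
        if motion_um is not None:
            if (abs(motion_um.iloc[i]["x_um"]) > motion_limit_um
                    or abs(motion_um.iloc[i]["y_um"]) > motion_limit_um):
                why.append("motion")
        flags[i] = bool(why)
        reasons.append(",".join(why))
    out["artifact"] = flags
    out["artifact_reason"] = reasons
    return out
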