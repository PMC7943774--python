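"""Pseudo-trial correction for reversion to the mean.

An autocorrelated signal such as pupil size spontaneously drifts back
toward its average: when the baseline is high the "response" tends to be
negative, and vice versa, which confounds baseline-sorted evoked measures.
The correction characterizes this spontaneous tendency on stimulus-free
pseudo-trials carved from the pre-stimulation period, fits a cubic of the
pseudo-response on the pseudo-baseline, and subtracts the cubic's
prediction (evaluated at each real trial's observed baseline) from the real
evoked responses.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conditioning import ConditionedSignal
from .config import Windows
from .evoked import epoch, evoked_scalar, _window_mean
from .session import StimTrain


@dataclass
class MeanReversionModel:
    """Cubic map from baseline value to predicted spontaneous change."""

    coefficients: np.ndarray          # ascending order: c0 + c1 x + c2 x^2 + c3 x^3
    bin_summary: pd.DataFrame         # 8 baseline-bin diagnostics
    windows: dict
    n_pseudo: int
    data_hash: str = ""
    applied_to: list = field(default_factory=list)

    def predict(self, baseline) -> np.ndarray:
        return np.polyval(self.coefficients[::-1], np.asarray(baseline, dtype=float))

    @property
    def baseline_range(self) -> tuple[float, float]:
        return (float(self.bin_summary["bin_min"].min()),
                float(self.bin_summary["bin_max"].max()))

    def to_dict(self) -> dict:
        return {
            "coefficients": list(map(float, self.coefficients)),
            "windows": self.windows,
            "n_pseudo": self.n_pseudo,
            "data_hash": self.data_hash,
            "bin_summary": self.bin_summary.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MeanReversionModel":
        return cls(coefficients=np.asarray(d["coefficients"], dtype=float),
                   bin_summary=pd.DataFrame(d["bin_summary"]),
                   windows=d["windows"], n_pseudo=d["n_pseudo"],
                   data_hash=d.get("data_hash", ""))


def extract_pseudo_trials(sig: ConditionedSignal, events: list[StimTrain],
                          windows: Windows) -> pd.DataFrame:
    """Stimulus-free pseudo baselines and pseudo "responses" before each train.

    One pseudo-trial per eligible real trial: the pseudo-onset is placed at
    (true onset - response window end) so the pseudo response window ends
    exactly at the true onset, with its baseline window immediately before
    it.  Events lacking a clean ``windows.pre_span`` of pre-onset data are
    skipped.
    """
    pseudo_events = []
    kept = []
    t0, t1 = sig.times[0], sig.times[-1]
    need = windows.pre_span
    for i, ev in enumerate(events):
        p_onset = ev.onset - windows.response[1]
        if (ev.onset - need) < t0:
            continue
        if p_onset + windows.baseline[0] < t0 or p_onset + windows.response[1] > t1:
            continue
        pseudo_events.append(StimTrain(onset=p_onset, amplitude=ev.amplitude,
                                       width=ev.width, rate=ev.rate,
                                       duration=ev.duration))
        kept.append(i)
    if not pseudo_events:
        return pd.DataFrame(columns=["event_index", "pseudo_onset_s",
                                     "pseudo_baseline", "pseudo_response"])
    ep = epoch(sig, pseudo_events, windows.epoch)
    baseline = _window_mean(ep, windows.baseline)
    response = evoked_scalar(ep, windows.response, windows.baseline)
    return pd.DataFrame({
        "event_index": kept,
        "pseudo_onset_s": [e.onset for e in pseudo_events],
        "pseudo_baseline": baseline,
        "pseudo_response": response,
    })


def fit_correction(pseudo: pd.DataFrame, n_bins: int = 8,
                   min_trials: int = 20) -> MeanReversionModel:
    """Least-squares cubic of pseudo-response on pseudo-baseline.

    The cubic is fitted to trial-level pseudo data; the ``n_bins``
    equal-count baseline bins are diagnostics only.
    """
    x = pseudo["pseudo_baseline"].to_numpy(dtype=float)
    y = pseudo["pseudo_response"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < min_trials:
        raise ValueError(f"need >= {min_trials} pseudo trials, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant pseudo-baselines: cubic fit is rank-deficient")
    coef_desc = np.polyfit(x, y, 3)
    coefficients = coef_desc[::-1].copy()

    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1))
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        rows.append({
            "bin": b + 1,
            "n": int(sel.sum()),
            "bin_min": float(x[sel].min()) if sel.any() else np.nan,
            "bin_max": float(x[sel].max()) if sel.any() else np.nan,
            "baseline_mean": float(x[sel].mean()) if sel.any() else np.nan,
            "pseudo_response_mean": float(y[sel].mean()) if sel.any() else np.nan,
            "pseudo_response_sem": float(y[sel].std(ddof=1) / np.sqrt(sel.sum()))
            if sel.sum() > 1 else np.nan,
        })
    h = hashlib.sha256(json.dumps([x.tolist(), y.tolist()]).encode()).hexdigest()[:16]
    return MeanReversionModel(coefficients=coefficients,
                              bin_summary=pd.DataFrame(rows),
                              windows={}, n_pseudo=int(x.size), data_hash=h)


def apply_correction(trials: pd.DataFrame, model: MeanReversionModel,
                     response_col: str = "response_pupil",
                     baseline_col: str = "baseline_pupil") -> pd.DataFrame:
    """Subtract the predicted spontaneous change from each observed response.

    The uncorrected column is kept as ``<response_col>_uncorrected``.
    Re-applying a correction to an already-corrected column is refused.
    """
    if response_col in model.applied_to:
        raise ValueError(f"correction already applied to {response_col!r}; "
                         "a second application would be double-corrected")
    out = trials.copy()
    baseline = out[baseline_col].to_numpy(dtype=float)
    lo, hi = model.baseline_range
    outside = (baseline < lo) | (baseline > hi)
    if outside.any():
        import warnings

        warnings.warn(f"{int(outside.sum())} trial baselines outside the fitted "
                      f"range [{lo:.3g}, {hi:.3g}]; correcting by extrapolation")
    out[f"{response_col}_uncorrected"] = out[response_col]
    out[response_col] = out[response_col] - model.predict(baseline)
    model.applied_to.append(response_col)
    return out
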