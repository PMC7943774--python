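"""Per-channel signal conditioning.

The preprocessing chains mirror the study's pupillometry pipeline:

* pupil / eyelid : resample to 50 Hz → blink detection on the z-scored
  temporal derivative → linear interpolation of bad spans (padded 150 ms
  each side) → zero-phase 3rd-order Butterworth low-pass at 3 Hz →
  conversion to percent of the series' 99.9th percentile.
* eye position   : resample → interpolate the blink spans detected on the
  pupil → z-score.
* velocity       : resample only (cm/s kept as-is).
* calcium        : resample → low-pass → linear detrend of bleaching
  rundown → percent of the 99.9th percentile.

Filtering is applied forward and backward (``scipy.signal.filtfilt``) so
evoked-response latencies are not phase-shifted; the effective attenuation
is the squared one-pass Butterworth magnitude response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .session import Channel

CHANNEL_KINDS = ("pupil", "eyelid", "eye_position", "velocity", "calcium")


@dataclass
class ConditionedSignal:
    """Uniformly sampled conditioned signal.

    ``gap_mask`` is True exactly where samples were interpolated rather than
    measured; ``provenance`` is the ordered list of applied steps.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    gap_mask: np.ndarray = None
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.values.shape, dtype=bool)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    def index_of(self, t: float) -> int:
        """Index of the grid sample at or immediately after time ``t``."""
        return int(np.ceil((t - self.t0) * self.rate - 1e-9))


def resample_uniform(channel: Channel, target_rate: float) -> ConditionedSignal:
    """Linearly interpolate an (ir)regularly sampled channel onto a uniform grid.

    Missing source samples (NaN) are carried through as gap-masked grid
    samples; their values are filled later by :func:`interpolate_gaps`.
    """
    t = channel.times
    v = channel.values
    if t.size < 2:
        raise ValueError("resampling requires at least 2 samples")
    n = int(np.floor((t[-1] - t[0]) * target_rate)) + 1
    grid = t[0] + np.arange(n) / target_rate

    good = np.isfinite(v)
    if good.sum() == 0:
        out = np.full(n, np.nan)
        mask = np.ones(n, dtype=bool)
    else:
        out = np.interp(grid, t[good], v[good])
        # A grid point is "missing" if its nearest source sample was NaN.
        nearest = np.searchsorted(t, grid)
        nearest = np.clip(nearest, 0, t.size - 1)
        left = np.clip(nearest - 1, 0, t.size - 1)
        use_left = np.abs(grid - t[left]) <= np.abs(t[nearest] - grid)
        nearest = np.where(use_left, left, nearest)
        mask = ~good[nearest]
        out[mask] = np.nan
    sig = ConditionedSignal(out, target_rate, t0=float(t[0]), gap_mask=mask)
    sig.provenance.append(("resample_uniform", {"target_rate": target_rate}))
    return sig


def detect_blinks(sig: ConditionedSignal, z_threshold: float = 3.0,
                  pad_s: float = 0.15) -> list[tuple[int, int]]:
    """Detect blink/artifact spans as outliers of the z-scored first difference.

    Returns half-open sample-index intervals ``(start, stop)``, each extended
    by ``pad_s`` on both sides, merged where overlapping.  Samples already
    flagged missing (NaN / gap-masked) are always included.
    """
    v = sig.values
    if v.size < 3:
        raise ValueError("need at least 3 samples")
    bad = ~np.isfinite(v) | sig.gap_mask
    d = np.diff(v)
    finite_d = d[np.isfinite(d)]
    if finite_d.size and np.std(finite_d) > 0:
        z = (d - np.mean(finite_d)) / np.std(finite_d)
        spike = np.abs(z) > z_threshold
        # a spike in the derivative taints both samples it joins
        bad[:-1] |= spike & np.isfinite(z)
        bad[1:] |= spike & np.isfinite(z)
    if not bad.any():
        return []
    pad = int(round(pad_s * sig.rate))
    idx = np.flatnonzero(bad)
    intervals: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i > prev + 1:
            intervals.append((start, prev + 1))
            start = i
        prev = i
    intervals.append((start, prev + 1))
    padded = [(max(0, a - pad), min(v.size, b + pad)) for a, b in intervals]
    merged = [padded[0]]
    for a, b in padded[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def interpolate_gaps(sig: ConditionedSignal,
                     intervals: list[tuple[int, int]]) -> ConditionedSignal:
    """Replace samples inside ``intervals`` by linear interpolation.

    Interpolation bridges between the nearest good neighbours; leading or
    trailing gaps are filled with the nearest good value.
    """
    v = sig.values.copy()
    mask = sig.gap_mask.copy()
    for a, b in intervals:
        mask[a:b] = True
        v[a:b] = np.nan
    good = np.isfinite(v) & ~mask
    if good.sum() == 0:
        raise ValueError("no good samples to interpolate from")
    idx = np.arange(v.size)
    v = np.interp(idx, idx[good], v[good])
    out = ConditionedSignal(v, sig.rate, t0=sig.t0, gap_mask=mask,
                            provenance=list(sig.provenance))
    out.provenance.append(("interpolate_gaps", {"n_intervals": len(intervals)}))
    return out


def lowpass_zero_phase(sig: ConditionedSignal, order: int = 3,
                       cutoff_hz: float = 3.0) -> ConditionedSignal:
    """Zero-phase Butterworth low-pass (forward-backward, DC gain 1)."""
    nyq = sig.rate / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz >= Nyquist {nyq} Hz")
    if not np.all(np.isfinite(sig.values)):
        raise ValueError("low-pass filtering requires gap-free input; interpolate first")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=sig.rate, output="sos")
    v = sps.sosfiltfilt(sos, sig.values)
    out = ConditionedSignal(v, sig.rate, t0=sig.t0, gap_mask=sig.gap_mask.copy(),
                            provenance=list(sig.provenance))
    out.provenance.append(("lowpass_zero_phase", {"order": order, "cutoff_hz": cutoff_hz}))
    return out


def _percentile_normalize(sig: ConditionedSignal, q: float) -> ConditionedSignal:
    ref = np.percentile(sig.values, q)
    if ref == 0:
        raise ValueError("percentile reference is zero; cannot normalize")
    out = ConditionedSignal(100.0 * sig.values / ref, sig.rate, t0=sig.t0,
                            gap_mask=sig.gap_mask.copy(), provenance=list(sig.provenance))
    out.provenance.append(("percentile_normalize", {"q": q}))
    return out


def _zscore(sig: ConditionedSignal) -> ConditionedSignal:
    sd = np.std(sig.values)
    if sd == 0:
        raise ValueError("zero-variance signal cannot be z-scored")
    out = ConditionedSignal((sig.values - np.mean(sig.values)) / sd, sig.rate,
                            t0=sig.t0, gap_mask=sig.gap_mask.copy(),
                            provenance=list(sig.provenance))
    out.provenance.append(("zscore", {}))
    return out


def _detrend_linear(sig: ConditionedSignal) -> ConditionedSignal:
    # single least-squares line over the full session (bleaching rundown);
    # the mean is retained so percentile normalization stays meaningful
    t = np.arange(sig.values.size, dtype=float)
    slope, intercept = np.polyfit(t, sig.values, 1)
    v = sig.values - slope * t - intercept + np.mean(sig.values)
    out = ConditionedSignal(v, sig.rate, t0=sig.t0, gap_mask=sig.gap_mask.copy(),
                            provenance=list(sig.provenance))
    out.provenance.append(("detrend_linear", {"slope_per_sample": float(slope)}))
    return out


def condition_channel(channel: Channel, kind: str, *, rate: float = 50.0,
                      blink_z: float = 3.0, pad_s: float = 0.15,
                      filter_order: int = 3, cutoff_hz: float = 3.0,
                      percentile: float = 99.9,
                      blink_intervals: list[tuple[int, int]] | None = None,
                      ) -> ConditionedSignal:
    """Run the full conditioning chain for one channel kind.

    Parameters
    ----------
    blink_intervals
        For ``eye_position``, the bad spans detected on the *pupil* channel
        (the pupil ellipse fit drives both signals); detected locally when
        not given.
    """
    if kind not in CHANNEL_KINDS:
        raise ValueError(f"unknown channel kind {kind!r}; expected one of {CHANNEL_KINDS}")
    sig = resample_uniform(channel, rate)
    if kind in ("pupil", "eyelid", "eye_position"):
        intervals = blink_intervals
        if intervals is None:
            intervals = detect_blinks(sig, z_threshold=blink_z, pad_s=pad_s)
        sig = interpolate_gaps(sig, intervals)
        if kind == "eye_position":
            return _zscore(sig)
        sig = lowpass_zero_phase(sig, order=filter_order, cutoff_hz=cutoff_hz)
        return _percentile_normalize(sig, percentile)
    if kind == "velocity":
        if sig.gap_mask.any():
            sig = interpolate_gaps(sig, [])
        return sig
    # calcium
    if sig.gap_mask.any():
        sig = interpolate_gaps(sig, [])
    sig = lowpass_zero_phase(sig, order=filter_order, cutoff_hz=cutoff_hz)
    sig = _detrend_linear(sig)
    return _percentile_normalize(sig, percentile)
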