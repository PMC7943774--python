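"""Stimulation-current diagnostics: leak fraction and pulse-width filtering.

The applied current is compared with the return current measured across a
sensing resistor.  Two effects are characterized: a session-wise leak
fraction L = 1 - Am/Ai (current escaping to ground, prominent in grounded
preparations), and a sigmoidal attenuation of narrow pulses,
Am(W) = s / (1 + exp(-a (W - b))), fitted over the tested pulse widths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class LeakFilterFit:
    leak: float
    a_measured: float
    a_intended: float
    sigmoid_s: float | None = None
    sigmoid_a: float | None = None
    sigmoid_b: float | None = None
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {"leak": self.leak, "a_measured": self.a_measured,
                "a_intended": self.a_intended, "sigmoid_s": self.sigmoid_s,
                "sigmoid_a": self.sigmoid_a, "sigmoid_b": self.sigmoid_b,
                "degenerate": self.degenerate}


def leak_fraction(measured: pd.DataFrame, intended_minimum: float,
                  min_width_ms: float = 0.4) -> float:
    """Session leak fraction L = 1 - Am/Ai.

    Am is the mean across the minimum measured amplitude for each unique
    (pulse width, rate) group; narrow widths (below ``min_width_ms``,
    i.e. the 0.1 and 0.2 ms pulses) are excluded because the width filter
    would masquerade as leak.  Small negative L is tolerated as measurement
    noise but flagged with a warning.
    """
    elig = measured.loc[measured["width_ms"] >= min_width_ms]
    if elig.empty:
        raise ValueError(f"no pulses with width >= {min_width_ms} ms")
    group_min = elig.groupby(["width_ms", "rate_hz"])["measured_ma"].min()
    a_m = float(group_min.mean())
    L = 1.0 - a_m / float(intended_minimum)
    if L < -0.05:
        raise ValueError(f"leak fraction {L:.3f} < -0.05: measured exceeds intended "
                         "beyond measurement noise")
    if L < 0:
        warnings.warn(f"slightly negative leak fraction {L:.4f}; treating as noise")
    return L


def fit_width_filter(measured: pd.DataFrame) -> LeakFilterFit:
    """Sigmoid fit of mean measured amplitude against pulse width.

    Returns the plateau ``s`` (mA), steepness ``a`` (1/ms) and half-plateau
    width ``b`` (ms).  A flat profile (no filtering) is detected and
    reported as a degenerate fit with plateau = mean.
    """
    by_width = measured.groupby("width_ms")["measured_ma"].mean()
    W = by_width.index.to_numpy(dtype=float)
    Am = by_width.to_numpy(dtype=float)
    if W.size < 3:
        raise ValueError("need at least 3 distinct pulse widths")
    a_i = float(measured["intended_ma"].min())

    if np.ptp(Am) < 1e-3 * max(abs(Am).max(), 1e-12):
        warnings.warn("measured amplitudes flat across widths; no filtering detectable")
        fit = LeakFilterFit(leak=np.nan, a_measured=float(Am.mean()), a_intended=a_i,
                            sigmoid_s=float(Am.mean()), degenerate=True)
        return fit

    def sigmoid(w, s, a, b):
        return s / (1.0 + np.exp(-a * (w - b)))

    p0 = (float(Am.max()), 10.0, float(np.median(W)))
    try:
        popt, _ = optimize.curve_fit(sigmoid, W, Am, p0=p0,
                                     bounds=([0, 0.01, -1.0], [np.inf, 500.0, 2.0]),
                                     maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"width-filter fit failed on widths={W.tolist()}, "
                           f"amplitudes={Am.tolist()}") from err
    return LeakFilterFit(leak=np.nan, a_measured=float(Am.mean()), a_intended=a_i,
                         sigmoid_s=float(popt[0]), sigmoid_a=float(popt[1]),
                         sigmoid_b=float(popt[2]))


def characterize_session(measured: pd.DataFrame, intended_minimum: float | None = None,
                         min_width_ms: float = 0.4) -> LeakFilterFit:
    """Joint leak + width-filter characterization of one session's pulses."""
    if intended_minimum is None:
        intended_minimum = float(measured["intended_ma"].min())
    L = leak_fraction(measured, intended_minimum, min_width_ms=min_width_ms)
    fit = fit_width_filter(measured)
    fit.leak = L
    fit.a_intended = float(intended_minimum)
    return fit
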