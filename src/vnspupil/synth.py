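"""Synthetic VNS session generator.

Emulates the statistical structure the analysis pipeline assumes, so every
downstream stage is testable without recorded data:

* a slow mean-reverting baseline pupil process (exact-discretization
  Ornstein-Uhlenbeck; mean reversion is precisely the confound the
  pseudo-trial correction removes),
* VNS-evoked transients whose peak amplitude follows a separable
  log-logistic surface over (amplitude, width, rate) with multiplicative
  log-normal trial noise,
* a coupled axonal-calcium latent drive (shared trial noise factor routes a
  configurable proportion of the pupil drive through calcium),
* probabilistic walking bouts, blinks/dropouts, and a measured stimulation
  current with a leak fraction and width-dependent sigmoidal filtering.

Every bundle written to disk carries a ``truth.json`` sidecar for recovery
tests.  All randomness flows from a single seeded generator.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose import loglogistic_term
from .session import Channel, SessionMeta, SessionRecord, StimTrain

FULL_GRID = ((0.1, 0.3, 0.5, 0.7, 0.9), (0.1, 0.2, 0.4, 0.8), (5.0, 10.0, 20.0))
IMAGING_GRID = ((0.1, 0.3, 0.5, 0.7, 0.9), (0.1, 0.2, 0.4), (10.0, 20.0))


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SurfaceTruth:
    """Generative dose-response surface, full (A, W, R) or reduced (C, R) form."""

    kind: str = "reduced"
    s: float = 10.0
    a: tuple = (0.15, 9.0)
    b: tuple = (2.0, 2.0)

    def __post_init__(self) -> None:
        if self.kind not in ("full", "reduced"):
            raise ValueError("kind must be 'full' or 'reduced'")
        n = 3 if self.kind == "full" else 2
        if len(self.a) != n or len(self.b) != n:
            raise ValueError(f"{self.kind} surface needs {n} (a, b) pairs")
        if self.s != 0 and any(v <= 0 for v in (*self.a, *self.b)):
            raise ValueError("scale/shape parameters must be > 0")

    def evaluate(self, amplitude, width, rate) -> np.ndarray:
        if self.s == 0:
            return np.zeros(np.broadcast(np.asarray(amplitude), np.asarray(rate)).shape)
        if self.kind == "full":
            out = (self.s
                   * loglogistic_term(amplitude, self.a[0], self.b[0])
                   * loglogistic_term(width, self.a[1], self.b[1])
                   * loglogistic_term(rate, self.a[2], self.b[2]))
        else:
            charge = np.asarray(amplitude, dtype=float) * np.asarray(width, dtype=float)
            out = (self.s
                   * loglogistic_term(charge, self.a[0], self.b[0])
                   * loglogistic_term(rate, self.a[1], self.b[1]))
        return out


@dataclass
class BaselineTruth:
    tau_s: float = 40.0     # OU mean-reversion time constant
    sd: float = 6.0         # stationary SD, % units
    mean: float = 50.0      # mean level, % units


@dataclass
class KernelTruth:
    rise_s: float = 2.5
    decay_s: float = 12.0
    latency_s: float = 0.0


@dataclass
class ElectronicsTruth:
    leak: float = 0.0            # leak fraction L in [0, 1)
    filter_a: float = 20.0       # sigmoid steepness, 1/ms
    filter_b: float = 0.12       # half-plateau width, ms

    def width_filter(self, width_ms) -> np.ndarray:
        w = np.asarray(width_ms, dtype=float)
        return 1.0 / (1.0 + np.exp(-self.filter_a * (w - self.filter_b)))


@dataclass
class GroundTruthParams:
    """All generative parameters; defaults are the emulated study conditions."""

    surfaces: dict = field(default_factory=lambda: {
        # half-max charges anchored to the reported values: pupil 0.15 uC
        # (intact nerve), eyelid 0.32 uC, calcium 0.062 uC, walking 0.17 uC
        "pupil": SurfaceTruth(kind="reduced", s=10.0, a=(0.15, 9.0), b=(2.0, 2.0)),
        "eyelid": SurfaceTruth(kind="reduced", s=5.0, a=(0.32, 9.0), b=(1.5, 2.0)),
        "calcium": SurfaceTruth(kind="reduced", s=20.0, a=(0.062, 9.0), b=(2.0, 2.0)),
        "walk_prob": SurfaceTruth(kind="reduced", s=0.45, a=(0.17, 9.0), b=(2.0, 2.0)),
    })
    baseline: BaselineTruth = field(default_factory=BaselineTruth)
    kernels: dict = field(default_factory=lambda: {
        "standard": KernelTruth(rise_s=2.5, decay_s=12.0),   # peaks ~5 s post-onset
        "imaging": KernelTruth(rise_s=6.0, decay_s=25.0),    # slow dim-light dilation
        "calcium": KernelTruth(rise_s=1.5, decay_s=8.0),     # GCaMP-like
    })
    # trial noise: mean-preserving log-normal on evoked amplitude plus
    # additive Gaussian on the scalar; calibrated so the reduced-model
    # trial-level variance explained for the default pupil surface matches
    # the reported 26.33%
    trial_lognormal_sigma: float = 0.4
    scalar_noise_sd: float = 3.45
    sample_noise_sd: float = 0.5        # additive, per conditioned sample
    # calcium coupling
    calcium_route_proportion: float = 0.5   # share of pupil drive routed via calcium
    # walking
    walk_speed_scale: float = 0.35      # cm/s during the train
    walk_decay_s: float = 3.0
    spont_walk_rate_per_min: float = 0.2
    # blinks
    blink_rate_per_min: float = 2.0
    blink_duration_s: float = 0.25
    # grounded-preparation artifact: eye-position wiggle at the train rate
    grounded_wiggle_z: float = 1.0
    electronics: ElectronicsTruth = field(default_factory=ElectronicsTruth)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def null_truth(**kwargs) -> GroundTruthParams:
    """Truth with all evoked surfaces silenced (s = 0); pure baseline + noise."""
    t = GroundTruthParams(**kwargs)
    for surf in t.surfaces.values():
        surf.s = 0.0
    return t


# ---------------------------------------------------------------------------
# protocol


def generate_protocol(grid=FULL_GRID, repetitions: int = 1, seed: int = 0,
                      intertrain: tuple[float, float] = (106.0, 130.0),
                      duration: float = 10.0, t_start: float = 60.0) -> list[StimTrain]:
    """Full factorial crossing of (amplitudes, widths, rates), shuffled.

    Each combination occurs ``repetitions`` times; intertrain intervals are
    drawn uniformly on ``intertrain`` (106-130 s, mean 118 s, to reduce
    expectancy); each train lasts ``duration`` seconds.
    """
    amps, widths, rates = (tuple(g) for g in grid)
    combos = [(a, w, r) for a in amps for w in widths for r in rates] * int(repetitions)
    if not combos:
        return []
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(combos))
    gaps = rng.uniform(intertrain[0], intertrain[1], size=len(combos))
    onsets = t_start + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
    return [StimTrain(onset=float(onsets[i]), amplitude=combos[j][0],
                      width=combos[j][1], rate=combos[j][2], duration=duration)
            for i, j in enumerate(order)]


# ---------------------------------------------------------------------------
# building blocks


def ou_process(n: int, dt: float, tau: float, sd: float, mean: float,
               rng: np.random.Generator, x0: float | None = None) -> np.ndarray:
    """Exact discretization of an Ornstein-Uhlenbeck process."""
    from scipy.signal import lfilter

    rho = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - rho ** 2)
    start = rng.normal(0, sd) if x0 is None else x0 - mean
    eps = np.concatenate([[start], rng.normal(0.0, innov_sd, size=n - 1)])
    # AR(1) recursion x_i = rho * x_{i-1} + eps_i as an IIR filter
    return mean + lfilter([1.0], [1.0, -rho], eps)


def evoked_kernel(t: np.ndarray, kernel: KernelTruth) -> np.ndarray:
    """Difference-of-exponentials transient, peak-normalized to 1."""
    tt = np.asarray(t, dtype=float) - kernel.latency_s
    k = np.where(tt > 0, np.exp(-tt / kernel.decay_s) - np.exp(-tt / kernel.rise_s), 0.0)
    tpk = (np.log(kernel.decay_s / kernel.rise_s)
           * kernel.rise_s * kernel.decay_s / (kernel.decay_s - kernel.rise_s))
    peak = np.exp(-tpk / kernel.decay_s) - np.exp(-tpk / kernel.rise_s)
    return k / peak


def kernel_window_factor(kernel: KernelTruth, response_window: tuple[float, float],
                         baseline_window: tuple[float, float], rate: float = 1000.0) -> float:
    """Mean of the unit kernel over the response window minus the baseline window.

    The evoked scalar of a noiseless trial equals the surface value times
    this factor; used by recovery tests to undo the windowing attenuation.
    """
    def wmean(w):
        t = np.arange(w[0], w[1], 1.0 / rate)
        return float(np.mean(evoked_kernel(t, kernel)))

    return wmean(response_window) - wmean(baseline_window)


def _mean_preserving_lognormal(rng, sigma, size):
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=size))


# ---------------------------------------------------------------------------
# trial-scalar fast path


def generate_trial_scalars(protocol: list[StimTrain], truth: GroundTruthParams,
                           seed: int = 0) -> pd.DataFrame:
    """Draw trial-level evoked scalars directly from the generative model.

    Statistically identical to running the full time-series simulation
    followed by perfect epoching (windowing factor 1): response =
    surface(A, W, R) x mean-preserving log-normal + additive Gaussian.
    Pupil and calcium share the multiplicative trial factor through the
    routed proportion, which is what makes calcium a partial mediator of
    the parameter -> pupil path.
    """
    rng = np.random.default_rng(seed)
    A = np.array([e.amplitude for e in protocol])
    W = np.array([e.width for e in protocol])
    R = np.array([e.rate for e in protocol])
    n = len(protocol)
    rho = truth.calcium_route_proportion
    shared = _mean_preserving_lognormal(rng, truth.trial_lognormal_sigma, n)
    own = _mean_preserving_lognormal(rng, truth.trial_lognormal_sigma, n)
    pupil_gain = rho * shared + (1.0 - rho) * own

    df = pd.DataFrame({
        "onset_s": [e.onset for e in protocol],
        "amplitude_ma": A, "width_ms": W, "rate_hz": R, "charge_uc": A * W,
    })
    surf = truth.surfaces
    df["response_pupil"] = (surf["pupil"].evaluate(A, W, R) * pupil_gain
                            + rng.normal(0, truth.scalar_noise_sd, n))
    df["response_eyelid"] = (surf["eyelid"].evaluate(A, W, R)
                             * _mean_preserving_lognormal(rng, truth.trial_lognormal_sigma, n)
                             + rng.normal(0, truth.scalar_noise_sd, n))
    df["response_calcium"] = (surf["calcium"].evaluate(A, W, R) * shared
                              + rng.normal(0, truth.scalar_noise_sd, n))
    p_walk = np.clip(surf["walk_prob"].evaluate(A, W, R), 0, 1)
    walked = rng.random(n) < p_walk
    df["walk_speed"] = np.where(
        walked, truth.walk_speed_scale * _mean_preserving_lognormal(rng, 0.2, n),
        rng.normal(0, 0.01, n))
    df["walked"] = np.abs(df["walk_speed"]) > 0.05
    df["artifact"] = False
    return df


# ---------------------------------------------------------------------------
# full session simulation


def _insert_bouts(v: np.ndarray, t: np.ndarray, onsets: np.ndarray,
                  truth: GroundTruthParams, rng) -> None:
    for onset in onsets:
        speed = truth.walk_speed_scale * float(_mean_preserving_lognormal(rng, 0.2, 1)[0])
        rel = t - onset
        core = (rel >= 0) & (rel < 10.0)
        tail = rel >= 10.0
        v[core] += speed
        v[tail] += speed * np.exp(-(rel[tail] - 10.0) / truth.walk_decay_s)


def generate_session(protocol: list[StimTrain], truth: GroundTruthParams | None = None,
                     duration: float | None = None, seed: int = 0,
                     meta: SessionMeta | None = None,
                     with_calcium: bool | None = None,
                     pupil_rate: float | None = None) -> tuple[SessionRecord, dict]:
    """Simulate one full recording session.

    Returns ``(record, truth_annotations)`` where the annotations hold the
    per-trial generative evoked amplitudes for recovery tests.

    Channels and native rates: pupil/eyelid/eye position at the camera rate
    (143 Hz standard setup, 15 Hz imaging setup), velocity at 50 Hz,
    calcium (imaging sessions) at 15 Hz.
    """
    truth = truth or GroundTruthParams()
    meta = meta or SessionMeta()
    rng = np.random.default_rng(seed)
    lum = meta.luminance_class
    if with_calcium is None:
        with_calcium = meta.experiment_kind == "axon_imaging"
    if pupil_rate is None:
        pupil_rate = 15.0 if lum == "imaging" else 143.0

    if duration is None:
        duration = (protocol[-1].onset + 60.0) if protocol else 300.0
    if protocol and protocol[-1].onset + protocol[-1].duration > duration:
        raise ValueError("protocol overruns the session duration")

    A = np.array([e.amplitude for e in protocol])
    W = np.array([e.width for e in protocol])
    R = np.array([e.rate for e in protocol])
    onsets = np.array([e.onset for e in protocol])
    n_ev = len(protocol)
    surf = truth.surfaces

    rho = truth.calcium_route_proportion
    shared = _mean_preserving_lognormal(rng, truth.trial_lognormal_sigma, n_ev)
    own = _mean_preserving_lognormal(rng, truth.trial_lognormal_sigma, n_ev)
    pupil_amp = surf["pupil"].evaluate(A, W, R) * (rho * shared + (1 - rho) * own)
    eyelid_amp = (surf["eyelid"].evaluate(A, W, R)
                  * _mean_preserving_lognormal(rng, truth.trial_lognormal_sigma, n_ev))
    calcium_amp = surf["calcium"].evaluate(A, W, R) * shared

    def add_transients(base, t, amps, kernel):
        out = base.copy()
        for onset, amp in zip(onsets, amps):
            sel = (t >= onset) & (t < onset + 8 * kernel.decay_s)
            out[sel] += amp * evoked_kernel(t[sel] - onset, kernel)
        return out

    channels: dict[str, Channel] = {}

    # --- pupil & eyelid ----------------------------------------------------
    tp = np.arange(0.0, duration, 1.0 / pupil_rate)
    base = ou_process(tp.size, 1.0 / pupil_rate, truth.baseline.tau_s,
                      truth.baseline.sd, truth.baseline.mean, rng)
    pupil_kernel = truth.kernels["imaging" if lum == "imaging" else "standard"]
    pupil = add_transients(base, tp, pupil_amp, pupil_kernel)
    pupil += rng.normal(0, truth.sample_noise_sd, tp.size)

    eyelid_base = 0.5 * (base - truth.baseline.mean) + truth.baseline.mean \
        + ou_process(tp.size, 1.0 / pupil_rate, truth.baseline.tau_s,
                     0.5 * truth.baseline.sd, 0.0, rng)
    eyelid = add_transients(eyelid_base, tp, eyelid_amp, pupil_kernel)
    eyelid += rng.normal(0, truth.sample_noise_sd, tp.size)

    # blinks: dropouts (ellipse-fit failure -> NaN) with spiky edges
    n_blinks = rng.poisson(truth.blink_rate_per_min * duration / 60.0)
    blink_starts = rng.uniform(0, duration, n_blinks)
    for b0 in blink_starts:
        dur = rng.exponential(truth.blink_duration_s)
        sel = (tp >= b0) & (tp < b0 + dur)
        edge = (tp >= b0 - 0.05) & (tp < b0)
        pupil[edge] *= 0.6  # lid occlusion transient
        eyelid[edge] *= 0.6
        pupil[sel] = np.nan
        eyelid[sel] = np.nan
    channels["pupil"] = Channel(tp, pupil)
    channels["eyelid"] = Channel(tp, eyelid)

    # --- eye position -------------------------------------------------------
    for name in ("eye_x", "eye_y"):
        pos = ou_process(tp.size, 1.0 / pupil_rate, 2.0, 1.0, 0.0, rng)
        if meta.grounded:
            for e in protocol:
                sel = (tp >= e.onset) & (tp < e.onset + e.duration)
                pos[sel] += truth.grounded_wiggle_z * np.sin(
                    2 * np.pi * e.rate * (tp[sel] - e.onset))
        pos[np.isnan(pupil)] = np.nan
        channels[name] = Channel(tp, pos)

    # --- velocity ------------------------------------------------------------
    tv = np.arange(0.0, duration, 1.0 / 50.0)
    v = rng.normal(0, 0.01, tv.size)
    n_spont = rng.poisson(truth.spont_walk_rate_per_min * duration / 60.0)
    _insert_bouts(v, tv, rng.uniform(0, duration, n_spont), truth, rng)
    p_walk = np.clip(surf["walk_prob"].evaluate(A, W, R), 0, 1) if n_ev else np.empty(0)
    walked = rng.random(n_ev) < p_walk
    _insert_bouts(v, tv, onsets[walked], truth, rng)
    channels["velocity"] = Channel(tv, v)

    # --- calcium -------------------------------------------------------------
    if with_calcium:
        tc = np.arange(0.0, duration, 1.0 / 15.0)
        cbase = ou_process(tc.size, 1.0 / 15.0, truth.baseline.tau_s, 2.0, 30.0, rng)
        cbase -= (tc / duration) * 3.0  # bleaching rundown, removed by detrending
        cal = add_transients(cbase, tc, calcium_amp, truth.kernels["calcium"])
        cal += rng.normal(0, truth.sample_noise_sd, tc.size)
        channels["fluorescence"] = Channel(tc, cal)

    record = SessionRecord(channels=channels, events=list(protocol), meta=meta)
    annotations = {
        "seed": seed,
        "truth": truth.to_dict(),
        "evoked_amplitudes": {
            "pupil": pupil_amp.tolist(),
            "eyelid": eyelid_amp.tolist(),
            "calcium": calcium_amp.tolist(),
            "walked": walked.tolist(),
        },
    }
    return record, annotations


# ---------------------------------------------------------------------------
# image stack / measured current / mediation fixtures


def generate_image_stack(truth: GroundTruthParams, protocol: list[StimTrain],
                         shape: tuple[int, int] = (64, 64), seed: int = 0,
                         mask_pixels: int = 900, effect_size: float = 1.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial evoked-response pixel maps plus the ground-truth axon mask.

    Background pixels are unit-variance noise; pixels inside a contiguous
    disk ("axon plexus") add an evoked response proportional to the calcium
    surface at that trial's parameters, scaled so the per-pixel effect size
    (mean/SD across trials) averages ``effect_size``.  A ``mask_pixels`` of
    0 yields a pure-null stack.
    """
    if shape[0] > 128 or shape[1] > 128:
        raise ValueError("desk-scale stacks only (<= 128 x 128)")
    rng = np.random.default_rng(seed)
    n = len(protocol)
    stack = rng.normal(0.0, 1.0, size=(n, *shape))
    mask = np.zeros(shape, dtype=bool)
    if mask_pixels > 0:
        r = np.sqrt(mask_pixels / np.pi)
        cy, cx = shape[0] / 2, shape[1] / 2
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        d2 = (yy - cy + 0.5) ** 2 + (xx - cx + 0.5) ** 2
        order = np.argsort(d2.ravel())
        mask.ravel()[order[:mask_pixels]] = True
        A = np.array([e.amplitude for e in protocol])
        W = np.array([e.width for e in protocol])
        R = np.array([e.rate for e in protocol])
        amp = truth.surfaces["calcium"].evaluate(A, W, R)
        m = float(np.mean(amp))
        if m > 0:
            amp = amp * (effect_size / m)
        stack[:, mask] += amp[:, None]
    return stack, mask


def generate_measured_current(trains: list[StimTrain], truth: GroundTruthParams,
                              noise_sd: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Per-train measured pulse amplitudes with leak and width filtering.

    measured = intended x (1 - L) x sigmoidal width filter (plateau 1).
    """
    el = truth.electronics
    if not 0.0 <= el.leak < 1.0:
        raise ValueError("leak fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    A = np.array([e.amplitude for e in trains])
    W = np.array([e.width for e in trains])
    measured = A * (1.0 - el.leak) * el.width_filter(W)
    if noise_sd > 0:
        measured = measured + rng.normal(0, noise_sd, measured.size)
    return pd.DataFrame({
        "train": np.arange(len(trains)),
        "width_ms": W,
        "rate_hz": [e.rate for e in trains],
        "intended_ma": A,
        "measured_ma": measured,
    })


def generate_mediation_trials(protocol: list[StimTrain], truth: GroundTruthParams | None = None,
                              a: float = 1.0, b: float = 0.5, c_direct: float = 0.5,
                              noise_scale: float = 0.5, seed: int = 0) -> pd.DataFrame:
    """Trials with an explicit mediation structure for path-analysis tests.

    N is the true engagement (pupil surface at the trial parameters);
    C = a*N + noise, P = c_direct*N + b*C + noise.  The true proportion
    mediated is a*b / (c_direct + a*b) (0.5 at the defaults).  Noise SDs are
    ``noise_scale`` times the SD of the respective signal component.
    """
    truth = truth or GroundTruthParams()
    rng = np.random.default_rng(seed)
    A = np.array([e.amplitude for e in protocol])
    W = np.array([e.width for e in protocol])
    R = np.array([e.rate for e in protocol])
    N = truth.surfaces["pupil"].evaluate(A, W, R)
    sd_n = float(np.std(N)) or 1.0
    C = a * N + rng.normal(0, noise_scale * abs(a) * sd_n, N.size)
    P = c_direct * N + b * C + rng.normal(
        0, noise_scale * float(np.std(c_direct * N + b * a * N)) if np.std(N) else 1.0,
        N.size)
    return pd.DataFrame({
        "amplitude_ma": A, "width_ms": W, "rate_hz": R, "charge_uc": A * W,
        "engagement_true": N, "response_calcium": C, "response_pupil": P,
        "artifact": False,
    })
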