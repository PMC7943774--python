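"""Auxiliary statistics: sequential polynomial regression, BH-FDR,
cluster-based sign-flip permutation testing of pixel maps, and phase-locked
spectral power of eye movements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal as sps, stats as spstats
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# sequential polynomial regression (constant -> linear -> quadratic)


@dataclass
class PolyFitResult:
    coefficients: np.ndarray      # on the orthogonalized regressors
    f_stats: list[float]          # incremental F per added order (1..max)
    f_dof: list[tuple[int, int]]
    f_pvalues: list[float]
    bic: list[float]              # per order 0..max
    selected_order: int           # by sequential F tests
    selected_order_bic: int       # by BIC with a delta >= 10 rule
    fitted: np.ndarray


def sequential_poly_regression(Y, X, max_order: int = 2,
                               alpha: float = 0.05) -> PolyFitResult:
    """Test whether higher polynomial orders of X explain Y significantly.

    Builds the design [1, X, X^2, ...], orthogonalizes the columns by QR
    decomposition, and adds one order at a time.  Each step's F statistic is
    the drop in residual sum of squares over the residual mean square of the
    *highest-order* model, F = (SS_{k-1} - SS_k) / (SS_full / df_full).
    BIC per order uses the Gaussian form n*ln(SS/n) + k*ln(n) (additive
    constants cancel in comparisons); a higher order is preferred by BIC
    only when it improves BIC by at least 10.
    """
    y = np.asarray(Y, dtype=float)
    x = np.asarray(X, dtype=float)
    n = y.size
    if x.size != n:
        raise ValueError("Y and X must have equal length")
    if not np.all(np.isfinite(x)) or not np.all(np.isfinite(y)):
        raise ValueError("Y and X must be finite")
    if np.ptp(x) == 0:
        raise ValueError("X is constant; polynomial regression undefined")
    if n <= max_order + 1:
        raise ValueError("need n > max_order + 1 observations")

    design = np.column_stack([x ** k for k in range(max_order + 1)])
    Q, _ = np.linalg.qr(design)

    ss_res = []
    coefs = np.zeros(max_order + 1)
    for k in range(max_order + 1):
        Qk = Q[:, : k + 1]
        beta = Qk.T @ y  # orthonormal columns: OLS is a projection
        resid = y - Qk @ beta
        ss_res.append(float(resid @ resid))
        coefs[: k + 1] = beta
    fitted = Q @ coefs

    df_full = n - (max_order + 1)
    mse_full = ss_res[-1] / df_full
    f_stats, f_p, f_dof = [], [], []
    for k in range(1, max_order + 1):
        F = (ss_res[k - 1] - ss_res[k]) / mse_full if mse_full > 0 else np.inf
        f_stats.append(float(F))
        f_dof.append((1, df_full))
        f_p.append(float(spstats.f.sf(F, 1, df_full)))

    selected = 0
    for k in range(1, max_order + 1):
        if f_p[k - 1] < alpha:
            selected = k
        else:
            break

    bic = [n * np.log(ss / n) + (k + 1) * np.log(n) for k, ss in enumerate(ss_res)]
    selected_bic = 0
    for k in range(1, max_order + 1):
        if bic[selected_bic] - bic[k] >= 10.0:
            selected_bic = k
    return PolyFitResult(coefficients=coefs, f_stats=f_stats, f_dof=f_dof,
                         f_pvalues=f_p, bic=[float(b) for b in bic],
                         selected_order=selected, selected_order_bic=selected_bic,
                         fitted=fitted)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg FDR


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Step-up Benjamini-Hochberg correction.

    Returns (adjusted p, rejection mask).  NaN entries are excluded from the
    family and returned as NaN / not rejected.
    """
    p = np.asarray(p_values, dtype=float)
    adj = np.full(p.shape, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        r, a, *_ = multipletests(p[ok], alpha=q, method="fdr_bh")
        adj[ok] = a
        rej[ok] = r
    return adj, rej


# ---------------------------------------------------------------------------
# cluster-based permutation test on pixel maps


@dataclass
class ClusterMap:
    t_map: np.ndarray                 # per-pixel one-sample t
    clusters: list[np.ndarray]        # boolean masks, one per candidate cluster
    cluster_p: list[float]
    significant_mask: np.ndarray
    n_significant: int
    threshold_t: float


def _cluster_stats(t_map: np.ndarray, thresh: float) -> tuple[list[np.ndarray], list[float]]:
    """4-connected clusters of supra-threshold pixels, scored by summed t.

    Positive and negative excursions are clustered separately (two-tailed).
    """
    masks, sums = [], []
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for sign in (1.0, -1.0):
        lab, n = ndimage.label(sign * t_map > thresh, structure=structure)
        for i in range(1, n + 1):
            m = lab == i
            masks.append(m)
            sums.append(float(np.abs(t_map[m].sum())))
    return masks, sums


def _t_map(data: np.ndarray) -> np.ndarray:
    # one-sample t across trials (axis 0); zero-variance pixels -> t = 0
    n = data.shape[0]
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def cluster_permutation_map(pixel_epochs: np.ndarray, n_perm: int = 10000,
                            cluster_alpha: float = 0.01,
                            forming_alpha: float = 0.05,
                            seed: int = 0) -> ClusterMap:
    """Cluster-corrected pixelwise one-sample test of evoked responses.

    ``pixel_epochs``: trials × height × width per-trial response maps.  Per
    pixel a one-sample t against 0 is computed; 4-connected clusters of
    pixels exceeding the two-sided ``forming_alpha`` t threshold are scored
    by their summed t; the null distribution of the maximum cluster score is
    built from random per-trial sign flips, and cluster-level
    p = (1 + #null >= observed) / (1 + n_perm).  Clusters with p below
    ``cluster_alpha`` form the significant mask.
    """
    data = np.asarray(pixel_epochs, dtype=float)
    if data.ndim != 3:
        raise ValueError("pixel_epochs must be trials x height x width")
    n_trials = data.shape[0]
    if n_trials < 8:
        raise ValueError("need at least 8 trials")
    thresh = float(spstats.t.ppf(1 - forming_alpha / 2, n_trials - 1))

    t_obs = _t_map(data)
    masks, sums = _cluster_stats(t_obs, thresh)

    rng = np.random.default_rng(seed)
    flat = data.reshape(n_trials, -1)
    # sign flips leave E[x^2] untouched, so the flipped-sample variance is
    # (msq - m^2) * n/(n-1) -- no need to touch the full matrix per draw
    msq = (flat ** 2).mean(axis=0)
    null_max = np.empty(n_perm)
    shape = data.shape[1:]
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n_trials)
        m = signs @ flat / n_trials
        var = np.maximum(msq - m ** 2, 0.0) * n_trials / (n_trials - 1)
        sd = np.sqrt(var)
        sd[sd == 0] = np.inf  # zero-variance pixels can never pass threshold
        t_p = (m / (sd / np.sqrt(n_trials))).reshape(shape)
        _, s = _cluster_stats(t_p, thresh)
        null_max[i] = max(s) if s else 0.0

    pvals = [float((1 + np.sum(null_max >= s)) / (1 + n_perm)) for s in sums]
    sig = np.zeros(shape, dtype=bool)
    for m, p in zip(masks, pvals):
        if p < cluster_alpha:
            sig |= m
    return ClusterMap(t_map=t_obs, clusters=masks, cluster_p=pvals,
                      significant_mask=sig, n_significant=int(sig.sum()),
                      threshold_t=thresh)


# ---------------------------------------------------------------------------
# phase-locked eye-movement power


@dataclass
class SpectralResult:
    freqs: np.ndarray
    times: np.ndarray                  # window-centre times relative to onset
    power_change: np.ndarray           # freq x time, % change vs baseline
    phase_locked_power: float          # scalar at the train rate over the train
    rate_bin_hz: float


def phase_locked_power(epochs: np.ndarray, rate_hz: float, fs: float,
                       epoch_start: float, train_window: tuple[float, float] = (0.0, 10.0),
                       baseline_window: tuple[float, float] = (-5.5, -0.5),
                       win_s: float = 1.0, hop_s: float = 0.25) -> SpectralResult:
    """Time-frequency power of epoched eye position, phase-locked scalar.

    A 1-s Hann-window spectrogram (hop 0.25 s) is computed per trial and
    averaged; power per frequency is expressed as percent change from the
    pre-stimulation baseline window, and the scalar is the mean change at
    the frequency bin nearest the train rate over the 10-s train.
    """
    x = np.atleast_2d(np.asarray(epochs, dtype=float))
    if rate_hz >= fs / 2:
        raise ValueError("train rate at or above Nyquist of the conditioned signal")
    nper = int(round(win_s * fs))
    hop = int(round(hop_s * fs))
    freqs, times, S = sps.spectrogram(x, fs=fs, window=sps.get_window("hann", nper),
                                      nperseg=nper, noverlap=nper - hop,
                                      mode="psd", axis=-1)
    power = S.mean(axis=0)  # freq x time, averaged over trials
    times = times + epoch_start

    base = (times >= baseline_window[0]) & (times < baseline_window[1])
    if not base.any():
        raise ValueError("epoch does not cover the baseline window")
    base_power = power[:, base].mean(axis=1, keepdims=True)
    base_power[base_power == 0] = np.nan
    change = 100.0 * (power - base_power) / base_power

    fi = int(np.argmin(np.abs(freqs - rate_hz)))
    during = (times >= train_window[0]) & (times < train_window[1])
    if not during.any():
        raise ValueError("epoch does not cover the train window")
    scalar = float(np.nanmean(change[fi, during]))
    return SpectralResult(freqs=freqs, times=times, power_change=change,
                          phase_locked_power=scalar, rate_bin_hz=float(freqs[fi]))
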