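"""Multivariate log-logistic dose-response surfaces and charge-bin statistics.

The evoked response P is modelled as a separable product of log-logistic
growth terms in the stimulation parameters.  Full model (amplitude A [mA],
width W [ms], rate R [Hz]):

    P = s / (1 + (A/a1)^-b1) * 1 / (1 + (W/a2)^-b2) * 1 / (1 + (R/a3)^-b3)

Reduced model (charge per pulse C = A*W [μC], rate R):

    P = s / (1 + (C/a1)^-b1) * 1 / (1 + (R/a2)^-b2)

Each location parameter ``a_i`` is the half-maximal value of its factor
(log-logistic midpoint); in particular the reduced-model ``a1`` is the
charge at half-maximal response.  Fits are trial-level nonlinear least
squares with a small multi-start grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .stats import bh_fdr

FULL_PARAM_NAMES = ("s", "a1", "b1", "a2", "b2", "a3", "b3")
REDUCED_PARAM_NAMES = ("s", "a1", "b1", "a2", "b2")


def loglogistic_term(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """Single log-logistic growth factor 1 / (1 + (x/a)^-b), in (0, 1)."""
    x = np.asarray(x, dtype=float)
    return 1.0 / (1.0 + (x / a) ** (-b))


def surface_full(A, W, R, s, a1, b1, a2, b2, a3, b3) -> np.ndarray:
    return (s * loglogistic_term(A, a1, b1) * loglogistic_term(W, a2, b2)
            * loglogistic_term(R, a3, b3))


def surface_reduced(C, R, s, a1, b1, a2, b2) -> np.ndarray:
    return s * loglogistic_term(C, a1, b1) * loglogistic_term(R, a2, b2)


@dataclass
class LogLogisticFit:
    """Fitted surface parameters with fit quality and optional bootstrap draws."""

    model: str  # "full" or "reduced"
    params: dict[str, float]
    variance_explained: float  # percent of trialwise variance
    n_trials: int
    ss_res: float
    ss_tot: float
    start_losses: list = field(default_factory=list)
    bootstrap: np.ndarray | None = None  # draws x params

    @property
    def param_names(self) -> tuple[str, ...]:
        return FULL_PARAM_NAMES if self.model == "full" else REDUCED_PARAM_NAMES

    def predict(self, trials: pd.DataFrame) -> np.ndarray:
        p = self.params
        if self.model == "full":
            return surface_full(trials["amplitude_ma"].to_numpy(),
                                trials["width_ms"].to_numpy(),
                                trials["rate_hz"].to_numpy(),
                                p["s"], p["a1"], p["b1"], p["a2"], p["b2"],
                                p["a3"], p["b3"])
        return surface_reduced(trials["charge_uc"].to_numpy(),
                               trials["rate_hz"].to_numpy(),
                               p["s"], p["a1"], p["b1"], p["a2"], p["b2"])

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "params": dict(self.params),
            "variance_explained": self.variance_explained,
            "n_trials": self.n_trials,
            "ss_res": self.ss_res,
            "ss_tot": self.ss_tot,
        }
        if self.bootstrap is not None:
            d["bootstrap_sd"] = {
                name: float(np.std(self.bootstrap[:, i]))
                for i, name in enumerate(self.param_names)
            }
        return d


def _factors(trials: pd.DataFrame, model: str) -> list[np.ndarray]:
    if model == "full":
        cols = ("amplitude_ma", "width_ms", "rate_hz")
    elif model == "reduced":
        cols = ("charge_uc", "rate_hz")
    else:
        raise ValueError(f"model must be 'full' or 'reduced', got {model!r}")
    return [trials[c].to_numpy(dtype=float) for c in cols]


def _surface_eval(theta: np.ndarray, factors: list[np.ndarray]) -> np.ndarray:
    out = np.full(factors[0].shape, theta[0])
    for i, x in enumerate(factors):
        out = out * loglogistic_term(x, theta[1 + 2 * i], theta[2 + 2 * i])
    return out


def fit_surface(trials: pd.DataFrame, response: str = "response_pupil",
                model: str = "reduced", positive_scale: bool = True,
                x0: np.ndarray | None = None) -> LogLogisticFit:
    """Fit the log-logistic surface to trialwise responses by least squares.

    Artifact-flagged rows (column ``artifact``, if present) are excluded.
    Multi-start initialisation: location parameters at the {25, 50, 75}th
    percentile of each factor's values, shape parameters at {1, 2}; a
    warm start ``x0`` replaces the grid (used by bootstrap refits).
    """
    t = trials
    if "artifact" in t.columns:
        t = t.loc[~t["artifact"].astype(bool)]
    y = t[response].to_numpy(dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite for all non-artifact trials")
    factors = _factors(t, model)
    for x in factors:
        if np.any(x <= 0):
            raise ValueError("all stimulation factor values must be > 0")
    k = len(factors)

    lo = np.empty(1 + 2 * k)
    hi = np.empty(1 + 2 * k)
    # the saturation parameter is bounded by the data scale: when the tested
    # range ends below the plateau, s and the midpoint are only jointly
    # identified through s/a^b, and an unbounded s lets the fit escape along
    # that power-law ridge
    s_cap = 5.0 * _max_abs_cell_mean(t, response, model)
    if s_cap == 0:
        s_cap = 1e-6
    lo[0], hi[0] = (0.0, s_cap) if positive_scale else (-s_cap, s_cap)
    for i, x in enumerate(factors):
        lo[1 + 2 * i], hi[1 + 2 * i] = x.min() / 10.0, x.max() * 10.0
        lo[2 + 2 * i], hi[2 + 2 * i] = 0.1, 20.0

    if x0 is not None:
        starts = [np.clip(np.asarray(x0, dtype=float), lo + 1e-12, hi)]
    else:
        s0 = _max_cell_mean(t, response, model)
        if positive_scale:
            s0 = max(s0, 1e-6)
        starts = []
        for q in (25.0, 50.0, 75.0):
            a0 = [np.percentile(x, q) for x in factors]
            for b0 in (1.0, 2.0):
                theta = [s0]
                for a in a0:
                    theta += [a, b0]
                starts.append(np.clip(np.asarray(theta), lo + 1e-12, hi))

    def resid(theta):
        return _surface_eval(theta, factors) - y

    best = None
    losses = []
    for theta0 in starts:
        try:
            sol = optimize.least_squares(resid, theta0, bounds=(lo, hi),
                                         method="trf", xtol=1e-10, ftol=1e-10)
        except Exception:
            continue
        losses.append(float(sol.cost))
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(f"surface fit failed to converge from all {len(starts)} starts")

    theta = best.x
    pred = _surface_eval(theta, factors)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    ve = 100.0 * (1.0 - ss_res / ss_tot) if ss_tot > 0 else 0.0
    names = FULL_PARAM_NAMES if model == "full" else REDUCED_PARAM_NAMES
    return LogLogisticFit(model=model, params=dict(zip(names, map(float, theta))),
                          variance_explained=ve, n_trials=int(y.size),
                          ss_res=ss_res, ss_tot=ss_tot, start_losses=losses)


def _max_cell_mean(trials: pd.DataFrame, response: str, model: str) -> float:
    keys = (["amplitude_ma", "width_ms", "rate_hz"] if model == "full"
            else ["charge_uc", "rate_hz"])
    return float(trials.groupby(keys)[response].mean().max())


def _max_abs_cell_mean(trials: pd.DataFrame, response: str, model: str) -> float:
    keys = (["amplitude_ma", "width_ms", "rate_hz"] if model == "full"
            else ["charge_uc", "rate_hz"])
    return float(trials.groupby(keys)[response].mean().abs().max())


def compare_full_vs_reduced(trials: pd.DataFrame,
                            response: str = "response_pupil",
                            positive_scale: bool = True) -> dict:
    """Variance explained by the full (A, W, R) vs reduced (C, R) surface."""
    full = fit_surface(trials, response, model="full", positive_scale=positive_scale)
    reduced = fit_surface(trials, response, model="reduced", positive_scale=positive_scale)
    return {
        "variance_explained_full": full.variance_explained,
        "variance_explained_reduced": reduced.variance_explained,
        "difference": full.variance_explained - reduced.variance_explained,
        "full": full,
        "reduced": reduced,
    }


# ---------------------------------------------------------------------------
# charge bins


@dataclass
class ChargeBinSummary:
    edges: np.ndarray  # n_bins + 1 edges, μC, log-spaced
    labels: list[str]
    assignment: pd.Series  # per-trial bin index (1-based)
    table: pd.DataFrame | None = None  # per bin x rate statistics

    def mapping_table(self, trials: pd.DataFrame) -> pd.DataFrame:
        """Unique (amplitude, width) → bin mapping, for comparison with the grid figure."""
        df = trials.assign(charge_bin=self.assignment.values)
        return (df.groupby(["amplitude_ma", "width_ms"])
                  .agg(charge_uc=("charge_uc", "first"), charge_bin=("charge_bin", "first"))
                  .reset_index())


def bin_labels(n_bins: int) -> list[str]:
    # lowest bin: no effect; highest: off-target current spread; middle: optimal
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    return (["no-effect"] + ["optimal"] * (n_bins - 2) + ["off-target"])


def assign_charge_bins(trials: pd.DataFrame, n_bins: int = 5) -> ChargeBinSummary:
    """Label every trial with one of ``n_bins`` log-spaced charge/pulse bins.

    Edges are equally spaced in log10 over the tested charge range; the top
    edge is inclusive so the maximum tested charge falls in the last bin.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    c = trials["charge_uc"].to_numpy(dtype=float)
    if np.any(c <= 0):
        raise ValueError("charges must be > 0")
    lo, hi = c.min(), c.max()
    if lo == hi:
        import warnings

        warnings.warn("all trials share one charge; single occupied bin")
        hi = lo * (1 + 1e-9)
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, c, side="right") - 1, 0, n_bins - 1) + 1
    return ChargeBinSummary(edges=edges, labels=bin_labels(n_bins),
                            assignment=pd.Series(idx, index=trials.index, name="charge_bin"))


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def binwise_tests(trials: pd.DataFrame, bins: ChargeBinSummary,
                  response: str = "response_pupil", mode: str = "vs_zero",
                  q: float = 0.05) -> ChargeBinSummary:
    """Per (charge bin × rate) significance tests with BH-FDR correction.

    ``vs_zero``: two-sided one-sample t test of the responses against 0
    (pupil, eyelid, walking).  ``vs_lowest_bin``: two-sided paired t test of
    each of the upper bins against the lowest bin at the same rate — used
    for the calcium responses, whose region of interest was defined by their
    own significance and must not be re-tested against zero.  Pairing is by
    within-cell rank order after sorting by charge then trial order; unequal
    cells are truncated to the shorter.
    """
    df = trials.copy()
    if "artifact" in df.columns:
        df = df.loc[~df["artifact"].astype(bool)]
    df["charge_bin"] = bins.assignment.reindex(df.index)
    rows = []
    n_bins = len(bins.edges) - 1
    for rate, g in df.groupby("rate_hz"):
        lowest = g.loc[g["charge_bin"] == 1, response].to_numpy()
        for b in range(1, n_bins + 1):
            cell = g.loc[g["charge_bin"] == b, response].to_numpy()
            row = {"rate_hz": rate, "charge_bin": b, "label": bins.labels[b - 1],
                   "n": int(cell.size), "mean": float(np.mean(cell)) if cell.size else np.nan,
                   "sem": float(stats.sem(cell)) if cell.size > 1 else np.nan,
                   "stat": np.nan, "p": np.nan}
            if mode == "vs_zero":
                if cell.size >= 2:
                    t, p = stats.ttest_1samp(cell, 0.0)
                    row["stat"], row["p"] = float(t), float(p)
            elif mode == "vs_lowest_bin":
                if b > 1 and cell.size >= 2 and lowest.size >= 2:
                    m = min(cell.size, lowest.size)
                    a = np.sort(cell)[:m]
                    ref = np.sort(lowest)[:m]
                    t, p = stats.ttest_rel(a, ref)
                    row["stat"], row["p"] = float(t), float(p)
            else:
                raise ValueError("mode must be 'vs_zero' or 'vs_lowest_bin'")
            rows.append(row)
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    adj = np.full(len(table), np.nan)
    rej = np.zeros(len(table), dtype=bool)
    if tested.any():
        adj_t, rej_t = bh_fdr(table.loc[tested, "p"].to_numpy(), q=q)
        adj[tested.to_numpy()] = adj_t
        rej[tested.to_numpy()] = rej_t
    table["p_fdr"] = adj
    table["significant"] = rej
    table["stars"] = [_stars(p) for p in table["p_fdr"]]
    return ChargeBinSummary(edges=bins.edges, labels=bins.labels,
                            assignment=bins.assignment, table=table)


# ---------------------------------------------------------------------------
# half-maximal charge


def half_max_charge(trials: pd.DataFrame, response: str = "response_pupil",
                    n_boot: int = 5000, seed: int = 0,
                    positive_scale: bool = True) -> dict:
    """Charge at half-maximal response: the reduced-model midpoint ``a1``.

    Uncertainty is the SD of ``a1`` over ``n_boot`` trial-resampled refits
    (warm-started at the full-sample solution).
    """
    fit = fit_surface(trials, response, model="reduced", positive_scale=positive_scale)
    rng = np.random.default_rng(seed)
    theta0 = np.array([fit.params[k] for k in REDUCED_PARAM_NAMES])
    t = trials
    if "artifact" in t.columns:
        t = t.loc[~t["artifact"].astype(bool)]
    n = len(t)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            bfit = fit_surface(t.iloc[idx], response, model="reduced",
                               positive_scale=positive_scale, x0=theta0)
            draws.append([bfit.params[k] for k in REDUCED_PARAM_NAMES])
        except Exception:
            failures += 1
    if n_boot and failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    draws = np.asarray(draws) if draws else np.empty((0, len(REDUCED_PARAM_NAMES)))
    fit.bootstrap = draws
    a1 = draws[:, 1] if draws.size else np.empty(0)
    return {
        "estimate_uc": fit.params["a1"],
        "bootstrap_sd_uc": float(np.std(a1)) if a1.size else np.nan,
        "draws_uc": a1,
        "fit": fit,
        "n_failures": failures,
    }


def compare_half_max(draws_1: np.ndarray, draws_2: np.ndarray) -> float:
    """Two-sided bootstrap p for a difference in half-maximal charge.

    p = 2 * min(Pr(diff <= 0), Pr(diff >= 0)) over paired resampled
    differences, floored at 2/n (n = number of paired draws).
    """
    d1 = np.asarray(draws_1, dtype=float)
    d2 = np.asarray(draws_2, dtype=float)
    if d1.size == 0 or d2.size == 0:
        raise ValueError("both draw sets must be nonempty")
    n = min(d1.size, d2.size)
    diff = d1[:n] - d2[:n]
    p = 2.0 * min(np.mean(diff <= 0), np.mean(diff >= 0))
    return float(min(max(p, 2.0 / n), 1.0))
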