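"""Cross-validated nerve engagement and mediation path analysis.

The engagement vector N reduces the three-dimensional stimulation parameter
space to one dimension: for each trial, N is the log-logistic surface
prediction of the pupil response, fitted on the other folds of a 20-fold
cross-validation (so no trial is predicted by a model that saw it).  The
mediation analysis then asks how much of the total parameter -> pupil
effect is routed through the cholinergic calcium response:

    P = i0 + c  N          (total effect)
    C = i1 + a  N          (engagement -> mediator)
    P = i2 + c' N + b C    (direct + mediator -> outcome)

indirect effect = a*b, proportion mediated = a*b / c.  For OLS on a common
sample the identity c = c' + a*b holds exactly.  Inference is by
trial-resampled bootstrap (5000 draws), reporting each effect's draw
distribution and the fraction of draws below zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .dose import assign_charge_bins, fit_surface


@dataclass
class EngagementVector:
    values: np.ndarray
    fold: np.ndarray
    fold_params: list = field(default_factory=list)


def predict_engagement_cv(trials: pd.DataFrame, folds: int = 20, seed: int = 0,
                          response: str = "response_pupil",
                          model: str = "full") -> EngagementVector:
    """Out-of-fold surface predictions of the evoked response.

    Folds are a seeded random partition stratified by charge bin, so every
    training set spans the tested parameter range.  If a fold's surface fit
    fails it is merged into the next fold and refitted.
    """
    n = len(trials)
    if folds < 2 or folds > n:
        raise ValueError("folds must be in [2, n_trials]")
    rng = np.random.default_rng(seed)
    bins = assign_charge_bins(trials, n_bins=min(5, trials["charge_uc"].nunique()))
    fold = np.empty(n, dtype=int)
    for _, idx in pd.Series(np.arange(n)).groupby(bins.assignment.to_numpy()):
        ids = idx.to_numpy()
        rng.shuffle(ids)
        fold[ids] = np.arange(ids.size) % folds
    values = np.full(n, np.nan)
    fold_params = []
    pending: list[int] = []
    for f in range(folds):
        members = list(np.flatnonzero(fold == f)) + pending
        if not members:
            continue
        train = trials.iloc[[i for i in range(n) if i not in set(members)]]
        try:
            fit = fit_surface(train, response=response, model=model)
        except Exception:
            pending = members  # merge into the next fold and retry
            continue
        pending = []
        held = trials.iloc[members]
        values[members] = fit.predict(held)
        fold_params.append({"fold": f, "params": fit.params, "n_train": len(train)})
    if pending:
        raise RuntimeError("surface fit failed even after merging folds")
    return EngagementVector(values=values, fold=fold, fold_params=fold_params)


# ---------------------------------------------------------------------------


def _ols(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


@dataclass
class MediationFit:
    c: float
    a: float
    b: float
    c_prime: float
    intercepts: tuple[float, float, float]
    indirect: float
    proportion_mediated: float | None
    n: int
    se_c: float
    bootstrap: dict | None = None
    sign_fractions: dict | None = None

    def to_dict(self) -> dict:
        d = {
            "c_total": self.c, "a": self.a, "b": self.b, "c_prime": self.c_prime,
            "indirect": self.indirect, "proportion_mediated": self.proportion_mediated,
            "intercepts": list(self.intercepts), "n": self.n, "se_c": self.se_c,
        }
        if self.bootstrap is not None:
            d["bootstrap"] = {
                k: {"mean": float(np.mean(v)),
                    "p2.5": float(np.percentile(v, 2.5)),
                    "p97.5": float(np.percentile(v, 97.5))}
                for k, v in self.bootstrap.items()
            }
            d["sign_fractions"] = self.sign_fractions
        return d


def fit_mediation(P, C, N) -> MediationFit:
    """Three OLS path models on aligned trials (see module docstring)."""
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    n = P.size
    if not (C.size == n and N.size == n):
        raise ValueError("P, C, N must be aligned")
    if n < 4:
        raise ValueError("need more trials than parameters")
    if np.ptp(N) == 0:
        raise ValueError("engagement vector is constant")
    r = np.corrcoef(N, C)[0, 1]
    if abs(r) > 0.999:
        raise ValueError("N and C are collinear (|r| > 0.999)")

    one = np.ones(n)
    Xn = np.column_stack([one, N])
    i0, c = _ols(P, Xn)
    i1, a = _ols(C, Xn)
    i2, c_p, b = _ols(P, np.column_stack([one, N, C]))
    indirect = a * b

    resid = P - Xn @ np.array([i0, c])
    sigma2 = resid @ resid / (n - 2)
    cov = sigma2 * np.linalg.inv(Xn.T @ Xn)
    se_c = float(np.sqrt(cov[1, 1]))
    # the proportion mediated is meaningless when the total effect is
    # indistinguishable from zero
    prop = float(indirect / c) if abs(c) >= 2 * se_c else None
    return MediationFit(c=float(c), a=float(a), b=float(b), c_prime=float(c_p),
                        intercepts=(float(i0), float(i1), float(i2)),
                        indirect=float(indirect), proportion_mediated=prop,
                        n=n, se_c=se_c)


def bootstrap_mediation(P, C, N, n_boot: int = 5000, seed: int = 0,
                        max_degenerate: float = 0.05) -> MediationFit:
    """Trial-resampled bootstrap of the mediation paths.

    Returns the full-sample fit augmented with draw distributions for the
    total, indirect and direct effects and the fraction of draws below zero
    for each.
    """
    fit = fit_mediation(P, C, N)
    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    n = P.size
    rng = np.random.default_rng(seed)
    draws = {"total": [], "indirect": [], "direct": []}
    degenerate = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            f = fit_mediation(P[idx], C[idx], N[idx])
        except (ValueError, np.linalg.LinAlgError):
            degenerate += 1
            continue
        draws["total"].append(f.c)
        draws["indirect"].append(f.indirect)
        draws["direct"].append(f.c_prime)
    if degenerate > max_degenerate * n_boot:
        raise RuntimeError(f"{degenerate}/{n_boot} degenerate bootstrap resamples")
    fit.bootstrap = {k: np.asarray(v) for k, v in draws.items()}
    fit.sign_fractions = {k: float(np.mean(v < 0)) for k, v in fit.bootstrap.items()}
    return fit


def partial_residual_correlation(P, C, N) -> dict:
    """Correlation of pupil and calcium after removing the stimulation effect.

    Residualizes P and C each on [1, N] and correlates the residuals
    (Pearson); also runs the sequential polynomial test on the residual
    relationship to ask whether it is linear or curved.
    """
    from .stats import sequential_poly_regression

    P = np.asarray(P, dtype=float)
    C = np.asarray(C, dtype=float)
    N = np.asarray(N, dtype=float)
    one = np.ones(P.size)
    Xn = np.column_stack([one, N])
    rP = P - Xn @ _ols(P, Xn)
    rC = C - Xn @ _ols(C, Xn)
    r, p = spstats.pearsonr(rC, rP)
    poly = sequential_poly_regression(rP, rC, max_order=2)
    return {"r": float(r), "p": float(p), "poly": poly,
            "residual_P": rP, "residual_C": rC}
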