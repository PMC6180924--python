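"""Repeated-LASSO stability selection and correlation screens.

A single LASSO-Cox fit on a small cohort is unstable: which features carry
nonzero coefficients depends on the sample.  Stability selection therefore
repeats the fit many times (default 1000), each time on a bootstrap resample
of subjects with the penalty chosen by 10-fold cross-validated partial-
likelihood deviance inside the resample, and retains the features whose
selection frequency exceeds one half.

The penalized path itself is solved by the glmnet-style coordinate-descent
implementation in scikit-survival; the unpenalized limit uses a direct
Newton-type maximization of the Breslow partial likelihood.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "breslow_loglik",
    "fit_lasso_cox",
    "StabilityResult",
    "stability_select",
    "correlation_screen",
    "correlation_report",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# partial likelihood


def breslow_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray,
                   event: np.ndarray) -> float:
    """Breslow partial log-likelihood sum_{i:event} [eta_i - log sum_{t_j>=t_i} e^eta_j]."""
    eta = X @ beta
    order = np.argsort(-time, kind="stable")  # descending time
    eta_o = eta[order]
    # log cumulative sum of exp(eta) over the risk set, tie-safe:
    m = eta_o.max()
    cum = np.logaddexp.accumulate(eta_o - m) + m
    t_o = time[order]
    # risk set of t_i is every j with t_j >= t_i: count via the descending order
    n_ge = np.searchsorted(-t_o, -time, side="right")
    log_risk = cum[n_ge - 1]
    mask = event.astype(bool)
    return float(np.sum(eta[mask] - log_risk[mask]))


def _neg_loglik_grad(beta, X, time, event):
    """Negative Breslow log-likelihood and gradient (for the unpenalized fit)."""
    n, p = X.shape
    eta = X @ beta
    w = np.exp(eta - eta.max())
    order = np.argsort(-time, kind="stable")
    w_o = w[order]
    X_o = X[order]
    cum_w = np.cumsum(w_o)
    cum_wx = np.cumsum(w_o[:, None] * X_o, axis=0)
    n_ge = np.searchsorted(-time[order], -time, side="right")
    risk_w = cum_w[n_ge - 1]
    risk_wx = cum_wx[n_ge - 1]
    mask = event.astype(bool)
    ll = np.sum(eta[mask] - (np.log(risk_w[mask]) + eta.max()))
    grad = X[mask].sum(axis=0) - (risk_wx[mask] / risk_w[mask, None]).sum(axis=0)
    return -ll, -grad


def fit_lasso_cox(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                  lam: float) -> np.ndarray:
    """L1-penalized Cox partial-likelihood maximizer at a single penalty.

    Columns are expected to be standardized (mean 0, sd 1); constant columns
    are dropped with a warning and get coefficient 0.  ``lam = 0`` returns
    the unpenalized maximum partial-likelihood solution; large ``lam``
    (above the data's lambda_max) returns the all-zero model.  Coefficients
    outside the active set are exactly zero.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant column(s)", stacklevel=2)
    beta = np.zeros(X.shape[1])
    Xk = X[:, keep]
    if Xk.shape[1] == 0:
        return beta
    if lam == 0.0:
        res = optimize.minimize(_neg_loglik_grad, np.zeros(Xk.shape[1]),
                                args=(Xk, time, event), jac=True, method="BFGS",
                                options={"gtol": 1e-9, "maxiter": 500})
        beta[keep] = res.x
        return beta
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[lam], normalize=False,
                                   fit_baseline_model=False, tol=1e-9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xk, y)
    beta[keep] = model.coef_[:, 0]
    return beta


def _coxnet_path(X, y, alphas=None, n_alphas=50, alpha_min_ratio=0.01):
    """Fit the full LASSO path; returns (alphas, coef matrix p x n_alphas)."""
    kwargs = dict(l1_ratio=1.0, normalize=False, fit_baseline_model=False, tol=1e-7)
    if alphas is not None:
        model = CoxnetSurvivalAnalysis(alphas=alphas, **kwargs)
    else:
        model = CoxnetSurvivalAnalysis(n_alphas=n_alphas,
                                       alpha_min_ratio=alpha_min_ratio, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return np.asarray(model.alphas_), model.coef_


# ---------------------------------------------------------------------------
# stability selection


@dataclass
class StabilityResult:
    """Selection frequencies over repeated penalized fits."""

    counts: pd.Series            # per-feature selection count
    n_runs: int
    threshold: float
    seed: int

    @property
    def frequency(self) -> pd.Series:
        return self.counts / self.n_runs

    @property
    def selected(self) -> list[str]:
        """Features selected in strictly more than ``threshold`` of the runs."""
        freq = self.frequency
        return list(freq.index[freq > self.threshold])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"count": self.counts, "frequency": self.frequency,
                             "selected": self.frequency > self.threshold})


def _cv_deviance_best_alpha(Xs, time, event, alphas, cv_folds, rng_seed,
                            rule: str = "1se"):
    """Pick the path penalty by cross-validated partial-likelihood deviance.

    Held-out deviance per fold follows Verweij & Van Houwelingen:
    -2 * [ll(all data; beta_fold) - ll(train; beta_fold)].  ``rule='min'``
    takes the deviance-minimizing penalty; ``rule='1se'`` (default) the
    largest penalty whose deviance is within one standard error of the
    minimum, which guards against the near-flat tail of the curve admitting
    every feature.
    """
    k = max(2, min(cv_folds, int(event.sum())))
    n_cens = int((1 - event).sum())
    if 0 < n_cens < k:
        k = max(2, n_cens)  # stratified folds need every class >= k members
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed % (2**32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # tiny-class fold notices
        splits = list(skf.split(Xs, event))
    fold_dev = []
    for train_idx, _ in splits:
        Xtr, ttr, etr = Xs[train_idx], time[train_idx], event[train_idx]
        if etr.sum() == 0:
            continue
        ytr = Surv.from_arrays(event=etr.astype(bool), time=ttr)
        try:
            _, coefs = _coxnet_path(Xtr, ytr, alphas=list(alphas))
        except Exception as exc:
            logger.debug("fold path failed: %s", exc)
            continue
        row = np.full(len(alphas), np.nan)
        # the coordinate-descent solver may truncate the tail of the path
        for a_idx in range(min(len(alphas), coefs.shape[1])):
            b = coefs[:, a_idx]
            row[a_idx] = -2.0 * (breslow_loglik(b, Xs, time, event)
                                 - breslow_loglik(b, Xtr, ttr, etr))
        fold_dev.append(row)
    if not fold_dev:
        return 0
    fold_dev = np.asarray(fold_dev)
    complete = ~np.isnan(fold_dev).any(axis=0)
    if not complete.any():
        return 0
    cvm = np.where(complete, fold_dev.sum(axis=0), np.inf)
    best = int(np.argmin(cvm))
    if rule == "min":
        return best
    # standard error of the summed deviance at the minimizer
    se = fold_dev[:, best].std(ddof=1) * np.sqrt(len(fold_dev)) \
        if len(fold_dev) > 1 else 0.0
    within = np.flatnonzero(complete & (cvm <= cvm[best] + se))
    return int(within[0])  # alphas are descending: first index = largest penalty


def stability_select(features: pd.DataFrame, time, event, n_runs: int = 1000,
                     threshold: float = 0.5, seed: int = 0, cv_folds: int = 10,
                     n_alphas: int = 50, resample: str = "bootstrap",
                     lambda_rule: str = "1se") -> StabilityResult:
    """Repeat CV-tuned LASSO-Cox fits and count how often each feature is active.

    Each run draws a bootstrap resample of subjects (``resample='none'``
    keeps the original subjects and only re-randomizes the CV folds),
    standardizes the feature columns within the resample, picks the penalty
    by ``cv_folds``-fold cross-validated deviance on a ``n_alphas``-point log
    grid, refits on the whole resample at that penalty, and records the
    active set.  Features active in more than ``threshold`` of the runs form
    the selected set.  All-censored resamples are redrawn (logged).
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if resample not in ("bootstrap", "none"):
        raise ValueError(f"unknown resample mode {resample!r}")
    X_full = features.to_numpy(dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X_full.shape
    counts = np.zeros(p, dtype=int)
    root = np.random.SeedSequence(seed)
    run_seeds = root.generate_state(2 * n_runs)

    for r in range(n_runs):
        rng = np.random.default_rng(run_seeds[2 * r])
        if resample == "bootstrap":
            for _attempt in range(100):
                idx = rng.integers(0, n, size=n)
                if event[idx].sum() >= 2:
                    break
                logger.info("run %d: all-censored resample redrawn", r)
            else:
                raise RuntimeError("could not draw a resample with events")
        else:
            idx = np.arange(n)
        Xr, tr, er = X_full[idx], time[idx], event[idx]
        mu = Xr.mean(axis=0)
        sd = Xr.std(axis=0)
        live = sd > 0
        Xs = np.zeros_like(Xr)
        Xs[:, live] = (Xr[:, live] - mu[live]) / sd[live]
        yr = Surv.from_arrays(event=er.astype(bool), time=tr)
        try:
            alphas, _ = _coxnet_path(Xs[:, live], yr, n_alphas=n_alphas)
        except Exception as exc:
            logger.warning("run %d: path fit failed (%s); run skipped", r, exc)
            continue
        best = _cv_deviance_best_alpha(Xs[:, live], tr, er, alphas, cv_folds,
                                       int(run_seeds[2 * r + 1]), rule=lambda_rule)
        _, coefs = _coxnet_path(Xs[:, live], yr, alphas=list(alphas))
        active = np.zeros(p, dtype=bool)
        active[np.flatnonzero(live)] = coefs[:, min(best, coefs.shape[1] - 1)] != 0
        counts += active
    return StabilityResult(counts=pd.Series(counts, index=features.columns),
                           n_runs=n_runs, threshold=threshold, seed=seed)


# ---------------------------------------------------------------------------
# correlation screens


def correlation_screen(values_a, values_b, method: str = "spearman") -> float:
    """Spearman (average ranks for ties) or Pearson correlation in [-1, 1].

    Constant input is undefined and returned as NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.unique(a).size == 1 or np.unique(b).size == 1:
        return np.nan
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    raise ValueError(f"unknown method {method!r}")


def correlation_report(features: pd.DataFrame, selected: list[str],
                       clinical: pd.DataFrame | None = None,
                       spearman_limit: float = 0.6,
                       pearson_limit: float = 0.2) -> pd.DataFrame:
    """Flag redundant feature pairs and feature-clinical dependences.

    Selected-feature pairs with |Spearman rho| >= 0.6 indicate redundancy;
    feature-clinical pairs with |Pearson rho| >= 0.2 indicate the feature is
    not independent of the clinical covariate.  Returns one row per checked
    pair with the coefficient and a ``flagged`` boolean.
    """
    rows = []
    for i, fa in enumerate(selected):
        for fb in selected[i + 1:]:
            rho = correlation_screen(features[fa], features[fb], "spearman")
            rows.append({"a": fa, "b": fb, "method": "spearman", "rho": rho,
                         "flagged": bool(abs(rho) >= spearman_limit) if np.isfinite(rho) else False})
    if clinical is not None:
        for fa in selected:
            for col in clinical.columns:
                rho = correlation_screen(features[fa], clinical[col], "pearson")
                rows.append({"a": fa, "b": col, "method": "pearson", "rho": rho,
                             "flagged": bool(abs(rho) >= pearson_limit) if np.isfinite(rho) else False})
    return pd.DataFrame(rows, columns=["a", "b", "method", "rho", "flagged"])
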