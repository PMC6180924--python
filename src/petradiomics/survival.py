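"""Survival statistics: Cox models, Harrell's c-index, cross-validation,
Kaplan-Meier curves, the rank-sum group test and the recurrence-pattern rule.

Cox proportional-hazards fits use the Efron approximation for tied event
times (via lifelines).  Harrell's concordance index is implemented directly
from its pairwise definition so that the comparable-pair rule — a pair counts
iff the shorter observed time is an event — is explicit and testable; model
comparison is a paired bootstrap over subjects of the c-index difference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "CoxFit", "cox_fit", "c_index", "crossvalidated_cindex", "CindexComparison",
    "compare_cindex", "KMEstimate", "km_estimate", "km_median_split",
    "wilcoxon_rank_sum", "classify_recurrence_pattern",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cox regression


@dataclass
class CoxFit:
    """Per-covariate hazard ratios with Wald intervals, plus model c-index."""

    summary: pd.DataFrame        # index: covariate; columns coef, HR, HR_lower, HR_upper, p
    c_index: float
    n: int
    n_events: int
    converged: bool
    covariates: list[str]
    _fitter: CoxPHFitter | None = field(default=None, repr=False)

    def linear_predictor(self, df: pd.DataFrame) -> np.ndarray:
        """Risk score X beta for new subjects (higher = higher hazard)."""
        X = df[self.covariates].astype(float)
        beta = self.summary.loc[self.covariates, "coef"].to_numpy()
        return X.to_numpy() @ beta


def _design_matrix(cohort: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design matrix; known categorical covariates become 0/1 dummies."""
    cols = {}
    for cov in covariates:
        s = cohort[cov]
        if s.dtype == object or s.dtype.name == "category":
            vals = set(s.unique())
            if vals <= {"M", "F"}:
                cols[cov] = (s == "F").astype(float)  # F vs M: HR for female
            elif vals <= {"III", "IV"}:
                cols[cov] = (s == "IV").astype(float)
            elif vals <= {"oropharynx", "other"}:
                cols[cov] = (s == "other").astype(float)
            elif vals <= {"yes", "no"}:
                cols[cov] = (s == "yes").astype(float)
            else:
                raise ValueError(f"cannot encode covariate {cov!r} with levels {vals}")
        else:
            cols[cov] = s.astype(float)
    return pd.DataFrame(cols, index=cohort.index)


def cox_fit(cohort: pd.DataFrame, covariates: list[str],
            time_col: str = "time_months", event_col: str = "event") -> CoxFit:
    """Maximum partial-likelihood Cox fit (Efron ties) with Wald inference.

    Categorical covariates (gender, stage, site group, CHT) are dummy-coded.
    A fit that fails to converge, or shows the monotone-likelihood pathology
    (a coefficient running to +-infinity, i.e. an absurdly large |log HR|),
    is flagged via ``converged=False`` rather than raised.
    """
    if cohort[event_col].sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    X = _design_matrix(cohort, covariates)
    nunique = X.nunique()
    constant = list(nunique[nunique <= 1].index)
    if constant:
        raise ValueError(f"constant covariate(s): {constant}")
    df = X.copy()
    df["_time"] = cohort[time_col].to_numpy(dtype=float)
    df["_event"] = cohort[event_col].to_numpy(dtype=int)

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(df, duration_col="_time", event_col="_event",
                    fit_options={"precision": 1e-10})
        except Exception as exc:  # monotone likelihood / singularity
            logger.warning("Cox fit failed (%s); retrying with ridge guard", exc)
            converged = False
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="_time", event_col="_event")
    # monotone-likelihood guard: a coefficient escaping to +-infinity shows up
    # as an extreme estimate and/or an exploding Wald standard error
    if np.abs(cph.params_).max() > 50 or cph.summary["se(coef)"].max() > 50:
        converged = False

    summ = pd.DataFrame({
        "coef": cph.params_,
        "HR": np.exp(cph.params_),
        "HR_lower": np.exp(cph.confidence_intervals_.iloc[:, 0]),
        "HR_upper": np.exp(cph.confidence_intervals_.iloc[:, 1]),
        "p": cph.summary["p"],
    })
    fit = CoxFit(summary=summ, c_index=np.nan, n=len(df),
                 n_events=int(df["_event"].sum()), converged=converged,
                 covariates=list(X.columns), _fitter=cph)
    risk = fit.linear_predictor(X)
    fit.c_index = c_index(risk, df["_time"].to_numpy(), df["_event"].to_numpy())
    return fit


# ---------------------------------------------------------------------------
# concordance


def c_index(risk_scores, times, events) -> float:
    """Harrell's concordance index.

    A pair is comparable iff the member with the shorter observed time had an
    event (ties in time are not comparable).  A comparable pair is concordant
    when the shorter survivor carries the higher risk score; tied risk scores
    count 1/2.  Returns (concordant + 0.5 * ties) / comparable.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if not (len(r) == len(t) == len(e)):
        raise ValueError("risk, time and event vectors must have equal length")
    # pair (i, j) comparable iff t_i < t_j and e_i == 1
    shorter = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(shorter.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    dr = r[:, None] - r[None, :]
    concordant = int((shorter & (dr > 0)).sum())
    tied = int((shorter & (dr == 0)).sum())
    return (concordant + 0.5 * tied) / n_comp


def _event_stratified_folds(events: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Fold assignment stratified on the event indicator.

    Stratification guarantees events in every training fold whenever the
    cohort has at least k events.  If one class is present but rarer than k
    subjects, plain shuffled folds are used instead.
    """
    from sklearn.model_selection import KFold

    counts = np.bincount(events, minlength=2)
    if 0 < counts.min() < k:
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
        return [test for _, test in kf.split(np.zeros(len(events)))]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(events)), events)]


def crossvalidated_cindex(cohort: pd.DataFrame, covariates: list[str], k: int = 10,
                          seed: int = 0, time_col: str = "time_months",
                          event_col: str = "event",
                          return_scores: bool = False):
    """k-fold cross-validated Harrell c-index.

    Each fold's model is fit on the remaining k-1 folds; its linear predictor
    scores the held-out subjects.  The c-index is computed once over the
    pooled out-of-fold risk scores.  Folds are stratified on the event
    indicator (so every training set contains events) and seeded.
    """
    n = len(cohort)
    if n < k:
        raise ValueError(f"n={n} smaller than k={k}")
    events = cohort[event_col].to_numpy(dtype=int)
    if events.sum() < k:
        raise ValueError("need at least k events for event-stratified folds")
    folds = _event_stratified_folds(events, k, seed)
    scores = np.empty(n)
    cohort = cohort.reset_index(drop=True)
    for test_idx in folds:
        train = cohort.drop(index=test_idx)
        fit = cox_fit(train, covariates, time_col=time_col, event_col=event_col)
        X_test = _design_matrix(cohort.iloc[test_idx], covariates)
        scores[test_idx] = fit.linear_predictor(X_test)
    c = c_index(scores, cohort[time_col].to_numpy(), events)
    if return_scores:
        return c, scores
    return c


@dataclass
class CindexComparison:
    """Paired-bootstrap comparison of two risk scores on one cohort."""

    delta: float          # c_a - c_b on the full cohort
    ci_lower: float
    ci_upper: float
    p_value: float
    n_boot: int


def compare_cindex(risk_a, risk_b, times, events, n_boot: int = 2000,
                   seed: int = 0) -> CindexComparison:
    """Paired bootstrap over subjects of the c-index difference c_a - c_b.

    Both scores are evaluated on the same resampled subjects, so the pairing
    absorbs the shared sampling variability.  The two-sided p-value inverts
    the percentile interval for delta = 0; resamples with no comparable pairs
    are redrawn (logged).
    """
    risk_a = np.asarray(risk_a, dtype=float)
    risk_b = np.asarray(risk_b, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    n = len(t)
    delta_full = c_index(risk_a, t, e) - c_index(risk_b, t, e)
    if np.array_equal(risk_a, risk_b):
        return CindexComparison(delta=0.0, ci_lower=0.0, ci_upper=0.0,
                                p_value=1.0, n_boot=n_boot)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_boot)
    b = 0
    redraws = 0
    while b < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            deltas[b] = c_index(risk_a[idx], t[idx], e[idx]) - \
                c_index(risk_b[idx], t[idx], e[idx])
        except ValueError:
            redraws += 1
            if redraws > 10 * n_boot:
                raise RuntimeError("too many degenerate bootstrap resamples")
            continue
        b += 1
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)
    lo, hi = np.percentile(deltas, [2.5, 97.5])
    # two-sided p: twice the smaller tail probability of 0 under the bootstrap law
    p = 2.0 * min(np.mean(deltas <= 0.0), np.mean(deltas >= 0.0))
    p = min(1.0, max(p, 1.0 / n_boot))
    return CindexComparison(delta=delta_full, ci_lower=float(lo), ci_upper=float(hi),
                            p_value=float(p), n_boot=n_boot)


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KMEstimate:
    """Product-limit survival curve with right-continuous evaluation."""

    times: np.ndarray           # distinct event times (ascending)
    survival: np.ndarray        # S(t) just after each event time
    at_risk: np.ndarray         # risk-set size at each event time
    n: int

    def at(self, t: float) -> float:
        """S(t), right-continuous; 1.0 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier product-limit estimator."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("empty sample")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    event_times = np.asarray(kmf.event_table.index[kmf.event_table["observed"] > 0],
                             dtype=float)
    surv = np.asarray([kmf.predict(x) for x in event_times], dtype=float)
    at_risk = np.asarray(
        kmf.event_table.loc[event_times, "at_risk"], dtype=float).astype(int) \
        if event_times.size else np.array([], dtype=int)
    return KMEstimate(times=event_times, survival=surv, at_risk=at_risk, n=len(t))


@dataclass
class MedianSplitResult:
    low: KMEstimate             # feature <= median
    high: KMEstimate            # feature > median
    median: float
    logrank_statistic: float
    logrank_p: float


def km_median_split(cohort: pd.DataFrame, feature: str,
                    time_col: str = "time_months",
                    event_col: str = "event") -> MedianSplitResult:
    """KM curves for the cohort split at the feature median, with a log-rank test.

    Subjects at exactly the median go to the low group.
    """
    x = cohort[feature].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError(f"feature {feature!r} is constant: cannot median-split")
    med = float(np.median(x))
    low = x <= med
    if low.sum() < 2 or (~low).sum() < 2:
        warnings.warn("median split produced a group with < 2 subjects", stacklevel=2)
    t = cohort[time_col].to_numpy(dtype=float)
    e = cohort[event_col].to_numpy(dtype=int)
    res = logrank_test(t[low], t[~low], event_observed_A=e[low], event_observed_B=e[~low])
    return MedianSplitResult(
        low=km_estimate(t[low], e[low]), high=km_estimate(t[~low], e[~low]),
        median=med, logrank_statistic=float(res.test_statistic),
        logrank_p=float(res.p_value))


# ---------------------------------------------------------------------------
# group test and recurrence rule


def wilcoxon_rank_sum(group1, group2) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both groups have at most 20
    observations and the data are tie-free, otherwise the normal
    approximation with tie and continuity corrections.  Two identical
    constant groups give p = 1.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not has_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def classify_recurrence_pattern(fraction_inside_95_isodose: float) -> str:
    """Classify a recurrence by its overlap with the prescription 95% isodose.

    More than 80% of the recurrent lesion inside the isodose surface is an
    in-field failure, 20-80% a marginal failure, below 20% out-field.
    """
    f = float(fraction_inside_95_isodose)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {f}")
    if f > 0.80:
        return "in-field"
    if f >= 0.20:
        return "marginal"
    return "out-field"
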