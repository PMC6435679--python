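"""Univariate survival machinery.

The central primitive is the two-group log-rank test, evaluated many
thousands of times while scanning candidate cut-offs, so it is implemented
as a vectorised numpy routine (:class:`LogrankScanner`) with the standard
chi-square form: at every distinct event time the observed minus expected
events in one group accumulate under the hypergeometric variance, and the
squared standardised sum is referred to chi-square with 1 df.  lifelines'
``logrank_test`` serves as an independent cross-check in the test suite.

Dichotomisation of a continuous feature uses the *optimal cut-off*: the
candidate cut-off (midpoints of consecutive sorted unique values) meeting a
minimum group prevalence whose low/high split minimises the log-rank
p-value.  To keep the reported statistics honest despite this optimisation,
cut-offs are chosen by leave-one-out *pre-validation*: patient i's low/high
label comes from the cut-off optimised on the other N-1 patients, so no
patient's outcome informs their own grouping; tests and Cox fits then run on
the pre-validated labels.

Multiple testing over the m = 7 budding features uses the Benjamini-Hochberg
step-up with the null proportion fixed at 1 (the most conservative q-value
variant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateDataError(ValueError):
    """Raised when data cannot support the requested analysis."""


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class LogrankScanner:
    """Fast repeated two-group log-rank tests on a fixed (time, event) sample.

    Sorting and the per-time event/at-risk bookkeeping that do not depend on
    the grouping are precomputed once; each call to :meth:`chi2` then costs a
    few bincounts.  Used for cut-off scans, permutation oracles, and the
    survival decision tree.
    """

    def __init__(self, time, event):
        time = np.asarray(time, float)
        event = np.asarray(event, float)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if np.any(time < 0):
            raise ValueError("negative survival times")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event must be binary")
        self.n = len(time)
        order = np.argsort(time, kind="stable")
        self._order = order
        t = time[order]
        e = event[order]
        ut, inv = np.unique(t, return_inverse=True)
        self._inv = inv
        self._e_sorted = e
        self._d = np.bincount(inv, weights=e)           # events per distinct time
        c = np.bincount(inv)                            # subjects leaving per time
        self._n_at_risk = self.n - np.cumsum(c) + c     # at risk at each time
        self._event_times = self._d > 0

    def chi2(self, group) -> tuple[float, float]:
        """Two-group log-rank statistic and p-value for a binary grouping.

        ``group`` is any binary array over the original sample order; both
        groups must be non-empty.  Returns (statistic, p) with statistic 0
        and p 1 when the variance degenerates (e.g. identical groups).
        """
        g = np.asarray(group)
        if g.shape != (self.n,):
            raise ValueError("group has wrong length")
        g = g.astype(float)
        if g.sum() in (0, self.n):
            raise DegenerateDataError("both groups must be non-empty")
        gs = g[self._order]
        d1 = np.bincount(self._inv, weights=self._e_sorted * gs, minlength=len(self._d))
        c1 = np.bincount(self._inv, weights=gs, minlength=len(self._d))
        n1 = gs.sum() - np.cumsum(c1) + c1
        m = self._event_times & (self._n_at_risk > 1)
        d, n, n1m = self._d[m], self._n_at_risk[m], n1[m]
        frac = n1m / n
        u = float(np.sum(d1[m] - d * frac))
        var = float(np.sum(d * frac * (1.0 - frac) * (n - d) / (n - 1.0)))
        if var <= 0:
            return 0.0, 1.0
        stat = u * u / var
        return stat, float(sps.chi2.sf(stat, df=1))


def logrank_test(time, event, group) -> tuple[float, float]:
    """Standard two-group log-rank test: (chi-square statistic, p), df = 1."""
    return LogrankScanner(time, event).chi2(group)


# ---------------------------------------------------------------------------
# Cox regression (lifelines, Efron ties)
# ---------------------------------------------------------------------------

def cox_univariate(time, event, x) -> tuple[float, tuple[float, float], float, float]:
    """Univariate Cox PH fit: (HR, (ci_low, ci_high), Wald p, log-likelihood).

    Partial likelihood with Efron tie handling (lifelines).  Degenerate
    covariates (constant) and event-free samples raise
    :class:`DegenerateDataError`; non-convergence (e.g. complete separation)
    is surfaced as :class:`ConvergenceError` from lifelines.
    """
    from lifelines import CoxPHFitter

    x = np.asarray(x, float)
    event = np.asarray(event, int)
    if np.ptp(x) == 0:
        raise DegenerateDataError("covariate is constant")
    if event.sum() == 0:
        raise DegenerateDataError("no events observed")
    df = pd.DataFrame({"time": np.asarray(time, float), "event": event, "x": x})
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    hr = float(np.exp(cph.params_["x"]))
    ci = cph.confidence_intervals_
    lo = float(np.exp(ci.iloc[0, 0]))
    hi = float(np.exp(ci.iloc[0, 1]))
    p = float(cph.summary.loc["x", "p"])
    return hr, (lo, hi), p, float(cph.log_likelihood_)


# ---------------------------------------------------------------------------
# optimal cut-off and leave-one-out pre-validation
# ---------------------------------------------------------------------------

def candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique feature values."""
    u = np.unique(np.asarray(values, float))
    if len(u) < 2:
        return np.empty(0)
    return (u[:-1] + u[1:]) / 2.0


def optimal_cutoff(
    feature, time, event, min_prevalence: float = 0.25,
    scanner: LogrankScanner | None = None,
) -> tuple[float, float]:
    """Log-rank-optimal dichotomisation cut-off.

    Scans all candidate cut-offs (midpoints of consecutive sorted unique
    values); a candidate is feasible when both the low (feature <= cut) and
    high (feature > cut) groups hold at least ``min_prevalence`` of the
    sample.  Returns (cutoff, p) minimising the log-rank p; ties go to the
    smallest cut-off.  Raises :class:`DegenerateDataError` when no candidate
    is feasible.
    """
    x = np.asarray(feature, float)
    cuts = candidate_cutoffs(x)
    if len(cuts) == 0:
        raise DegenerateDataError("feature has fewer than 2 distinct values")
    if scanner is None:
        scanner = LogrankScanner(time, event)
    n = scanner.n
    best_p, best_cut = None, None
    for cut in cuts:
        low = x <= cut
        n_low = int(low.sum())
        if n_low < min_prevalence * n or (n - n_low) < min_prevalence * n:
            continue
        _, p = scanner.chi2(low)
        if best_p is None or p < best_p:
            best_p, best_cut = p, float(cut)
    if best_cut is None:
        raise DegenerateDataError(
            f"no cut-off satisfies the {min_prevalence:.0%} minimum prevalence"
        )
    return best_cut, best_p


def loo_prevalidated_grouping(
    feature, time, event, min_prevalence: float = 0.25
) -> tuple[np.ndarray, np.ndarray]:
    """Leave-one-out pre-validated low/high labels.

    For each patient i the optimal cut-off is computed on the other N-1
    patients and patient i is labelled high when their feature exceeds that
    cut-off.  Returns (labels, per-patient cutoffs); labels are boolean with
    True = high.  Each patient is thereby left out of the selection of their
    own decision.
    """
    x = np.asarray(feature, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = len(x)
    if n < 8:
        raise DegenerateDataError("need at least 8 patients")
    cutoffs = np.empty(n)
    labels = np.empty(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        rest = idx != i
        cut, _ = optimal_cutoff(x[rest], time[rest], event[rest], min_prevalence)
        cutoffs[i] = cut
        labels[i] = x[i] > cut
    return labels, cutoffs


@dataclass
class UnivariateResult:
    """Pre-validated univariate statistics for one feature (one table row)."""

    feature_name: str
    logrank_stat: float
    logrank_p: float
    hr: float
    hr_ci_low: float
    hr_ci_high: float
    cox_p: float
    cutoff_per_patient: np.ndarray
    group_high: np.ndarray
    q_logrank: float | None = None
    q_cox: float | None = None


def univariate_feature(
    name: str, feature, time, event, min_prevalence: float = 0.25
) -> UnivariateResult:
    """Log-rank and Cox statistics on the pre-validated dichotomisation."""
    labels, cutoffs = loo_prevalidated_grouping(feature, time, event, min_prevalence)
    if labels.all() or not labels.any():
        raise DegenerateDataError(
            f"pre-validated grouping for {name!r} is degenerate (single group)"
        )
    stat, p = logrank_test(time, event, labels)
    hr, (lo, hi), cox_p, _ = cox_univariate(time, event, labels.astype(float))
    return UnivariateResult(name, stat, p, hr, lo, hi, cox_p, cutoffs, labels)


def univariate_table(
    cohort: pd.DataFrame,
    feature_names,
    time_col: str = "time_months",
    event_col: str = "event",
    min_prevalence: float = 0.25,
    m: int | None = None,
) -> pd.DataFrame:
    """Per-feature pre-validated log-rank/Cox table with BH q-values.

    ``m`` is the number of hypotheses used in the correction (defaults to the
    number of features analysed); features whose analysis degenerates
    (constant values, single pre-validated group) are flagged and excluded
    from the correction.
    """
    time = cohort[time_col].to_numpy(float)
    event = cohort[event_col].to_numpy(int)
    rows, results = [], []
    for name in feature_names:
        try:
            res = univariate_feature(name, cohort[name].to_numpy(float), time, event, min_prevalence)
        except DegenerateDataError as exc:
            rows.append({"feature": name, "excluded": str(exc)})
            continue
        results.append(res)
        rows.append({
            "feature": name,
            "logrank_p": res.logrank_p,
            "hr": res.hr,
            "hr_ci_low": res.hr_ci_low,
            "hr_ci_high": res.hr_ci_high,
            "cox_p": res.cox_p,
            "excluded": "",
        })
    table = pd.DataFrame(rows).set_index("feature")
    ok = table["excluded"] == ""
    if ok.any():
        m_eff = m if m is not None else int(ok.sum())
        table.loc[ok, "q_logrank"] = benjamini_correct(table.loc[ok, "logrank_p"].to_numpy(), m=m_eff)
        table.loc[ok, "q_cox"] = benjamini_correct(table.loc[ok, "cox_p"].to_numpy(), m=m_eff)
    return table


# ---------------------------------------------------------------------------
# multiple testing and association
# ---------------------------------------------------------------------------

def benjamini_correct(pvalues, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with the null proportion set to 1.

    ``q_i = min_{j : p_j >= p_i} m * p_j / rank_j`` clipped to 1.  ``m`` may
    exceed ``len(pvalues)`` when only a subset of the tested hypotheses is
    being corrected (it defaults to the vector length, the textbook BH).
    """
    p = np.asarray(pvalues, float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m is None:
        m = k
    if m < k:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, k + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(k)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def chi2_association(a, b) -> tuple[float, float]:
    """Pearson chi-square test of independence on a 2x2 table, df = 1.

    ``a`` and ``b`` are binary per-patient indicators; no continuity
    correction is applied.  All four margins must be positive.
    """
    a = np.asarray(a).astype(int)
    b = np.asarray(b).astype(int)
    table = np.zeros((2, 2))
    for i in (0, 1):
        for j in (0, 1):
            table[i, j] = np.sum((a == i) & (b == j))
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateDataError("2x2 table has a zero margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)
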