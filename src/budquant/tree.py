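"""Survival decision tree and the three-group TB stage model.

Unlike a classification tree, which minimises a misclassification rate over
arbitrary outcome classes, this tree chooses at each node the (feature,
cut-off) pair whose two resulting branches differ most in their survival
distributions, quantified by the two-group log-rank p-value under a minimum
branch prevalence of 25%.  Time and censoring information is therefore used
directly, without discretising survival into classes.

The staging model restricts the tree to depth two and splits only the most
populated depth-1 node, yielding exactly three leaves, comparable to TNM
stages II/III/IV.  Overfitting of the optimised decisions is controlled by
leave-one-out pre-validation: each patient is routed through the tree grown
on the other N-1 patients, so their own outcome never informs their
grouping.  The three groups are labelled II' (low branch of the second
split), III' (high branch) and IV (the root branch that is not split
further).  A categorical Cox model with the low-risk group as baseline then
compares the staging against survival (per-group hazard ratios plus overall
likelihood-ratio, Wald and score log-rank tests on 2 df).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator

from . import cohort as C
from .stats import (
    DegenerateDataError,
    LogrankScanner,
    benjamini_correct,
    candidate_cutoffs,
    logrank_test,
)

GROUPS = ("II'", "III'", "IV")


@dataclass
class SplitDecision:
    """One tree decision: numeric cut-off or categorical one-vs-rest."""

    feature_name: str
    kind: str  # "numeric-cutoff" | "categorical-one-vs-rest"
    cutoff: float | None
    category: object | None
    logrank_p: float
    child_sizes: tuple[int, int]  # (low/rest, high/category)

    def route_high(self, df: pd.DataFrame) -> np.ndarray:
        """True where a patient goes to the high (or in-category) branch."""
        kind, x = C.encode_feature(df, self.feature_name)
        if self.kind == "numeric-cutoff":
            return np.asarray(x, float) > self.cutoff
        return np.asarray(x) == self.category

    def to_dict(self) -> dict:
        return {
            "feature": self.feature_name,
            "kind": self.kind,
            "cutoff": self.cutoff,
            "category": self.category,
            "logrank_p": self.logrank_p,
            "child_sizes": list(self.child_sizes),
        }


def best_split(
    df: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    min_prevalence: float = 0.25,
    features=C.ALL_FEATURES,
) -> SplitDecision | None:
    """Globally log-rank-optimal split of one node.

    Numeric (and ordinally encoded) features are scanned over all midpoint
    cut-offs; strictly categorical features are scanned one-vs-rest per
    category.  Candidates violating the minimum prevalence of either branch
    are skipped.  Ties in p are broken by the fixed feature order (clinical
    features first, then the budding features) and, within a feature, by the
    smallest cut-off / first category.  Returns None when no feasible split
    exists (the node becomes a leaf).
    """
    n = len(df)
    scanner = LogrankScanner(time, event)
    best: SplitDecision | None = None
    for name in features:
        kind, x = C.encode_feature(df, name)
        if kind == "numeric":
            x = np.asarray(x, float)
            for cut in candidate_cutoffs(x):
                high = x > cut
                n_high = int(high.sum())
                if n_high < min_prevalence * n or (n - n_high) < min_prevalence * n:
                    continue
                _, p = scanner.chi2(high)
                if best is None or p < best.logrank_p:
                    best = SplitDecision(name, "numeric-cutoff", float(cut), None,
                                         p, (n - n_high, n_high))
        else:
            for cat in pd.unique(x):
                high = np.asarray(x) == cat
                n_high = int(high.sum())
                if n_high < min_prevalence * n or (n - n_high) < min_prevalence * n:
                    continue
                _, p = scanner.chi2(high)
                if best is None or p < best.logrank_p:
                    best = SplitDecision(name, "categorical-one-vs-rest", None, cat,
                                         p, (n - n_high, n_high))
    return best


def _grow_depth2(
    df: pd.DataFrame,
    min_prevalence: float,
    min_node_size: int,
    fixed_second_feature: str | None,
    features,
) -> tuple[SplitDecision | None, SplitDecision | None, bool]:
    """Root split, second split on the most populated depth-1 node.

    Returns (root, second, split_high_branch) where the flag records which
    root branch was split further.  Population ties go to the lower-risk
    branch (smaller observed event fraction; further ties to the low
    branch).
    """
    time, event = C.survival_arrays(df)
    if len(df) < min_node_size:
        return None, None, False
    root = best_split(df, time, event, min_prevalence, features)
    if root is None:
        return None, None, False
    high = root.route_high(df)
    n_low, n_high = int((~high).sum()), int(high.sum())
    if n_high > n_low:
        split_high = True
    elif n_high < n_low:
        split_high = False
    else:
        split_high = event[high].mean() < event[~high].mean()
    node = high if split_high else ~high
    sub = df.loc[node]
    second = None
    if len(sub) >= min_node_size:
        feats = (fixed_second_feature,) if fixed_second_feature else features
        second = best_split(sub, time[node], event[node], min_prevalence, feats)
    return root, second, split_high


def _route(df, root, second, split_high) -> np.ndarray:
    """Assign each patient in ``df`` to II'/III'/IV through the decisions."""
    n = len(df)
    groups = np.empty(n, dtype=object)
    if root is None:
        groups[:] = GROUPS[0]
        return groups
    high = root.route_high(df)
    node = high if split_high else ~high
    groups[~node] = GROUPS[2]  # the branch not split further
    if second is None:
        groups[node] = GROUPS[0]  # root decision only (second split infeasible)
        return groups
    sub_high = second.route_high(df.loc[node])
    idx = np.flatnonzero(node)
    groups[idx[~sub_high]] = GROUPS[0]
    groups[idx[sub_high]] = GROUPS[1]
    return groups


class SurvivalTree(BaseEstimator):
    """Depth-2 log-rank survival decision tree with LOO pre-validation.

    Parameters
    ----------
    min_prevalence : minimum fraction of a node's patients in each branch.
    min_node_size : smallest node for which a split is attempted.
    fixed_second_feature : force the second decision's feature (its cut-off
        is still optimised, and cross-validated per fold); None searches all
        features.
    prevalidate : when True (default), ``groups_`` holds the leave-one-out
        pre-validated assignments; when False, the full-data tree's.
    features : scan order of candidate features (tie-break precedence).

    Attributes (after :meth:`fit`)
    ------------------------------
    root_split_, second_split_ : full-data :class:`SplitDecision`s.
    groups_ : per-patient group labels in {"II'", "III'", "IV"}.
    feature_votes_ : per-node Counters of features chosen across LOO runs.
    loo_second_cutoffs_ : per-fold second-split cut-offs (numeric splits).
    fold_log_ : per-fold record of both decisions (pre-validation audit).
    """

    def __init__(
        self,
        min_prevalence: float = 0.25,
        min_node_size: int = 8,
        fixed_second_feature: str | None = None,
        prevalidate: bool = True,
        features=C.ALL_FEATURES,
    ) -> None:
        self.min_prevalence = min_prevalence
        self.min_node_size = min_node_size
        self.fixed_second_feature = fixed_second_feature
        self.prevalidate = prevalidate
        self.features = features

    def fit(self, X: pd.DataFrame, y=None) -> "SurvivalTree":
        """Fit on a cohort table (must carry time/event columns)."""
        df = X.reset_index(drop=True)
        root, second, split_high = _grow_depth2(
            df, self.min_prevalence, self.min_node_size,
            self.fixed_second_feature, self.features,
        )
        if root is None:
            raise DegenerateDataError("no feasible root split")
        self.root_split_ = root
        self.second_split_ = second
        self.split_high_branch_ = split_high
        if self.prevalidate:
            self._fit_loo(df)
            self.groups_ = self.loo_groups_
        else:
            self.groups_ = _route(df, root, second, split_high)
        self.group_sizes_ = pd.Series(self.groups_).value_counts().to_dict()
        return self

    def _fit_loo(self, df: pd.DataFrame) -> None:
        n = len(df)
        groups = np.empty(n, dtype=object)
        root_votes: Counter = Counter()
        second_votes: Counter = Counter()
        second_cutoffs: list[float] = []
        fold_log = []
        for i in range(n):
            rest = df.index != i
            root, second, split_high = _grow_depth2(
                df.loc[rest], self.min_prevalence, self.min_node_size,
                self.fixed_second_feature, self.features,
            )
            if root is None:
                raise DegenerateDataError(f"fold {i}: no feasible root split")
            groups[i] = _route(df.iloc[[i]], root, second, split_high)[0]
            root_votes[root.feature_name] += 1
            if second is not None:
                second_votes[second.feature_name] += 1
                if second.cutoff is not None:
                    second_cutoffs.append(second.cutoff)
            fold_log.append({
                "fold": i,
                "root": root.to_dict(),
                "second": second.to_dict() if second else None,
                "split_high_branch": split_high,
                "assigned": groups[i],
            })
        self.loo_groups_ = groups
        self.feature_votes_ = {"root": root_votes, "second": second_votes}
        self.loo_second_cutoffs_ = np.array(second_cutoffs)
        self.fold_log_ = fold_log

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Route new patients through the full-data tree."""
        return _route(X.reset_index(drop=True), self.root_split_,
                      self.second_split_, self.split_high_branch_)

    def to_dict(self) -> dict:
        out = {
            "root": self.root_split_.to_dict(),
            "second": self.second_split_.to_dict() if self.second_split_ else None,
            "split_high_branch": self.split_high_branch_,
            "group_sizes": {k: int(v) for k, v in self.group_sizes_.items()},
        }
        if hasattr(self, "feature_votes_"):
            out["feature_votes"] = {k: dict(v) for k, v in self.feature_votes_.items()}
        return out


def loo_prevalidated_tree(df: pd.DataFrame, **params) -> SurvivalTree:
    """Fit the pre-validated depth-2 tree on a cohort table."""
    return SurvivalTree(prevalidate=True, **params).fit(df)


def fix_and_revalidate(df: pd.DataFrame, fixed_second_feature: str, **params) -> SurvivalTree:
    """Re-fit with the second decision's feature forced (cut-off re-optimised
    per fold), ensuring a unique model."""
    return SurvivalTree(prevalidate=True, fixed_second_feature=fixed_second_feature,
                        **params).fit(df)


# ---------------------------------------------------------------------------
# staging comparison (categorical Cox) and Kaplan-Meier outputs
# ---------------------------------------------------------------------------

@dataclass
class StagingComparison:
    """Categorical Cox comparison of a 3-group staging against survival."""

    baseline: str
    per_group: pd.DataFrame  # index: non-baseline groups; hr, ci, p, (q)
    lr_stat: float
    lr_p: float
    wald_stat: float
    wald_p: float
    score_stat: float
    score_p: float
    lr_q: float | None = None
    wald_q: float | None = None
    score_q: float | None = None


def staging_cox(
    time, event, groups, baseline: str = "II'", m: int | None = None
) -> StagingComparison:
    """Cox PH on group indicators vs the baseline group.

    Reports per-group HRs with 95% CIs and Wald p, plus the three overall
    tests on 2 df: likelihood ratio G, Wald z^2, and the score test (the
    k-group log-rank statistic).  With ``m`` given, p-values are corrected
    as q = min(1, m p) for the m quantification hypotheses.
    """
    from lifelines import CoxPHFitter
    from lifelines.statistics import multivariate_logrank_test

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups, dtype=object)
    levels = [g for g in pd.unique(groups)]
    if baseline not in levels:
        raise ValueError(f"baseline group {baseline!r} not present")
    others = sorted(g for g in levels if g != baseline)
    if len(others) != 2:
        raise DegenerateDataError("staging comparison needs exactly 3 non-empty groups")
    df = pd.DataFrame({"time": time, "event": event})
    for g in others:
        df[f"g_{g}"] = (groups == g).astype(float)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    rows = []
    for g in others:
        name = f"g_{g}"
        ci = cph.confidence_intervals_.loc[name]
        row = {
            "group": g,
            "hr": float(np.exp(cph.params_[name])),
            "hr_ci_low": float(np.exp(ci.iloc[0])),
            "hr_ci_high": float(np.exp(ci.iloc[1])),
            "p": float(cph.summary.loc[name, "p"]),
        }
        if m is not None:
            row["q"] = min(1.0, m * row["p"])
        rows.append(row)
    per_group = pd.DataFrame(rows).set_index("group")
    lrt = cph.log_likelihood_ratio_test()
    lr_stat, lr_p = float(lrt.test_statistic), float(lrt.p_value)
    beta = cph.params_.to_numpy()
    cov = cph.variance_matrix_.to_numpy()
    wald_stat = float(beta @ np.linalg.solve(cov, beta))
    wald_p = float(sps.chi2.sf(wald_stat, df=2))
    mlr = multivariate_logrank_test(time, groups, event)
    score_stat, score_p = float(mlr.test_statistic), float(mlr.p_value)
    qs = {}
    if m is not None:
        qs = {"lr_q": min(1.0, m * lr_p), "wald_q": min(1.0, m * wald_p),
              "score_q": min(1.0, m * score_p)}
    return StagingComparison(baseline, per_group, lr_stat, lr_p,
                             wald_stat, wald_p, score_stat, score_p, **qs)


def kaplan_meier_table(time, event, groups, time_grid=None) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves with numbers at risk per group.

    Returns ``{"curves": ..., "at_risk": ..., "median": ...}`` where curves
    holds the stepwise KM estimate per group, at_risk the risk counts on the
    time grid (default: every 12 months to the last follow-up), and median
    the per-group median survival (NaN when never below 0.5).
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups, dtype=object)
    if time_grid is None:
        time_grid = np.arange(0.0, time.max() + 12.0, 12.0)
    curves, at_risk, medians = [], {}, {}
    for g in sorted(pd.unique(groups)):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=str(g))
        sf = kmf.survival_function_
        sf.columns = [str(g)]
        curves.append(sf)
        counts = [int((time[sel] >= t).sum()) for t in time_grid]
        at_risk[str(g)] = counts
        medians[str(g)] = float(kmf.median_survival_time_)
    return {
        "curves": pd.concat(curves, axis=1).ffill(),
        "at_risk": pd.DataFrame(at_risk, index=pd.Index(time_grid, name="time_months")),
        "median": pd.Series(medians, name="median_survival_months"),
    }


def plot_kaplan_meier(time, event, groups, path=None, title: str | None = None):
    """Kaplan-Meier plot with at-risk table; saves to ``path`` when given."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from lifelines import KaplanMeierFitter
    from lifelines.plotting import add_at_risk_counts

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups, dtype=object)
    fig, ax = plt.subplots(figsize=(7, 5))
    fitters = []
    for g in sorted(pd.unique(groups)):
        sel = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel], label=str(g))
        kmf.plot_survival_function(ax=ax)
        fitters.append(kmf)
    add_at_risk_counts(*fitters, ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("disease-specific survival")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
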