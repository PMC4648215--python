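"""Group-level statistics: means ± SEM, unpaired Student's t-tests, and
one-way ANOVA.

Conventions follow the source study's analysis style: the t-test is the
pooled-variance (equal-variance) two-tailed Student's t by default, with
Welch's correction available as an option; significance is declared at
raw p < 0.05 with no multiple-testing correction (the number of tests
performed is recorded alongside the results so readers can judge).

Degenerate inputs — all observations identical in every group — yield
p = 1 with a ``degenerate`` flag rather than an error, so simulated
edge cases do not abort a pipeline run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InferenceError
from .overlap import COMPARISON_GROUPS, OverlapRecord, overlap_table
from .types import TissueGroup

__all__ = [
    "GroupComparisonResult",
    "t_test_unpaired",
    "anova_one_way",
    "compare_metric_across_groups",
    "sem",
]

DEFAULT_ALPHA = 0.05

_TISSUE_ORDER = ["normal", "non_lesional", "lesional"]


def sem(x) -> float:
    """Standard error of the mean: sample SD (ddof=1) / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise InferenceError("SEM requires at least two observations")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


@dataclass(frozen=True)
class GroupComparisonResult:
    metric: str
    test: str  # "t_test" or "anova"
    group_labels: tuple[str, ...]
    group_means: tuple[float, ...]
    group_sems: tuple[float, ...]
    statistic: float
    df: tuple[float, ...]
    p_value: float
    significant: bool
    degenerate: bool = False
    n_obs: tuple[int, ...] = field(default=())

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "test": self.test,
            "groups": list(self.group_labels),
            "means": list(self.group_means),
            "sems": list(self.group_sems),
            "n": list(self.n_obs),
            "statistic": self.statistic,
            "df": list(self.df),
            "p_value": self.p_value,
            "significant": self.significant,
            "degenerate": self.degenerate,
        }


def t_test_unpaired(
    x,
    y,
    *,
    welch: bool = False,
    alpha: float = DEFAULT_ALPHA,
    metric: str = "",
    labels: tuple[str, str] = ("x", "y"),
) -> GroupComparisonResult:
    """Two-sample two-tailed Student's t-test (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InferenceError("t-test requires at least two observations per group")
    degenerate = False
    if np.var(x, ddof=1) == 0.0 and np.var(y, ddof=1) == 0.0:
        if x.mean() == y.mean():
            t_stat, p, df = 0.0, 1.0, float(x.size + y.size - 2)
            degenerate = True
        else:
            t_stat = np.inf if x.mean() > y.mean() else -np.inf
            p, df = 0.0, float(x.size + y.size - 2)
            degenerate = True
    else:
        res = stats.ttest_ind(x, y, equal_var=not welch)
        t_stat, p, df = float(res.statistic), float(res.pvalue), float(res.df)
    return GroupComparisonResult(
        metric=metric,
        test="t_test",
        group_labels=labels,
        group_means=(float(x.mean()), float(y.mean())),
        group_sems=(sem(x), sem(y)),
        statistic=t_stat,
        df=(df,),
        p_value=p,
        significant=bool(p < alpha),
        degenerate=degenerate,
        n_obs=(int(x.size), int(y.size)),
    )


def anova_one_way(
    groups,
    *,
    labels: tuple[str, ...] | None = None,
    alpha: float = DEFAULT_ALPHA,
    metric: str = "",
) -> GroupComparisonResult:
    """One-way fixed-effects ANOVA across k >= 2 groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise InferenceError("ANOVA requires at least two groups")
    if any(a.size < 2 for a in arrays):
        raise InferenceError("ANOVA requires at least two observations per group")
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(arrays)))
    k = len(arrays)
    n = sum(a.size for a in arrays)
    df = (float(k - 1), float(n - k))
    within_var = sum(float(np.var(a, ddof=1)) for a in arrays)
    grand = np.concatenate(arrays).mean()
    between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    degenerate = False
    if within_var == 0.0:
        # zero within-group variance: F is undefined (p=1) when the
        # group means also coincide, and trivially extreme otherwise
        degenerate = True
        if between == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        res = stats.f_oneway(*arrays)
        f_stat, p = float(res.statistic), float(res.pvalue)
    return GroupComparisonResult(
        metric=metric,
        test="anova",
        group_labels=tuple(labels),
        group_means=tuple(float(a.mean()) for a in arrays),
        group_sems=tuple(sem(a) for a in arrays),
        statistic=f_stat,
        df=df,
        p_value=p,
        significant=bool(p < alpha),
        degenerate=degenerate,
        n_obs=tuple(int(a.size) for a in arrays),
    )


def _pairwise(
    vectors: dict[str, np.ndarray],
    metric: str,
    alpha: float,
    welch: bool,
) -> list[GroupComparisonResult]:
    out = []
    names = list(vectors)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            if vectors[a].size < 2 or vectors[b].size < 2:
                continue
            out.append(
                t_test_unpaired(
                    vectors[a],
                    vectors[b],
                    alpha=alpha,
                    metric=metric,
                    labels=(a, b),
                    welch=welch,
                )
            )
    return out


def compare_metric_across_groups(
    diversity: pd.DataFrame | None = None,
    overlaps: list[OverlapRecord] | pd.DataFrame | None = None,
    metric: str = "unique_count",
    *,
    alpha: float = DEFAULT_ALPHA,
    welch: bool = False,
) -> list[GroupComparisonResult]:
    """Replicate the study's test structure for one metric.

    ``unique_count`` / ``clonality``: the three pairwise tissue-group
    t-tests on the per-sample diversity table.  ``overlap_score``: one
    ANOVA across the pooled comparison groups followed by pairwise
    t-tests; excluded (within-patient NL-LS) records never enter.
    """
    if metric in ("unique_count", "clonality"):
        if diversity is None or len(diversity) == 0:
            raise InferenceError("diversity table required for this metric")
        col = "n_unique" if metric == "unique_count" else "clonality"
        vectors = {}
        for g in _TISSUE_ORDER:
            v = diversity.loc[diversity["group"] == g, col].to_numpy(dtype=float)
            if v.size == 0:
                raise InferenceError(f"tissue group {g!r} missing from diversity table")
            vectors[g] = v
        return _pairwise(vectors, metric, alpha, welch)

    if metric == "overlap_score":
        if overlaps is None:
            raise InferenceError("overlap records required for this metric")
        df = overlaps if isinstance(overlaps, pd.DataFrame) else overlap_table(overlaps)
        if len(df) == 0:
            raise InferenceError("no overlap records")
        pooled = df[~df["excluded"]]
        vectors = {
            g: pooled.loc[pooled["comparison_group"] == g, "score"].to_numpy(dtype=float)
            for g in COMPARISON_GROUPS
            if (pooled["comparison_group"] == g).sum() >= 2
        }
        if len(vectors) < 2:
            raise InferenceError("fewer than two pooled comparison groups with n >= 2")
        results = [
            anova_one_way(
                list(vectors.values()),
                labels=tuple(vectors),
                alpha=alpha,
                metric=metric,
            )
        ]
        results.extend(_pairwise(vectors, metric, alpha, welch))
        return results

    raise InferenceError(f"unknown metric {metric!r}")
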