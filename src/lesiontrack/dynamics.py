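"""State-transition structure and trend/group statistics for myeloid behavior.

Behavior sequences are per-lesion categorical time series over the four
organizational states, sampled at biweekly imaging sessions. The transition map
reports, per state, the probability of maintaining versus changing behavior
between consecutive sessions — estimated per mouse and then averaged across
mice (mean +/- SEM), matching how the imaging cohort was summarised.

Maintenance-versus-age trends are tested with the Cochran–Armitage trend test,
implemented here with both the asymptotic normal approximation and an exact
conditional permutation p-value for small tables. Group comparisons (e.g.
myeloid displacement stratified by state) use the Kruskal–Wallis omnibus test
with pairwise Mann–Whitney post hocs and multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .types import MYELOID_STATES

__all__ = [
    "TransitionMap",
    "TransitionMapEstimator",
    "transition_map",
    "maintenance_by_age",
    "cochran_armitage",
    "CochranArmitageResult",
    "compare_groups",
    "GroupComparisonResult",
]


@dataclass(frozen=True)
class TransitionMap:
    """Per-state maintenance and change probabilities, mean +/- SEM across mice.

    ``maintenance`` is indexed by state with columns ``mean``, ``sem``,
    ``n_mice``; ``change`` is indexed by (from_state, to_state) with the same
    columns; ``per_mouse`` holds the underlying per-mouse conditional
    frequencies and transition counts.
    """

    maintenance: pd.DataFrame
    change: pd.DataFrame
    per_mouse: pd.DataFrame
    n_transitions: pd.Series


class TransitionMapEstimator(BaseEstimator):
    """Estimate the 4-state behavior transition map from lesion sequences.

    ``fit`` consumes a long-format table with columns ``lesion_id``,
    ``mouse_id``, ``session`` and ``state``; consecutive sessions of the same
    lesion form one transition. Conditional frequencies are computed per mouse
    (states with zero outgoing transitions in a mouse are excluded from that
    mouse's average for that state), then averaged unweighted across mice with
    the standard error of that mean. Set ``pooled=True`` to pool transitions
    across mice instead.
    """

    def __init__(self, pooled: bool = False, states: tuple = MYELOID_STATES):
        self.pooled = pooled
        self.states = states

    def _transition_pairs(self, X: pd.DataFrame) -> pd.DataFrame:
        unknown = set(X["state"]) - set(self.states)
        if unknown:
            raise ValueError(f"unknown state names: {sorted(unknown)}")
        pairs = []
        for (lesion, mouse), grp in X.groupby(["lesion_id", "mouse_id"], sort=True):
            grp = grp.sort_values("session")
            s = grp["state"].to_numpy()
            for a, b in zip(s[:-1], s[1:]):
                pairs.append((mouse, lesion, a, b))
        return pd.DataFrame(pairs, columns=["mouse_id", "lesion_id", "from_state", "to_state"])

    def fit(self, X: pd.DataFrame, y=None):  # noqa: ARG002
        pairs = self._transition_pairs(X)
        if pairs.empty:
            raise ValueError("no transitions observed (need >= 2 sessions for some lesion)")
        group_col = "__all__" if self.pooled else "mouse_id"
        if self.pooled:
            pairs = pairs.assign(__all__="pooled")
        rows = []
        for (unit, frm), grp in pairs.groupby([group_col, "from_state"], sort=True):
            n = len(grp)
            maintain = float((grp["to_state"] == frm).mean())
            row = {"unit": unit, "from_state": frm, "n": n, "maintain": maintain}
            for dest in self.states:
                if dest != frm:
                    row[f"to:{dest}"] = float((grp["to_state"] == dest).mean())
            rows.append(row)
        per_mouse = pd.DataFrame(rows)

        def mean_sem(series: pd.Series) -> tuple[float, float, int]:
            vals = series.dropna().to_numpy(dtype=float)
            if vals.size == 0:
                return np.nan, np.nan, 0
            sem = 0.0 if vals.size == 1 else float(vals.std(ddof=1) / np.sqrt(vals.size))
            return float(vals.mean()), sem, int(vals.size)

        maint_rows, change_rows = [], []
        for frm in self.states:
            sub = per_mouse[per_mouse["from_state"] == frm]
            if sub.empty:
                continue
            m, s, k = mean_sem(sub["maintain"])
            maint_rows.append({"state": frm, "mean": m, "sem": s, "n_mice": k})
            for dest in self.states:
                if dest == frm:
                    continue
                m, s, k = mean_sem(sub[f"to:{dest}"])
                change_rows.append(
                    {"from_state": frm, "to_state": dest, "mean": m, "sem": s, "n_mice": k}
                )
        self.map_ = TransitionMap(
            maintenance=pd.DataFrame(maint_rows).set_index("state"),
            change=pd.DataFrame(change_rows).set_index(["from_state", "to_state"]),
            per_mouse=per_mouse,
            n_transitions=pairs.groupby("from_state").size(),
        )
        return self

    def change_probability(self, state: str) -> float:
        """1 - mean maintenance probability for ``state``."""
        return 1.0 - float(self.map_.maintenance.loc[state, "mean"])


def transition_map(sequences: pd.DataFrame, pooled: bool = False) -> TransitionMap:
    """Functional wrapper over :class:`TransitionMapEstimator`."""
    return TransitionMapEstimator(pooled=pooled).fit(sequences).map_


@dataclass(frozen=True)
class CochranArmitageResult:
    statistic: float  # Z
    p_value: float  # two-sided asymptotic
    p_exact: float | None  # two-sided exact permutation, when computed
    n: int


def _exact_trend_p(successes: np.ndarray, totals: np.ndarray, scores: np.ndarray) -> float:
    """Exact conditional two-sided p for the score-weighted success count.

    Enumerates every table with the observed margins (multivariate
    hypergeometric null) and sums the probability of tables whose |T - E[T]|
    is at least the observed one. Feasible for small n.
    """
    R1 = int(successes.sum())
    N = int(totals.sum())
    t_obs = float(scores @ successes)
    e_t = R1 / N * float(scores @ totals)
    target = abs(t_obs - e_t) - 1e-9
    denom = comb(N, R1)
    K = len(totals)

    p = 0.0
    stack = [(0, R1, 1, 0.0)]  # (col index, successes left, ways, partial T)
    while stack:
        k, left, ways, t_part = stack.pop()
        if k == K - 1:
            if 0 <= left <= totals[k]:
                t = t_part + scores[k] * left
                if abs(t - e_t) >= target:
                    p += ways * comb(int(totals[k]), left) / denom
            continue
        rest = int(totals[k + 1 :].sum())
        lo = max(0, left - rest)
        hi = min(int(totals[k]), left)
        for x in range(lo, hi + 1):
            stack.append((k + 1, left - x, ways * comb(int(totals[k]), x), t_part + scores[k] * x))
    return min(p, 1.0)


def cochran_armitage(
    table, scores=None, method: str = "asymptotic"
) -> CochranArmitageResult:
    """Cochran–Armitage test for trend in a 2 x K table of counts.

    Row 0 holds "successes" (e.g. maintained), row 1 "failures" across K
    ordered categories. The statistic is Z = (T - E[T]) / sqrt(Var T) with
    T the score-weighted success count and the variance taken conditional on
    the margins (hypergeometric, including the N/(N-1) factor); the two-sided
    p-value uses the normal approximation. ``method="exact"`` adds a full
    conditional permutation p-value (intended for total n <= ~30). Z is
    invariant under affine transformation of the scores.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2 or table.shape[1] < 2:
        raise ValueError("table must be 2 x K with K >= 2")
    if np.any(table < 0) or not np.all(np.isfinite(table)):
        raise ValueError("counts must be non-negative and finite")
    K = table.shape[1]
    scores = np.arange(K, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if scores.shape != (K,) or np.any(np.diff(scores) <= 0):
        raise ValueError("scores must be K strictly increasing values")
    successes = table[0]
    totals = table.sum(axis=0)
    N = float(totals.sum())
    R1 = float(successes.sum())
    if N == 0 or R1 == 0 or R1 == N:
        raise ValueError("degenerate table: a zero margin leaves the trend undefined")
    pbar = R1 / N
    t = float(scores @ successes)
    e_t = pbar * float(scores @ totals)
    s2 = float(totals @ scores**2) - float(totals @ scores) ** 2 / N
    var = pbar * (1.0 - pbar) * (N / (N - 1.0)) * s2
    if var <= 0:
        raise ValueError("zero trend variance (all mass in one column)")
    z = (t - e_t) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    p_exact = None
    if method == "exact":
        p_exact = _exact_trend_p(successes.astype(int), totals.astype(int), scores)
    elif method != "asymptotic":
        raise ValueError(f"unknown method {method!r}")
    return CochranArmitageResult(statistic=float(z), p_value=float(p), p_exact=p_exact, n=int(N))


def maintenance_by_age(
    sequences: pd.DataFrame,
    state: str,
    age_bin_edges,
    scores=None,
    method: str = "asymptotic",
):
    """Maintenance probability of ``state`` per lesion-age bin, with trend test.

    ``sequences`` needs columns ``lesion_id``, ``mouse_id``, ``session``,
    ``state`` and ``lesion_age`` (weeks since the lesion's first detected
    session, attached to the *origin* session of each transition). Transitions
    out of ``state`` are binned by age; each bin contributes (maintained,
    changed) counts to a 2 x K table tested by :func:`cochran_armitage` with
    bin-midpoint scores unless ``scores`` is given.

    Returns (DataFrame per bin, CochranArmitageResult).
    """
    edges = np.asarray(age_bin_edges, dtype=float)
    if edges.size < 3:
        raise ValueError("need at least 2 age bins (3 edges)")
    rows = []
    for (lesion, mouse), grp in sequences.groupby(["lesion_id", "mouse_id"], sort=True):
        grp = grp.sort_values("session")
        s = grp["state"].to_numpy()
        age = grp["lesion_age"].to_numpy(dtype=float)
        for i in range(len(s) - 1):
            if s[i] == state:
                rows.append((age[i], s[i + 1] == state))
    if not rows:
        raise ValueError(f"no transitions out of state {state!r}")
    df = pd.DataFrame(rows, columns=["age", "maintained"])
    df["bin"] = pd.cut(df["age"], edges, right=False, include_lowest=True)
    tab = df.groupby("bin", observed=False)["maintained"].agg(["sum", "count"])
    keep = tab["count"] > 0
    tab = tab[keep]
    if len(tab) < 2:
        raise ValueError("fewer than 2 age bins contain transitions")
    maintained = tab["sum"].to_numpy(dtype=float)
    totals = tab["count"].to_numpy(dtype=float)
    mid = np.array([(iv.left + iv.right) / 2 for iv in tab.index], dtype=float)
    use_scores = mid if scores is None else np.asarray(scores, dtype=float)[keep.to_numpy()]
    result = cochran_armitage(
        np.vstack([maintained, totals - maintained]), use_scores, method=method
    )
    out = pd.DataFrame(
        {
            "age_mid": mid,
            "n_transitions": totals.astype(int),
            "maintenance": maintained / totals,
        }
    )
    return out, result


@dataclass(frozen=True)
class GroupComparisonResult:
    statistic: float  # Kruskal-Wallis H (tie corrected)
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, u_statistic, p, p_adj


def compare_groups(groups: dict, adjust: str = "fdr_bh") -> GroupComparisonResult:
    """Kruskal–Wallis omnibus with pairwise Mann–Whitney post hocs.

    ``groups`` maps group name to a 1D array of observations (each nonempty).
    Pairwise two-sided Mann–Whitney p-values are adjusted by Benjamini–
    Hochberg by default (``adjust="holm"`` for Holm). Identical values across
    all groups yield statistic 0 and p 1.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    for g, arr in zip(names, arrays):
        if arr.size == 0:
            raise ValueError(f"group {g!r} has zero observations")
    if np.ptp(np.concatenate(arrays)) == 0:  # identical values: statistic 0 by convention
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            u, pw = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            rows.append({"group1": names[i], "group2": names[j], "u_statistic": float(u), "p": float(pw)})
    pairwise = pd.DataFrame(rows)
    pairwise["p_adj"] = multipletests(pairwise["p"], method=adjust)[1]
    return GroupComparisonResult(statistic=float(h), p_value=float(p), pairwise=pairwise)
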