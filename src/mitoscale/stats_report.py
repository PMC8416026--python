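"""Two-tier statistics for grouped per-nucleus measurements.

Imaging measurements arrive as (condition, replicate, nucleus, value)
records.  Within a replicate, conditions are compared with a two-tailed
Mann-Whitney U test; across replicates, values are first normalized so the
control condition's median is exactly 1 in every replicate, per-replicate
medians are aggregated, and conditions are compared with an unpaired
equal-variance Student's t-test on those medians.  This separates
within-experiment significance from between-experiment reproducibility
without assuming normality of the per-nucleus distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupedMeasurements",
    "normalize_to_control",
    "mann_whitney",
    "MannWhitneyResult",
    "t_test_on_medians",
    "TTestResult",
    "condition_summary",
]


@dataclass
class GroupedMeasurements:
    """Records of (condition, replicate, unit, value) with a control label."""

    df: pd.DataFrame
    control: str = "dIgG"

    def __post_init__(self):
        required = {"condition", "replicate", "value"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        if len(self.df) == 0:
            raise ValueError("no measurement records")

    @classmethod
    def from_csv(cls, path, control="dIgG") -> "GroupedMeasurements":
        return cls(pd.read_csv(path), control=control)

    def values(self, condition, replicate=None) -> np.ndarray:
        sel = self.df["condition"] == condition
        if replicate is not None:
            sel &= self.df["replicate"] == replicate
        return self.df.loc[sel, "value"].to_numpy(dtype=float)

    @property
    def replicates(self) -> list:
        return sorted(self.df["replicate"].unique())

    @property
    def conditions(self) -> list:
        return list(self.df["condition"].unique())


def normalize_to_control(g: GroupedMeasurements) -> GroupedMeasurements:
    """Divide every value by its replicate's control median.

    After normalization the control median is exactly 1 in each replicate;
    the operation is idempotent.
    """
    out = g.df.copy()
    for rep in g.replicates:
        ctrl = g.values(g.control, rep)
        if len(ctrl) == 0:
            raise ValueError(f"control condition {g.control!r} absent in replicate {rep!r}")
        med = float(np.median(ctrl))
        if med == 0:
            raise ValueError(f"control median is zero in replicate {rep!r}")
        sel = out["replicate"] == rep
        out.loc[sel, "value"] = out.loc[sel, "value"] / med
    return GroupedMeasurements(out, control=g.control)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float          # min(U_a, U_b) convention
    p: float          # two-tailed
    n_a: int
    n_b: int
    method: str       # "exact" or "normal"


def _exact_u_distribution(n: int, m: int) -> np.ndarray:
    """Counts of rank configurations per U value (no ties), via the standard
    recurrence f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u)."""
    # table[u] for current (n_cur, m); build up in n
    max_u = n * m
    prev = np.zeros((m + 1, max_u + 1), dtype=float)
    prev[:, 0] = 1.0  # n_cur = 0
    for n_cur in range(1, n + 1):
        cur = np.zeros_like(prev)
        cur[0, 0] = 1.0
        for m_cur in range(1, m + 1):
            shifted = np.zeros(max_u + 1)
            shifted[m_cur:] = prev[m_cur, :max_u + 1 - m_cur]
            cur[m_cur] = shifted + cur[m_cur - 1]
        prev = cur
    return prev[m]


def mann_whitney(a, b) -> MannWhitneyResult:
    """Two-tailed Mann-Whitney U test.

    U is reported as min(U_a, U_b).  With no ties and both groups of 20 or
    fewer, the p-value is exact: the permutation probability that min(U)
    is at most the observed value under the null.  Otherwise a normal
    approximation with tie correction and continuity correction is used.
    If all pooled values are identical, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(n_a * n_b / 2.0, 1.0, n_a, n_b, "degenerate")
    ranks = sps.rankdata(pooled)
    r_a = ranks[:n_a].sum()
    u_a = r_a - n_a * (n_a + 1) / 2.0
    u_b = n_a * n_b - u_a
    u = min(u_a, u_b)
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    if not has_ties and max(n_a, n_b) <= 20:
        dist = _exact_u_distribution(n_a, n_b)
        total = dist.sum()
        lo = dist[: int(u) + 1].sum()
        hi = dist[int(np.ceil(n_a * n_b - u)):].sum()
        p = min(1.0, (lo + hi) / total) if u < n_a * n_b - u else 1.0
        return MannWhitneyResult(float(u), float(p), n_a, n_b, "exact")
    n = n_a + n_b
    mu = n_a * n_b / 2.0
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return MannWhitneyResult(float(u), 1.0, n_a, n_b, "normal")
    z = (u - mu + 0.5) / np.sqrt(var)  # continuity correction toward the mean
    p = min(1.0, 2.0 * sps.norm.cdf(z))
    return MannWhitneyResult(float(u), float(p), n_a, n_b, "normal")


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    medians_a: tuple
    medians_b: tuple
    degenerate: bool = False


def replicate_medians(g: GroupedMeasurements, condition) -> np.ndarray:
    meds = [np.median(g.values(condition, rep)) for rep in g.replicates
            if len(g.values(condition, rep))]
    return np.asarray(meds, dtype=float)


def t_test_on_medians(g: GroupedMeasurements, cond_a, cond_b) -> TTestResult:
    """Unpaired equal-variance Student's t-test on per-replicate medians.

    Each replicate contributes its median as one observation, so the test
    reflects between-experiment reproducibility.  With zero pooled variance
    the result is flagged degenerate (unless the means also agree, in which
    case t = 0, p = 1).
    """
    ma = replicate_medians(g, cond_a)
    mb = replicate_medians(g, cond_b)
    if len(ma) < 2 or len(mb) < 2:
        raise ValueError("need >= 2 replicates per condition for the t-test")
    if np.var(ma) == 0 and np.var(mb) == 0:
        if ma.mean() == mb.mean():
            return TTestResult(0.0, 1.0, tuple(ma), tuple(mb))
        return TTestResult(np.nan, np.nan, tuple(ma), tuple(mb), degenerate=True)
    t, p = sps.ttest_ind(ma, mb, equal_var=True)
    return TTestResult(float(t), float(p), tuple(ma), tuple(mb))


def condition_summary(g: GroupedMeasurements, test: str = "mw") -> pd.DataFrame:
    """Per-condition summary versus the control: n, median, and p-value.

    ``test="mw"`` pools all values per condition (Mann-Whitney, two-tailed);
    ``test="t-medians"`` compares per-replicate medians (Student's t).
    """
    rows = []
    for cond in g.conditions:
        vals = g.values(cond)
        row = {"condition": cond, "n": len(vals), "median": float(np.median(vals))}
        if cond != g.control:
            if test == "mw":
                res = mann_whitney(g.values(g.control), vals)
                row.update({"statistic": res.u, "p": res.p, "test": "mann-whitney-U(min)"})
            elif test == "t-medians":
                res = t_test_on_medians(g, g.control, cond)
                row.update({"statistic": res.t, "p": res.p, "test": "t-on-medians"})
            else:
                raise ValueError(f"unknown test {test!r}")
        rows.append(row)
    return pd.DataFrame(rows)
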