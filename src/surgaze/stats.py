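"""Group-level inference from summary statistics.

The study reports each gaze and tear metric as per-group mean +/- SD with
n = 5 participants per group, and analyses them with a five-group one-way
ANOVA followed by Tukey's HSD (alpha = 0.05) and Pearson correlations. Raw
per-participant values were not deposited, so this module implements the
entire inference layer directly from (label, n, mean, sd) tuples:

* one-way ANOVA from summaries — SS_between = sum n_i (m_i - grand)^2,
  MS_within = pooled variance = sum (n_i - 1) s_i^2 / sum (n_i - 1);
* Tukey HSD for the balanced design — q_ij = |m_i - m_j| / sqrt(MS_w / n),
  with p-values from the studentized range distribution (k groups,
  df = sum (n_i - 1));
* Pearson product-moment correlation with a two-sided t-test p-value.

These reductions are exact: an ANOVA computed from summaries equals the
ANOVA of any raw sample whose per-group moments match, which is how the
implementation is cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyPair",
    "TukeyResult",
    "CorrelationResult",
    "anova_oneway_from_summary",
    "tukey_hsd_from_summary",
    "studentized_range_sf",
    "pearson_correlation",
    "moment_matched_sample",
    "read_group_summaries",
    "write_group_summaries",
]


@dataclass(frozen=True)
class GroupSummary:
    """One group's printed summary: label, sample size, mean, SD (ddof=1)."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0 or not math.isfinite(self.sd):
            raise ValueError(f"group {self.label!r}: sd must be finite and >= 0")
        if not math.isfinite(self.mean):
            raise ValueError(f"group {self.label!r}: mean must be finite")


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    p: float
    reason: str | None = None


@dataclass(frozen=True)
class TukeyPair:
    label_i: str
    label_j: str
    mean_diff: float
    q: float
    p: float
    significant: bool


@dataclass(frozen=True)
class TukeyResult:
    pairs: list[TukeyPair] = field(default_factory=list)
    ms_within: float = float("nan")
    df_within: int = 0
    k: int = 0
    alpha: float = 0.05

    def pair(self, a: str, b: str) -> TukeyPair:
        """Look up a contrast by its two labels, order-insensitively."""
        for p in self.pairs:
            if {p.label_i, p.label_j} == {a, b}:
                return p
        raise KeyError(f"no contrast between {a!r} and {b!r}")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    r_squared: float
    n: int
    p: float


def _check_groups(groups: list[GroupSummary]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")


def anova_oneway_from_summary(groups: list[GroupSummary]) -> AnovaResult:
    """One-way fixed-effects ANOVA computed from per-group (n, mean, sd).

    Equals the raw-data ANOVA of any sample matching those moments exactly.
    When every group mean is identical and every SD is zero the F statistic
    is 0/0; the result carries NaNs and a reason string instead.
    """
    _check_groups(groups)
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups], dtype=float)
    s = np.array([g.sd for g in groups], dtype=float)

    df_b = len(groups) - 1
    df_w = int(np.sum(n - 1))
    grand = float(np.sum(n * m) / np.sum(n))
    ss_b = float(np.sum(n * (m - grand) ** 2))
    ss_w = float(np.sum((n - 1) * s**2))
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        if ss_b == 0.0:
            return AnovaResult(
                F=float("nan"), df_between=df_b, df_within=df_w,
                ms_between=ms_b, ms_within=ms_w, p=float("nan"),
                reason="all group means equal and all SDs zero: F undefined",
            )
        # separated means with zero spread: F diverges
        return AnovaResult(
            F=float("inf"), df_between=df_b, df_within=df_w,
            ms_between=ms_b, ms_within=ms_w, p=0.0,
        )
    F = ms_b / ms_w
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(F=F, df_between=df_b, df_within=df_w,
                       ms_between=ms_b, ms_within=ms_w, p=p)


def studentized_range_sf(q: float, k: int, df: int) -> float:
    """Upper-tail probability of the studentized range distribution.

    P(Q > q) for the range of k independent group means over the pooled
    standard error with df error degrees of freedom. Monotone decreasing
    in q; this is the reference null for Tukey's HSD.
    """
    if not (q >= 0 and math.isfinite(q)) and not math.isinf(q):
        raise ValueError(f"q must be >= 0, got {q}")
    if q < 0:
        raise ValueError(f"q must be >= 0, got {q}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if q == 0.0:
        return 1.0
    if math.isinf(q):
        return 0.0
    return float(sps.studentized_range.sf(q, k, df))


def tukey_hsd_from_summary(groups: list[GroupSummary], alpha: float = 0.05) -> TukeyResult:
    """All-pairs Tukey HSD for a balanced design, from group summaries.

    Requires equal n across groups (the study's design; the Tukey-Kramer
    unequal-n extension is deliberately out of scope). Each contrast gets
    q_ij = |m_i - m_j| / sqrt(MS_within / n) and a p-value from the
    studentized range with k groups and df = k (n - 1).
    """
    _check_groups(groups)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    ns = {g.n for g in groups}
    if len(ns) != 1:
        raise ValueError(f"Tukey HSD requires equal group sizes, got n = {sorted(ns)}")
    n = groups[0].n
    k = len(groups)
    df_w = k * (n - 1)
    ms_w = float(np.mean([g.sd**2 for g in groups]))  # pooled, equal n
    se = math.sqrt(ms_w / n) if ms_w > 0 else 0.0

    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gi.mean - gj.mean
            if se > 0:
                q = abs(diff) / se
                p = studentized_range_sf(q, k, df_w)
            else:
                q = float("inf") if diff != 0 else 0.0
                p = 0.0 if diff != 0 else 1.0
            pairs.append(TukeyPair(gi.label, gj.label, diff, q, p, p < alpha))
    return TukeyResult(pairs=pairs, ms_within=ms_w, df_within=df_w, k=k, alpha=alpha)


def pearson_correlation(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p (t, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return CorrelationResult(r=r, r_squared=r * r, n=len(x), p=float(res.pvalue))


def moment_matched_sample(n: int, mean: float, sd: float, rng=None) -> np.ndarray:
    """A raw sample of size n with *exactly* the given mean and SD (ddof=1).

    Draws a base sample (or uses a fixed pattern when rng is None) and
    standardises it, so summary-statistic formulas can be cross-checked
    against raw-data routines.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if rng is None:
        base = np.linspace(-1.0, 1.0, n)
    else:
        base = rng.standard_normal(n)
        while np.std(base) == 0:  # pragma: no cover - measure-zero event
            base = rng.standard_normal(n)
    z = (base - base.mean()) / np.std(base, ddof=1)
    return mean + sd * z


def read_group_summaries(path) -> list[GroupSummary]:
    """Read `label,n,mean,sd` CSV rows into GroupSummary objects."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"label", "n", "mean", "sd"}
    if not required.issubset(df.columns):
        raise ValueError(f"summary CSV must have columns {sorted(required)}")
    return [
        GroupSummary(str(r.label), int(r.n), float(r.mean), float(r.sd))
        for r in df.itertuples()
    ]


def write_group_summaries(groups: list[GroupSummary], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [{"label": g.label, "n": g.n, "mean": g.mean, "sd": g.sd} for g in groups]
    ).to_csv(path, index=False)
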