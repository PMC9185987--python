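"""Cross-sectional group comparisons: Welch's t-test and one-way ANOVA.

The summary-statistics entry point is first-class: published tables report
mean +/- SD and n per group, and Welch's test is fully determined by those,
so baseline comparisons are reproducible without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: star thresholds used in the comparison tables
STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD summary of one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2 per group, got n={self.n}")
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @classmethod
    def from_samples(cls, x) -> "GroupSummary":
        x = np.asarray(x, dtype=float)
        return cls(mean=float(x.mean()), sd=float(x.std(ddof=1)), n=x.size)


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch's two-sided t-test from group summaries or raw samples.

    Arguments may be :class:`GroupSummary` instances or raw sample arrays
    (summaries are computed first, so both paths agree exactly).  Returns
    ``(t, df, p)`` with the Welch–Satterthwaite degrees of freedom

        t  = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
        df = (s_a^2/n_a + s_b^2/n_b)^2 /
             [ (s_a^2/n_a)^2/(n_a-1) + (s_b^2/n_b)^2/(n_b-1) ]
    """
    if not isinstance(a, GroupSummary):
        a = GroupSummary.from_samples(a)
    if not isinstance(b, GroupSummary):
        b = GroupSummary.from_samples(b)
    va, vb = a.sd**2 / a.n, b.sd**2 / b.n
    se = np.sqrt(va + vb)
    t = (a.mean - b.mean) / se
    df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def anova_oneway(*groups) -> tuple[float, float]:
    """One-way ANOVA F-test across >= 2 raw samples."""
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups, got {len(groups)}")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs n >= 2")
    f, p = sps.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def significance_stars(p: float) -> str:
    """Star marker at the 0.05/0.01/0.001/0.0001 conventions ('' if ns)."""
    for level, stars in STAR_LEVELS:
        if p < level:
            return stars
    return ""
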