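"""Group statistics: mean +/- SEM, one-way ANOVA, one-sided unpaired t-tests.

Matches the conventions of the morphometric group comparisons this package
supports: descriptive statistics as mean +/- SEM, omnibus comparison across
three treatment groups by fixed-effects one-way ANOVA, and directional
pairwise comparisons by the pooled-variance (Student's) unpaired t-test.
No multiple-testing correction is applied by default; per-comparison
p-values are reported as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass
class GroupSample:
    """Per-object metric values for one experimental group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class TestResult:
    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    groups: tuple[str, ...]
    direction: str | None = None
    flags: list[str] = field(default_factory=list)


def summarize(values: Sequence[float]) -> tuple[float, float | None, int]:
    """Mean, SEM (sample sd over sqrt(n); None when n = 1) and n."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else None
    return mean, sem, int(v.size)


def one_way_anova(samples: Sequence[GroupSample]) -> TestResult:
    """Classical fixed-effects one-way ANOVA across k groups."""
    if len(samples) < 2:
        raise ValueError("ANOVA needs at least two groups")
    for s in samples:
        if s.n < 2:
            raise ValueError(f"group {s.label!r} has n={s.n}; ANOVA needs n >= 2 per group")
    f, p = sps.f_oneway(*[s.values for s in samples])
    k = len(samples)
    n_total = sum(s.n for s in samples)
    return TestResult(
        test="one-way ANOVA",
        statistic=float(f),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(p),
        groups=tuple(s.label for s in samples),
    )


def one_sided_t(
    sample_a: GroupSample,
    sample_b: GroupSample,
    direction: str,
    equal_var: bool = True,
) -> TestResult:
    """One-sided unpaired t-test (pooled variance by default; Welch optional).

    ``direction`` states the alternative hypothesis explicitly: ``"a>b"`` or
    ``"b>a"``.  When both samples are constant and equal, the test is
    undefined; by convention p = 0.5 is reported with a flag.
    """
    if direction not in ("a>b", "b>a"):
        raise ValueError("direction must be 'a>b' or 'b>a' (no silent default)")
    if sample_a.n < 2 or sample_b.n < 2:
        raise ValueError("each group needs n >= 2")
    alternative = "greater" if direction == "a>b" else "less"
    import warnings

    with warnings.catch_warnings():
        # near-constant input is handled explicitly below via the p=0.5 convention
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(
            sample_a.values, sample_b.values, equal_var=equal_var, alternative=alternative
        )
    df = float(res.df)
    stat, p = float(res.statistic), float(res.pvalue)
    flags: list[str] = []
    if not np.isfinite(stat):  # zero pooled variance
        if np.isclose(sample_a.values.mean(), sample_b.values.mean()):
            stat, p = 0.0, 0.5
            flags.append("zero_variance_equal_means")
        else:
            p = 0.0 if (sample_a.values.mean() > sample_b.values.mean()) == (
                direction == "a>b"
            ) else 1.0
            stat = np.inf if p == 0.0 else -np.inf
            flags.append("zero_variance")
    return TestResult(
        test="Student's t (unpaired, one-sided)" if equal_var else "Welch t (one-sided)",
        statistic=stat,
        df=(df,),
        p_value=p,
        groups=(sample_a.label, sample_b.label),
        direction=direction,
        flags=flags,
    )
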