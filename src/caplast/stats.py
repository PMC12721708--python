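"""Normality-gated test selection.

Every comparison first runs the Lilliefors test (Kolmogorov–Smirnov with
estimated mean and variance) on each sample at α = 0.05.  The decision
table is total:

====================  =========================  =========================
design                normality outcome          chosen test
====================  =========================  =========================
paired                both normal                paired t-test
paired                otherwise                  Wilcoxon signed-rank
unpaired              both normal, equal var     unpaired (Student) t-test
unpaired              both normal, unequal var   Welch's t-test
unpaired              otherwise                  Wilcoxon rank-sum
categorical           —                          Chi-squared (no continuity
                                                 correction)
factorial             —                          two-way ANOVA (fixed
                                                 effects with interaction)
====================  =========================  =========================

Variance equality is judged by a two-sided F-ratio test at α = 0.05.
Samples too small for Lilliefors (n < 4) fall back to the non-parametric
branch with a warning.  Significance labels: * p<0.05, ** p<0.01,
*** p<0.001, else n.s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .errors import ValidationError

__all__ = ["TestDecision", "lilliefors", "select_and_run", "significance_label"]

ALPHA = 0.05


@dataclass
class TestDecision:
    design: str
    chosen_test: str
    statistic: float
    p_value: float
    normal_a: bool | None = None
    normal_b: bool | None = None
    equal_var: bool | None = None
    label: str = ""
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.label:
            self.label = significance_label(self.p_value)


def significance_label(p: float) -> str:
    if np.isnan(p):
        return "undefined"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "n.s."


def lilliefors(sample) -> tuple[float, float]:
    """Lilliefors normality test: KS distance to a normal with estimated
    mean/SD, p from the published small-sample table.  Constant samples are
    degenerate and reported maximally non-normal (p = 0)."""
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 4:
        raise ValidationError("Lilliefors needs n >= 4")
    if np.ptp(x) == 0:
        return np.inf, 0.0
    stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def _is_normal(x, alpha=ALPHA):
    try:
        _, p = lilliefors(x)
    except ValidationError:
        return None  # too small to assess
    return p >= alpha


def _f_ratio_equal_var(a, b, alpha=ALPHA) -> bool:
    """Two-sided F-ratio test of equal variances at ``alpha``."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        return True
    hi, lo = max(va, vb), min(va, vb)
    if lo == 0:
        return False
    n_hi = len(a) if va >= vb else len(b)
    n_lo = len(b) if va >= vb else len(a)
    f = hi / lo
    p = 2.0 * sps.f.sf(f, n_hi - 1, n_lo - 1)
    return min(p, 1.0) >= alpha


def select_and_run(design: str, sample_a, sample_b=None, alpha: float = ALPHA,
                   data: pd.DataFrame | None = None) -> TestDecision:
    """Run the normality-gated comparison appropriate for ``design``.

    design="paired"/"unpaired": sample_a, sample_b are the two samples.
    design="categorical": sample_a is the contingency table.
    design="factorial": ``data`` is a DataFrame with columns y, a, b; the
    reported statistic/p are the interaction term's.
    """
    if design == "categorical":
        table = np.asarray(sample_a, dtype=float)
        res = sps.chi2_contingency(table, correction=False)
        return TestDecision(
            design=design,
            chosen_test="chi-squared",
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            details={"dof": int(res.dof)},
        )

    if design == "factorial":
        if data is None:
            raise ValidationError("factorial design needs a DataFrame (y, a, b)")
        model = ols("y ~ C(a) * C(b)", data=data).fit()
        table = anova_lm(model, typ=2)
        inter = table.loc["C(a):C(b)"]
        return TestDecision(
            design=design,
            chosen_test="two-way ANOVA",
            statistic=float(inter["F"]),
            p_value=float(inter["PR(>F)"]),
            details={"anova_table": table},
        )

    a = np.asarray(sample_a, dtype=float).ravel()
    if sample_b is None:
        raise ValidationError("two samples required for paired/unpaired designs")
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("samples must be non-empty")

    if design == "paired":
        if a.size != b.size:
            raise ValidationError("paired samples must have equal length")
        na, nb = _is_normal(a, alpha), _is_normal(b, alpha)
        if na is None or nb is None:
            warnings.warn(
                "sample too small for Lilliefors; falling back to signed-rank",
                stacklevel=2,
            )
            na = nb = False
        diffs = a - b
        if np.all(diffs == 0):
            # degenerate: both tests sit at their null centre
            name = "paired t-test" if (na and nb) else "wilcoxon signed-rank"
            return TestDecision(design, name, 0.0, 1.0,
                                normal_a=na, normal_b=nb,
                                details={"note": "all differences zero"})
        if na and nb:
            t, p = sps.ttest_rel(a, b)
            return TestDecision(design, "paired t-test", float(t), float(p),
                                normal_a=na, normal_b=nb)
        stat, p = sps.wilcoxon(a, b)
        return TestDecision(design, "wilcoxon signed-rank", float(stat), float(p),
                            normal_a=na, normal_b=nb)

    if design == "unpaired":
        na, nb = _is_normal(a, alpha), _is_normal(b, alpha)
        if na is None or nb is None:
            warnings.warn(
                "sample too small for Lilliefors; falling back to rank-sum",
                stacklevel=2,
            )
            na = nb = False
        if na and nb:
            equal = _f_ratio_equal_var(a, b, alpha)
            if equal:
                t, p = sps.ttest_ind(a, b, equal_var=True)
                return TestDecision(design, "unpaired t-test", float(t), float(p),
                                    normal_a=na, normal_b=nb, equal_var=True)
            t, p = sps.ttest_ind(a, b, equal_var=False)
            return TestDecision(design, "welch t-test", float(t), float(p),
                                normal_a=na, normal_b=nb, equal_var=False)
        stat, p = sps.ranksums(a, b)
        return TestDecision(design, "wilcoxon rank-sum", float(stat), float(p),
                            normal_a=na, normal_b=nb)

    raise ValidationError(f"unknown design {design!r}")
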