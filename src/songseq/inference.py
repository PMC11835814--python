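"""Cross-context statistical comparisons.

Wraps the standard tests used to compare song features and degree of
learning across social contexts: two-sample proportion test (chi-square,
optionally continuity-corrected, as in R's ``prop.test``), one-way ANOVA
with Tukey-Kramer pairwise comparisons, main-effects N-way ANOVA, paired
t-tests, and Pearson correlation. Each returns a :class:`TestResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "TestResult",
    "two_proportion_test",
    "oneway_anova",
    "nway_anova_main_effects",
    "paired_t",
    "pearson_correlation",
    "results_to_frame",
]


@dataclass
class TestResult:
    statistic_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    groups: list[str] = field(default_factory=list)
    effect_direction: str | None = None
    pairwise: pd.DataFrame | None = None
    degenerate: bool = False

    def as_row(self) -> dict:
        df = self.df
        df_str = f"{df[0]:g},{df[1]:g}" if isinstance(df, tuple) else f"{df:g}"
        return {
            "test": self.statistic_name,
            "groups": "|".join(self.groups),
            "statistic": self.statistic,
            "df": df_str,
            "p": self.p_value,
        }


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([r.as_row() for r in results])


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, continuity: bool = True
) -> TestResult:
    """Chi-square test of equal proportions for two samples."""
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1:
            raise ValueError("each sample needs at least one trial")
        if not 0 <= k <= n:
            raise ValueError("successes must lie in [0, n]")
    p1, p2 = k1 / n1, k2 / n2
    direction = "decrease" if p2 < p1 else ("increase" if p2 > p1 else "none")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        # Degenerate table: no variation, hence no evidence of a difference.
        return TestResult("two_proportion_chi2", 0.0, 1.0, 1.0,
                          groups=["group1", "group2"], effect_direction="none",
                          degenerate=True)
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    res = st.chi2_contingency(table, correction=continuity)
    return TestResult("two_proportion_chi2", float(res.statistic), float(res.dof),
                      float(res.pvalue), groups=["group1", "group2"],
                      effect_direction=direction)


def oneway_anova(
    values: Sequence[float], groups: Sequence[str]
) -> TestResult:
    """One-way ANOVA with Tukey-Kramer pairwise comparisons."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    levels = sorted(set(groups.tolist()))
    samples = [values[groups == g] for g in levels]
    if len(levels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >= 2 groups with >= 2 values each")
    grand = values.mean()
    ssb = sum(len(s) * (s.mean() - grand) ** 2 for s in samples)
    ssw = sum(((s - s.mean()) ** 2).sum() for s in samples)
    dfb = len(levels) - 1
    dfw = len(values) - len(levels)
    degenerate = False
    if ssw <= 1e-12 * max(1.0, abs(grand)):
        degenerate = True
        if ssb <= 1e-12 * max(1.0, abs(grand)):
            f, p = 0.0, 1.0
        else:
            f, p = np.inf, 0.0
    else:
        f = (ssb / dfb) / (ssw / dfw)
        p = float(st.f.sf(f, dfb, dfw))
    pairwise = None
    if not degenerate:
        tk = pairwise_tukeyhsd(values, groups)
        pairwise = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    return TestResult("oneway_anova_F", float(f), (float(dfb), float(dfw)), float(p),
                      groups=levels, pairwise=pairwise, degenerate=degenerate)


def nway_anova_main_effects(
    values: Sequence[float], factors: Mapping[str, Sequence]
) -> dict[str, TestResult]:
    """Main-effects-only ANOVA for several crossed categorical factors.

    Fits ``y ~ C(f1) + C(f2) + ...`` by least squares; the error df is
    ``N - 1 - sum(levels - 1)``. Raises on rank-deficient (aliased)
    designs, naming the offending factors.
    """
    data = pd.DataFrame({name: pd.Categorical(vals) for name, vals in factors.items()})
    data["y"] = np.asarray(values, dtype=float)
    if any(len(v) != len(data) for v in factors.values()):
        raise ValueError("all factors must match the response length")
    formula = "y ~ " + " + ".join(f"C({name})" for name in factors)
    model = smf.ols(formula, data=data)
    rank = np.linalg.matrix_rank(model.exog)
    if rank < model.exog.shape[1]:
        aliased = _find_aliased(data, list(factors))
        raise ValueError(f"rank-deficient design; aliased factors: {aliased}")
    fit = model.fit()
    expected_df_resid = len(data) - 1 - sum(len(set(map(str, v))) - 1
                                            for v in factors.values())
    if expected_df_resid < 1:
        raise ValueError(
            f"no error degrees of freedom (N={len(data)} too small for the "
            "main-effects design)")
    y = data["y"].to_numpy()
    if np.var(y) <= 1e-20 * max(1.0, float(np.mean(y)) ** 2):
        # constant response: no variation to attribute to any factor
        return {
            name: TestResult(f"anova_main_{name}", 0.0,
                             (float(len(set(map(str, factors[name]))) - 1),
                              float(expected_df_resid)), 1.0,
                             groups=sorted(set(map(str, factors[name]))),
                             degenerate=True)
            for name in factors
        }
    table = sm.stats.anova_lm(fit, typ=2)
    out: dict[str, TestResult] = {}
    for name in factors:
        row = table.loc[f"C({name})"]
        f, p = float(row["F"]), float(row["PR(>F)"])
        if not np.isfinite(f):  # zero residual variance (e.g. constant response)
            ss_effect = float(row["sum_sq"])
            f, p = (0.0, 1.0) if ss_effect <= 1e-12 else (np.inf, 0.0)
        out[name] = TestResult(
            f"anova_main_{name}", f,
            (float(row["df"]), float(expected_df_resid)), p,
            groups=sorted(set(map(str, factors[name]))),
        )
    return out


def _find_aliased(data: pd.DataFrame, names: list[str]) -> list[str]:
    """Factors whose removal restores full rank (aliased with the rest)."""
    aliased = []
    for name in names:
        others = [n for n in names if n != name]
        if not others:
            continue
        formula = "y ~ " + " + ".join(f"C({n})" for n in others)
        sub = smf.ols(formula, data=data)
        if np.linalg.matrix_rank(sub.exog) == sub.exog.shape[1]:
            aliased.append(name)
    return aliased


def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t-test on element-wise differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples of size >= 2")
    d = x - y
    n = len(d)
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            t, p = 0.0, 1.0
        else:
            t, p = np.sign(d.mean()) * np.inf, 0.0
        return TestResult("paired_t", float(t), float(n - 1), float(p),
                          groups=["x", "y"], degenerate=True)
    res = st.ttest_rel(x, y)
    direction = "increase" if d.mean() > 0 else "decrease"
    return TestResult("paired_t", float(res.statistic), float(n - 1),
                      float(res.pvalue), groups=["x", "y"],
                      effect_direction=direction)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with df = n - 2 and two-sided p via the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise ValueError("zero variance input")
    res = st.pearsonr(x, y)
    return TestResult("pearson_r", float(res.statistic), float(len(x) - 2),
                      float(res.pvalue), groups=["x", "y"],
                      effect_direction="positive" if res.statistic > 0 else "negative")
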