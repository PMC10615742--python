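"""Hypothesis tests with effect sizes and magnitude labels.

Every comparison in the package reports both statistical significance (a
p-value) and substantive significance (a standardized effect size): Cohen's
d for t-tests, rank r = |Z|/sqrt(N) for rank tests, eta-squared for ANOVA,
and phi for 2x2 contingency tables.  Magnitude labels follow the standard
behavioural-science conventions (d > 0.2/0.5/0.8 = small/medium/large, etc.).

Exact p-values are used for the rank tests at desk scale (total N <= 12, no
ties) and a tie-corrected normal approximation otherwise; the switch point is
a documented constant, not a heuristic.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateDataError",
    "EffectMetric",
    "Magnitude",
    "EffectSize",
    "TestResult",
    "cohens_d",
    "welch_or_student_t",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "fishers_exact_2x2",
    "two_way_anova",
    "repeated_measures_crossover_anova",
    "kruskal_wallis",
    "adjust_pvalues",
    "magnitude_label",
]

#: total sample size at or below which rank tests use exact enumeration
EXACT_ENUMERATION_MAX_N = 12


class DegenerateDataError(ValueError):
    """Raised when the data carry no information for the requested test
    (zero pooled variance, all observations tied, no nonzero differences)."""


class EffectMetric(str, enum.Enum):
    cohens_d = "cohens_d"
    rank_r = "rank_r"
    eta_squared = "eta_squared"
    phi = "phi"


class Magnitude(str, enum.Enum):
    none = "none"
    very_small = "very_small"
    small = "small"
    medium = "medium"
    large = "large"


# Threshold ladders; a value must strictly exceed a threshold to earn the label.
_THRESHOLDS: dict[EffectMetric, list[tuple[float, Magnitude]]] = {
    EffectMetric.cohens_d: [
        (0.8, Magnitude.large),
        (0.5, Magnitude.medium),
        (0.2, Magnitude.small),
        (0.01, Magnitude.very_small),
    ],
    EffectMetric.rank_r: [
        (0.5, Magnitude.large),
        (0.3, Magnitude.medium),
        (0.1, Magnitude.small),
    ],
    EffectMetric.eta_squared: [
        (0.14, Magnitude.large),
        (0.06, Magnitude.medium),
        (0.01, Magnitude.small),
    ],
    EffectMetric.phi: [
        (0.5, Magnitude.large),
        (0.3, Magnitude.medium),
        (0.1, Magnitude.small),
    ],
}


def magnitude_label(metric: EffectMetric | str, value: float) -> Magnitude:
    """Label an (absolute) effect-size value as none/very_small/small/medium/large."""
    if value < 0:
        raise ValueError("magnitude_label expects a nonnegative (absolute) value")
    try:
        ladder = _THRESHOLDS[EffectMetric(metric)]
    except (KeyError, ValueError):
        raise ValueError(f"unknown effect-size metric: {metric!r}") from None
    for threshold, label in ladder:
        if value > threshold:
            return label
    return Magnitude.none


@dataclass(frozen=True)
class EffectSize:
    """A standardized effect size.

    ``value`` is always nonnegative; the sign of a directed effect (which
    group was larger) is carried separately in ``direction`` (+1, -1 or 0).
    ``defined`` is False when the effect size is not computable (e.g. phi on
    a table with a zero margin) and the value is reported as 0 by convention.
    """

    metric: EffectMetric
    value: float
    direction: int = 0
    defined: bool = True
    magnitude: Magnitude = field(init=False)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("EffectSize.value must be nonnegative")
        object.__setattr__(self, "magnitude", magnitude_label(self.metric, self.value))

    @property
    def signed_value(self) -> float:
        return self.direction * self.value if self.direction else self.value


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_per_group: list[int]
    effect: EffectSize | None
    p_adjusted: float | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")
        if self.p_adjusted is not None and self.p_adjusted < self.p_value - 1e-12:
            raise ValueError("p_adjusted must be >= p_value")

    def to_record(self) -> dict:
        """Flat record for TSV/JSON serialization."""
        eff = self.effect
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p": self.p_value,
            "p_adj": self.p_adjusted,
            "effect_metric": eff.metric.value if eff else None,
            "effect_value": eff.value if eff else None,
            "effect_direction": eff.direction if eff else None,
            "magnitude": eff.magnitude.value if eff else None,
        }


# ---------------------------------------------------------------------------
# two-sample location tests


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size and not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite values")
    return a


def cohens_d(x, y) -> EffectSize:
    """Cohen's d with the pooled (df-weighted) standard deviation.

    d = |mean(x) - mean(y)| / s_pooled,
    s_pooled^2 = ((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2).
    The sign of mean(x) - mean(y) is reported in ``direction``.
    """
    x, y = _as_1d(x), _as_1d(y)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("cohens_d needs at least 2 observations per group")
    diff = x.mean() - y.mean()
    s2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
        len(x) + len(y) - 2
    )
    if s2 <= 0:
        raise DegenerateDataError("zero pooled variance: Cohen's d undefined")
    d = diff / math.sqrt(s2)
    return EffectSize(EffectMetric.cohens_d, abs(d), direction=int(np.sign(d)))


def welch_or_student_t(x, y, variant: str = "welch", sides: str = "two-sided") -> TestResult:
    """Two-sample t-test (Welch by default; Student by ``variant='student'``)."""
    x, y = _as_1d(x), _as_1d(y)
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant: {variant!r}")
    res = sps.ttest_ind(x, y, equal_var=(variant == "student"), alternative=sides)
    effect = cohens_d(x, y)
    return TestResult(
        method=f"t-test ({variant})",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=[len(x), len(y)],
        effect=effect,
        extra={"df": float(res.df)},
    )


def _rank_z(u: float, x: np.ndarray, y: np.ndarray) -> float:
    """Z for the Mann-Whitney U statistic, with tie correction, no continuity
    correction (matches the plain large-sample formula)."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        raise DegenerateDataError("all observations tied: rank test undefined")
    return (u - n1 * n2 / 2.0) / math.sqrt(var_u)


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test with rank r = |Z|/sqrt(N) as effect size.

    Exact p by enumeration when n1+n2 <= 12 and the data are tie-free;
    otherwise the tie-corrected normal approximation.  The rank-biserial
    correlation is reported in ``extra`` as an alternative effect measure.
    """
    x, y = _as_1d(x), _as_1d(y)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("mann_whitney_u needs at least 1 observation per group")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all observations tied: U-test undefined")
    has_ties = len(np.unique(pooled)) < n
    method = "exact" if (n <= EXACT_ENUMERATION_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    u = float(res.statistic)
    z = _rank_z(u, x, y)
    r = abs(z) / math.sqrt(n)
    rank_biserial = 1.0 - 2.0 * u / (n1 * n2)
    return TestResult(
        method=f"Mann-Whitney U ({method})",
        statistic=u,
        p_value=float(res.pvalue),
        n_per_group=[n1, n2],
        effect=EffectSize(EffectMetric.rank_r, min(r, 1.0), direction=int(np.sign(z)) or 0),
        extra={"z": z, "rank_biserial": rank_biserial},
    )


def wilcoxon_signed_rank(before, after, alternative: str = "two-sided") -> TestResult:
    """Paired Wilcoxon signed-rank test; rank r = |Z|/sqrt(n_effective).

    Zero differences are dropped before ranking.  Exact p by sign-flip
    enumeration for n_effective <= 12 with untied |differences|, otherwise the
    normal approximation (no continuity correction).
    """
    before, after = _as_1d(before), _as_1d(after)
    if len(before) != len(after):
        raise ValueError("paired samples must have equal length")
    diffs = after - before
    diffs = diffs[diffs != 0]
    n = len(diffs)
    if n == 0:
        raise DegenerateDataError("no nonzero differences: signed-rank test undefined")
    has_ties = len(np.unique(np.abs(diffs))) < n
    mode = "exact" if (n <= EXACT_ENUMERATION_MAX_N and not has_ties) else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns about the approx at small n
        res = sps.wilcoxon(diffs, alternative=alternative, method=mode, correction=False)
    w = float(res.statistic)
    # Z from the normal approximation (tie-corrected variance of W+).
    ranks = sps.rankdata(np.abs(diffs))
    mean_w = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(diffs), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    if var_w <= 0:
        raise DegenerateDataError("degenerate differences: signed-rank variance zero")
    w_plus = ranks[diffs > 0].sum()
    z = (w_plus - mean_w) / math.sqrt(var_w)
    r = abs(z) / math.sqrt(n)
    return TestResult(
        method=f"Wilcoxon signed-rank ({mode})",
        statistic=w,
        p_value=float(res.pvalue),
        n_per_group=[n],
        effect=EffectSize(EffectMetric.rank_r, min(r, 1.0), direction=int(np.sign(z)) or 0),
        extra={"z": z, "n_dropped_zero": int(len(before) - n)},
    )


def fishers_exact_2x2(table, alternative: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table with phi as effect size.

    Two-sided p is the sum of hypergeometric point probabilities no larger
    than that of the observed table.  phi = (ad-bc)/sqrt of the product of
    the margins; on a table with a zero margin the test is uninformative
    (p = 1) and phi is reported as 0 with ``defined=False``.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be nonnegative")
    if t.sum() == 0:
        raise ValueError("empty table")
    a, b = t[0]
    c, d = t[1]
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        return TestResult(
            method="Fisher exact",
            statistic=float("nan"),
            p_value=1.0,
            n_per_group=[int(a + b), int(c + d)],
            effect=EffectSize(EffectMetric.phi, 0.0, defined=False),
            extra={"odds_ratio": float("nan"), "phi_defined": False},
        )
    res = sps.fisher_exact(t, alternative=alternative)
    num = float(a) * d - float(b) * c
    phi = num / math.sqrt(float(margins[0]) * margins[1] * margins[2] * margins[3])
    return TestResult(
        method="Fisher exact",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        n_per_group=[int(a + b), int(c + d)],
        effect=EffectSize(EffectMetric.phi, abs(phi), direction=int(np.sign(num)) or 0),
        extra={"odds_ratio": float(res.statistic), "phi_defined": True},
    )


# ---------------------------------------------------------------------------
# ANOVA


def _eta_squared_table(aov: pd.DataFrame) -> pd.DataFrame:
    ss_total = aov["sum_sq"].sum()
    aov = aov.copy()
    aov["eta_sq"] = aov["sum_sq"] / ss_total
    resid_ss = aov.loc["Residual", "sum_sq"]
    aov["partial_eta_sq"] = aov["sum_sq"] / (aov["sum_sq"] + resid_ss)
    return aov


def two_way_anova(values, factor_a, factor_b, interaction: bool = True) -> list[TestResult]:
    """Two-way fixed-effects ANOVA with classical eta-squared per effect.

    eta^2 = SS_effect / SS_total (partial eta^2 also reported in ``extra``).
    Requires at least one observation per cell when the interaction is
    requested.
    """
    df = pd.DataFrame(
        {"y": _as_1d(values), "A": np.asarray(factor_a), "B": np.asarray(factor_b)}
    )
    for f in ("A", "B"):
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f} needs at least 2 levels")
    if interaction:
        cells = df.groupby(["A", "B"], observed=True).size()
        n_expected = df["A"].nunique() * df["B"].nunique()
        if len(cells) < n_expected:
            raise ValueError("empty factor cells: interaction not estimable")
    formula = "y ~ C(A) * C(B)" if interaction else "y ~ C(A) + C(B)"
    model = ols(formula, data=df).fit()
    aov = _eta_squared_table(anova_lm(model, typ=2))
    names = {"C(A)": "A", "C(B)": "B", "C(A):C(B)": "A:B"}
    results = []
    for row_name, row in aov.iterrows():
        if row_name == "Residual":
            continue
        eta = float(row["eta_sq"])
        results.append(
            TestResult(
                method="two-way ANOVA",
                statistic=float(row["F"]),
                p_value=float(row["PR(>F)"]),
                n_per_group=[len(df)],
                effect=EffectSize(EffectMetric.eta_squared, min(max(eta, 0.0), 1.0)),
                extra={
                    "effect_name": names.get(str(row_name), str(row_name)),
                    "sum_sq": float(row["sum_sq"]),
                    "df": float(row["df"]),
                    "partial_eta_sq": float(row["partial_eta_sq"]),
                },
            )
        )
    return results


def repeated_measures_crossover_anova(
    data: pd.DataFrame,
    value_col: str = "episodes",
    subject_col: str = "subject",
    period_col: str = "period",
    group_col: str = "sequence",
) -> TestResult:
    """Treatment effect in a two-group, two-period (AB/BA) crossover design.

    Each subject is observed once per period; subjects in sequence "AB"
    receive treatment in period 1, sequence "BA" in period 2.  The treatment
    effect is the within-subject contrast, tested by OLS with subject fixed
    effects plus period and treatment terms; F is taken against the
    within-subject residual and eta^2 = SS_treatment / SS_total.

    Subjects missing a period are excluded with a warning.
    """
    df = data[[subject_col, period_col, group_col, value_col]].copy()
    df.columns = ["subject", "period", "sequence", "y"]
    periods = sorted(df["period"].unique())
    if len(periods) != 2:
        raise ValueError("crossover analysis needs exactly 2 periods")
    counts = df.groupby("subject")["period"].nunique()
    incomplete = counts[counts < 2].index
    if len(incomplete):
        warnings.warn(
            f"excluding {len(incomplete)} subject(s) missing a period", stacklevel=2
        )
        df = df[~df["subject"].isin(incomplete)]
    if df["subject"].nunique() < 3:
        raise ValueError("too few complete subjects for crossover ANOVA")
    first = periods[0]
    df["treatment"] = np.where(
        ((df["sequence"] == df["sequence"].unique()[0]) == (df["period"] == first)),
        "T",
        "C",
    )
    # Recode so 'T' is the treated condition of the first-listed sequence in
    # period 1; the F-test is invariant to the labelling.
    model = ols("y ~ C(subject) + C(period) + C(treatment)", data=df).fit()
    aov = anova_lm(model, typ=2)
    ss_total = aov["sum_sq"].sum()
    row = aov.loc["C(treatment)"]
    eta = float(row["sum_sq"] / ss_total) if ss_total > 0 else 0.0
    n_seq = df.groupby("sequence")["subject"].nunique()
    return TestResult(
        method="crossover repeated-measures ANOVA",
        statistic=float(row["F"]),
        p_value=float(row["PR(>F)"]) if np.isfinite(row["F"]) else 1.0,
        n_per_group=[int(v) for v in n_seq],
        effect=EffectSize(EffectMetric.eta_squared, min(max(eta, 0.0), 1.0)),
        extra={
            "ss_treatment": float(row["sum_sq"]),
            "ss_total": float(ss_total),
            "period_p": float(aov.loc["C(period)", "PR(>F)"]),
        },
    )


def kruskal_wallis(groups: list) -> TestResult:
    """Kruskal-Wallis H test (tie-corrected) across >= 2 groups."""
    groups = [_as_1d(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all observations tied: Kruskal-Wallis undefined")
    res = sps.kruskal(*groups)
    n = len(pooled)
    # eta^2-like epsilon estimate from H for convenience
    h = float(res.statistic)
    return TestResult(
        method="Kruskal-Wallis",
        statistic=h,
        p_value=float(res.pvalue),
        n_per_group=[len(g) for g in groups],
        effect=None,
        extra={"df": len(groups) - 1, "n_total": n},
    )


# ---------------------------------------------------------------------------
# multiple-testing corrections


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Bonferroni or Benjamini-Hochberg adjusted p-values, input order kept."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown correction method: {method!r}")
    return multipletests(p, method=key)[1]
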