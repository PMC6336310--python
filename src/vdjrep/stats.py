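"""Three-way factorial statistics for per-animal repertoire features.

Implements the study-style analysis battery: a full-factorial linear model
``y ~ AOS * TT * CpG`` per feature with F tests for the three main effects
and all interactions; Tukey HSD post-hoc contrasts; the per-animal variance
statistic (squared deviation of each animal's percent from the across-animal
mean, summed over features) compared across treatment cells via
least-squares means; usage-vector regression R²; and the two-fold/0.05
marker screen on TPM tables.

The ANOVA runs on raw percentages (no compositional transform) and, on the
balanced designs produced here, type-I sums of squares coincide with
type-II/III, so term p-values are invariant to factor order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .model import Design
from .usage import UsageTable

__all__ = [
    "AnovaResult",
    "MarkerScreenResult",
    "threeway_anova",
    "anova_by_feature",
    "tukey_posthoc",
    "animal_variance",
    "whole_animal_variation",
    "compare_variance",
    "usage_regression",
    "marker_screen",
]

#: Canonical term order of the full 2x2x2 factorial model.
ANOVA_TERMS = ("AOS", "TT", "CpG", "AOSxTT", "AOSxCpG", "TTxCpG", "AOSxTTxCpG")

_TERM_MAP = {
    "aos": "AOS",
    "tt": "TT",
    "cpg": "CpG",
    "aos:tt": "AOSxTT",
    "aos:cpg": "AOSxCpG",
    "tt:cpg": "TTxCpG",
    "aos:tt:cpg": "AOSxTTxCpG",
}


@dataclass
class AnovaResult:
    """Per-feature factorial ANOVA: F and p for each term."""

    feature: str
    table: pd.DataFrame  # index = ANOVA_TERMS, columns = F, p
    degenerate: bool = False

    def p(self, term: str) -> float:
        return float(self.table.at[term, "p"])

    def significant_terms(self, alpha: float = 0.05) -> list[str]:
        return [t for t in self.table.index if self.table.at[t, "p"] < alpha]


def _design_frame(values: pd.Series, design: Design) -> pd.DataFrame:
    df = design.to_frame().set_index("animal_id")
    missing = [a for a in values.index if a not in df.index]
    if missing:
        raise ValueError(f"animals not in design: {missing}")
    out = df.loc[values.index, ["aos", "tt", "cpg"]].astype(int)
    out["y"] = values.astype(float).values
    return out


def threeway_anova(
    values: pd.Series, design: Design, feature: str = ""
) -> AnovaResult:
    """Fit ``y ~ AOS * TT * CpG`` and return per-term F and p.

    Requires at least 2 animals in each of the 8 cells.  A zero-variance
    response is flagged degenerate with all p = 1.
    """
    df = _design_frame(values, design)
    cells = df.groupby(["aos", "tt", "cpg"]).size()
    for a in (0, 1):
        for t in (0, 1):
            for c in (0, 1):
                if cells.get((a, t, c), 0) < 2:
                    cell = "".join("+" if f else "-" for f in (a, t, c))
                    raise ValueError(
                        f"cell {cell} has fewer than 2 animals; ANOVA not estimable"
                    )
    if np.isclose(df["y"].var(ddof=0), 0.0):
        table = pd.DataFrame(
            {"F": [0.0] * len(ANOVA_TERMS), "p": [1.0] * len(ANOVA_TERMS)},
            index=list(ANOVA_TERMS),
        )
        return AnovaResult(feature=feature, table=table, degenerate=True)
    fit = smf.ols("y ~ aos * tt * cpg", data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=1)
    rows = {}
    for raw, name in _TERM_MAP.items():
        rows[name] = (float(aov.at[raw, "F"]), float(aov.at[raw, "PR(>F)"]))
    table = pd.DataFrame(rows, index=["F", "p"]).T.loc[list(ANOVA_TERMS)]
    return AnovaResult(feature=feature, table=table)


def anova_by_feature(table: UsageTable, design: Design) -> pd.DataFrame:
    """Run the factorial ANOVA for every feature of a usage table.

    Returns tidy rows (feature, term, F, p, significant at 0.05).  Per the
    study's reporting, no multiple-testing correction is applied across
    features.
    """
    rows = []
    for feature in table.features:
        res = threeway_anova(table.percent[feature], design, feature=str(feature))
        for term in ANOVA_TERMS:
            f, p = res.table.at[term, "F"], res.table.at[term, "p"]
            rows.append(
                {
                    "feature": str(feature),
                    "term": term,
                    "F": float(f),
                    "p": float(p),
                    "significant": bool(p < 0.05),
                }
            )
    return pd.DataFrame(rows, columns=["feature", "term", "F", "p", "significant"])


def tukey_posthoc(
    values: pd.Series, groups: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """All pairwise group-mean differences with Tukey-HSD adjusted p-values."""
    groups = groups.loc[values.index]
    if groups.nunique() < 2:
        raise ValueError("Tukey post-hoc needs at least 2 groups")
    res = pairwise_tukeyhsd(values.values.astype(float), groups.values, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=[str(c) for c in res.summary().data[0]]
    )
    frame = frame.rename(
        columns={"group1": "group_a", "group2": "group_b", "meandiff": "difference", "p-adj": "p_adj"}
    )
    for col in ("difference", "p_adj", "lower", "upper"):
        frame[col] = frame[col].astype(float)
    frame["reject"] = frame["reject"].astype(bool)
    return frame[["group_a", "group_b", "difference", "p_adj", "lower", "upper", "reject"]]


def animal_variance(table: UsageTable) -> pd.DataFrame:
    """Per-animal, per-feature squared deviation from the across-animal mean.

    Variation = (percent of repertoire per animal − average percent)²,
    computed feature-wise; summing a row gives whole-animal variation.
    """
    if len(table.percent) < 2:
        raise ValueError("animal_variance needs at least 2 animals")
    mean = table.percent.mean(axis=0)
    return (table.percent - mean) ** 2


def whole_animal_variation(table: UsageTable) -> pd.Series:
    """Whole-animal variation: the per-feature squared deviations summed."""
    return animal_variance(table).sum(axis=1).rename("whole_animal_variation")


@dataclass
class VarianceComparison:
    """LS-means comparison of whole-animal variation across treatment cells."""

    lsmeans: pd.Series  # cell -> least-squares (marginal) mean
    contrasts: pd.DataFrame  # Tukey-adjusted pairwise contrasts
    global_F: float
    global_p: float


def compare_variance(totals: pd.Series, design: Design) -> VarianceComparison:
    """Compare whole-animal variation across the 8 treatment cells.

    Fits a cell-means linear model (LS-means reduce to cell means on this
    balanced one-way layout), reports the global F test and all pairwise
    Tukey-adjusted contrasts.
    """
    cell = pd.Series({a: design[a].cell for a in totals.index})
    counts = cell.value_counts()
    if (counts < 2).any():
        raise ValueError("compare_variance needs >= 2 animals per group")
    df = pd.DataFrame({"y": totals.astype(float), "cell": cell})
    if np.isclose(df["y"].var(ddof=0), 0.0):
        lsmeans = df.groupby("cell")["y"].mean()
        pairs = []
        labels = list(lsmeans.index)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                pairs.append(
                    {"group_a": a, "group_b": b, "difference": 0.0, "p_adj": 1.0,
                     "lower": 0.0, "upper": 0.0, "reject": False}
                )
        return VarianceComparison(
            lsmeans=lsmeans, contrasts=pd.DataFrame(pairs), global_F=0.0, global_p=1.0
        )
    fit = smf.ols("y ~ C(cell)", data=df).fit()
    aov = sm.stats.anova_lm(fit, typ=1)
    contrasts = tukey_posthoc(df["y"], df["cell"])
    return VarianceComparison(
        lsmeans=df.groupby("cell")["y"].mean(),
        contrasts=contrasts,
        global_F=float(aov.at["C(cell)", "F"]),
        global_p=float(aov.at["C(cell)", "PR(>F)"]),
    )


def usage_regression(mean_a: pd.Series, mean_b: pd.Series) -> tuple[float, float]:
    """OLS regression of one group-mean usage vector on another.

    Returns (R², slope p-value) over the shared feature universe.
    """
    common = mean_a.index.intersection(mean_b.index)
    if len(common) < 3:
        raise ValueError("usage_regression needs >= 3 shared features")
    x = mean_a.loc[common].astype(float)
    y = mean_b.loc[common].astype(float)
    if np.isclose(x.var(ddof=0), 0.0):
        raise ValueError("zero-variance predictor")
    res = sps.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)


@dataclass(frozen=True)
class MarkerScreenResult:
    """One gene's differential-expression screen outcome for one factor."""

    gene: str
    fold_change: float  # signed: -(m-/m+) when the '+' level is lower
    p_value: float
    flagged: bool
    defined: bool = True


def marker_screen(
    tpm: pd.DataFrame, design: Design, factor: str
) -> list[MarkerScreenResult]:
    """Two-fold/0.05 marker screen of a gene x animal TPM table for one factor.

    Signed fold change FC = m₊/m₋ if m₊ ≥ m₋ else −(m₋/m₊) (so |FC| ≥ 1 and
    the sign marks direction); p from a Welch two-sample t test on
    log₂(TPM+1).  A gene is flagged iff |FC| > 2 AND p < 0.05.  Genes with a
    zero mean in either level are reported undefined and never flagged.
    """
    plus = [a for a in tpm.columns if design.factor_level(a, factor)]
    minus = [a for a in tpm.columns if not design.factor_level(a, factor)]
    if len(plus) < 2 or len(minus) < 2:
        raise ValueError("marker_screen needs >= 2 animals per factor level")
    out: list[MarkerScreenResult] = []
    for gene, row in tpm.iterrows():
        m_plus = float(row[plus].mean())
        m_minus = float(row[minus].mean())
        if m_plus <= 0 or m_minus <= 0:
            out.append(MarkerScreenResult(str(gene), float("nan"), float("nan"), False, defined=False))
            continue
        fc = m_plus / m_minus if m_plus >= m_minus else -(m_minus / m_plus)
        log_plus = np.log2(row[plus].astype(float) + 1.0)
        log_minus = np.log2(row[minus].astype(float) + 1.0)
        if np.isclose(log_plus.var(ddof=0) + log_minus.var(ddof=0), 0.0):
            p = 1.0
        else:
            p = float(sps.ttest_ind(log_plus, log_minus, equal_var=False).pvalue)
        flagged = bool(abs(fc) > 2.0 and p < 0.05)
        out.append(MarkerScreenResult(str(gene), float(fc), p, flagged))
    return out
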