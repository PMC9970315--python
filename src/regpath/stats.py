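"""Relative-expression and cohort statistics.

Implements the quantitative arm of the pipeline: ΔΔCt relative
quantification of qPCR data against a reference gene, percent
suppression/induction conversions, calcification-assay normalization,
descriptive cohort summaries, and the pooled (equal-variance) two-sample
t-test in both raw-data and summary-statistic forms.

Conventions
-----------
* ΔCt is computed per sample as ``Ct_gene - Ct_reference`` (replicate Cts
  within a sample are averaged first), group ΔCt is the mean of per-sample
  ΔCts, ΔΔCt = ΔCt_treated - ΔCt_control, and relative expression (fold
  change) is ``2**-ΔΔCt``.
* Percent suppression follows the reduced-BY convention:
  ``100 * (1 - fold)``, so a fold of 0.42 is 58% suppression.  Percent
  change is ``100 * (fold - 1)``, so a fold of 1.71 is a 71% induction.
* The t-test pools variances and uses ``n1 + n2 - 2`` degrees of freedom
  (Student's independent t-test, not Welch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FoldChangeResult",
    "TTestResult",
    "NormalizedMeasurement",
    "CohortSummary",
    "delta_delta_ct",
    "percent_suppression",
    "fold_from_suppression",
    "percent_change",
    "pooled_t_test",
    "t_test_from_summary",
    "normalize_measurement",
    "cohort_summary",
]

QPCR_COLUMNS = ("sample", "group", "gene", "ct")


@dataclass(frozen=True)
class FoldChangeResult:
    """ΔΔCt-derived relative expression for one gene and one contrast."""

    gene: str
    treated: str
    control: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float
    percent_change: float
    n_treated: int
    n_control: int

    @property
    def percent_suppression(self) -> float:
        """Percent reduction relative to control; negative = induction."""
        return 100.0 * (1.0 - self.fold_change)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.gene} [{self.treated} vs {self.control}]: "
            f"ddCt={self.delta_delta_ct:+.3f}, fold={self.fold_change:.3f} "
            f"({self.percent_change:+.1f}%)"
        )


@dataclass(frozen=True)
class TTestResult:
    """Pooled two-sample comparison (t, df, two-sided p)."""

    t: float
    df: int
    p: float
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def summary(self) -> str:
        return (
            f"{self.mean1:.2f} ± {self.sd1:.2f} (n={self.n1}) vs "
            f"{self.mean2:.2f} ± {self.sd2:.2f} (n={self.n2}): "
            f"t({self.df}) = {self.t:.3f}, p = {self.p:.3f}"
        )


@dataclass(frozen=True)
class NormalizedMeasurement:
    """An assay value divided by a per-well denominator (protein or cells)."""

    raw: float
    denominator: float
    normalized: float
    raw_units: str = ""
    denominator_units: str = ""

    @property
    def units(self) -> str:
        if self.raw_units and self.denominator_units:
            return f"{self.raw_units}/{self.denominator_units}"
        return ""


@dataclass(frozen=True)
class GroupSummary:
    n: int
    age_mean: float
    age_sd: float
    sex_count: int
    sex_percent: float
    biomarkers: dict = field(default_factory=dict)  # name -> (mean, sd)


@dataclass(frozen=True)
class CohortSummary:
    """Descriptive summary of a two(+)-group cohort table."""

    total_n: int
    sex_category: str
    sex_count: int
    sex_percent: float
    age_mean: float
    age_sd: float
    overall_biomarkers: dict
    groups: dict  # group label -> GroupSummary

    def summary(self) -> str:
        lines = [
            f"{self.total_n} participants, age {self.age_mean:.1f} ± "
            f"{self.age_sd:.1f} y, {self.sex_count} ({self.sex_percent:.1f}%) "
            f"{self.sex_category}"
        ]
        for label, g in self.groups.items():
            bio = ", ".join(
                f"{k} {m:.2f} ± {s:.2f}" for k, (m, s) in g.biomarkers.items()
            )
            lines.append(f"  {label}: n={g.n}, {bio}")
        return "\n".join(lines)


def _check_qpcr(qpcr: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in QPCR_COLUMNS if c not in qpcr.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns: {missing}")
    return qpcr


def _group_delta_ct(
    sub: pd.DataFrame, gene: str, reference_gene: str, group: str
) -> tuple[float, int]:
    """Mean per-sample ΔCt for one group; samples lacking either Ct drop."""
    # replicate Cts within a sample average first
    per = sub.groupby(["sample", "gene"], sort=False)["ct"].mean().unstack()
    for g in (gene, reference_gene):
        if g not in per.columns:
            per[g] = np.nan
    dct = (per[gene] - per[reference_gene]).dropna()
    n_dropped = len(per) - len(dct)
    if n_dropped:
        import warnings

        warnings.warn(
            f"dropped {n_dropped} sample(s) in group '{group}' lacking a Ct "
            f"for '{gene}' or '{reference_gene}'",
            stacklevel=3,
        )
    if dct.empty:
        raise ValueError(
            f"group '{group}' has no sample with Ct for both '{gene}' and "
            f"'{reference_gene}'"
        )
    return float(dct.mean()), int(len(dct))


def delta_delta_ct(
    qpcr: pd.DataFrame,
    gene: str,
    reference_gene: str,
    treated: str,
    control: str,
) -> FoldChangeResult:
    """Relative expression of ``gene`` in ``treated`` vs ``control``.

    Parameters
    ----------
    qpcr
        Long table with columns ``sample, group, gene, ct``; several rows
        per (sample, gene) are treated as technical replicates and
        averaged.
    gene, reference_gene
        Target gene and the endogenous control (e.g. GAPDH or β-actin)
        used to form per-sample ΔCt.
    treated, control
        Group labels of the contrast.

    Returns
    -------
    FoldChangeResult
        With ``fold_change = 2**-ΔΔCt``; values < 1 mean suppression in
        the treated group.
    """
    qpcr = _check_qpcr(qpcr)
    out = {}
    for label in (treated, control):
        sub = qpcr[qpcr["group"] == label]
        if sub.empty:
            raise ValueError(f"group '{label}' not present in qPCR table")
        out[label] = _group_delta_ct(sub, gene, reference_gene, label)
    dct_t, n_t = out[treated]
    dct_c, n_c = out[control]
    ddct = dct_t - dct_c
    fold = 2.0 ** (-ddct)
    return FoldChangeResult(
        gene=gene,
        treated=treated,
        control=control,
        delta_ct_treated=dct_t,
        delta_ct_control=dct_c,
        delta_delta_ct=ddct,
        fold_change=fold,
        percent_change=100.0 * (fold - 1.0),
        n_treated=n_t,
        n_control=n_c,
    )


def percent_suppression(fold: float) -> float:
    """Percent reduction relative to control: ``100 * (1 - fold)``.

    A fold of 0.42 maps to 58% suppression; folds above 1 give negative
    values (i.e. induction).
    """
    if not fold > 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    return 100.0 * (1.0 - fold)


def fold_from_suppression(percent: float) -> float:
    """Inverse of :func:`percent_suppression`: ``1 - percent/100``."""
    fold = 1.0 - percent / 100.0
    if not fold > 0:
        raise ValueError(f"suppression of {percent}% implies nonpositive fold")
    return fold


def percent_change(fold: float) -> float:
    """Percent change relative to control: ``100 * (fold - 1)``."""
    if not fold > 0:
        raise ValueError(f"fold change must be positive, got {fold}")
    return 100.0 * (fold - 1.0)


def t_test_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
) -> TTestResult:
    """Pooled two-sample t-test from group means, SDs and sizes.

    Identical to :func:`pooled_t_test` applied to any raw samples having
    exactly these summaries; useful when only published summary values
    are available.
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0.0:
        if mean1 == mean2:
            return TTestResult(0.0, df, 1.0, mean1, sd1, n1, mean2, sd2, n2)
        raise ValueError(
            "zero pooled variance with unequal means: t is undefined"
        )
    t = (mean1 - mean2) / math.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p), mean1, sd1, n1, mean2, sd2, n2)


def pooled_t_test(x, y) -> TTestResult:
    """Student's independent (pooled-variance) t-test on raw samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    return t_test_from_summary(
        float(x.mean()), float(x.std(ddof=1)), x.size,
        float(y.mean()), float(y.std(ddof=1)), y.size,
    )


def normalize_measurement(
    raw: float,
    denominator: float,
    raw_units: str = "",
    denominator_units: str = "",
) -> NormalizedMeasurement:
    """Normalize an assay value to protein amount or cell count."""
    if not denominator > 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    return NormalizedMeasurement(
        raw=float(raw),
        denominator=float(denominator),
        normalized=float(raw) / float(denominator),
        raw_units=raw_units,
        denominator_units=denominator_units,
    )


def cohort_summary(
    cohort: pd.DataFrame,
    sex_category: str = "M",
    group_col: str = "group",
    sex_col: str = "sex",
    age_col: str = "age",
) -> CohortSummary:
    """Per-group and overall descriptive statistics of a cohort table.

    Every numeric column other than ``age`` is treated as a biomarker and
    summarized as mean ± SD. Sex is reported as a count and a percentage
    (one decimal) of ``sex_category``.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    for col in (group_col, sex_col, age_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort table missing required column '{col}'")
    biomarker_cols = [
        c
        for c in cohort.columns
        if c not in (group_col, sex_col, age_col)
        and pd.api.types.is_numeric_dtype(cohort[c])
    ]

    def _bio(sub: pd.DataFrame) -> dict:
        return {
            c: (float(sub[c].mean()), float(sub[c].std(ddof=1)))
            for c in biomarker_cols
        }

    def _sd(s: pd.Series) -> float:
        v = s.std(ddof=1)
        return 0.0 if pd.isna(v) else float(v)

    total = len(cohort)
    sex_n = int((cohort[sex_col] == sex_category).sum())
    groups = {}
    for label, sub in cohort.groupby(group_col, sort=False):
        g_sex = int((sub[sex_col] == sex_category).sum())
        groups[label] = GroupSummary(
            n=len(sub),
            age_mean=float(sub[age_col].mean()),
            age_sd=_sd(sub[age_col]),
            sex_count=g_sex,
            sex_percent=round(100.0 * g_sex / len(sub), 1),
            biomarkers=_bio(sub),
        )
    return CohortSummary(
        total_n=total,
        sex_category=sex_category,
        sex_count=sex_n,
        sex_percent=round(100.0 * sex_n / total, 1),
        age_mean=float(cohort[age_col].mean()),
        age_sd=_sd(cohort[age_col]),
        overall_biomarkers=_bio(cohort),
        groups=groups,
    )
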