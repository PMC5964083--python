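"""Metabolic phenotyping statistics defining and comparing extreme cases.

Covers the quantities used to characterize hyperinsulinemic extremes in a
longitudinally phenotyped cohort:

* HOMA-IR, the homeostasis-model insulin-resistance index
  ``fasting glucose [mmol/L] x fasting insulin [uU/ml] / 22.5``;
* trapezoidal areas under glucose/insulin excursions (IVGTT-style
  sampling at 0, 1, 3, 5, 10, 15, 20, 30, 45, 60 min);
* extreme-individual selection by a mean + k*SD rule against a reference
  group (the formalization of "extremely elevated relative to the rest of
  the group");
* the comparison tests used on such cohorts: two-sided unpaired Student's
  t-test (pooled variance), two-way ANOVA (type-II sums of squares) and a
  Kolmogorov-Smirnov normality check.

Units are explicit: the 22.5 constant assumes mmol/L glucose and uU/ml
insulin, and the phenotype-table loader refuses mg/dL rather than
converting silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

log = logging.getLogger(__name__)

HOMA_IR_DENOMINATOR = 22.5

_ACCEPTED_UNITS = {
    "fasting_glucose": {"mmol/L"},
    "fasting_insulin": {"uU/ml", "μU/ml"},
}


@dataclass(frozen=True)
class PhenotypeRecord:
    """One subject x timepoint measurement of the fasting panel."""

    subject_id: str
    group: str
    timepoint_months: float
    fasting_glucose_mmol: float
    fasting_insulin_uU: float

    def __post_init__(self) -> None:
        if self.fasting_glucose_mmol <= 0:
            raise ValueError("fasting glucose must be > 0")
        if self.fasting_insulin_uU < 0:
            raise ValueError("fasting insulin must be >= 0")
        if self.timepoint_months < 0:
            raise ValueError("timepoint must be >= 0")

    @property
    def homa_ir(self) -> float:
        return homa_ir(self.fasting_glucose_mmol, self.fasting_insulin_uU)


@dataclass(frozen=True)
class Excursion:
    """A timed analyte excursion (e.g., glucose or insulin during IVGTT)."""

    subject_id: str
    times_min: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times_min) != len(self.values):
            raise ValueError("times and values must have equal length")
        if len(self.times_min) < 2:
            raise ValueError("an excursion needs at least two samples")
        if self.times_min[0] != 0:
            raise ValueError("excursion times must start at 0")
        diffs = np.diff(self.times_min)
        if np.any(diffs <= 0):
            raise ValueError("times must be strictly increasing (no duplicates)")


def homa_ir(fasting_glucose_mmol: float, fasting_insulin_uU: float) -> float:
    """HOMA-IR = glucose [mmol/L] x insulin [uU/ml] / 22.5 (unitless).

    Inputs measured in mg/dL must be converted by the caller first; the
    constant is only meaningful in the mmol/L x uU/ml convention.
    """
    if fasting_glucose_mmol <= 0:
        raise ValueError("fasting glucose must be > 0 mmol/L")
    if fasting_insulin_uU < 0:
        raise ValueError("fasting insulin must be >= 0 uU/ml")
    return fasting_glucose_mmol * fasting_insulin_uU / HOMA_IR_DENOMINATOR


def auc_trapezoid(
    excursion: Excursion,
    baseline_subtract: bool = False,
    floor_at_zero: bool = False,
) -> float:
    """Composite trapezoidal area under an excursion (analyte x min).

    ``baseline_subtract`` subtracts the t=0 value first (incremental AUC);
    ``floor_at_zero`` additionally clips the shifted curve at zero so
    below-baseline intervals contribute nothing.  Both are off by default.
    """
    values = np.asarray(excursion.values, dtype=float)
    if baseline_subtract:
        values = values - values[0]
        if floor_at_zero:
            values = np.clip(values, 0.0, None)
    return float(np.trapezoid(values, np.asarray(excursion.times_min, dtype=float)))


def extreme_select(
    values_by_subject: Mapping[str, float],
    reference_ids: Sequence[str],
    k: float = 3.0,
) -> list[str]:
    """Flag subjects exceeding mean(reference) + k * SD(reference).

    The SD uses the n-1 denominator and the inequality is strict.  When a
    subject belongs to the reference group its own value is excluded from
    the statistics (leave-one-out), so an extreme individual does not mask
    itself; masking by *other* extremes is diluted by using a large
    reference (e.g., the whole cohort).  A zero-variance reference flags
    any value strictly above the mean.  Deterministic and
    scale-equivariant.
    """
    ref_ids = list(reference_ids)
    if len(ref_ids) < 3:
        raise ValueError("reference group must have at least 3 subjects")
    missing = [r for r in ref_ids if r not in values_by_subject]
    if missing:
        raise ValueError(f"reference subjects without values: {missing}")
    flagged = []
    for subject, value in values_by_subject.items():
        ref = [values_by_subject[r] for r in ref_ids if r != subject]
        if len(ref) < 2:
            raise ValueError("reference too small after excluding the subject")
        mean = float(np.mean(ref))
        sd = float(np.std(ref, ddof=1))
        threshold = mean if sd == 0.0 else mean + k * sd
        if value > threshold:
            flagged.append(subject)
    return sorted(flagged)


def t_test_unpaired(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided unpaired Student's t-test (pooled variance).

    Returns ``(t, p)`` with ``n_a + n_b - 2`` degrees of freedom.  Zero
    pooled variance is an error rather than an infinite statistic.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = ((len(a) - 1) * np.var(a, ddof=1) + (len(b) - 1) * np.var(b, ddof=1)) / (
        len(a) + len(b) - 2
    )
    if pooled == 0.0:
        raise ValueError("zero pooled variance; t statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class AnovaResult:
    f_a: float
    p_a: float
    f_b: float
    p_b: float
    f_interaction: float
    p_interaction: float
    table: pd.DataFrame


def anova_two_way(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
) -> AnovaResult:
    """Two-way ANOVA with interaction, type-II sums of squares.

    Handles balanced and unbalanced complete designs; the interaction
    requires replication (a saturated design with zero residual df is an
    error).  Each factor must have at least two levels.
    """
    df = pd.DataFrame(
        {
            "y": np.asarray(values, dtype=float),
            "a": pd.Categorical([str(x) for x in factor_a]),
            "b": pd.Categorical([str(x) for x in factor_b]),
        }
    )
    for col in ("a", "b"):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} has fewer than two levels")
    fit = smf.ols("y ~ C(a) * C(b)", data=df).fit()
    if fit.df_resid <= 0:
        raise ValueError("no residual degrees of freedom; replication required")
    table = sm.stats.anova_lm(fit, typ=2)
    return AnovaResult(
        f_a=float(table.loc["C(a)", "F"]),
        p_a=float(table.loc["C(a)", "PR(>F)"]),
        f_b=float(table.loc["C(b)", "F"]),
        p_b=float(table.loc["C(b)", "PR(>F)"]),
        f_interaction=float(table.loc["C(a):C(b)", "F"]),
        p_interaction=float(table.loc["C(a):C(b)", "PR(>F)"]),
        table=table,
    )


def anova_one_way(values: Sequence[float], factor: Sequence) -> tuple[float, float]:
    """One-factor ANOVA F test (for two levels, F equals the t-test's t^2)."""
    df = pd.DataFrame(
        {"y": np.asarray(values, dtype=float),
         "a": pd.Categorical([str(x) for x in factor])}
    )
    if df["a"].nunique() < 2:
        raise ValueError("factor has fewer than two levels")
    fit = smf.ols("y ~ C(a)", data=df).fit()
    table = sm.stats.anova_lm(fit, typ=2)
    return float(table.loc["C(a)", "F"]), float(table.loc["C(a)", "PR(>F)"])


def ks_normality(sample: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test against a normal with the sample's mean and SD.

    Parameters are estimated from the data, as commonly practiced; the
    asymptotic p-value is therefore anti-conservative (the Lilliefors
    caveat), which is logged rather than corrected.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) < 5:
        raise ValueError("normality test needs at least 5 observations")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("constant sample; normality test undefined")
    log.debug(
        "KS normality with estimated parameters; asymptotic p is "
        "anti-conservative (Lilliefors caveat)"
    )
    res = stats.kstest(x, "norm", args=(float(np.mean(x)), sd))
    return float(res.statistic), float(res.pvalue)


def load_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read a long-format phenotype TSV and validate units.

    Expected columns: ``subject``, ``group``, ``timepoint_months``,
    ``analyte``, ``value``, ``unit``.  Glucose in mg/dL (or insulin in
    pmol/L) is rejected with instructions to convert first -- the HOMA-IR
    constant assumes mmol/L x uU/ml.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"subject", "group", "timepoint_months", "analyte", "value", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path} lacks required columns {sorted(missing)}")
    for analyte, allowed in _ACCEPTED_UNITS.items():
        units = set(df.loc[df["analyte"] == analyte, "unit"].unique())
        bad = units - allowed
        if bad:
            raise ValueError(
                f"analyte {analyte!r} has unit(s) {sorted(bad)}; convert to "
                f"{sorted(allowed)} before loading (no silent mg/dL acceptance)"
            )
    return df


def homa_ir_table(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Per subject x timepoint HOMA-IR from a long-format phenotype table."""
    wide = phenotypes.pivot_table(
        index=["subject", "group", "timepoint_months"],
        columns="analyte",
        values="value",
    ).reset_index()
    if not {"fasting_glucose", "fasting_insulin"} <= set(wide.columns):
        raise ValueError("table must contain fasting_glucose and fasting_insulin")
    wide["homa_ir"] = [
        homa_ir(g, i)
        for g, i in zip(wide["fasting_glucose"], wide["fasting_insulin"])
    ]
    return wide[["subject", "group", "timepoint_months", "homa_ir"]]
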