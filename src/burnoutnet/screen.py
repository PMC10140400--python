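"""Association screening between survey variables and burnout status.

Categorical variables are tested with the Pearson chi-squared test on the
level-by-burnout contingency table, deliberately *without* the Yates
continuity correction — the uncorrected convention is what reproduces the
reference cohort's published p-values (e.g. high blood pressure 0.09, not
the 0.11 the corrected statistic gives).  Continuous variables use the
Wilcoxon rank-sum test with midranks, tie-corrected variance and a
continuity correction on the normal approximation.  No multiple-testing
adjustment is applied: the screen mirrors the per-variable convention of
baseline-characteristics tables.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .schema import BURNOUT_HIGH, BURNOUT_LOW, SurveySchema

logger = logging.getLogger(__name__)


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """r x 2 table of level counts by burnout group (low, high)."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...] = (BURNOUT_LOW, BURNOUT_HIGH)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] != 2:
            raise ScreenError("contingency table must be r x 2 with r >= 2")
        if np.any(counts < 0) or np.any(counts != np.rint(counts)):
            raise ScreenError("counts must be nonnegative integers")
        if counts.sum() <= 0:
            raise ScreenError("contingency table is empty")
        if len(self.row_labels) != counts.shape[0]:
            raise ScreenError("row label count mismatch")


@dataclass(frozen=True)
class TestResult:
    variable: str
    statistic: float
    p_value: float
    test_name: str
    df: int | None = None

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def contingency_from_survey(table: pd.DataFrame, variable: str,
                            levels, label: str = "burnout"
                            ) -> ContingencyTable:
    """Cross-tabulate one categorical variable against the burnout label."""
    counts = np.zeros((len(levels), 2))
    values = table[variable].astype(str).to_numpy()
    status = table[label].to_numpy()
    for i, lv in enumerate(levels):
        sel = values == lv
        counts[i, 0] = np.sum(sel & (status == BURNOUT_LOW))
        counts[i, 1] = np.sum(sel & (status == BURNOUT_HIGH))
    return ContingencyTable(counts, tuple(levels))


def chi_squared_test(table: ContingencyTable,
                     variable: str = "") -> TestResult:
    """Pearson chi-squared test of independence, no continuity correction.

    Expected counts come from the table margins; the p-value is the upper
    tail of the chi-squared distribution on (r-1)(c-1) degrees of freedom.
    Empty rows or columns make the statistic undefined and raise, naming
    the empty level.  Expected counts below 5 trigger a warning only — the
    asymptotic test is still computed.
    """
    counts = table.counts
    row_margin = counts.sum(axis=1)
    col_margin = counts.sum(axis=0)
    if np.any(row_margin == 0):
        empty = table.row_labels[int(np.argmin(row_margin))]
        raise ScreenError(f"level {empty!r} has zero margin")
    if np.any(col_margin == 0):
        empty = table.col_labels[int(np.argmin(col_margin))]
        raise ScreenError(f"group {empty!r} has zero margin")
    total = counts.sum()
    expected = np.outer(row_margin, col_margin) / total
    if np.any(expected < 5):
        logger.warning(
            "variable %r: %d expected cell(s) below 5; chi-squared "
            "approximation may be poor", variable,
            int(np.sum(expected < 5)))
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(chi2.sf(statistic, df))
    return TestResult(variable, statistic, p, "chi_squared", df)


def wilcoxon_rank_sum(x, y, variable: str = "") -> TestResult:
    """Two-sided Wilcoxon rank-sum test, normal approximation.

    Midranks are assigned to ties; the null variance carries the standard
    tie correction and a 0.5 continuity correction is applied.  The
    statistic reported is the rank sum of the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ScreenError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # midranks for ties
    w = float(ranks[:n1].sum())
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:  # all values identical
        return TestResult(variable, w, 1.0, "wilcoxon")
    diff = w - mean_w
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_w) if diff != 0 else 0.0
    p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return TestResult(variable, w, p, "wilcoxon")


def test_variable(table: pd.DataFrame, schema: SurveySchema,
                  name: str, label: str = "burnout") -> TestResult:
    """Run the kind-appropriate test for one schema variable."""
    var = schema[name]
    if var.is_categorical:
        ct = contingency_from_survey(table, name, var.levels, label)
        # drop unobserved levels rather than failing on a sparse draw
        keep = ct.counts.sum(axis=1) > 0
        if keep.sum() < 2:
            raise ScreenError(f"variable {name!r} is constant in this table")
        if not keep.all():
            ct = ContingencyTable(
                ct.counts[keep],
                tuple(np.asarray(ct.row_labels, dtype=object)[keep]))
        return chi_squared_test(ct, name)
    status = table[label].to_numpy()
    x = table[name].to_numpy(dtype=float)[status == BURNOUT_LOW]
    y = table[name].to_numpy(dtype=float)[status == BURNOUT_HIGH]
    return wilcoxon_rank_sum(x, y, name)


def screen_variables(table: pd.DataFrame, schema: SurveySchema,
                     alpha: float = 0.05, label: str = "burnout"
                     ) -> dict[str, list[str]]:
    """Variables significantly associated with burnout, grouped by category.

    Runs chi-squared (categorical) or Wilcoxon (numeric) per schema
    variable and keeps those with p < alpha, in schema order.
    """
    if not 0.0 < alpha <= 1.0:
        raise ScreenError("alpha must lie in (0, 1]")
    selected: dict[str, list[str]] = {}
    for var in schema.variables:
        if var.name not in table.columns:
            continue
        result = test_variable(table, schema, var.name, label)
        if result.p_value < alpha:
            selected.setdefault(var.category, []).append(var.name)
    return selected


def screen_results(table: pd.DataFrame, schema: SurveySchema,
                   label: str = "burnout") -> list[TestResult]:
    """All per-variable test results, in schema order."""
    return [test_variable(table, schema, v.name, label)
            for v in schema.variables if v.name in table.columns]


def _fmt_p(p: float) -> str:
    return "< 0.01" if p < 0.005 else f"{p:.2f}"


def table_one_report(table: pd.DataFrame, schema: SurveySchema,
                     label: str = "burnout") -> pd.DataFrame:
    """Baseline-characteristics ("table one") report by burnout group.

    One row per categorical level with count (percent) per group, one row
    per numeric variable with median (IQR), and the test p-value on the
    variable's first row.
    """
    status = table[label].to_numpy()
    masks = {BURNOUT_LOW: status == BURNOUT_LOW,
             BURNOUT_HIGH: status == BURNOUT_HIGH}
    rows = []
    for var in schema.variables:
        if var.name not in table.columns:
            continue
        p = _fmt_p(test_variable(table, schema, var.name, label).p_value)
        if var.is_categorical:
            values = table[var.name].astype(str).to_numpy()
            first = True
            for lv in var.levels:
                cells = {}
                for grp, mask in masks.items():
                    n_grp = int(mask.sum())
                    c = int(np.sum(mask & (values == lv)))
                    pct = 100.0 * c / n_grp if n_grp else 0.0
                    cells[grp] = f"{c} ({pct:.1f})"
                rows.append({"category": var.category, "variable": var.name,
                             "level": lv, **cells,
                             "p": p if first else ""})
                first = False
        else:
            x = table[var.name].to_numpy(dtype=float)
            cells = {}
            for grp, mask in masks.items():
                med = np.median(x[mask])
                q1, q3 = np.percentile(x[mask], [25, 75])
                cells[grp] = f"{med:.1f} ({q1:.0f}-{q3:.0f})"
            rows.append({"category": var.category, "variable": var.name,
                         "level": "median (IQR)", **cells, "p": p})
    return pd.DataFrame(rows)


def write_report(report: pd.DataFrame, path, fmt: str = "tsv") -> None:
    if fmt == "tsv":
        report.to_csv(path, sep="\t", index=False)
    elif fmt == "markdown":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(report.to_markdown(index=False))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
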