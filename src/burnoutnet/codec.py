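"""Survey table I/O, MBI-GS burnout scoring, and feature encoding.

Feature encoding turns respondents into the unit-interval attribute vectors
the similarity network is built on: numeric columns are min-max scaled,
ordinal columns mapped to equally spaced codes in [0, 1] (preserving order),
and nominal/binary columns one-hot expanded.  "Standardizing" here must keep
every entry inside [0, 1] — z-scores would not — which is why min-max is the
only numeric scaling offered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import BURNOUT_HIGH, BURNOUT_LOW, SurveySchema
from .synthetic import DEFAULT_BOUNDARIES, MBI_SUBSCALE_ITEMS

logger = logging.getLogger(__name__)

MBI_ITEM_COLUMNS = tuple(c for items in MBI_SUBSCALE_ITEMS.values()
                         for c in items)


class SurveyInputError(ValueError):
    """Raised when a survey file violates the table contract."""


def _validate_table(table: pd.DataFrame, label: str = "burnout") -> None:
    if "respondent_id" not in table.columns:
        raise SurveyInputError("missing 'respondent_id' column")
    ids = table["respondent_id"]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise SurveyInputError(f"duplicate respondent id {dup!r}")
    has_label = label in table.columns
    has_items = all(c in table.columns for c in MBI_ITEM_COLUMNS)
    if not has_label and not has_items:
        raise SurveyInputError(
            f"table carries neither a {label!r} column nor the 16 MBI-GS "
            "item columns")
    if has_label:
        bad = set(table[label].unique()) - {BURNOUT_LOW, BURNOUT_HIGH}
        if bad:
            raise SurveyInputError(
                f"invalid burnout labels: {sorted(map(str, bad))}")
    if table.isna().any().any():
        col = table.columns[table.isna().any()][0]
        row = int(table.index[table[col].isna()][0])
        raise SurveyInputError(
            f"missing value at row {row}, column {col!r}; missing cells "
            "are not supported")


def read_survey(path, schema: SurveySchema | None = None,
                label: str = "burnout") -> pd.DataFrame:
    """Read a survey CSV and validate it (optionally against a schema)."""
    try:
        table = pd.read_csv(path, dtype={"respondent_id": str})
    except pd.errors.EmptyDataError:
        raise SurveyInputError(f"{path}: empty survey file") from None
    if table.empty:
        raise SurveyInputError(f"{path}: survey has no rows")
    _validate_table(table, label)
    if schema is not None:
        for var in schema.variables:
            if var.name not in table.columns:
                continue
            if var.is_categorical:
                observed = set(table[var.name].astype(str).unique())
                bad = observed - set(var.levels)
                if bad:
                    rows = table.index[
                        table[var.name].astype(str).isin(bad)]
                    raise SurveyInputError(
                        f"column {var.name!r}, row {int(rows[0])}: "
                        f"unknown level {sorted(bad)[0]!r}")
            else:
                table[var.name] = pd.to_numeric(table[var.name])
    return table


def write_survey(table: pd.DataFrame, path) -> None:
    """Write a survey table as UTF-8 CSV (round-trips with read_survey)."""
    table.to_csv(path, index=False, encoding="utf-8")


@dataclass(frozen=True)
class MbiProfile:
    """Scored MBI-GS profile for one respondent.

    Subscale means are on the 0–6 item scale.  ``label`` is high iff at
    least two subscale scores strictly exceed their critical boundaries,
    with the professional-efficacy subscale compared after reversal
    (``6 - mean``) when ``efficacy_reversed`` was on.
    """

    exhaustion_mean: float
    cynicism_mean: float
    efficacy_mean: float
    boundaries: tuple[float, float, float]
    label: str
    n_exceeded: int


def score_mbi(items, boundaries=DEFAULT_BOUNDARIES,
              efficacy_reversed: bool = True) -> MbiProfile:
    """Score 16 MBI-GS item responses into a burnout label.

    ``items`` may be a sequence of 16 integers in the fixed subscale order
    (5 exhaustion, 5 cynicism, 6 efficacy) or a mapping/Series keyed by the
    ``mbi_1`` … ``mbi_16`` column names.
    """
    if isinstance(items, (dict, pd.Series)):
        values = [items[c] for c in MBI_ITEM_COLUMNS]
    else:
        values = list(items)
    arr = np.asarray(values, dtype=float)
    if arr.shape != (16,):
        raise SurveyInputError(f"expected 16 items, got {arr.size}")
    if np.any((arr < 0) | (arr > 6) | (arr != np.rint(arr))):
        bad = arr[(arr < 0) | (arr > 6) | (arr != np.rint(arr))][0]
        raise SurveyInputError(
            f"item score {bad} outside the 0..6 Likert range")

    exh = float(arr[:5].mean())
    cyn = float(arr[5:10].mean())
    eff = float(arr[10:].mean())
    eff_score = 6.0 - eff if efficacy_reversed else eff
    exceed = sum(score > b for score, b in
                 zip((exh, cyn, eff_score), boundaries))
    label = BURNOUT_HIGH if exceed >= 2 else BURNOUT_LOW
    return MbiProfile(exh, cyn, eff, tuple(boundaries), label, exceed)


def score_survey(table: pd.DataFrame, boundaries=DEFAULT_BOUNDARIES,
                 efficacy_reversed: bool = True,
                 label: str = "burnout") -> pd.DataFrame:
    """Score every respondent's MBI items and add/overwrite the label column."""
    missing = [c for c in MBI_ITEM_COLUMNS if c not in table.columns]
    if missing:
        raise SurveyInputError(f"missing MBI item columns: {missing}")
    arr = table[list(MBI_ITEM_COLUMNS)].to_numpy(dtype=float)
    if np.any((arr < 0) | (arr > 6)):
        raise SurveyInputError("item scores outside the 0..6 Likert range")
    exh = arr[:, :5].mean(axis=1)
    cyn = arr[:, 5:10].mean(axis=1)
    eff = arr[:, 10:].mean(axis=1)
    eff_score = 6.0 - eff if efficacy_reversed else eff
    exceed = ((exh > boundaries[0]).astype(int)
              + (cyn > boundaries[1]).astype(int)
              + (eff_score > boundaries[2]).astype(int))
    out = table.copy()
    out[label] = np.where(exceed >= 2, BURNOUT_HIGH, BURNOUT_LOW)
    return out


@dataclass
class FeatureMatrix:
    """Respondents-by-features matrix with every entry in [0, 1]."""

    values: np.ndarray
    row_ids: list[str]
    column_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape != (len(self.row_ids), len(self.column_names)):
            raise ValueError("shape/label mismatch")
        if self.values.size and (self.values.min() < -1e-12
                                 or self.values.max() > 1 + 1e-12):
            raise ValueError("feature values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids,
                            columns=self.column_names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="respondent_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path, sep="\t", index_col="respondent_id")
        return cls(frame.to_numpy(dtype=float),
                   [str(i) for i in frame.index], list(frame.columns))


def encode_features(table: pd.DataFrame, schema: SurveySchema,
                    selected: list[str] | None = None) -> FeatureMatrix:
    """Encode selected survey variables as a [0, 1] feature matrix.

    numeric -> min-max scaled on the observed range; ordinal -> level index
    mapped to {0, 1/(L-1), ..., 1}; nominal and binary -> one-hot columns.
    Constant columns carry no similarity information and are dropped with a
    warning; an entirely constant table is an error.
    """
    if selected is None:
        selected = schema.names
    if not selected:
        raise SurveyInputError("no variables selected for encoding")
    unknown = [s for s in selected if s not in schema]
    if unknown:
        raise SurveyInputError(f"selected variables not in schema: {unknown}")

    columns: list[np.ndarray] = []
    names: list[str] = []
    for name in selected:
        var = schema[name]
        col = table[name]
        if var.kind == "numeric":
            x = col.to_numpy(dtype=float)
            lo, hi = x.min(), x.max()
            if hi == lo:
                logger.warning("dropping constant numeric column %r", name)
                continue
            columns.append((x - lo) / (hi - lo))
            names.append(name)
        elif var.kind == "ordinal":
            codes = pd.Categorical(col.astype(str), categories=var.levels,
                                   ordered=True).codes.astype(float)
            if np.any(codes < 0):
                raise SurveyInputError(f"unknown level in column {name!r}")
            if len(np.unique(codes)) == 1:
                logger.warning("dropping constant ordinal column %r", name)
                continue
            columns.append(codes / (len(var.levels) - 1))
            names.append(name)
        else:  # nominal / binary -> one-hot
            values = col.astype(str).to_numpy()
            if len(np.unique(values)) == 1:
                logger.warning("dropping constant column %r", name)
                continue
            for level in var.levels:
                columns.append((values == level).astype(float))
                names.append(f"{name}={level}")
    if not columns:
        raise SurveyInputError(
            "all selected columns are constant: empty feature space")
    values = np.column_stack(columns)
    return FeatureMatrix(values, [str(i) for i in table["respondent_id"]],
                         names)
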