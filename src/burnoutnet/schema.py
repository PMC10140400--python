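"""Survey schema: typed variable definitions and simulation configuration.

A :class:`SurveySchema` declares the variables a survey table carries — their
measurement kind (numeric / ordinal / nominal / binary), category
(demographic, work-related, health, lifestyle) and, for simulation, their
marginal level probabilities or numeric location/scale.  The default schema
mirrors the airport-workforce cohort profile in :mod:`burnoutnet._cohort`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from . import _cohort

CATEGORIES = ("demographic", "work_related", "health", "lifestyle")
KINDS = ("numeric", "ordinal", "nominal", "binary")

BURNOUT_LOW = "low"
BURNOUT_HIGH = "high"


class SchemaError(ValueError):
    """Raised for invalid variable or schema definitions."""


@dataclass
class VariableSpec:
    """One survey variable.

    Parameters
    ----------
    name : str
        Unique variable name within a schema.
    category : str
        One of ``demographic``, ``work_related``, ``health``, ``lifestyle``.
    kind : str
        ``numeric``, ``ordinal``, ``nominal`` or ``binary``.
    levels : tuple of str
        Ordered level labels; empty for numeric variables.
    range : tuple of float, optional
        ``(min, max)`` for numeric variables.
    level_probs : tuple of float, optional
        Marginal level probabilities used by the simulator (categorical
        kinds).  Uniform if omitted.
    loc, scale : float, optional
        Location / scale of the truncated-normal simulator for numeric
        variables.  Defaults: midpoint of the range, range / 6.
    """

    name: str
    category: str
    kind: str
    levels: tuple[str, ...] = ()
    range: tuple[float, float] | None = None
    level_probs: tuple[float, ...] | None = None
    loc: float | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise SchemaError(
                f"{self.name!r}: unknown category {self.category!r}")
        if self.kind not in KINDS:
            raise SchemaError(f"{self.name!r}: unknown kind {self.kind!r}")
        self.levels = tuple(self.levels)
        if self.kind == "numeric":
            if self.levels:
                raise SchemaError(f"{self.name!r}: numeric takes no levels")
            if self.range is None or not self.range[0] < self.range[1]:
                raise SchemaError(
                    f"{self.name!r}: numeric needs range with min < max")
            lo, hi = self.range
            if self.loc is None:
                self.loc = 0.5 * (lo + hi)
            if self.scale is None:
                self.scale = (hi - lo) / 6.0
        else:
            if len(self.levels) < 2:
                raise SchemaError(f"{self.name!r}: needs >= 2 levels")
            if len(set(self.levels)) != len(self.levels):
                raise SchemaError(f"{self.name!r}: duplicate levels")
            if self.kind == "binary" and len(self.levels) != 2:
                raise SchemaError(f"{self.name!r}: binary needs 2 levels")
            if self.level_probs is None:
                self.level_probs = tuple(
                    [1.0 / len(self.levels)] * len(self.levels))
            else:
                self.level_probs = tuple(float(p) for p in self.level_probs)
                if len(self.level_probs) != len(self.levels):
                    raise SchemaError(
                        f"{self.name!r}: level_probs length mismatch")
                if any(p < 0 for p in self.level_probs):
                    raise SchemaError(f"{self.name!r}: negative probability")
                s = sum(self.level_probs)
                if s <= 0:
                    raise SchemaError(f"{self.name!r}: zero probability mass")
                self.level_probs = tuple(p / s for p in self.level_probs)

    @property
    def is_categorical(self) -> bool:
        return self.kind != "numeric"

    def to_dict(self) -> dict:
        d = {"name": self.name, "category": self.category, "kind": self.kind}
        if self.is_categorical:
            d["levels"] = list(self.levels)
            d["level_probs"] = list(self.level_probs)
        else:
            d["range"] = list(self.range)
            d["loc"] = self.loc
            d["scale"] = self.scale
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSpec":
        return cls(
            name=d["name"], category=d["category"], kind=d["kind"],
            levels=tuple(d.get("levels", ())),
            range=tuple(d["range"]) if d.get("range") else None,
            level_probs=tuple(d["level_probs"]) if d.get("level_probs") else None,
            loc=d.get("loc"), scale=d.get("scale"),
        )


@dataclass
class SurveySchema:
    """An ordered collection of :class:`VariableSpec` plus the label column."""

    variables: list[VariableSpec]
    burnout_label_name: str = "burnout"

    def __post_init__(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate variable names in schema")
        if self.burnout_label_name in names:
            raise SchemaError("label name collides with a variable name")

    def __getitem__(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(v.name == name for v in self.variables)

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def by_category(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in CATEGORIES}
        for v in self.variables:
            out[v.category].append(v.name)
        return out

    def to_json(self, path) -> None:
        payload = {
            "burnout_label_name": self.burnout_label_name,
            "variables": [v.to_dict() for v in self.variables],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SurveySchema":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            variables=[VariableSpec.from_dict(d) for d in payload["variables"]],
            burnout_label_name=payload.get("burnout_label_name", "burnout"),
        )


#: Default high-burnout prevalence: 728 high-risk among 5,794 respondents.
DEFAULT_PREVALENCE = _cohort.N_HIGH / _cohort.N_VALID
#: Default cohort size.
DEFAULT_N = _cohort.N_VALID


@dataclass
class SimulationConfig:
    """Settings for one synthetic cohort draw.

    ``effect_sizes`` maps variable names to burnout effects: for categorical
    variables a per-level log-odds shift applied to the high-burnout group's
    level probabilities (zero vector = exact null); for numeric variables a
    location shift expressed in units of the variable's range.
    """

    n_respondents: int = DEFAULT_N
    burnout_prevalence: float = DEFAULT_PREVALENCE
    effect_sizes: dict[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_respondents < 2:
            raise SchemaError("n_respondents must be >= 2")
        if not 0.0 < self.burnout_prevalence < 1.0:
            raise SchemaError("burnout_prevalence must lie in (0, 1)")

    def validate_against(self, schema: SurveySchema) -> None:
        for name, eff in self.effect_sizes.items():
            if name not in schema:
                raise SchemaError(
                    f"effect size for unknown variable {name!r}")
            var = schema[name]
            if var.is_categorical:
                if len(tuple(eff)) != len(var.levels):
                    raise SchemaError(
                        f"{name!r}: effect vector length != number of levels")
            else:
                float(eff)  # must be scalar


def _iqr_to_scale(iqr: tuple[float, float]) -> float:
    # Normal quartile spread: IQR = 2 * 0.6745 * sigma
    return (iqr[1] - iqr[0]) / 1.349


def default_schema() -> SurveySchema:
    """Schema mirroring the reference airport-workforce cohort.

    Marginal level probabilities are the cohort's overall proportions
    (derived from the low + high group counts); numeric variables get a
    truncated-normal location at the cohort median and a scale matched to
    the reported interquartile range.
    """
    variables: list[VariableSpec] = []
    for category, name, rng, med, iqr, *_ in _cohort.NUMERIC_SUMMARIES:
        variables.append(VariableSpec(
            name=name, category=category, kind="numeric", range=rng,
            loc=med, scale=_iqr_to_scale(iqr)))
    for category, name, kind, counts in _cohort.CATEGORICAL_COUNTS:
        levels = tuple(counts)
        totals = [counts[lv][0] + counts[lv][1] for lv in levels]
        variables.append(VariableSpec(
            name=name, category=category, kind=kind, levels=levels,
            level_probs=tuple(t / sum(totals) for t in totals)))
    return SurveySchema(variables=variables)


def cohort_effect_sizes(schema: SurveySchema | None = None) -> dict[str, object]:
    """Burnout effect sizes reproducing the reference cohort's group contrast.

    For each categorical variable the effect is the per-level log odds ratio
    ``log(p_high / p_low)`` between the two burnout groups (so the simulated
    high-burnout group matches the cohort's high-group marginals); for numeric
    variables it is the between-group median shift in units of the range.
    """
    import math

    if schema is None:
        schema = default_schema()
    effects: dict[str, object] = {}
    for category, name, rng, _m, _i, med_lo, _il, med_hi, _ih in (
            _cohort.NUMERIC_SUMMARIES):
        if name in schema:
            effects[name] = (med_hi - med_lo) / (rng[1] - rng[0])
    for _category, name, _kind, counts in _cohort.CATEGORICAL_COUNTS:
        if name not in schema:
            continue
        var = schema[name]
        lo = [counts[lv][0] for lv in var.levels]
        hi = [counts[lv][1] for lv in var.levels]
        nlo, nhi = sum(lo), sum(hi)
        effects[name] = tuple(
            math.log(max(h, 0.5) / nhi) - math.log(max(l, 0.5) / nlo)
            for l, h in zip(lo, hi))
    return effects
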