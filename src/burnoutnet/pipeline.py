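"""End-to-end orchestration: simulate/load -> screen -> infer -> fit -> report.

Every stage draws its randomness from a stage-keyed seed split off one root
seed, so stages are independently reproducible and a rerun with the same
configuration yields identical artifacts.  A provenance JSON (config +
config hash + stage seeds + key counts) is written beside the outputs and
is sufficient to re-execute the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import codec, ergm, network, screen, synthetic
from .schema import (
    DEFAULT_N,
    DEFAULT_PREVALENCE,
    SchemaError,
    SimulationConfig,
    SurveySchema,
    default_schema,
    cohort_effect_sizes,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Validated settings for one pipeline run.

    Exactly one of ``threshold`` / ``target_avg_degree`` selects the
    network-construction rule.  ``feature_mode`` chooses whether all
    schema variables or only the screen's significant ones feed the
    similarity encoder.  ``effects`` is ``"cohort"`` (reference-cohort
    contrast), ``"null"`` (no burnout effects) or a mapping.
    """

    survey_path: str | None = None
    schema_path: str | None = None
    n_respondents: int = DEFAULT_N
    prevalence: float = DEFAULT_PREVALENCE
    effects: object = "cohort"
    alpha: float = 0.05
    feature_mode: str = "significant"
    threshold: float | None = None
    target_avg_degree: float | None = None
    ergm_method: str = "exact"
    mcmc: dict = field(default_factory=dict)
    seed: int | None = 0
    out_dir: str = "burnoutnet_run"

    def __post_init__(self) -> None:
        if (self.threshold is None) == (self.target_avg_degree is None):
            raise ConfigError(
                "exactly one of 'threshold' and 'target_avg_degree' must "
                "be set")
        if self.threshold is not None and not 0 <= self.threshold <= 1:
            raise ConfigError("'threshold' must lie in [0, 1]")
        if self.feature_mode not in ("all", "significant"):
            raise ConfigError("'feature_mode' must be 'all' or 'significant'")
        if self.ergm_method not in ("exact", "mcmc"):
            raise ConfigError("'ergm_method' must be 'exact' or 'mcmc'")
        if not 0 < self.alpha <= 1:
            raise ConfigError("'alpha' must lie in (0, 1]")
        stochastic = self.survey_path is None or self.ergm_method == "mcmc"
        if stochastic and self.seed is None:
            raise ConfigError(
                "'seed' is mandatory when any stage is stochastic "
                "(simulation or MCMC)")

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["effects"], (str, type(None))):
            d["effects"] = {k: list(v) if hasattr(v, "__len__") else v
                            for k, v in dict(self.effects).items()}
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def validate_config(path) -> PipelineConfig:
    """Parse a YAML/JSON config file into a validated PipelineConfig."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    if "threshold" not in raw and "target_avg_degree" not in raw:
        raw["threshold"] = network.DEFAULT_THRESHOLD
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def stage_seed(root_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (root_seed * 1000003 + zlib.crc32(stage.encode())) % (2**31)


def _resolve_effects(config: PipelineConfig, schema: SurveySchema):
    if config.effects == "cohort":
        return cohort_effect_sizes(schema)
    if config.effects in ("null", None):
        return {}
    if isinstance(config.effects, dict):
        return config.effects
    raise ConfigError(f"unknown effects setting {config.effects!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write artifacts to ``config.out_dir``.

    Artifacts: survey.csv, table_one.tsv, screen.json, edges.tsv,
    nodes.tsv, ergm_zero.json, ergm_burnout.json, comparison.json,
    provenance.json.  Returns a summary dict of the run.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "init"
    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
    }
    try:
        stage = "schema"
        schema = (SurveySchema.from_json(config.schema_path)
                  if config.schema_path else default_schema())

        stage = "survey"
        if config.survey_path:
            table = codec.read_survey(config.survey_path, schema)
        else:
            seed = stage_seed(config.seed, "simulate")
            sim = SimulationConfig(
                n_respondents=config.n_respondents,
                burnout_prevalence=config.prevalence,
                effect_sizes=_resolve_effects(config, schema),
                seed=seed)
            table = synthetic.generate_survey(schema, sim)
            provenance["stages"]["simulate"] = {"seed": seed,
                                                "n": len(table)}
        codec.write_survey(table, out / "survey.csv")
        logger.info("stage=survey n=%d elapsed=%.1fs", len(table),
                    time.time() - t0)

        stage = "screen"
        report = screen.table_one_report(table, schema)
        screen.write_report(report, out / "table_one.tsv")
        selected = screen.screen_variables(table, schema, config.alpha)
        flat_selected = [v for vs in selected.values() for v in vs]
        with open(out / "screen.json", "w", encoding="utf-8") as fh:
            json.dump({"alpha": config.alpha, "selected": selected}, fh,
                      indent=2)
        provenance["stages"]["screen"] = {
            "alpha": config.alpha, "n_selected": len(flat_selected)}
        logger.info("stage=screen selected=%d elapsed=%.1fs",
                    len(flat_selected), time.time() - t0)

        stage = "network"
        use = (flat_selected if config.feature_mode == "significant"
               else schema.names)
        if not use:
            raise screen.ScreenError(
                "no variables passed the screen; cannot build features "
                "(set feature_mode: all)")
        features = codec.encode_features(table, schema, use)
        sims = network.cosine_similarity_matrix(features)
        if config.threshold is not None:
            t = config.threshold
        else:
            t = network.calibrate_threshold(sims, config.target_avg_degree)
        attrs = dict(zip(table["respondent_id"].astype(str),
                         table[schema.burnout_label_name]))
        g = network.threshold_network(sims, t, attrs)
        network.write_network(g, out / "edges.tsv", out / "nodes.tsv")
        summary = network.network_summary(g)
        provenance["stages"]["network"] = {
            "threshold": t, "n_features": features.shape[1], **{
                k: v for k, v in summary.items() if k != "threshold_used"}}
        logger.info("stage=network edges=%d threshold=%.4f elapsed=%.1fs",
                    summary["n_edges"], t, time.time() - t0)

        stage = "ergm"
        spec_zero = ergm.zero_spec()
        spec_attr = ergm.burnout_spec(attribute="burnout", base="low")
        if config.ergm_method == "exact":
            fit_zero = ergm.fit_exact(g, spec_zero)
            fit_attr = ergm.fit_exact(g, spec_attr)
        else:
            control = ergm.ErgmControl(
                seed=stage_seed(config.seed, "mcmc"), **config.mcmc)
            fit_zero = ergm.fit_mcmcmle(g, spec_zero, control)
            fit_attr = ergm.fit_mcmcmle(g, spec_attr, control)
        fit_zero.to_json(out / "ergm_zero.json")
        fit_attr.to_json(out / "ergm_burnout.json")
        (out / "ergm_burnout.txt").write_text(
            fit_attr.summary_table() + "\n", encoding="utf-8")
        comparison = ergm.compare_models(fit_zero, fit_attr)
        with open(out / "comparison.json", "w", encoding="utf-8") as fh:
            json.dump(comparison.to_dict(), fh, indent=2)
        provenance["stages"]["ergm"] = {
            "method": config.ergm_method,
            "selected": comparison.selected,
            "coefficients": dict(zip(fit_attr.spec.labels,
                                     fit_attr.coefficients.tolist()))}
        logger.info("stage=ergm selected=%s elapsed=%.1fs",
                    comparison.selected, time.time() - t0)
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc}") from exc

    provenance["elapsed_seconds"] = time.time() - t0
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2)
    return {
        "out_dir": str(out),
        "config_hash": provenance["config_hash"],
        "n_respondents": len(table),
        "selected_variables": flat_selected,
        "network": summary,
        "comparison": comparison.to_dict(),
        "fit_burnout": fit_attr.to_dict(),
        "fit_zero": fit_zero.to_dict(),
    }


def rerun_from_provenance(provenance_path) -> dict:
    """Re-execute a run from its provenance record (closure property)."""
    with open(provenance_path, encoding="utf-8") as fh:
        record = json.load(fh)
    return run_pipeline(PipelineConfig(**record["config"]))
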