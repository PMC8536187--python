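"""End-to-end orchestration: config, stage order, report bundle.

``run_pipeline`` executes the fixed stage order

    read -> cohort -> linkage -> classification -> statistics -> temporal

and writes a report bundle of CSV tables (attrition log, episode table,
interpretation table, effect/latency/hour tables, ANOVA and optional
regression) plus a plain-text run log.  The bundle is bit-identical across
reruns on identical config and inputs; the run log carries wall-clock
ISO-8601 timestamps and is therefore excluded from that guarantee.  On any
stage error, partial outputs are removed and the error names the stage.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as raio
from .classify import interpretation_table, near_miss_frequencies, repletion_fraction
from .cohort import AttritionLog, ExclusionRule, build_cohort, default_exclusion_rules
from .errors import ConfigError, DataError
from .linkage import LinkageConfig, LinkageResult, link_episodes, scenario_frequencies
from .model import ReferenceRange, default_reference_ranges
from .stats import decision_regression, pre_post_effect, threshold_anova
from .temporal import hour_histogram, latency_summary, threshold_by_hour

ALL_ANALYSES = ("ranges", "effect", "temporal", "anova", "regression")


@dataclass
class PipelineConfig:
    """Validated configuration for one pipeline run."""

    table_paths: dict = field(default_factory=dict)  # {kind+'s': path}
    out_dir: str = "report"
    schema_maps: dict = field(default_factory=dict)
    item_maps: dict = field(default_factory=dict)
    exclusion_rules: list = field(default_factory=default_exclusion_rules)
    linkage: LinkageConfig = field(default_factory=LinkageConfig)
    ranges: dict = field(default_factory=default_reference_ranges)
    analyses: tuple = ALL_ANALYSES
    electrolytes: tuple = ("potassium", "magnesium", "phosphate")
    seed: int = 0

    def validate(self) -> None:
        for name in ("stays", "labs", "repletions", "diagnoses"):
            if name not in self.table_paths:
                raise ConfigError(f"config lacks a path for the {name} table")
            if not os.path.exists(self.table_paths[name]):
                raise ConfigError(f"{name} table not found: {self.table_paths[name]}")
        for elec in self.electrolytes:
            if elec not in self.ranges:
                raise ConfigError(
                    f"no reference range configured for analyzed electrolyte {elec!r}"
                )
        unknown = set(self.analyses) - set(ALL_ANALYSES)
        if unknown:
            raise ConfigError(f"unknown analyses: {sorted(unknown)}")


def load_config(path: str | os.PathLike) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Recognized keys: ``tables`` (mapping kind to CSV path), ``out_dir``,
    ``schema_maps`` (``mimic`` selects the shipped MIMIC-III mapping),
    ``item_maps``, ``exclusions`` (list of ``{name, kind, payload}``;
    omit for the defaults), ``ranges`` (``{electrolyte: [low, high]}``),
    ``window_minutes``, ``analyses``, ``electrolytes``, ``seed``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = PipelineConfig()
    cfg.table_paths = dict(raw.get("tables", {}))
    cfg.out_dir = raw.get("out_dir", cfg.out_dir)
    for kind, mp in (raw.get("schema_maps") or {}).items():
        cfg.schema_maps[kind] = raio.MIMIC_SCHEMA_MAPS[kind] if mp == "mimic" else dict(mp)
    cfg.item_maps = {k: dict(v) for k, v in (raw.get("item_maps") or {}).items()}
    if "exclusions" in raw:
        cfg.exclusion_rules = [
            ExclusionRule(r["name"], r["kind"], r["payload"]) for r in raw["exclusions"]
        ]
    if "ranges" in raw:
        cfg.ranges = {
            elec: ReferenceRange(elec, float(lo), float(hi))
            for elec, (lo, hi) in raw["ranges"].items()
        }
    if "window_minutes" in raw:
        cfg.linkage = LinkageConfig(window_minutes=float(raw["window_minutes"]))
    if "analyses" in raw:
        cfg.analyses = tuple(raw["analyses"])
    if "electrolytes" in raw:
        cfg.electrolytes = tuple(raw["electrolytes"])
    cfg.seed = int(raw.get("seed", 0))
    return cfg


def _hist_frame(hist) -> pd.DataFrame:
    return hist.to_frame()


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run every stage and return (and optionally write) the report bundle.

    Returns a dict holding the in-memory results: ``tables``, ``cohort``,
    ``attrition`` (:class:`AttritionLog`), ``linkage``
    (:class:`LinkageResult`) and one DataFrame per analysis output.
    """
    config.validate()
    log_lines: list[str] = []
    written: list[str] = []

    def _log(msg: str) -> None:
        log_lines.append(f"{_dt.datetime.now().isoformat(timespec='seconds')} {msg}")

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                _log(f"stage {name}: start")

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    for p in written:
                        if os.path.exists(p):
                            os.remove(p)
                    raise DataError(f"stage {name!r} failed: {exc}") from exc
                _log(f"stage {name}: done")

        return _Ctx()

    bundle: dict = {}
    outputs: dict[str, pd.DataFrame] = {}

    with _stage("read"):
        tables = {}
        for name, kind in (
            ("stays", "stay"), ("labs", "lab"),
            ("repletions", "repletion"), ("diagnoses", "diagnosis"),
        ):
            df, report = raio.read_events_table(
                config.table_paths[name],
                kind,
                schema_map=config.schema_maps.get(kind),
                item_map=config.item_maps.get(kind),
            )
            tables[name] = df
            _log(
                f"read {name}: {report.n_rows_read} rows, "
                f"{report.n_rows_rejected} rejected {report.rejection_reasons or ''}"
            )
        keep = tables["labs"]["electrolyte"].isin(config.electrolytes)
        tables["labs"] = tables["labs"].loc[keep].reset_index(drop=True)
        keep = tables["repletions"]["electrolyte"].isin(config.electrolytes)
        tables["repletions"] = tables["repletions"].loc[keep].reset_index(drop=True)
        bundle["tables"] = tables

    with _stage("cohort"):
        cohort, attrition = build_cohort(tables, config.exclusion_rules)
        bundle["cohort"] = cohort
        bundle["attrition"] = attrition
        outputs["attrition"] = attrition.to_frame()
        _log(f"cohort: {len(cohort['stays'])} stays, {len(cohort['labs'])} labs remain")

    with _stage("linkage"):
        result: LinkageResult = link_episodes(
            cohort["labs"], cohort["repletions"], config.linkage
        )
        bundle["linkage"] = result
        outputs["episodes"] = result.episodes
        outputs["ignored_labs"] = result.ignored_labs
        outputs["unanchored_repletions"] = result.unanchored_repletions
        outputs["orphan_labs"] = result.orphan_labs
        outputs["scenario_frequencies"] = scenario_frequencies(result.episodes)
        n_labs = len(cohort["labs"])
        n_roles = len(result.episodes) + len(result.ignored_labs) + len(result.orphan_labs)
        if n_roles != n_labs:
            raise DataError(f"lab conservation violated: {n_roles} roles vs {n_labs} labs")
        _log(
            f"linkage: {len(result.episodes)} episodes, "
            f"{len(result.ignored_labs)} ignored, "
            f"{len(result.unanchored_repletions)} unanchored orders"
        )

    episodes = bundle["linkage"].episodes
    if "ranges" in config.analyses:
        with _stage("classification"):
            outputs["interpretation_table"] = interpretation_table(episodes, config.ranges)
            outputs["repletion_fraction"] = repletion_fraction(episodes)
            outputs["near_miss"] = near_miss_frequencies(episodes, config.ranges)

    if "effect" in config.analyses:
        with _stage("effect"):
            outputs["effect_sizes"] = pre_post_effect(episodes)

    if "temporal" in config.analyses:
        with _stage("temporal"):
            outputs["lab_hour_histogram"] = _hist_frame(hour_histogram(episodes, "index_time"))
            rep_ep = episodes.loc[episodes["order_time"].notna()]
            outputs["order_hour_histogram"] = _hist_frame(hour_histogram(rep_ep, "order_time"))
            outputs["followup_hour_histogram"] = _hist_frame(
                hour_histogram(rep_ep.loc[rep_ep["followup_time"].notna()], "followup_time")
            )
            outputs["latency_summary"] = latency_summary(episodes)
            outputs["threshold_by_hour"] = threshold_by_hour(episodes)

    if "anova" in config.analyses:
        with _stage("anova"):
            unit_of = cohort["stays"].set_index("stay_id")["unit_type"]
            rep_ep = episodes.loc[episodes["order_time"].notna()]
            rows = []
            for elec in config.electrolytes:
                sub = rep_ep.loc[rep_ep["electrolyte"] == elec]
                groups = sub["stay_id"].map(unit_of)
                ok = groups.notna()
                if ok.sum() < 4 or groups[ok].nunique() < 2:
                    continue
                res = threshold_anova(sub.loc[ok, "index_value"].to_numpy(float), groups[ok])
                rows.append(
                    {
                        "electrolyte": elec,
                        "f_statistic": res.f_statistic,
                        "df_between": res.df_between,
                        "df_within": res.df_within,
                        "p_value": res.p_value,
                    }
                )
            outputs["threshold_anova"] = pd.DataFrame(
                rows, columns=["electrolyte", "f_statistic", "df_between", "df_within", "p_value"]
            )

    if "regression" in config.analyses:
        with _stage("regression"):
            # post-repletion level on pre level + demographics + unit code;
            # the audit's fuller covariate set needs external feature tables
            stays_idx = cohort["stays"].set_index("stay_id")
            rep_ep = episodes.loc[
                episodes["order_time"].notna() & episodes["followup_value"].notna()
            ]
            frames = []
            for elec in config.electrolytes:
                sub = rep_ep.loc[rep_ep["electrolyte"] == elec].copy()
                if len(sub) < 10:
                    continue
                sub["age"] = sub["stay_id"].map(stays_idx["age_years"])
                if "weight_kg" in stays_idx.columns:
                    sub["weight"] = sub["stay_id"].map(stays_idx["weight_kg"])
                unit_codes = {u: i for i, u in enumerate(sorted(stays_idx["unit_type"].unique()))}
                sub["unit"] = sub["stay_id"].map(stays_idx["unit_type"]).map(unit_codes)
                predictors = [c for c in ("index_value", "age", "weight", "unit") if c in sub]
                predictors = [c for c in predictors if sub[c].std() > 0]
                try:
                    fit = decision_regression(sub, "followup_value", predictors)
                except DataError:
                    continue
                frame = fit.to_frame()
                frame.insert(0, "electrolyte", elec)
                frame["n_observations"] = fit.n_observations
                frame["r_squared"] = fit.r_squared
                frames.append(frame)
            outputs["regression"] = (
                pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
            )

    bundle["outputs"] = outputs

    if write:
        with _stage("write"):
            os.makedirs(config.out_dir, exist_ok=True)
            for name in sorted(outputs):
                path = os.path.join(config.out_dir, f"{name}.csv")
                raio.write_summary_table(outputs[name], path)
                written.append(path)
            txt = os.path.join(config.out_dir, "attrition.txt")
            with open(txt, "w") as fh:
                fh.write(str(bundle["attrition"]) + "\n")
            written.append(txt)
        _log("pipeline complete")
        with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return bundle
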