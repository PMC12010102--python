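"""Config-driven orchestration of the full analysis chain.

Stages: simulate -> score -> describe -> mediate -> alff -> associate ->
isrsa, each toggleable, all seeded from one integer so a run is
reproducible end to end. The config is a plain-text INI file (sections
of key = value); unknown sections or keys are rejected before any stage
runs. Every run writes a ``run_info.json`` carrying the resolved config
and a hash of it; a stage whose outputs already exist is recomputed
unless the recorded hash matches the current config.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import alff as alff_mod
from . import association as assoc_mod
from . import isrsa as isrsa_mod
from . import mediation as med_mod
from . import psychometrics as psy
from . import synthetic as synth

__all__ = ["PipelineConfig", "ConfigError", "StageError", "run_pipeline"]

log = logging.getLogger("svamech")

ALL_STAGES = ("simulate", "score", "describe", "mediate", "alff", "associate", "isrsa")


class ConfigError(ValueError):
    """Invalid or unknown pipeline configuration."""


class StageError(RuntimeError):
    """A pipeline stage failed; .stage carries the stage name."""

    def __init__(self, stage, original):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    stages: tuple = ALL_STAGES
    # simulate
    n_subjects: int = 500
    a_true: float = 0.4
    b_true: float = 0.3
    cprime_true: float = 0.18
    item_loading: float = 0.8
    female_prop: float = 0.5915
    # neuro simulate
    n_neuro_subjects: int = 60
    n_parcels: int = 50
    n_voxels: int = 16
    n_timepoints: int = 300
    tr_seconds: float = 2.0
    coupling_parcels: tuple = (7,)
    coupling_strength: float = 0.5
    pattern_parcels: tuple = (3, 11)
    # analysis
    f_low: float = 0.01
    f_high: float = 0.1
    n_boot: int = 1000
    ci_level: float = 0.95
    correction: str = "bonferroni"
    alpha: float = 0.05
    cutoff_female: int = 33
    cutoff_male: int = 31

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ConfigError("ci_level must lie in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        parser = configparser.ConfigParser()
        read = parser.read(path)
        if not read:
            raise ConfigError(f"config file not found: {path}")
        valid = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        kwargs = {}
        for section in parser.sections():
            for key, value in parser.items(section):
                if key not in valid:
                    raise ConfigError(f"unknown config key [{section}] {key}")
                kwargs[key] = _coerce(key, value, cls)
        return cls(**kwargs)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _coerce(key, value, cls):
    default = cls.__dataclass_fields__[key].default  # type: ignore[attr-defined]
    if key in ("stages", "coupling_parcels", "pattern_parcels"):
        parts = [v.strip() for v in value.split(",") if v.strip()]
        return tuple(parts) if key == "stages" else tuple(int(v) for v in parts)
    if isinstance(default, bool):
        return value.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(value)
    if isinstance(default, float):
        return float(value)
    return value


def _stage(cfg, name):
    def deco(fn):
        def wrapped(ctx):
            log.info("[%s seed=%d] start", name, cfg.seed)
            try:
                fn(ctx)
            except (ConfigError, StageError):
                raise
            except Exception as exc:  # tag the failing stage for diagnostics
                raise StageError(name, exc) from exc
            log.info("[%s seed=%d] done", name, cfg.seed)
        return wrapped
    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the toggled stages; returns {artifact name: path}.

    Raises ConfigError / StageError; artifacts embed the config hash so
    downstream partial re-runs can tell whether upstream outputs match.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    info_path = out / "run_info.json"
    cfg_hash = cfg.hash()
    prior_hash = None
    if info_path.exists():
        try:
            prior_hash = json.loads(info_path.read_text()).get("config_hash")
        except json.JSONDecodeError:
            prior_hash = None
    reuse = prior_hash == cfg_hash

    ctx: dict = {"paths": {}}
    scales = psy.default_scales()
    sva_items = list(scales["SVA"].items)

    def simulate(ctx):
        qpath = out / "questionnaire.csv"
        if reuse and qpath.exists():
            ctx["table"] = pd.read_csv(qpath)
        else:
            params = synth.GenParams(
                n_subjects=cfg.n_subjects, a_true=cfg.a_true, b_true=cfg.b_true,
                cprime_true=cfg.cprime_true, item_loading=cfg.item_loading,
                female_prop=cfg.female_prop, seed=cfg.seed,
            )
            table, truth = synth.gen_questionnaire_cohort(params)
            table.to_csv(qpath, index=False)
            truth["latents"].to_csv(out / "truth_latents.csv")
            ctx["table"] = table
        ctx["paths"]["questionnaire"] = qpath

        # neural cohort: first n_neuro_subjects, trait = SVA total
        sub = ctx["table"].iloc[: cfg.n_neuro_subjects]
        trait = sub[sva_items].sum(axis=1).to_numpy(dtype=float)
        manifest = out / "parcels" / "manifest.json"
        if not (reuse and manifest.exists()):
            nparams = synth.NeuroGenParams(
                n_subjects=len(sub), n_parcels=cfg.n_parcels,
                n_voxels_per_parcel=cfg.n_voxels, n_timepoints=cfg.n_timepoints,
                tr_seconds=cfg.tr_seconds, coupling_parcels=cfg.coupling_parcels,
                coupling_strength=cfg.coupling_strength,
                pattern_coupling_parcels=cfg.pattern_parcels, seed=cfg.seed,
                band=(cfg.f_low, cfg.f_high),
            )
            pts, _ = synth.gen_resting_parcels(
                nparams, trait, item_profile=sub[sva_items].to_numpy(dtype=float)
            )
            alff_mod.write_parcel_set(pts, out / "parcels")
        ctx["paths"]["parcel_manifest"] = manifest
        ctx["neuro_trait"] = trait
        ctx["neuro_table"] = sub

    def score(ctx):
        table = ctx.get("table")
        if table is None:
            table = pd.read_csv(ctx["paths"]["questionnaire"])
        sc = dict(scales)
        sc["SVA"] = replace(
            sc["SVA"], cutoffs={"F": cfg.cutoff_female, "M": cfg.cutoff_male}
        )
        scored = psy.score_cohort(table, scales=sc)
        scored.insert(0, "subject_id", table["subject_id"].to_numpy())
        path = out / "scored.csv"
        scored.to_csv(path, index=False)
        ctx["scored"] = scored
        ctx["paths"]["scored"] = path

    def describe(ctx):
        scored = ctx["scored"]
        table = ctx["table"]
        stats_out = {"config_hash": cfg_hash, "n": int(len(scored))}
        desc = scored[["SVA", "BV", "VB", "PB", "RB", "NA", "PA"]].agg(["mean", "std"])
        stats_out["descriptives"] = desc.round(4).to_dict()
        r, p = psy.pearson_corr_matrix(scored, ["SVA", "BV", "VB", "PB", "RB", "NA"])
        r.to_csv(out / "correlations.csv")
        for scale_name, sdef in scales.items():
            stats_out[f"alpha_{scale_name}"] = round(
                psy.cronbach_alpha(table[list(sdef.items)]), 4
            )
        items = [i for d in scales.values() for i in d.items]
        n_f, pct = psy.harman_single_factor(table[items])
        stats_out["harman_n_factors"] = n_f
        stats_out["harman_first_factor_pct"] = round(pct, 2)
        stats_out["addicted_n"] = int((scored["addiction_class"] == "addicted").sum())
        path = out / "descriptives.json"
        path.write_text(json.dumps(stats_out, indent=2, sort_keys=True))
        ctx["paths"]["descriptives"] = path

    def mediate(ctx):
        scored = ctx["scored"]
        rows = []
        for xvar in ["BV", "VB", "PB", "RB"]:
            res = med_mod.mediate(
                scored[xvar], scored["NA"], scored["SVA"],
                n_boot=cfg.n_boot, ci_level=cfg.ci_level, seed=cfg.seed,
            )
            rows.append({"x": xvar, "subgroup": "all", **res.summary_row()})
            for level, sub in med_mod.subgroup_mediate(
                scored, xvar, "NA", "SVA", n_boot=cfg.n_boot,
                ci_level=cfg.ci_level, seed=cfg.seed,
            ).items():
                rows.append({"x": xvar, "subgroup": level,
                             **sub["mediation"].summary_row(), **sub["screen"]})
        path = out / "mediation.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        ctx["paths"]["mediation"] = path

    def alff_stage(ctx):
        pts = alff_mod.read_parcel_set(ctx["paths"]["parcel_manifest"])
        maps = alff_mod.alff_maps(pts, band=(cfg.f_low, cfg.f_high))
        ctx["alff_maps"] = maps
        path = out / "alff_parcel_means.csv"
        alff_mod.parcel_mean_table(maps).to_csv(path)
        ctx["paths"]["alff_parcel_means"] = path

    def associate(ctx):
        maps = ctx["alff_maps"]
        sub = ctx["neuro_table"]
        cov = np.column_stack([
            sub["age"].to_numpy(float),
            (sub["gender"] == "F").to_numpy(float),
            sub["mother_edu"].to_numpy(float),
            sub["father_edu"].to_numpy(float),
            sub["fd"].to_numpy(float),
        ])
        res = assoc_mod.parcel_association(
            maps, ctx["neuro_trait"], covariates=cov,
            correction=cfg.correction, alpha=cfg.alpha,
        )
        path = out / "association.csv"
        res.to_csv(path, index=False)
        ctx["paths"]["association"] = path

    def isrsa_stage(ctx):
        maps = ctx["alff_maps"]
        behav = isrsa_mod.behavioral_rdm(
            ctx["neuro_table"][sva_items], subject_ids=maps.subject_ids
        )
        res = isrsa_mod.isrsa_map(behav, maps, alpha=cfg.alpha)
        top = int(res.sort_values("r", ascending=False).iloc[0]["parcel"])
        r_obs, p_perm = isrsa_mod.mantel_permutation(
            behav, isrsa_mod.neural_rdm(maps, top), n_perm=999, seed=cfg.seed
        )
        res["p_perm_top"] = np.where(res["parcel"] == top, p_perm, np.nan)
        path = out / "isrsa.csv"
        res.to_csv(path, index=False)
        ctx["paths"]["isrsa"] = path

    stage_fns = {
        "simulate": simulate, "score": score, "describe": describe,
        "mediate": mediate, "alff": alff_stage, "associate": associate,
        "isrsa": isrsa_stage,
    }
    needs = {
        "score": ("simulate",), "describe": ("score",), "mediate": ("score",),
        "alff": ("simulate",), "associate": ("alff",), "isrsa": ("alff",),
    }
    to_run = [s for s in ALL_STAGES if s in cfg.stages]
    closure = set(to_run)
    for s in to_run:  # pull in upstream stages a toggled stage depends on
        stack = list(needs.get(s, ()))
        while stack:
            dep = stack.pop()
            if dep not in closure:
                closure.add(dep)
                stack.extend(needs.get(dep, ()))
    for name in ALL_STAGES:
        if name in closure:
            _stage(cfg, name)(stage_fns[name])(ctx)

    info_path.write_text(json.dumps(
        {"config_hash": cfg_hash, "config": asdict(cfg),
         "artifacts": {k: str(v) for k, v in ctx["paths"].items()}},
        indent=2, sort_keys=True, default=list,
    ))
    ctx["paths"]["run_info"] = info_path
    return {k: Path(v) for k, v in ctx["paths"].items()}
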