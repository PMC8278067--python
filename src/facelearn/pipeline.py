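"""Staged analysis pipeline with manifest-based reproducibility.

Stages: simulate -> preprocess -> {fit-rl, fit-ddm} -> compare / contrasts
-> report.  Every randomized step draws its stream from the single
top-level seed via named substreams; rerunning with an identical config
reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import ddm as ddm_mod
from . import preprocess as pp
from . import rl as rl_mod
from .synth import GeneratorConfig, generate_dataset, truth_report
from .task import generate_schedule

__all__ = ["RunConfig", "run_pipeline", "STAGES", "PipelineError"]

STAGES = ("simulate", "preprocess", "fit-rl", "fit-ddm", "compare", "contrasts", "report")

_STAGE_DEPS = {
    "simulate": (),
    "preprocess": ("records.csv",),
    "fit-rl": ("filtered.csv",),
    "fit-ddm": ("filtered.csv",),
    "compare": ("filtered.csv",),
    "contrasts": ("ddm_population_draws.csv",),
    "report": ("filter_report.json",),
}


class PipelineError(RuntimeError):
    pass


class SamplerBlock(BaseModel):
    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int | None = None
    thin: int = 1


class RunConfig(BaseModel):
    """Full pipeline configuration; serializes losslessly to JSON/YAML."""

    seed: int = 0
    generator: GeneratorConfig = GeneratorConfig()
    generator_mode: str = "rl_choices"
    fast_cutoff_ms: float = pp.FAST_CUTOFF_MS
    slow_cutoff_ms: float = pp.SLOW_CUTOFF_MS
    rl_models: list[str] = Field(default_factory=lambda: ["copy_bias"])
    compare_models: list[str] = Field(
        default_factory=lambda: ["copy_bias", "baseline_no_bias"]
    )
    rl_sampler: SamplerBlock = SamplerBlock()
    ddm_sampler: SamplerBlock = SamplerBlock(n_chains=6, n_iter=10_000, n_warmup=1_000)
    predict_draws: int = 50
    predict_sims_per_draw: int = 100

    def fast_variant(self) -> "RunConfig":
        cfg = self.model_copy(deep=True)
        cfg.generator.n_participants = min(cfg.generator.n_participants, 8)
        cfg.rl_sampler = SamplerBlock(n_chains=2, n_iter=600)
        cfg.ddm_sampler = SamplerBlock(n_chains=2, n_iter=600)
        cfg.predict_draws = 20
        cfg.predict_sims_per_draw = 20
        return cfg


def _substream_seeds(seed: int) -> dict[str, int]:
    names = ("simulate", "fit-rl", "fit-ddm", "compare", "predict")
    states = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0]) for n, s in zip(names, states)}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.model_dump(), sort_keys=True).encode()
    ).hexdigest()


_ARTIFACT_SOURCE = {
    "records.csv": "simulate",
    "filtered.csv": "preprocess",
    "filter_report.json": "preprocess",
    "ddm_population_draws.csv": "fit-ddm",
}


def _require(outdir: Path, stage: str) -> None:
    for dep in _STAGE_DEPS[stage]:
        if not (outdir / dep).exists():
            raise PipelineError(
                f"stage '{stage}' requires artifact '{dep}' from missing "
                f"upstream stage '{_ARTIFACT_SOURCE[dep]}'"
            )


def _load_filtered(outdir: Path) -> pd.DataFrame:
    df = pd.read_csv(outdir / "filtered.csv")
    pp.validate_records(df)
    return df


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    stages: list[str] | None = None,
) -> dict:
    """Run the requested stages, writing artifacts and a manifest to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    seeds = _substream_seeds(config.seed)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "substream_seeds": seeds,
        "stages": {},
        "outputs": {},
    }

    for stage in [s for s in STAGES if s in stages]:
        _require(outdir, stage)
        t_start = time.perf_counter()
        written: list[str] = []

        if stage == "simulate":
            gen_cfg = config.generator.model_copy(update={"seed": seeds["simulate"]})
            ds = generate_dataset(gen_cfg, mode=config.generator_mode)
            rec = ds.records.copy()
            rec["artifact"] = ds.artifact_labels.to_numpy()
            rec.to_csv(outdir / "records.csv", index=False)
            truth_report(ds, outdir / "truth.json")
            written = ["records.csv", "truth.json"]

        elif stage == "preprocess":
            rec = pd.read_csv(outdir / "records.csv")
            kept, report = pp.filter_trials(
                rec, config.fast_cutoff_ms, config.slow_cutoff_ms
            )
            kept = pp.add_condition_trial_number(kept)
            kept.to_csv(outdir / "filtered.csv", index=False)
            (outdir / "filter_report.json").write_text(
                json.dumps(report.to_dict(), indent=1)
            )
            pp.summarize_behaviour(kept).to_csv(outdir / "summary.csv", index=False)
            pp.learning_curves(kept).to_csv(outdir / "curves.csv", index=False)
            pp.reversal_early_late(kept).to_csv(outdir / "reversal.csv", index=False)
            written = [
                "filtered.csv", "filter_report.json", "summary.csv",
                "curves.csv", "reversal.csv",
            ]

        elif stage == "fit-rl":
            data = _load_filtered(outdir)
            sampler = rl_mod.SamplerConfig(
                seed=seeds["fit-rl"], **config.rl_sampler.model_dump()
            )
            summaries = {}
            for name in config.rl_models:
                fit = rl_mod.fit_rl_hierarchical(data, name, sampler)
                summaries[name] = {
                    "population_means": fit.population_means(),
                    "population_cri95": fit.population_intervals(),
                    "diagnostics": fit.draws.summary_dict(),
                }
                if name == config.rl_models[0]:
                    sched = generate_schedule(seed=seeds["predict"])
                    pred = rl_mod.posterior_predict(
                        fit,
                        sched,
                        n_sims_per_draw=config.predict_sims_per_draw,
                        n_draws=config.predict_draws,
                        seed=seeds["predict"],
                    )
                    pred.to_csv(outdir / "rl_predicted_curves.csv", index=False)
                    written.append("rl_predicted_curves.csv")
            (outdir / "rl_fit.json").write_text(json.dumps(summaries, indent=1))
            written.append("rl_fit.json")

        elif stage == "fit-ddm":
            data = _load_filtered(outdir)
            fit = ddm_mod.fit_ddm_hierarchical(
                data,
                seed=seeds["fit-ddm"],
                **config.ddm_sampler.model_dump(),
            )
            cells = fit.population_cell_draws()
            draw_frame = pd.DataFrame(
                np.column_stack([cells["v"], cells["a"], cells["z"], cells["t0"]]),
                columns=[f"v_{t}_{r}" for t, r in ddm_mod.CELLS]
                + [f"a_{t}_{r}" for t, r in ddm_mod.CELLS]
                + ["z_smile", "z_frown", "t0"],
            )
            draw_frame.to_csv(outdir / "ddm_population_draws.csv", index=False)
            (outdir / "ddm_fit.json").write_text(
                json.dumps(fit.draws.summary_dict(), indent=1)
            )
            written = ["ddm_population_draws.csv", "ddm_fit.json"]

        elif stage == "compare":
            data = _load_filtered(outdir)
            sampler = rl_mod.SamplerConfig(
                seed=seeds["compare"], **config.rl_sampler.model_dump()
            )
            table = rl_mod.compare_models(data, config.compare_models, sampler)
            table.to_csv(outdir / "model_comparison.csv", index=False)
            written = ["model_comparison.csv"]

        elif stage == "contrasts":
            draws = pd.read_csv(outdir / "ddm_population_draws.csv")
            v = draws[[f"v_{t}_{r}" for t, r in ddm_mod.CELLS]].to_numpy()
            a = draws[[f"a_{t}_{r}" for t, r in ddm_mod.CELLS]].to_numpy()
            z = draws[["z_smile", "z_frown"]].to_numpy()
            cong = ddm_mod.contrast_drift_congruency(v)
            out = {
                "drift_congruency_sum": cong["sum"].to_dict(),
                "drift_congruency_mean": cong["mean"].to_dict(),
                "drift_expression": ddm_mod.contrast_expression(
                    {"v": v}, "v_abs"
                ).to_dict(),
                "boundary_expression": ddm_mod.contrast_expression(
                    {"a": a}, "a"
                ).to_dict(),
                "bias_expression": ddm_mod.contrast_expression({"z": z}, "z").to_dict(),
            }
            (outdir / "contrasts.json").write_text(json.dumps(out, indent=1))
            written = ["contrasts.json"]

        elif stage == "report":
            report: dict = {
                "filter_report": json.loads((outdir / "filter_report.json").read_text())
            }
            for name in ("rl_fit.json", "ddm_fit.json", "contrasts.json"):
                if (outdir / name).exists():
                    report[name.removesuffix(".json")] = json.loads(
                        (outdir / name).read_text()
                    )
            for name in ("summary.csv", "model_comparison.csv"):
                if (outdir / name).exists():
                    report[name.removesuffix(".csv")] = pd.read_csv(
                        outdir / name
                    ).to_dict(orient="records")
            (outdir / "report.json").write_text(json.dumps(report, indent=1))
            written = ["report.json"]

        manifest["stages"][stage] = {
            "duration_s": round(time.perf_counter() - t_start, 3),
            "outputs": written,
        }
        for name in written:
            manifest["outputs"][name] = _sha256(outdir / name)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
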