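"""End-to-end orchestration of the four-step workflow.

STEP 1 simulates the 36-cell crossed Taguchi plan, STEP 2 fits the
dynamic SN analysis and trains the desirability surrogate (architecture
search included), STEP 3 runs the genetic algorithm on the surrogate, and
STEP 4 produces the one-factor-at-a-time sensitivity tables.  Every stage
writes its artifact under the output directory and can be re-run from the
cached artifacts of earlier stages.

Randomness is stream-split from one master seed: each stage (and each
simulation replication) derives its own substream through a documented
``SeedSequence`` counter scheme, so re-seeding the GA does not perturb
the simulated responses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig
from .desirability import DesirabilityBounds, bounds_from_responses
from .errors import InvalidParameterError, MissingArtifactError
from .ga import Chromosome, optimize, surrogate_fitness
from .sensitivity import ofat_sweep
from .surrogate import SurrogateModel, architecture_search, build_training_table
from .taguchi import build_plan, cell_means, main_effects, run_plan, select_optimal_levels, sn_table

__all__ = ["STAGES", "PipelineReport", "run_pipeline", "stage_seed"]

STAGES = ("simulate", "taguchi", "surrogate", "optimize", "sensitivity")
_STAGE_TAG = {name: i for i, name in enumerate(STAGES)}


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage substream seed: SeedSequence([master, stage index])."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_TAG[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


@dataclass
class PipelineReport:
    config: ExperimentConfig
    master_seed: int
    out_dir: Path
    artifacts: dict[str, str]
    results: dict[str, object]

    def to_json(self) -> str:
        payload = {
            "version": __version__,
            "master_seed": self.master_seed,
            "profile": self.config.profile,
            "stage_seeds": {s: stage_seed(self.master_seed, s) for s in STAGES},
            "config": _config_echo(self.config),
            "artifacts": self.artifacts,
            "results": self.results,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def _config_echo(config: ExperimentConfig) -> dict:
    def unwrap(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: unwrap(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {k: unwrap(v) for k, v in obj.items()}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [unwrap(v) for v in obj]
        return obj

    return unwrap(config)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"stage {stage!r} needs {path.name}, which has not been produced; "
            f"run the earlier stages first"
        )
    return path


def run_pipeline(
    config: ExperimentConfig,
    out_dir: str | Path,
    seed: int = 0,
    stages: Sequence[str] = STAGES,
) -> PipelineReport:
    """Execute the requested stages in order, reusing cached artifacts.

    Fully deterministic given ``seed``; the report echoes the resolved
    configuration, the per-stage seeds and every artifact path.
    """
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise InvalidParameterError(f"unknown stage(s) {unknown}; choose from {STAGES}")
    stages = [s for s in STAGES if s in stages]  # canonical order
    config = config.resolved()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    results: dict[str, object] = {}

    responses_path = out / "responses.csv"
    sn_paths = {r: out / f"sn_table_{r}.csv" for r in ("edwinc", "st")}
    effects_paths = {r: out / f"main_effects_{r}.csv" for r in ("edwinc", "st")}
    taguchi_path = out / "taguchi_optima.json"
    bounds_path = out / "bounds.json"
    training_path = out / "training_table.csv"
    comparison_path = out / "surrogate_comparison.csv"
    model_path = out / "surrogate_model.json"
    optimum_path = out / "optimum.json"
    history_path = out / "ga_history.csv"

    plan = build_plan(
        signal_levels=config.taguchi.signal_levels,
        noise_levels=config.taguchi.noise_levels,
        replications=config.taguchi.replications,
        base_config=config.scenario,
    )

    if "simulate" in stages:
        responses = run_plan(plan, master_seed=stage_seed(seed, "simulate"))
        responses.to_csv(responses_path, index=False)
        plan_df = pd.DataFrame(
            [
                {"cell": i, "row": c.row, "A": c.levels[0], "B": c.levels[1],
                 "C": c.levels[2], "D": c.levels[3], "M": c.signal_M, "Z": c.noise_lambda}
                for i, c in enumerate(plan.cells)
            ]
        )
        plan_df.to_csv(out / "plan.csv", index=False)
        artifacts["plan"] = "plan.csv"
        artifacts["responses"] = "responses.csv"
        results["n_cells"] = len(plan.cells)
        results["replications"] = plan.replications

    if "taguchi" in stages:
        responses = pd.read_csv(_require(responses_path, "taguchi"))
        means = cell_means(responses)
        optima = {}
        for resp, col in (("edwinc", "mean_edwinc"), ("st", "mean_st")):
            table = sn_table(means, col, config.taguchi)
            table.to_csv(sn_paths[resp], index=False)
            effects = main_effects(table)
            effects.to_csv(effects_paths[resp], index=False)
            setting, predicted = select_optimal_levels(effects)
            optima[resp] = {"setting": setting, "predicted_sn_db": predicted}
            artifacts[f"sn_table_{resp}"] = sn_paths[resp].name
            artifacts[f"main_effects_{resp}"] = effects_paths[resp].name
        taguchi_path.write_text(json.dumps(optima, indent=1, sort_keys=True))
        artifacts["taguchi_optima"] = taguchi_path.name
        results["taguchi_optima"] = optima

    if "surrogate" in stages:
        responses = pd.read_csv(_require(responses_path, "surrogate"))
        means = cell_means(responses)
        bounds = bounds_from_responses(means, margin=config.surrogate.bounds_margin)
        bounds_path.write_text(json.dumps(dataclasses.asdict(bounds), indent=1, sort_keys=True))
        sur_seed = stage_seed(seed, "surrogate")
        table = build_training_table(means, bounds, config.surrogate, seed=sur_seed)
        table.frame.to_csv(training_path, index=False)
        model, comparison = architecture_search(table, config.surrogate, seed=sur_seed)
        comparison.to_csv(comparison_path, index=False)
        model_path.write_text(model.to_json())
        artifacts.update(
            bounds=bounds_path.name,
            training_table=training_path.name,
            surrogate_comparison=comparison_path.name,
            surrogate_model=model_path.name,
        )
        results["surrogate"] = {
            "structure": list(model.structure),
            "rmse_train": model.rmse_train,
            "rmse_test": model.rmse_test,
        }

    signal_noise = tuple(
        (m, z) for m in config.taguchi.signal_levels for z in config.taguchi.noise_levels
    )

    if "optimize" in stages:
        model = SurrogateModel.from_json(_require(model_path, "optimize").read_text())
        fitness = surrogate_fitness(model, config.ga.aggregation, signal_noise)
        optimum = optimize(fitness, config.ga, seed=stage_seed(seed, "optimize"))
        optimum_path.write_text(
            json.dumps(
                {
                    "setting": dataclasses.asdict(optimum.setting),
                    "tp": optimum.tp,
                    "generations": config.ga.generations,
                    "population": config.ga.population,
                },
                indent=1,
                sort_keys=True,
            )
        )
        pd.DataFrame({"generation": range(len(optimum.history)), "best_tp": optimum.history}).to_csv(
            history_path, index=False
        )
        artifacts["optimum"] = optimum_path.name
        artifacts["ga_history"] = history_path.name
        results["optimum"] = {
            "factor_A": round(optimum.setting.factor_A, 4),
            "factor_B": optimum.setting.factor_B,
            "factor_C": optimum.setting.factor_C,
            "factor_D": optimum.setting.factor_D,
            "tp": optimum.tp,
        }

    if "sensitivity" in stages:
        model = SurrogateModel.from_json(_require(model_path, "sensitivity").read_text())
        opt_data = json.loads(_require(optimum_path, "sensitivity").read_text())
        optimum_chrom = Chromosome(**opt_data["setting"])
        fitness = surrogate_fitness(model, config.ga.aggregation, signal_noise)
        tables = ofat_sweep(fitness, optimum_chrom, tp_opt=opt_data["tp"],
                            settings=config.sensitivity)
        sens_summary = {}
        for factor, table in tables.items():
            path = out / f"sensitivity_factor_{factor}.csv"
            table.to_frame().to_csv(path, index=False)
            artifacts[f"sensitivity_{factor}"] = path.name
            sens_summary[factor] = {
                "levels": list(table.levels),
                "tp": [round(t, 6) for t in table.tp],
                "adjusted_tp_percent": list(table.adjusted_tp_percent),
            }
        results["sensitivity"] = sens_summary

    report = PipelineReport(
        config=config, master_seed=seed, out_dir=out, artifacts=artifacts, results=results
    )
    (out / "report.json").write_text(report.to_json())
    return report
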