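"""End-to-end in-silico reciprocal cross-infection study.

A *study* is a set of named scenarios — an infection model plus selection
strengths — each simulated for ``generations`` generations and surveyed
every ``sampling_interval`` generations with a factorial cross-infection
experiment whose outcomes are variance-partitioned.  The default scenario
set covers matching-alleles, inverse matching-alleles and gene-for-gene
models at strong (s_h = 0.67, s_p = 0.69) and moderate (s_h = 0.37,
s_p = 0.39) selection, a constant-matrix control without functional G×G,
and a selection-off control in which the fitness effects of infection are
zero.  GFG scenarios carry resistance/virulence costs tau_h = 0.12,
tau_p = 0.09 (strong) or 0.08, 0.05 (moderate).

Every random draw derives deterministically from the study's master seed;
the manifest records all seeds, parameters and output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gxglink.coevolution_simulator import SimulationParams, run_simulation, TrajectoryRecord
from gxglink.cross_infection_experiment import (
    CrossInfectionTable,
    ExperimentDesign,
    longitudinal_survey,
)
from gxglink.infection_models import build_infection_matrix
from gxglink.likelihood_inference import compare_models
from gxglink.variance_partitioning import component_timeseries

__all__ = [
    "ScenarioConfig",
    "StudyConfig",
    "ScenarioResult",
    "StudyReport",
    "default_scenarios",
    "default_config",
    "run_study",
    "summarize_gxg_detection",
]

#: selection strengths from the two coevolution regimes
STRONG_SELECTION = {"s_h": 0.67, "s_p": 0.69}
MODERATE_SELECTION = {"s_h": 0.37, "s_p": 0.39}
STRONG_GFG_COSTS = {"tau_h": 0.12, "tau_p": 0.09}
MODERATE_GFG_COSTS = {"tau_h": 0.08, "tau_p": 0.05}


@dataclass
class ScenarioConfig:
    """Simulation settings for one named scenario."""

    model_name: str = "MA"
    K: int = 3
    s_h: float = 0.67
    s_p: float = 0.69
    tau_h: float = 0.0
    tau_p: float = 0.0
    N: int = 100_000
    mu: float = 1e-5
    generations: int = 1000
    selection: bool = True
    drift: bool = True
    matrix_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(
                f"unknown scenario keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        return cls(**d)

    def simulation_params(self, seed: int) -> SimulationParams:
        model = build_infection_matrix(self.model_name, self.K, **self.matrix_params)
        return SimulationParams(
            model=model,
            N=self.N,
            mu=self.mu,
            s_h=self.s_h,
            s_p=self.s_p,
            tau_h=self.tau_h,
            tau_p=self.tau_p,
            generations=self.generations,
            seed=seed,
            drift=self.drift,
            selection=self.selection,
        )


def default_scenarios(**overrides) -> dict[str, ScenarioConfig]:
    """The eight standard scenarios; ``overrides`` apply to every scenario
    (e.g. ``N=10_000`` for a scaled-down run)."""
    base = {
        "ma_strong": dict(model_name="MA", **STRONG_SELECTION),
        "ma_moderate": dict(model_name="MA", **MODERATE_SELECTION),
        "ima_strong": dict(model_name="IMA", **STRONG_SELECTION),
        "ima_moderate": dict(model_name="IMA", **MODERATE_SELECTION),
        "gfg_strong": dict(model_name="GFG", **STRONG_SELECTION, **STRONG_GFG_COSTS),
        "gfg_moderate": dict(model_name="GFG", **MODERATE_SELECTION, **MODERATE_GFG_COSTS),
        "const_control": dict(model_name="CONST", **STRONG_SELECTION),
        "no_selection": dict(model_name="MA", **STRONG_SELECTION, selection=False),
    }
    return {
        name: ScenarioConfig.from_dict({**kw, **overrides}) for name, kw in base.items()
    }


@dataclass
class StudyConfig:
    """Configuration of a full study run."""

    scenarios: dict[str, ScenarioConfig] = field(default_factory=default_scenarios)
    design: ExperimentDesign = field(
        default_factory=lambda: ExperimentDesign(error_rate=0.05)
    )
    out_dir: str = "study_out"
    master_seed: int = 0
    replicates: int = 1
    run_anova: bool = True
    run_likelihood: bool = False
    likelihood_models: tuple = (("MA", 3), ("GFG", 3), ("CONST", 3))
    anova_response: str = "count"
    negligible_threshold_frac: float = 0.05
    make_plots: bool = False
    write_tables: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - valid
        if unknown:
            raise ValueError(
                f"unknown study keys {sorted(unknown)}; valid keys: {sorted(valid)}"
            )
        d = dict(d)
        if "scenarios" in d:
            d["scenarios"] = {
                name: ScenarioConfig.from_dict(sc) for name, sc in d["scenarios"].items()
            }
        if "design" in d:
            d["design"] = ExperimentDesign(**d["design"])
        if "likelihood_models" in d:
            d["likelihood_models"] = tuple(tuple(m) for m in d["likelihood_models"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        if not isinstance(payload, dict):
            raise ValueError("study config must be a YAML mapping")
        return cls.from_dict(payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["likelihood_models"] = [list(m) for m in self.likelihood_models]
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def default_config(out_dir: str = "study_out", **overrides) -> StudyConfig:
    return StudyConfig(out_dir=out_dir, **overrides)


@dataclass
class ScenarioResult:
    name: str
    config: ScenarioConfig
    trajectories: list[TrajectoryRecord]
    tables: list[list[CrossInfectionTable]]  # [replicate][survey index]
    components: pd.DataFrame | None
    files: dict = field(default_factory=dict)


@dataclass
class StudyReport:
    config: StudyConfig
    scenarios: dict[str, ScenarioResult]
    manifest: dict
    out_dir: Path


def _derived_seeds(master_seed: int, scenario_index: int, replicate: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(scenario_index, replicate))
    sim_seed, survey_seed = (int(x) % 2**31 for x in ss.generate_state(2))
    return sim_seed, survey_seed


def run_study(config: StudyConfig) -> StudyReport:
    """Run every scenario (simulation → surveys → ANOVA → optional model
    comparison), write CSV outputs and a manifest, and return the report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "master_seed": int(config.master_seed),
        "config": config.to_dict(),
        "files": [],
        "scenarios": {},
    }
    results: dict[str, ScenarioResult] = {}

    def record(path: Path) -> str:
        rel = str(path.relative_to(out))
        manifest["files"].append(rel)
        return rel

    for idx, (name, sc) in enumerate(config.scenarios.items()):
        sdir = out / name
        sdir.mkdir(exist_ok=True)
        trajectories, all_tables, comp_frames = [], [], []
        seeds = []
        for rep in range(config.replicates):
            sim_seed, survey_seed = _derived_seeds(config.master_seed, idx, rep)
            seeds.append({"replicate": rep, "sim_seed": sim_seed, "survey_seed": survey_seed})
            params = sc.simulation_params(sim_seed)
            traj = run_simulation(params)
            rng = np.random.default_rng(survey_seed)
            tables = longitudinal_survey(traj, config.design, rng)
            trajectories.append(traj)
            all_tables.append(tables)
            if config.run_anova:
                comp = component_timeseries(tables, response=config.anova_response)
                comp.insert(0, "replicate", rep)
                comp_frames.append(comp)
        components = pd.concat(comp_frames, ignore_index=True) if comp_frames else None

        files: dict = {}
        traj_path = sdir / "trajectory.csv"
        trajectories[0].to_csv(traj_path)
        files["trajectory"] = record(traj_path)
        files["trajectory_params"] = record(traj_path.with_suffix(".params.json"))
        if components is not None:
            comp_path = sdir / "components.csv"
            components.to_csv(comp_path, index=False)
            files["components"] = record(comp_path)
        if config.write_tables:
            for tab in all_tables[0]:
                tpath = sdir / f"table_gen{tab.generation:05d}.csv"
                tab.to_csv(tpath, truth_path=sdir / f"truth_gen{tab.generation:05d}.csv")
                record(tpath)
                record(sdir / f"truth_gen{tab.generation:05d}.csv")
        if config.run_likelihood:
            last = all_tables[0][-1]
            cmp_res = compare_models(
                last, list(config.likelihood_models), epsilon=max(config.design.error_rate, 0.01)
            )
            inf_path = sdir / "inference.json"
            inf_path.write_text(json.dumps(cmp_res.to_json_dict(), indent=2))
            files["inference"] = record(inf_path)
        if config.make_plots and components is not None:
            from gxglink.plotting import plot_scenario

            fig_path = sdir / "figure.png"
            plot_scenario(trajectories[0], components[components["replicate"] == 0], fig_path)
            files["figure"] = record(fig_path)

        manifest["scenarios"][name] = {
            "index": idx,
            "seeds": seeds,
            "params": sc.simulation_params(seeds[0]["sim_seed"]).to_dict(),
            "files": files,
        }
        results[name] = ScenarioResult(name, sc, trajectories, all_tables, components, files)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return StudyReport(config=config, scenarios=results, manifest=manifest, out_dir=out)


def summarize_gxg_detection(
    report: StudyReport,
    threshold_frac: float | None = None,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Fraction of sampled generations with negligible statistical G×G.

    A generation counts as a detection failure when its estimated
    ``sigma2_gxg`` falls below the threshold — by default 5% of the
    scenario-replicate's mean error variance (scale-free, tied to the error
    stratum), or an absolute ``threshold`` if given.
    """
    if not report.scenarios:
        raise ValueError("empty study report")
    if threshold_frac is None:
        threshold_frac = report.config.negligible_threshold_frac
    rows = []
    for name, res in report.scenarios.items():
        if res.components is None or res.components.empty:
            raise ValueError(f"scenario {name!r} has no variance components")
        for rep, sub in res.components.groupby("replicate"):
            thr = threshold if threshold is not None else threshold_frac * sub["sigma2_error"].mean()
            rows.append(
                {
                    "scenario": name,
                    "replicate": int(rep),
                    "threshold": float(thr),
                    "fraction_negligible": float((sub["sigma2_gxg"] < thr).mean()),
                }
            )
    return pd.DataFrame(rows)
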