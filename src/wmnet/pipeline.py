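"""End-to-end pipeline: simulate -> preprocess -> connect -> network -> stats.

A single JSON-serializable configuration plus one global seed reproduces a
whole run; the seed fans out deterministically into per-stage child seeds
so stages can be re-run in isolation.  Intermediate artifacts are written
as plain text (TSV matrices, CSV tables, JSON reports).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import connectivity_for_subject
from .graph import DegreeGrid, compute_metric_table, find_small_world_regime, verify_regime
from .synthetic import PlantedGraphParams, SyntheticCohort, generate_cohort
from .stats import StatReport, run_statistics
from .timecourse import preprocess_subject

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run (with the seed)."""

    seed: int = 0
    n_per_group: int = 35
    n_runs: int = 3
    tr_seconds: float = 2.0
    low_factor: float = 0.01
    high_factor: float = 0.9
    filter_order: int = 5
    shrinkage: float | str = "auto"
    grid_size: int = 16
    n_nulls: int = 25
    sigma_margin: float = 0.15
    alpha: float = 0.05
    planted: dict = field(default_factory=dict)   # PlantedGraphParams overrides
    out_dir: str | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def planted_params(self) -> PlantedGraphParams:
        overrides = dict(self.planted)
        if "rewiring_prob" in overrides:
            overrides["rewiring_prob"] = {
                (k.split("/")[0], k.split("/")[1]): v
                for k, v in overrides["rewiring_prob"].items()
            }
        return PlantedGraphParams(**overrides)


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    names = ("simulate", "network", "stats")
    return {n: int(s.generate_state(1)[0] % (2**31))
            for n, s in zip(names, ss.spawn(len(names)))}


def connectivity_matrices(
    cohort: SyntheticCohort, config: PipelineConfig
) -> dict[tuple[str, str], np.ndarray]:
    """Preprocess every subject and build Fisher-z partial-correlation matrices."""
    zs: dict[tuple[str, str], np.ndarray] = {}
    for subj in cohort.subjects["subject"]:
        series = preprocess_subject(
            cohort.timecourses[subj], cohort.schedule,
            low_factor=config.low_factor, high_factor=config.high_factor,
            order=config.filter_order,
        )
        zs.update(connectivity_for_subject(series, subj, shrinkage=config.shrinkage))
    return zs


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SyntheticCohort
    z_matrices: dict[tuple[str, str], np.ndarray]
    grid: DegreeGrid
    regime_check: pd.DataFrame
    metric_table: pd.DataFrame
    stats: StatReport
    summary: dict


def run_pipeline(
    config: PipelineConfig,
    cohort: SyntheticCohort | None = None,
    verify: bool = True,
) -> PipelineResult:
    """Execute every stage and assemble the summary report.

    A pre-built cohort (e.g. loaded from disk) can be passed in place of
    the simulation stage.
    """
    seeds = stage_seeds(config.seed)
    if cohort is None:
        log.info("simulating cohort (n=%d per group)", config.n_per_group)
        cohort = generate_cohort(
            n_per_group=config.n_per_group,
            params=config.planted_params(),
            seed=seeds["simulate"],
            n_runs=config.n_runs,
            tr_seconds=config.tr_seconds,
        )
    log.info("preprocessing and connectivity")
    zs = connectivity_matrices(cohort, config)
    log.info("small-world regime search over %d networks", len(zs))
    grid = find_small_world_regime(
        list(zs.values()), grid_size=config.grid_size,
        n_nulls=config.n_nulls, seed=seeds["network"],
        sigma_margin=config.sigma_margin,
    )
    regime_check = pd.DataFrame()
    if verify:
        regime_check = verify_regime(zs, grid, seed=seeds["network"] + 1)
    table = compute_metric_table(zs, grid, cohort.subject_info)
    report = run_statistics(
        table, behavior=cohort.behavior, motion=cohort.motion,
        subject_info=cohort.subject_info, alpha=config.alpha,
    )
    summary = summarize(config, grid, regime_check, report)
    result = PipelineResult(
        config=config, cohort=cohort, z_matrices=zs, grid=grid,
        regime_check=regime_check, metric_table=table,
        stats=report, summary=summary,
    )
    if config.out_dir:
        write_outputs(result, Path(config.out_dir))
    return result


def summarize(
    config: PipelineConfig,
    grid: DegreeGrid,
    regime_check: pd.DataFrame,
    report: StatReport,
) -> dict:
    """Compact JSON-ready digest: regime bounds, headline statistics."""
    alpha = config.alpha
    interactions = {
        r["measure"]: r["p"]
        for _, r in report.anova.iterrows() if r["term"] == "group:load"
    }
    load_sig = {}
    for meas in ("C_net", "L_net", "E_local", "E_global"):
        for load in ("L1", "L3", "L5"):
            gt = report.group_tests[f"{meas}@{load}"]
            load_sig[f"{meas}@{load}"] = int((gt["p_fdr"] < alpha).sum())
    c3 = {k: v for k, v in load_sig.items() if k.startswith("C_net")}
    flagged = max(c3, key=c3.get).split("@")[1] if c3 else None
    out = {
        "regime": {"k_min": grid.k_min, "k_max": grid.k_max,
                   "increment": grid.increment, "degrees": grid.degrees},
        "interaction_p": interactions,
        "fdr_significant_observations": load_sig,
        "load_with_most_C_net_differences": flagged,
    }
    if len(regime_check):
        out["regime_check"] = {
            "all_connected": bool(regime_check["connected"].all()),
            "min_sigma": float(regime_check["sigma"].min()),
            "n_networks_x_degrees": int(len(regime_check)),
        }
    return out


def write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_json(out / "config.json")
    result.metric_table.to_csv(out / "metrics.tsv", sep="\t", index=False)
    if len(result.regime_check):
        result.regime_check.assign(
            network=result.regime_check["network"].astype(str)
        ).to_csv(out / "regime_check.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1))
    (out / "stats.json").write_text(json.dumps(result.stats.to_dict(), indent=1))
    zdir = out / "connectivity"
    zdir.mkdir(exist_ok=True)
    for (subj, load), z in result.z_matrices.items():
        np.savetxt(zdir / f"{subj}_{load}_z.tsv", z, delimiter="\t", fmt="%.6g")


# --------------------------------------------------------------------------
# input validation
# --------------------------------------------------------------------------

def validate_inputs(path: str | Path) -> dict:
    """Check a cohort directory for format and consistency problems.

    Verifies the schedule parses and fits its runs, every subject's series
    matches the schedule's frame count and node count, and the behavior
    table covers every subject x load.  Returns {"ok": bool, "errors": [...]}.
    """
    path = Path(path)
    errors: list[str] = []
    try:
        from .design import DesignSchedule
        schedule = DesignSchedule.from_json(path / "schedule.json")
        schedule.validate()
    except Exception as e:  # noqa: BLE001 - collect everything for the report
        return {"ok": False, "errors": [f"schedule.json: {e}"]}
    try:
        subjects = pd.read_csv(path / "subjects.csv")
    except Exception as e:
        return {"ok": False, "errors": [f"subjects.csv: {e}"]}

    n_trs = schedule.n_trs_per_run
    n_nodes = None
    for subj in subjects["subject"]:
        files = sorted((path / "timecourses").glob(f"{subj}_run*.tsv"))
        if len(files) != schedule.n_runs:
            errors.append(
                f"{subj}: {len(files)} run files, schedule has {schedule.n_runs} runs"
            )
        for f in files:
            x = np.loadtxt(f, delimiter="\t", skiprows=1)
            if x.shape[1] != n_trs:
                errors.append(
                    f"{f.name}: {x.shape[1]} frames, schedule needs {n_trs}"
                )
            if n_nodes is None:
                n_nodes = x.shape[0]
            elif x.shape[0] != n_nodes:
                errors.append(
                    f"{f.name}: {x.shape[0]} nodes, expected {n_nodes}"
                )
    beh_path = path / "behavior.csv"
    if beh_path.exists():
        beh = pd.read_csv(beh_path)
        for subj in subjects["subject"]:
            got = set(beh[beh["subject"] == subj]["load"])
            missing = {"L1", "L3", "L5"} - got
            if missing:
                errors.append(f"behavior.csv: {subj} missing loads {sorted(missing)}")
    else:
        errors.append("behavior.csv: file not found")
    return {"ok": not errors, "errors": errors}
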