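"""Synthetic block-design working-memory cohorts with planted network truth.

The generator emulates the structure of a two-site Sternberg-paradigm fMRI
study: 105 network nodes, TR = 2 s, three 6-minute runs of six blocks (two
per load level L1/L3/L5), 35 healthy controls (HC) and 35 patients (SZ).
Each subject x load cell carries a planted Watts-Strogatz-style graph whose
rewiring probability is set per (group, load); the patient group's medium
load is rewired more heavily, planting exactly the deficit pattern the
pipeline is meant to detect (lower clustering and local efficiency at L3,
a V-shaped load trajectory in patients, a flat one in controls).

The graph is turned into a Gaussian graphical model: a precision matrix
with -coupling on edges, so that the *partial* correlations of the
simulated series recover the planted edges.  Block spans of the BOLD-like
series are drawn from the load's covariance plus a task-locked activation
and slow drift; fixation spans are unit-variance noise.  Behavior (accuracy
and correct-trial reaction time) is anchored to published SIRP group means
and negatively coupled to each subject's planted clustering.  Motion traces
are smooth random walks, scaled per group, independent of network truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .design import DesignSchedule, LOADS, make_design_schedule
from .graph import clustering_coefficients

GROUPS = ("HC", "SZ")
SITES = ("siteA", "siteB")

#: Group-mean reaction times (ms) and accuracies per load used as behavior
#: anchors; patients are slower and less accurate, both groups slow with load.
RT_ANCHOR_MS = {
    "HC": {"L1": 550.0, "L3": 636.0, "L5": 691.0},
    "SZ": {"L1": 594.0, "L3": 702.0, "L5": 764.0},
}
ACC_ANCHOR = {
    "HC": {"L1": 0.992, "L3": 0.984, "L5": 0.973},
    "SZ": {"L1": 0.967, "L3": 0.955, "L5": 0.954},
}


@dataclass
class PlantedGraphParams:
    """Ground-truth network parameters for one cohort."""

    n_nodes: int = 105
    target_degree: int = 4
    #: per (group, load) Watts-Strogatz rewiring probability; higher value
    #: => lower planted clustering.  Default plants a patient deficit at the
    #: medium load only.
    rewiring_prob: dict = field(default_factory=lambda: {
        ("HC", "L1"): 0.05, ("HC", "L3"): 0.05, ("HC", "L5"): 0.05,
        ("SZ", "L1"): 0.05, ("SZ", "L3"): 0.22, ("SZ", "L5"): 0.05,
    })
    coupling_strength: float = 4.0
    diag_margin: float = 1.0
    noise_sd: float = 0.15
    drift_amplitude: float = 0.15
    activation_amplitude: float = 0.3
    rt_slope_ms: float = 350.0
    rt_noise_sd_ms: float = 55.0
    acc_noise_sd: float = 0.012
    motion_step_mm: dict = field(default_factory=lambda: {"HC": 0.02, "SZ": 0.035})
    motion_step_rad: dict = field(default_factory=lambda: {"HC": 2e-4, "SZ": 3.5e-4})

    def validate(self) -> None:
        if self.target_degree % 2 != 0:
            raise ValueError("target_degree must be even (ring-lattice base)")
        if not (0 < self.target_degree < self.n_nodes):
            raise ValueError("target_degree must be in (0, n_nodes)")
        for cell, p in self.rewiring_prob.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"rewiring_prob{cell} outside [0, 1]")
        if self.coupling_strength <= 0:
            raise ValueError("coupling_strength must be positive")


def sample_planted_graph(
    params: PlantedGraphParams,
    group: str,
    load: str,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 100,
) -> np.ndarray:
    """Connected Watts-Strogatz-style graph as a uint8 adjacency matrix.

    Starts from a ring lattice with ``target_degree`` neighbours and rewires
    each edge with the cell's probability; disconnected draws are resampled
    (bounded retries).  Expected clustering decreases monotonically with the
    rewiring probability, which is how group x load effects are planted.
    """
    params.validate()
    p = params.rewiring_prob[(group, load)]
    rng = np.random.default_rng(seed)
    nx_seed = int(rng.integers(0, 2**31 - 1))
    g = nx.connected_watts_strogatz_graph(
        params.n_nodes, params.target_degree, p, tries=max_tries, seed=nx_seed
    )
    adj = nx.to_numpy_array(g, dtype=np.uint8, nodelist=range(params.n_nodes))
    return adj


def graph_to_covariance(
    adj: np.ndarray,
    coupling_strength: float,
    diag_margin: float = 1.0,
    standardize: bool = True,
) -> np.ndarray:
    """Covariance whose partial correlations reproduce the graph.

    Builds the precision matrix P with P_ij = -coupling on edges, 0
    elsewhere, and P_ii = 1 + K_i * coupling * diag_margin (strictly
    diagonally dominant, hence positive definite for margin >= 1), and
    returns its inverse.  Non-edges have exactly zero partial correlation.
    By default the result is rescaled to unit diagonal (a correlation
    matrix) so simulated block signal has the same per-node variance as
    fixation noise; diagonal scaling leaves partial correlations unchanged.
    """
    adj = np.asarray(adj)
    n = adj.shape[0]
    deg = adj.sum(axis=1).astype(float)
    prec = -coupling_strength * adj.astype(float)
    np.fill_diagonal(prec, 1.0 + deg * coupling_strength * diag_margin)
    eigmin = float(np.linalg.eigvalsh(prec)[0])
    if eigmin <= 0:
        raise ValueError(
            f"precision matrix not positive definite (min eigenvalue {eigmin:.3g}); "
            "reduce coupling_strength or raise diag_margin"
        )
    cov = np.linalg.inv(prec)
    cov = 0.5 * (cov + cov.T)
    if standardize:
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
    return cov


def _hrf_kernel(tr_seconds: float, duration_s: float = 30.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at the TR."""
    from scipy.stats import gamma as gamma_dist
    t = np.arange(0, duration_s, tr_seconds)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    s = h.sum()
    return h / s if s > 0 else h


def simulate_subject_timecourses(
    schedule: DesignSchedule,
    covariance_by_load: dict[str, np.ndarray],
    activation_amplitude: float = 0.4,
    noise_sd: float = 0.3,
    drift_amplitude: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> list[np.ndarray]:
    """One node x time matrix per run.

    Within each block's encode+probe span the signal is drawn from the
    load's covariance (Cholesky sampling); fixation and prompt frames are
    unit-variance white noise.  A task-locked boxcar convolved with a
    canonical haemodynamic response is added to every node, plus a slow
    random-phase sinusoidal drift per node and white measurement noise.
    """
    rng = np.random.default_rng(seed)
    loads_present = {b.load for run in schedule.runs for b in run}
    for load in loads_present:
        if load not in covariance_by_load:
            raise ValueError(f"no covariance supplied for load {load}")
    n = next(iter(covariance_by_load.values())).shape[0]
    chol = {}
    for load, cov in covariance_by_load.items():
        cov = np.asarray(cov, dtype=float)
        if cov.shape != (n, n):
            raise ValueError(
                f"covariance for load {load} has shape {cov.shape}, expected {(n, n)}"
            )
        chol[load] = np.linalg.cholesky(cov)

    tr = schedule.tr_seconds
    n_trs = schedule.n_trs_per_run
    hrf = _hrf_kernel(tr)
    runs_out = []
    for run in schedule.runs:
        x = rng.standard_normal((n, n_trs))  # fixation / prompt baseline
        boxcar = np.zeros(n_trs)
        for blk in run:
            i0 = int(round(blk.encode_onset / tr))
            i1 = int(round(blk.end / tr))
            i1 = min(i1, n_trs)
            x[:, i0:i1] = chol[blk.load] @ rng.standard_normal((n, i1 - i0))
            boxcar[i0:i1] = 1.0
        if activation_amplitude:
            act = np.convolve(boxcar, hrf)[:n_trs]
            x += activation_amplitude * act[None, :]
        if drift_amplitude:
            t = np.arange(n_trs) * tr
            periods = rng.uniform(120.0, 360.0, size=n)
            phases = rng.uniform(0, 2 * np.pi, size=n)
            x += drift_amplitude * np.sin(
                2 * np.pi * t[None, :] / periods[:, None] + phases[:, None]
            )
        if noise_sd:
            x += noise_sd * rng.standard_normal((n, n_trs))
        runs_out.append(x)
    return runs_out


def simulate_behavior(
    planted_clustering: float,
    group: str,
    load: str,
    cell_mean_clustering: float,
    params: PlantedGraphParams,
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Accuracy and mean correct-trial RT for one subject x load.

    RT = anchor(group, load) + slope * (cell mean clustering - subject's
    planted clustering) + noise, so that within a cell RT correlates
    negatively with planted clustering while cell means track the anchors
    (RT increases with load in both groups).  Accuracy is anchored likewise
    and clipped to [0.9, 1.0].
    """
    rng = np.random.default_rng(seed)
    rt = (
        RT_ANCHOR_MS[group][load]
        + params.rt_slope_ms * (cell_mean_clustering - planted_clustering)
        + rng.normal(0.0, params.rt_noise_sd_ms)
    )
    acc = ACC_ANCHOR[group][load] + rng.normal(0.0, params.acc_noise_sd)
    return {"accuracy": float(np.clip(acc, 0.9, 1.0)), "rt_ms": float(rt)}


def simulate_motion(
    n_frames: int,
    group: str,
    params: PlantedGraphParams,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Smooth rigid-body trace: 3 translations (mm) + 3 rotations (rad)."""
    rng = np.random.default_rng(seed)
    t_step = params.motion_step_mm[group]
    r_step = params.motion_step_rad[group]
    steps = np.concatenate([
        rng.normal(0, t_step, size=(n_frames, 3)),
        rng.normal(0, r_step, size=(n_frames, 3)),
    ], axis=1)
    trace = np.cumsum(steps, axis=0)
    trace[0] = 0.0
    return trace


@dataclass
class SyntheticCohort:
    """Complete simulated study with its ground-truth channel."""

    params: PlantedGraphParams
    schedule: DesignSchedule
    subjects: pd.DataFrame                    # subject, group, site
    timecourses: dict[str, list[np.ndarray]]  # subject -> per-run node x time
    behavior: pd.DataFrame                    # subject, group, load, accuracy, rt_ms
    motion: dict[str, list[np.ndarray]]       # subject -> per-run frames x 6
    truth_graphs: dict[tuple[str, str], np.ndarray]   # (subject, load) -> adjacency
    truth: pd.DataFrame                       # subject, group, load, clustering, rewiring_prob
    seed: int | None = None

    @property
    def subject_info(self) -> dict[str, dict]:
        return {
            r.subject: {"group": r.group, "site": r.site}
            for r in self.subjects.itertuples()
        }

    # ---- on-disk layout ---------------------------------------------------

    def to_dir(self, out: str | Path) -> None:
        """Write the cohort as plain-text artifacts (TSV/CSV/JSON)."""
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        self.schedule.to_json(out / "schedule.json")
        self.subjects.to_csv(out / "subjects.csv", index=False)
        self.behavior.to_csv(out / "behavior.csv", index=False)
        ts_dir = out / "timecourses"
        ts_dir.mkdir(exist_ok=True)
        info = self.subject_info
        for subj, runs in self.timecourses.items():
            for r, x in enumerate(runs):
                base = ts_dir / f"{subj}_run{r + 1}"
                _write_matrix_tsv(base.with_suffix(".tsv"), x)
                side = {"subject": subj, "run": r + 1, **info[subj],
                        "tr_seconds": self.schedule.tr_seconds}
                base.with_suffix(".json").write_text(json.dumps(side, indent=1))
        mo_dir = out / "motion"
        mo_dir.mkdir(exist_ok=True)
        for subj, runs in self.motion.items():
            for r, tr_ in enumerate(runs):
                df = pd.DataFrame(
                    tr_, columns=["tx", "ty", "tz", "rx", "ry", "rz"]
                )
                df.insert(0, "frame", np.arange(len(df)))
                df.to_csv(mo_dir / f"{subj}_run{r + 1}.csv", index=False)
        truth_dir = out / "truth"
        truth_dir.mkdir(exist_ok=True)
        self.truth.to_csv(truth_dir / "planted.csv", index=False)
        for (subj, load), adj in self.truth_graphs.items():
            np.savetxt(truth_dir / f"{subj}_{load}_adj.tsv", adj, fmt="%d",
                       delimiter="\t")

    @classmethod
    def from_dir(cls, path: str | Path) -> "SyntheticCohort":
        path = Path(path)
        schedule = DesignSchedule.from_json(path / "schedule.json")
        subjects = pd.read_csv(path / "subjects.csv")
        behavior = pd.read_csv(path / "behavior.csv")
        timecourses: dict[str, list[np.ndarray]] = {}
        for subj in subjects["subject"]:
            runs = sorted((path / "timecourses").glob(f"{subj}_run*.tsv"))
            timecourses[subj] = [_read_matrix_tsv(p) for p in runs]
        motion: dict[str, list[np.ndarray]] = {}
        for subj in subjects["subject"]:
            runs = sorted((path / "motion").glob(f"{subj}_run*.csv"))
            motion[subj] = [
                pd.read_csv(p).drop(columns="frame").to_numpy() for p in runs
            ]
        truth = pd.read_csv(path / "truth" / "planted.csv")
        truth_graphs = {}
        for p in (path / "truth").glob("*_adj.tsv"):
            subj, load, _ = p.stem.rsplit("_", 2)
            truth_graphs[(subj, load)] = np.loadtxt(p, dtype=np.uint8)
        return cls(
            params=PlantedGraphParams(), schedule=schedule, subjects=subjects,
            timecourses=timecourses, behavior=behavior, motion=motion,
            truth_graphs=truth_graphs, truth=truth,
        )


def _write_matrix_tsv(path: Path, x: np.ndarray) -> None:
    """Node x TR matrix, tab-separated, header row of TR indices."""
    header = "\t".join(str(i) for i in range(x.shape[1]))
    np.savetxt(path, x, delimiter="\t", header=header, comments="", fmt="%.17g")


def _read_matrix_tsv(path: Path) -> np.ndarray:
    return np.loadtxt(path, delimiter="\t", skiprows=1)


def generate_cohort(
    n_per_group: int = 35,
    params: PlantedGraphParams | None = None,
    seed: int | None = 0,
    n_runs: int = 3,
    tr_seconds: float = 2.0,
    loads: tuple[str, ...] = LOADS,
) -> SyntheticCohort:
    """Simulate a full two-group, two-site cohort with ground truth.

    Every quantity is a pure function of (params, seed): the seed fans out
    through a SeedSequence tree, one branch per subject and stage.  Sites
    alternate within each group so groups are balanced across sites.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    params = params or PlantedGraphParams()
    params.validate()
    root = np.random.SeedSequence(seed)
    sched_seed, subj_root = root.spawn(2)
    schedule = make_design_schedule(
        tr_seconds=tr_seconds, n_runs=n_runs,
        seed=int(sched_seed.generate_state(1)[0] % (2**31)), loads=loads,
    )

    subjects = []
    for g in GROUPS:
        for i in range(n_per_group):
            subjects.append({
                "subject": f"{g}{i + 1:03d}",
                "group": g,
                "site": SITES[i % 2],
            })
    subjects_df = pd.DataFrame(subjects)

    timecourses: dict[str, list[np.ndarray]] = {}
    motion: dict[str, list[np.ndarray]] = {}
    truth_graphs: dict[tuple[str, str], np.ndarray] = {}
    truth_rows = []
    subj_seqs = subj_root.spawn(len(subjects))
    for rec, seq in zip(subjects, subj_seqs):
        subj, group = rec["subject"], rec["group"]
        g_seq, ts_seq, mo_seq = seq.spawn(3)
        cov_by_load = {}
        for load, gseed in zip(loads, g_seq.spawn(len(loads))):
            adj = sample_planted_graph(
                params, group, load, seed=np.random.default_rng(gseed)
            )
            truth_graphs[(subj, load)] = adj
            _, c_net = clustering_coefficients(adj)
            truth_rows.append({
                "subject": subj, "group": group, "load": load,
                "clustering": c_net,
                "rewiring_prob": params.rewiring_prob[(group, load)],
            })
            cov_by_load[load] = graph_to_covariance(
                adj, params.coupling_strength, params.diag_margin
            )
        timecourses[subj] = simulate_subject_timecourses(
            schedule, cov_by_load,
            activation_amplitude=params.activation_amplitude,
            noise_sd=params.noise_sd,
            drift_amplitude=params.drift_amplitude,
            seed=np.random.default_rng(ts_seq),
        )
        mo_rng = np.random.default_rng(mo_seq)
        motion[subj] = [
            simulate_motion(schedule.n_trs_per_run, group, params, seed=mo_rng)
            for _ in range(n_runs)
        ]
    truth_df = pd.DataFrame(truth_rows)

    # behavior: RT negatively coupled to planted clustering within each cell
    cell_means = truth_df.groupby(["group", "load"])["clustering"].mean()
    beh_rows = []
    beh_root, = root.spawn(1)
    beh_seqs = iter(beh_root.spawn(len(truth_rows)))
    for row in truth_rows:
        b = simulate_behavior(
            row["clustering"], row["group"], row["load"],
            float(cell_means[(row["group"], row["load"])]),
            params, seed=np.random.default_rng(next(beh_seqs)),
        )
        beh_rows.append({"subject": row["subject"], "group": row["group"],
                         "load": row["load"], **b})
    behavior_df = pd.DataFrame(beh_rows)

    return SyntheticCohort(
        params=params, schedule=schedule, subjects=subjects_df,
        timecourses=timecourses, behavior=behavior_df, motion=motion,
        truth_graphs=truth_graphs, truth=truth_df, seed=seed,
    )
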