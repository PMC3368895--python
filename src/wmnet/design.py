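"""Block-design schedules for the Sternberg item-recognition paradigm (SIRP).

A run is a sequence of working-memory blocks, each consisting of a 2 s
"Learn" prompt, a 6 s encode epoch (the memory set of 1, 3 or 5 digits) and
a 38 s probe epoch (14 single-digit probes), separated by fixation gaps.
Each run holds two blocks per load level in pseudo-random order and lasts
six minutes by default.  All onsets live on the TR grid so that epochs map
to whole scan frames.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

LOADS = ("L1", "L3", "L5")

PROMPT_DUR_S = 2.0
ENCODE_DUR_S = 6.0
PROBE_DUR_S = 38.0
N_PROBES = 14
RUN_DURATION_S = 360.0


@dataclass(frozen=True)
class Block:
    """One prompt→encode→probe working-memory block."""

    load: str
    prompt_onset: float
    prompt_dur: float = PROMPT_DUR_S
    encode_dur: float = ENCODE_DUR_S
    probe_dur: float = PROBE_DUR_S
    n_probes: int = N_PROBES

    @property
    def encode_onset(self) -> float:
        return self.prompt_onset + self.prompt_dur

    @property
    def probe_onset(self) -> float:
        return self.encode_onset + self.encode_dur

    @property
    def end(self) -> float:
        return self.probe_onset + self.probe_dur

    @property
    def duration(self) -> float:
        return self.prompt_dur + self.encode_dur + self.probe_dur


@dataclass
class DesignSchedule:
    """Per-run block timing on a TR grid."""

    tr_seconds: float
    runs: list[list[Block]] = field(default_factory=list)
    run_duration_s: float = RUN_DURATION_S

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_trs_per_run(self) -> int:
        return int(round(self.run_duration_s / self.tr_seconds))

    def blocks_by_load(self) -> dict[str, list[tuple[int, Block]]]:
        """Blocks grouped by load, each tagged with its run index,
        ordered by (run, onset)."""
        out: dict[str, list[tuple[int, Block]]] = {}
        for r, run in enumerate(self.runs):
            for blk in sorted(run, key=lambda b: b.prompt_onset):
                out.setdefault(blk.load, []).append((r, blk))
        return out

    def validate(self) -> None:
        tr = self.tr_seconds
        if tr <= 0:
            raise ValueError("tr_seconds must be positive")
        for r, run in enumerate(self.runs):
            prev_end = -1.0
            for blk in sorted(run, key=lambda b: b.prompt_onset):
                for name, t in (
                    ("prompt_onset", blk.prompt_onset),
                    ("prompt_dur", blk.prompt_dur),
                    ("encode_dur", blk.encode_dur),
                    ("probe_dur", blk.probe_dur),
                ):
                    if abs(t / tr - round(t / tr)) > 1e-9:
                        raise ValueError(
                            f"run {r}: {name}={t} s is not a multiple of TR={tr} s"
                        )
                if blk.prompt_onset < prev_end - 1e-9:
                    raise ValueError(f"run {r}: overlapping blocks")
                if blk.end > self.run_duration_s + 1e-9:
                    raise ValueError(f"run {r}: block ends past run duration")
                prev_end = blk.end

    # ---- JSON round trip --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "tr_seconds": self.tr_seconds,
            "run_duration_s": self.run_duration_s,
            "runs": [{"blocks": [asdict(b) for b in run]} for run in self.runs],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "DesignSchedule":
        runs = [[Block(**b) for b in run["blocks"]] for run in d["runs"]]
        return cls(
            tr_seconds=d["tr_seconds"],
            runs=runs,
            run_duration_s=d.get("run_duration_s", RUN_DURATION_S),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignSchedule":
        return cls.from_dict(json.loads(Path(path).read_text()))


def make_design_schedule(
    tr_seconds: float = 2.0,
    n_runs: int = 3,
    blocks_per_load_per_run: int = 2,
    gap_policy: str = "even",
    seed: int | None = 0,
    run_duration_s: float = RUN_DURATION_S,
    loads: tuple[str, ...] = LOADS,
) -> DesignSchedule:
    """Build a seeded SIRP-style schedule.

    Block order within each run is a seeded permutation of the load labels
    (``blocks_per_load_per_run`` copies of each).  Fixation time left over
    after the blocks is split as evenly as possible (in whole TRs) across
    the ``n_blocks + 1`` gaps; ``gap_policy="none"`` packs blocks
    back-to-back and shrinks the run accordingly.
    """
    rng = np.random.default_rng(seed)
    for name, dur in (
        ("prompt_dur", PROMPT_DUR_S),
        ("encode_dur", ENCODE_DUR_S),
        ("probe_dur", PROBE_DUR_S),
    ):
        if abs(dur / tr_seconds - round(dur / tr_seconds)) > 1e-9:
            raise ValueError(
                f"{name}={dur} s is not divisible by TR={tr_seconds} s"
            )
    block_dur = PROMPT_DUR_S + ENCODE_DUR_S + PROBE_DUR_S
    n_blocks = blocks_per_load_per_run * len(loads)

    if gap_policy == "none":
        run_duration_s = block_dur * n_blocks
        gap_trs = [0] * (n_blocks + 1)
    elif gap_policy == "even":
        gap_total = run_duration_s - block_dur * n_blocks
        if gap_total < -1e-9:
            raise ValueError(
                f"run_duration_s={run_duration_s} too short for {n_blocks} blocks"
            )
        total_gap_trs = int(round(gap_total / tr_seconds))
        n_gaps = n_blocks + 1
        base, extra = divmod(total_gap_trs, n_gaps)
        gap_trs = [base + (1 if i < extra else 0) for i in range(n_gaps)]
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")

    runs: list[list[Block]] = []
    for _ in range(n_runs):
        labels = list(loads) * blocks_per_load_per_run
        rng.shuffle(labels)
        t = gap_trs[0] * tr_seconds
        blocks = []
        for i, lab in enumerate(labels):
            blocks.append(Block(load=lab, prompt_onset=t))
            t += block_dur + gap_trs[i + 1] * tr_seconds
        runs.append(blocks)

    sched = DesignSchedule(
        tr_seconds=tr_seconds, runs=runs, run_duration_s=run_duration_s
    )
    sched.validate()
    return sched
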