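"""Node time-series preprocessing: averaging, band-pass, load-wise epochs.

The pipeline filters whole runs first, then cuts each run into its
working-memory blocks (dropping the 2 s "Learn" prompt, keeping the
encode+probe span) and concatenates, per subject, all blocks of the same
load across runs.  With the default design (3 runs x 2 blocks/load, 44 s
of encode+probe at TR = 2 s) each load yields 6 x 22 = 132 frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .design import Block, DesignSchedule


def average_voxel_blocks(
    voxel_matrix: np.ndarray,
    block_assignment: dict[int, list[int]] | np.ndarray,
) -> np.ndarray:
    """Average voxel rows into node (spatial-block) time courses.

    ``block_assignment`` is either a mapping node -> voxel row indices or a
    per-voxel label vector (label < 0 = unassigned).  Each node's series is
    the unweighted mean of its voxels'.
    """
    voxel_matrix = np.asarray(voxel_matrix, dtype=float)
    if isinstance(block_assignment, dict):
        items = sorted(block_assignment.items())
    else:
        labels = np.asarray(block_assignment)
        items = [(int(b), list(np.nonzero(labels == b)[0]))
                 for b in np.unique(labels) if b >= 0]
    seen: set[int] = set()
    rows = []
    for node, vox in items:
        if not len(vox):
            raise ValueError(f"spatial block {node} has no voxels assigned")
        if seen & set(vox):
            raise ValueError(f"voxel assigned to more than one block (block {node})")
        seen |= set(vox)
        rows.append(voxel_matrix[list(vox)].mean(axis=0))
    return np.asarray(rows)


def filter_passband(
    tr_seconds: float, low_factor: float = 0.01, high_factor: float = 0.9
) -> tuple[float, float]:
    """Band edges in Hz: factors applied to the Nyquist frequency 1/(2 TR)."""
    nyquist = 1.0 / (2.0 * tr_seconds)
    return low_factor * nyquist, high_factor * nyquist


def bandpass_filter(
    series: np.ndarray,
    tr_seconds: float,
    low_factor: float = 0.01,
    high_factor: float = 0.9,
    order: int = 5,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis.

    Cutoffs are ``[low_factor, high_factor] * Nyquist`` (0.0025-0.225 Hz at
    TR = 2 s), which removes drift and scanner noise while keeping the
    6 s-encode (0.167 Hz) and 38 s-probe (0.026 Hz) task frequencies.
    Applied forward-backward so task-locked structure is not delayed.
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    if not (0 < low_factor < high_factor < 1):
        raise ValueError(
            f"cutoff factors ({low_factor}, {high_factor}) must satisfy "
            "0 < low < high < 1 (fractions of Nyquist)"
        )
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if series.shape[-1] <= 3 * order:
        raise ValueError(
            f"series length {series.shape[-1]} too short for filter order {order}"
        )
    b, a = butter(order, [low_factor, high_factor], btype="bandpass")
    return filtfilt(b, a, series, axis=-1)


@dataclass
class BlockSegment:
    """Encode+probe frames of one block with full provenance."""

    data: np.ndarray          # nodes x frames
    load: str
    run: int
    block_index: int          # onset order within the run
    tr_span: tuple[int, int]  # [start, stop) frame indices within the run


@dataclass
class LoadSeries:
    """All same-load blocks of one subject, concatenated in (run, onset) order."""

    load: str
    data: np.ndarray
    provenance: list[BlockSegment] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.data.shape[1]


def extract_blocks(
    series: np.ndarray,
    schedule: DesignSchedule,
    run: int,
) -> list[BlockSegment]:
    """Cut one run into its blocks, keeping encode+probe and dropping the prompt."""
    series = np.asarray(series)
    tr = schedule.tr_seconds
    segments = []
    blocks = sorted(schedule.runs[run], key=lambda b: b.prompt_onset)
    for idx, blk in enumerate(blocks):
        i0 = int(round(blk.encode_onset / tr))
        i1 = int(round(blk.end / tr))
        if i1 > series.shape[1]:
            raise ValueError(
                f"run {run} block {idx} ({blk.load}) extends past the series "
                f"end ({i1} > {series.shape[1]} frames)"
            )
        segments.append(BlockSegment(
            data=series[:, i0:i1], load=blk.load, run=run,
            block_index=idx, tr_span=(i0, i1),
        ))
    return segments


def concat_by_load(
    segments: list[BlockSegment], strict: bool = False
) -> dict[str, LoadSeries]:
    """Concatenate block segments per load in canonical (run, onset) order."""
    import warnings

    by_load: dict[str, list[BlockSegment]] = {}
    for seg in segments:
        by_load.setdefault(seg.load, []).append(seg)
    counts = {load: len(v) for load, v in by_load.items()}
    if len(set(counts.values())) > 1:
        msg = f"unequal block counts across loads: {counts}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    out = {}
    for load, segs in by_load.items():
        segs = sorted(segs, key=lambda s: (s.run, s.tr_span[0]))
        out[load] = LoadSeries(
            load=load,
            data=np.concatenate([s.data for s in segs], axis=1),
            provenance=segs,
        )
    return out


def preprocess_subject(
    runs: list[np.ndarray],
    schedule: DesignSchedule,
    low_factor: float = 0.01,
    high_factor: float = 0.9,
    order: int = 5,
    apply_filter: bool = True,
) -> dict[str, LoadSeries]:
    """Filter each run, extract blocks, and group them by load."""
    if len(runs) != schedule.n_runs:
        raise ValueError(
            f"{len(runs)} run matrices for a {schedule.n_runs}-run schedule"
        )
    segments: list[BlockSegment] = []
    for r, x in enumerate(runs):
        if apply_filter:
            x = bandpass_filter(
                x, schedule.tr_seconds, low_factor, high_factor, order
            )
        segments.extend(extract_blocks(x, schedule, r))
    return concat_by_load(segments)
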