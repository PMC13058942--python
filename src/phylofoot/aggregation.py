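"""Projection of per-run motifs onto the target and peak calling.

Each pipeline run votes at most once per target position: a run's combined
motifs are projected onto the target promoter (kept only when anchored on
the target and simultaneously present in enough orthologs — the
footprinting requirement), their covered positions are OR-ed within the
run, and runs are summed into a positional support histogram. Peaks are
maximal above-threshold segments after gap merging, so the histogram reads
directly as "fraction of runs supporting a motif here".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifdiscovery import Motif


@dataclass
class PositionHistogram:
    """Per-position count of runs supporting a motif at that position."""

    target_id: str
    length: int
    counts: np.ndarray  # int vector of length `length`
    n_runs: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (self.length,):
            raise ValueError("counts length mismatch")
        if self.counts.min(initial=0) < 0 or self.counts.max(initial=0) > self.n_runs:
            raise ValueError("counts must lie in [0, n_runs]")


@dataclass
class Peak:
    peak_id: int  # 1-based, numbered left to right
    start: int
    end: int  # 0-based half-open on the target
    height: int
    support_frac: float

    @property
    def width(self) -> int:
        return self.end - self.start


def project_run(
    run_motifs: Sequence[Motif],
    target_id: str,
    min_ortholog_support: int = 6,
) -> list[tuple[int, int]]:
    """Target intervals of motifs passing the footprinting requirement.

    A motif contributes only when it has an instance on the target promoter
    and instances on at least ``min_ortholog_support`` distinct non-target
    promoters; the default (half a 12-promoter subset) operationalizes
    "simultaneously detected in orthologous promoters".
    """
    intervals: list[tuple[int, int]] = []
    for motif in run_motifs:
        target_instances = [i for i in motif.instances if i.promoter_id == target_id]
        orthologs = {i.promoter_id for i in motif.instances} - {target_id}
        if target_instances and len(orthologs) >= min_ortholog_support:
            for inst in target_instances:
                intervals.append((inst.start, inst.start + motif.width))
    return intervals


def accumulate_histogram(
    per_run_intervals: Sequence[Sequence[tuple[int, int]]],
    target_id: str,
    target_length: int,
    n_runs: int | None = None,
) -> PositionHistogram:
    """Sum per-run 0/1 coverage into the positional support histogram.

    A run contributes at most 1 per position regardless of how many of its
    motifs cover it.
    """
    n_runs = len(per_run_intervals) if n_runs is None else n_runs
    counts = np.zeros(target_length, dtype=int)
    for intervals in per_run_intervals:
        covered = np.zeros(target_length, dtype=bool)
        for start, end in intervals:
            if start < 0 or end > target_length or start >= end:
                raise ValueError(
                    f"interval [{start}, {end}) outside target [0, {target_length})"
                )
            covered[start:end] = True
        counts += covered
    return PositionHistogram(
        target_id=target_id, length=target_length, counts=counts, n_runs=n_runs
    )


def call_peaks(
    hist: PositionHistogram,
    min_support_frac: float = 0.25,
    min_width: int = 6,
    merge_gap: int = 5,
) -> list[Peak]:
    """Threshold the histogram into peaks.

    Positions with count >= ceil(min_support_frac * n_runs) form candidate
    segments; segments separated by fewer than ``merge_gap`` positions are
    merged; merged segments narrower than ``min_width`` are discarded. Peaks
    are numbered left to right.
    """
    if hist.n_runs < 1:
        raise ValueError("histogram has no runs")
    threshold = max(1, math.ceil(min_support_frac * hist.n_runs))
    above = hist.counts >= threshold
    segments: list[list[int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            segments.append([start, i])
            start = None
    if start is not None:
        segments.append([start, hist.length])

    merged: list[list[int]] = []
    for seg in segments:
        if merged and seg[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = seg[1]
        else:
            merged.append(seg)

    peaks = []
    for seg_start, seg_end in merged:
        if seg_end - seg_start < min_width:
            continue
        height = int(hist.counts[seg_start:seg_end].max())
        peaks.append(
            Peak(
                peak_id=len(peaks) + 1,
                start=seg_start,
                end=seg_end,
                height=height,
                support_frac=height / hist.n_runs,
            )
        )
    return peaks


def peaks_to_bed(
    peaks: Sequence[Peak], path: str | Path, chrom: str = "promoter", chrom_offset: int = 0
) -> None:
    """BED6 export: name = peak_k, score = round(1000 * support_frac)."""
    with open(path, "w") as fh:
        for p in peaks:
            score = round(1000 * p.support_frac)
            fh.write(
                f"{chrom}\t{p.start + chrom_offset}\t{p.end + chrom_offset}\t"
                f"peak_{p.peak_id}\t{score}\t.\n"
            )
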