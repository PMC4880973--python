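"""Per-base depth over target footprints and coverage summaries.

Depth is stored only over the bases of a target design (the footprint),
in design order — everything the analysis reports is an on-target
quantity.  In ``unmerged`` mode each read pair contributes its two read
segments, double-counting the mate overlap, which is exactly what a naive
depth tool reports on unmerged pairs; in ``merged`` mode each merged
fragment contributes a single segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, TargetDesign


@dataclass
class DepthProfile:
    """Per-base integer depth over a design footprint, in design order."""

    design: TargetDesign
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if self.depths.ndim != 1 or len(self.depths) != self.design.footprint_size:
            raise ValueError("depths length must equal the design footprint size")
        if (self.depths < 0).any():
            raise ValueError("depths must be non-negative")

    @property
    def footprint(self) -> int:
        return len(self.depths)


@dataclass
class CoverageSummary:
    mean_coverage: float
    fraction_at_10x: float
    footprint: int


def depth_from_segments(
    segments: Iterable[GenomicInterval],
    design: TargetDesign,
    mode: str = "merged",
) -> DepthProfile:
    """Count, per footprint base, the segments covering it.

    ``segments`` are read or fragment intervals (ungapped); portions
    falling outside the design footprint are ignored.  ``mode`` is
    carried for bookkeeping only — callers supply two segments per pair
    in ``unmerged`` mode and one per fragment in ``merged`` mode.
    """
    if mode not in ("merged", "unmerged"):
        raise ValueError("mode must be 'merged' or 'unmerged'")
    known_refs = set(design.by_ref())
    # per-ref sorted design arrays plus footprint offsets for fast mapping
    ref_index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    offset = 0
    for ref, ivs in design.by_ref().items():
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        offs = offset + np.concatenate([[0], np.cumsum(ends - starts)])[:-1]
        ref_index[ref] = (starts, ends, offs)
        offset += int((ends - starts).sum())

    diff = np.zeros(design.footprint_size + 1, dtype=np.int64)
    for seg in segments:
        entry = ref_index.get(seg.ref_name)
        if entry is None:
            if seg.ref_name not in known_refs:
                raise ValueError(f"segment on unknown reference {seg.ref_name!r}")
            continue
        starts, ends, offs = entry
        i = int(np.searchsorted(ends, seg.start, side="right"))
        j = int(np.searchsorted(starts, seg.end, side="left"))
        for k in range(i, j):
            lo = max(seg.start, int(starts[k]))
            hi = min(seg.end, int(ends[k]))
            if lo < hi:
                a = int(offs[k]) + lo - int(starts[k])
                diff[a] += 1
                diff[a + hi - lo] -= 1
    return DepthProfile(design, np.cumsum(diff[:-1]))


def mean_coverage(profile: DepthProfile) -> float:
    """Arithmetic mean depth over the footprint, zero-depth bases included."""
    if profile.footprint == 0:
        raise ValueError("mean coverage undefined for an empty footprint")
    return float(profile.depths.mean())


def fraction_at_depth(profile: DepthProfile, k: int = 10) -> float:
    """Fraction of footprint bases with depth >= k."""
    if k < 0:
        raise ValueError("depth threshold must be >= 0")
    if profile.footprint == 0:
        raise ValueError("fraction undefined for an empty footprint")
    return float((profile.depths >= k).mean())


def summarize(profile: DepthProfile, k: int = 10) -> CoverageSummary:
    return CoverageSummary(
        mean_coverage=mean_coverage(profile),
        fraction_at_10x=fraction_at_depth(profile, k),
        footprint=profile.footprint,
    )


def estimate_insert_peak(insert_lengths: Sequence[int]) -> int:
    """Mode of the 1-bp-binned insert-length histogram (ties -> smallest)."""
    lengths = np.asarray(insert_lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("cannot estimate a peak from no insert lengths")
    counts = np.bincount(lengths)
    return int(np.argmax(counts))  # argmax returns the first (smallest) mode


def pair_segments(
    fragment: GenomicInterval | object, read_length: int
) -> list[GenomicInterval]:
    """The two read segments a fragment contributes in unmerged mode.

    Each mate covers ``read_length`` bases from its end of the insert
    (clipped to the insert when it is shorter than one read); the mate
    overlap region is covered twice.
    """
    ref, s, e = fragment.ref_name, fragment.start, fragment.end
    return [
        GenomicInterval(ref, s, min(e, s + read_length)),
        GenomicInterval(ref, max(s, e - read_length), e),
    ]


def write_depth_tsv(profile: DepthProfile, path: str | Path) -> None:
    """Export depth as bedGraph-like runs (ref, start, end, depth)."""
    with Path(path).open("w") as fh:
        pos = 0
        for iv in profile.design:
            d = profile.depths[pos : pos + iv.length]
            pos += iv.length
            run_start = 0
            for i in range(1, iv.length + 1):
                if i == iv.length or d[i] != d[run_start]:
                    fh.write(
                        f"{iv.ref_name}\t{iv.start + run_start}\t"
                        f"{iv.start + i}\t{int(d[run_start])}\n"
                    )
                    run_start = i
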