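"""Interval algebra over capture target designs.

Capture designs (targets, baits) are sets of genomic bases represented as
sorted, merged, 0-based half-open intervals — the BED convention.  All
metrics here are per-base set measures: footprint size, intersection, and
the fraction of one design's bases contained in another (the quantity
reported when comparing a core exome design to an extended +UTR design).
Strand is ignored throughout: capture targets are strandless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


class BedParseError(ValueError):
    """A BED line could not be parsed (bad coordinates, too few fields)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval ``[start, end)`` on a named sequence."""

    ref_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.ref_name}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different ref)."""
        if self.ref_name != other.ref_name:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class TargetDesign:
    """A canonical set of target intervals: sorted, non-overlapping, merged.

    Overlapping or book-ended input intervals are merged on construction, so
    two designs describing the same base set compare equal regardless of how
    their BED lines were split.
    """

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = _canonicalize(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def footprint_size(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def by_ref(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.ref_name, []).append(iv)
        return out


def _canonicalize(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    ivs = sorted(intervals, key=lambda iv: (iv.ref_name, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].ref_name == iv.ref_name and iv.start <= merged[-1].end:
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = GenomicInterval(prev.ref_name, prev.start, iv.end)
        else:
            merged.append(iv)
    return merged


def read_bed(path: str | Path, name: str | None = None) -> TargetDesign:
    """Read a BED3+ file into a canonical :class:`TargetDesign`.

    ``track``/``browser`` and ``#`` comment lines are skipped; columns
    beyond the third are ignored (strandless per-base semantics).
    """
    path = Path(path)
    intervals = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{lineno}: require 0 <= start < end")
            intervals.append(GenomicInterval(fields[0], start, end))
    return TargetDesign(name or path.stem, intervals)


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    """Read BED lines as raw intervals, without canonicalization.

    Use for read/fragment segments where multiplicity matters;
    :func:`read_bed` merges overlaps and is for designs.
    """
    path = Path(path)
    out = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(design: TargetDesign, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for iv in design:
            fh.write(f"{iv.ref_name}\t{iv.start}\t{iv.end}\n")


def footprint_size(design: TargetDesign) -> int:
    """Total number of unique bases covered by the design."""
    return design.footprint_size


def intersect(a: TargetDesign, b: TargetDesign, name: str | None = None) -> TargetDesign:
    """Per-base intersection of two designs (may be empty)."""
    out: list[GenomicInterval] = []
    b_by_ref = b.by_ref()
    for ref, a_ivs in a.by_ref().items():
        b_ivs = b_by_ref.get(ref, [])
        i = j = 0
        while i < len(a_ivs) and j < len(b_ivs):
            lo = max(a_ivs[i].start, b_ivs[j].start)
            hi = min(a_ivs[i].end, b_ivs[j].end)
            if lo < hi:
                out.append(GenomicInterval(ref, lo, hi))
            if a_ivs[i].end <= b_ivs[j].end:
                i += 1
            else:
                j += 1
    return TargetDesign(name or f"{a.name}&{b.name}", out)


def contained_fraction(a: TargetDesign, b: TargetDesign) -> float:
    """Fraction of ``a``'s bases that lie inside ``b``.

    Returns 1.0 iff every base of ``a`` is in ``b``.  Raises
    :class:`ValueError` for an empty ``a`` (the fraction is undefined).
    """
    fa = a.footprint_size
    if fa == 0:
        raise ValueError("contained_fraction undefined for an empty design")
    return intersect(a, b).footprint_size / fa
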