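"""Read-level processing: quality/adapter trimming, mate-pair overlap
merging, coordinate-based duplicate removal, and the overlap-redundancy
statistic.

When the sequencing insert is shorter than twice the read length, the two
mates of a pair overlap; the overlapping bases re-read the same molecule
and carry no extra evidence.  Merging collapses each overlapping pair into
a single consensus read covering the insert exactly once, keeping the
higher base quality at each disagreement — the key preprocessing step that
separates nominal from effective coverage in short-insert libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Iterable, Sequence, TypeVar

import numpy as np

from .synthetic_data import DEFAULT_ADAPTER, revcomp

T = TypeVar("T")


@dataclass
class TrimConfig:
    quality_threshold: int = 20  # Phred; 3' bases below this are trimmed
    adapter: str = DEFAULT_ADAPTER
    min_length: int = 20

    def __post_init__(self) -> None:
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class MergeConfig:
    min_overlap: int = 6
    max_mismatch_fraction: float = 0.08

    def __post_init__(self) -> None:
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.max_mismatch_fraction < 0.5:
            raise ValueError("max_mismatch_fraction must be in [0, 0.5)")


@dataclass
class MergedRead:
    seq: str
    qual: str
    source_pair_id: str
    merged: bool = True


def trim_read(
    seq: str, qual: str, cfg: TrimConfig | None = None
) -> tuple[str, str] | None:
    """3' quality- and adapter-trim one read; ``None`` means discarded.

    First the maximal 3' run of bases below ``quality_threshold`` is
    removed, then adapter contamination: a full adapter occurrence
    anywhere, or a read suffix equal to an adapter prefix of >= 4 bases,
    is cut off.  Reads shorter than ``min_length`` afterwards are
    discarded.
    """
    cfg = cfg or TrimConfig()
    if len(seq) != len(qual):
        raise ValueError("seq and qual lengths differ")
    # iterate to a fixpoint so trimming is idempotent: an adapter cut can
    # expose a low-quality 3' end and vice versa
    while True:
        end = len(seq)
        while end > 0 and ord(qual[end - 1]) - 33 < cfg.quality_threshold:
            end -= 1
        seq, qual = seq[:end], qual[:end]

        hit = seq.find(cfg.adapter)
        if hit >= 0:
            seq, qual = seq[:hit], qual[:hit]
            continue
        for k in range(min(len(cfg.adapter), len(seq)), 3, -1):
            if seq.endswith(cfg.adapter[:k]):
                seq, qual = seq[: len(seq) - k], qual[: len(qual) - k]
                break
        else:
            break
    if len(seq) < cfg.min_length:
        return None
    return seq, qual


def merge_pair(
    r1: tuple[str, str],
    r2: tuple[str, str],
    cfg: MergeConfig | None = None,
    pair_id: str = "",
) -> MergedRead | None:
    """Overlap-merge a trimmed pair; ``None`` when no acceptable overlap.

    ``r2`` is given in sequencing orientation and reverse-complemented
    internally.  All relative placements of the reverse-complemented r2
    against r1 with an overlap of at least ``min_overlap`` bases are
    scanned — including read-through placements where the insert is
    shorter than a read and each mate runs past the other's start into
    adapter remnants.  The placement maximizing matched bases, subject to
    mismatch fraction <= ``max_mismatch_fraction``, wins.  Within the
    overlap each disagreement keeps the higher-quality base (tie -> r1's
    base) and the kept quality is the max of the two.  Overhangs past the
    mate's outer end (read-through placements) are adapter remnants and
    are dropped; genomic tails are kept, so for a standard placement the
    merged length is ``len1 + len2 - overlap``.
    """
    cfg = cfg or MergeConfig()
    s1, q1 = r1
    s2, q2 = r2
    if not s1 or not s2:
        raise ValueError("cannot merge an empty read")
    s2r = revcomp(s2)
    q2r = q2[::-1]
    len1, len2 = len(s1), len(s2r)

    a1 = np.frombuffer(s1.encode(), dtype=np.uint8)
    a2 = np.frombuffer(s2r.encode(), dtype=np.uint8)

    # d = offset of s2r[0] in r1 coordinates; overlap is [lo, hi) in r1
    def _span(d: int) -> tuple[int, int]:
        return max(0, d), min(len1, len2 + d)

    candidates = sorted(
        range(cfg.min_overlap - len2, len1 - cfg.min_overlap + 1),
        key=lambda d: _span(d)[0] - _span(d)[1],
    )
    best_d, best_matched = None, -1
    for d in candidates:
        lo, hi = _span(d)
        e = hi - lo
        if e <= best_matched:
            break  # candidates are in decreasing-overlap order
        mism = int(np.count_nonzero(a1[lo:hi] != a2[lo - d : hi - d]))
        if mism / e <= cfg.max_mismatch_fraction and e - mism > best_matched:
            best_matched, best_d = e - mism, d
    if best_d is None:
        return None

    d = best_d
    lo, hi = _span(d)
    ov_seq, ov_qual = [], []
    for i in range(lo, hi):
        b1, b2 = s1[i], s2r[i - d]
        p1, p2 = q1[i], q2r[i - d]
        ov_seq.append(b1 if (b1 == b2 or p1 >= p2) else b2)
        ov_qual.append(max(p1, p2))
    # left tail of r1 (genomic insert start) and right tail of r2
    # (genomic insert end) are kept; overhangs on the other sides are
    # adapter read-through and dropped
    left_seq, left_qual = (s1[:lo], q1[:lo]) if d > 0 else ("", "")
    right_seq, right_qual = (
        (s2r[hi - d :], q2r[hi - d :]) if hi - d < len2 else ("", "")
    )
    seq = left_seq + "".join(ov_seq) + right_seq
    qual = left_qual + "".join(ov_qual) + right_qual
    return MergedRead(seq, qual, pair_id, merged=True)


def remove_duplicates(
    items: Sequence[T],
    coords: Callable[[T], tuple[Hashable, int, int]],
    quality: Callable[[T], float] | None = None,
) -> tuple[list[T], int]:
    """Coordinate-based duplicate removal.

    Among items sharing identical ``(ref_name, start, end)`` outer
    coordinates exactly one is retained: the highest ``quality`` (total
    base quality, typically), ties broken toward the earliest in input
    order.  Returns the retained items (input order) and the removed
    count.
    """
    best: dict[tuple[Hashable, int, int], tuple[float, int]] = {}
    for idx, item in enumerate(items):
        key = coords(item)
        q = quality(item) if quality is not None else 0.0
        if key not in best or q > best[key][0]:
            best[key] = (q, idx)
    keep = {idx for _, idx in best.values()}
    kept = [item for i, item in enumerate(items) if i in keep]
    return kept, len(items) - len(kept)


def overlap_redundancy(insert_lengths: Iterable[int], read_length: int = 101) -> float:
    """Fraction of sequenced bases that are redundant mate overlap.

    For a pair with insert length L and read length R the mates overlap
    over max(0, 2R - L) bases; the statistic is
    sum(max(0, 2R - L_i)) / sum(2R) over all pairs.
    """
    lengths = np.asarray(list(insert_lengths), dtype=float)
    if lengths.size == 0:
        raise ValueError("overlap_redundancy undefined for empty input")
    two_r = 2 * read_length
    return float(np.maximum(0.0, two_r - lengths).sum() / (two_r * lengths.size))
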