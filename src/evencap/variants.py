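"""Threshold variant detection and cross-subclone missed-mutation accounting.

The caller is deliberately minimal: a site is called iff its read depth is
at least ``min_depth`` (default 10, inclusive) and at least ``min_alt``
reads (default 2) support the most frequent alternative base.  For
isogenic subclones the interesting quantity is not the calls themselves
but the misses: of all sites called in at least one subclone, how many
does each sample fail to call — a direct false-negative count when the
subclones are known to share their variants.  The depth-discordance
filter selects sites deeply covered (>= hi, default 20) in every sample
of one insert-length group yet shallow (< lo, default 10, strict) in
every sample of the other — the "valley" sites where insert length
decides detectability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

Site = tuple[str, int]


@dataclass
class PileupSite:
    ref_name: str
    pos: int  # 0-based
    ref_base: str
    depth: int = 0
    alt_base: str | None = None
    alt_count: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError("require 0 <= alt_count <= depth")


@dataclass
class CallConfig:
    min_depth: int = 10  # inclusive: depth >= min_depth
    min_alt: int = 2  # inclusive: alt reads >= min_alt

    def __post_init__(self) -> None:
        if self.min_depth < 1 or self.min_alt < 1:
            raise ValueError("min_depth and min_alt must be >= 1")


@dataclass
class VariantCall:
    ref_name: str
    pos: int
    ref_base: str
    alt_base: str
    depth: int
    alt_count: int


@dataclass
class VariantCallSet:
    sample: str
    calls: list[VariantCall] = field(default_factory=list)

    @property
    def sites(self) -> set[Site]:
        return {(c.ref_name, c.pos) for c in self.calls}


@dataclass
class MissedMutationReport:
    union_size: int
    missed_per_sample: dict[str, int]
    union_sites: set[Site]
    missed_sites_per_sample: dict[str, set[Site]]


def pileup(
    reads: Iterable[object],
    sites: Sequence[tuple[str, int, str]],
    ref_lengths: Mapping[str, int] | None = None,
) -> list[PileupSite]:
    """Tally depth and alternative-allele support at the given sites.

    ``reads`` are placed sequence segments — objects with ``ref_name``,
    ``start`` and ``seq`` attributes (truth-placed merged reads in
    simulation, alignment segments in real-data mode); ``sites`` are
    ``(ref_name, pos, ref_base)``.  The alternative allele reported per
    site is the most frequent non-reference base observed there.
    """
    if ref_lengths is not None:
        for ref_name, pos, _ in sites:
            if ref_name not in ref_lengths or not 0 <= pos < ref_lengths[ref_name]:
                raise ValueError(f"site {ref_name}:{pos} outside reference")
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for idx, (ref_name, pos, _) in enumerate(sites):
        by_ref.setdefault(ref_name, []).append((pos, idx))

    depth = [0] * len(sites)
    base_counts: list[dict[str, int]] = [{} for _ in sites]
    for read in reads:
        targets = by_ref.get(read.ref_name)
        if not targets:
            continue
        start = read.start
        end = start + len(read.seq)
        for pos, idx in targets:
            if start <= pos < end:
                depth[idx] += 1
                b = read.seq[pos - start]
                base_counts[idx][b] = base_counts[idx].get(b, 0) + 1

    out = []
    for idx, (ref_name, pos, ref_base) in enumerate(sites):
        alts = {b: n for b, n in base_counts[idx].items() if b != ref_base}
        if alts:
            # most frequent non-reference base; ties broken alphabetically
            alt_base = min(alts, key=lambda b: (-alts[b], b))
            alt_count = alts[alt_base]
        else:
            alt_base, alt_count = None, 0
        out.append(PileupSite(ref_name, pos, ref_base, depth[idx], alt_base, alt_count))
    return out


def call_variants(
    pileups: Iterable[PileupSite], cfg: CallConfig | None = None, sample: str = ""
) -> VariantCallSet:
    """Double-threshold caller: depth >= min_depth and alt_count >= min_alt."""
    cfg = cfg or CallConfig()
    calls = [
        VariantCall(p.ref_name, p.pos, p.ref_base, p.alt_base, p.depth, p.alt_count)
        for p in pileups
        if p.depth >= cfg.min_depth and p.alt_count >= cfg.min_alt and p.alt_base
    ]
    return VariantCallSet(sample, calls)


def missed_mutations(call_sets: Mapping[str, VariantCallSet]) -> MissedMutationReport:
    """Union of called sites across samples and per-sample missed counts."""
    if not call_sets:
        raise ValueError("missed_mutations needs at least one call set")
    union: set[Site] = set()
    for cs in call_sets.values():
        union |= cs.sites
    missed_sites = {name: union - cs.sites for name, cs in call_sets.items()}
    return MissedMutationReport(
        union_size=len(union),
        missed_per_sample={name: len(s) for name, s in missed_sites.items()},
        union_sites=union,
        missed_sites_per_sample=missed_sites,
    )


def discordant_depth_sites(
    depth_maps: Mapping[str, Mapping[Site, int]],
    group_a: Sequence[str],
    group_b: Sequence[str],
    hi: int = 20,
    lo: int = 10,
) -> list[tuple[Site, str]]:
    """Sites deep (>= hi) in every sample of one group and shallow (< lo)
    in every sample of the other; returned with direction ``"a-high"`` or
    ``"b-high"``.
    """
    if hi <= lo:
        raise ValueError("require hi > lo for a meaningful discordance filter")
    universes = [set(depth_maps[s]) for s in list(group_a) + list(group_b)]
    if any(u != universes[0] for u in universes[1:]):
        raise ValueError("site universes differ between samples")
    out = []
    for site in sorted(universes[0]):
        a = [depth_maps[s][site] for s in group_a]
        b = [depth_maps[s][site] for s in group_b]
        if all(d >= hi for d in a) and all(d < lo for d in b):
            out.append((site, "a-high"))
        elif all(d >= hi for d in b) and all(d < lo for d in a):
            out.append((site, "b-high"))
    return out


def fn_experiment(cfg=None, seed: int = 0):
    """Two-arm false-negative comparison; see :func:`evencap.pipeline.fn_experiment`."""
    from .pipeline import fn_experiment as _fn

    return _fn(cfg, seed=seed)


def write_vcf(call_set: VariantCallSet, path: str | Path) -> None:
    """Minimal VCF export (CHROM, 1-based POS, REF, ALT, INFO DP/AD)."""
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=evencap sample={call_set.sample}\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(call_set.calls, key=lambda c: (c.ref_name, c.pos)):
            fh.write(
                f"{c.ref_name}\t{c.pos + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\t.\t"
                f"DP={c.depth};AD={c.alt_count}\n"
            )
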