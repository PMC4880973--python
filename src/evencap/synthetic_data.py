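"""Synthetic hybrid-capture sequencing experiment generator.

Produces everything the downstream analysis consumes, with full truth
tracks so no read alignment is needed:

* a toy reference with exon-like target regions (median length ~120 bp,
  the median human exon length, plus a few >=1 kbp "long exon" targets);
* two nested capture designs — a ``core`` design contained in an
  ``extended`` design, emulating a coding exome kit nested inside a
  +UTR kit — and capture baits tiled across the extended design with
  inter-bait gaps that create coverage "valleys";
* subclone genomes sharing most SNVs with a few private ones;
* captured DNA fragments whose insert lengths follow a peaked
  (truncated-normal) distribution, retained only if they overlap a bait,
  plus a configurable off-target fraction and exact-coordinate PCR
  duplicates;
* 2 x read_length paired-end reads with per-base qualities, sequencing
  errors, and adapter read-through for inserts shorter than one read.

Determinism: every stage draws from a sub-stream derived from
``(config.seed, subclone, stage)``, so identical configuration yields
bit-identical fragments, reads and files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .intervals import GenomicInterval, TargetDesign, write_bed

# Illumina TruSeq read-1 adapter prefix; read into when insert < read length.
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCA"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = bytes.maketrans(b"ACGT", b"TGCA")

INSERT_MIN = 30
INSERT_MAX = 2000


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationConfig:
    """Per-sample simulation parameters.

    ``insert_peak``/``insert_sd`` parameterize the truncated-normal insert
    length distribution (truncated to [30, 2000] bp and rounded).  A
    fragment is captured iff it overlaps a single bait by at least
    ``capture_min_overlap`` bases; an ``off_target_rate`` fraction of
    fragments bypasses the capture filter entirely.
    """

    seed: int = 0
    read_length: int = 101
    insert_peak: int = 170
    insert_sd: float = 15.0
    n_pairs: int = 6000
    duplicate_rate: float = 0.05
    base_error_rate: float = 0.001
    quality_high: int = 37
    quality_low: int = 11
    low_quality_tail: int = 8
    capture_min_overlap: int = 40
    off_target_rate: float = 0.02
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if self.insert_peak <= 0 or self.insert_sd < 0:
            raise ValueError("insert_peak must be positive and insert_sd >= 0")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not 0 <= self.off_target_rate < 1:
            raise ValueError("off_target_rate must be in [0, 1)")
        if not 0 <= self.base_error_rate < 1:
            raise ValueError("base_error_rate must be in [0, 1)")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass
class SyntheticReference:
    """Reference sequences plus the nested target designs and baits."""

    sequences: dict[str, str]
    core_design: TargetDesign
    extended_design: TargetDesign
    baits: TargetDesign

    def seq_array(self, ref_name: str) -> np.ndarray:
        return np.frombuffer(self.sequences[ref_name].encode(), dtype=np.uint8)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class SubcloneSpec:
    """SNVs carried by one subclone: shared across subclones plus private.

    Variants are ``(ref_name, pos, ref_base, alt_base)`` with 0-based
    positions; ``allele_fraction`` is the per-molecule probability of
    carrying the alternative allele (0.5 emulates a heterozygous SNV).
    """

    subclone_id: str
    shared_variants: list[tuple[str, int, str, str]] = field(default_factory=list)
    private_variants: list[tuple[str, int, str, str]] = field(default_factory=list)
    allele_fraction: float = 0.5

    @property
    def variants(self) -> list[tuple[str, int, str, str]]:
        return list(self.shared_variants) + list(self.private_variants)

    def validate(self, ref: SyntheticReference) -> None:
        for ref_name, pos, ref_base, alt_base in self.variants:
            seq = ref.sequences.get(ref_name)
            if seq is None or not 0 <= pos < len(seq):
                raise ValueError(f"variant position {ref_name}:{pos} off reference")
            if seq[pos] != ref_base:
                raise ValueError(
                    f"ref base mismatch at {ref_name}:{pos}: "
                    f"reference has {seq[pos]}, spec says {ref_base}"
                )
            if alt_base == ref_base:
                raise ValueError(f"alt equals ref at {ref_name}:{pos}")


@dataclass
class Fragment:
    """A captured DNA molecule (the sequencing insert), 0-based half-open."""

    ref_name: str
    start: int
    end: int
    molecule_id: str
    subclone_id: str
    is_duplicate_of: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadPair:
    """Both reads of one fragment, in sequencing orientation.

    r1 is the fragment's 5' prefix on the forward strand; r2 is the
    reverse complement of its 3' suffix.  If the fragment is shorter than
    the read length the reads run past the insert into the adapter.
    """

    pair_id: str
    r1_seq: str
    r2_seq: str
    r1_qual: str
    r2_qual: str
    truth: Fragment


def _stage_rng(seed: int, subclone_id: str, stage: str) -> np.random.Generator:
    # independent per-stage streams: adding fragments must not shift read errors
    return np.random.default_rng(
        [seed, zlib.crc32(subclone_id.encode()), zlib.crc32(stage.encode())]
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def make_reference(
    n_targets: int = 200,
    target_length_median: int = 120,
    n_long_targets: int = 1,
    seed: int = 0,
    *,
    long_target_min: int = 1000,
    long_target_max: int = 1600,
    bait_length: int = 120,
    bait_gap: int = 60,
    core_fraction: float = 2 / 3,
    intergap_min: int = 200,
    intergap_max: int = 600,
) -> SyntheticReference:
    """Build a toy reference with nested target designs and tiled baits.

    Target lengths are log-normal around ``target_length_median`` (clipped
    at 50 bp) plus ``n_long_targets`` long targets of >= 1 kbp.  Baits of
    ``bait_length`` bp tile each target from its start with ``bait_gap``
    bp between baits, so targets longer than ``bait_length + bait_gap``
    acquire inter-bait coverage valleys.  A random ~``core_fraction`` of
    targets is flagged coding and forms the core design; all targets form
    the extended design, so the core is contained in the extended design
    by construction.
    """
    if n_targets < 1:
        raise ValueError("n_targets must be >= 1")
    if target_length_median < 50:
        raise ValueError("target_length_median must be >= 50")
    rng = np.random.default_rng([seed, zlib.crc32(b"reference")])

    lengths = np.rint(
        target_length_median * np.exp(rng.normal(0.0, 0.35, n_targets))
    ).astype(int)
    lengths = np.maximum(lengths, 50)
    if n_long_targets > 0:
        long_lengths = rng.integers(long_target_min, long_target_max + 1, n_long_targets)
        lengths = np.concatenate([lengths, long_lengths])
        rng.shuffle(lengths)

    gaps = rng.integers(intergap_min, intergap_max + 1, len(lengths))
    targets: list[GenomicInterval] = []
    pos = int(gaps[0])
    for L, gap in zip(lengths, gaps):
        targets.append(GenomicInterval("chr1", pos, pos + int(L)))
        pos += int(L) + int(gap)
    ref_len = pos + 300

    coding = rng.random(len(targets)) < core_fraction
    if not coding.any():
        coding[0] = True
    core = [t for t, c in zip(targets, coding) if c]

    baits: list[GenomicInterval] = []
    step = bait_length + bait_gap
    for t in targets:
        for s in range(t.start, t.end, step):
            baits.append(GenomicInterval("chr1", s, min(s + bait_length, ref_len)))

    sequence = _random_dna(rng, ref_len)
    return SyntheticReference(
        sequences={"chr1": sequence},
        core_design=TargetDesign("core", core),
        extended_design=TargetDesign("extended", targets),
        baits=TargetDesign("baits", baits),
    )


def _inter_bait_gaps(ref: SyntheticReference) -> list[GenomicInterval]:
    """Target sub-regions not covered by any bait (the coverage valleys)."""
    gaps: list[GenomicInterval] = []
    baits_by_ref = ref.baits.by_ref()
    for ref_name, targets in ref.extended_design.by_ref().items():
        b = baits_by_ref.get(ref_name, [])
        for t in targets:
            cursor = t.start
            for bait in b:
                if bait.end <= t.start or bait.start >= t.end:
                    continue
                if bait.start > cursor:
                    gaps.append(GenomicInterval(ref_name, cursor, min(bait.start, t.end)))
                cursor = max(cursor, bait.end)
            if cursor < t.end:
                gaps.append(GenomicInterval(ref_name, cursor, t.end))
    return gaps


def make_subclones(
    ref: SyntheticReference,
    n_subclones: int = 2,
    n_shared: int = 30,
    n_private: int = 4,
    seed: int = 0,
    allele_fraction: float = 0.5,
    private_placement: str = "gap",
) -> list[SubcloneSpec]:
    """Isogenic subclones: identical shared SNVs plus a few private SNVs.

    ``private_placement='gap'`` plants private variants at the centers of
    inter-bait gaps inside targets — the low-coverage valleys where
    short-insert libraries are expected to miss them; ``'target'`` places
    them uniformly over target bases.
    """
    rng = np.random.default_rng([seed, zlib.crc32(b"subclones")])

    def _pick(intervals: Sequence[GenomicInterval], n: int, centered: bool) -> list[tuple[str, int]]:
        if not intervals:
            raise ValueError("no intervals available for variant placement")
        sizes = np.array([iv.length for iv in intervals], dtype=float)
        out: list[tuple[str, int]] = []
        seen: set[tuple[str, int]] = set()
        while len(out) < n:
            iv = intervals[rng.choice(len(intervals), p=sizes / sizes.sum())]
            pos = (iv.start + iv.end) // 2 if centered else int(rng.integers(iv.start, iv.end))
            key = (iv.ref_name, pos)
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def _snv(sites: Iterable[tuple[str, int]]) -> list[tuple[str, int, str, str]]:
        variants = []
        for ref_name, pos in sites:
            ref_base = ref.sequences[ref_name][pos]
            alt = "ACGT".replace(ref_base, "")[rng.integers(0, 3)]
            variants.append((ref_name, pos, ref_base, alt))
        return variants

    shared = _snv(_pick(list(ref.extended_design), n_shared, centered=False))
    gaps = _inter_bait_gaps(ref) if private_placement == "gap" else list(ref.extended_design)
    wide_gaps = [g for g in gaps if g.length >= 20] or gaps

    subclones = []
    used = {(v[0], v[1]) for v in shared}
    for i in range(n_subclones):
        private = []
        while len(private) < n_private:
            (site,) = _pick(wide_gaps, 1, centered=(private_placement == "gap"))
            if site in used:
                # centered gap picks collide across subclones; jitter instead
                ref_name, pos = site
                pos = int(pos + rng.integers(-5, 6))
                site = (ref_name, pos)
                if site in used:
                    continue
            used.add(site)
            private.extend(_snv([site]))
        subclones.append(
            SubcloneSpec(
                subclone_id=f"subclone{i + 1}",
                shared_variants=list(shared),
                private_variants=private,
                allele_fraction=allele_fraction,
            )
        )
    for sc in subclones:
        sc.validate(ref)
    return subclones


def _max_bait_overlap(
    start: int, end: int, bait_starts: np.ndarray, bait_ends: np.ndarray
) -> int:
    """Largest single-bait overlap of fragment [start, end) (baits disjoint)."""
    i = int(np.searchsorted(bait_starts, start, side="right")) - 1
    j = int(np.searchsorted(bait_starts, end, side="left"))  # exclusive
    best = 0
    for k in range(max(i, 0), j):
        ov = min(end, int(bait_ends[k])) - max(start, int(bait_starts[k]))
        if ov > best:
            best = ov
    return best


def simulate_fragments(
    ref: SyntheticReference, cfg: SimulationConfig, subclone: SubcloneSpec
) -> list[Fragment]:
    """Draw captured fragments for one sample.

    Insert lengths ~ round(TruncNormal(insert_peak, insert_sd, [30, 2000])),
    fragment midpoints uniform over the genome; a fragment is retained iff
    it overlaps some bait by >= ``capture_min_overlap`` bases, except an
    ``off_target_rate`` fraction retained unconditionally.  Exactly
    ``n_pairs`` fragments are returned, followed by
    ``round(duplicate_rate * n_pairs)`` exact-coordinate duplicates.
    """
    if len(ref.baits) == 0:
        raise ValueError("capture is impossible: reference has no baits")
    rng = _stage_rng(cfg.seed, subclone.subclone_id, "fragments")

    ref_names = list(ref.sequences)
    ref_lens = np.array([len(ref.sequences[r]) for r in ref_names], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(ref_lens)])
    total = int(offsets[-1])
    baits_by_ref = {}
    for rn in ref_names:
        ivs = ref.baits.by_ref().get(rn, [])
        baits_by_ref[rn] = (
            np.array([iv.start for iv in ivs], dtype=np.int64),
            np.array([iv.end for iv in ivs], dtype=np.int64),
        )

    fragments: list[Fragment] = []
    while len(fragments) < cfg.n_pairs:
        batch = max(4 * (cfg.n_pairs - len(fragments)), 512)
        lengths = np.rint(rng.normal(cfg.insert_peak, cfg.insert_sd, batch)).astype(int)
        ok_len = (lengths >= INSERT_MIN) & (lengths <= INSERT_MAX)
        mids = rng.integers(0, total, batch)
        bypass = rng.random(batch) < cfg.off_target_rate
        for L, mid, off in zip(lengths[ok_len], mids[ok_len], bypass[ok_len]):
            ri = int(np.searchsorted(offsets, mid, side="right")) - 1
            pos = int(mid - offsets[ri])
            start = pos - int(L) // 2
            end = start + int(L)
            if start < 0 or end > ref_lens[ri]:
                continue
            rn = ref_names[ri]
            bs, be = baits_by_ref[rn]
            if not off and (
                len(bs) == 0
                or _max_bait_overlap(start, end, bs, be) < cfg.capture_min_overlap
            ):
                continue
            fragments.append(
                Fragment(rn, start, end, f"{subclone.subclone_id}:f{len(fragments)}",
                         subclone.subclone_id)
            )
            if len(fragments) == cfg.n_pairs:
                break

    n_dup = int(round(cfg.duplicate_rate * cfg.n_pairs))
    if n_dup:
        dup_rng = _stage_rng(cfg.seed, subclone.subclone_id, "duplicates")
        for k, idx in enumerate(dup_rng.integers(0, cfg.n_pairs, n_dup)):
            t = fragments[int(idx)]
            fragments.append(
                Fragment(t.ref_name, t.start, t.end,
                         f"{subclone.subclone_id}:d{k}", t.subclone_id,
                         is_duplicate_of=t.molecule_id)
            )
    return fragments


def simulate_reads(
    fragments: Sequence[Fragment],
    ref: SyntheticReference,
    cfg: SimulationConfig,
    subclone: SubcloneSpec,
) -> list[ReadPair]:
    """Sequence fragments into 2 x read_length pairs with qualities.

    Alternative alleles are injected per molecule with probability
    ``allele_fraction``; PCR duplicates inherit their template molecule's
    alleles.  Every base is substituted with probability
    ``base_error_rate``.  Qualities follow a two-level profile:
    ``quality_high`` except for a ``low_quality_tail``-long 3' tail at
    ``quality_low`` (below the usual Q20 trimming threshold).
    """
    allele_rng = _stage_rng(cfg.seed, subclone.subclone_id, "alleles")
    err_rng = _stage_rng(cfg.seed, subclone.subclone_id, "errors")
    R = cfg.read_length
    adapter = np.frombuffer(cfg.adapter.encode(), dtype=np.uint8)
    arrays = {rn: ref.seq_array(rn) for rn in ref.sequences}
    variants_by_ref: dict[str, list[tuple[int, str]]] = {}
    for rn, pos, _rb, ab in subclone.variants:
        variants_by_ref.setdefault(rn, []).append((pos, ab))

    qual = (
        chr(cfg.quality_high + 33) * max(0, R - cfg.low_quality_tail)
        + chr(cfg.quality_low + 33) * min(R, cfg.low_quality_tail)
    )

    molecule_alleles: dict[str, dict[int, str]] = {}
    pairs: list[ReadPair] = []
    for frag in fragments:
        arr = arrays.get(frag.ref_name)
        if arr is None or frag.start < 0 or frag.end > len(arr):
            raise RuntimeError(f"fragment {frag.molecule_id} outside reference bounds")
        if frag.is_duplicate_of is not None:
            alleles = molecule_alleles.get(frag.is_duplicate_of, {})
        else:
            alleles = {}
            for pos, alt in variants_by_ref.get(frag.ref_name, []):
                if frag.start <= pos < frag.end and allele_rng.random() < subclone.allele_fraction:
                    alleles[pos] = alt
            molecule_alleles[frag.molecule_id] = alleles

        insert = arr[frag.start : frag.end].copy()
        for pos, alt in alleles.items():
            insert[pos - frag.start] = ord(alt)

        fwd = insert
        rev = insert[::-1]
        rev = np.frombuffer(rev.tobytes().translate(_COMP), dtype=np.uint8)

        def _read(template: np.ndarray) -> str:
            if len(template) >= R:
                read = template[:R].copy()
            else:
                read = np.full(R, ord("A"), dtype=np.uint8)
                read[: len(template)] = template
                tail = adapter[: R - len(template)]
                read[len(template) : len(template) + len(tail)] = tail
            errs = np.nonzero(err_rng.random(R) < cfg.base_error_rate)[0]
            for e in errs:
                read[e] = _BASES[(np.searchsorted(_BASES, read[e]) + err_rng.integers(1, 4)) % 4]
            return read.tobytes().decode()

        pairs.append(
            ReadPair(frag.molecule_id, _read(fwd), _read(rev), qual, qual, frag)
        )
    return pairs


# ---------------------------------------------------------------------------
# truth / file output

def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    with Path(path).open() as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            out.append((header.rstrip("\n")[1:], seq, qual))
    return out


def write_fasta(ref: SyntheticReference, path: str | Path, width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in ref.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(
    fragments: Sequence[Fragment],
    reads: Sequence[ReadPair],
    outdir: str | Path,
    subclone: SubcloneSpec | None = None,
    prefix: str = "sample",
) -> dict[str, Path]:
    """Write FASTQ pair plus fragment/variant truth tables (plain TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "r1": outdir / f"{prefix}_R1.fastq",
        "r2": outdir / f"{prefix}_R2.fastq",
        "fragments": outdir / f"{prefix}_fragments.tsv",
        "variants": outdir / f"{prefix}_variants.tsv",
    }
    write_fastq(((p.pair_id, p.r1_seq, p.r1_qual) for p in reads), paths["r1"])
    write_fastq(((p.pair_id, p.r2_seq, p.r2_qual) for p in reads), paths["r2"])
    with paths["fragments"].open("w") as fh:
        fh.write("ref_name\tstart\tend\tmolecule_id\tsubclone_id\tis_duplicate_of\n")
        for f in fragments:
            fh.write(
                f"{f.ref_name}\t{f.start}\t{f.end}\t{f.molecule_id}\t"
                f"{f.subclone_id}\t{f.is_duplicate_of or '.'}\n"
            )
    with paths["variants"].open("w") as fh:
        fh.write("ref_name\tpos\tref\talt\tkind\n")
        if subclone is not None:
            for rn, pos, rb, ab in subclone.shared_variants:
                fh.write(f"{rn}\t{pos}\t{rb}\t{ab}\tshared\n")
            for rn, pos, rb, ab in subclone.private_variants:
                fh.write(f"{rn}\t{pos}\t{rb}\t{ab}\tprivate\n")
    return paths


def read_fragments_tsv(path: str | Path) -> list[Fragment]:
    out = []
    with Path(path).open() as fh:
        header = fh.readline()
        assert header.startswith("ref_name")
        for line in fh:
            rn, s, e, mid, sid, dup = line.rstrip("\n").split("\t")
            out.append(Fragment(rn, int(s), int(e), mid, sid,
                                None if dup == "." else dup))
    return out


def write_designs(ref: SyntheticReference, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, design in (
        ("core", ref.core_design),
        ("extended", ref.extended_design),
        ("baits", ref.baits),
    ):
        paths[label] = outdir / f"{label}.bed"
        write_bed(design, paths[label])
    return paths
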