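"""Two-arm insert-length experiment: simulate -> trim -> merge -> dedup ->
coverage -> evenness -> variants -> report.

The experiment contrasts a short-insert arm against a long-insert arm
(typically 130 vs 170 bp peaks) on the same synthetic reference, with
arms constrained to differ *only* in their insert-length distribution so
any metric difference is attributable to insert length.  Mirroring the
two capture kits of a core-vs-extended exome comparison, each arm is
analysed on its own ("respective") target design and on the common
design (the intersection of the two); by default the short-insert arm
uses the extended design and the long-insert arm the core design.

Every stage draws its randomness from sub-streams derived from one
experiment seed, so re-running a configuration reproduces all
intermediate files and the report byte-identically.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import readops
from .coverage import (
    DepthProfile,
    depth_from_segments,
    estimate_insert_peak,
    fraction_at_depth,
    mean_coverage,
)
from .evenness import evenness_score
from .intervals import GenomicInterval, TargetDesign, intersect, write_bed
from .readops import MergeConfig, TrimConfig
from .synthetic_data import (
    Fragment,
    ReadPair,
    SimulationConfig,
    SubcloneSpec,
    SyntheticReference,
    make_reference,
    make_subclones,
    simulate_fragments,
    simulate_reads,
    write_truth,
)
from .variants import (
    CallConfig,
    MissedMutationReport,
    VariantCallSet,
    call_variants,
    discordant_depth_sites,
    missed_mutations,
    pileup,
    write_vcf,
)

logger = logging.getLogger("evencap")

# simulation parameters allowed to differ between arms
_ARM_VARIABLE_FIELDS = {"insert_peak", "insert_sd"}


@dataclass
class ArmConfig:
    label: str
    sim: SimulationConfig
    design_label: str = "extended"  # which design this arm is analysed on

    def __post_init__(self) -> None:
        if self.design_label not in ("core", "extended"):
            raise ValueError("design_label must be 'core' or 'extended'")


@dataclass
class ExperimentConfig:
    arms: list[ArmConfig] = field(default_factory=list)
    seed: int = 0
    n_targets: int = 200
    target_length_median: int = 120
    n_long_targets: int = 1
    n_subclones: int = 2
    n_shared_variants: int = 30
    n_private_variants: int = 4
    allele_fraction: float = 0.5
    private_placement: str = "gap"
    trim: TrimConfig = field(default_factory=TrimConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    call: CallConfig = field(default_factory=CallConfig)
    depth_threshold: int = 10
    output_dir: str | None = None
    allow_confounds: bool = False

    def __post_init__(self) -> None:
        if not self.arms:
            self.arms = default_arms(self.seed)
        if not self.allow_confounds:
            _check_confounds(self.arms)


def default_arms(seed: int = 0, n_pairs: int = 6000) -> list[ArmConfig]:
    """The default 130 vs 170 bp contrast at matched read budgets."""
    base = SimulationConfig(seed=seed, n_pairs=n_pairs)
    return [
        ArmConfig("130bp", base.replace(insert_peak=130), design_label="extended"),
        ArmConfig("170bp", base.replace(insert_peak=170), design_label="core"),
    ]


def _check_confounds(arms: Sequence[ArmConfig]) -> None:
    """Arms may differ only in their insert-length distribution."""
    if len(arms) < 2:
        return
    ref = dataclasses.asdict(arms[0].sim)
    for arm in arms[1:]:
        other = dataclasses.asdict(arm.sim)
        for k, v in other.items():
            if k not in _ARM_VARIABLE_FIELDS and v != ref[k]:
                raise ValueError(
                    f"confound guard: arms differ in {k!r} "
                    "(only insert_peak/insert_sd may vary; "
                    "set allow_confounds=True to override)"
                )


@dataclass
class PlacedRead:
    """A base-called sequence at a known reference position."""

    ref_name: str
    start: int
    seq: str


@dataclass
class SampleResult:
    sample: str
    arm: str
    stats: dict[str, float]
    profiles: dict[tuple[str, str], DepthProfile]  # (mode, design_label) -> profile
    insert_peak_estimate: int
    call_set: VariantCallSet
    depth_at_sites: dict[tuple[str, int], int]
    truth_sites: set[tuple[str, int]]


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    reference: SyntheticReference
    subclones: list[SubcloneSpec]
    designs: dict[str, TargetDesign]
    samples: list[SampleResult]
    metrics: pd.DataFrame
    missed: MissedMutationReport
    missed_vs_truth: dict[str, int]
    discordant: list

    def arm_samples(self, arm_label: str) -> list[SampleResult]:
        return [s for s in self.samples if s.arm == arm_label]


def _placed_reads_for_pair(
    pair: ReadPair, trimmed1: tuple[str, str], trimmed2: tuple[str, str]
) -> list[PlacedRead]:
    """Truth placement of an unmerged pair's two reads on the reference."""
    from .synthetic_data import revcomp

    frag = pair.truth
    s1 = trimmed1[0][: frag.length]
    s2 = trimmed2[0][: frag.length]
    return [
        PlacedRead(frag.ref_name, frag.start, s1),
        PlacedRead(frag.ref_name, frag.end - len(s2), revcomp(s2)),
    ]


def process_sample(
    ref: SyntheticReference,
    subclone: SubcloneSpec,
    arm: ArmConfig,
    cfg: ExperimentConfig,
    designs: dict[str, TargetDesign],
    sites: Sequence[tuple[str, int, str]],
    outdir: Path | None = None,
) -> SampleResult:
    """Run one sample through the full stage chain and collect metrics."""
    sample = f"{arm.label}:{subclone.subclone_id}"
    R = arm.sim.read_length
    fragments = simulate_fragments(ref, arm.sim, subclone)
    pairs = simulate_reads(fragments, ref, arm.sim, subclone)
    logger.info("stage=simulate sample=%s fragments=%d", sample, len(fragments))
    if outdir is not None:
        write_truth(fragments, pairs, outdir, subclone, prefix=sample.replace(":", "_"))

    # trim
    bases_in = bases_out = 0
    trimmed: list[tuple[ReadPair, tuple[str, str], tuple[str, str]]] = []
    for pair in pairs:
        t1 = readops.trim_read(pair.r1_seq, pair.r1_qual, cfg.trim)
        t2 = readops.trim_read(pair.r2_seq, pair.r2_qual, cfg.trim)
        bases_in += len(pair.r1_seq) + len(pair.r2_seq)
        if t1 is None or t2 is None:
            continue
        bases_out += len(t1[0]) + len(t2[0])
        trimmed.append((pair, t1, t2))
    logger.info("stage=trim sample=%s pairs_kept=%d", sample, len(trimmed))

    # dedup on truth outer coordinates (highest total base quality wins)
    deduped, n_dup_removed = readops.remove_duplicates(
        trimmed,
        coords=lambda t: (t[0].truth.ref_name, t[0].truth.start, t[0].truth.end),
        quality=lambda t: sum(ord(c) for c in t[1][1] + t[2][1]),
    )
    logger.info("stage=dedup sample=%s removed=%d", sample, n_dup_removed)

    # merge
    merged_placed: list[PlacedRead] = []
    unmerged_segments: list[GenomicInterval] = []
    merged_segments: list[GenomicInterval] = []
    pass_through_placed: list[PlacedRead] = []
    n_merged = 0
    for pair, t1, t2 in deduped:
        frag = pair.truth
        for placed in _placed_reads_for_pair(pair, t1, t2):
            if placed.seq:
                unmerged_segments.append(
                    GenomicInterval(placed.ref_name, placed.start,
                                    placed.start + len(placed.seq))
                )
        m = readops.merge_pair(t1, t2, cfg.merge, pair_id=pair.pair_id)
        if m is not None:
            n_merged += 1
            seg_end = min(frag.start + len(m.seq), frag.end)
            if seg_end > frag.start:
                merged_segments.append(
                    GenomicInterval(frag.ref_name, frag.start, seg_end)
                )
            merged_placed.append(PlacedRead(frag.ref_name, frag.start, m.seq))
        else:
            placed = _placed_reads_for_pair(pair, t1, t2)
            for p in placed:
                if p.seq:
                    merged_segments.append(
                        GenomicInterval(p.ref_name, p.start, p.start + len(p.seq))
                    )
            pass_through_placed.extend(p for p in placed if p.seq)
    logger.info("stage=merge sample=%s merged=%d/%d", sample, n_merged, len(deduped))

    profiles = {}
    for design_label in ("respective", "common"):
        design = designs[arm.design_label if design_label == "respective" else "common"]
        profiles[("unmerged", design_label)] = depth_from_segments(
            unmerged_segments, design, mode="unmerged"
        )
        profiles[("merged", design_label)] = depth_from_segments(
            merged_segments, design, mode="merged"
        )

    # variant evidence from the merged stream (merged reads + pass-throughs)
    placed_all = merged_placed + pass_through_placed
    ref_lengths = {rn: len(s) for rn, s in ref.sequences.items()}
    piles = pileup(placed_all, sites, ref_lengths)
    call_set = call_variants(piles, cfg.call, sample=sample)
    depth_at_sites = {(p.ref_name, p.pos): p.depth for p in piles}

    insert_lengths = [t[0].truth.length for t in deduped]
    stats = {
        "pairs_in": float(len(pairs)),
        "pairs_after_trim": float(len(trimmed)),
        "duplicates_removed": float(n_dup_removed),
        "pairs_analysed": float(len(deduped)),
        "merged_fraction": n_merged / len(deduped) if deduped else float("nan"),
        "trimmed_base_fraction": 1.0 - bases_out / bases_in if bases_in else 0.0,
        "overlap_redundancy": readops.overlap_redundancy(insert_lengths, R),
    }
    truth_sites = {(rn, pos) for rn, pos, _, _ in subclone.variants}
    return SampleResult(
        sample=sample,
        arm=arm.label,
        stats=stats,
        profiles=profiles,
        insert_peak_estimate=estimate_insert_peak(insert_lengths),
        call_set=call_set,
        depth_at_sites=depth_at_sites,
        truth_sites=truth_sites,
    )


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    """Run the full two-arm experiment and assemble the metric grid."""
    if not logging.getLogger().handlers and not logger.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(name)s %(message)s")
    outdir = Path(cfg.output_dir) if cfg.output_dir else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    ref = make_reference(
        n_targets=cfg.n_targets,
        target_length_median=cfg.target_length_median,
        n_long_targets=cfg.n_long_targets,
        seed=cfg.seed,
    )
    subclones = make_subclones(
        ref,
        n_subclones=cfg.n_subclones,
        n_shared=cfg.n_shared_variants,
        n_private=cfg.n_private_variants,
        seed=cfg.seed,
        allele_fraction=cfg.allele_fraction,
        private_placement=cfg.private_placement,
    )
    designs = {
        "core": ref.core_design,
        "extended": ref.extended_design,
        "common": intersect(ref.core_design, ref.extended_design, name="common"),
    }
    if outdir is not None:
        for label, design in designs.items():
            write_bed(design, outdir / f"{label}.bed")
        write_bed(ref.baits, outdir / "baits.bed")

    # union of planted variant sites across subclones = candidate sites
    site_set: dict[tuple[str, int], str] = {}
    for sc in subclones:
        for rn, pos, rb, _ in sc.variants:
            site_set[(rn, pos)] = rb
    sites = [(rn, pos, rb) for (rn, pos), rb in sorted(site_set.items())]

    samples: list[SampleResult] = []
    for arm in cfg.arms:
        for sc in subclones:
            samples.append(
                process_sample(ref, sc, arm, cfg, designs, sites, outdir)
            )

    rows = []
    for s in samples:
        for (mode, design_label), profile in s.profiles.items():
            rows.append(
                {
                    "sample": s.sample,
                    "arm": s.arm,
                    "mode": mode,
                    "design": design_label,
                    "footprint": profile.footprint,
                    "mean_coverage": mean_coverage(profile),
                    "evenness": evenness_score(profile).score,
                    "fraction_10x": fraction_at_depth(profile, cfg.depth_threshold),
                    "insert_peak_estimate": s.insert_peak_estimate,
                    "overlap_redundancy": s.stats["overlap_redundancy"],
                }
            )
    metrics = pd.DataFrame(rows)

    missed = missed_mutations({s.sample: s.call_set for s in samples})
    missed_vs_truth = {
        s.sample: len(s.truth_sites - s.call_set.sites) for s in samples
    }
    arm_labels = [a.label for a in cfg.arms]
    discordant = []
    if len(arm_labels) >= 2:
        group_a = [s.sample for s in samples if s.arm == arm_labels[0]]
        group_b = [s.sample for s in samples if s.arm == arm_labels[1]]
        discordant = discordant_depth_sites(
            {s.sample: s.depth_at_sites for s in samples}, group_a, group_b
        )

    report = ExperimentReport(
        config=cfg,
        reference=ref,
        subclones=subclones,
        designs=designs,
        samples=samples,
        metrics=metrics,
        missed=missed,
        missed_vs_truth=missed_vs_truth,
        discordant=discordant,
    )
    if outdir is not None:
        _write_report(report, outdir)
    return report


def _write_report(report: ExperimentReport, outdir: Path) -> None:
    report.metrics.to_csv(outdir / "metrics.tsv", sep="\t", index=False,
                          float_format="%.6g")
    for s in report.samples:
        write_vcf(s.call_set, outdir / f"{s.sample.replace(':', '_')}.vcf")
    with (outdir / "missed_mutations.tsv").open("w") as fh:
        fh.write("sample\tmissed_vs_union\tmissed_vs_truth\tunion_size\n")
        for s in report.samples:
            fh.write(
                f"{s.sample}\t{report.missed.missed_per_sample[s.sample]}\t"
                f"{report.missed_vs_truth[s.sample]}\t{report.missed.union_size}\n"
            )
    with (outdir / "summary.txt").open("w") as fh:
        fh.write(format_summary(report))


def format_summary(report: ExperimentReport) -> str:
    lines = ["evencap experiment summary", "=" * 26, ""]
    g = report.metrics.groupby(["arm", "mode", "design"])
    for (arm, mode, design), df in g:
        lines.append(
            f"arm={arm:6s} mode={mode:8s} design={design:10s} "
            f"C={df['mean_coverage'].mean():7.2f}  "
            f"E={df['evenness'].mean():6.4f}  "
            f"frac>=10x={df['fraction_10x'].mean():6.4f}"
        )
    lines.append("")
    lines.append(f"union of called sites: {report.missed.union_size}")
    for s in report.samples:
        lines.append(
            f"  {s.sample}: missed vs union = "
            f"{report.missed.missed_per_sample[s.sample]}, "
            f"vs planted truth = {report.missed_vs_truth[s.sample]}"
        )
    lines.append(f"depth-discordant sites: {len(report.discordant)}")
    return "\n".join(lines) + "\n"


def fn_experiment(cfg: ExperimentConfig | None = None, seed: int = 0) -> pd.DataFrame:
    """Two-arm false-negative comparison table (one row per arm).

    Counts, per arm, the variants called, the union-missed and
    truth-missed totals over its samples, and the depth-discordant sites
    in its favour.  The confound guard of :class:`ExperimentConfig`
    ensures the arms differ only in insert length.
    """
    cfg = cfg or ExperimentConfig(seed=seed)
    report = run_experiment(cfg)
    rows = []
    for arm in cfg.arms:
        arm_samples = report.arm_samples(arm.label)
        rows.append(
            {
                "arm": arm.label,
                "insert_peak": arm.sim.insert_peak,
                "samples": len(arm_samples),
                "called": sum(len(s.call_set.calls) for s in arm_samples),
                "missed_vs_union": sum(
                    report.missed.missed_per_sample[s.sample] for s in arm_samples
                ),
                "missed_vs_truth": sum(
                    report.missed_vs_truth[s.sample] for s in arm_samples
                ),
                "union_size": report.missed.union_size,
            }
        )
    return pd.DataFrame(rows)


def plot_report(report: ExperimentReport, outdir: str | Path) -> list[Path]:
    """Coverage-curve, evenness-bar and insert-length figures (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .evenness import coverage_curve

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for s in report.samples:
        profile = s.profiles[("unmerged", "common")]
        try:
            curve = coverage_curve(profile)
        except ValueError:
            logger.warning("plot skipped for %s: zero coverage", s.sample)
            continue
        axes[0].plot(curve.xs * mean_coverage(profile), curve.ds, label=s.sample)
        axes[1].plot(curve.xs, curve.ds, label=s.sample)
    axes[0].set_xlabel("coverage (x)")
    axes[1].set_xlabel("normalized coverage u")
    for ax in axes:
        ax.set_ylabel("fraction of target bases >= x")
        ax.legend(fontsize=7)
    path = outdir / "coverage_curves.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(8, 4))
    df = report.metrics[report.metrics["design"] == "common"]
    labels = [f"{r.arm}\n{r.sample.split(':')[1]}\n{r.mode}" for r in df.itertuples()]
    ax.bar(range(len(df)), df["evenness"])
    ax.set_xticks(range(len(df)), labels, fontsize=6)
    ax.set_ylabel("evenness score E")
    ax.set_ylim(0, 1)
    path = outdir / "evenness.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    return written
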