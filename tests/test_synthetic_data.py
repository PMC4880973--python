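"""Simulator truth checks: determinism, capture law, insert distribution,
mate-overlap arithmetic, adapter read-through, and the emergent
"mountain-valley" depth shape that motivates the whole analysis."""

import numpy as np
import pytest
from scipy import stats

from evencap.coverage import depth_from_segments, estimate_insert_peak
from evencap.intervals import GenomicInterval, contained_fraction
from evencap.readops import trim_read
from evencap.synthetic_data import (
    SimulationConfig,
    _inter_bait_gaps,
    make_reference,
    make_subclones,
    read_fastq,
    simulate_fragments,
    simulate_reads,
    write_truth,
)


class TestMakeReference:
    def test_deterministic_for_fixed_seed(self):
        a = make_reference(n_targets=10, n_long_targets=1, seed=3)
        b = make_reference(n_targets=10, n_long_targets=1, seed=3)
        assert a.sequences == b.sequences
        assert a.extended_design.intervals == b.extended_design.intervals
        assert a.baits.intervals == b.baits.intervals

    def test_core_contained_in_extended(self, small_ref):
        assert contained_fraction(small_ref.core_design, small_ref.extended_design) == 1.0

    def test_every_bait_overlaps_an_extended_target(self, small_ref):
        targets = small_ref.extended_design.intervals
        for bait in small_ref.baits:
            assert any(bait.overlap(t) > 0 for t in targets)

    def test_long_targets_present(self, small_ref):
        assert sum(iv.length >= 1000 for iv in small_ref.extended_design) >= 1

    def test_median_target_length_tracks_parameter(self):
        ref = make_reference(n_targets=200, target_length_median=120,
                             n_long_targets=0, seed=11)
        lengths = [iv.length for iv in ref.extended_design]
        assert abs(np.median(lengths) - 120) <= 10

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            make_reference(n_targets=0)
        with pytest.raises(ValueError):
            make_reference(target_length_median=10)


class TestSimulationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"read_length": 0},
            {"insert_peak": -5},
            {"duplicate_rate": 1.0},
            {"off_target_rate": -0.1},
            {"n_pairs": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)


class TestSimulateFragments:
    def test_capture_law_without_off_target(self, small_ref, small_subclones):
        cfg = SimulationConfig(seed=5, n_pairs=500, off_target_rate=0.0,
                               duplicate_rate=0.0)
        frags = simulate_fragments(small_ref, cfg, small_subclones[0])
        assert len(frags) == 500
        baits = small_ref.baits.intervals
        for f in frags:
            iv = GenomicInterval(f.ref_name, f.start, f.end)
            assert max(iv.overlap(b) for b in baits) >= cfg.capture_min_overlap

    def test_no_duplicates_at_zero_rate(self, small_ref, small_subclones):
        cfg = SimulationConfig(seed=5, n_pairs=200, duplicate_rate=0.0)
        frags = simulate_fragments(small_ref, cfg, small_subclones[0])
        assert all(f.is_duplicate_of is None for f in frags)

    def test_duplicates_copy_template_coordinates(self, small_ref, small_subclones):
        cfg = SimulationConfig(seed=5, n_pairs=200, duplicate_rate=0.2)
        frags = simulate_fragments(small_ref, cfg, small_subclones[0])
        by_id = {f.molecule_id: f for f in frags}
        dups = [f for f in frags if f.is_duplicate_of is not None]
        assert len(dups) == 40
        for d in dups:
            t = by_id[d.is_duplicate_of]
            assert (d.ref_name, d.start, d.end) == (t.ref_name, t.start, t.end)

    def test_insert_peak_recovered_from_sample(self, small_ref, small_subclones):
        cfg = SimulationConfig(seed=9, n_pairs=20_000, insert_peak=130,
                               insert_sd=15, duplicate_rate=0.0)
        frags = simulate_fragments(small_ref, cfg, small_subclones[0])
        mode = estimate_insert_peak([f.length for f in frags])
        assert abs(mode - 130) <= 3

    def test_no_baits_is_a_config_error(self, small_ref, small_subclones):
        bare = make_reference(n_targets=5, seed=1)
        bare.baits.intervals = []
        with pytest.raises(ValueError, match="bait"):
            simulate_fragments(bare, SimulationConfig(n_pairs=10), small_subclones[0])

    def test_mean_mate_overlap_matches_truncated_normal_expectation(
        self, small_ref, small_subclones
    ):
        R, peak, sd = 101, 130, 15.0
        # off_target_rate ~1 makes capture non-selective, isolating the
        # insert-length law from capture's bias toward longer fragments
        cfg = SimulationConfig(seed=13, n_pairs=20_000, insert_peak=peak,
                               insert_sd=sd, duplicate_rate=0.0,
                               off_target_rate=0.999)
        frags = simulate_fragments(small_ref, cfg, small_subclones[0])
        overlaps = np.maximum(0, 2 * R - np.array([f.length for f in frags]))
        # expectation of max(0, 2R - L) for L = round(N(peak, sd)) truncated
        lengths = np.arange(30, 2001)
        pmf = stats.norm.cdf(lengths + 0.5, peak, sd) - stats.norm.cdf(
            lengths - 0.5, peak, sd
        )
        pmf /= pmf.sum()
        values = np.maximum(0, 2 * R - lengths)
        expected = float((pmf * values).sum())
        se = float(np.sqrt((pmf * (values - expected) ** 2).sum() / len(frags)))
        assert abs(overlaps.mean() - expected) <= 3 * se


class TestSimulateReads:
    def test_mate_overlap_arithmetic(self, small_ref, small_subclones):
        # a 130 bp fragment read as 2x101 overlaps over 2*101-130 = 72 bases
        sc = small_subclones[0]
        target = small_ref.extended_design.intervals[0]
        frag = _one_fragment(small_ref, target.start, 130, sc)
        cfg = SimulationConfig(seed=1, base_error_rate=0.0, low_quality_tail=0)
        (pair,) = simulate_reads([frag], small_ref, cfg, sc)
        from evencap.synthetic_data import revcomp

        r2f = revcomp(pair.r2_seq)  # forward-strand orientation
        assert pair.r1_seq[-72:] == r2f[:72]

    def test_long_fragment_has_no_mate_overlap(self, small_ref, small_subclones):
        sc = small_subclones[0]
        frag = _one_fragment(small_ref, 10, 210, sc)
        cfg = SimulationConfig(seed=1, base_error_rate=0.0, low_quality_tail=0)
        (pair,) = simulate_reads([frag], small_ref, cfg, sc)
        from evencap.synthetic_data import revcomp

        seq = small_ref.sequences[frag.ref_name][frag.start : frag.end]
        assert pair.r1_seq == seq[:101]
        assert revcomp(pair.r2_seq) == seq[-101:]

    def test_short_fragment_reads_into_adapter(self, small_ref, small_subclones):
        sc = small_subclones[0]
        cfg = SimulationConfig(seed=1, base_error_rate=0.0, low_quality_tail=0)
        frag = _one_fragment(small_ref, 50, 60, sc)
        (pair,) = simulate_reads([frag], small_ref, cfg, sc)
        assert pair.r1_seq[60 : 60 + len(cfg.adapter)] == cfg.adapter

    def test_homozygous_variant_in_every_covering_read(self, small_ref):
        target = small_ref.extended_design.intervals[2]
        pos = (target.start + target.end) // 2
        ref_base = small_ref.sequences["chr1"][pos]
        alt = "ACGT".replace(ref_base, "")[0]
        sc_hom = make_subclones(small_ref, n_subclones=1, n_shared=1, n_private=0,
                                seed=3, allele_fraction=1.0)[0]
        sc_hom.shared_variants = [("chr1", pos, ref_base, alt)]
        cfg = SimulationConfig(seed=2, n_pairs=300, base_error_rate=0.0,
                               duplicate_rate=0.0)
        frags = simulate_fragments(small_ref, cfg, sc_hom)
        pairs = simulate_reads(frags, small_ref, cfg, sc_hom)
        covering = 0
        for p in pairs:
            f = p.truth
            if not (f.start <= pos < f.end):
                continue
            off = pos - f.start
            if off < len(p.r1_seq) and f.length >= 101:
                covering += 1
                assert p.r1_seq[off] == alt
        assert covering > 0

    def test_out_of_bounds_fragment_is_internal_error(self, small_ref, small_subclones):
        sc = small_subclones[0]
        from evencap.synthetic_data import Fragment

        bad = Fragment("chr1", 0, 10**9, "x", sc.subclone_id)
        with pytest.raises(RuntimeError):
            simulate_reads([bad], small_ref, SimulationConfig(), sc)


class TestDeterminismAndTruthFiles:
    def test_identical_seed_gives_byte_identical_outputs(
        self, tmp_path, small_ref, small_subclones
    ):
        cfg = SimulationConfig(seed=21, n_pairs=150)
        sc = small_subclones[0]
        outputs = []
        for d in ("a", "b"):
            frags = simulate_fragments(small_ref, cfg, sc)
            reads = simulate_reads(frags, small_ref, cfg, sc)
            paths = write_truth(frags, reads, tmp_path / d, sc)
            outputs.append({k: p.read_bytes() for k, p in paths.items()})
        assert outputs[0] == outputs[1]

    def test_fastq_round_trip(self, tmp_path, small_ref, small_subclones):
        cfg = SimulationConfig(seed=4, n_pairs=50)
        sc = small_subclones[0]
        frags = simulate_fragments(small_ref, cfg, sc)
        reads = simulate_reads(frags, small_ref, cfg, sc)
        paths = write_truth(frags, reads, tmp_path, sc)
        back = read_fastq(paths["r1"])
        assert [(p.pair_id, p.r1_seq, p.r1_qual) for p in reads] == back

    def test_truth_tables_complete(self, tmp_path, small_ref, small_subclones):
        cfg = SimulationConfig(seed=4, n_pairs=50, duplicate_rate=0.1)
        sc = small_subclones[0]
        frags = simulate_fragments(small_ref, cfg, sc)
        reads = simulate_reads(frags, small_ref, cfg, sc)
        paths = write_truth(frags, reads, tmp_path, sc)
        frag_lines = paths["fragments"].read_text().strip().splitlines()
        assert len(frag_lines) - 1 == len(frags)
        var_lines = paths["variants"].read_text().strip().splitlines()
        assert len(var_lines) - 1 == len(sc.variants)


class TestSubclones:
    def test_shared_variants_identical_across_subclones(self, small_subclones):
        a, b = small_subclones
        assert a.shared_variants == b.shared_variants
        assert a.private_variants != b.private_variants

    def test_variants_match_reference_base(self, small_ref, small_subclones):
        for sc in small_subclones:
            sc.validate(small_ref)  # raises on any ref-base mismatch

    def test_gap_placement_puts_private_variants_outside_baits(
        self, small_ref, small_subclones
    ):
        bait_set = {
            (iv.ref_name, p) for iv in small_ref.baits for p in range(iv.start, iv.end)
        }
        for sc in small_subclones:
            for rn, pos, _, _ in sc.private_variants:
                assert (rn, pos) not in bait_set


def test_mountain_valley_profile_sharper_for_short_inserts(small_ref, small_subclones):
    """Depth peaks at bait centers and dips in inter-bait gaps; the
    peak-to-valley contrast is stronger for 130 bp than 170 bp inserts."""
    sc = small_subclones[0]
    ratios = {}
    gaps = [g for g in _inter_bait_gaps(small_ref) if g.length >= 40]
    for peak in (130, 170):
        cfg = SimulationConfig(seed=17, n_pairs=8000, insert_peak=peak,
                               duplicate_rate=0.0, off_target_rate=0.0)
        frags = simulate_fragments(small_ref, cfg, sc)
        segs = [GenomicInterval(f.ref_name, f.start, f.end) for f in frags]
        profile = depth_from_segments(segs, small_ref.extended_design)
        depth_at = _depth_lookup(profile)
        bait_centers = [
            (b.ref_name, (b.start + b.end) // 2)
            for b in small_ref.baits
            if any(b.overlap(t) == b.length for t in small_ref.extended_design)
        ]
        gap_centers = [(g.ref_name, (g.start + g.end) // 2) for g in gaps]
        peak_depth = np.mean([depth_at(*c) for c in bait_centers])
        valley_depth = np.mean([depth_at(*c) for c in gap_centers])
        assert peak_depth > valley_depth
        ratios[peak] = peak_depth / valley_depth
    assert ratios[130] > ratios[170]


def _depth_lookup(profile):
    index = {}
    pos = 0
    for iv in profile.design:
        for p in range(iv.start, iv.end):
            index[(iv.ref_name, p)] = pos
            pos += 1

    def depth_at(ref_name, p):
        return profile.depths[index[(ref_name, p)]]

    return depth_at


def _one_fragment(ref, start, length, sc):
    from evencap.synthetic_data import Fragment

    return Fragment("chr1", start, start + length, "m0", sc.subclone_id)
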