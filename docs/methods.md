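# Methods

`evencap` studies how the length of the sequenced DNA insert shapes the
uniformity of on-target coverage in hybrid-capture (exome-style)
paired-end sequencing, and how that uniformity translates into variant
detection. Because the question is about the *geometry* of capture —
where fragments sit relative to baits and how far 2×R read pairs reach
into inter-bait gaps — it can be studied end-to-end on synthetic data
with full truth tracks, with no read alignment step: every simulated
fragment knows its coordinates.

## The evenness score

Let `c_j` be the read depth at base `j` of a target footprint of `N`
bases, `C = (1/N) Σ c_j` the mean on-target depth, and `u_j = c_j / C`
the normalized coverage (the coverage curve then integrates to 1). With
the survival curve `D(x) = |{j : u_j ≥ x}| / N`, the evenness score is

    E = ∫₀¹ D(x) dx  =  (1/N) Σ_j min(u_j, 1)  ∈ [0, 1].

The closed form on the right is the exact area under the step function
`D` between 0 and 1 and is adopted as the definition; grid evaluation of
`D` exists only for plotting and as an independent test oracle. `E = 1`
iff every base sits exactly at the mean; zero-depth bases are counted in
`N` (uncovered target bases must hurt the score); depths are not capped
before normalization, so excess coverage piled above the mean is wasted
rather than rewarded. `E` is invariant under scaling all depths by a
constant, and moving depth from a below-mean base to an above-mean base
never increases it.

## The synthetic experiment

**Reference and designs.** One random-DNA chromosome carries `n_targets`
exon-like targets with log-normal lengths (median 120 bp — the median
human exon length — σ_log = 0.35, minimum 50 bp) plus `n_long_targets`
targets of 1000–1600 bp emulating long exons, separated by 200–600 bp
gaps. All targets form the *extended* design; a random ~2/3 subset
(flagged "coding") forms the *core* design, so the core is contained in
the extended design by construction — emulating a coding exome kit
nested inside a +UTR kit. Capture baits of 120 bp tile each target from
its start with a 60 bp inter-bait gap; targets longer than 180 bp thus
acquire periodic bait-free "valleys", the mechanism behind the
mountain-valley depth profile.

**Inserts and capture.** Insert lengths are drawn from a normal
distribution with configurable peak and standard deviation, truncated to
[30, 2000] bp and rounded — the simplest unimodal peaked model;
real libraries show unimodal peaked insert distributions, and the peak
is the quantity of interest. Fragment midpoints are uniform over the
genome; a fragment is retained iff it overlaps a single bait by at
least `capture_min_overlap` (default 40 bp), except a uniform
`off_target_rate` (default 2 %) retained unconditionally. This hard
threshold-plus-leak model reproduces the qualitative geometry of
enrichment (on-bait peaks, inter-bait valleys, off-target background)
without modelling hybridization thermodynamics. PCR duplicates are
exact-coordinate copies appended at rate `duplicate_rate` (default 5 %),
matching the coordinate-based deduplication used downstream.

**Reads.** Each fragment is sequenced as a 2×101 pair: read 1 is the
insert's 5′ prefix on the forward strand, read 2 the reverse complement
of its 3′ suffix. Inserts shorter than a read run into a fixed TruSeq
adapter prefix (so the trimming stage is exercised). Per-molecule
alternative alleles are injected at SNV positions with probability
`allele_fraction` (default 0.5, heterozygous); duplicates inherit their
template's alleles. Every base is substituted with probability
`base_error_rate` (default 10⁻³). Qualities follow a two-level profile:
Q37 except the last 8 cycles at Q11, giving the Q20 quality trimmer
something real to do. Each stage draws from an RNG sub-stream derived
from `(seed, subclone, stage)`, so outputs are byte-reproducible and
adding fragments does not shift read errors.

**Subclones.** All subclones of an experiment share one set of SNVs
(default 30) and carry a few private SNVs each (default 4),
`allele_fraction` 0.5. Private variants are planted at the centers of
inter-bait gaps — the low-coverage valleys — because the question is
whether short-insert libraries miss exactly those.

## Stage chain

simulate → trim → dedup → merge → coverage → evenness → variants:

* **Trim**: 3′ bases below Q20 are removed, then adapter read-through
  (a full adapter occurrence anywhere, or a 3′ suffix equal to an
  adapter prefix of ≥ 4 bases); the two rules iterate to a fixpoint so
  trimming is idempotent. Reads under 20 bp are discarded (with their
  mate).
* **Dedup**: among pairs with identical truth outer coordinates one is
  kept — highest total base quality, ties to input order.
* **Merge**: all relative placements of revcomp(r2) against r1 with
  ≥ `min_overlap` (default 6) overlapping bases are scanned, including
  read-through placements where a mate extends past the other's outer
  end; the placement maximizing matched bases wins, subject to a
  mismatch fraction ≤ 0.08. Read-through overhangs are adapter remnants
  and are dropped; within the overlap the higher-quality base is kept
  (tie → r1) with the max of the two qualities. Pairs with no
  acceptable overlap pass through unmerged.
* **Coverage**: depth is accumulated only over footprint bases. In
  *unmerged* mode each pair contributes its two (trimmed) read
  segments, double-counting the mate overlap — what a naive depth tool
  reports; in *merged* mode each merged read contributes one segment
  (pass-throughs contribute their two reads). Summaries: mean coverage
  `C`, fraction of bases ≥ 10×, evenness `E`, each on the arm's own
  ("respective") design and on the common design.
* **Variants**: pileups at the union of planted SNV sites from the
  merged stream; a site is called iff depth ≥ 10 and ≥ 2 reads support
  the most frequent non-reference base (both thresholds inclusive; only
  the top alternative base is considered). Missed mutations are counted
  per sample against the union of all samples' calls and, separately,
  against the planted truth. The depth-discordance filter flags sites
  ≥ 20× in every sample of one arm and < 10× (strict) in every sample
  of the other, in either direction.

## The two-arm experiment

Arms differ **only** in their insert-length distribution (a confound
guard enforces this; everything else, including the read budget, is
matched). Mirroring a core-vs-extended kit comparison, the short-insert
arm (130 bp peak) is analysed on the extended design and the
long-insert arm (170 bp peak) on the core design; the common design is
their intersection. The headline orderings — higher evenness and
fraction-≥10× for the long-insert arm, higher raw unmerged mean
coverage for the short-insert arm, fewer missed valley variants for
long inserts, and an evenness gain from merging — are asserted as mean
behaviour over five seeds.

Cross-arm mean-coverage and fraction-≥10× comparisons are made on the
common design: at matched read budgets, normalizing each arm by its own
footprint (the footprints differ by ~1.5×) would fold the footprint
ratio into the comparison for reasons unrelated to insert length.
Evenness orderings hold on both respective and common designs and are
reported for both.

## Default problem sizes

| parameter | default | why |
|---|---|---|
| targets | 200 (one ≥ 1 kbp) | enough short/long-target mix for stable medians; ~27 kb footprint |
| read pairs per sample | 6,000 | ≈ 25–30× on-target unmerged depth — the working regime where a 10× threshold is informative |
| subclones per arm | 2 | the minimal isogenic comparison |
| insert peaks | 130 vs 170 bp | the contrast under study |
| insert sd | 15 bp | free parameter (peaks, not spreads, are what library QC reports); narrow enough to keep the two arms distinct |

A full two-arm, five-seed run takes under a minute on one CPU.

## What the simulator does not emulate

GC-dependent capture efficiency; sequencer de-phasing error curves
(qualities are a two-level profile); indels and structural variants;
bait-balancing differences between kits; read mapping (truth coordinates
replace alignment, so mapping ambiguity and soft-clipping artifacts are
absent). Consequently, passing tests demonstrate the *geometric*
mechanism linking insert length to coverage evenness and valley
false-negatives, not absolute real-data values: in particular, real
per-sample join rates and trimming percentages depend on library
chemistry and are not reproduced here, and real evenness values depend
on the full bait design of the kit used.

## Numerical choices and degenerate inputs

Zero mean coverage makes normalized coverage, and hence `E`, undefined —
an error per profile, reported as NaN cells in grid reports so one empty
cell cannot sink a table. Insert-peak estimation is the mode of the
1-bp histogram, ties to the smallest length. The merge scan orders
candidate placements by decreasing overlap and stops once no remaining
placement can beat the best matched-base count; equal-match ties keep
the larger overlap. Dedup and merge tie-breaks are fixed (input order /
r1's base) so all outputs are deterministic; report files are written
with pinned float formatting, making re-runs byte-identical.
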