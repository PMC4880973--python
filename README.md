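# evencap

Insert-length effects on hybrid-capture coverage evenness and variant
detection.

In whole-exome and other hybrid-capture paired-end sequencing, the DNA
insert is often shorter than the combined read length (2×101 bp), so the
two mates overlap and re-sequence the same bases, and fragments cluster
tightly on capture baits. The result is a "mountain-valley" depth
profile along long exons: high peaks on baits, shallow valleys between
them — and heterozygous variants sitting in valleys fall below calling
thresholds even when mean coverage looks ample. `evencap` is a synthetic
hybrid-capture experiment generator plus the analysis stack needed to
quantify this: interval algebra over nested capture designs, read
trimming/overlap-merging/deduplication, footprint-restricted depth
profiles, the coverage evenness score, and cross-subclone
missed-mutation accounting. It is aimed at people designing capture
libraries or benchmarking coverage-uniformity metrics.

## The statistic

With per-base on-target depths `c_j`, mean `C`, and normalized coverage
`u_j = c_j / C`, define the survival curve `D(x) = frac{j : u_j ≥ x}`.
The **evenness score** is the area under `D` between 0 and 1,

    E = ∫₀¹ D(x) dx = (1/N) Σ_j min(u_j, 1),   0 ≤ E ≤ 1,

which equals 1 only for perfectly uniform coverage, penalizes uncovered
and under-covered bases, and gives no credit for depth piled above the
mean. Companion metrics: mean coverage `C`, fraction of target bases
covered ≥ 10×, the mate-overlap redundancy `Σ max(0, 2R − L_i) / Σ 2R`,
and per-sample missed-mutation counts against the union of calls across
isogenic samples (caller: depth ≥ 10 and ≥ 2 alternative reads).

## Worked example

Run the default two-arm experiment — 130 vs 170 bp peak inserts, matched
read budgets (6,000 pairs/sample), two subclones per arm, nested
core/extended target designs with tiled baits:

```python
import evencap
from evencap.pipeline import format_summary

report = evencap.run_experiment(evencap.ExperimentConfig(seed=1))
print(format_summary(report))
```

```
evencap experiment summary
==========================

arm=130bp  mode=merged   design=common     C=  17.26  E=0.8949  frac>=10x=0.9545
arm=130bp  mode=merged   design=respective C=  17.17  E=0.8916  frac>=10x=0.9533
arm=130bp  mode=unmerged design=common     C=  25.11  E=0.8933  frac>=10x=0.9873
arm=130bp  mode=unmerged design=respective C=  25.00  E=0.8910  frac>=10x=0.9869
arm=170bp  mode=merged   design=common     C=  19.39  E=0.9029  frac>=10x=0.9851
arm=170bp  mode=merged   design=respective C=  19.39  E=0.9029  frac>=10x=0.9851
arm=170bp  mode=unmerged design=common     C=  21.42  E=0.9012  frac>=10x=0.9909
arm=170bp  mode=unmerged design=respective C=  21.42  E=0.9012  frac>=10x=0.9909

union of called sites: 37
  130bp:subclone1: missed vs union = 6, vs planted truth = 3
  130bp:subclone2: missed vs union = 7, vs planted truth = 4
  170bp:subclone1: missed vs union = 3, vs planted truth = 0
  170bp:subclone2: missed vs union = 4, vs planted truth = 1
depth-discordant sites: 0
```

Reading it: the short-insert arm has the *higher* raw unmerged mean
coverage on the common design (25.1× vs 21.4× — its reads double-count
mate overlap and hug the baits) yet the *lower* evenness (0.893 vs
0.901) and the lower fraction of bases at ≥ 10× (0.987 vs 0.991), and it
misses roughly twice as many of the union mutations (13 vs 7) — the
private variants planted in inter-bait valleys. Merging overlapping
mates raises evenness in both arms. The same experiment is available
from the shell (`evencap run --outdir out --seed 1`), along with
subcommands for the individual stages (`evencap intervals|simulate|
trim|merge|coverage`).

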