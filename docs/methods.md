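# Methods

## Quality model and operator definitions

A PHRED score `Q` asserts a base-call error probability `p = 10^(-Q/10)`.
Both quality-control operators share one boundary convention: a base is
*retained* iff `Q >= min_q` (default 20, i.e. error <= 1 %). Fixing the
boundary identically for masking and trimming makes the two arms directly
comparable and gives the subset property used in the tests: the set of
bases surviving trimming is always a subset of the bases left unmasked at
the same cutoff.

**Masking** substitutes the mask character (default `'N'`, configurable to
`'n'`; both are accepted on input) at every failing position. Qualities are
left untouched in the output FASTQ — no information is destroyed beyond
the base identity itself, and the operation is idempotent because the
failing set depends only on the (unchanged) qualities.

**Dynamic trimming** keeps the longest contiguous run of retained bases
and discards the read if that run is shorter than `min_len` (default 25).
When two runs tie for longest, the 5′-most is kept: a deterministic choice
consistent with Illumina quality degrading 3′-ward. `min_len` applies to
the kept run, so a raw read shorter than `min_len` can never survive.
Zero-length reads pass through masking unchanged and are discarded by
trimming.

## Evaluation statistics

False-positive rate `FP/(FP+TN)` is defined over validated negative sites,
false-negative rate `FN/(FN+TP)` over validated positive sites. Both are
scale-invariant and undefined (an error, not 0) when their denominator is
empty.

`fisher_exact` enumerates the hypergeometric distribution of the first
cell with all margins fixed, in log-factorial (`lgamma`) space. This is
exact and stable both at verification-panel scale (n ≈ 170) and at
SNP-catalogue scale (n ≈ 3×10⁵). Sidedness: `greater` = P(X ≥ a),
`less` = P(X ≤ a), `two_sided` = total probability of tables no more
likely than the observed one (the R convention). The default for
comparing false-positive counts is one-sided `greater` with the
no-quality-control arm in row 1 — verified against independent
enumeration and against the published panel comparisons before being
frozen as the default.

`chi_square` computes the Pearson statistic with independence-model
expected counts (uniform expected counts for a one-row table) and takes
the p-value from the upper χ² tail; the Yates continuity correction is off
by default and available as a flag. The asymptotic p-value is only
trustworthy for large-count tables: under the margin-fixed permutation
null the observed table carries a discrete atom of probability mass, so
for small tables the exact test — not χ² — is the right tool (our
acceptance check therefore validates χ² against a mid-p Monte-Carlo
permutation null at catalogue-scale counts, where the approximation is in
its valid regime).

## Synthetic data generator

`simulate_dataset` emulates the statistical skeleton of a 76-cycle
single-end resequencing run:

| parameter | default | meaning |
| --- | --- | --- |
| `ref_length` | 100,000 bp | uniform-random A/C/G/T reference |
| `n_snps` | 100 | planted homozygous substitutions |
| `ems_bias` | on | restrict SNPs to G→A / C→T (EMS transition chemistry) |
| `read_length` | 76 | fixed read length, single-end |
| `mean_coverage` | 22× | read count = `round(coverage · ref_length / read_length)` |
| `q_high`, `q_low` | 38, 12 | per-cycle mean PHRED at first/last cycle, linear in between |
| `q_sd` | 3 | Gaussian noise around the per-cycle mean |

Emitted scores are rounded and clamped to [2, 41] (the modern Illumina
range). Each base is then miscalled with probability exactly `10^(-q/10)`
of its *emitted* score, substituting uniformly among the other three
bases — a sequencer emits concrete calls, so the simulator never writes
`N`. Minus-strand reads are reverse-complemented with the quality vector
applying in sequencing order. All draws come from one `numpy` PRNG stream
seeded by `SimConfig.seed`, so a (seed, config) pair fully determines the
dataset. Truth output uses 0-based coordinates internally and in the
placements TSV; the truth VCF is 1-based per that format's convention.

The linear-decay profile is a deliberate simplification: it produces the
low-quality 3′ tails the operators act on without modelling
platform-specific error motifs, GC bias, duplicates, indels, heterozygous
sites or paired ends. The defaults give roughly the last fifth of each
read a sub-Q20 tail (≈25–30 % of bases masked), which is aggressive
relative to a good modern run but exercises both operators strongly. The
SNP density (100 per 100 kb) is likewise desk-scale — denser than an EMS
mutant genome — so that false-negative statistics have support at small
reference sizes.

## End-to-end comparison and its scope

`compare_methods` simulates once, pushes the identical read set through
the no-QC / trim / mask arms, piles reads up at their **true** placements,
and calls a homozygous SNP wherever a non-reference base reaches
`hom_frac` (default 0.8) of a column with depth ≥ `min_depth` (default 3),
ties broken alphabetically. These caller thresholds are this package's
choices for a transparent baseline; no attempt is made to reproduce a
production haplotype caller.

Because alignment is bypassed, the mechanism by which masking reduces
false positives in real pipelines — low-quality mismatches steering the
aligner or the caller wrong — is only partially present: with true
placements and 22× coverage, scattered miscalls essentially never reach
80 % of a well-covered column, so all three arms typically score FP = 0
and the comparison's value at desk scale is (a) exact parameter recovery
under a clean profile and (b) the accounting identities (masking preserves
read count; trimming's FN excess traces to SNP columns whose depth fell
below `min_depth`). Assessed negatives are *all* non-SNP reference
positions, a far larger denominator than a Sanger-validated candidate
panel, so absolute FP rates are not comparable to panel-based ones — only
orderings and the pairwise Fisher tests are.

## Numerical and interface choices

* Quality encodings: Phred+33 default; autodetection classifies any ASCII
  code < 59 as Phred+33, all codes in [64, 104] with some > 74 as
  Phred+64, and resolves the ambiguous overlap to Phred+33 with a logged
  warning. Gzip is detected from magic bytes, never the filename.
* The FASTQ parser accepts only the 4-line dialect; wrapped records are a
  parse error (with line number), not silently joined. Bases outside
  {A,C,G,T,N} pass through unchanged but are counted in the parse summary.
* Gzip output is written with zero mtime and no embedded filename so that
  identical inputs give byte-identical outputs.
* Rates are displayed as percentages to one decimal and p-values to two
  significant figures; full precision is always available programmatically.
* Exit codes: 0 success, 1 usage error, 2 data/parse error.

## Known limitations

* No aligner in the loop: aligner-dependent effects (global vs local
  alignment, mapping-rate differences between masked and trimmed reads)
  are out of scope by design.
* The naive caller has no genotype likelihoods, no indel support and no
  mapping-quality notion; FN behaviour under heavy masking is governed
  purely by the depth gate.
* The simulator's quality profile is a stand-in, not a fit to any
  particular instrument run.
* χ² p-values for small-count tables are approximate; use
  `fisher_exact` there (the package's default for panel-scale
  comparisons).
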