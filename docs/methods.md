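# Methods

## Coordinate model

All internal coordinates are 0-based half-open; the GFF3 and TSV
annotation dialects (1-based inclusive) are converted only at the I/O
boundary. A circular replicon encodes an origin-spanning feature as
`end <= start`; `end > L` is never used, so the encoding is canonical and
checkable. "Coding" is strand-agnostic: a position is coding when covered
by at least one gene on either strand, which makes the coding/intergenic
split a true two-way partition whose site counts sum to the total. Gene
footprints include the stop codon, hence mean protein length =
mean gene length / 3 − 1 codons.

## The stem-loop site model

A site is `left-arm + loop + right-arm` where the left arm equals the
reverse complement of the right arm up to `max_mismatches` substitutions.
Bulges and asymmetric loops are deliberately excluded: with substitutions
only, the scanner is a finite combinatorial object whose output can be
compared, case by case, against a brute-force enumeration of every
(loop start, loop length, stem length) triple — the test suite does
exactly that. N never pairs and always counts as a mismatch.

Defaults: stem ≥ 10 bp, loop 3–8 nt, ≤ 1 mismatch. These describe a
strong terminator-like hairpin; any genome-wide total is a function of
the descriptor, so the resolved parameters are embedded in every report
and all limits are configurable per run.

The scanner enumerates loop placements `(a, l)` and extends the stem
outward while the mismatch budget holds; the maximal extension per
placement is the only candidate that placement contributes. Candidates
sharing a loop midpoint (the same physical hairpin seen at different
stem/loop partitions) are collapsed: maximal stem, then fewest
mismatches, then smallest loop, then smallest left-arm start. The loop
midpoint (`center`, left-rounded for even loops) is the single coordinate
used downstream; classification by center rather than by any-overlap
guarantees the two-way partition. The center-based rule and the
alternatives considered (full containment, any overlap) differ only for
sites straddling a gene boundary, which are rare at realistic densities.
The hot loop is optionally JIT-compiled with numba; a pure-Python
fallback runs the identical code path.

## Hairpin folding and cleavage placement

`fold_hairpin` maximizes Watson–Crick pair count over every outer-pair
placement of a single contiguous stem closed by a loop of ≥ 3 nt — no
G:U pairs, no energy model, no multi-branch structures. Ties prefer the
smaller left index, then the larger right index (shortest 3′ tail). This
is intentionally a structural cartoon: it reproduces the stem/loop
partition of a short 3′ UTR well enough to ask whether an observed
cleavage position falls in the loop, in the stem, or outside, which is
the only question the pipeline asks of it. Thermodynamic folding is out
of scope.

## Occupancy statistics

Expected counts under uniform placement are `round_half_even(n·f)`
coding and the remainder intergenic, kept integer so the observed and
expected rows form a bona fide 2×2 table. The Fisher exact test is
implemented from scratch: hypergeometric log-probabilities via
`lgamma`, two-sided p as the sum over tables (same margins) whose
probability is ≤ the observed one within a relative factor 1 + 1e−7.
The construction "observed row vs expected row" mirrors how such tables
are usually printed, but the expected row is a deterministic function of
the observed total, not an independent sample; the report flags this and
always includes the exact binomial p (`scipy.stats.binomtest`) of the
observed coding count at success probability f, which is the
statistically conventional test and is the quantity used in the
calibration checks. One known arithmetic quirk is documented rather than
corrected: an expected row of (204, 22) for 226 sites is consistent with
a coding fraction of ≈ 0.902, not with exactly 0.90 (`round(226·0.90)` =
203); the counts-only mode therefore takes the fraction explicitly.

The Pearson test uses the product-moment formula with the two-sided t
transform `t = r·sqrt((n−2)/(1−r²))` on n−2 degrees of freedom.

## Metagene profiles

For each gene the anchor is the first nt of the start codon or the last
nt of the stop codon; offsets are signed in the gene's reading direction
(+1 = downstream), computed modulo L on circles with the shorter arc.
Each (gene, site) pair within ±window (default 300 nt, 1-nt bins) counts
once. The stratum is the orientation of the neighboring gene — upstream
for start anchors, downstream for stop anchors, nearest boundary in the
relevant genomic direction, found circularly; on a linear genome a gene
with no neighbor on that side is skipped.

## Proteome processing

Fixed order: peptide filter (≥ 2 peptides) → column-sum normalization →
summed-score ranking → ortholog pairing. Division by the column sum is
the simplest reading of "column-wise normalized" and makes ranks
invariant to any per-column rescaling of the raw intensities (property-
tested); ties receive average ranks, the standard choice for rank
correlation. Ranking is pooled over viral and host proteins within each
virion, matching a whole-particle ranking; the correlation is restricted
to viral ortholog pairs, while proteins detected in a single virion are
excluded from the correlation but reported in the shared/unique
breakdown.

## Synthetic data

The genome generator lays out `n_genes` non-overlapping genes (lengths in
whole codons, Dirichlet-jittered around the mean) and gaps summing
exactly to the target coding fraction, assigns strands i.i.d., plants
palindromes (random arm + exact reverse-complement arm, loop drawn
uniformly from the scan range) into coding or intergenic free space with
per-compartment Bernoulli(p_intergenic) assignment, then applies a random
rotation so genes and sites can span the origin. Defaults mirror the
study conditions at 50 kb scale: coding fraction 0.90, mean gap ≈ 88 nt,
GC 0.43, 30 planted sites of which ~2/3 intergenic. An `after_stop` mode
places intergenic sites at exponentially distributed offsets downstream
of a random gene's stop codon instead of uniformly.

Background palindrome-freedom is enforced by rejection: the genome is
scanned and any unintended site has its footprint redrawn (or, when the
site is induced by planted content itself, the touching planted sites are
rewritten in place), iterating until the scan reports exactly the planted
centers. Planted perfect stems may extend by one tolerated mismatch into
their flanks, so truth matching is by loop midpoint; 1-nt guard bases
prevent silent extension by a perfect pair. What the generator does *not*
model: codon structure and usage, GC skew, repeat families, overlapping
genes, and real terminator sequence biases — so passing tests demonstrate
correctness of the detection and statistics machinery, not that any real
genome obeys the hairpin rule.

The proteome generator draws shared log-abundances from a bivariate
normal with correlation `true_rho` (σ = 1.5 log-units, spanning a few
orders of magnitude as iBAQ values do), multiplies per-replicate
log-normal noise (σ = 0.2), and appends unshared "bystander" entries at
reduced abundance. Note rank correlations estimate the Spearman
transform `6/π·asin(ρ/2)` of the generating ρ, a downward bias of ~0.01
at ρ = 0.9; tolerance in the recovery checks accounts for it.

## Problem sizes and numerical choices

Property checks run at sizes where the brute-force oracles stay exact
and fast: scanner equivalence on ≤ 2 kb genomes, Fisher enumeration on
totals ≤ 200 (exact rational arithmetic), recall on 8 kb genomes with 20
planted sites over 100 seeds, power at 80 kb / 200 sites over 100 seeds,
null calibration at 50 kb / 200 sites over 200 seeds — the binomial p is
discrete at this n, so "approximately uniform" is asserted by a KS test
at α = 0.01 rather than any finer criterion. All simulations are driven
by one `numpy.random.default_rng(seed)` stream per generator call;
reports contain no timestamps, so identical inputs give byte-identical
outputs.

## Known limitations

- No bulged or G:U-containing stems; hairpins with such features are
  invisible to both the scanner and the folder.
- The maximality rule keeps one site per loop midpoint; two genuinely
  nested hairpins sharing a midpoint are reported as one.
- Circular offset arithmetic uses the shorter arc, which is ambiguous
  only when the window approaches L/2 (not a practical regime).
- The counts-only statistics mode trusts its inputs; it cannot detect an
  inconsistent (counts, fraction) combination beyond the rounding check
  described above.
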