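# Methods

This note records the models, parameter choices and numerical decisions
behind `ystrkit`, and what the synthetic studies used by the test suite
and `scripts/acceptance.py` do and do not demonstrate.

## Tandem-repeat discovery

The scanner works on the k-periodic self-match structure of the
sequence: position *i* supports period *k* when `seq[i] == seq[i+k]`.
For each period *k* in 2–6 a reported region is a maximal interval
`[s, e)` whose endpoints sit on supporting positions and whose purity
`matches / (e − s − k)` is at least `min_purity` (default 0.9, i.e.
near-perfect repeats), containing no N (N breaks candidate runs).
Overlapping passing intervals of one period are merged. Three
refinements follow:

1. **Smallest-period reduction.** The repeat unit is read at the
   interval's center (edges may have absorbed impure flanking matches)
   and reduced to its primitive period, so an `(ACTACT)n` run is
   reported with period 3; regions whose unit collapses to period 1
   (homopolymers) are outside the period-2–6 scan range and are not
   reported. A region surfacing at several scan periods (a dinucleotide
   run also matches at lags 4 and 6) is merged per final period.
2. **Boundary refinement.** Interval ends are trimmed to the first/last
   clean in-phase unit, and terminal units separated from the interior
   by a full unit of mismatches (coincidental in-phase background hits)
   are dropped. Interior mismatches of impure repeats are untouched.
3. **Detection floor.** The scanner reports runs down to
   `scan_min_copies` (default 4) so that the selection tally is
   complete; *selection* applies the marker criteria: period 3–6
   (dinucleotides are excluded with an explicit reason rather than
   skipped, because their pronounced stutter makes them poor PCR
   markers), ≥ 8 copies (`min_copies`), length ≤ 100 bp (`max_len`, so
   short reads can span the locus and degraded non-invasive DNA can be
   typed), and no overlap with the PAR mask (any 1-bp overlap excludes;
   loci there are neither haploid nor male-specific). Each excluded
   locus carries exactly one reason, assigned in the priority order
   mask > period > copies > length, and |kept| + |excluded| equals the
   scan count.

Candidate intervals are capped at `max_scan_len` (2 kb) — selection
caps loci at 100 bp anyway, so this only bounds the merge search on
repeat-dense sequence. Motif labels are canonicalized to the
lexicographically smallest same-strand rotation; reverse-complement
collapsing is deliberately not applied since a single reference strand
orientation is analyzed. Tests verify the interval semantics against a
brute-force enumeration of all (start, end, period) triples on small
sequences.

This scanner is a deterministic functional substitute for
alignment-scoring repeat finders; counts on real chromosome-scale
references are not expected to match any particular external tool
region-for-region, but every locus passing the selection filters above
is found exactly (planted-recovery property).

## Haploid genotyping

Eligible reads are primary, properly paired alignments with
`mapq ≥ 10` (the ≥ matches `samtools view -q 10` semantics). A read is
*spanning* when its alignment covers the repeat tract plus `anchor_bp`
(10) on each side with no clipping inside that window. The observed
tract length is CIGAR arithmetic: reference tract length plus
insertions minus deletions inside `[start, end)`; an insertion at the
3′ boundary (reference position `end`) belongs to the tract — that is
where a net repeat-length gain sits in a left-aligned record. Indels
inside the 10-bp flank windows set the read's flank-indel flag.

The stutter emission is a fixed geometric model (defaults `p_s = 0.05`,
`ρ = 0.8`, `ε = 1e-4`): an exact length match has probability
`1 − p_s`; a slip of `u ≠ 0` whole units `p_s · ½(1−ρ)ρ^{|u|−1}`;
non-unit-multiple differences fall to `ε`, depressing the posterior
without counting toward the stutter fraction. Candidate alleles are the
distinct observed lengths; the call is the likelihood argmax under a
uniform prior (ties broken toward the reference length, then the
smaller allele, for determinism) and the posterior is the normalized
likelihood over candidates — a proper distribution by construction.
This replaces per-locus learned stutter models and haplotype
realignment: for spanning short reads over ≤ 100 bp loci the
length signal is already explicit in the CIGAR, and a fixed model keeps
calls deterministic and testable.

Genotype-level missingness (reason recorded in priority order):
no spanning reads; posterior < `q_min` (0.90, or 0.75 in low-coverage
mode); stutter-read fraction > 0.35; flank-indel fraction > 0.35 —
both fractions measured relative to the called allele, slips counted in
whole repeat units only. Site-level drops: missingness over male
samples > 0.50 (0.75 low-coverage), or any female sample with more than
two overlapping reads (strict inequality; a female at exactly two reads
is tolerated). The female rule defaults to per-sample counting, with an
aggregate mode (`female_aggregate`) summing across females behind a
switch. Coverage profiling (`depth_profile`) reports mean depth in
non-overlapping windows (≥ 100 bp) and flags runs of ≥ 3 zero-depth
windows as candidate deletions, the signature of lineage-specific
structural loss of markers.

## Haplotype analytics

Bruvo distances use real-valued repeat-unit differences (a 2-bp shift
at a period-3 locus contributes `1 − 2^(−2/3)`) rather than rounding,
avoiding arbitrary binning of flank-shifted alleles; missing data are
handled by pairwise deletion and the distance is NA only when two
samples share no genotyped locus. Genome-addition corrections for
unequal ploidy do not apply to haploid data and are omitted.

UPGMA is implemented directly with deterministic lowest-index-pair
tie-breaking; node heights are half the between-cluster average
distance, so the tree is ultrametric to 1e-9 and reproduces ultrametric
inputs exactly. The implementation is checked against an independent
brute-force average-linkage oracle on random 5-leaf matrices. Trees
reject NA distances rather than imputing: the caller restricts to
samples with overlapping loci. Node support resamples
`n_loci_per_resample` loci *without replacement* per replicate, rebuilds
Bruvo + UPGMA, and reports the fraction of replicates containing each
full-data clade; leaves always have support 1.0 and the procedure is
seeded.

Nei gene diversity defaults to the uncorrected `1 − Σp²` estimator;
the `n/(n−1)` correction and a polymorphic-loci-only averaging mode are
flags, since published panel summaries vary in both conventions and the
matching convention should be recorded per dataset. Group means exclude
loci with no data in that group; monomorphic loci contribute h = 0 by
default.

## Panel assignment

The similarity index `s = n_match / n_shared` is computed against every
member of each panel; NA comparisons (no shared loci) are discarded. A
query with fewer than two usable values against either panel stays
unassigned (the minimum-information floor; the choice of 2 is ours).
The two distributions are compared with a two-sided Wilcoxon rank-sum
test (exact for small untied samples, normal approximation with
continuity correction otherwise); p-values are adjusted across the
whole query batch (Benjamini–Hochberg by default; Holm and Bonferroni
available) and a significant query joins the panel with the larger
median similarity, median ties staying unassigned.

## Homology and in-silico PCR

Loci are extended by 200 bp of flank on each side (clipped at
chromosome ends) and compared all-vs-all by best local alignment
(match +1, mismatch −2, gap open −5, gap extend −2). Identity is
matches over alignment columns (gap columns included) and query
coverage the aligned query span over query length; both thresholds are
strict (> 0.80 and > 0.65). Only the single best local alignment per
pair is scored — multi-segment hit merging is not attempted, and
alignment-parameter sensitivity is a documented caveat rather than a
resolved question. Multi-copy markers are connected components
(single linkage, either orientation of the pair passing) of the
within-reference match graph with ≥ 2 members.

Primer binding uses Hamming matching only (no indels, matching the
practical behavior of in-silico PCR tools for short oligos; 3′-end
weighting is not modeled) with mismatch fraction ≤ 10% of primer
length — 2 mismatches pass on a 20-mer, fail on an 18-mer. Products are
enumerated from convergent site pairs on both strands, in both primer
orientations, with no product-length cap by default so the long-product
rule can operate: a pair is `locus_specific` with a single on-target
product, `acceptable` when its unique sub-10 kb product is on-target
and all others exceed 10 kb (long amplicons compete poorly against a
100–200 bp target and can be ignored in multiplex design), and
`non_specific` otherwise.

## Synthetic studies

The simulator generates the study conditions used by the tests and the
acceptance script: a reference with perfect repeats planted in vetted
repeat-free background (so scans recover planted loci and nothing
else), male genealogies whose alleles follow a single-step stepwise
mutation model, females carrying no Y-derived reads, and uniformly
placed reads that are *pre-aligned by construction* — mapping is out of
scope, so alignment noise enters only through the explicit channels:
whole-unit stutter slips of spanning reads (`p_stutter`), 1-bp flank
indels (`p_flank_indel`), and i.i.d. base errors (`base_error`). All
noise events are recorded per read in the truth table, and everything
is byte-deterministic under the seed.

Defaults, chosen once as a desk-scale analogue of a primate
resequencing panel: 80 kb chromosome; 40 loci with motif periods
weighted toward tetranucleotides (0.2/0.4/0.2/0.2 for 3/4/5/6 bp, the
composition typical of Y-STR catalogs) and 8–15 copies; ≥ 200 bp (and
always ≥ read length) of spacing so one read never spans two loci; 12
males and 4 females; 10X coverage with 150 bp reads; `p_stutter` 0.05,
`p_flank_indel` 0.02, base error 1e-3; founder alleles within ±3 repeat
units of the reference and a stepwise mutation probability of 0.002 per
locus per father→son transmission, the order of magnitude of measured
Y-STR mutation rates. Tests scale these down (30–40 kb, 8–15 loci, 2–8
samples) and the noise-free round trips use 20X with 250 bp reads so
that every locus has a comfortably positive expected spanning-read
count — with 150 bp reads a 90 bp locus leaves only a 40 bp placement
window, and a zero-spanning-read locus is a sampling event, not a
caller failure.

What the synthetic conditions do not emulate: mapping ambiguity and
reference bias, repetitive flanks, coverage heterogeneity along the
chromosome, index hopping or contamination (beyond the explicit
female-leak knob), multi-step mutations, and real stutter's dependence
on repeat length and purity. Passing round trips therefore demonstrate
the correctness of the bookkeeping, likelihood and filter cascade —
not field performance on real genomes.

## Known limitations

- The scanner's purity model annotates compound or interrupted repeats
  as single impure regions rather than structured sub-units.
- Stutter parameters are global, not learned per locus.
- Reads that only partially span a locus carry no length information
  here and are ignored; female-read counting is the only use of
  non-spanning overlap.
- Assignment supports exactly two panels; likelihood-based population
  assignment and admixture proportions are out of scope.
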