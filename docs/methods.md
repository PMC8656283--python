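# Methods

This note documents the models and procedures `uvsomatic` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical choices that affect results.

## Somatic filtering

A call is retained iff all three criteria hold, with inclusive
thresholds: tumor alternate reads ≥ `min_tumor_alt` (default 5), tumor
allele fraction ≥ `min_tumor_af` (default 0.05), and tumor AF at least
`min_tn_ratio` (default 5) times the matched-normal AF. Allele fractions
are computed from the AD field as alt/(sum of AD), not from DP, so the AF
used for filtering is always consistent with the counts used for support.
A normal AF of zero — including a normal with zero usable depth —
satisfies the ratio criterion: the ratio rule targets tumor-in-normal
contamination, and absence of any normal support is the strongest somatic
evidence available. A rejected call reports only its first failing
criterion in the fixed order (support, AF, ratio) so that reason codes
are deterministic. Germline-database and panel-of-normals sites are
handled as precomputed site lists keyed by (chrom, pos, ref, alt); calls
matching a list are flagged and excluded from all downstream counting.
No population-frequency cutoff is applied here — whatever produced the
site list owns that decision.

## Region classification and coding effects

Each position receives exactly one region class with fixed priority
CODING > SPLICE_SITE > UTR5 > UTR3 > INTRON > INTERGENIC when genes
overlap; exclusive classes keep per-region tallies additive. Splice
sites are intronic positions within ±`splice_window` (default 2) nt of an
exon boundary and are counted with coding mutations throughout.
Intronic positions within `intron_prox_window` (default 100) nt of a
boundary are INTRON; deeper positions are INTRON_DEEP and excluded from
all tallies, since exome capture does not cover them. The full annotated
3'UTR is classified UTR3 with no distance cutoff: recurrently mutated
3'UTR positions occur well beyond 100 nt downstream of the stop codon, so
the ~100 bp "captured 3'UTR" notion is modelled as simulator coverage
(`utr3_prox_window`), not as a classification rule.

Effects are predicted on one canonical transcript per gene — the longest
CDS, overridable — because multi-transcript effect sets would make
"nonsynonymous in ≥ N samples" ambiguous. Substitutions are translated
through the standard genetic code on the coding strand, retranslating
only the touched codons (the test suite checks this fast path against
full mutant-CDS translation). Indels are typed purely by net length
(frameshift unless divisible by 3); transcripts whose CDS length is not a
multiple of 3 are excluded from effect prediction and logged.

## Double substitutions and contexts

Runs of directly adjacent same-sample SNVs are merged transitively
*after* filtering: length-2 runs become DBS records labelled as HGVS
`delins` (CC>TT and its reverse-complement GG>AA flagged as the UV
hallmark), longer runs become a single multi-nucleotide `delins` typed
outside the DBS category and logged. Merging after filtering means a DBS
whose two constituent calls both pass is counted once, next to
post-filter totals. Trinucleotide contexts use the standard 96-channel
encoding: purine-reference substitutions are reverse-complemented
(flanks swapped and complemented) so every channel has a pyrimidine
reference; channel order is C>A, C>G, C>T, T>A, T>C, T>G × 5' base ×
3' base, each A/C/G/T.

## Signature refitting

Per-sample profiles are refit against a predefined signature matrix by
nonnegative least squares on frequency-normalized profiles, then
renormalized to sum to one. NNLS was chosen because it is deterministic,
convex, and standard for signature refitting; no de novo extraction is
attempted. Samples with fewer than `min_mutations` SNVs (default 30) are
excluded — with so few draws the 96-channel profile is mostly empty and
any fit would be noise. The built-in two-signature matrix (UV-like:
C>T at 5'-pyrimidine contexts with a small C>A remainder;
alkylation-like: C>T at 5'-purine contexts with a small T>C remainder) is
synthetic, designed for identifiability (cosine similarity < 0.1 between
rows); real signature matrices are accepted as TSV.

## Recurrence

A hotspot is a position mutated in at least `hotspot_min_samples`
(default 3) distinct samples; mutated positions at adjacency distance ≤
`merge_distance` (default 1) merge transitively, and a merged cluster
qualifies on the union of its carrier samples. A sample counts once per
hotspot regardless of how many mutations it contributes; a DBS
contributes both its positions. Frequently mutated genes are tallied per
region with distinct-sample counts: coding requires nonsynonymous
mutations (splice-site counted as coding) in ≥ 5 samples, either UTR ≥ 4,
introns ≥ 5 counting only mutations within `intron_recurrence_window`
(default 40) nt of an exon boundary. Genes on a user-supplied
hypermutated-passenger exclusion list are dropped before thresholding;
the package ships no curated list of its own.

## Functional-mutation-bias driver test

For each gene-region with mutations, the observed statistic is the
arithmetic mean of per-mutation functional scores: an SNV scores its
(position, alt) entry; a DBS the max over its scored positions; an indel
the max over `max_consecutive` (default 7) positions from its anchor.
The null draws the same number of position–allele pairs from the region
without replacement — a region position mutates at most once per
simulated sample set — with probability proportional to the cohort-wide
frequency of each pair's trinucleotide channel, so the null inherits the
cohort's mutational signature; pairs on zero-frequency channels are
unsampleable. Sampling uses the Gumbel top-k construction for speed and
exact seed reproducibility. The empirical p-value is
(1 + #{null ≥ observed}) / (1 + n_iterations) — the pseudocount keeps
p > 0 and the inclusive tie rule is conservative. Benjamini–Hochberg
correction runs separately within each region class (CDS, 5'UTR, 3'UTR,
intron are four separate analyses), and tiers are q < 0.025
(significant) and q < 0.01 (highly significant).

Note an inherent resolution limit: with n iterations the smallest
attainable p is 1/(n+1), so with m tested regions per class the smallest
attainable rank-1 q is m/(n+1). At the default 1000 iterations a class
with more than ~25 tested regions cannot produce q < 0.025 no matter how
extreme the signal; either raise `n_iterations` or test fewer regions.
The driver-power fixtures in the tests use compact genomes (20 genes) and
sparse backgrounds so that each planted driver's region contains
predominantly its planted mutations — which is the regime the test is
about; dense backgrounds dilute the observed mean with passenger scores.

## Cohort summary and statistics

Counts and percentages are reported per region (all, coding incl. splice
sites, noncoding, introns, 3'UTR, 5'UTR, intergenic) × type (single
substitution, double substitution, short indel < 4 nt). Percentages
round half-up to one decimal. Coverage and alternate-allele fraction are
unweighted means over mutations (mutation-weighted, not
sample-weighted). Burden is coding-region mutations per Mbp of coding
territory, with the territory a configuration input. Fisher's exact
test (two-sided, hypergeometric) is delegated to scipy; the tests verify
agreement with an exact integer enumeration oracle to < 1e-12 over all
small tables, and the odds ratio is the sample (a·d)/(b·c) with infinity
when b·c = 0.

## MLPA copy number

Each probe signal is divided by the geometric mean of the control-probe
signals of its run, the tumor normalized value by the matched-normal
normalized value, and the ratio multiplied by 2, so diploid reads 2.0, a
single-copy loss 1.0, a single-copy gain 3.0. The geometric mean makes
the normalization exactly invariant to rescaling all signals of a run by
any positive constant. Default call thresholds are loss ≤ 1.6 and gain ≥
2.4 — ±20% bands around the integer copy states, explicit here because
bar-plot presentations of such data typically carry no numeric cutoff.
Control probes with nonpositive signal abort the sample rather than
being silently dropped.

## Synthetic data generator

The generator emulates the study conditions of a UV-driven 27-sample
tumor/normal exome cohort on a compact genome:

- **Genome**: one contig (default 900 kb), 120 multi-exon genes on both
  strands; CDS built from non-stop codons with a terminal stop and length
  divisible by 3; UTRs of 60–150 / 150–300 nt; introns of 250–500 nt.
- **Coverage emulation**: mutations are placed only in exome-like
  windows — CDS, 5'UTR, the proximal 100 nt of the 3'UTR, introns within
  100 nt of a boundary, and 150 nt intergenic flanks.
- **Mutation loads**: per-sample counts are lognormal (median ~1.7k,
  cohort ~45–50k); two near-empty samples (~10 mutations) emulate the
  sparsely mutated samples such a cohort contains, and are excluded from
  signature fitting downstream.
- **Signatures**: per-sample UV weights are Beta-distributed with mean
  0.72; one sample is alkylation-dominant (UV weight 0.35). SNV channels
  are drawn from the sample's mixture and mapped to genomic positions
  whose context matches the channel, so UV C>T lands at dipyrimidines by
  construction.
- **Types**: double substitutions are emitted as two adjacent C>T (or
  G>A) calls at CC/GG dinucleotides, at 3.7% of events; short indels
  (1–3 nt) at homopolymer runs ≥ 3, at 1.8%; random SNV placement blocks
  accidental adjacency so realized type fractions match the configured
  ones to within sampling error.
- **Read support**: depths are negative-binomial around 180×; tumor AFs
  Beta with mean 0.35; supports are drawn so every true call passes the
  default filters, while spiked artifacts (low support / low AF / low
  tumor-normal ratio) fail them and spiked germline/panel sites pass the
  filters but appear on the emitted site lists.
- **Planted truth**: hotspots (configurable region, width 1–2, carrier
  count), driver regions (mutations placed at planted high-score
  positions of one gene-region per driver), and chromosome-arm CNAs in
  the MLPA signals (signal × copies/2 × lognormal noise, controls
  unaffected). All truth is emitted as machine-readable TSVs.

All randomness flows from one seed through fixed-order spawned
generators, so every emitted file is byte-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genome-scale territory (the compressed genome
makes background recurrence far denser than a real exome, so hotspot
*counts* are not comparable, only hotspot *recovery*); mapping and
calling artifacts beyond the three spiked classes; germline variation;
subclonal structure and copy-number-driven AF shifts; real signature
catalogs (the two built-in signatures are idealized); and real
functional-score distributions (background scores are i.i.d. Beta, so
score autocorrelation along the genome is absent).

## Problem sizes used in tests

The default end-to-end check runs the full 27-sample, ~45k-mutation
cohort twice and compares output checksums (~1 minute). Unit and
property tests use 4–12-sample cohorts on 120–260 kb genomes, chosen so
the whole suite stays interactive (~3 minutes) while every planted
feature is still exercised through the real pipeline.

## Known limitations

- HGVS labels cover substitutions, delins, deletions and insertions on
  the canonical transcript only; events spanning past a transcript edge
  get an empty label rather than an extrapolated one.
- The driver test is a simplified functional-bias method: it honors the
  amean statistic, signature-complement resampling, and the
  max-consecutive indel rule structurally, but is not a reimplementation
  of any specific tool's internals, and empirical p-values bound the
  attainable q as described above.
- Which transcript anchored any published annotation is generally
  unknowable from outside; the longest-CDS convention here is a
  deliberate, overridable default.
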