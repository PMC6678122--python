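# Methods

This note documents the models, rules and numerical choices behind
`seedmir`, the assumptions they rest on, and what the synthetic-data tests
do and do not demonstrate about real data.

## Study design being modelled

A bulk small-RNA-seq experiment over three seed developmental phases
(I embryogenesis, II seed filling, III desiccation), three biological
replicates each, sequenced as nine libraries (`MpSI-1` … `MpSIII-3`).
Reads are profiled against a de novo assembled unigene transcriptome; there
is no genome.  All coordinates in the package are therefore transcriptomic,
1-based and inclusive at the interfaces, and only the sense strand of
unigenes is scanned for precursors and target sites (transcripts are
single-stranded mRNA).

## Read preprocessing

Vendor small-RNA filters are rarely published, so every rule is declared
and configurable (`preprocess.filter_and_trim`), applied per read in this
order:

1. **low quality**: more than 20 % of bases below Phred 20 (Phred+33);
2. **5′-adapter contamination**: the last 8 nt of the 5′ adapter occur
   within the first 10 read positions;
3. **3′ adapter**: the first occurrence of the adapter's first 8 nt marks
   the insert end; reads without it are dropped (`require_adapter3=False`
   re-filters already-trimmed inserts idempotently);
4. **polyA**: insert ≥ 80 % A, or ending in ≥ 10 consecutive A;
5. **length**: insert outside 18–30 nt (the gel-excision range) is dropped,
   short and long counted separately.

Counts per removal class plus clean reads always sum to raw reads, and
collapsing conserves reads (`Σ tag counts = clean reads`).

## Bundled folding engine

Precursor evaluation needs thousands of deterministic folds plus an
enumerable oracle, so the package ships its own single-stem
nearest-neighbor engine (`fold`, `energy`):

* **Pairs**: Watson–Crick (AU, UA, CG, GC) and wobble (GU, UG).
* **Stacks**: the Turner 2004 37 °C stacking free energies for the 6×6
  pair-on-pair table, transcribed into `energy.STACK` (kcal/mol).
* **Loops**: simplified linear penalties — hairpin `5.0 + 0.25·(s−3)` for
  `s ≥ 3` unpaired bases, interior/bulge `2.2 + 0.5·u` for `u` total
  unpaired bases, at most 10 per side.  No dangles, no coaxial stacking,
  no multibranch loops: every structure is a nested chain of pairs closed
  by one terminal loop, and its energy is an explicit sum.
* **MFE**: dynamic program over closed intervals (vectorized per diagonal),
  ties broken toward the smallest 5′ index, then the shortest span, then
  stacked continuation — folds are bit-reproducible.  A 300-nt window folds
  in ~60 ms.

The restriction to single stems is an intentional trade: pre-miRNA hairpins
are single stems, the engine stays exhaustively checkable (the test suite
compares it against an independent recursive reference for ≤ 60 nt and
against full structure enumeration for tiny inputs), and external folders
(e.g. RNAfold) can be substituted wherever a `FoldResult` is consumed.
Absolute energies are not calibrated against experimental folds; only
ranking and thresholds within this engine are meaningful, which is why the
MFEI threshold is also applied under the same engine that the synthetic
generator uses to validate planted hairpins.

## ncRNA screening

Tags are classified rRNA/tRNA/snRNA/snoRNA by full-length ungapped match
with at most one mismatch, on either strand, against a labelled contaminant
FASTA (`class=` header key) — a deterministic desk-scale stand-in for
BLAST/Rfam screening, implemented with a pigeonhole half-tag seed index.
Multi-class hits resolve by the fixed priority rRNA > tRNA > snRNA >
snoRNA.  Identity/coverage thresholds of the original database screens are
unknown; this rule is declared, not reconstructed.

## miRNA identification

**Conserved**: a tag is a conserved miRNA iff identical to a reference
mature sequence (0 mismatches).  Names copy the matched reference with an
`mpi-` prefix; one sequence under several reference names takes the first
in file order, the rest become synonyms; families parse from the `miRNNN`
token (unparsable names warn and get family `unknown`).

**Precursor recovery**: candidate windows of 60–300 nt (20-nt steps) are
anchored on the mature locus.  Because the mature sits on an *arm*, a
window centered on it systematically halves the stem, so for each length
the search tries mature-centered, mature-left-aligned and
mature-right-aligned windows and keeps the qualifying window minimizing
MFEI.  Qualifying means: folds with negative MFE and the mature entirely
within one arm (windows whose terminal loop straddles the mature are
rejected).  A precursor is accepted when more than 10 reads anchor the 5p
and/or 3p arm, where an arm spans from the window edge to the terminal
loop and anchoring reads are tags fully contained in it.  AMFE and MFEI
are derived quantities and recompute exactly from MFE, length and GC on
every emitted record.  Summary statistics report the mean of per-precursor
MFEIs (`mean_mfei`) and also the ratio of means (`mfei_from_means`), since
published summaries are ambiguous between the two.

**Novel**: an unannotated tag (not ncRNA-classified, not conserved) becomes
a novel miRNA when some locus it maps to yields a window passing the
declared stem-loop criteria: mature length 18–26 nt, precursor MFE ≤ −18
kcal/mol, MFEI ≤ −0.85, ≥ 16 mature bases paired (G:U counts) and ≤ 4
unpaired.  Two supplementary rules keep degradation background from
spawning spurious calls: a candidate needs ≥ 5 reads in total (real novel
miRNAs are expressed; random degradation fragments are mostly singletons),
and an accepted hairpin claims its arm intervals so lower-abundance
fragments of the same stem (isomiR-like) do not found duplicate miRNAs —
one mature per arm, highest count wins, ties broken lexicographically.
Recovered conserved precursor spans and conserved mature loci are blocked
before the search.  For speed, a locus is folded only if the neighborhood
(±250 nt) contains an exact 12-mer of the tag's reverse complement — a
hairpin cannot exist without near-complementary star sequence nearby.
Ids are `mpi-nmiRNNNN-{5p,3p}` in discovery order; one tag mapping to
several unigenes yields several precursor records under one id.

**Arm and phase bookkeeping**: 5p/3p follows the mature's position
relative to the terminal loop.  A miRNA is present in a phase iff its
three replicate libraries contain ≥ 1 read in total; presence over the
three phases defines the 7-region Venn partition, reported separately for
conserved and novel miRNAs.

## Quantification and differential expression

TPM = count / total clean reads × 10⁶ per library; zero counts are floored
at 0.01 *after* normalization so fold changes are always defined (the
floor also produces the mirrored ±log₂FC signature of phase-exclusive
miRNAs).  Phase expression is the arithmetic mean of replicate TPMs.

The original significance test is unstated, so the package declares one:
Welch's two-sample t-test on log₂(TPM) across replicates (configurable);
both groups constant and equal gives P = 1.  No multiple-testing
correction is applied to DE calls (raw P ≤ 0.05, as published practice for
this analysis), while enrichment is FDR-controlled.  The published "fold
change" columns are signed, symmetric and include sub-2 values among
DEmiRs, so they are interpreted as log₂ ratios and the "absolute fold
change ≥ 2" threshold as |log₂FC| ≥ 1.  Trend classes combine the two
successive comparisons: (+,−) bell, (−,+) V, (+,+) up-up, (−,−) down-down,
exactly one significant change single-up/down, none ns; the four
double-significant classes partition the doubly significant set by
construction.

Replicate QC computes the 9×9 Pearson matrix on log₂(TPM) (constant
libraries report missing) and PCA as the eigendecomposition of the
library-by-library covariance of the centered log₂ matrix, with component
signs fixed by the largest loading.

Published TPM magnitudes need not be bit-reproducible here: the original
normalization denominator (all clean reads vs miRNA-matching reads) cannot
be determined from the printed numbers, and this package uses total clean
reads as documented.

## Target prediction

Sites are ungapped antiparallel windows of miRNA length on the unigene
sense strand (U≡T on input).  Position 1 is the miRNA 5′ terminal base;
each position is a WC match (0), G:U wobble (0.5) or mismatch (1).  A site
passes iff: total ≤ 4; no run of > 2 mismatches anywhere; no adjacent
mismatches within positions 2–12; no mismatches at 10–11 (G:U there is
*allowed* by default, `allow_gu_central=False` restores the stricter
reading — the original tool's configuration is not recoverable); penalty
sum over 1–12 ≤ 2.5 (G:U half-penalties count toward this cap, adjacency
rules consider only full mismatches); and duplex MFE ≥ 75 % of the
perfect-complement duplex.  Duplex energies are stack sums (initiation
+4.09 kcal/mol, stacks accrue over consecutive paired positions,
mismatches break stacking) under the same shipped table, which makes the
filter monotone: repairing a mismatch can only add negative stack terms,
so it never turns a passing site into a failing one, and no G:U
substitution can make |duplex MFE| exceed the perfect complement's.
The scanner evaluates every window with vectorized positional rules and
applies the energy filter to survivors; per-miRNA target-gene counts
de-duplicate genes with multiple sites.

## Enrichment

Upper-tail hypergeometric P for each term (k of n target genes vs K of N
background genes), BH step-up FDR within each family (GO MF, BP, CC,
KEGG) since categories are reported separately; terms with K < 2 are not
tested; FDR ≤ 0.05 flags significance.  Annotations are taken as given —
no GO-graph propagation to ancestors.

## Synthetic data: what it emulates

`synthetic.SimulationConfig` defaults define the conditions the pipeline
is validated at: 9 libraries × 10⁵ reads, 150 unigenes (400–800 nt),
20 planted conserved + 10 planted novel miRNAs, 30 decoy reference
matures, TruSeq-style adapters, artifact rates 2 % missing-3′-adapter,
2 % polyA, 3 % low-quality, 3 % too-short, contaminant fractions
8.3/4.0/5.9 % of clean-equivalent reads per phase (matching the published
phase pattern), and a 6 % miRNA fraction — miRNAs are a minor component of
seed small RNA, and the remaining ~80 % is degradation-like background
drawn as random unigene substrings whose length distribution peaks at
24 nt with a 21-nt (phase I) or 22-nt (phases II/III) runner-up, mirroring
the published length profiles.

Hairpins are constructed, not searched: mature + randomized 8–20-nt loop +
near-reverse-complement star with a 2-nt overhang, embedded in a random
unigene and *refolded with the bundled engine*; construction retries until
the planted precursor passes the same criteria the predictor applies
(single stem, MFE ≤ −18, MFEI ≤ −0.85, mature on one arm) and fails loudly
when the configured lengths cannot host one.  Planted target sites are
perfect complements or carry one designed G:U (score 0.5) or G:U plus one
3′-half mismatch (1.5), always rule-compliant by construction; one GO BP
term is planted across the target unigenes (plus two background genes) so
that exactly one term is enriched among DEmiR targets by design.

Expression: each planted miRNA gets a lognormal base abundance and a trend
profile — bell (1,4,1), V (4,1,4), monotone (1,4,16)/(16,4,1) matching the
published magnitude range for monotone DEmiRs, phase-exclusive
(1,0,0)/(0,1,0)/(0,0,1), flat — with lognormal replicate noise (σ = 0.2)
and Poisson sampling.  Phase-exclusive-II designs are expected to classify
as "bell" through the TPM floor (mirrored ±log₂FC), exclusive-I/III as
single-down/up; the trend-recovery metric scores only the
bell/V/up/down archetypes.

Deliberately **not** emulated: sequencing error, isomiR families around a
dominant mature, multi-locus miRNA genes with divergent precursors,
realistic ncRNA family structure, UMI chemistry.  Passing tests therefore
demonstrate the pipeline's logic (rule correctness, threshold behavior,
recovery under noise of the modelled kinds), not robustness to
base-calling error or to the full messiness of real degradomes.
Library-scale quantities (correlation coefficients ≈ 0.999 in the real
data) are not reproduced at 30 planted miRNAs; the suite asserts the
qualitative property instead (within-phase correlation > between-phase,
phases separable in PC space).

## Determinism and problem sizes

All randomness flows from one integer seed through
`numpy.random.default_rng`; per-library generators are derived as
`[seed, 7919 + library_index]`.  Equal seeds give byte-identical FASTA/
FASTQ/TSV outputs, and the pipeline itself is deterministic given its
inputs.  The shipped test suite runs the full default-scale study once
(~1.5 min) plus smaller studies (2–3 × 10⁴ reads/library) for unit-level
checks; the acceptance script repeats the default-scale run from scratch.
These sizes were chosen as the smallest at which all planted effects are
comfortably above the decision thresholds.

## Known limitations

* The energy model's loop terms are simplified; MFE values agree with the
  engine's own oracle, not with experimental thermodynamics.
* Conserved matching is exact-sequence only: isomiRs and near-matches are
  invisible (as in the modelled analysis).
* The novel-miRNA minimum-count and one-per-arm rules are pragmatic
  declarations, not published parameters; both are configurable.
* qRT-PCR utilities (`ddct`, `profile_correlation`) compute the standard
  2^−ΔΔCt and regression quantities but no wet-lab emulation is attempted.
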