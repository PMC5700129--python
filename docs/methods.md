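# Methods

## Scope and model

`ampedit` quantifies editing outcomes at a single CRISPR–Cas9 target locus
from single-orientation amplicon deep-sequencing reads. The analysis model
assumes: one guide with an NGG PAM and a blunt double-strand break 3 nt 5′
of the PAM; one ssODN donor whose programmed edits, applied to the
wild-type amplicon, define a unique expected HDR allele; and reads that
span the full primer-to-primer amplicon (no paired-end merging — merged or
single-end full-span reads are the expected input). Imprecise repair is
modeled as indel formation near the cut; substitution-only changes are
never counted as NHEJ, since indels are the imprecision currency of the
ratio statistic. Zygosity is out of scope: an HDR event templated by a
second wild-type allele is indistinguishable from a wild-type read.

All coordinates are 0-based on the plus strand of the amplicon; the cut
site and insertion positions are *bond* indices (between-base), and edits
are half-open reference intervals. This removes the off-by-one ambiguity
inherent in "cut between positions 17 and 18" phrasing.

## Pipeline stages and parameters

**Quality filter** — mean Phred ≥ `min_mean_q` (default 20). The
threshold is standard amplicon practice; the filter's role, not its exact
value, carries the analysis, and it is configurable.

**Collapse and frequency filter** — reads are collapsed to exact unique
sequences; unique sequences with count < `min_count` (default 10, strict
`< 10` removal: count 9 is dropped, count 10 kept) are discarded. Stages
run in the order quality → collapse → frequency → target identification.

**Target identification** — a unique sequence is a target when the
forward primer matches within the first 5 nt of one end and the reverse
complement of the reverse primer ends within the last 5 nt of the other,
in either orientation; matching allows `max_primer_mismatch`
substitutions (default 0, no indels). Reverse-orientation matches are
flipped to plus orientation; sequences are trimmed to the
primer-through-primer span and re-merged. The 5 nt anchor window
tolerates small end artifacts while keeping matching effectively exact.

**Alignment** — Needleman–Wunsch global alignment of each target against
the wild-type amplicon. Default scoring: affine, match +2, mismatch −1,
gap open −6, gap extend −1 (a gap of length L costs `open + L·extend`);
a linear mode charges `extend` per gapped base. The affine default
consolidates an NHEJ indel into one event instead of scattered single-base
gaps, matching how indels are counted as discrete events. Traceback is
deterministic (diagonal over deletion over insertion on ties), and every
indel run is then shifted to its leftmost score-equivalent position — the
variant-normalization convention — so event coordinates are reproducible
across runs and platforms. End gaps pay ordinary gap penalties: targets
are full-span after primer trimming, so end gaps are genuine indels.
The aligner is validated against exhaustive enumeration of all alignments
on short strings and against an independent library implementation.

**Classification** — decision order per target sequence:
1. equal to the expected HDR allele → HDR;
2. equal to the wild-type amplicon → WT;
3. in `edits_present` mode (default): all programmed edits reproduced, no
   other indel, no stray substitution inside the cut window, ≤
   `max_outside_mismatches` (default 2) stray substitutions elsewhere →
   HDR;
4. any non-programmed indel overlapping the cut-site window
   `cut ± window_nt` bonds (default 5) → NHEJ;
5. otherwise AMBIGUOUS.

The window half-width quantifies "near the cut"; NHEJ indels concentrate
at the break, and the parameter is exposed for sensitivity analysis (the
NHEJ count is non-decreasing in the window). `exact_allele` mode skips
rule 3; its HDR set is a subset of `edits_present`'s, and both are
reported. A read carrying the programmed edit plus an extra indel is
imprecise (NHEJ) — precise means scarless — and is flagged
`hdr_marker_present` for auditing. Programmed-edit signatures are obtained
by aligning the expected HDR allele to the amplicon with the same aligner,
so that left-normalization affects programmed and observed events
identically; comparing raw donor coordinates to normalized events would
misclassify valid HDR alleles whose insertion shares a base with its left
context. HDR-first precedence follows the order in which the outcome
definitions are stated; it is exposed in configuration only through the
mode parameters above.

**Reporting** — HDR% and NHEJ% are percentages of all classified target
reads; ambiguous reads stay in the denominator but in neither numerator.
Raw-read-denominator percentages are logged alongside, since either
denominator convention is defensible. The HDR:indel ratio is undefined
(flagged, not infinite) when no NHEJ reads exist; an optional +0.5
pseudocount mode is off by default to avoid fabricating finite
fold-changes. Fold enrichment is the ratio of ratios and propagates
undefined flags. Clone-mode input (one genotype label per isolated
clone, count 1 each) flows through the same statistic; 8 HDR and 8 indel
clones among 34 give a ratio of exactly 1.

## The synthetic-data generator

The simulator emulates the read classes the pipeline must separate, with
defaults set to a bulk-editing experiment: 50,000 reads, 4% HDR alleles,
16% NHEJ alleles, 0.1% per-base substitution error (Q30-scale), flat
Q35 qualities, plus optional nuisance classes (off-target reads as
shuffled amplicon lacking primers; low-quality reads at flat Q8;
reverse-orientation reads). Off-target and low-quality fractions carve
mass from the whole; the allele mixture shares the remainder
proportionally.

NHEJ reads carry one indel each: a deletion (probability 0.6) whose
interval is chosen uniformly among placements containing the cut bond,
length truncated-geometric (p = 0.5, max 12), or an insertion of uniform
random bases at the cut bond, length truncated-geometric (p = 0.8,
max 6). A `position_jitter_nt` parameter (default 0) additionally
displaces the targeted bond; deletion start placement already randomizes
breakpoints. These choices reflect the empirical NHEJ spectrum — small,
cut-proximal indels dominate, deletions outnumber insertions — without
modeling microhomology. A compound mode (off by default) superimposes the
indel on the HDR allele to emulate donor-plus-scar reads. One indel per
read; no PCR chimeras, adapter read-through, or position-dependent error
profiles are simulated.

What passing tests therefore show: correct geometry, alignment, event
extraction, classification logic, and ratio arithmetic under realistic
mixtures and uniform error. What they do not show: robustness to real
error profiles (position-dependent, context-dependent), PCR artifacts,
or paired-end merging effects.

## Numerical and degenerate-input choices

Ties in the alignment DP are broken by a fixed operator priority, then
left-shifting; identical inputs give byte-identical outputs everywhere
(the simulator is deterministic given its seed; the pipeline has no
randomness). Empty FASTQ input yields a valid all-zero summary with
flagged undefined percentages. Sequences containing N are discarded
during target identification (alignment requires pure A/C/G/T). A donor
identical to the reference is rejected; overlapping or out-of-bounds
edits are errors. Donors written on the non-PAM strand are
reverse-complemented into plus-strand coordinates (an involution);
biotin-end annotation is metadata with no computational effect. Donor
edits may be declared explicitly or inferred by anchored alignment of the
ssODN to the amplicon; explicit declarations win.

## Known limitations and an accounting subtlety

The `< 10` frequency filter interacts with per-base error in a
depth-dependent way worth knowing when interpreting percentages. At
50,000 reads and 0.1% error, each specific single-substitution variant of
the dominant wild-type allele recurs about `n·p_wt·e/3 ≈ 13` times —
above the threshold — so such variants survive filtering and are labelled
AMBIGUOUS (substitution-only, no indel), remaining in the percentage
denominator. Error variants of the much rarer HDR and NHEJ alleles fall
below the threshold and drop out. The net effect at these settings is a
systematic ~9% relative deflation of NHEJ% (about 1.4 points at a true
16%) and a smaller HDR% deflation (~0.27 points at a true 4%, partly
reclaimed by `edits_present` matching). The HDR:indel **ratio** and
fold-enrichment statistics are robust (within a few percent), because
class-proportional losses cancel; absolute percentages at high depth
should be read with this filter effect in mind. At lower depth (where
per-variant error counts stay below the threshold) the effect largely
disappears.

Problem sizes used in the test and acceptance runs — 10,000-read
noise-free samples, 50,000-read mixtures, 200 oracle alignment pairs,
1,000 random event-conservation cases — are the package's validation
design; larger runs change nothing structural.

Other limitations: one locus and one guide per run; no staggered-cut Cas
variants; no MMEJ/NHEJ distinction; no microhomology annotation; no
significance testing across biological replicates (the ratio layer stops
at fold enrichment).
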