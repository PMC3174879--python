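# Methods

## Digestion and amplification model

A transcript is a sense-strand 5'→3' sequence with the poly-A side at the
3' end. Cut positions are found by scanning the sense strand for the
degenerate recognition sequences; both default enzymes (BstYI = R/GATCY,
MseI = T/TAA) are palindromic under IUPAC complementation, so a
sense-strand scan finds every duplex site. This is asserted at import
time, and non-palindromic enzymes are rejected by the digestion engine
rather than approximated. An `N` in the transcript never matches a
recognition position: uncertain (masked) sequence produces no fragments,
which avoids phantom predictions at the cost of possibly missing real
sites in masked regions.

Candidate fragments are intervals between *consecutive* cuts in the union
of both enzymes' cut positions whose 5' boundary is a BstYI cut and whose
3' boundary is an MseI cut — only these carry both adapters and amplify
and are detected by the labelled BstYI primers. BstYI/BstYI and MseI/MseI
intervals are excluded by default (available behind
`include_homoflanked=True` for diagnostics). Products shorter than 6 bp
(the GATCY remnant plus the terminal MseI T) are discarded. `mode="last"`
(default) keeps only the fragment of maximal start — the poly-A-proximal
fragment the wet protocol isolates; `mode="all"` supports protocols that
keep every fragment.

The two amplification rounds of the protocol (+1 then +2 selective
nucleotides) are modelled as a single selectivity filter using the
final-round primers, because round-1 selectivity is a strict prefix of
round-2 and the surviving fragment set is identical.

### Selective contexts and the MseI orientation convention

The primer combination that amplifies a fragment is a deterministic
function of its sequence: the Y-variant base at fragment position 4, the
`k5` bases at positions 5..5+k5 (BstYI side), and — on the MseI side — the
reverse complement of the `k3` sense bases immediately 5' of the terminal
remnant T. The reverse-complement orientation follows from primer
annealing geometry (the MseI primer reads along the bottom strand) and is
verified in the test suite by a brute-force oracle that reconstructs the
literal amplicon (11-nt BstYI primer tail + fragment + 15-nt
reverse-complemented MseI primer tail) and checks whether both full 18-nt
primers occur at its ends. A fragment shorter than 5 + k5 + 1 + k3 bases
cannot carry non-overlapping contexts and is treated as unamplifiable for
that primer set.

### Size model

Predicted migrated size = cut-to-cut length + a constant correction,
default 26 bp: the 18-nt BstYI primer anneals 7 nt inside the fragment
(GATC + Y + 2 selective) and extends 11 nt beyond, and the 18-nt MseI
primer anneals 3 nt inside and extends 15 nt beyond. Capillary mobility
and dye shifts make the true offset assay-specific, so the correction is a
single configurable constant (`SizeModel`), and size linearity (predicted
− actual length is constant per model) is a tested invariant.

## TDF matching

The fragment index maps each primer combination to a size-sorted list of
(predicted size, gene, transcript) entries. A query with an observed
fractional size accepts candidates with |predicted − observed| ≤ tolerance
(default 1.0 bp, inclusive — "within 1 bp" read as a bound; fractional
capillary sizes are kept rather than rounded). Isoforms collapse to genes
before status assignment (unique = exactly one gene; ambiguous = several;
unmatched = none), each gene reporting its minimal deviation; up to three
nearest out-of-tolerance candidates are reported as near misses. Gene ids
derive from transcript ids by stripping a trailing `.<number>` isoform
suffix; an explicit id→gene map can be supplied by constructing
`TranscriptRecord` objects with `gene_id` set.

## Parent-of-origin calling

Capillary peaks are binned with a ±0.5 bp half-width, centers seeded from
the parental-self peaks (greedy left-to-right clustering; overlapping
candidate bins resolve to the nearest center). F1 peaks matching no
self-derived center cannot be a parental allele and are dropped, with the
count recorded in provenance. A TDF is polymorphic iff its allele is
present in every self sample of exactly one accession (the carrier) and
absent from every self of the other. Per timepoint, presence in the F1
where the carrier is the mother together with absence in the reciprocal
supports a maternal call (mirror for paternal); presence in both
directions is biallelic evidence; a timepoint missing a required sample is
uninformative rather than contradictory. A maternal (paternal) call
requires ≥ `min_stages` supporting timepoints (default 2) and no timepoint
supporting the opposite direction. Biallelic timepoints do not veto an
otherwise supported call — stage-dependent imprinting with biallelic
expression at other stages is a real phenomenon — but an all-biallelic or
mixed pattern is `not_uniparental`, and support below threshold is
`insufficient_evidence`. Replicate samples, if present, should be
collapsed to one call per (cross, timepoint) before table construction;
the table itself holds one 0/1 call per sample.

## Endosperm-enrichment ranking

Records (replicate-mean expression in seed coat, embryo, and peripheral /
micropylar / chalazal endosperm) are partitioned: probe problems →
excluded; not seed-expressed; seed-coat-only; hEF ≤ SC; hEF > SC
(endosperm dominant). Ties hEF = SC are excluded from candidacy — the
enrichment argument requires strictly higher endosperm expression.
Dominant genes rank 1..n by descending hEF − SC (absolute enrichment, the
primary key), with hEF / SC reported as the complementary relative key; a
zero seed-coat denominator yields an infinite ratio marker but the gene
still ranks by difference. Presence in seed is an input (array absence
calls are platform artifacts not recomputable here), falling back to a
numeric floor (default 0). The embryo column is never used — the embryo
is biparental and cannot separate seed-coat from endosperm origin — and a
permutation test asserts its inertness. The packaged 18-gene table stores
expression values rounded to 2 decimals, so recomputed enrichment columns
can differ from the stored reference statistics by ±0.01–0.02.

## Pyrosequencing summaries

`allele_fraction(m, p) = 100·m/(m+p)` (undefined → missing when both
signals are zero; complements sum to 100 by construction). A gene summary
is the arithmetic mean of the two reciprocal directions' maternal
percentages; with one direction only it is flagged and unclassified.
Classification thresholds are explicit configuration — the labels are
interpretive: defaults ≥90 maternal binary, 70–90 maternal preferential,
30–70 biallelic, mirrored below. These place a ~95% MEG control, a ~46%
biallelic control and a ~21% preferentially-paternal control in their
expected classes.

## DMR detection

Within a candidate gene's intergenic neighbourhood (from the end of the
nearest upstream gene body to the start of the nearest downstream one,
including the candidate's own body; chromosome ends when no neighbour;
truncation with a warning on overlap), a cytosine is differential when
|pct_b − pct_a| ≥ `min_diff` percentage points. Differential cytosines
chain while consecutive ones are ≤ `max_gap` bp apart; chains with ≥
`min_count` differential cytosines are DMRs. Defaults min_diff = 20,
min_count = 5, max_gap = 250 bp are conventional bisulfite heuristics;
they are mandatory in every report header so results are self-describing.
Emitted intervals span the first to last differential cytosine; counts
cover all cytosines inside, hypermethylation in condition B is counted
separately, and distance/side to the gene body is strand-aware
("downstream" = 3' of the gene on its own strand). Percentages without
read depths support no significance test, so none is attempted. Cytosine
context is pass-through metadata.

## Synthetic fixtures

The generator plants literal motifs rather than rejection-sampling:
filler sequence is drawn from {A, C, G}, so TT (the MseI core) and GATC
(the BstYI core) can occur only inside planted `R GATC Y … TTAA` blocks —
site-freeness holds at any spacing by construction and is asserted by a
post-scan. Each transcript carries one decoy fragment pair and one final
(poly-A-proximal) fragment followed by a site-free 3' UTR and a 20-nt
poly-A tail. Defaults: 200 genes, fragment interiors 30–250 bp (predicted
sizes ≈ 60–280 bp, within the assay's 50–500 bp detection band), half the
genes carrying a site-disrupting SNP in a randomly chosen accession
(screens of two diverged accessions find roughly half of detected TDFs
polymorphic). Site disruption mutates one base of the final fragment's
BstYI or MseI site (C→A in GATC, or the leading T→C of TTAA; neither
creates a new site), so the disrupted allele's poly-A-proximal fragment
shifts to the decoy — exactly the mechanism that makes a TDF
accession-specific.

Allele tables follow the 4-cross × 3-timepoint design (both selfs, both
reciprocal F1s at 3/4/5 dap). Of the polymorphic genes, 20% are planted
maternal: the observed uniparental rate of a real screen is far lower
(on the order of 2%), but at desk scale that would leave ~2 maternal genes
and make precision/recall degenerate; 20% populates every call category
with tens of cases while exercising identical logic. An optional fraction
of maternal genes express their F1 pattern at a single timepoint (expected
call: insufficient evidence), and dropout noise flips present→absent at a
configured rate. Methylation tracks place cytosines every ~25 bp with
baseline pct_b − pct_a bounded by ±5 points and plant DMRs of 8 cytosines
with a +40-point effect at well-separated anchors.

What the fixtures do *not* emulate: PCR efficiency and competition,
partial digestion, electropherogram noise and peak-calling, array
normalisation, bisulfite read-depth sampling. Passing tests therefore
demonstrate correctness of the decision logic under clean inputs, not
robustness to those instrument-level artifacts.

## Problem sizes and determinism

The acceptance computations use a 200-gene transcriptome, 100 random
transcripts for the digestion oracle, and 3 planted DMRs on a 60-kb track
— sizes at which every check runs in seconds while each call category
stays populated. All generators take a single integer seed and are
byte-deterministic under it; sub-streams derive from small fixed offsets
of that seed.

## Known limitations

* Only palindromic recognition sites are supported; non-palindromic
  enzymes are rejected explicitly.
* The size correction is a single constant per run; dye- or
  mobility-dependent (size-varying) corrections must be handled by
  recalibrating observed sizes upstream.
* Fragments too short for the configured selective lengths are treated as
  unamplifiable rather than modelling overlapping primer annealing.
* Polymorphism detection requires complete self-sample panels; partially
  observed selfs make a TDF non-polymorphic rather than guessing.
* Screen-scale totals (tens of thousands of TDFs over 128 primer
  combinations) are emulated synthetically; reproducing a real screen's
  counts requires its capillary data and era-specific transcript sets.
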