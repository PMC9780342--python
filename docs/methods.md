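# Methods

## Read model and junction calling

An anchored editing-outcome library is modeled as single-end reads of at
most 250 nt with the digital layout

    [UMI (12 nt)][fixed spacer ACGCGT][bait ... prey]

The bait begins at the nested-primer anchor, 60 bp upstream of the
protospacer, and runs toward the SpCas9 cut site (blunt, 3 bp 5' of the
NGG PAM; with a plus-strand protospacer starting at `s`, the cut
coordinate is `s+17`; the convention mirrors on the minus strand).  All
coordinates are 0-based, half-open (BED-compatible).

The junction is located by walking the payload colinearly along the
reference from the anchor.  An isolated mismatch whose following 10 nt
re-align (≤ 1 mismatch) is treated as a sequencing substitution; anything
else ends the bait.  Reads whose first 20 nt diverge from the anchor by
more than 2 mismatches are dropped as wrong-locus priming.  A read with no
junction and at least 10 colinear nt past the cut is **uncut**; a
junctioned read whose remaining prey is shorter than 20 nt is
**ambiguous** and excluded from every denominator.

Prey mapping is genome-first, then vector (a prey scoring above threshold
on both is assigned to the genome); decision order:

1. no junction → uncut;
2. an inserted segment at the joint that aligns to the vector →
   AAV integration, *buried* type;
3. prey aligning to the vector from its start → AAV integration, *fusion*;
4. prey colinear downstream on the bait chromosome within ±20 kb of the
   cut: net offset ≤ 200 bp (including duplication-like re-entries up to
   50 bp upstream) → **indel**; offset in (200 bp, 20 kb] → **large
   deletion**;
5. prey within ±100 bp of a known off-target cut site → **off-target
   translocation**;
6. otherwise (another chromosome, > 20 kb away, or inverted within the
   window) → **general translocation**.

Insertions at the joint of ≤ 50 nt that match neither genome nor vector
count as indels; longer unmatchable insertions are ambiguous.
Substitution-only reads are classed uncut: whether cut-site substitutions
should count as edited is a genuine ambiguity of anchored assays, and the
conservative reading is used here.

### Microhomology at junctions

Because the bait walk is maximal, bases shared between the bait
continuation and the prey reference make the breakpoint coordinate
ambiguous over a microhomology tract; at guide-similar off-target sites
this tract is long (the sequences are near-identical around the cut) and
biases plus-strand junction coordinates downstream.  Each call therefore
carries a signed microhomology span, and cut-site concordance tests
resolve every junction to the admissible coordinate closest to the
candidate cut before taking the median.

## Alignment

The internal aligner uses exact 20-bp seeds (the seed length a bwa-mem
pipeline would use) hashed over the references, grouped by diagonal and
extended ungapped by a maximum-scoring-segment scan with match +1,
mismatch −4, gap open −6, gap extend −1.  Since the only read artifact
modeled is substitution error, ungapped extension attains the full
Smith–Waterman optimum on this data; the test suite and acceptance script
verify ≥ 99% agreement (score and locus) with Biopython's
`PairwiseAligner` running full local alignment under identical scoring.
The default reporting floor is `min_score = 30`, so a 20-nt vector
fragment must match near-perfectly (the floor is relaxed to the segment
length when remapping a bounded inserted segment, which is the only place
shorter queries arise).  Alignments from an external mapper can be
imported from SAM (primary + supplementary segments) as an equivalent hit
source.

## Deduplication

Molecules, not reads, are the unit of every rate.  Reads sharing a
junction key — (class, prey reference, position bucketed to ±2 bp,
strand) — whose UMIs are identical or within Hamming distance 1 collapse
into one molecule, greedily from the most frequent UMI.  Distinct
junction keys never merge.

## Off-target discovery

Deduplicated translocation junctions are binned into 100-bp windows (two
tilings offset by half a bin, merged when adjacent); windows with ≥ 3
molecules become candidates.  A candidate survives when (i) the ±30-bp
padded window contains a 23-mer within 8 mismatches of the guide,
counting spacer and PAM jointly (ties resolved toward the window centre,
plus strand first; an optional switch additionally requires an intact
NGG), and (ii) the junction median sits within ±3 bp of that 23-mer's
inferred cut site.  The joint-count reading of the 8-mismatch bound — no
separate PAM requirement — is the package's interpretation; the switch
covers the alternative.  An exhaustive both-strand enumeration of every
23-mer placement provides the independent oracle: discovered sites must
be a subset of the enumeration at identical coordinates and mismatch
counts.

## Amplicon indel rates

Off-target indel burden from amplicon deep sequencing is quantified by
end-to-end alignment of each read to the amplicon (edlib, global mode),
discarding reads diverging > 10%, and counting reads with any insertion
or deletion overlapping the cut ± 10 bp.  Results from fewer than 100
aligned reads are flagged low-coverage.

## Summary conventions

With per-class molecule counts `indel, large_del, ot_tx, gen_tx, aav,
uncut` (ambiguous excluded):

* total events = all six classes;
* editing events (efficiency, translocation rates) = indel + large_del +
  ot_tx + gen_tx — AAV integrations excluded;
* editing events for AAV rates = the above + aav.

These force the identity `aav%_of_total / aav%_of_edited =
(edited + aav) / total`, which is property-tested.  Large deletions are
counted inside editing events by default (switchable and recorded in the
report metadata): anchored assays report them alongside indels and their
denominator role is otherwise unspecified.  Percentages are reported to
two decimals; zero denominators yield explicitly undefined fields.  Note
that one published normalization ("normalized to indels") can disagree
with the events-based definition used here; the package implements the
events-based definition and surfaces the raw counts so either can be
recomputed.

Group comparisons use the Welch (unequal-variance) form of the two-sided
t-test — figure-legend groups typically have unequal n — with degenerate
zero-variance groups handled explicitly; a permutation oracle bounds the
Welch p within 0.02 on 6-vs-6 groups in the tests.  Fold changes are
plain ratios to one decimal and are undefined for a zero baseline.
Vector junction profiles are per-position breakpoint histograms plus the
fraction of breakpoints inside the annotated ITR intervals.

## The simulator: what it emulates, and what it does not

`build_toy_genome` creates chr1 (60 kb) and chr2 (50 kb), embeds the
*Vegfa*-sg1 protospacer+PAM once at chr1:30000, and plants off-targets on
chr2 at exact mismatch distances (defaults 2, 3, 4 — the range real
off-targets of this guide occupy).  The random background is scrubbed so
no other 23-mer lies within 8 mismatches of the guide: planted sites are
then provably the complete oracle answer, which the discovery acceptance
test requires.  Mismatch counts of 0 are rejected (a second exact site
would break on-target uniqueness); counts > 8 are rejected as
unreachable by the similarity filter.

`simulate_library` draws per-molecule outcome classes from a configured
mixture.  Defaults model a realistic in vivo editing landscape at bench
scale: 83% uncut, 10% indels (65% deletions ≤ ~200 bp, 35% insertions
3–47 nt), 0.5% large deletions (210 bp – 19 kb), 1% off-target and 0.5%
general translocations, 5% AAV integrations split evenly between buried
and fusion, ITR junction bias 0.6, per-base substitution error 0.1%, and
a mean of 0.5 PCR duplicates per molecule (geometric).  Buried vector
fragments are 20–120 nt: the upper bound leaves a confidently mappable
genomic return within the 250-nt read (within a longer read budget the
natural upper bound would be larger; fragments longer than the read
remainder are indistinguishable from fusions by construction).  UMIs are
drawn pairwise Hamming ≥ 2 apart, emulating kits with error-robust UMI
whitelists; with fully random 12-mers, rare UMI near-collisions between
molecules sharing a junction would make exact molecule-count recovery
impossible by design rather than by defect.  General-translocation preys
avoid a 500-bp margin around the on-target window and off-target windows
so every truth label is unambiguous under the classifier's own rules.

Not modeled: paired ends, quality-score profiles, indel sequencing
errors, AAV concatemers, real ITR palindromic structure, germline
variation, or multi-fragment insertions.  Passing tests therefore show
the classification logic is correct under its stated read model — not
that the pipeline is robust to artifacts absent from that model.

## Numerical and design notes

* Scrubbing the genome background rewrites offending windows by
  anti-matching free positions (offenders abutting planted sites owe most
  of their similarity to protected bases); offenders overlapping a plant
  trigger a redraw of that plant's mutation positions.  The loop
  converges in a few rounds and is verified by an independent recount
  before the genome is returned.
* Tie-breaks are deterministic everywhere: alignment hits sort by
  (−score, reference, coordinate, strand); guide matches by (mismatches,
  centre distance, plus strand first); UMI merge order by (−count,
  lexicographic).
* `D_large = 200 bp` separates indels from large deletions; the boundary
  is a declared, configurable convention (the literature reports large
  deletions without defining the cut) and is echoed in report metadata.
* Inversions within the bait window are counted as general
  translocations; anchored assays do not give them a standard class.
* All validation problem sizes (20,000-molecule mixtures, 1,200-molecule
  translocation-rich libraries over 20 genome seeds, 1,000-molecule ITR
  runs, 500 alignment queries) were chosen as the smallest scales at
  which the binomial 3-SE acceptance bands are meaningfully narrow;
  the full suite runs in a few minutes on one CPU.

## Known limitations

* The bench-scale simulated rates validate the *machinery*; they do not
  reproduce any published in vivo percentages, which derive from animal
  sequencing data outside desk scale.
* Hotspot support (≥ 3 molecules) and bin width (100 bp) are artifact
  defaults; published pipelines do not state theirs.
* The aligner is ungapped by construction and would under-score preys
  containing true internal indels relative to full Smith–Waterman; for
  such data, import SAM from a gapped mapper instead.
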