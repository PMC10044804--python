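# Methods

This note documents the models, conventions and numerical choices behind
evotrace: what the simulator emulates, how the anchored diff resolves
events, how junctions and consequences are defined, and what the tests do
and do not establish about real data.

## The serial-passage evolution model

`evotrace.simulate` models an adaptive laboratory evolution (ALE)
experiment as a marked Poisson process on a single evolving chromosome.
Events arrive at `change_rate` per day over `days_total` days, are
timestamped uniformly, and are applied chronologically with full
coordinate bookkeeping. The default parameters are the study conditions
the package was built around:

| parameter | default | meaning |
|---|---|---|
| `change_rate` | 0.092 /day | observed fixed-change accumulation rate |
| `days_total` | 2,512 d | 1,256 transfers every 48 h |
| `divergence_day` | `days_total` − 400 | sibling lineages split ~400 d before the end |
| `dilution_factor`, `transfer_interval` | 8, 2 d | 1:8 dilution per 48-h transfer → 1.5 doublings/day |
| `spectrum_weights` | 0.65 on C:G→T:A | pyrimidine-collapsed SNP class weights |
| `p_event_class` | snp 0.65, small_indel 0.25, is_insertion 0.07, large_deletion 0.02, element_excision 0.01 | event-type mixture, matching the observed dominance of SNPs with a minority of indels and structural events |
| `tsd_length` | 9 bp | target-site duplication created by cut-and-paste IS insertion |
| `target_pwm` | YRCTNNRNN-shaped | per-position base probabilities for IS target choice (Y/R positions split 0.45/0.45, literals 0.85, N uniform) |
| `genome_length` | 200 kb | scaled-down chromosome (see below) |
| `deletion_size_log_mean/sd` | ln 1200, 0.8 | log-normal large-deletion sizes |
| `prophage_length` | 4 kb | excisable prophage-like element |
| `indel_length_geometric_p` | 0.7 | small-indel length ∼ Geometric(p) |

**Genome scaling.** Whole-experiment replicates (hundreds of simulated
lineages) need to be cheap, so the chromosome is 200 kb rather than
4.6 Mb, and the structural event sizes are scaled to keep their *genomic
proportions* realistic: the real deletions of 8.5–123 kb are 0.2–2.7% of
the genome, and the default log-normal (median 1.2 kb on 200 kb, 0.6%)
sits in that range. Keeping structural losses near a few percent of the
genome also keeps the fraction of earlier events erased by later deletions
small, as it is in the real strains. The `tiny` fixture scale (30 kb,
250 days) shrinks everything again for sub-second unit-test rounds.

**Event mechanics.**

* *SNPs* draw a collapsed class from `spectrum_weights`, then a strand
  uniformly, then a matching reference base; the realized spectrum is
  exactly multinomial in the weights.
* *Small indels* are insertions or deletions (1:1) with geometric lengths;
  half of the insertions duplicate the adjacent bases, which produces
  homopolymer-run changes (`A8→A7`-style) at natural rates.
* *IS insertions* score every genome position's 9-mer under `target_pwm`,
  sample a site proportionally, and insert the element (random strand)
  while duplicating the 9-bp target as flanking direct repeats.
* *Large deletions* recombine across short repeat pairs that
  `generate_ancestor` plants in the ancestor (lengths drawn from
  `microhomology_length_weights`, spacing from the deletion-size
  distribution): the deletion removes the segment between the two repeat
  copies plus one copy, so the surviving junction carries the planted
  microhomology *and the repeat pre-exists in the reference*, exactly as a
  real microhomology-mediated deletion's tract does. When no unused pair
  remains, a blunt deletion at a random site is applied instead.
* *Element excision* removes the annotated prophage-like element precisely
  at its boundaries, once per lineage.

**Overlap policy.** A new event whose footprint would fall within 3 bp of
an existing event's footprint is resampled; deletions may instead wholly
swallow earlier events, which are then flagged `erased` (invisible in the
final genome). The margin prevents adjacent edits from collapsing into a
single ambiguous representation, which would make "exact recovery"
ill-defined; it censors a vanishing fraction (<0.1%) of candidate sites.

**The ledger.** Every applied event stores its edit in the
application-time frame (replayable), its ancestor-frame interval, and its
evolved-frame footprint (updated as later events shift coordinates). The
replay invariant — applying the ledger to the ancestor reproduces the
evolved genome byte-for-byte — is asserted across 100 seeds in the
acceptance suite. `recoverable_variants` projects the ledger into
ancestor-frame variants, excluding events inside annotated mobile-element
repeats or within 25 bp of another IS insertion, where anchored placement
is inherently ambiguous; that subset is the denominator of all recovery
statistics.

**Sibling pairs** share one lineage to `divergence_day` (events flagged
`shared`), then continue with independent child seeds derived
deterministically from the master seed.

## Anchored genome comparison

Anchors are 21-mers unique in both reference and query (two-sided
uniqueness suppresses mis-anchoring inside repeated IS copies); the
longest collinear chain (patience LIS, ties toward the smaller query
position) defines exact-match blocks. Circular pairs are first rotated to
the chain start. Each inter-block gap is resolved in stages:

1. shared prefix/suffix trimming — a structural indel with a
   microhomologous junction reduces to one clean event instead of an
   arbitrary traceback split;
2. for strongly asymmetric cores (length ratio ≥ 2, difference > 20 bp),
   an end-anchored representation: the short side is aligned flush against
   one gap boundary (whichever end fits with fewer edits) and the overhang
   is emitted as a single indel; if neither end fits, the short side is
   located anywhere inside the long one (the new-IS-inside-old-IS case);
3. local re-anchoring with k-mers unique *within the two cores* (k = 15,
   halving on recursion, floor 8) — repeats that are genome-wide
   non-unique are often locally unique;
4. irreducible cores ≤ 64 bp go to unit-cost Needleman–Wunsch (edlib);
   cores larger than `max_gap` (default 5 kb) on both sides are reported
   as unresolved regions, never silently dropped.

Deletions ≥ `large_threshold` (50 bp) are classed `large_deletion` and
handed to junction characterization; the 6-bp small/large display split
used in reporting is a separate convention. The pipeline upgrades long
insertions matching a reference IS element (edit distance ≤ 10% of the
element, either strand) to `is_insertion`.

All variants are left-normalized: indels shift to the leftmost equivalent
placement (rotating the allele through repeated context), substitution
alleles are trimmed of shared flanks, and pure homopolymer-run changes are
annotated `run_before -> run_after`. Normalization is validated against a
brute-force enumeration of every equivalent placement (including allele
rotations) on 10,000 random instances.

## Junctions, fusions, circularization

Microhomology of a deletion [s, e) is suffix + prefix flank agreement,
capped at `max_m` (5 kb); the equivalent-placement range and the canonical
(leftmost) breakpoint follow directly. Placements can extend beyond the
deletion length in periodic sequence; the brute-force oracle in the tests
accounts for that. Classification priority: precise element excision
(placement matches an annotated element's boundaries; tolerance 0 bp by
default) → IS-flank recombination (breakpoint within ±3 bp of an IS copy
boundary) → microhomology (m ≥ 5) → blunt. The tolerances are parameters
because the field reports such calls with unstated slack.

Fusion calls fire when both breakpoints fall strictly inside same-strand
CDSs. Retained residue ranges are reported with the convention that the
homologous tract — present once in the fusion protein — is attributed to
*both* partners (5′ partner: rightmost placement; 3′ partner: leftmost),
which is how fusion endpoints are conventionally printed; the in-frame
test compares breakpoint offsets mod 3 and the fused ORF is translated
(bacterial table 11) to confirm a single terminal stop.

Scaffold circularization finds the longest prefix–suffix border (KMP, at
most half the scaffold), removes the right copy when it reaches
`min_repeat` (100 bp), and marks the record circular.

## Consequences and knockouts

Codon indices are 1-based; `total_codons` is the protein length (stop
excluded); `fraction_lost` = (total − affected + 1)/total for truncating
classes. A frameshift's affected codon is the codon containing the first
shifted base. A SNP that turns one valid bacterial start codon (ATG, GTG,
TTG) into another is classed silent — initiation still yields fMet — while
loss of the start is `start_codon_change`, a class deliberately separate
from knockouts because downstream near-cognate starts can rescue
expression. The knockout rule is: frameshift, truncation or in-gene IS
insertion losing more than `loss_threshold` (default 0.10) of the
residues, or whole-gene deletion; genes already interrupted in the
reference are excluded and reported separately. The annotator's codon
arithmetic is checked against a literal apply-and-translate oracle on
randomized gene/variant pairs on both strands.

## Statistics

* Spectrum classes are the six pyrimidine-collapsed substitution types;
  collapse is strand-symmetric by construction and tested as such.
* Rate CIs are exact Poisson (Garwood): [½χ²(α/2, 2n), ½χ²(1−α/2, 2n+2)]
  scaled by time. The interval is conservative (coverage ≥ 95%).
* Divergence dating divides the strain-specific count by the *unrounded*
  rate — the only convention that reproduces both 348 and 426 days from
  (32, 231/2512) and (41, 242/2512) — and propagates the Poisson CI of
  the count. With both the count (n ≈ 37) and the rate (n ≈ 235)
  estimated, CI coverage of the true split day is ≈ 95–97% on simulated
  pairs; a few-percent upward bias remains because events erased by later
  deletions deflate the rate denominator, the same censoring a real
  assembly comparison suffers.
* Expected load is µ·L doublings⁻¹ × doublings/day; with µ = 10⁻⁹ and the
  4.64-Mb genome this is 0.00464 per genome per generation and 0.00696
  per day, and the observed/expected ratio is ≈ 13.
* Tm enrichment restricts knockouts to genes with measured melting
  temperatures, counts those with Tm ≤ T_max + 5 °C, and runs an exact
  two-sided binomial test against the genome-wide background proportion
  (default 0.219). The original analysis only eyeballed comparability;
  the formal test is an extension and is validated against a brute-force
  tail sum. T_max is a required input, not a constant.

## What the tests show — and what they do not

The simulator provides what a real resequencing study never has: a
complete, replayable ground truth. Against it, the suite demonstrates
exact ledger replay (100 seeds), ≥ 99% exact-event recovery outside
repeats (100 seeds; in practice 100%), microhomology and normalization
agreement with exhaustive oracles (10,000 instances each), ≥ 90%
divergence-CI coverage and spectrum recovery on 200 whole-experiment-scale
sibling simulations, and consequence-class agreement with literal
translation.

The generator does **not** emulate: read-level error or coverage
structure (assemblies are taken as given), selection and clonal
interference within a culture, nested or overlapping structural events,
inversions and tandem duplications, plasmid gain/loss, or sequence
composition beyond GC fraction. Passing these tests therefore certifies
the *computational* pipeline — coordinate bookkeeping, anchoring, event
representation, arithmetic — not the upstream assembly quality of real
data, and real-genome validation (the three external-accession acceptance
checks) remains the appropriate end-to-end test where those inputs are
available.

## Problem sizes

Defaults used by the test suite and acceptance script: tiny scale 30 kb /
250 days (unit tests, replay and recovery sweeps), paper-like scale
200 kb / 2,512 days (parameter-recovery runs: 200 sibling pairs in the
acceptance suite, 60 in the acceptance script), 10,000-instance oracle
sweeps, and a 300-kb synthetic chromosome for the 17-copy IS scan. These
sizes were chosen so a full validation round completes in a couple of
minutes on one core while every statistical check retains enough events
(≥ 1,000 recovered events, ≈ 9,000 pooled SNPs) to be sharp.
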