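# Methods

## Coordinate and strand conventions

All coordinates are 1-based and inclusive, matching mitochondrial `m.####`
notation. The "plus" strand is the strand stored in the FASTA; for the
rodent/primate mitochondrial references this is the light (L) strand, and
"minus" is the heavy (H) strand. The L/H names are per-genome aliases, not
hard-wired. On circular genomes an interval with `start > end` wraps
through the origin; wrap-around requests on linear references raise a
coordinate error. Reference positions containing `N` are permitted but are
excluded from C·G counting and from off-target denominators.

The vertebrate mitochondrial genetic code (AGA/AGG = stop, ATA = Met,
TGA = Trp) is implemented as an explicit 64-codon table and cross-checked
in the test suite against Biopython's NCBI translation table 2.

## Editable-site scanning (TC context)

Current double-stranded cytidine deaminases edit cytosines whose 5'
neighbour on the same strand is thymine. For a run of consecutive
cytosines preceded by a thymine, both/all cytosines of the run are
editable, so the scanner marks a C as in-context when its 5' neighbour is
T *or* when it belongs to a contiguous C run whose 5'-most C is preceded
by T. This run extension is required for the canonical two-adjacent-C
target (minus strand 5'-TCC-3'): a strict immediate-T rule would accept
only the first C of the doublet. On the minus strand the 5' direction
corresponds to increasing plus coordinates, so a minus-strand C (reference
G at position p) is in context when position p+1 reads A on the plus
strand (run-extended through further Gs). Context neighbours may lie
outside the scanned spacer. Cytosines without context are reported only
behind an `include_non_tc` flag, since they are quantified but not
expected to mutagenize.

Spacer indexing: index 1 is the spacer base adjacent to the L-strand TALE
window, increasing toward the H-strand window. This is forced by the
printed correspondence C₁₂ ↦ m.9576 for the spacer m.9565–m.9583.

## Outcome prediction

`predict_outcomes` takes a codon frame (plus-strand position of the
codon's first base, mRNA-sense strand) and the target sites, and emits the
post-edit codon and amino-acid change for every non-empty subset of sites
within the codon. A C→T on the mRNA-sense strand appears directly; a C→T
on the template strand appears as G→A in the codon. Sites outside the
codon are ignored rather than an error, so a multi-codon window can be
processed per codon. Editing-window preferences of the different
deaminase splits/orientations are carried as descriptive metadata only;
efficiency prediction is out of scope.

## Read simulator

Each simulated molecule carries one haplotype drawn from a configurable
label → probability map (default labels G40K = both target cytosines
edited, G40E = second only, G40\* = first only, WT = none). This is what
links the two adjacent edits within reads, as they are linked on real
molecules. Three substitution channels are applied in a fixed order per
read — start position, haplotype, background flips, sequencing errors —
from a single generator seeded by the config, so a given seed yields
byte-identical FASTQ and truth files.

* **Background C:G→T:A flips**: independent Bernoulli(`offtarget_rate`)
  per non-target C·G site per read, strand-consistent (a minus-strand C→T
  is written as G→A on the plus strand). Default rate in the packaged
  controls: 3 × 10⁻⁴ per site, the scale of natural background
  heteroplasmy estimates in control tissue; the active-editor fixture uses
  7× that, matching the contrast reported between long-exposure active
  samples and controls.
* **Sequencing error**: uniform substitutions at `error_rate` (default
  10⁻³) with flat Phred qualities (default Q30, Sanger +33). There is no
  quality–error coupling: an erroneous base carries the same Q30 as a
  correct one, so quality filtering cannot remove simulated errors. This
  is deliberate — it makes the error channel a worst case for the
  downstream filters — but it means simulated data cannot demonstrate the
  benefit of base-quality filtering that real data shows.
* **Paired mode** emits abutting mates (inner-mate distance 0) from a
  fragment of twice the read length; fragment-size modelling, indels, PCR
  chimeras and adapter read-through are not simulated.

A JSON-lines truth file records each read's haplotype, span, injected
background positions and error positions; with the error channel off,
every read/reference mismatch is explained by the truth record (tested).

Genome-wide libraries tile the reference with overlapping long amplicons
(the long-range-PCR design that avoids nuclear pseudogene co-amplification);
reads are allocated to amplicons in proportion to length and the tiling
must cover the requested region.

## Alignment and pileup

The internal aligner is gapless seed-and-extend: exact k-mer seeds
(k = 20) at every k-th read offset plus the tail, candidate starts scored
by full-length Hamming distance against the (doubled, for circularity)
reference, unique best placement required. Ties and reads above a 10 %
mismatch fraction are left unaligned and counted. Unique placements get a
mapping-quality proxy of 60. This is adequate for substitution-only
amplicon reads; externally aligned SAM can be ingested instead, honouring
recorded MAPQ, skipping unmapped records and counting indel-bearing ones
(only gapless/soft-clipped alignments are usable downstream).

Pileups count A/C/G/T per reference position on the plus strand. A base
contributes iff its read's mapping quality ≥ 30 and its own Phred ≥ 30
(both exposed as config; the two printed settings — a mapping-quality
filter in the count-table step and a base-quality filter in the
genome-wide step — are applied uniformly to both tables). Raw depth
counts every aligned base. Per-site editing frequency is T/depth at a
plus-strand C and A/depth at a minus-strand C; zero depth yields an
explicit *undefined*, never 0.

## Per-read haplotype classification

Classification is alignment-free exact substring matching, mirroring the
zero-error trimming-tool procedure used on real data: four patterns are
built over a single window spanning both target cytosines plus 4-base
flanks (10 nt total for the two-base target — the printed window size read
as a total, centred window; the flank width is a config knob), and a read
is labelled by the unique pattern it or its reverse complement contains.
Reads with any other difference inside the window (sequencing error,
background flip) or not spanning it are "unclassified" and excluded from
the outcome distribution, whose denominator is the number of reads with an
edited label. Because errors are label-agnostic, growing the error rate
grows the unclassified fraction but leaves the label fractions unbiased
(tested). The classifier conditions only on the two primary sites; a
generalized N-site labelling is available by passing an explicit
subset → label map. Note the classification denominator (raw reads
containing the window) differs from the pileup depth at the sites.

## Off-target statistic

At every C·G site the off-base frequency is T/depth (C positions) or
A/depth (G positions). Sites below a minimum depth (default 100×, an
artifact choice — no threshold is printed for the original analysis) or in
a mask are excluded. The summary statistic is the sum of per-site
frequencies at unmasked, non-target sites divided by the genome's **total**
C·G site count — the denominator stays at the total even though on-target
sites are excluded from the numerator, following the formula as printed;
both choices are flags (`exclude_targets_from_numerator`,
`denominator_mode`). All target-spec sites (including bystanders) are
masked by default; whether the original numerator excluded only the two
primary sites or the whole spacer is not stated. Sequencing-error
background is not subtracted per site; instead vehicle / inactive-editor
control libraries are summarized identically and compared at the summary
level (fold change = active mean / mean of control means, with an explicit
infinity flag for zero-mean controls). On-/off-target association is
reported as both Pearson and Spearman coefficients, since no method is
canonical for it. NUMT regions are handled as independent linear
references with the same pileup machinery; a homologous site is flagged
only above `control mean + 3 × control SD`.

## Packaged toy study

`make_fixture` builds a 2-kb circular genome with one planted locus laid
out like the real target: TALE windows at 901–916 and 936–951, spacer
917–935 (19 bp) containing minus-strand TC-context cytosines at spacer
indices 6/12/13/17/18 and the GGA codon at indices 12–14, so the canonical
index-12/13 edit combinations give G40K/G40E/G40\*. Generation retries
with shifted seeds until the four classification windows are unique
genome-wide (so exact-match classification and unique alignment are
well-posed by construction). Study conditions of the fixture libraries:
20,000 reads over a 240-bp amplicon; active sample 35 % edited molecules
split 0.53/0.455/0.015 among G40K/G40E/G40\* (a mid-efficiency editor with
a G40E-skewed split, the hardest of the printed patterns to distinguish)
over 2.1 × 10⁻³ background; controls WT-only at 3 × 10⁻⁴ background;
error rate 10⁻³ at Q30.

Problem sizes used by the test suite and `scripts/acceptance.py` — 2-kb
genome, 20,000-read libraries, 200-bp genome-wide reads, six-sample
correlation sweep at 6,000 reads — were chosen so each statistical check
has power at 3-SD/total-variation tolerances while the whole analysis
remains a desk-scale computation.

## What passing tests do and do not show

The simulator reproduces the joint structure the analysis exploits
(linked on-target edits, independent background, uniform error) but not
real amplicon pathologies: PCR/recombination chimeras, strand bias,
position-dependent error, indels, quality–error correlation, or
NUMT co-amplification. Recovery of planted parameters therefore validates
the estimators and bookkeeping, not robustness to those artifacts.
Editing-efficiency prediction, TALE RVD design, quality/adapter trimming
of real reads, and nuclear genome-wide off-target discovery are explicitly
out of scope.

## Numerical conventions

Frequencies are exact integer ratios; undefined quantities (zero depth,
zero edited reads, zero-variance correlations, zero-mean controls) are
explicit flags, never silent zeros. Alignment ties break to "unaligned"
rather than arbitrary placement. Reports are JSON with sorted keys and no
timestamps, so identical configs and seeds produce byte-identical output.
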