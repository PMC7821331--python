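# Methods

This note describes the models behind `longmeta`: what each stage assumes,
the parameters that matter, and where the simulation deliberately departs
from real data.

## Synthetic world

**Taxonomy.** `simulate_taxonomy` builds a ranked tree (root →
superkingdom → kingdom → phylum → class → order → family → genus →
species) spanning three target groups — plants (Viridiplantae/
Streptophyta), macro-invertebrates (Arthropoda) and vertebrates
(Chordata).  Species can be named explicitly (species sharing a genus
epithet are placed in the same genus) or generated with pseudo-Latin
binomials.  Unranked ("no rank") intermediate nodes are legal; reported
ranks always fall back to the nearest standard level at or above a node,
since diet reports use the Linnaean ladder only.

**Marker references.** Each of the 11 primer pairs defines one marker.  A
reference amplicon is a concrete realization of the forward primer site, an
evolved marker core, and the reverse-complemented reverse primer site, plus
30 bp of random padding per side standing in for database context.  Cores
evolve by substitution only down the tree with per-edge rates (kingdom
0.12, phylum 0.10, class 0.08, order 0.06, family 0.05, genus 0.04;
species edges draw uniformly from [0.012, 0.045]).  These values were fixed
once so that congeners differ at roughly 2.4–8.8 % of sites (observed
pairwise identity ≈ 92–97 %) while conspecific templates (mutated at 0.3 %
when a community is composed) stay above 99 %.  That separation is the
premise that makes a 97.6 % identity gate meaningful; it is a design
choice, not an estimate from data.  No indels, no rate heterogeneity, no
GC-content structure — identity accounting stays exact, at the cost of
realism in alignment-gap behaviour.

**Communities.** A `CommunitySpec` lists members with template weights, a
mode, and an optional host at ≤ 20 % of total weight.  Template copies are
`round(weight × copies_per_unit)` (default `copies_per_unit` 50) for
pooled-DNA modes; in amplify-then-pool (MC2) mode every member contributes
equal copies, because separately amplified products are pooled equimolar.

## In-silico PCR

Primer binding tolerates 2 mismatches outside the 3′-terminal 3 bases and
none inside them (polymerase extension is 3′-sensitive; the tolerance is a
config-exposed choice — the wet-lab protocol does not state one).  IUPAC
degeneracy codes match their base sets; inosine behaves as N.  Both
template strands are scanned and products outside ±25 % of the pair's
expected length are discarded.  `run_panel` gives every pair an equal copy
budget (default 200 per pair; 600 in feeding-trial configurations, where
the 2 % host spike needs enough depth for its contig to assemble — the real
protocol's per-sample depth is orders of magnitude above either).  Within a
pair, pooled-DNA mode allocates the budget ∝ template copies × a lognormal
efficiency factor (σ = 0.5, seeded); that distortion is what later breaks
the biomass–read-count relationship.  Triplicate PCR is represented by the
single budgeted run.

## Shearing and sequencing

Fragment lengths are drawn sequentially from a normal(290, 60) truncated to
[50 bp, remaining length] until the remaining molecule is ≤ 1.5× the mean;
the remainder becomes the last fragment, so every copy tiles its amplicon
exactly.  A molecule that would stay uncut but exceeds 300 bp (the span two
150 bp mates can cover) receives one cut anyway: ultrasonication has no
mechanism for leaving a molecule intact yet unsequenceable.  The sampler's
raw draws follow the truncated normal exactly (rejection sampling);
tiling-constrained remainder pieces necessarily deviate from that marginal,
which is why distributional checks are made against the sampler.  With
amplicons uniform on [350, 1400] bp this yields a pool-wide mean fragment
length of ~280–290 bp.

Reads are 2×150 bp: mate 1 from the fragment 5′ end, mate 2 from the
reverse-complement end.  Errors are i.i.d. substitutions (default rate
0.002, loosely anchored to a run where 93 % of reads exceeded Q30);
correct bases get Q36, injected errors Q14.  No indels, adapters,
duplicates or per-cycle profiles.  A truth channel records each read's
source amplicon and taxon.

One geometric consequence worth knowing: positions ~100–140 bp from an
amplicon end are only covered by copies whose terminal fragment is 151–250
bp (~25 % of draws).  At per-amplicon coverage 10 an end therefore has a
~5 % chance of an unrecoverable gap — a property of 150 bp reads on
end-anchored fragments, not of the assembler.  Assembly-exactness suites
accordingly run at coverage 40.

## Assembly

A single-k (default 51) canonical-k-mer de Bruijn graph; odd k keeps a
k-mer distinct from its reverse complement.  k = 51 was chosen over
smaller values because conserved runs shared between confamilial amplicons
of the same marker create junctions at k = 31 that shred contigs; at k = 51
the short-contig fraction removed by the 150 bp filter lands in the
percent range.  Cleaning is k-mer-spectrum based: edges below
`solid_min_coverage` (2) are dropped; tips shorter than 4k edges and
junction-to-junction paths are removed only when their coverage is below
20 % of the continuing branch (recurrent sequencing errors at high coverage
create solid side paths, and topology alone cannot distinguish a real
amplicon terminus from a tip); simple bubbles up to 2k edges collapse onto
the higher-coverage branch, ties keeping the lexicographically smaller
sequence.  Contigs are maximal non-branching paths, deduplicated to
canonical orientation, emitted in lexicographic order (assemblies are
byte-reproducible), and filtered at 150 bp with the removed fraction
reported.  Paired-end distance information is unused — amplicons ≤ 1,400 bp
do not need scaffolding — and repeat resolution is out of scope.

## Search and assignment

Alignment is local affine-gap Smith–Waterman (match +1, mismatch −2, gap
open −5, extend −2) via Biopython's PairwiseAligner; identity is matching
columns over all alignment columns, reported to 2 decimals.  Contig strand
is arbitrary after assembly, so the better orientation per reference is
chosen (fast infix edit distance) before exact scoring; exact tracebacks
are computed only for candidates that can reach the top-5 list.  The
e-value is the closed-form Karlin–Altschul expression *E = K·m·n·e^(−λS)*
with K = 0.46, λ = 1.28 — a surrogate whose cutoff behaviour, not its
absolute values, is the contract.  Hits are ranked by bit score with frozen
tie-breaks (e-value, identity, accession), at most one hit per accession,
truncated to five.

The assignment census counts distinct taxa among gate-passing hits only
(identity ≥ 97.6 %, inclusive — the boundary case is retained; sub-gate
hits inside the top five are ignored).  One taxon → direct assignment;
several → lowest common ancestor; none → unassigned.  Checklist promotion
applies only to supra-species calls whose assigned taxon is itself a
checklist key, and never alters a species-level call.  Cross-sample
ecological reasoning (inferring a species from its occurrence in other
samples) is out of scope; candidates are left at their LCA rank.

## Quantification

Read pairs map to contigs by best single placement: candidates via a
shared-21-mer index, scored by infix edit distance of both mates in either
orientation, accepted at ≥ 95 % combined identity over ≥ 100 aligned bases
(looser than the assignment gate — mapping is counting, not
identification), ties broken lexicographically.  Abundance records keep one
row per contig; the same taxon recovered through several markers is
deliberately not merged, so the marker-to-marker spread of shares remains
visible.  The host report gives the fraction of raw read pairs on
host-assigned contigs.  The bias report computes the Spearman correlation
between ingested weight and summed read share per truth member and flags
runs where the heaviest member is not the most abundant; with the default
lognormal efficiency noise this flag fires in a substantial fraction of
replicate amplifications, which is the package's demonstration that read
abundance is not a biomass quantifier.

## Problem sizes and determinism

Default end-to-end runs use 19-member communities, a 200-copy budget per
primer pair (600 for feeding trials), and ~5,000–10,000 read pairs per
sample — sizes at which a full run takes under a minute and the whole test
suite a few minutes on one core.  Every stochastic stage takes an explicit
integer seed and derives independent substreams from it; identical seeds
give byte-identical FASTQ, contig, assignment and abundance outputs.

## What passing tests do and do not show

The simulation preserves the method's decision structure (multi-marker
amplification, shear-and-reassemble, gated LCA assignment) with controlled
divergences, substitution-only errors and uniform base composition.
Passing tests therefore demonstrate the internal consistency of the
pipeline and the reachability of the published summary statistics under
those assumptions — not the method's performance on real faecal DNA, where
reference databases are incomplete, markers differ in conservation,
chimeras and indel errors occur, and DNA degradation varies by prey.  The
validation tables shipped as fixtures are inputs for the summary
arithmetic, not outputs of the simulation.
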