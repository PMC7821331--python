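# longmeta

Long-metabarcoding diet analysis at desk scale: simulate multi-marker
amplicon libraries from mock communities and feeding trials, sequence them
in silico as 2×150 bp short reads, reassemble the full-length amplicons de
novo, and identify the taxa they came from.

## The problem

Diet analysis from faecal DNA usually relies on short barcodes (<100 bp)
because prey DNA is assumed to be degraded, and short barcodes often cannot
separate related species.  An alternative protocol amplifies **long**
barcodes (350–1,400 bp over COI, rbcL, matK, 28S rRNA and trnL–trnF with an
11-pair primer panel), shears the pooled amplicons to ~290 bp, sequences
them as ordinary Illumina 2×150 bp paired-end reads, and recovers the
full-length amplicons by de novo metagenome assembly.  Contigs are then
assigned taxonomically by the rule:

- search each contig against a reference database (local affine-gap
  alignment; Karlin–Altschul e-value gate *E* ≤ 10⁻²⁰) and keep the five
  most significant references;
- census the distinct taxa among hits with ≥ 97.6 % identity (the boundary
  value is retained);
- a single taxon is assigned directly; several taxa collapse to their
  **lowest common ancestor**; no gate-passing hit leaves the contig
  unassigned;
- a regional species checklist may promote a genus-level call to the only
  species of that genus known from the study area.

Read abundance per contig is computed by mapping the reads back, but is
deliberately reported as a *qualitative* signal: per-primer amplification
efficiencies distort the relationship between ingested biomass and read
counts.

This package implements that entire protocol as a seeded simulation plus
the analysis stages, so the method's guarantees (species-rank recovery from
mock communities, the identity-gate boundary, the contig-length filter, the
quantification bias) can be exercised and tested without sequencing data.
It is aimed at people developing or teaching metabarcoding pipelines who
need a controlled, fully reproducible test bed.

## Worked example

```python
from longmeta import pipeline

world = pipeline.build_world(pipeline.MC1_MEMBERS, seed=1)
spec = pipeline.community_spec(world, {n: 1.0 for n, _ in pipeline.MC1_MEMBERS})
result = pipeline.run_sample(world, spec, seed=1, sample_id="MC1")
report = pipeline.validate_truth(result, tree=world.tree)
print(len(result.contigs), result.removed_contig_fraction)
print(report.species_rank_recall, report.min_identity)
```

This simulates the 19-member pooled mock community (7 plants, 8
macro-invertebrates, 4 vertebrates) through every stage and prints

```
86 0.09473684210526316
1.0 99.38
```

i.e. 86 contigs survive the 150 bp length filter (9.5 % of raw contigs were
shorter — the filter's expected percent-range bite), all 19 members are
recovered **at species rank**, and the worst detection still aligns at
99.38 % identity, comfortably above the 97.6 % gate.  The same run is shown
with a per-member table in `examples/05_mock_community_validation.py`;
each script in `examples/` demonstrates one capability (world simulation,
in-silico PCR, shearing/sequencing, assembly, validation, quantification)
and prints a few annotated numbers.

A thin CLI wraps the same library calls
(`longmeta simulate | assemble | assign | quantify | run | validate |
report`, plus `defaults` to print a full YAML config).

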