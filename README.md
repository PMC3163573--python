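# genomering

Circular BLAST-ring comparison images for prokaryote genomes.

Comparing a newly sequenced bacterial genome against dozens of related
genomes is a routine need in microbial genomics, and a circular map is the
standard way to summarise it: the genome of interest forms the central
reference ring, and each comparison genome is drawn as a concentric ring
whose colour intensity encodes BLAST percent identity.  Fully shared
regions appear as solid colour, divergent regions fade, and sequence absent
from a query (a deleted island, a missing prophage) shows as a blank gap in
that ring.  `genomering` builds such images as a Python library plus a
small CLI, aimed at bacterial genomicists working with complete genomes,
draft assemblies (contigs/scaffolds with read coverage from ACE or SAM
files), gene panels, or even unassembled reads.

## The model

The reference — one genome, a concatenated multi-FASTA panel, or an
ordered draft assembly — defines a coordinate circle of length *L*; base
*p* maps to angle θ = 2π·p/L, clockwise from 12 o'clock.  The reference is
used as the BLAST **subject** database and each query is searched against
it (blastn for nucleotide comparisons, blastx for reads or divergent
sequences via translated search).  Each tabular hit with subject span
[s₁, s₂] and percent identity *pid* becomes an annular arc on the forward
interval [min−1, max) with opacity

    opacity(pid) = 0.1 + 0.9 · (pid − lower) / (upper − lower)

clamped to 1 at *pid* ≥ upper and **omitted** below *lower* (absence draws
as white).  Hits are painted in ascending bitscore so the strongest match
in any overlap is on top (z-order painting).  Additional rings carry GC
content and GC skew ((G−C)/(G+C) per window), per-base read coverage
(pileup of CIGAR M/=/X ops from SAM, or padded AF placements from ACE),
alternating contig-boundary segments, user graphs, and annotations pulled
from GenBank/EMBL feature tables.  A lift-over utility repositions a
coverage track onto a reordered assembly through a BLASTn interval mapping.

## Worked example

Build a small comparison entirely from synthetic data — a 50 kb genome
against a variant carrying three known 2 kb deletions:

```python
import pathlib
from genomering import blastops, ringmodel, render, seqio, synthetic

wd = pathlib.Path("scratch"); wd.mkdir(exist_ok=True)
genome = synthetic.synth_genome(50_000, gc_fraction=0.5, seed=1, id="ref")
variant, truth = synthetic.mutate_genome(
    genome, deletions=[(10_000, 2_000), (25_000, 2_000), (40_000, 2_000)])

ref = seqio.write_fasta([genome], wd / "ref.fasta")
db = blastops.make_database(ref, "nucl", wd / "db")
tab = blastops.run_comparison(
    "blastn", seqio.write_fasta([variant], wd / "var.fasta"), db)
hits = blastops.parse_tabular(tab)

refmap = seqio.build_reference_map([genome])
spec = ringmodel.RingSpec(kind="blast", members=("variant",),
                          lower_identity=70, legend_text="deletion variant")
model = ringmodel.assemble(refmap, [spec], {"variant": hits})
render.render_svg(model, wd / "image.svg")

gaps = ringmodel.uncovered_intervals(
    [blastops.orient_to_reference(h) for h in hits], genome.length)
print(len(hits), "hits;", "gaps:", gaps)
```

This prints:

```
4 hits; gaps: [(10002, 11998), (25001, 27000), (40000, 41995)]
```

Four arcs cover everything except three blank intervals that recover the
planted deletions to within a few bases (Jaccard ≈ 0.998) — exactly how
gene or island absence reads off the finished image.  `scratch/image.svg`
shows the variant ring with three white gaps.

The same pipeline is scriptable through profiles:

```sh
genomering init --template large-genome --out profile.json
genomering render --profile profile.json --out image.svg
genomering render --profile profile.json --out image.svg --dry-run   # plan only
```

Other subcommands: `blast` (tabular hits only), `coverage` (SAM/ACE →
graph file), `remap` (lift a track over a reordered assembly), `annotate`
(GenBank/EMBL features → annotation table).

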