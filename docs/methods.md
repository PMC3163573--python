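# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open.  Formats that are 1-based
inclusive (GenBank/EMBL feature locations, BLAST subject/query spans, SAM
POS, ACE padded offsets, the 3-column graph dialect, the annotation table)
convert exactly once, at their parser or writer.  A multi-record reference
(multi-FASTA, or multi-record GenBank/EMBL, treated identically) is
concatenated in file order; each record becomes a named segment with a
cumulative offset, and everything downstream — hits, tracks, annotations,
ticks — lives in the concatenated frame.  Position 0 renders at 12 o'clock
with angles increasing clockwise; this is the single geometry contract and
is asserted by the trig oracle tests.

## BLAST rings

The reference is the subject database (`makeblastdb`), queries are
searched with blastn/blastx/tblastx and exchanged as standard 12-column
tabular rows.  Read sets are passed to blastx as nucleotide queries; the
translation into peptides happens inside blastx.  Filtering keeps hits
with pident ≥ min_identity **and** evalue ≤ max_evalue, both boundaries
inclusive — "cut-off" is directionless, so the inclusive reading was
chosen and frozen.  Every HSP is retained and drawn as its own arc; no
per-query collapsing.  Subject spans with sstart > send (minus strand) map
to the same forward interval as their swap.

Arcs paint in ascending bitscore (stable sort), so the highest-scoring hit
in any pile-up is drawn last and ends on top.  The identity gradient is a
continuous linear map from opacity 0.1 at the lower threshold to 1.0 at
the upper; 0.1 keeps the faintest retained match visible on white.  Hits
below the lower threshold are omitted entirely rather than drawn at zero
opacity, so absence reads as a blank region.  Both thresholds are per-ring
settings.  BLAST's low-complexity filter is left at its default; note that
with it on, repetitive reference regions can produce short (~30 bp) blank
bands across *all* rings that are easily misread as unique sequence — pass
`-dust no` (blastn) or `-seg no` (blastx) through `extra_options` to
disable it.

## Tracks

`ValueTrack` stores run-length-compacted `(start, end, value)` bins plus
the reference length; per-base arrays are materialised only where exact
per-base arithmetic is required.  Mean and standard deviation are
length-weighted over the binned positions; the sd is the population form
(the track is the whole population of positions, not a sample).

**GC statistics.**  Windows start at 0, step, 2·step…; the default is
10 kb non-overlapping windows, scaled down to roughly total/100 on small
references so a plasmid still gets ~100 bins.  On circular references the
final windows wrap past the origin; on linear (panel) references the last
window truncates.  GC content is (G+C)/(A+C+G+T) and GC skew (G−C)/(G+C),
with non-ACGT characters excluded from numerator and denominator and a
skew of 0 defined for windows with no G or C at all (avoids undefined bins
in AT-only stretches).

**Graph scaling.**  The default display mode is skew-from-mean: subtract
the length-weighted mean (making the track mean exactly 0, idempotently),
then normalise so the largest |deviation| is 1; positive bars render
outward of the ring midline, negative inward.  The alternative
zero-to-max mode clamps to [0, user_max] and scales into [0, 1] from the
ring base — the right choice for coverage, where "30× and above is
saturated" is more informative than deviation shape.

**SAM coverage.**  A position is covered when a CIGAR M/=/X op consumes
it; D and N advance along the reference without covering; unmapped
(0x4), secondary (0x100) and supplementary (0x800) records are skipped —
standard pileup semantics.  Parsing goes through pysam; headerless SAM is
accepted by synthesising @SQ lines from the reference map.

**ACE coverage.**  Coverage is computed on the contig's *padded*
coordinates — every read whose AF placement spans a padded column counts —
and then projected to unpadded coordinates by deleting the contig's `*`
columns.  This padded-then-depad order is an assumption (the alternative
would be to clip reads to their QA ranges first); it matches how the
placement lines are defined and is frozen here.  QA clipping is not
applied.  The primary parser is Bio.Sequencing.Ace; because it cannot
represent a contig that carries zero reads, a minimal CO/AF/RD section
scanner backs it up for files the primary parser rejects.

**Anomaly intervals.**  Maximal runs with |value − mean| > k·sd (two-sided;
one-sided flagging would hide collapsed-repeat peaks or dropouts depending
on direction), merged across adjacent bins, emitted as BED.  A constant
track has sd 0 and no anomalies by definition.

**Lift-over (remap).**  A BLASTn of the original assembly (query) against
the reordered assembly (subject) yields interval blocks; orientation is −1
when exactly one of the two spans is inverted, and gapped blocks whose
spans differ are truncated to the shorter length measured from each start
(a conservative approximation that never invents positions).  Transport is
per-base: each new position takes the value of its mapped old position,
reversed within −1 blocks; where blocks overlap, the highest-bitscore
block wins — the same dominance principle as z-order painting.  Uncovered
positions are 0.

## Rendering

Output is SVG 1.1 generated by deterministic string templating: fixed
4-decimal float formatting, fixed iteration order, no randomness, and SVGZ
written with a zeroed gzip timestamp, so identical inputs give
byte-identical files (asserted end-to-end).  Ring annuli stack outward
from an inner radius of 25% of the half-image (default image 3000×3000 px);
relative ring widths scale down uniformly, with a logged warning, when the
stack would collide with the label margin — never up, and never an error.
An annular sector below the minimum visible sweep (the angle subtending
1 px at the ring's outer radius) is widened symmetrically to that minimum,
so a single gene on a multi-megabase circle cannot vanish; full-circle
sweeps are emitted as two joined half-annuli because a single SVG arc
command cannot represent 2π.  Label anti-collision is a greedy pass:
labels sorted by angle, each pushed past its predecessor by at least one
font-height of arc — deterministic by construction.  Ticks default to a
"nice" 1/2/5×10^k spacing giving ~10 major ticks; templates preset
500 kb/100 kb (chromosome), 5 kb/1 kb (plasmid) and 1 kb/200 bp (gene
panel) spacings.  PNG/JPEG rasterisation is out of scope; SVG/SVGZ are the
faithful, testable artifacts.

## Profiles and CLI

A profile is JSON with an explicit `format_version` ("1"): reference
descriptor, named sources (roles: query, tabular, sam, ace, graph,
annotation), ordered ring specs, BLAST settings, image settings.  Ring
members must reference declared sources or the builtins `:gc-content`,
`:gc-skew`, `:contigs`, `:headers`, which are computed from the reference
itself.  Save/load is lossless field-for-field.  The CLI decomposes the
pipeline into `render`, `blast`, `coverage`, `remap`, `annotate` and
`init`; `render --dry-run` validates and prints the planned external
commands without executing anything.  Exit codes: 2 validation, 3
external tool, 4 I/O.

## Synthetic data

The generators exist so every stage — including live-BLAST comparisons and
end-to-end rendering — is testable offline with known truth.  They are
pure functions of their arguments including the seed (one numpy Generator
per call, no global state).

- `synth_genome`: i.i.d. bases with P(G)+P(C) = gc_fraction split evenly.
  Defaults used in the shipped experiments: 50 kb genomes at GC 0.5 for
  whole-genome comparisons, 20 kb for coverage runs.
- `mutate_genome`: non-overlapping deletions applied 5'→3' plus
  Bernoulli(snp_rate) substitutions outside deletions, never silent.  The
  deletion-recovery experiment plants three 2 kb deletions — large enough
  that blastn fragments cleanly around them, island-sized relative to the
  50 kb genome.
- `synth_reads`: uniform start positions, uniform strand, substitution
  errors only.  100 bp reads emulate short-read shotgun data; 1,000 reads
  on 20 kb gives ~5× mean coverage, enough for a non-trivial pileup that
  still compares exactly against the brute-force oracle.
- `synth_sam`: one primary all-M alignment per placement, so the pileup of
  the file equals the placement oracle exactly by construction.
- `synth_blast_tabular`: rows whose oriented subject intervals reproduce a
  stated truth set exactly — the fixture mode that exercises the entire
  downstream pipeline without BLAST+ installed.

What the generators deliberately do **not** emulate: realistic error
models (no indels, no quality-dependent error rates), repeats and mobile
elements, GC-biased composition structure, chimeric reads, or assembly
artefacts.  Green tests on this data demonstrate coordinate and pipeline
correctness — exact pileups, exact transports, exact geometry — not
robustness of BLAST parameter choices on messy real genomes, where
low-complexity filtering and repeat structure (see the BLAST-rings note
above) dominate image quality.

## Numerical and degenerate-input choices

- Inclusive filter boundaries (≥ identity, ≤ e-value).
- GC skew 0/0 → 0; graph peak 0 → flat zero profile rather than NaN.
- `scale_zero_to_max` clamps negatives to 0 and requires user_max > 0.
- Remap overlap tie-break: equal scores resolve to the later mapping entry
  (stable ascending sort, last write wins) — deterministic.
- Zero-sweep arcs are widened, not dropped; empty rings render as a valid
  image with reference circle, ticks and title.
- A window longer than a linear reference is an error; on a circular
  reference windows wrap instead.

## Problem sizes in the shipped checks

The acceptance script runs a 50 kb self-comparison and deletion recovery
(live blastn), 1,000-read pileups on 20 kb, 2,000-bp remap transports, and
~30 kb of rendered fixture images; the whole script completes in seconds.
These sizes were chosen as the smallest at which each behaviour is
non-trivially exercised (multiple windows per track, fragmented BLAST
hits, overlapping reads) while staying hand-checkable.
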