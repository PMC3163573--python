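"""Deterministic synthetic genomes, variants, reads, SAM and BLAST tabular.

Every generator is a pure function of its arguments including the seed, so
fixtures for any stage — through to end-to-end rendering — can be built
offline with known truth.  The read model is deliberately simple:
substitution errors only, no indels, so a read's placement is an exact
interval and the pileup oracle is exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .seqio import SequenceRecord

BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Placement:
    """Where a read came from: forward-strand interval plus strand."""

    read_id: str
    start: int
    length: int
    strand: int  # +1 forward, -1 reverse

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class VariantTruth:
    """Truth for one mutated genome: what was deleted and where SNPs landed
    (positions in base-genome coordinates)."""

    deletions: tuple[tuple[int, int], ...]  # (start, length)
    snp_positions: tuple[int, ...]


@dataclass(frozen=True)
class TruthSet:
    """Aggregate truth for a simulated study: base genome, variants with
    their truth, read placements, and the master seed."""

    base: SequenceRecord
    variants: tuple[tuple[SequenceRecord, VariantTruth], ...]
    placements: tuple[Placement, ...]
    seed: int


def synth_genome(length: int, gc_fraction: float = 0.5, seed: int = 0,
                 id: str = "synth") -> SequenceRecord:
    """I.i.d. random genome with P(G)+P(C) = gc_fraction, split evenly."""
    if length < 1:
        raise ValidationError("length must be >= 1")
    if not (0.0 <= gc_fraction <= 1.0):
        raise ValidationError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return SequenceRecord(id=id, description=f"synthetic length={length} "
                          f"gc={gc_fraction:g} seed={seed}",
                          residues="".join(BASES[idx]))


def mutate_genome(base: SequenceRecord,
                  deletions: Sequence[tuple[int, int]] = (),
                  snp_rate: float = 0.0, seed: int = 0,
                  id: str | None = None) -> tuple[SequenceRecord, VariantTruth]:
    """Apply known deletions then Bernoulli SNPs (never silent) to a genome.

    Deletions are (start, length) in base coordinates, must not overlap, and
    are applied 5'->3'; SNPs land only outside deleted intervals.  Returns
    the variant plus the truth needed to score recovery.
    """
    dels = sorted(deletions)
    prev_end = 0
    for (s, ln) in dels:
        if s < prev_end:
            raise ValidationError("deletions overlap")
        if ln <= 0 or s < 0 or s + ln > base.length:
            raise ValidationError(f"deletion ({s}, {ln}) out of bounds")
        prev_end = s + ln
    rng = np.random.default_rng(seed)
    deleted = np.zeros(base.length, dtype=bool)
    for (s, ln) in dels:
        deleted[s:s + ln] = True
    residues = np.array(list(base.residues))
    snp_positions: list[int] = []
    if snp_rate > 0:
        flips = rng.random(base.length) < snp_rate
        for pos in np.flatnonzero(flips & ~deleted):
            old = residues[pos]
            choices = [b for b in "ACGT" if b != old]
            residues[pos] = choices[rng.integers(len(choices))]
            snp_positions.append(int(pos))
    kept = residues[~deleted]
    variant = SequenceRecord(
        id=id or f"{base.id}_variant",
        description=f"variant of {base.id}: {len(dels)} deletion(s), "
                    f"{len(snp_positions)} SNP(s)",
        residues="".join(kept),
    )
    truth = VariantTruth(deletions=tuple((s, ln) for (s, ln) in dels),
                         snp_positions=tuple(snp_positions))
    return variant, truth


def synth_reads(genome: SequenceRecord, n_reads: int, read_length: int = 100,
                error_rate: float = 0.0, seed: int = 0,
                id_prefix: str = "read") -> tuple[list[SequenceRecord], list[Placement]]:
    """Uniformly-placed substitution-error reads from both strands.

    Emulates short-read shotgun sampling: start positions uniform on the
    valid range, strand uniform, per-base substitution errors at
    *error_rate*.  The returned placements are the truth for the pileup
    oracle.
    """
    if read_length > genome.length:
        raise ValidationError("read_length exceeds the genome length")
    rng = np.random.default_rng(seed)
    reads: list[SequenceRecord] = []
    placements: list[Placement] = []
    if n_reads == 0:
        return reads, placements
    starts = rng.integers(0, genome.length - read_length + 1, size=n_reads)
    strands = rng.choice([1, -1], size=n_reads)
    for i, (start, strand) in enumerate(zip(starts, strands)):
        start = int(start)
        sub = genome.residues[start:start + read_length]
        if error_rate > 0:
            arr = np.array(list(sub))
            errs = np.flatnonzero(rng.random(read_length) < error_rate)
            for pos in errs:
                old = arr[pos]
                choices = [b for b in "ACGT" if b != old]
                arr[pos] = choices[rng.integers(len(choices))]
            sub = "".join(arr)
        if strand == -1:
            sub = reverse_complement(sub)
        rid = f"{id_prefix}_{i:06d}"
        reads.append(SequenceRecord(id=rid, description="", residues=sub))
        placements.append(Placement(read_id=rid, start=start,
                                    length=read_length, strand=int(strand)))
    return reads, placements


def placement_coverage(placements: Sequence[Placement], genome_length: int) -> np.ndarray:
    """Brute-force per-base pileup oracle: one counter increment per
    placed base."""
    cov = np.zeros(genome_length, dtype=np.int64)
    for p in placements:
        cov[p.start:p.end] += 1
    return cov


def synth_sam(placements: Sequence[Placement], genome: SequenceRecord,
              path: str | Path) -> Path:
    """Write one primary all-M alignment per placement as plain-text SAM.

    SEQ is the forward-strand reference substring; FLAG carries the strand
    bit.  The pileup of this file equals :func:`placement_coverage` exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{genome.id}\tLN:{genome.length}\n")
        for p in placements:
            if not (0 <= p.start and p.end <= genome.length):
                raise ValidationError(f"placement {p.read_id} out of bounds")
            flag = 16 if p.strand == -1 else 0
            seq = genome.residues[p.start:p.end]
            fh.write(f"{p.read_id}\t{flag}\t{genome.id}\t{p.start + 1}\t60\t"
                     f"{p.length}M\t*\t0\t0\t{seq}\t*\n")
    return path


def synth_blast_tabular(truth: Sequence[tuple[int, int, float, float]],
                        path: str | Path,
                        query_prefix: str = "q", subject_id: str = "reference",
                        minus: Sequence[bool] | None = None) -> Path:
    """Write 12-column tabular rows whose oriented subject intervals
    reproduce the truth ``(ref_start, ref_end, pident, bitscore)`` exactly.

    ``minus[i]`` swaps sstart/send to emulate a minus-strand match.
    """
    path = Path(path)
    minus = list(minus) if minus is not None else [False] * len(truth)
    if len(minus) != len(truth):
        raise ValidationError("minus flags must match truth length")
    with open(path, "w") as fh:
        for i, (start, end, pident, bitscore) in enumerate(truth):
            if not (0 <= start < end):
                raise ValidationError(f"truth interval [{start}, {end}) invalid")
            ln = end - start
            sstart, send = start + 1, end
            if minus[i]:
                sstart, send = send, sstart
            mism = int(round(ln * (100.0 - pident) / 100.0))
            fh.write(f"{query_prefix}{i}\t{subject_id}\t{pident:.2f}\t{ln}\t"
                     f"{mism}\t0\t1\t{ln}\t{sstart}\t{send}\t1e-50\t{bitscore:g}\n")
    return path
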