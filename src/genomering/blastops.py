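"""BLAST database creation, comparison runs, and tabular hit handling.

The central reference sequence is always the BLAST *subject* database; each
query genome (or read set) is searched against it and the hits are drawn on
the reference coordinate system.  The interchange format is the standard
12-column tabular output (``-outfmt 6``), which also serves as the fixture
mode: a precomputed tabular file can stand in for a live BLAST run, so the
whole downstream pipeline works without BLAST+ installed.
"""

from __future__ import annotations

import shlex
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ExternalToolError, InputOutputError, ParseError, ValidationError

#: program -> database type it searches against
PROGRAM_DBTYPE = {"blastn": "nucl", "blastx": "prot", "tblastx": "nucl"}


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular output (subject = reference)."""

    query_id: str
    subject_id: str
    pident: float
    aln_length: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self):
        if not (0.0 <= self.pident <= 100.0):
            raise ValidationError(f"pident {self.pident} outside [0, 100]")
        if self.aln_length < 1:
            raise ValidationError("alignment length must be >= 1")
        if self.evalue < 0:
            raise ValidationError("evalue must be >= 0")


@dataclass(frozen=True)
class HitFilter:
    """Inclusive identity/E-value cut-offs plus pass-through BLAST options."""

    min_identity: float = 0.0
    max_evalue: float = 10.0
    extra_options: str = ""

    def __post_init__(self):
        if not (0.0 <= self.min_identity <= 100.0):
            raise ValidationError("min_identity must be in [0, 100]")
        if self.max_evalue <= 0:
            raise ValidationError("max_evalue must be > 0")


def _require_executable(name: str) -> str:
    exe = shutil.which(name)
    if exe is None:
        raise ExternalToolError(
            f"{name} not found on PATH: install BLAST+ or supply precomputed "
            f"tabular files (fixture mode)"
        )
    return exe


def make_database(reference_fasta: str | Path, dbtype: str = "nucl",
                  out_prefix: str | Path | None = None) -> Path:
    """Run makeblastdb; returns the database prefix path."""
    if dbtype not in ("nucl", "prot"):
        raise ValidationError(f"dbtype must be nucl or prot, got {dbtype!r}")
    reference_fasta = Path(reference_fasta)
    if not reference_fasta.exists() or reference_fasta.stat().st_size == 0:
        raise InputOutputError(f"missing or empty FASTA: {reference_fasta}")
    exe = _require_executable("makeblastdb")
    prefix = Path(out_prefix) if out_prefix else reference_fasta.with_suffix(".blastdb")
    cmd = [exe, "-in", str(reference_fasta), "-dbtype", dbtype, "-out", str(prefix)]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalToolError(f"makeblastdb failed ({proc.returncode}): {proc.stderr.strip()}")
    return prefix


def database_dbtype(db: str | Path) -> str:
    """Infer a database's type from its index files."""
    db = Path(db)
    if db.with_suffix(db.suffix + ".nin").exists() or Path(str(db) + ".nin").exists():
        return "nucl"
    if db.with_suffix(db.suffix + ".pin").exists() or Path(str(db) + ".pin").exists():
        return "prot"
    raise InputOutputError(f"no BLAST database index found at prefix {db}")


def run_comparison(program: str, query_fasta: str | Path, db: str | Path,
                   filter: HitFilter | None = None,
                   out_path: str | Path | None = None) -> Path:
    """Run blastn/blastx/tblastx with the reference database as subject.

    Read sets go to blastx directly as nucleotide queries; blastx performs
    the translation into peptides internally.  Extra options in the filter
    are appended verbatim, so any BLAST switch (e.g. ``-dust no`` to disable
    the low-complexity filter) can be passed through.
    """
    if program not in PROGRAM_DBTYPE:
        raise ValidationError(f"unknown program {program!r}")
    filter = filter or HitFilter()
    expected = PROGRAM_DBTYPE[program]
    actual = database_dbtype(db)
    if actual != expected:
        raise ValidationError(
            f"{program} needs a {expected} database but {db} is {actual}"
        )
    query_fasta = Path(query_fasta)
    if not query_fasta.exists() or query_fasta.stat().st_size == 0:
        raise InputOutputError(f"missing or empty query FASTA: {query_fasta}")
    exe = _require_executable(program)
    out = Path(out_path) if out_path else query_fasta.with_suffix(".blast.tab")
    cmd = [exe, "-query", str(query_fasta), "-db", str(db), "-outfmt", "6",
           "-evalue", repr(filter.max_evalue), "-out", str(out)]
    if filter.extra_options:
        cmd.extend(shlex.split(filter.extra_options))
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise ExternalToolError(f"{program} failed ({proc.returncode}): {proc.stderr.strip()}")
    return out


def parse_tabular(path: str | Path) -> list[BlastHit]:
    """Parse 12-column tabular output; '#' comment lines are ignored."""
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    hits = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"expected >= 12 tab-separated fields, got {len(fields)}",
                                 path=str(path), line=lineno)
            try:
                hits.append(BlastHit(
                    query_id=fields[0], subject_id=fields[1],
                    pident=float(fields[2]), aln_length=int(fields[3]),
                    mismatches=int(fields[4]), gapopens=int(fields[5]),
                    qstart=int(fields[6]), qend=int(fields[7]),
                    sstart=int(fields[8]), send=int(fields[9]),
                    evalue=float(fields[10]), bitscore=float(fields[11]),
                ))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"bad field: {exc}", path=str(path), line=lineno) from exc
    return hits


def filter_hits(hits: Iterable[BlastHit], filter: HitFilter) -> list[BlastHit]:
    """Keep hits with pident >= min_identity and evalue <= max_evalue (inclusive)."""
    return [h for h in hits
            if h.pident >= filter.min_identity and h.evalue <= filter.max_evalue]


def orient_to_reference(hit: BlastHit) -> tuple[int, int]:
    """Subject span as a forward 0-based half-open reference interval.

    Minus-strand matches report sstart > send; both orderings map to the
    same forward interval.
    """
    if hit.sstart < 1 or hit.send < 1:
        raise ValidationError("subject coordinates must be >= 1")
    return min(hit.sstart, hit.send) - 1, max(hit.sstart, hit.send)


def hit_is_reverse(hit: BlastHit) -> bool:
    """True when query and subject run in opposite directions."""
    return (hit.sstart > hit.send) != (hit.qstart > hit.qend)


def sort_for_drawing(hits: Sequence[BlastHit]) -> list[BlastHit]:
    """Ascending bitscore, stable: the highest-scoring hits are drawn last
    and therefore painted on top of weaker overlapping matches."""
    return sorted(hits, key=lambda h: h.bitscore)
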