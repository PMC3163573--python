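"""Sequence input/output and the concatenated reference coordinate system.

All coordinates inside the package are 0-based half-open; GenBank/EMBL
(1-based inclusive) convert at the parser edge.  A multi-record input file
(multi-FASTA, or multi-record GenBank/EMBL) is concatenated in file order to
form the central reference ring, with each record becoming one named segment
of the :class:`ReferenceMap`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import InputOutputError, ParseError, ValidationError

_FORMATS = {"fasta": "fasta", "genbank": "genbank", "embl": "embl"}

DECORATIONS = ("arc", "arrow_cw", "arrow_ccw", "bar")
PLACEMENTS = ("inside", "outside")


@dataclass(frozen=True)
class SequenceRecord:
    """One sequence: id is the first whitespace-delimited word of the header."""

    id: str
    description: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValidationError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r} has no residues")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Segment:
    name: str
    offset: int
    length: int

    @property
    def end(self) -> int:
        return self.offset + self.length


@dataclass(frozen=True)
class ReferenceMap:
    """Concatenated reference: ordered segments with cumulative offsets."""

    segments: tuple[Segment, ...]
    circular: bool = True

    def __post_init__(self):
        if not self.segments:
            raise ValidationError("ReferenceMap needs at least one segment")
        pos = 0
        for seg in self.segments:
            if seg.offset != pos:
                raise ValidationError(
                    f"segment {seg.name!r} offset {seg.offset} != cumulative {pos}"
                )
            if seg.length <= 0:
                raise ValidationError(f"segment {seg.name!r} has non-positive length")
            pos += seg.length

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def segment_by_name(self, name: str) -> Segment:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise ValidationError(f"no reference segment named {name!r}")


@dataclass(frozen=True)
class FeatureAnnotation:
    """A labelled span on the reference, 0-based half-open."""

    start: int
    end: int
    label: str = ""
    color: str = "#000000"
    decoration: str = "arc"
    placement: str = "outside"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"annotation span [{self.start}, {self.end}) is empty or negative"
            )
        if self.decoration not in DECORATIONS:
            raise ValidationError(f"unknown decoration {self.decoration!r}")
        if self.placement not in PLACEMENTS:
            raise ValidationError(f"unknown placement {self.placement!r}")


def read_sequences(path: str | Path, format: str = "fasta") -> list[SequenceRecord]:
    """Read FASTA/GenBank/EMBL into records (residues uppercased)."""
    if format not in _FORMATS:
        raise ValidationError(f"unknown sequence format {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    try:
        seqs = list(SeqIO.parse(str(path), _FORMATS[format]))
    except Exception as exc:  # biopython raises ValueError and friends
        raise ParseError(f"cannot parse as {format}: {exc}", path=str(path)) from exc
    records = []
    for rec in seqs:
        desc = rec.description or ""
        # Bio.SeqIO keeps the id as the first word of the description; strip it.
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        residues = str(rec.seq).upper()
        if not residues:
            raise ParseError(f"record {rec.id!r} has an empty sequence", path=str(path))
        records.append(SequenceRecord(id=rec.id, description=desc, residues=residues))
    if not records:
        raise ParseError("zero records", path=str(path))
    return records


def write_fasta(records: Sequence[SequenceRecord], path: str | Path, width: int = 70) -> Path:
    """Write multi-FASTA, wrapping sequence lines at *width* columns."""
    if not records:
        raise ValidationError("refusing to write an empty FASTA")
    path = Path(path)
    try:
        with open(path, "w") as fh:
            for rec in records:
                header = f">{rec.id} {rec.description}".rstrip()
                fh.write(header + "\n")
                for i in range(0, rec.length, width):
                    fh.write(rec.residues[i:i + width] + "\n")
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc
    return path


def build_reference_map(records: Sequence[SequenceRecord], circular: bool = True) -> ReferenceMap:
    """Concatenate records (input order) into the reference coordinate system."""
    if not records:
        raise ValidationError("reference needs at least one sequence")
    segments = []
    offset = 0
    for rec in records:
        segments.append(Segment(name=rec.id, offset=offset, length=rec.length))
        offset += rec.length
    return ReferenceMap(segments=tuple(segments), circular=circular)


def concatenate(records: Sequence[SequenceRecord], id: str = "reference") -> SequenceRecord:
    """Join records into the single concatenated reference sequence."""
    if not records:
        raise ValidationError("nothing to concatenate")
    return SequenceRecord(
        id=id,
        description=f"concatenation of {len(records)} sequence(s)",
        residues="".join(r.residues for r in records),
    )


def header_annotations(refmap: ReferenceMap, color: str = "#333333") -> list[FeatureAnnotation]:
    """One outside label per reference segment, spanning the segment exactly.

    This is how a concatenated gene-panel reference gets labelled with its
    FASTA headers around the outside of the image.
    """
    return [
        FeatureAnnotation(
            start=seg.offset,
            end=seg.end,
            label=seg.name,
            color=color,
            decoration="arc",
            placement="outside",
        )
        for seg in refmap.segments
    ]


def _sniff_flatfile_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return "embl" if line.startswith("ID ") else "genbank"
    raise ParseError("empty file", path=str(path))


def extract_annotations(
    path: str | Path,
    feature_key: str,
    qualifier_substring: str = "",
    format: str | None = None,
    color: str = "#000080",
    placement: str = "outside",
) -> list[FeatureAnnotation]:
    """Pull features of *feature_key* whose qualifier text contains a substring.

    All qualifier values of a feature are concatenated and searched
    case-sensitively; an empty substring matches every feature of the key.
    Multi-record files are treated as concatenated: feature coordinates are
    shifted by the cumulative offset of their record.  Compound locations are
    flattened to their outer span; strand shows up only as the arrow
    decoration.
    """
    if not feature_key:
        raise ValidationError("feature_key must be non-empty")
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    fmt = format or _sniff_flatfile_format(path)
    try:
        seqs = list(SeqIO.parse(str(path), _FORMATS[fmt]))
    except Exception as exc:
        raise ParseError(f"cannot parse as {fmt}: {exc}", path=str(path)) from exc
    out: list[FeatureAnnotation] = []
    offset = 0
    for rec in seqs:
        for feat in rec.features:
            if feat.type != feature_key:
                continue
            blob = " ".join(
                str(v) for values in feat.qualifiers.values() for v in values
            )
            if qualifier_substring and qualifier_substring not in blob:
                continue
            start = int(feat.location.start) + offset
            end = int(feat.location.end) + offset
            if end <= start:
                continue
            strand = feat.location.strand
            deco = "arrow_cw" if strand == 1 else "arrow_ccw" if strand == -1 else "arc"
            label = ""
            for key in ("label", "gene", "note"):
                if key in feat.qualifiers and feat.qualifiers[key]:
                    label = str(feat.qualifiers[key][0])
                    break
            out.append(
                FeatureAnnotation(
                    start=start, end=end, label=label, color=color,
                    decoration=deco, placement=placement,
                )
            )
        offset += len(rec.seq)
    return out


_HEX_RE = re.compile(r"^#[0-9a-fA-F]{6}$")


def read_annotation_table(path: str | Path) -> list[FeatureAnnotation]:
    """Read a tab-delimited annotation table.

    Columns: start, end (1-based inclusive, as users write them), label,
    colour (#rrggbb), decoration, placement.  Label onward are optional;
    lines starting with '#' are comments.
    """
    path = Path(path)
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError("need at least start and end columns",
                                 path=str(path), line=lineno)
            try:
                start1, end1 = int(fields[0]), int(fields[1])
            except ValueError as exc:
                raise ParseError(f"non-integer coordinate: {exc}",
                                 path=str(path), line=lineno) from exc
            label = fields[2] if len(fields) > 2 else ""
            color = fields[3] if len(fields) > 3 and fields[3] else "#000000"
            if not _HEX_RE.match(color):
                raise ParseError(f"bad colour {color!r} (want #rrggbb)",
                                 path=str(path), line=lineno)
            deco = fields[4] if len(fields) > 4 and fields[4] else "arc"
            placement = fields[5] if len(fields) > 5 and fields[5] else "outside"
            try:
                out.append(FeatureAnnotation(start=start1 - 1, end=end1, label=label,
                                             color=color, decoration=deco,
                                             placement=placement))
            except ValidationError as exc:
                raise ParseError(str(exc), path=str(path), line=lineno) from exc
    return out


def write_annotation_table(annotations: Iterable[FeatureAnnotation], path: str | Path) -> Path:
    """Inverse of :func:`read_annotation_table` (1-based inclusive on disk)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# start\tend\tlabel\tcolor\tdecoration\tplacement\n")
        for a in annotations:
            fh.write(f"{a.start + 1}\t{a.end}\t{a.label}\t{a.color}"
                     f"\t{a.decoration}\t{a.placement}\n")
    return path
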