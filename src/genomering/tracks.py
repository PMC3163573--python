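"""Numeric tracks over the reference.

GC content and GC skew in sliding windows, user-supplied graph files,
per-base read coverage from SAM or ACE assemblies, contig-boundary
segments, coverage-anomaly intervals, and the lift-over of a track across a
reordered assembly via a BLASTn interval mapping.

A :class:`ValueTrack` stores run-length-compacted bins so multi-megabase
per-base tracks stay memory-light; ``to_array`` expands to a per-base numpy
array when exact per-base arithmetic is needed.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam
from Bio.Sequencing import Ace

from .blastops import BlastHit, hit_is_reverse, orient_to_reference
from .errors import InputOutputError, ParseError, ValidationError
from .seqio import ReferenceMap, SequenceRecord


@dataclass(frozen=True)
class ValueTrack:
    """Binned numeric values over [0, reference_length).

    Bins are sorted, non-overlapping ``(start, end, value)`` triples;
    positions not covered by any bin are implicitly 0.  ``mean`` and ``sd``
    are the length-weighted mean and population standard deviation over the
    binned positions.
    """

    bins: tuple[tuple[int, int, float], ...]
    reference_length: int

    def __post_init__(self):
        prev_end = 0
        for (s, e, _v) in self.bins:
            if not (0 <= s < e <= self.reference_length):
                raise ValidationError(f"bin [{s}, {e}) outside [0, {self.reference_length})")
            if s < prev_end:
                raise ValidationError(f"bin [{s}, {e}) overlaps previous bin")
            prev_end = e

    @property
    def covered_length(self) -> int:
        return sum(e - s for (s, e, _v) in self.bins)

    @property
    def mean(self) -> float:
        n = self.covered_length
        if n == 0:
            return 0.0
        return float(sum(v * (e - s) for (s, e, v) in self.bins)) / n

    @property
    def sd(self) -> float:
        n = self.covered_length
        if n == 0:
            return 0.0
        mu = self.mean
        var = sum((v - mu) ** 2 * (e - s) for (s, e, v) in self.bins) / n
        return float(np.sqrt(var))

    def to_array(self) -> np.ndarray:
        """Per-base expansion; uncovered positions are 0."""
        arr = np.zeros(self.reference_length, dtype=float)
        for (s, e, v) in self.bins:
            arr[s:e] = v
        return arr

    @property
    def values(self) -> list[float]:
        return [v for (_s, _e, v) in self.bins]


def track_from_array(arr: np.ndarray, reference_length: int | None = None) -> ValueTrack:
    """Run-length compact a per-base array into a ValueTrack (zero runs kept
    as explicit bins so the track tiles the reference)."""
    arr = np.asarray(arr, dtype=float)
    n = len(arr) if reference_length is None else reference_length
    if len(arr) != n:
        raise ValidationError("array length disagrees with reference_length")
    if n == 0:
        return ValueTrack(bins=(), reference_length=0)
    change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    bins = tuple((int(s), int(e), float(arr[s])) for s, e in zip(starts, ends))
    return ValueTrack(bins=bins, reference_length=n)


@dataclass(frozen=True)
class ContigSegments:
    """Reference tiling by contig, with alternating colour indices."""

    segments: tuple[tuple[int, int, str, int], ...]  # (start, end, name, color_index)
    total_length: int

    def __post_init__(self):
        pos = 0
        for i, (s, e, _name, ci) in enumerate(self.segments):
            if s != pos or e <= s:
                raise ValidationError("contig segments must tile the reference")
            if ci != i % 2:
                raise ValidationError("color_index must alternate starting at 0")
            pos = e
        if self.segments and pos != self.total_length:
            raise ValidationError("contig segments do not cover the reference")


@dataclass(frozen=True)
class MappingEntry:
    old_start: int
    old_end: int
    new_start: int
    new_end: int
    orientation: int  # +1 or -1
    score: float

    def __post_init__(self):
        if self.old_end - self.old_start != self.new_end - self.new_start:
            raise ValidationError("mapping entry spans differ in length")
        if self.orientation not in (1, -1):
            raise ValidationError("orientation must be +1 or -1")
        if self.score < 0:
            raise ValidationError("score must be >= 0")


IntervalMapping = tuple  # alias: tuple[MappingEntry, ...]


# ---------------------------------------------------------------------------
# GC statistics

def _window_starts(length: int, window: int, step: int, circular: bool) -> list[int]:
    if not (1 <= step <= window):
        raise ValidationError("need 1 <= step <= window")
    if window > length:
        if not circular:
            raise ValidationError(f"window {window} exceeds sequence length {length}")
        raise ValidationError("window longer than the sequence is not supported")
    return list(range(0, length, step))


def _window_seq(residues: str, start: int, window: int, circular: bool) -> str:
    end = start + window
    if end <= len(residues):
        return residues[start:end]
    if circular:
        return residues[start:] + residues[:end - len(residues)]
    return residues[start:]  # final truncated window on a linear sequence


def _gc_track(seq: SequenceRecord, window: int, step: int, circular: bool,
              skew: bool) -> ValueTrack:
    residues = seq.residues
    L = seq.length
    bins = []
    for start in _window_starts(L, window, step, circular):
        w = _window_seq(residues, start, window, circular)
        g = w.count("G")
        c = w.count("C")
        if skew:
            denom = g + c
            value = (g - c) / denom if denom else 0.0
        else:
            denom = g + c + w.count("A") + w.count("T")
            value = (g + c) / denom if denom else 0.0
        bin_end = min(start + step, L)
        bins.append((start, bin_end, value))
    return ValueTrack(bins=tuple(bins), reference_length=L)


def gc_content(seq: SequenceRecord, window: int = 10_000, step: int | None = None,
               circular: bool = True) -> ValueTrack:
    """GC fraction (#G+#C)/(#A+#C+#G+#T) per sliding window.

    Non-ACGT characters are excluded from both numerator and denominator.
    With the default step == window the windows are non-overlapping; on a
    circular sequence the last windows wrap past the origin.
    """
    return _gc_track(seq, window, step or window, circular, skew=False)


def gc_skew(seq: SequenceRecord, window: int = 10_000, step: int | None = None,
            circular: bool = True) -> ValueTrack:
    """GC skew (#G-#C)/(#G+#C) per window; 0 where the window has no G or C.

    Sign changes of the cumulative skew conventionally mark the replication
    origin and terminus in prokaryote chromosomes.
    """
    return _gc_track(seq, window, step or window, circular, skew=True)


def skew_from_mean(track: ValueTrack) -> ValueTrack:
    """Centre a track on its length-weighted mean (the default graph mode)."""
    if not track.bins:
        raise ValidationError("cannot centre an empty track")
    mu = track.mean
    bins = tuple((s, e, v - mu) for (s, e, v) in track.bins)
    return ValueTrack(bins=bins, reference_length=track.reference_length)


def scale_zero_to_max(track: ValueTrack, user_max: float) -> ValueTrack:
    """Clamp to [0, user_max] then scale into [0, 1] for the renderer."""
    if user_max <= 0:
        raise ValidationError("user_max must be > 0")
    bins = tuple((s, e, min(max(v, 0.0), user_max) / user_max) for (s, e, v) in track.bins)
    return ValueTrack(bins=bins, reference_length=track.reference_length)


# ---------------------------------------------------------------------------
# User graph files

def read_graph_file(path: str | Path, reference_length: int) -> ValueTrack:
    """Read a space/tab-delimited user graph file.

    Two dialects: three columns ``start stop value`` with 1-based inclusive
    coordinates, or a single column with one value per base (line i is the
    value for base i-1; the line count must equal the reference length).
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    rows: list[list[str]] = []
    ncols = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if ncols is None:
                ncols = len(fields)
                if ncols not in (1, 3):
                    raise ParseError(f"expected 1 or 3 columns, got {ncols}",
                                     path=str(path), line=lineno)
            elif len(fields) != ncols:
                raise ParseError(f"mixed column counts ({len(fields)} vs {ncols})",
                                 path=str(path), line=lineno)
            rows.append(fields)
    if ncols == 3:
        bins = []
        for fields in rows:
            try:
                start1, stop1, value = int(fields[0]), int(fields[1]), float(fields[2])
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", path=str(path)) from exc
            bins.append((start1 - 1, stop1, value))
        bins.sort(key=lambda b: b[0])
        return ValueTrack(bins=tuple(bins), reference_length=reference_length)
    if len(rows) != reference_length:
        raise ParseError(
            f"per-base dialect has {len(rows)} values but the reference is "
            f"{reference_length} bp", path=str(path))
    try:
        arr = np.array([float(r[0]) for r in rows])
    except ValueError as exc:
        raise ParseError(f"non-numeric value: {exc}", path=str(path)) from exc
    return track_from_array(arr, reference_length)


# ---------------------------------------------------------------------------
# Coverage from read mappings

_COV_CONSUME = {0, 7, 8}       # M, =, X cover the reference
_REF_ADVANCE = {0, 2, 3, 7, 8}  # + D, N advance without covering


def _ensure_sam_header(path: Path, refmap: ReferenceMap) -> Path:
    """pysam needs @SQ lines; synthesise them from the refmap if absent."""
    with open(path) as fh:
        text = fh.read()
    if any(line.startswith("@SQ") for line in text.splitlines()):
        return path
    header = "".join(f"@SQ\tSN:{s.name}\tLN:{s.length}\n" for s in refmap.segments)
    tmp = tempfile.NamedTemporaryFile("w", suffix=".sam", delete=False)
    tmp.write(header)
    tmp.write(text)
    tmp.close()
    return Path(tmp.name)


def coverage_from_sam(path: str | Path, refmap: ReferenceMap) -> ValueTrack:
    """Per-base read coverage over the concatenated reference from a SAM file.

    A position counts as covered when a CIGAR M/=/X op consumes it; deletion
    (D) and skip (N) spans advance along the reference without covering.
    Unmapped, secondary and supplementary records are ignored.  Reads may
    map to any named reference segment; coordinates shift by the segment
    offset into the concatenated frame.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    sam_path = _ensure_sam_header(path, refmap)
    counts = np.zeros(refmap.total_length, dtype=np.int64)
    offsets = {s.name: s.offset for s in refmap.segments}
    lengths = {s.name: s.length for s in refmap.segments}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            rname = rec.reference_name
            if rname not in offsets:
                raise ParseError(f"read {rec.query_name!r} maps to unknown "
                                 f"reference {rname!r}", path=str(path))
            pos = rec.reference_start
            if pos < 0 or rec.cigartuples is None:
                continue
            for op, ln in rec.cigartuples:
                if op in _COV_CONSUME:
                    if pos + ln > lengths[rname]:
                        raise ParseError(
                            f"read {rec.query_name!r} extends past the end of "
                            f"{rname!r} ({pos + ln} > {lengths[rname]})", path=str(path))
                    o = offsets[rname]
                    counts[o + pos:o + pos + ln] += 1
                    pos += ln
                elif op in _REF_ADVANCE:
                    pos += ln
    return track_from_array(counts.astype(float), refmap.total_length)


def _ace_contigs_via_biopython(path: Path):
    with open(path) as fh:
        ace = Ace.read(fh)
    out = []
    for contig in ace.contigs:
        read_len = {rd.rd.name: len(rd.rd.sequence) for rd in contig.reads if rd.rd}
        placements = [(af.name, af.padded_start) for af in contig.af]
        out.append((contig.name, contig.sequence, placements, read_len))
    return out


def _ace_contigs_via_scanner(path: Path):
    """Minimal CO/AF/RD section scanner, used only when the primary parser
    rejects the file (e.g. a contig that carries zero reads)."""
    out = []
    name = None
    padded: list[str] = []
    placements: list[tuple[str, int]] = []
    read_len: dict[str, int] = {}
    rd_name = None
    rd_seq: list[str] = []
    mode = None  # "co" or "rd" while accumulating sequence lines

    def flush_rd():
        nonlocal rd_name, rd_seq
        if rd_name is not None:
            read_len[rd_name] = len("".join(rd_seq))
            rd_name, rd_seq = None, []

    def flush_contig():
        nonlocal name, padded, placements, read_len
        flush_rd()
        if name is not None:
            out.append((name, "".join(padded), placements, read_len))
        name, padded, placements, read_len = None, [], [], {}

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            tag = line.split(" ", 1)[0] if line else ""
            if tag == "CO":
                flush_contig()
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError("malformed CO line", path=str(path))
                name = fields[1]
                mode = "co"
            elif tag == "AF":
                fields = line.split()
                if len(fields) < 4:
                    raise ParseError("malformed AF line", path=str(path))
                placements.append((fields[1], int(fields[3])))
                mode = None
            elif tag == "RD":
                flush_rd()
                fields = line.split()
                if len(fields) < 2:
                    raise ParseError("malformed RD line", path=str(path))
                rd_name = fields[1]
                mode = "rd"
            elif tag in ("AS", "BQ", "BS", "QA", "DS", "CT{", "RT{", "WA{", "}"):
                mode = None
            elif line.strip():
                if mode == "co":
                    padded.append(line.strip())
                elif mode == "rd":
                    rd_seq.append(line.strip())
    flush_contig()
    return out


def coverage_from_ace(path: str | Path) -> tuple[dict[str, ValueTrack], list[str]]:
    """Per-contig read coverage from an ACE assembly file.

    Coverage is counted on the contig's padded coordinates — a position is
    covered by every read whose padded placement (AF line) spans it — then
    projected to unpadded coordinates by dropping the contig's ``*`` pad
    columns.  Returns the tracks keyed by contig name plus the contig order.
    """
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    try:
        contigs = _ace_contigs_via_biopython(path)
    except Exception:
        try:
            contigs = _ace_contigs_via_scanner(path)
        except ParseError:
            raise
        except Exception as exc:
            raise ParseError(f"cannot parse ACE: {exc}", path=str(path)) from exc
    tracks: dict[str, ValueTrack] = {}
    order: list[str] = []
    for (name, padded, placements, read_len) in contigs:
        counts = np.zeros(len(padded), dtype=np.int64)
        for (af_name, padded_start) in placements:
            if af_name not in read_len:
                raise ParseError(f"AF entry {af_name!r} has no matching RD section",
                                 path=str(path))
            start = padded_start - 1  # AF is 1-based padded
            end = start + read_len[af_name]
            counts[max(start, 0):min(end, len(padded))] += 1
        keep = np.array([b != "*" for b in padded])
        depadded = counts[keep].astype(float)
        tracks[name] = track_from_array(depadded, int(keep.sum()))
        order.append(name)
    if not order:
        raise ParseError("no CO contig sections found", path=str(path))
    return tracks, order


def concat_contig_tracks(tracks: dict[str, ValueTrack], refmap: ReferenceMap) -> ValueTrack:
    """Lay per-contig tracks onto the concatenated reference frame."""
    arr = np.zeros(refmap.total_length)
    for seg in refmap.segments:
        if seg.name not in tracks:
            continue
        t = tracks[seg.name]
        if t.reference_length != seg.length:
            raise ValidationError(
                f"track for {seg.name!r} is {t.reference_length} bp but the "
                f"segment is {seg.length} bp")
        arr[seg.offset:seg.end] = t.to_array()
    return track_from_array(arr, refmap.total_length)


def contig_boundaries(refmap: ReferenceMap) -> ContigSegments:
    """Alternating red/blue contig segments for the draft-assembly ring."""
    segs = tuple(
        (seg.offset, seg.end, seg.name, i % 2)
        for i, seg in enumerate(refmap.segments)
    )
    return ContigSegments(segments=segs, total_length=refmap.total_length)


# ---------------------------------------------------------------------------
# Coverage lift-over across a reordered assembly

def mapping_from_blast(hits: Sequence[BlastHit]) -> tuple[MappingEntry, ...]:
    """Interval mapping from a BLASTn of the original assembly (query)
    against the reordered reference (subject).

    Orientation is -1 when exactly one of the query/subject spans is
    inverted.  Gapped hits whose query and subject spans differ in length
    are truncated to the shorter span, measured from each interval's start.
    """
    entries = []
    for hit in hits:
        old_start = min(hit.qstart, hit.qend) - 1
        old_end = max(hit.qstart, hit.qend)
        new_start, new_end = orient_to_reference(hit)
        span = min(old_end - old_start, new_end - new_start)
        entries.append(MappingEntry(
            old_start=old_start, old_end=old_start + span,
            new_start=new_start, new_end=new_start + span,
            orientation=-1 if hit_is_reverse(hit) else 1,
            score=hit.bitscore,
        ))
    return tuple(entries)


def remap_track(track: ValueTrack, mapping: Sequence[MappingEntry],
                new_length: int) -> ValueTrack:
    """Transport per-base values through an interval mapping.

    Each new position takes the value of its mapped old position; where
    mapping entries overlap, the highest-score entry wins (ties: the later
    entry in the input).  Uncovered new positions are 0.  Orientation -1
    reverses the transported values within the block.
    """
    old = track.to_array()
    new = np.zeros(new_length)
    for entry in sorted(mapping, key=lambda e: e.score):
        if entry.old_end > len(old) or entry.new_end > new_length:
            raise ValidationError("mapping entry outside track bounds")
        block = old[entry.old_start:entry.old_end]
        if entry.orientation == -1:
            block = block[::-1]
        new[entry.new_start:entry.new_end] = block
    return track_from_array(new, new_length)


# ---------------------------------------------------------------------------
# Anomalies

def coverage_anomalies(track: ValueTrack, k: float = 1.0) -> list[tuple[int, int]]:
    """Maximal runs where |value - mean| > k standard deviations.

    Deviation is two-sided and uses the population standard deviation of
    the track; a constant track (sd = 0) has no anomalies.  Adjacent
    anomalous bins merge into one interval.
    """
    if k <= 0:
        raise ValidationError("k must be > 0")
    mu, sd = track.mean, track.sd
    if sd == 0:
        return []
    out: list[tuple[int, int]] = []
    for (s, e, v) in track.bins:
        if abs(v - mu) > k * sd:
            if out and out[-1][1] == s:
                out[-1] = (out[-1][0], e)
            else:
                out.append((s, e))
    return out


def write_bed(intervals: Iterable[tuple[int, int]], path: str | Path,
              name: str = "anomaly") -> Path:
    """Write intervals as BED (0-based half-open)."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, (s, e) in enumerate(intervals):
            fh.write(f"ref\t{s}\t{e}\t{name}_{i + 1}\n")
    return path


def write_graph_file(track: ValueTrack, path: str | Path) -> Path:
    """Write a track in the 3-column graph dialect (1-based inclusive)."""
    path = Path(path)
    with open(path, "w") as fh:
        for (s, e, v) in track.bins:
            fh.write(f"{s + 1}\t{e}\t{v:g}\n")
    return path
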