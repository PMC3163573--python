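"""Resolve ring specifications plus parsed data into a renderer-ready model.

A ring is one annulus of the circular image.  BLAST rings turn tabular hits
into arcs whose opacity encodes percent identity between user thresholds
(the identity gradient); graph rings carry signed or scaled bin heights;
contig rings alternate two colours; annotation rings carry labelled spans.
Everything here is a pure function of its inputs so that repeated runs on
identical data render byte-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .blastops import BlastHit, orient_to_reference, sort_for_drawing
from .errors import ValidationError
from .seqio import FeatureAnnotation, ReferenceMap
from .tracks import ContigSegments, ValueTrack, scale_zero_to_max, skew_from_mean

RING_KINDS = ("blast", "graph", "contigs", "annotations")
GRAPH_MODES = ("mean_skew", "zero_to_max")

#: minimum opacity of a hit that just clears the lower identity threshold —
#: faint but still visible against a white background
O_MIN = 0.1


@dataclass(frozen=True)
class RingSpec:
    """Declarative description of one ring, innermost-first in a profile."""

    kind: str
    members: tuple[str, ...] = ()
    color: str = "#cc0000"
    width: float = 30.0
    lower_identity: float = 70.0
    upper_identity: float = 100.0
    legend_text: str = ""
    graph_mode: str = "mean_skew"
    graph_max: float | None = None

    def __post_init__(self):
        if self.kind not in RING_KINDS:
            raise ValidationError(f"unknown ring kind {self.kind!r}")
        if not self.members:
            raise ValidationError("ring needs at least one member data source")
        if len(self.members) > 1 and self.kind != "blast":
            raise ValidationError("only blast rings may collate multiple members")
        if not (0 <= self.lower_identity <= self.upper_identity <= 100):
            raise ValidationError("need 0 <= lower_identity <= upper_identity <= 100")
        if self.width <= 0:
            raise ValidationError("ring width must be > 0")
        if self.graph_mode not in GRAPH_MODES:
            raise ValidationError(f"unknown graph_mode {self.graph_mode!r}")
        if self.graph_mode == "zero_to_max" and self.kind == "graph" and (
                self.graph_max is None or self.graph_max <= 0):
            raise ValidationError("zero_to_max graphs need graph_max > 0")


@dataclass(frozen=True)
class Arc:
    """One drawable annular span; z is the paint rank within its ring."""

    start: int
    end: int
    color: str
    opacity: float
    z: int
    ring_index: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValidationError("arc span empty or negative")
        if not (0 < self.opacity <= 1):
            raise ValidationError("opacity must be in (0, 1]")


@dataclass(frozen=True)
class GraphProfile:
    """Heights per bin: [-1, 1] for mean_skew, [0, 1] for zero_to_max."""

    bins: tuple[tuple[int, int, float], ...]
    mode: str


@dataclass(frozen=True)
class ResolvedRing:
    spec: RingSpec
    ring_index: int
    arcs: tuple[Arc, ...] = ()
    graph: GraphProfile | None = None
    contigs: ContigSegments | None = None
    annotations: tuple[FeatureAnnotation, ...] = ()


@dataclass(frozen=True)
class ImageModel:
    """Everything the renderer needs, innermost ring first."""

    refmap: ReferenceMap
    rings: tuple[ResolvedRing, ...]
    annotations: tuple[FeatureAnnotation, ...]
    tick_major: int
    tick_minor: int
    title: str = ""
    legend: tuple[tuple[str, str, float, float], ...] = ()
    # legend entries: (text, color, lower_identity, upper_identity)


def identity_to_opacity(pident: float, lower: float, upper: float,
                        o_min: float = O_MIN) -> float | None:
    """Map percent identity to opacity on the sliding identity gradient.

    Below *lower* the hit is omitted entirely (``None``) — gene absence shows
    as a blank/white region rather than a ghost arc.  At or above *upper*
    the arc is fully opaque; between the two the map is linear from *o_min*
    to 1.
    """
    if lower > upper:
        raise ValidationError("lower threshold exceeds upper")
    if pident < lower:
        return None
    if pident >= upper:
        return 1.0
    return o_min + (1.0 - o_min) * (pident - lower) / (upper - lower)


def split_wrapping(start: int, end: int, total: int) -> list[tuple[int, int]]:
    """Split an interval that crosses the origin of a circular reference.

    ``end`` may exceed ``total`` (wrap notation); the result is one or two
    in-bounds intervals whose lengths sum to the original length.
    """
    if end <= total:
        return [(start, end)]
    return [(start, total), (0, end - total)]


def build_blast_ring(hit_sets: Sequence[tuple[str, Sequence[BlastHit]]],
                     spec: RingSpec, refmap: ReferenceMap,
                     ring_index: int = 0) -> list[Arc]:
    """Pool hits from all member sources into one collated ring of arcs.

    Hits below the lower identity threshold are dropped; the rest are
    oriented onto the reference, sorted ascending by bitscore, and assigned
    increasing z so the strongest matches paint last (on top).
    """
    if spec.kind != "blast":
        raise ValidationError("build_blast_ring needs a blast-kind spec")
    loaded = {sid for sid, _ in hit_sets}
    missing = [m for m in spec.members if m not in loaded]
    if missing:
        raise ValidationError(f"ring member(s) with no loaded data: {missing}")
    pooled: list[BlastHit] = []
    for sid, hits in hit_sets:
        if sid in spec.members:
            pooled.extend(hits)
    arcs: list[Arc] = []
    z = 0
    total = refmap.total_length
    for hit in sort_for_drawing(pooled):
        opacity = identity_to_opacity(hit.pident, spec.lower_identity, spec.upper_identity)
        if opacity is None:
            continue
        start, end = orient_to_reference(hit)
        if end > total:
            raise ValidationError(
                f"hit {hit.query_id!r} subject span [{start}, {end}) exceeds the "
                f"reference length {total}")
        for (s, e) in split_wrapping(start, end, total):
            arcs.append(Arc(start=s, end=e, color=spec.color, opacity=opacity,
                            z=z, ring_index=ring_index))
            z += 1
    return arcs


def uncovered_intervals(intervals: Sequence[tuple[int, int]],
                        total_length: int) -> list[tuple[int, int]]:
    """Maximal reference spans not covered by any interval.

    These are the blank/white regions of a ring — the visual signature of
    sequence absent from a query genome.
    """
    mask = [False] * total_length
    for (s, e) in intervals:
        for (ws, we) in split_wrapping(s, e, total_length):
            for i in range(ws, we):
                mask[i] = True
    gaps: list[tuple[int, int]] = []
    start = None
    for i, covered in enumerate(mask):
        if not covered and start is None:
            start = i
        elif covered and start is not None:
            gaps.append((start, i))
            start = None
    if start is not None:
        gaps.append((start, total_length))
    return gaps


def build_graph_ring(track: ValueTrack, spec: RingSpec) -> GraphProfile:
    """Scale a track into renderer heights.

    ``mean_skew`` (the default): centre on the length-weighted mean, then
    scale so the largest |height| is 1 (an all-constant track becomes flat
    zero).  ``zero_to_max``: clamp to [0, graph_max] and scale into [0, 1].
    """
    if spec.kind != "graph":
        raise ValidationError("build_graph_ring needs a graph-kind spec")
    if spec.graph_mode == "zero_to_max":
        scaled = scale_zero_to_max(track, spec.graph_max)
        return GraphProfile(bins=scaled.bins, mode="zero_to_max")
    centred = skew_from_mean(track)
    peak = max((abs(v) for v in centred.values), default=0.0)
    if peak == 0:
        bins = tuple((s, e, 0.0) for (s, e, _v) in centred.bins)
    else:
        bins = tuple((s, e, v / peak) for (s, e, v) in centred.bins)
    return GraphProfile(bins=bins, mode="mean_skew")


def default_ticks(total_length: int) -> tuple[int, int]:
    """Pick 'nice' major/minor tick spacings (1/2/5 x 10^k, ~10 majors)."""
    target = max(total_length / 10, 1)
    best = 1
    for exp in range(0, 12):
        for m in (1, 2, 5):
            cand = m * 10 ** exp
            if cand <= target:
                best = cand
    return best, max(best // 5, 1)


def assemble(refmap: ReferenceMap,
             ring_specs: Sequence[RingSpec],
             data: Mapping[str, object],
             annotations: Sequence[FeatureAnnotation] = (),
             tick_major: int | None = None,
             tick_minor: int | None = None,
             title: str = "") -> ImageModel:
    """Resolve ring specs against loaded data into a deterministic ImageModel.

    ``data`` maps source ids to loaded objects: a list of BlastHit for blast
    rings, a ValueTrack for graph rings, a ContigSegments for contig rings,
    or a list of FeatureAnnotation for annotation rings.  Member ids that
    resolve to nothing raise; sharing one source between rings is allowed.
    """
    rings: list[ResolvedRing] = []
    legend: list[tuple[str, str, float, float]] = []
    for i, spec in enumerate(ring_specs):
        for m in spec.members:
            if m not in data:
                raise ValidationError(f"ring {i}: member {m!r} has no loaded data")
        if spec.kind == "blast":
            hit_sets = [(m, data[m]) for m in spec.members]
            arcs = build_blast_ring(hit_sets, spec, refmap, ring_index=i)
            rings.append(ResolvedRing(spec=spec, ring_index=i, arcs=tuple(arcs)))
            legend.append((spec.legend_text or "/".join(spec.members), spec.color,
                           spec.lower_identity, spec.upper_identity))
        elif spec.kind == "graph":
            track = data[spec.members[0]]
            if not isinstance(track, ValueTrack):
                raise ValidationError(f"member {spec.members[0]!r} is not a track")
            rings.append(ResolvedRing(spec=spec, ring_index=i,
                                      graph=build_graph_ring(track, spec)))
        elif spec.kind == "contigs":
            segs = data[spec.members[0]]
            if not isinstance(segs, ContigSegments):
                raise ValidationError(f"member {spec.members[0]!r} is not contig segments")
            rings.append(ResolvedRing(spec=spec, ring_index=i, contigs=segs))
        else:  # annotations
            anns = data[spec.members[0]]
            rings.append(ResolvedRing(spec=spec, ring_index=i,
                                      annotations=tuple(anns)))
    major, minor = (tick_major, tick_minor)
    if major is None or minor is None:
        d_major, d_minor = default_ticks(refmap.total_length)
        major = major or d_major
        minor = minor or d_minor
    return ImageModel(
        refmap=refmap,
        rings=tuple(rings),
        annotations=tuple(annotations),
        tick_major=major,
        tick_minor=minor,
        title=title,
        legend=tuple(legend),
    )
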