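"""Circular SVG rendering of an ImageModel.

Coordinate contract: reference position 0 sits at 12 o'clock and angles
increase clockwise, matching the usual orientation of circular prokaryote
genome maps.  Rendering is fully deterministic — fixed float formatting,
fixed iteration order, gzip with a zeroed timestamp for SVGZ — so identical
models produce byte-identical files.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

from .errors import InputOutputError, ValidationError
from .ringmodel import ImageModel, ResolvedRing, identity_to_opacity
from .seqio import FeatureAnnotation

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * math.pi

#: alternating colours for contig-boundary segments (red, blue)
CONTIG_COLORS = ("#cc2222", "#2222cc")


@dataclass(frozen=True)
class PolarLayout:
    """Resolved pixel geometry: ring annuli innermost-first."""

    center: tuple[float, float]
    ring_radii: tuple[tuple[float, float], ...]
    label_radius: float
    image_size: float

    def __post_init__(self):
        prev_outer = 0.0
        for (r_in, r_out) in self.ring_radii:
            if not (0 < r_in < r_out):
                raise ValidationError("ring radii must satisfy 0 < inner < outer")
            if r_in < prev_outer:
                raise ValidationError("rings overlap or are out of order")
            prev_outer = r_out


def bp_to_angle(p: float, L: float) -> float:
    """Angle in radians, clockwise from 12 o'clock, for base position p of L."""
    if L <= 0:
        raise ValidationError("reference length must be > 0")
    if not (0 <= p <= L):
        raise ValidationError(f"position {p} outside [0, {L}]")
    return TWO_PI * p / L


def _pt(center: tuple[float, float], r: float, theta: float) -> tuple[float, float]:
    # clockwise from 12 o'clock in SVG's y-down frame
    return center[0] + r * math.sin(theta), center[1] - r * math.cos(theta)


def layout_rings(widths: Sequence[float], inner_radius: float, spacing: float,
                 image_size: float = 3000.0,
                 label_margin: float | None = None) -> PolarLayout:
    """Stack ring annuli outward from inner_radius.

    Relative widths are scaled down uniformly (with a logged warning) when
    the stack plus the label margin would not fit inside the image; they are
    never scaled up.
    """
    if inner_radius <= 0:
        raise ValidationError("inner_radius must be > 0")
    if spacing < 0:
        raise ValidationError("spacing must be >= 0")
    if label_margin is None:
        label_margin = 0.10 * image_size
    half = image_size / 2.0
    n = len(widths)
    total_width = float(sum(widths))
    fixed = inner_radius + max(n - 1, 0) * spacing
    available = half - label_margin - fixed
    scale = 1.0
    if n and total_width > 0:
        if available <= 0:
            raise ValidationError(
                f"image of {image_size:g} px cannot fit {n} rings inside the "
                f"label margin even at zero width")
        if total_width > available:
            scale = available / total_width
            logger.warning("ring stack exceeds the image; scaling widths by %.3f", scale)
    radii = []
    r = inner_radius
    for w in widths:
        radii.append((r, r + w * scale))
        r += w * scale + spacing
    return PolarLayout(center=(half, half), ring_radii=tuple(radii),
                       label_radius=half - label_margin + 10.0,
                       image_size=image_size)


def tick_positions(L: int, major: int, minor: int) -> tuple[list[int], list[int]]:
    """Major ticks at multiples of *major* below L; minor ticks at multiples
    of *minor* that are not also major positions."""
    if not (0 < minor <= major):
        raise ValidationError("need 0 < minor <= major")
    majors = list(range(0, L, major))
    major_set = set(majors)
    minors = [p for p in range(0, L, minor) if p not in major_set]
    return majors, minors


def _sector(center, r_inner, r_outer, t1, t2) -> str:
    large = 1 if (t2 - t1) > math.pi else 0
    x1, y1 = _pt(center, r_outer, t1)
    x2, y2 = _pt(center, r_outer, t2)
    x3, y3 = _pt(center, r_inner, t2)
    x4, y4 = _pt(center, r_inner, t1)
    f = "{:.4f}".format
    return (f"M {f(x1)} {f(y1)} "
            f"A {f(r_outer)} {f(r_outer)} 0 {large} 1 {f(x2)} {f(y2)} "
            f"L {f(x3)} {f(y3)} "
            f"A {f(r_inner)} {f(r_inner)} 0 {large} 0 {f(x4)} {f(y4)} Z")


def arc_path(center: tuple[float, float], r_inner: float, r_outer: float,
             theta1: float, theta2: float, min_sweep: float = 0.0) -> str:
    """SVG path data for an annular sector from theta1 to theta2 (radians).

    Sweeps below *min_sweep* are widened symmetrically about their midpoint
    so tiny features stay visible; a full-circle sweep is emitted as two
    joined half-annuli because a single SVG arc cannot span 2*pi.
    """
    if not (theta1 <= theta2 <= theta1 + TWO_PI + 1e-12):
        raise ValidationError("need theta1 <= theta2 <= theta1 + 2*pi")
    sweep = theta2 - theta1
    if sweep >= TWO_PI - 1e-9:
        mid = theta1 + math.pi
        return _sector(center, r_inner, r_outer, theta1, mid) + " " + \
            _sector(center, r_inner, r_outer, mid, theta1 + TWO_PI)
    if sweep < min_sweep:
        centre_t = (theta1 + theta2) / 2.0
        theta1 = centre_t - min_sweep / 2.0
        theta2 = centre_t + min_sweep / 2.0
    return _sector(center, r_inner, r_outer, theta1, theta2)


# ---------------------------------------------------------------------------
# SVG document assembly

def _fmt(x: float) -> str:
    return f"{x:.4f}"


def _min_sweep(r_outer: float) -> float:
    # the angle subtending one pixel at the ring's outer edge
    return 1.0 / max(r_outer, 1.0)


def _arc_elements(model: ImageModel, ring: ResolvedRing, radii, center) -> list[str]:
    L = model.refmap.total_length
    r_in, r_out = radii
    ms = _min_sweep(r_out)
    out = []
    for arc in sorted(ring.arcs, key=lambda a: a.z):
        t1 = bp_to_angle(arc.start, L)
        t2 = bp_to_angle(arc.end, L)
        d = arc_path(center, r_in, r_out, t1, t2, min_sweep=ms)
        out.append(f'<path class="blast-arc" d="{d}" fill="{arc.color}" '
                   f'fill-opacity="{_fmt(arc.opacity)}" stroke="none"/>')
    return out


def _graph_elements(model: ImageModel, ring: ResolvedRing, radii, center) -> list[str]:
    L = model.refmap.total_length
    r_in, r_out = radii
    half = (r_out - r_in) / 2.0
    mid = (r_in + r_out) / 2.0
    color = ring.spec.color
    out = [f'<circle cx="{_fmt(center[0])}" cy="{_fmt(center[1])}" '
           f'r="{_fmt(mid if ring.graph.mode == "mean_skew" else r_in)}" '
           f'fill="none" stroke="{color}" stroke-opacity="0.3" stroke-width="0.5"/>']
    for (s, e, h) in ring.graph.bins:
        if h == 0:
            continue
        t1 = bp_to_angle(s, L)
        t2 = bp_to_angle(e, L)
        if ring.graph.mode == "mean_skew":
            lo, hi = (mid, mid + h * half) if h > 0 else (mid + h * half, mid)
        else:
            lo, hi = r_in, r_in + h * (r_out - r_in)
        if hi - lo < 1e-9:
            continue
        d = arc_path(center, lo, hi, t1, t2, min_sweep=_min_sweep(r_out))
        out.append(f'<path class="graph-bar" d="{d}" fill="{color}" stroke="none"/>')
    return out


def _contig_elements(model: ImageModel, ring: ResolvedRing, radii, center) -> list[str]:
    L = model.refmap.total_length
    r_in, r_out = radii
    out = []
    for (s, e, name, ci) in ring.contigs.segments:
        d = arc_path(center, r_in, r_out, bp_to_angle(s, L), bp_to_angle(e, L),
                     min_sweep=_min_sweep(r_out))
        out.append(f'<path class="contig" d="{d}" fill="{CONTIG_COLORS[ci]}" '
                   f'stroke="none"><title>{escape(name)}</title></path>')
    return out


def _annotation_sector(model: ImageModel, ann: FeatureAnnotation, radii, center) -> str:
    L = model.refmap.total_length
    r_in, r_out = radii
    t1 = bp_to_angle(ann.start, L)
    t2 = bp_to_angle(min(ann.end, L), L)
    ms = _min_sweep(r_out)
    if ann.decoration == "arc":
        quarter = (r_out - r_in) / 4.0
        body = arc_path(center, r_in + quarter, r_out - quarter, t1, t2, min_sweep=ms)
    elif ann.decoration in ("arrow_cw", "arrow_ccw"):
        sweep = t2 - t1
        tip = min(sweep * 0.25, 0.05)
        if ann.decoration == "arrow_cw":
            body = arc_path(center, r_in, r_out, t1, t2 - tip, min_sweep=ms)
            tip_pts = [_pt(center, r_out, t2 - tip), _pt(center, r_in, t2 - tip),
                       _pt(center, (r_in + r_out) / 2, t2)]
        else:
            body = arc_path(center, r_in, r_out, t1 + tip, t2, min_sweep=ms)
            tip_pts = [_pt(center, r_out, t1 + tip), _pt(center, r_in, t1 + tip),
                       _pt(center, (r_in + r_out) / 2, t1)]
        pts = " ".join(f"{_fmt(x)},{_fmt(y)}" for (x, y) in tip_pts)
        return (f'<path class="annotation" d="{body}" fill="{ann.color}" stroke="none"/>'
                f'<polygon points="{pts}" fill="{ann.color}" stroke="none"/>')
    else:  # bar
        body = arc_path(center, r_in, r_out, t1, t2, min_sweep=ms)
    return f'<path class="annotation" d="{body}" fill="{ann.color}" stroke="none"/>'


def _nudge_labels(entries: list[tuple[float, str, str]], label_radius: float,
                  font_size: float) -> list[tuple[float, str, str]]:
    """Greedy deterministic anti-collision pass: sort by angle, push any
    label closer than the minimum angular gap to its predecessor."""
    min_gap = font_size / max(label_radius, 1.0)
    ordered = sorted(entries, key=lambda t: (t[0], t[1]))
    out = []
    last = -math.inf
    for (theta, text, color) in ordered:
        if theta - last < min_gap:
            theta = last + min_gap
        out.append((theta, text, color))
        last = theta
    return out


def _annotation_labels(model: ImageModel, anns: Sequence[FeatureAnnotation],
                       band_outer: float, layout: PolarLayout,
                       font_size: float) -> list[str]:
    L = model.refmap.total_length
    center = layout.center
    outside = [(bp_to_angle((a.start + min(a.end, L)) / 2.0, L), a.label, a.color)
               for a in anns if a.label and a.placement == "outside"]
    inside = [(bp_to_angle((a.start + min(a.end, L)) / 2.0, L), a.label, a.color)
              for a in anns if a.label and a.placement == "inside"]
    out = []
    for (theta, text, color) in _nudge_labels(outside, layout.label_radius, font_size):
        lx, ly = _pt(center, layout.label_radius, theta)
        ax, ay = _pt(center, band_outer + 2.0, theta)
        anchor = "start" if math.sin(theta) >= -1e-12 else "end"
        out.append(f'<line x1="{_fmt(ax)}" y1="{_fmt(ay)}" x2="{_fmt(lx)}" '
                   f'y2="{_fmt(ly)}" stroke="#888888" stroke-width="0.6"/>')
        out.append(f'<text x="{_fmt(lx)}" y="{_fmt(ly)}" font-size="{_fmt(font_size)}" '
                   f'text-anchor="{anchor}" fill="{color}" '
                   f'font-family="Helvetica,Arial,sans-serif">{escape(text)}</text>')
    inner_r = layout.ring_radii[0][0] * 0.92 if layout.ring_radii else band_outer * 0.5
    for (theta, text, color) in _nudge_labels(inside, inner_r, font_size):
        lx, ly = _pt(center, inner_r, theta)
        anchor = "end" if math.sin(theta) >= -1e-12 else "start"
        out.append(f'<text x="{_fmt(lx)}" y="{_fmt(ly)}" font-size="{_fmt(font_size)}" '
                   f'text-anchor="{anchor}" fill="{color}" '
                   f'font-family="Helvetica,Arial,sans-serif">{escape(text)}</text>')
    return out


def _tick_elements(model: ImageModel, radius: float, layout: PolarLayout,
                   font_size: float) -> list[str]:
    L = model.refmap.total_length
    center = layout.center
    majors, minors = tick_positions(L, model.tick_major, model.tick_minor)
    out = []
    for p in majors:
        theta = bp_to_angle(p, L)
        x1, y1 = _pt(center, radius, theta)
        x2, y2 = _pt(center, radius + 12.0, theta)
        out.append(f'<line class="tick-major" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
                   f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="#000000" stroke-width="1.2"/>')
        tx, ty = _pt(center, radius + 16.0 + font_size, theta)
        label = _format_bp(p)
        out.append(f'<text x="{_fmt(tx)}" y="{_fmt(ty)}" font-size="{_fmt(font_size)}" '
                   f'text-anchor="middle" fill="#000000" '
                   f'font-family="Helvetica,Arial,sans-serif">{escape(label)}</text>')
    for p in minors:
        theta = bp_to_angle(p, L)
        x1, y1 = _pt(center, radius, theta)
        x2, y2 = _pt(center, radius + 6.0, theta)
        out.append(f'<line class="tick-minor" x1="{_fmt(x1)}" y1="{_fmt(y1)}" '
                   f'x2="{_fmt(x2)}" y2="{_fmt(y2)}" stroke="#555555" stroke-width="0.8"/>')
    return out


def _format_bp(p: int) -> str:
    if p == 0:
        return "0"
    if p % 1_000_000 == 0:
        return f"{p // 1_000_000} Mbp"
    if p % 1_000 == 0:
        return f"{p // 1_000} kbp"
    return f"{p} bp"


def _legend_elements(model: ImageModel, font_size: float) -> list[str]:
    out = []
    x0, y0 = 20.0, 60.0
    sw = font_size * 1.2
    for i, (text, color, lower, upper) in enumerate(model.legend):
        y = y0 + i * (sw + 10.0)
        mid = (lower + upper) / 2.0
        for j, ident in enumerate((lower, mid, upper)):
            op = identity_to_opacity(ident, lower, upper)
            op = 1.0 if op is None else op
            x = x0 + j * (sw + 2.0)
            out.append(f'<rect x="{_fmt(x)}" y="{_fmt(y)}" width="{_fmt(sw)}" '
                       f'height="{_fmt(sw)}" fill="{color}" '
                       f'fill-opacity="{_fmt(op)}" stroke="#000000" stroke-width="0.4"/>')
        pct = f"{lower:g}% / {mid:g}% / {upper:g}%"
        out.append(f'<text x="{_fmt(x0 + 3 * (sw + 2.0) + 6.0)}" y="{_fmt(y + sw * 0.8)}" '
                   f'font-size="{_fmt(font_size)}" fill="#000000" '
                   f'font-family="Helvetica,Arial,sans-serif">'
                   f'{escape(text)} ({escape(pct)})</text>')
    return out


def svg_string(model: ImageModel, image_size: float = 3000.0,
               inner_radius: float | None = None, spacing: float = 6.0) -> str:
    """Render the model to an SVG 1.1 document string (deterministic)."""
    if inner_radius is None:
        inner_radius = 0.25 * (image_size / 2.0)
    widths = [r.spec.width for r in model.rings]
    ann_band_width = 24.0 if model.annotations else 0.0
    layout = layout_rings(widths, inner_radius, spacing, image_size=image_size)
    ring_radii = layout.ring_radii
    center = layout.center
    font_size = max(image_size / 150.0, 8.0)
    body: list[str] = []
    # reference circle
    ref_r = inner_radius - 12.0
    body.append(f'<circle class="reference" cx="{_fmt(center[0])}" '
                f'cy="{_fmt(center[1])}" r="{_fmt(ref_r)}" fill="none" '
                f'stroke="#000000" stroke-width="2"/>')
    for ring, radii in zip(model.rings, ring_radii):
        if ring.spec.kind == "blast":
            body.extend(_arc_elements(model, ring, radii, center))
        elif ring.spec.kind == "graph":
            body.extend(_graph_elements(model, ring, radii, center))
        elif ring.spec.kind == "contigs":
            body.extend(_contig_elements(model, ring, radii, center))
        else:
            for ann in ring.annotations:
                body.append(_annotation_sector(model, ann, radii, center))
            body.extend(_annotation_labels(model, ring.annotations, radii[1],
                                           layout, font_size))
    stack_outer = ring_radii[-1][1] if ring_radii else inner_radius
    if model.annotations:
        band = (stack_outer + spacing, stack_outer + spacing + ann_band_width)
        for ann in model.annotations:
            body.append(_annotation_sector(model, ann, band, center))
        body.extend(_annotation_labels(model, model.annotations, band[1],
                                       layout, font_size))
        stack_outer = band[1]
    body.extend(_tick_elements(model, stack_outer + 4.0, layout, font_size))
    if model.title:
        body.append(f'<text x="{_fmt(center[0])}" y="{_fmt(font_size * 2.5)}" '
                    f'font-size="{_fmt(font_size * 1.6)}" text-anchor="middle" '
                    f'fill="#000000" font-family="Helvetica,Arial,sans-serif">'
                    f'{escape(model.title)}</text>')
    body.extend(_legend_elements(model, font_size))
    size = _fmt(image_size)
    head = (f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
            f'width="{size}" height="{size}" viewBox="0 0 {size} {size}">'
            f'<rect width="{size}" height="{size}" fill="#ffffff"/>')
    return head + "".join(body) + "</svg>"


def render_svg(model: ImageModel, path: str | Path, format: str = "svg",
               image_size: float = 3000.0, inner_radius: float | None = None,
               spacing: float = 6.0) -> Path:
    """Write the model as SVG or SVGZ; SVGZ is the gzip stream of the
    identical SVG bytes (zeroed timestamp, so repeated runs match)."""
    if format not in ("svg", "svgz"):
        raise ValidationError(f"unknown output format {format!r}")
    doc = svg_string(model, image_size=image_size, inner_radius=inner_radius,
                     spacing=spacing).encode()
    path = Path(path)
    try:
        if format == "svg":
            path.write_bytes(doc)
        else:
            with open(path, "wb") as raw:
                with gzip.GzipFile(fileobj=raw, mode="wb", filename="", mtime=0) as gz:
                    gz.write(doc)
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc
    return path
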