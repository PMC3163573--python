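"""Profile execution: load -> BLAST (or fixture tabular) -> tracks ->
assemble -> render, with per-stage logging and timings.

This is the non-interactive equivalent of the select-data / customise-ring /
confirm workflow: everything is declared up front in the profile, then run
end to end.  Relative source paths resolve against the profile's directory.
"""

from __future__ import annotations

import logging
import tempfile
import time
from contextlib import contextmanager
from pathlib import Path

from . import blastops, render, seqio, tracks
from .errors import ValidationError
from .profiles import BUILTIN_SOURCES, Profile
from .ringmodel import ImageModel, RingSpec, assemble

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("[%s] start", name)
    yield
    logger.info("[%s] done in %.2f s", name, time.perf_counter() - t0)


def _resolve(path: str, base_dir: Path) -> Path:
    p = Path(path)
    return p if p.is_absolute() else base_dir / p


def _gc_window(total_length: int) -> int:
    # 10 kb windows on chromosome-scale references, proportionally finer
    # on small references so the track keeps ~100 bins
    return max(1, min(10_000, total_length // 100))


def plan_blast(profile: Profile, base_dir: Path) -> list[str]:
    """The external commands a run would execute (for --dry-run)."""
    cmds = []
    queries = [(sid, src) for sid, src in sorted(profile.sources.items())
               if src.role == "query"]
    if queries:
        dbtype = blastops.PROGRAM_DBTYPE[profile.blast.program]
        cmds.append(f"makeblastdb -in <concatenated reference> -dbtype {dbtype}")
        for sid, src in queries:
            cmds.append(
                f"{profile.blast.program} -query {_resolve(src.path, base_dir)} "
                f"-db <reference db> -outfmt 6 -evalue {profile.blast.max_evalue:g}"
                + (f" {profile.blast.extra_options}" if profile.blast.extra_options else ""))
    return cmds


def load_reference(profile: Profile, base_dir: Path):
    records = seqio.read_sequences(_resolve(profile.reference.path, base_dir),
                                   profile.reference.format)
    refmap = seqio.build_reference_map(records, circular=profile.reference.circular)
    return records, refmap


def _builtin_data(name: str, records, refmap: seqio.ReferenceMap):
    concat = seqio.concatenate(records)
    window = _gc_window(refmap.total_length)
    if name == ":gc-content":
        return tracks.gc_content(concat, window=window, circular=refmap.circular)
    if name == ":gc-skew":
        return tracks.gc_skew(concat, window=window, circular=refmap.circular)
    if name == ":contigs":
        return tracks.contig_boundaries(refmap)
    if name == ":headers":
        return seqio.header_annotations(refmap)
    raise ValidationError(f"unknown builtin source {name!r}")


def load_data(profile: Profile, base_dir: Path, workdir: Path,
              records, refmap: seqio.ReferenceMap) -> dict[str, object]:
    """Resolve every declared source plus the builtins rings refer to."""
    data: dict[str, object] = {}
    hit_filter = blastops.HitFilter(min_identity=profile.blast.min_identity,
                                    max_evalue=profile.blast.max_evalue,
                                    extra_options=profile.blast.extra_options)
    query_ids = [sid for sid, src in sorted(profile.sources.items())
                 if src.role == "query"]
    db = None
    if query_ids:
        with _stage("makeblastdb"):
            ref_fasta = workdir / "reference.fasta"
            seqio.write_fasta(records, ref_fasta)
            dbtype = blastops.PROGRAM_DBTYPE[profile.blast.program]
            db = blastops.make_database(ref_fasta, dbtype=dbtype,
                                        out_prefix=workdir / "refdb")
    for sid, src in sorted(profile.sources.items()):
        path = _resolve(src.path, base_dir)
        if src.role == "query":
            with _stage(f"blast:{sid}"):
                tab = blastops.run_comparison(profile.blast.program, path, db,
                                              filter=hit_filter,
                                              out_path=workdir / f"{sid}.tab")
                data[sid] = blastops.filter_hits(blastops.parse_tabular(tab), hit_filter)
        elif src.role == "tabular":
            with _stage(f"tabular:{sid}"):
                data[sid] = blastops.filter_hits(blastops.parse_tabular(path), hit_filter)
        elif src.role == "sam":
            with _stage(f"coverage-sam:{sid}"):
                data[sid] = tracks.coverage_from_sam(path, refmap)
        elif src.role == "ace":
            with _stage(f"coverage-ace:{sid}"):
                per_contig, _order = tracks.coverage_from_ace(path)
                data[sid] = tracks.concat_contig_tracks(per_contig, refmap)
        elif src.role == "graph":
            with _stage(f"graph:{sid}"):
                data[sid] = tracks.read_graph_file(path, refmap.total_length)
        elif src.role == "annotation":
            with _stage(f"annotation:{sid}"):
                data[sid] = seqio.read_annotation_table(path)
    used_builtins = {m for ring in profile.rings for m in ring.members
                     if m in BUILTIN_SOURCES}
    for name in sorted(used_builtins):
        data[name] = _builtin_data(name, records, refmap)
    return data


def build_model(profile: Profile, base_dir: Path, workdir: Path) -> ImageModel:
    with _stage("reference"):
        records, refmap = load_reference(profile, base_dir)
    data = load_data(profile, base_dir, workdir, records, refmap)
    with _stage("assemble"):
        model = assemble(refmap, profile.rings, data,
                         tick_major=profile.image.tick_major,
                         tick_minor=profile.image.tick_minor,
                         title=profile.image.title)
    return model


def run(profile: Profile, base_dir: Path, out_path: Path,
        output_format: str | None = None, workdir: Path | None = None,
        dry_run: bool = False) -> Path | None:
    """Execute a profile end to end; returns the written image path."""
    base_dir = Path(base_dir)
    if dry_run:
        for cmd in plan_blast(profile, base_dir):
            logger.info("[plan] %s", cmd)
        logger.info("[plan] render -> %s", out_path)
        return None
    if workdir is None:
        workdir = Path(tempfile.mkdtemp(prefix="genomering-"))
    workdir.mkdir(parents=True, exist_ok=True)
    model = build_model(profile, base_dir, workdir)
    with _stage("render"):
        fmt = output_format or profile.image.output_format
        out = render.render_svg(model, out_path, format=fmt,
                                image_size=profile.image.size)
    return out
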