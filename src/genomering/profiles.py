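"""Session profiles: a complete, reloadable description of one image.

A profile is structured JSON with an explicit ``format_version``: the
reference descriptor, named data sources, ordered ring specifications,
BLAST settings and image settings.  ``load_profile(save_profile(p)) == p``
field-for-field.  Named templates preset image size and tick spacing for
common genome scales.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

from .errors import InputOutputError, ParseError, ValidationError
from .ringmodel import RingSpec

FORMAT_VERSION = "1"

SOURCE_ROLES = ("query", "tabular", "sam", "ace", "graph", "annotation")

#: ring members computed from the reference itself rather than a file
BUILTIN_SOURCES = (":gc-content", ":gc-skew", ":contigs", ":headers")
SOURCE_FORMATS = ("fasta", "genbank", "embl", "tabular", "sam", "ace", "graph", "annotation")


@dataclass(frozen=True)
class SourceSpec:
    """One named data source a ring can reference."""

    path: str
    format: str = "fasta"
    role: str = "query"

    def __post_init__(self):
        if self.role not in SOURCE_ROLES:
            raise ValidationError(f"unknown source role {self.role!r}")
        if self.format not in SOURCE_FORMATS:
            raise ValidationError(f"unknown source format {self.format!r}")


@dataclass(frozen=True)
class ReferenceSpec:
    path: str
    format: str = "fasta"
    circular: bool = True


@dataclass(frozen=True)
class BlastSettings:
    program: str = "blastn"
    min_identity: float = 0.0
    max_evalue: float = 10.0
    extra_options: str = ""


@dataclass(frozen=True)
class ImageSettings:
    size: float = 3000.0
    tick_major: int | None = None
    tick_minor: int | None = None
    title: str = ""
    output_format: str = "svg"


@dataclass(frozen=True)
class Profile:
    reference: ReferenceSpec
    sources: Mapping[str, SourceSpec] = field(default_factory=dict)
    rings: tuple[RingSpec, ...] = ()
    blast: BlastSettings = field(default_factory=BlastSettings)
    image: ImageSettings = field(default_factory=ImageSettings)
    format_version: str = FORMAT_VERSION

    def __post_init__(self):
        if self.format_version != FORMAT_VERSION:
            raise ValidationError(
                f"unknown profile format_version {self.format_version!r} "
                f"(this build reads version {FORMAT_VERSION})")
        declared = set(self.sources) | set(BUILTIN_SOURCES)
        for i, ring in enumerate(self.rings):
            for m in ring.members:
                if m not in declared:
                    raise ValidationError(
                        f"ring {i} references undeclared source {m!r}")


def _profile_to_dict(profile: Profile) -> dict:
    d = {
        "format_version": profile.format_version,
        "reference": asdict(profile.reference),
        "sources": {k: asdict(v) for k, v in sorted(profile.sources.items())},
        "rings": [asdict(r) for r in profile.rings],
        "blast": asdict(profile.blast),
        "image": asdict(profile.image),
    }
    for r in d["rings"]:
        r["members"] = list(r["members"])
    return d


def save_profile(profile: Profile, path: str | Path) -> Path:
    path = Path(path)
    try:
        with open(path, "w") as fh:
            json.dump(_profile_to_dict(profile), fh, indent=2, sort_keys=True)
            fh.write("\n")
    except OSError as exc:
        raise InputOutputError(f"cannot write {path}: {exc}") from exc
    return path


def load_profile(path: str | Path) -> Profile:
    path = Path(path)
    if not path.exists():
        raise InputOutputError(f"no such file: {path}")
    try:
        with open(path) as fh:
            raw = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot parse profile JSON: {exc}", path=str(path)) from exc
    try:
        return Profile(
            format_version=raw.get("format_version", ""),
            reference=ReferenceSpec(**raw["reference"]),
            sources={k: SourceSpec(**v) for k, v in raw.get("sources", {}).items()},
            rings=tuple(
                RingSpec(**{**r, "members": tuple(r.get("members", ()))})
                for r in raw.get("rings", ())
            ),
            blast=BlastSettings(**raw.get("blast", {})),
            image=ImageSettings(**raw.get("image", {})),
        )
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed profile: {exc}", path=str(path)) from exc


#: named templates with size/tick presets for common genome scales
TEMPLATES: dict[str, ImageSettings] = {
    # a plasmid or phage-sized reference (tens of kb)
    "small-genome": ImageSettings(size=2000.0, tick_major=5_000, tick_minor=1_000),
    # a typical bacterial chromosome (several Mb)
    "large-genome": ImageSettings(size=3000.0, tick_major=500_000, tick_minor=100_000),
    # a concatenated multi-gene panel (tens of kb, dense labels)
    "gene-panel": ImageSettings(size=2400.0, tick_major=1_000, tick_minor=200),
}


def template_profile(name: str, reference_path: str = "reference.fasta") -> Profile:
    """A starter profile for one of the named templates."""
    if name not in TEMPLATES:
        raise ValidationError(
            f"unknown template {name!r}; available: {sorted(TEMPLATES)}")
    return Profile(
        reference=ReferenceSpec(path=reference_path, format="fasta",
                                circular=(name != "gene-panel")),
        sources={"query1": SourceSpec(path="query1.fasta")},
        rings=(RingSpec(kind="blast", members=("query1",), legend_text="query1"),),
        image=TEMPLATES[name],
    )
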