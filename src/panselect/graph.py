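"""GFA v1 input/output and the in-memory pangenome graph model.

A pangenome variation graph stores the genomes of several haplotypes of one
species as walks over shared sequence chunks.  Nodes ("segments") carry
sequence; each haplotype is an ordered, oriented list of segments (a GFA
P-line path or W-line walk).  A segment traversed by several haplotypes
represents homologous sequence shared between them.

This module parses and writes single-chromosome graphs.  Coordinates are
0-based, half-open throughout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from os import PathLike
from typing import IO, Iterable, Union

FORWARD = "+"
REVERSE = "-"

#: P-line overlap fields must describe blunt segment concatenation.
_ALLMATCH_CIGAR = re.compile(r"^(\*|\d+M)$")
_LN_TAG = re.compile(r"^LN:i:(\d+)$")
_WALK_TOKEN = re.compile(r"([><])([^><]+)")


class GFAError(ValueError):
    """Base class for GFA parsing and graph validation failures."""


class GFAParseError(GFAError):
    """A malformed or inconsistent GFA record."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"GFA line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class GraphValidationError(GFAError):
    """A structurally invalid graph (independent of file syntax)."""


class NotAPangenomeError(GraphValidationError):
    """Raised when a graph holds fewer than two haplotype paths.

    Pairwise path similarity is undefined on a single genome.
    """


@dataclass(frozen=True)
class Step:
    """One oriented traversal of a segment by a path."""

    segment_id: str
    orientation: str  # "+" (forward) or "-" (reverse complement)

    def __post_init__(self) -> None:
        if self.orientation not in (FORWARD, REVERSE):
            raise GraphValidationError(
                f"invalid orientation {self.orientation!r} for segment "
                f"{self.segment_id!r}"
            )

    def flipped(self) -> "Step":
        """The same segment traversed in the opposite direction."""
        return Step(
            self.segment_id,
            REVERSE if self.orientation == FORWARD else FORWARD,
        )

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.segment_id}{self.orientation}"


@dataclass
class Segment:
    """A node of the graph: a sequence chunk present in >= 1 haplotype."""

    id: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.length < 0:
            raise GraphValidationError(
                f"segment {self.id!r} has negative length"
            )
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GraphValidationError(
                f"segment {self.id!r}: sequence length "
                f"{len(self.sequence)} != declared length {self.length}"
            )


@dataclass
class HaplotypePath:
    """One haplotype's chromosome as an ordered list of oriented steps."""

    name: str
    steps: list[Step]


@dataclass(frozen=True)
class Link:
    """A GFA L-line; read for optional validation only."""

    from_id: str
    from_orient: str
    to_id: str
    to_orient: str


@dataclass
class PangenomeGraph:
    """A validated single-chromosome pangenome graph.

    Attributes
    ----------
    segments : dict
        Segment id -> :class:`Segment`.
    paths : list of :class:`HaplotypePath`
        All haplotypes, in input order.
    reference_name : str
        Name of the path used as the coordinate backbone.
    links : list of :class:`Link`
        Edges, kept only for optional adjacency validation.
    """

    segments: dict[str, Segment]
    paths: list[HaplotypePath]
    reference_name: str
    links: list[Link] = field(default_factory=list, compare=False)

    def validate(self) -> None:
        if len(self.paths) < 2:
            raise NotAPangenomeError(
                f"not a pangenome: {len(self.paths)} path(s); "
                "at least 2 haplotypes are required"
            )
        names = [p.name for p in self.paths]
        if len(set(names)) != len(names):
            raise GraphValidationError("duplicate path names")
        if names.count(self.reference_name) != 1:
            raise GraphValidationError(
                f"reference path {self.reference_name!r} not found"
            )
        for path in self.paths:
            if not path.steps:
                raise GraphValidationError(f"path {path.name!r} is empty")
            for step in path.steps:
                if step.segment_id not in self.segments:
                    raise GraphValidationError(
                        f"path {path.name!r} references unknown segment "
                        f"{step.segment_id!r}"
                    )
            if self.path_length(path.name) <= 0:
                raise GraphValidationError(
                    f"path {path.name!r} has zero total length"
                )

    def get_path(self, name: str) -> HaplotypePath:
        for path in self.paths:
            if path.name == name:
                return path
        raise KeyError(name)

    @property
    def reference_path(self) -> HaplotypePath:
        return self.get_path(self.reference_name)

    def path_length(self, name: str) -> int:
        return sum(
            self.segments[s.segment_id].length
            for s in self.get_path(name).steps
        )

    @property
    def reference_length(self) -> int:
        return self.path_length(self.reference_name)


def _parse_steps_pline(token: str, lineno: int) -> list[Step]:
    steps = []
    for item in token.split(","):
        if len(item) < 2 or item[-1] not in (FORWARD, REVERSE):
            raise GFAParseError(
                f"malformed path step {item!r}", lineno
            )
        steps.append(Step(item[:-1], item[-1]))
    return steps


def _parse_walk(token: str, lineno: int) -> list[Step]:
    consumed = 0
    steps = []
    for match in _WALK_TOKEN.finditer(token):
        consumed += len(match.group(0))
        orient = FORWARD if match.group(1) == ">" else REVERSE
        steps.append(Step(match.group(2), orient))
    if consumed != len(token) or not steps:
        raise GFAParseError(f"malformed walk {token!r}", lineno)
    return steps


def parse_gfa(
    source: Union[str, PathLike, IO[str], Iterable[str]],
    reference_name: str | None = None,
) -> PangenomeGraph:
    """Parse a GFA v1 text stream into a :class:`PangenomeGraph`.

    Accepts S-lines (segments, with ``LN:i`` honoured when the sequence is
    ``*``), P-lines and W-lines (haplotypes) and L-lines (kept for optional
    validation); other record types are skipped.  W-line walks are named
    ``sample#haplotype#seqid``; several walks with the same name are
    concatenated in file order.  Record order is free: segment references
    are resolved after reading the whole file.

    Parameters
    ----------
    source : path, open text stream, or iterable of lines
    reference_name : str, optional
        Path to use as coordinate backbone; defaults to the first path in
        file order.

    Raises
    ------
    GFAParseError
        On malformed records, duplicate segments, a path step citing a
        missing segment (the offending line and id are named), or a
        segment with neither sequence nor ``LN`` tag.
    NotAPangenomeError
        When fewer than two paths are present.
    """
    if isinstance(source, (str, PathLike)):
        with open(source, "rt", encoding="utf-8") as handle:
            return parse_gfa(handle, reference_name)

    segments: dict[str, Segment] = {}
    seg_lineno: dict[str, int] = {}
    # name -> (first line number, steps); order preserved
    raw_paths: dict[str, tuple[int, list[Step]]] = {}
    walk_contig: dict[tuple[str, str], str] = {}
    links: list[Link] = []
    path_step_lineno: dict[str, int] = {}

    for lineno, line in enumerate(source, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "S":
            if len(fields) < 3:
                raise GFAParseError("truncated S-line", lineno)
            name, seq = fields[1], fields[2]
            if name in segments:
                raise GFAParseError(f"duplicate segment {name!r}", lineno)
            ln: int | None = None
            for extra in fields[3:]:
                m = _LN_TAG.match(extra)
                if m:
                    ln = int(m.group(1))
            if seq == "*":
                if ln is None:
                    raise GFAParseError(
                        f"segment {name!r} has neither sequence nor LN tag",
                        lineno,
                    )
                segments[name] = Segment(name, ln, None)
            else:
                if ln is not None and ln != len(seq):
                    raise GFAParseError(
                        f"segment {name!r}: LN tag {ln} contradicts "
                        f"sequence length {len(seq)}",
                        lineno,
                    )
                segments[name] = Segment(name, len(seq), seq)
            seg_lineno[name] = lineno
        elif tag == "P":
            if len(fields) < 3:
                raise GFAParseError("truncated P-line", lineno)
            name = fields[1]
            if name in raw_paths:
                raise GFAParseError(f"duplicate path name {name!r}", lineno)
            steps = _parse_steps_pline(fields[2], lineno)
            if len(fields) > 3 and fields[3]:
                for cigar in fields[3].split(","):
                    if not _ALLMATCH_CIGAR.match(cigar):
                        raise GFAParseError(
                            f"unsupported P-line overlap {cigar!r}; only "
                            "'*' or all-match CIGARs are accepted",
                            lineno,
                        )
            raw_paths[name] = (lineno, steps)
            path_step_lineno[name] = lineno
        elif tag == "W":
            if len(fields) < 7:
                raise GFAParseError("truncated W-line", lineno)
            sample, hap, seqid = fields[1], fields[2], fields[3]
            prev = walk_contig.setdefault((sample, hap), seqid)
            if prev != seqid:
                raise GFAParseError(
                    f"sample {sample}#{hap} walks two contigs "
                    f"({prev!r}, {seqid!r}); one GFA must describe a "
                    "single chromosome",
                    lineno,
                )
            name = f"{sample}#{hap}#{seqid}"
            steps = _parse_walk(fields[6], lineno)
            if name in raw_paths:
                raw_paths[name][1].extend(steps)
            else:
                raw_paths[name] = (lineno, steps)
                path_step_lineno[name] = lineno
        elif tag == "L":
            if len(fields) < 5:
                raise GFAParseError("truncated L-line", lineno)
            links.append(Link(fields[1], fields[2], fields[3], fields[4]))
        # other record types (H, C, ...) are tolerated and skipped

    paths = []
    for name, (lineno, steps) in sorted(
        raw_paths.items(), key=lambda item: item[1][0]
    ):
        for step in steps:
            if step.segment_id not in segments:
                raise GFAParseError(
                    f"path {name!r} references missing segment "
                    f"{step.segment_id!r}",
                    path_step_lineno[name],
                )
        paths.append(HaplotypePath(name, steps))

    if reference_name is None:
        if not paths:
            raise NotAPangenomeError("not a pangenome: no paths found")
        reference_name = paths[0].name

    graph = PangenomeGraph(segments, paths, reference_name, links)
    graph.validate()
    return graph


def write_gfa(
    graph: PangenomeGraph,
    sink: IO[str],
    dialect: str = "P",
) -> None:
    """Write a graph as GFA v1 with sequences inlined.

    S-lines are emitted first, then one path record per haplotype.  With
    ``dialect="W"`` paths are written as walks, which requires PanSN-style
    ``sample#haplotype#seqid`` path names.  ``parse_gfa`` on the output
    reproduces the graph (links, which are not re-emitted, excepted).
    """
    if dialect not in ("P", "W"):
        raise ValueError(f"unknown GFA dialect {dialect!r}")
    for segment in graph.segments.values():
        if segment.length == 0:
            raise GraphValidationError(
                f"segment {segment.id!r} has empty sequence; refusing to "
                "write an unrepresentable GFA record"
            )
    sink.write("H\tVN:Z:1.0\n")
    for segment in graph.segments.values():
        if segment.sequence is not None:
            sink.write(f"S\t{segment.id}\t{segment.sequence}\n")
        else:
            sink.write(f"S\t{segment.id}\t*\tLN:i:{segment.length}\n")
    for path in graph.paths:
        if dialect == "P":
            body = ",".join(
                f"{s.segment_id}{s.orientation}" for s in path.steps
            )
            sink.write(f"P\t{path.name}\t{body}\t*\n")
        else:
            parts = path.name.split("#")
            if len(parts) != 3:
                raise GraphValidationError(
                    f"path {path.name!r} is not PanSN-named "
                    "(sample#haplotype#seqid); cannot write a W-line"
                )
            sample, hap, seqid = parts
            length = sum(
                graph.segments[s.segment_id].length for s in path.steps
            )
            walk = "".join(
                (">" if s.orientation == FORWARD else "<") + s.segment_id
                for s in path.steps
            )
            sink.write(
                f"W\t{sample}\t{hap}\t{seqid}\t0\t{length}\t{walk}\n"
            )


def reference_positions(
    graph: PangenomeGraph,
) -> dict[str, list[tuple[int, int]]]:
    """Reference-coordinate intervals of every segment on the reference.

    Returns a map segment id -> list of 0-based half-open ``(start, end)``
    intervals, one per traversal, obtained by cumulative sum of step
    lengths along the reference path.  Segments absent from the reference
    are absent from the map.
    """
    positions: dict[str, list[tuple[int, int]]] = {}
    offset = 0
    for step in graph.reference_path.steps:
        length = graph.segments[step.segment_id].length
        positions.setdefault(step.segment_id, []).append(
            (offset, offset + length)
        )
        offset += length
    return positions


def validate_links(graph: PangenomeGraph) -> list[tuple[str, int]]:
    """Check path adjacency against the graph's L-lines.

    Returns a list of ``(path_name, step_index)`` pairs where consecutive
    steps are not joined by any link (in either direction).  Paths alone
    determine the analysis, so this is diagnostic only.
    """
    edges = set()
    for link in graph.links:
        edges.add(
            (link.from_id, link.from_orient, link.to_id, link.to_orient)
        )
        # the reverse traversal of the same edge
        flip = {FORWARD: REVERSE, REVERSE: FORWARD}
        edges.add(
            (link.to_id, flip[link.to_orient], link.from_id,
             flip[link.from_orient])
        )
    missing = []
    for path in graph.paths:
        for i in range(len(path.steps) - 1):
            a, b = path.steps[i], path.steps[i + 1]
            key = (a.segment_id, a.orientation, b.segment_id, b.orientation)
            if key not in edges:
                missing.append((path.name, i))
    return missing
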