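"""Boundary-segment detection and window binning along the reference path.

The genome is partitioned into windows ("bins") of roughly a user-chosen
size ``s``.  Bin edges are *boundary segments*: segments traversed exactly
once by every haplotype, so that each haplotype's sub-path between two
consecutive boundaries is well defined and comparable.  Boundaries are
greedily thinned so consecutive ones sit at least ``s`` bases apart on the
reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Mapping

from .graph import FORWARD, PangenomeGraph, Step, reference_positions

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BoundarySegment:
    """A single-copy universal segment anchoring a bin edge."""

    segment_id: str
    reference_interval: tuple[int, int]  # 0-based half-open
    #: path name -> step index of this segment's unique occurrence
    per_path_index: Mapping[str, int]


@dataclass(frozen=True)
class BinningParams:
    """Window size ``s`` in bases (typical values 1000, 10000, 100000)."""

    window_size: int

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")


@dataclass
class Bin:
    """A reference window together with each haplotype's sub-path.

    ``left_boundary``/``right_boundary`` are ``None`` at the chromosome
    ends (path-start / path-end sentinels).  Sub-paths exclude the
    boundary segments themselves: boundaries are shared by construction
    and would only add constant mass to every similarity comparison.
    """

    index: int
    reference_interval: tuple[int, int]
    left_boundary: BoundarySegment | None
    right_boundary: BoundarySegment | None
    subpaths: dict[str, list[Step]] = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.reference_interval[0]

    @property
    def end(self) -> int:
        return self.reference_interval[1]


def find_boundary_candidates(
    graph: PangenomeGraph,
    strict_forward: bool = False,
    min_anchor_length: int = 1,
) -> list[BoundarySegment]:
    """All segments usable as bin anchors, in reference order.

    A segment qualifies when every path (reference included) traverses it
    exactly once, with an orientation consistent with that path's dominant
    orientation.  The dominant orientation of a path is the majority
    orientation of its single-copy universal segments relative to the
    reference; requiring consistency with it keeps anchors working on
    globally reverse-complemented haplotypes while rejecting anchors that
    sit inside a local inversion.  ``strict_forward`` instead demands a
    forward traversal in every path.

    Returns an empty list (not an error) when no segment qualifies.
    """
    # occurrences[path][segment] -> list of (step index, orientation)
    occurrences: list[dict[str, list[tuple[int, str]]]] = []
    for path in graph.paths:
        occ: dict[str, list[tuple[int, str]]] = {}
        for idx, step in enumerate(path.steps):
            occ.setdefault(step.segment_id, []).append(
                (idx, step.orientation)
            )
        occurrences.append(occ)

    universal = [
        seg_id
        for seg_id in occurrences[0]
        if all(len(occ.get(seg_id, ())) == 1 for occ in occurrences)
    ]
    if not universal:
        return []

    ref_occ = occurrences[
        [p.name for p in graph.paths].index(graph.reference_name)
    ]

    def rel(occ: dict, seg_id: str) -> int:
        return 1 if occ[seg_id][0][1] == ref_occ[seg_id][0][1] else -1

    if strict_forward:
        kept = [
            seg_id
            for seg_id in universal
            if all(occ[seg_id][0][1] == FORWARD for occ in occurrences)
        ]
    else:
        dominant = [
            1 if sum(rel(occ, seg) for seg in universal) >= 0 else -1
            for occ in occurrences
        ]
        kept = [
            seg_id
            for seg_id in universal
            if all(
                rel(occ, seg_id) == dom
                for occ, dom in zip(occurrences, dominant)
            )
        ]

    positions = reference_positions(graph)
    candidates = []
    for seg_id in kept:
        interval = positions[seg_id][0]
        if interval[1] - interval[0] < min_anchor_length:
            continue
        per_path = {
            path.name: occ[seg_id][0][0]
            for path, occ in zip(graph.paths, occurrences)
        }
        candidates.append(
            BoundarySegment(seg_id, interval, MappingProxyType(per_path))
        )
    candidates.sort(key=lambda b: b.reference_interval)
    return candidates


def select_boundaries(
    candidates: list[BoundarySegment],
    params: BinningParams,
    reference_length: int,
) -> list[BoundarySegment]:
    """Greedy left-to-right thinning of candidates to ``s``-spaced anchors.

    The first candidate is always selected; thereafter the first candidate
    whose reference start lies at least ``s`` bases after the end of the
    previously selected one.  Deterministic and O(n).
    """
    selected: list[BoundarySegment] = []
    for candidate in candidates:
        if not selected:
            selected.append(candidate)
        elif (
            candidate.reference_interval[0]
            >= selected[-1].reference_interval[1] + params.window_size
        ):
            selected.append(candidate)
    return selected


def _subpath_between(
    path_steps: list[Step],
    left_idx: int | None,
    right_idx: int | None,
) -> list[Step]:
    """Steps strictly between two boundary occurrences on one path.

    ``None`` indices are the path-start / path-end sentinels.  When the
    haplotype traverses the region in reverse (the right boundary occurs
    before the left one), the extracted steps are reversed with flipped
    orientations so that stored sub-paths always read left-to-right in
    reference direction.
    """
    if left_idx is None and right_idx is None:
        return list(path_steps)
    if left_idx is None:
        return path_steps[:right_idx]
    if right_idx is None:
        return path_steps[left_idx + 1:]
    if left_idx < right_idx:
        return path_steps[left_idx + 1:right_idx]
    return [s.flipped() for s in reversed(path_steps[right_idx + 1:left_idx])]


def build_bins(
    graph: PangenomeGraph,
    boundaries: list[BoundarySegment],
) -> list[Bin]:
    """One bin per consecutive boundary pair, plus end flanks.

    Bin reference intervals run from the end of one boundary to the end of
    the next; the leading bin starts at 0 and the trailing one ends at the
    reference length.  The intervals therefore tile the reference exactly
    while sub-paths still exclude the anchor segments.  With no boundaries
    at all the whole chromosome is one bin (a warning is logged).
    """
    ref_len = graph.reference_length
    bins: list[Bin] = []

    if not boundaries:
        logger.warning(
            "no boundary segment found; the whole chromosome is one bin"
        )
        edges: list[tuple[int, BoundarySegment | None]] = []
    else:
        edges = [(b.reference_interval[1], b) for b in boundaries]

    # (interval, left boundary, right boundary)
    layout: list[tuple[tuple[int, int],
                       BoundarySegment | None,
                       BoundarySegment | None]] = []
    prev_edge = 0
    prev_boundary: BoundarySegment | None = None
    for edge, boundary in edges:
        if edge > prev_edge:
            layout.append(((prev_edge, edge), prev_boundary, boundary))
        prev_edge, prev_boundary = edge, boundary
    if ref_len > prev_edge or not layout:
        layout.append(((prev_edge, ref_len), prev_boundary, None))

    for index, (interval, left, right) in enumerate(layout):
        subpaths = {}
        for path in graph.paths:
            for side in (left, right):
                if side is not None and path.name not in side.per_path_index:
                    raise RuntimeError(
                        f"boundary {side.segment_id!r} missing from path "
                        f"{path.name!r}: universality violated"
                    )
            left_idx = left.per_path_index[path.name] if left else None
            right_idx = right.per_path_index[path.name] if right else None
            subpaths[path.name] = _subpath_between(
                path.steps, left_idx, right_idx
            )
        bins.append(Bin(index, interval, left, right, subpaths))
    return bins


def make_bins(
    graph: PangenomeGraph,
    window_size: int,
    strict_forward: bool = False,
    min_anchor_length: int = 1,
) -> tuple[list[Bin], list[BoundarySegment]]:
    """Convenience pipeline: candidates -> selection -> bins."""
    candidates = find_boundary_candidates(
        graph,
        strict_forward=strict_forward,
        min_anchor_length=min_anchor_length,
    )
    boundaries = select_boundaries(
        candidates, BinningParams(window_size), graph.reference_length
    )
    return build_bins(graph, boundaries), boundaries
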