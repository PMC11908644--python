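"""Weighted Jaccard similarity of sub-paths and the per-bin score.

Two haplotypes' sub-paths through a bin are compared as length-weighted
multisets of the segments they traverse: with ``c_A(g)`` the number of
times sub-path A traverses segment ``g`` and ``len(g)`` its length,

    J(A, B) = sum_g min(c_A(g), c_B(g)) * len(g)
              ---------------------------------
              sum_g max(c_A(g), c_B(g)) * len(g)

J is 1 for identical traversals and 0 for disjoint ones.  A bin's score is
x = -ln(J_mean) with J_mean the arithmetic mean of J over all unordered
path pairs; small x = conserved, large x = divergent.  Orientation is
ignored: an inverted copy of the same sequence still shares its content.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .binning import Bin
from .graph import PangenomeGraph, Step


@dataclass
class SegmentMultiset:
    """Traversal counts of a sub-path, with segment lengths as weights."""

    counts: dict[str, int]
    lengths: dict[str, int]

    @property
    def total_weight(self) -> int:
        return sum(
            count * self.lengths[seg] for seg, count in self.counts.items()
        )


def to_multiset(
    subpath: Iterable[Step], graph: PangenomeGraph
) -> SegmentMultiset:
    """Orientation-blind traversal counts of a sub-path."""
    counts = Counter(step.segment_id for step in subpath)
    lengths = {seg: graph.segments[seg].length for seg in counts}
    return SegmentMultiset(dict(counts), lengths)


def weighted_jaccard(a: SegmentMultiset, b: SegmentMultiset) -> float:
    """Length-weighted multiset Jaccard index in [0, 1].

    Two empty multisets score 1: haplotypes that both deleted a region
    carry identical (null) sequence there.
    """
    inter = 0
    union = 0
    for seg in a.counts.keys() | b.counts.keys():
        ca = a.counts.get(seg, 0)
        cb = b.counts.get(seg, 0)
        length = a.lengths.get(seg) or b.lengths.get(seg) or 0
        inter += min(ca, cb) * length
        union += max(ca, cb) * length
    if union == 0:
        return 1.0
    return inter / union


def _pair_stats(
    bin_: Bin, graph: PangenomeGraph
) -> tuple[float, int, int]:
    """(mean pairwise J, number of pairs, max pair union weight)."""
    multisets = {
        name: to_multiset(steps, graph)
        for name, steps in bin_.subpaths.items()
    }
    names = [p.name for p in graph.paths]
    total = 0.0
    n_pairs = 0
    max_union = 0
    for pa, pb in combinations(names, 2):
        a, b = multisets[pa], multisets[pb]
        union = 0
        inter = 0
        for seg in a.counts.keys() | b.counts.keys():
            ca = a.counts.get(seg, 0)
            cb = b.counts.get(seg, 0)
            length = a.lengths.get(seg) or b.lengths.get(seg) or 0
            inter += min(ca, cb) * length
            union += max(ca, cb) * length
        total += 1.0 if union == 0 else inter / union
        max_union = max(max_union, union)
        n_pairs += 1
    return total / n_pairs, n_pairs, max_union


@dataclass
class BinScore:
    """Mean pairwise Jaccard of one bin and its -log score."""

    bin_index: int
    ref_start: int
    ref_end: int
    mean_jaccard: float
    score: float
    n_pairs: int
    p_conserved: float | None = None
    p_divergent: float | None = None


def bin_mean_jaccard(
    bin_: Bin,
    graph: PangenomeGraph,
    jaccard_floor: float | None = None,
) -> BinScore:
    """Score one bin: mean pairwise J and x = -ln(max(J, floor)).

    The floor keeps x finite when every pair is disjoint (J = 0); by
    default it is 1/(1 + this bin's largest pair union weight), i.e. just
    below the smallest non-zero J the bin could produce.  p-values are
    left unset.
    """
    if len(graph.paths) < 2:
        raise ValueError("at least 2 paths are required")
    mean_j, n_pairs, max_union = _pair_stats(bin_, graph)
    if jaccard_floor is None:
        jaccard_floor = 1.0 / (1.0 + max_union)
    score = -math.log(max(mean_j, jaccard_floor)) + 0.0  # never -0.0
    return BinScore(
        bin_.index, bin_.start, bin_.end, mean_j, score, n_pairs
    )


def score_all_bins(
    bins: Sequence[Bin],
    graph: PangenomeGraph,
    jaccard_floor: float | None = None,
) -> tuple[list[BinScore], float]:
    """Score every bin with one shared Jaccard floor.

    The default floor is 1/(1 + W) with W the largest pair union weight
    over all bins, so every representable non-zero J stays above it.
    Returns ``(scores, floor)``; the floor is echoed in output headers.
    """
    stats = [_pair_stats(b, graph) for b in bins]
    if jaccard_floor is None:
        max_union = max((s[2] for s in stats), default=0)
        jaccard_floor = 1.0 / (1.0 + max_union)
    scores = [
        BinScore(
            b.index,
            b.start,
            b.end,
            mean_j,
            -math.log(max(mean_j, jaccard_floor)) + 0.0,
            n_pairs,
        )
        for b, (mean_j, n_pairs, _) in zip(bins, stats)
    ]
    return scores, jaccard_floor
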