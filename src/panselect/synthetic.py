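"""Seeded pangenome-graph simulator with exact per-region ground truth.

The simulator emits the graph topology the scoring pipeline assumes: a
backbone of universal anchor segments, each traversed forward exactly once
by every haplotype, interleaved with variable regions realised as
per-haplotype allele walks.  Divergence is injected at segment
granularity: each reference segment of a region is, per haplotype,
replaced by a private segment of the same length with the region's
divergence probability, so the divergence parameter is the expected
fraction of region sequence private to a haplotype.  A structural-variant
knob can additionally drop (deletion) or double (tandem duplication) a
haplotype's whole region allele.

The first haplotype is the reference and always carries the reference
alleles, so anchor coordinates are fixed and known exactly.  All
randomness flows from one seed: identical parameters give byte-identical
GFA output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from typing import IO, Sequence

import numpy as np

from .binning import Bin
from .graph import FORWARD, HaplotypePath, PangenomeGraph, Segment, Step
from .similarity import BinScore

_BASES = np.array(list("ACGT"))


@dataclass
class SynthParams:
    """Simulation controls.

    Defaults describe the standard benchmark graph: 4 haplotypes over 20
    regions of 1 kb whose divergence rises linearly from 0 to 0.9,
    anchored by 100 bp universal segments, with region alleles cut into
    25 bp segments (the granularity of small-variant bubbles) and no
    whole-region structural variants.
    """

    n_haplotypes: int = 4
    n_regions: int = 20
    anchor_length: int = 100
    region_length: int = 1000
    per_region_divergence: Sequence[float] | None = None
    sv_probability: float = 0.0
    segment_length: int = 25
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_haplotypes < 2:
            raise ValueError("need >= 2 haplotypes")
        if self.n_regions < 1:
            raise ValueError("need >= 1 region")
        if self.anchor_length < 1:
            raise ValueError("anchor_length must be >= 1")
        if self.region_length < 1 or self.segment_length < 1:
            raise ValueError("lengths must be >= 1")
        if not 0.0 <= self.sv_probability <= 1.0:
            raise ValueError("sv_probability must be in [0, 1]")
        if self.per_region_divergence is None:
            self.per_region_divergence = (
                np.linspace(0.0, 0.9, self.n_regions).tolist()
                if self.n_regions > 1
                else [0.0]
            )
        self.per_region_divergence = [
            float(d) for d in self.per_region_divergence
        ]
        if len(self.per_region_divergence) != self.n_regions:
            raise ValueError(
                "per_region_divergence must have n_regions entries"
            )
        if not all(0.0 <= d <= 1.0 for d in self.per_region_divergence):
            raise ValueError("divergence values must be in [0, 1]")


@dataclass(frozen=True)
class RegionTruth:
    index: int
    ref_start: int
    ref_end: int
    divergence: float


@dataclass
class GroundTruth:
    """Known per-region divergence of one simulated graph."""

    regions: list[RegionTruth]
    reference_name: str
    anchor_length: int
    region_length: int


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _piece_lengths(total: int, piece: int) -> list[int]:
    """Cut ``total`` into near-equal pieces of about ``piece`` bases."""
    n = max(1, round(total / piece))
    base, extra = divmod(total, n)
    return [base + (1 if i < extra else 0) for i in range(n)]


def generate_graph(
    params: SynthParams,
) -> tuple[PangenomeGraph, GroundTruth]:
    """Build a synthetic graph and its ground truth.

    With divergence 0 everywhere all haplotypes are identical; with
    divergence 1 in a region every haplotype's allele there is fully
    private, so pairwise similarity in that region is 0 by construction.
    """
    rng = np.random.default_rng(params.seed)
    segments: dict[str, Segment] = {}
    counter = 0

    def new_segment(length: int) -> str:
        nonlocal counter
        counter += 1
        seg_id = f"s{counter}"
        segments[seg_id] = Segment(
            seg_id, length, _random_sequence(rng, length)
        )
        return seg_id

    names = [f"hap{h}#1#chr1" for h in range(params.n_haplotypes)]
    step_lists: list[list[Step]] = [[] for _ in names]
    regions: list[RegionTruth] = []
    offset = 0

    def add_anchor() -> None:
        nonlocal offset
        seg = new_segment(params.anchor_length)
        for steps in step_lists:
            steps.append(Step(seg, FORWARD))
        offset += params.anchor_length

    add_anchor()
    for r, divergence in enumerate(params.per_region_divergence):
        lengths = _piece_lengths(params.region_length, params.segment_length)
        ref_allele = [new_segment(length) for length in lengths]
        regions.append(
            RegionTruth(r, offset, offset + params.region_length, divergence)
        )
        for h, steps in enumerate(step_lists):
            if h == 0:
                allele = [Step(seg, FORWARD) for seg in ref_allele]
            else:
                allele = []
                for seg in ref_allele:
                    if rng.random() < divergence:
                        allele.append(
                            Step(new_segment(segments[seg].length), FORWARD)
                        )
                    else:
                        allele.append(Step(seg, FORWARD))
                if params.sv_probability and rng.random() < params.sv_probability:
                    allele = [] if rng.random() < 0.5 else allele * 2
            steps.extend(allele)
        offset += params.region_length
        add_anchor()

    paths = [
        HaplotypePath(name, steps)
        for name, steps in zip(names, step_lists)
    ]
    graph = PangenomeGraph(segments, paths, reference_name=names[0])
    graph.validate()
    truth = GroundTruth(
        regions, names[0], params.anchor_length, params.region_length
    )
    return graph, truth


def expected_bin_ranking(truth: GroundTruth) -> list[int]:
    """Region indices from most to least divergent, ties by index."""
    return sorted(
        range(len(truth.regions)),
        key=lambda i: (-truth.regions[i].divergence, i),
    )


def match_regions_to_bins(
    truth: GroundTruth,
    bins: Sequence[Bin] | Sequence[BinScore],
) -> list[int]:
    """For each region, the index into ``bins`` covering its midpoint.

    Accepts :class:`~panselect.binning.Bin` or
    :class:`~panselect.similarity.BinScore` sequences.  Raises if a
    region's midpoint is covered by no bin.
    """
    intervals = [
        (b.start, b.end) if isinstance(b, Bin) else (b.ref_start, b.ref_end)
        for b in bins
    ]
    out = []
    for region in truth.regions:
        mid = (region.ref_start + region.ref_end) // 2
        for i, (start, end) in enumerate(intervals):
            if start <= mid < end:
                out.append(i)
                break
        else:
            raise ValueError(
                f"region {region.index} midpoint {mid} not covered by "
                "any bin"
            )
    return out


def write_truth_tsv(truth: GroundTruth, sink: IO[str]) -> None:
    sink.write("region_index\tref_start\tref_end\tdivergence\n")
    for region in truth.regions:
        sink.write(
            f"{region.index}\t{region.ref_start}\t{region.ref_end}\t"
            f"{region.divergence:.6g}\n"
        )


def graph_to_gfa_text(graph: PangenomeGraph, dialect: str = "P") -> str:
    """The graph as a GFA string (convenience for fixtures and tests)."""
    from .graph import write_gfa

    buffer = StringIO()
    write_gfa(graph, buffer, dialect=dialect)
    return buffer.getvalue()
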