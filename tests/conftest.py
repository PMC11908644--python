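import io

import pytest

import panselect as ps


@pytest.fixture
def three_segment_gfa() -> str:
    """Two identical paths over segments of lengths 5, 3, 5."""
    return (
        "S\ta\tAAAAA\n"
        "S\tb\tCCC\n"
        "S\tc\tGGGGG\n"
        "P\tp1\ta+,b+,c+\t*\n"
        "P\tp2\ta+,b+,c+\t*\n"
    )


@pytest.fixture
def three_segment_graph(three_segment_gfa) -> ps.PangenomeGraph:
    return ps.parse_gfa(io.StringIO(three_segment_gfa))


@pytest.fixture
def bubble_graph() -> ps.PangenomeGraph:
    """Shared anchors a/c with a bi-allelic bubble (b vs d) in between."""
    gfa = (
        "S\ta\tAAAAA\n"
        "S\tb\tCCC\n"
        "S\td\tTTT\n"
        "S\tc\tGGGGG\n"
        "P\tp1\ta+,b+,c+\t*\n"
        "P\tp2\ta+,d+,c+\t*\n"
    )
    return ps.parse_gfa(io.StringIO(gfa))


def make_graph(path_defs: dict[str, str], lengths: dict[str, int],
               reference: str | None = None) -> ps.PangenomeGraph:
    """Build a graph from compact walk strings like {"p1": "a+ b- c+"}."""
    segments = {
        seg: ps.Segment(seg, length, "A" * length)
        for seg, length in lengths.items()
    }
    paths = [
        ps.HaplotypePath(
            name,
            [ps.Step(tok[:-1], tok[-1]) for tok in walk.split()],
        )
        for name, walk in path_defs.items()
    ]
    graph = ps.PangenomeGraph(
        segments, paths, reference or paths[0].name
    )
    graph.validate()
    return graph
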