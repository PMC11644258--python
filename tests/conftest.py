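import numpy as np
import pandas as pd
import pytest

from seedgrn.containers import DirectedGRN, ExpressionMatrix, GRNEdge


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    """8 genes x (4 time points x 2 replicates), deterministic values."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(8)]
    times = [0.0, 2.0, 4.0, 6.0]
    cols, tt, rr = [], [], []
    for t in times:
        for r in (1, 2):
            cols.append(f"T{t:g}_R{r}")
            tt.append(t)
            rr.append(r)
    values = pd.DataFrame(
        rng.uniform(0.0, 10.0, size=(len(genes), len(cols))),
        index=pd.Index(genes, name="gene"),
        columns=cols,
    )
    samples = pd.DataFrame({"sample_id": cols, "time_dap": tt, "replicate": rr})
    return ExpressionMatrix(values=values, samples=samples)


def random_digraph(n_nodes: int, n_edges: int, seed: int) -> DirectedGRN:
    """Uniform loop-free random directed network on named nodes."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    possible = [(a, b) for a in nodes for b in nodes if a != b]
    picks = rng.choice(len(possible), size=min(n_edges, len(possible)), replace=False)
    edges = [GRNEdge(*possible[int(k)]) for k in picks]
    return DirectedGRN(edges=edges, nodes=set(nodes))


def reciprocity_free_digraph(n_nodes: int, n_edges: int, seed: int) -> DirectedGRN:
    """Random loop-free digraph containing no mutual (reciprocal) dyads."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i}" for i in range(n_nodes)]
    chosen: set[tuple[str, str]] = set()
    while len(chosen) < n_edges:
        i, j = rng.integers(0, n_nodes, 2)
        if i == j:
            continue
        a, b = nodes[int(i)], nodes[int(j)]
        if (a, b) in chosen or (b, a) in chosen:
            continue
        chosen.add((a, b))
    return DirectedGRN([GRNEdge(a, b) for a, b in sorted(chosen)], nodes=set(nodes))


@pytest.fixture
def ffl_net() -> DirectedGRN:
    return DirectedGRN([GRNEdge("A", "B"), GRNEdge("A", "C"), GRNEdge("B", "C")])
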