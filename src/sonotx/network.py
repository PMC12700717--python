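"""Stage-progression miRNA regulatory network.

mRNAs whose group means decrease monotonically along the progression axis
healthy -> T2c -> T3b, and miRNAs whose means increase monotonically, are
joined with a miRNA -> target interaction table; the induced bipartite
subgraph is ranked by miRNA out-degree and high-degree miRNAs are reported
as hubs (candidate progression drivers).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

__all__ = ["trend_filter", "BipartiteGRN", "build_grn"]

GROUP_ORDER = ("healthy", "T2c", "T3b")


def trend_filter(
    norm_matrix: pd.DataFrame,
    groups: pd.Series,
    direction: str,
    delta: float = 0.0,
    group_order: tuple[str, ...] = GROUP_ORDER,
) -> list[str]:
    """Features whose group means are monotone along ``group_order``.

    ``direction`` is "decreasing" (each successive mean lower by more than
    ``delta``) or "increasing" (the reverse).  ``delta`` defaults to 0,
    i.e. weak monotonicity of the means.
    """
    if direction not in ("decreasing", "increasing"):
        raise ValueError("direction must be 'decreasing' or 'increasing'")
    groups = groups.loc[norm_matrix.columns]
    for g in group_order:
        if not (groups == g).any():
            raise ValueError(f"group {g!r} has no samples")
    means = pd.DataFrame(
        {g: norm_matrix.loc[:, groups.index[groups == g]].mean(axis=1)
         for g in group_order}
    )
    diffs = means.diff(axis=1).iloc[:, 1:]
    if direction == "decreasing":
        keep = (diffs < -delta).all(axis=1)
    else:
        keep = (diffs > delta).all(axis=1)
    return sorted(means.index[keep])


@dataclass
class BipartiteGRN:
    """miRNA -> gene bipartite network with hub ranking."""

    graph: nx.DiGraph
    degrees: pd.Series  # per-miRNA out-degree, descending then lexicographic
    hubs: list[str]
    hub_min_degree: int

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def covered_genes(self, mirnas=None) -> set[str]:
        mirnas = self.hubs if mirnas is None else mirnas
        return {g for m in mirnas for g in self.graph.successors(m)}

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [{"node": n, "kind": d["kind"]} for n, d in self.graph.nodes(data=True)]
        ).sort_values(["kind", "node"], ignore_index=True)
        edges = pd.DataFrame(
            [{"mirna": u, "gene": v} for u, v in self.graph.edges()]
        ).sort_values(["mirna", "gene"], ignore_index=True)
        return nodes, edges


def build_grn(
    mirnas: list[str],
    genes: list[str],
    interactions: pd.DataFrame,
    hub_min_degree: int = 2,
) -> BipartiteGRN:
    """Induce the miRNA x gene subgraph of an interaction edge list.

    ``interactions`` needs columns ``mirna`` and ``gene``; duplicate edges
    are collapsed so each pair counts once toward the degree.  An empty
    interaction table is an error; filters that leave no edge yield an
    explicit empty network.
    """
    if not {"mirna", "gene"}.issubset(interactions.columns):
        raise ValueError("interaction table needs 'mirna' and 'gene' columns")
    if interactions.empty:
        raise ValueError("empty interaction table")
    mirna_set, gene_set = set(mirnas), set(genes)
    edges = interactions[["mirna", "gene"]].drop_duplicates()
    edges = edges[edges["mirna"].isin(mirna_set) & edges["gene"].isin(gene_set)]

    g = nx.DiGraph()
    for m in sorted(mirna_set & set(edges["mirna"])):
        g.add_node(m, kind="mirna")
    for t in sorted(gene_set & set(edges["gene"])):
        g.add_node(t, kind="gene")
    g.add_edges_from(edges.itertuples(index=False, name=None))

    deg = pd.Series(
        {m: g.out_degree(m) for m, d in g.nodes(data=True) if d["kind"] == "mirna"},
        dtype=int,
    )
    deg = deg.sort_index().sort_values(ascending=False, kind="mergesort")
    hubs = [m for m, k in deg.items() if k >= hub_min_degree]
    return BipartiteGRN(graph=g, degrees=deg, hubs=hubs,
                        hub_min_degree=hub_min_degree)
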