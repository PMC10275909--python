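"""Pathway–pathway functional association via CSEA.

Two pathways are functionally associated when their gene lists share
many molecular concepts, even if they share few genes.  Entry (i, j) of
the association matrix is the NES of pathway j when pathway i's genes
are used as a CSEA target list; the matrix is symmetrized (mean by
default) and the diagonal is set to each row's maximum for display.
Exports: TSV matrix, TSV edge list and GraphML for network views, where
node size maps to enrichment NES and edge weight to association.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .compendium import ConceptCompendium, ValidationError
from .enrich import EnrichmentParams, PathwayTable, run_csea

logger = logging.getLogger("uniconsig.association")


@dataclass(frozen=True)
class AssociationMatrix:
    """Square symmetric matrix of pathway association scores."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    symmetrization: str = "mean"

    def __post_init__(self) -> None:
        k = len(self.ids)
        if self.matrix.shape != (k, k):
            raise ValidationError("matrix dimensions must match the id list")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="pathway")

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrix[i, j])


def associate(
    pathway_ids: Sequence[str],
    pathways: ConceptCompendium,
    compendium: ConceptCompendium,
    params: EnrichmentParams,
    symmetrization: str = "mean",
) -> AssociationMatrix:
    """Pairwise CSEA association among ``pathway_ids``.

    Row i comes from one CSEA run with pathway i's genes as the target
    and the selected pathways as the tested collection.  A pathway
    disjoint from the concept universe yields a zero row with a warning.
    """
    ids = tuple(pathway_ids)
    if len(ids) < 2:
        raise ValidationError("association requires at least 2 pathways")
    for i in ids:
        if i not in pathways:
            raise ValidationError(f"pathway {i!r} not in the collection")
    if symmetrization not in ("mean", "max"):
        raise ValidationError(f"unknown symmetrization {symmetrization!r}")
    tested = pathways.subset(ids)
    k = len(ids)
    raw = np.zeros((k, k))
    for i, pid in enumerate(ids):
        target = set(pathways[pid].genes)
        if not (target & compendium.universe):
            warnings.warn(
                f"pathway {pid!r} shares no genes with the concept universe; zero row"
            )
            continue
        table = run_csea(target, compendium, tested, params, direction="up")
        for r in table.results:
            raw[i, ids.index(r.pathway_id)] = r.nes
    if symmetrization == "mean":
        sym = (raw + raw.T) / 2.0
    else:
        sym = np.maximum(raw, raw.T)
    np.fill_diagonal(sym, sym.max(axis=1))
    return AssociationMatrix(ids=ids, matrix=sym, symmetrization=symmetrization)


def export_network(
    matrix: AssociationMatrix,
    enrichments: PathwayTable | None = None,
    edge_threshold: float = 0.0,
) -> nx.Graph:
    """Association network: every pathway is a node (attribute ``nes``
    from ``enrichments``, 0 if absent); edges connect pairs whose
    symmetrized association is >= ``edge_threshold``."""
    if edge_threshold < 0:
        raise ValidationError("edge_threshold must be >= 0")
    g = nx.Graph()
    for pid in matrix.ids:
        nes = 0.0
        if enrichments is not None:
            try:
                nes = enrichments[pid].nes
            except KeyError:
                pass
        g.add_node(pid, nes=float(nes))
    k = len(matrix.ids)
    for i in range(k):
        for j in range(i + 1, k):
            w = float(matrix.matrix[i, j])
            if w >= edge_threshold:
                g.add_edge(matrix.ids[i], matrix.ids[j], weight=w)
    return g


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = sorted((min(u, v), max(u, v), d["weight"]) for u, v, d in graph.edges(data=True))
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)
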