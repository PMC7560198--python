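"""Cell-type-resolved ligand-receptor communication map.

Joins three datasets: cell-type-specifically *secreted* proteins (ligand
side), cell-type-specifically *expressed* membrane proteins from lysate
proteomes (receptor side), and a binary protein-protein interaction table.
An edge secreting-cell-type -> receiving-cell-type is drawn for every
interaction pair whose secreted partner has a specificity call and whose
membrane partner is both lysate-specific and annotated as a membrane
protein.  Autocrine (self-group) edges are allowed.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import pandas as pd

from .types import AnnotationRecord, InteractionTable

__all__ = ["build_map", "to_graphml"]

MEMBRANE_KEYWORDS = {"membrane", "transmembrane_single_pass"}


def strip_isoform(accession: str) -> str:
    """Primary accession without an isoform suffix (``P12345-2`` -> ``P12345``)."""
    return accession.split("-")[0]


def build_map(
    cts_calls: pd.DataFrame,
    lysate_calls: pd.Series,
    interactions: InteractionTable,
    annotations: list[AnnotationRecord],
) -> pd.DataFrame:
    """Emit directed ligand -> receptor edges between cell types.

    An edge (a -> b) requires: ``a`` has a ``specific_group`` secretion call,
    (a, b) is an interaction pair, ``b`` has a lysate-specific group, and
    ``b`` carries a membrane/transmembrane keyword.  When both partners
    qualify in both roles, two directed edges are emitted.  Output order is
    deterministic (sorted by ligand, receptor).
    """
    ligand_group = {
        strip_isoform(pid): g
        for pid, g in cts_calls["specific_group"].items()
        if g is not None
    }
    receptor_group = {
        strip_isoform(pid): g for pid, g in lysate_calls.items() if g is not None
    }
    membrane = {
        strip_isoform(a.protein_id)
        for a in annotations
        if a.keywords & MEMBRANE_KEYWORDS
    }

    edges = []
    for a, b, source in interactions:
        a, b = strip_isoform(a), strip_isoform(b)
        for ligand, receptor in ((a, b), (b, a)):
            if (
                ligand in ligand_group
                and receptor in receptor_group
                and receptor in membrane
            ):
                edges.append(
                    (
                        ligand,
                        ligand_group[ligand],
                        receptor,
                        receptor_group[receptor],
                        source,
                    )
                )
    result = pd.DataFrame(
        edges,
        columns=["ligand", "ligand_group", "receptor", "receptor_group", "source"],
    )
    return result.sort_values(["ligand", "receptor"]).reset_index(drop=True)


def to_graphml(edges: pd.DataFrame, path: str | Path) -> None:
    """Write the edge list as GraphML for network viewers."""
    graph = nx.MultiDiGraph()
    for row in edges.itertuples(index=False):
        graph.add_node(row.ligand, group=row.ligand_group, role="ligand")
        graph.add_node(row.receptor, group=row.receptor_group, role="receptor")
        graph.add_edge(row.ligand, row.receptor, source=row.source)
    nx.write_graphml(graph, str(path))
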