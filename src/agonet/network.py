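"""Assembly and annotation of the miRNA-mRNA interaction network.

The network is a directed bipartite graph miRNA -> gene. Edges come from
two evidence streams — assigned MREs in binding-site clusters, and
chimera reads — merged at gene level (``evidence`` is ``mre``,
``chimera`` or ``both``). Node statuses are overlaid from the
differential results: miRNAs carry up / down (abundance) or
more_associated / less_associated (AGO2 loading) labels; genes carry an
expression status and an AGO2-binding status. Damage-coregulation motifs
(feedforward-style loops with the damage response as apex regulator) are
counted edge-locally from these statuses.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

MIRNA_STATUSES = ("up", "down", "more_associated", "less_associated", "none")
GENE_STATUSES = ("up", "down", "none")

_CATEGORY_TO_STATUS = {
    ("abundance_concordant", "up"): "up",
    ("abundance_concordant", "down"): "down",
    ("association_only", "up"): "more_associated",
    ("association_only", "down"): "less_associated",
}


def mirna_status_from_classification(classification: pd.DataFrame) -> dict[str, str]:
    """Map joint IP/total categories to node statuses (total_only and
    unchanged miRNAs get 'none')."""
    return {
        mid: _CATEGORY_TO_STATUS.get((row.category, row.direction), "none")
        for mid, row in classification.iterrows()
    }


def assemble_network(
    mres: Mapping[str, object] | Iterable,
    chimeras: Iterable,
    gene_map: Mapping[str, str],
    cluster_transcripts: Mapping[str, str] | None = None,
) -> nx.DiGraph:
    """Build the gene-level interaction graph from assigned MREs and
    chimera reads.

    `mres` is the ``{cluster_id: MRE}`` mapping from
    :func:`agonet.mre.assign_all` (or any iterable of assigned MREs);
    when MRE objects do not know their transcript, `cluster_transcripts`
    maps cluster ids to transcript ids. Transcript isoforms collapse onto
    their gene; duplicate (miRNA, gene) support within one evidence
    stream is counted in the edge's ``n_mre`` / ``n_chimera`` weights.
    """
    graph = nx.DiGraph()
    unmapped: set[str] = set()

    def gene_of(transcript_id: str) -> str | None:
        gene = gene_map.get(transcript_id)
        if gene is None:
            unmapped.add(transcript_id)
        return gene

    def add(mirna_id: str, gene: str, evidence: str) -> None:
        for node, kind in ((mirna_id, "mirna"), (gene, "gene")):
            if not graph.has_node(node):
                graph.add_node(node, kind=kind, status="none")
        if not graph.has_edge(mirna_id, gene):
            graph.add_edge(mirna_id, gene, evidence=evidence,
                           n_mre=0, n_chimera=0)
        data = graph.edges[mirna_id, gene]
        if data["evidence"] != evidence:
            data["evidence"] = "both"
        data["n_mre" if evidence == "mre" else "n_chimera"] += 1

    mre_items = mres.items() if isinstance(mres, Mapping) else [
        (getattr(m, "cluster_id", None), m) for m in mres
    ]
    for cluster_id, mre in mre_items:
        tid = getattr(mre, "transcript_id", None)
        if tid is None:
            if cluster_transcripts is None:
                raise ValueError(
                    "MREs lack transcript ids and no cluster_transcripts "
                    "mapping was given"
                )
            tid = cluster_transcripts[cluster_id]
        gene = gene_of(tid)
        if gene is not None:
            add(mre.mirna_id, gene, "mre")
    for chim in chimeras:
        gene = gene_of(chim.transcript_id)
        if gene is not None:
            add(chim.mirna_id, gene, "chimera")
    if unmapped:
        raise KeyError(
            f"transcripts missing from gene map: {sorted(unmapped)}"
        )
    return graph


def overlay_expression(
    graph: nx.DiGraph,
    mirna_status: Mapping[str, str] | None = None,
    gene_expression_status: Mapping[str, str] | None = None,
    gene_binding_status: Mapping[str, str] | None = None,
) -> nx.DiGraph:
    """Annotate node statuses in place (idempotent; absent entries mean
    'none'; never adds or removes topology)."""
    for node, data in graph.nodes(data=True):
        if data["kind"] == "mirna":
            data["status"] = (mirna_status or {}).get(node, data.get("status", "none"))
        else:
            data["status"] = (gene_expression_status or {}).get(
                node, data.get("status", "none")
            )
            data["binding_status"] = (gene_binding_status or {}).get(
                node, data.get("binding_status", "none")
            )
    return graph


def extract_subnetwork(graph: nx.DiGraph,
                       mirna_status_filter: set[str]) -> nx.DiGraph:
    """Induced subgraph on the miRNAs whose status is in the filter, plus
    all of their targets (edges preserved)."""
    unknown = set(mirna_status_filter) - set(MIRNA_STATUSES)
    if unknown:
        raise ValueError(f"unknown miRNA status values: {sorted(unknown)}")
    keep_mirnas = {
        n
        for n, d in graph.nodes(data=True)
        if d["kind"] == "mirna" and d.get("status", "none") in mirna_status_filter
    }
    keep = set(keep_mirnas)
    for m in keep_mirnas:
        keep.update(graph.successors(m))
    return graph.subgraph(keep).copy()


_ACTIVATED = {"up", "more_associated"}
_REPRESSED = {"down", "less_associated"}


def count_ffl(graph: nx.DiGraph) -> dict[str, int]:
    """Count damage-coregulation motifs over annotated edges.

    For every edge whose miRNA and gene both carry non-'none' damage
    statuses: an activated miRNA (up / more_associated) targeting a
    down-regulated gene is a *coherent* loop (both arms push the gene
    down); an activated miRNA targeting an up-regulated gene is
    *incoherent*; symmetrically for repressed miRNAs (repressed miRNA ->
    up gene is coherent, -> down gene incoherent).
    """
    counts = {"coherent": 0, "incoherent": 0}
    for mirna, gene in graph.edges():
        ms = graph.nodes[mirna].get("status", "none")
        gs = graph.nodes[gene].get("status", "none")
        if ms == "none" or gs not in ("up", "down"):
            continue
        if ms in _ACTIVATED:
            counts["coherent" if gs == "down" else "incoherent"] += 1
        elif ms in _REPRESSED:
            counts["coherent" if gs == "up" else "incoherent"] += 1
    return counts


def edges_frame(graph: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "mirna_id": m, "gene_id": g, "evidence": d["evidence"],
            "n_mre": d.get("n_mre", 0), "n_chimera": d.get("n_chimera", 0),
        }
        for m, g, d in graph.edges(data=True)
    ]
    return pd.DataFrame(
        rows, columns=["mirna_id", "gene_id", "evidence", "n_mre", "n_chimera"]
    )


def nodes_frame(graph: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {
            "node_id": n, "kind": d["kind"], "status": d.get("status", "none"),
            "binding_status": d.get("binding_status", ""),
        }
        for n, d in graph.nodes(data=True)
    ]
    return pd.DataFrame(rows, columns=["node_id", "kind", "status",
                                       "binding_status"])


def write_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.DiGraph:
    return nx.read_graphml(path)
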