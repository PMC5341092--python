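"""PPI network cleanup and per-gene node-degree extraction.

The input is an edge list of protein accessions plus a mapping table
describing each accession's status (current / deleted / renamed), gene
membership, biotype and review status.  Cleanup mirrors curated-interactome
practice: deleted accessions leave with their edges, renamed ones are
replaced, products of non-protein-coding genes are dropped (with an
optional rescue flag for genes called protein-coding by HGNC), and
unreviewed accessions whose gene also has a reviewed accession are merged
into it, their interactions inherited.  The final graph is simple and
undirected; a gene's degree is that of its highest-degree accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class MappingEntry:
    accession: str
    status: str = "current"  # current | deleted | renamed
    replacement: str | None = None
    gene_ids: frozenset = frozenset()
    biotype: str = "protein_coding"
    reviewed: bool = True
    hgnc_protein_coding: bool = False

    def __post_init__(self):
        self.gene_ids = frozenset(self.gene_ids)
        if self.status == "renamed" and not self.replacement:
            raise ValueError(f"{self.accession}: renamed without replacement")
        if self.status == "deleted" and self.replacement:
            raise ValueError(
                f"{self.accession}: marked both deleted and renamed"
            )


@dataclass
class CleanupLog:
    deleted: list = field(default_factory=list)
    renamed: list = field(default_factory=list)
    non_coding_removed: list = field(default_factory=list)
    merged: list = field(default_factory=list)
    multi_gene: list = field(default_factory=list)


def normalize_identifiers(edges, mapping: dict, hgnc_rescue: bool = True):
    """Apply the identifier-cleanup rules to a raw edge list.

    ``mapping`` maps accession -> :class:`MappingEntry`.  Returns
    ``(edges, node_genes, log)`` where ``node_genes`` maps each surviving
    accession to its gene-id set (multi-gene accessions stay in the graph
    but are not selectable at gene level).
    """
    log = CleanupLog()

    def entry_for(acc: str) -> MappingEntry:
        return mapping.get(acc, MappingEntry(acc, gene_ids=frozenset()))

    # 1. renames
    def resolve(acc: str) -> str | None:
        entry = entry_for(acc)
        if entry.status == "renamed":
            log.renamed.append(acc)
            return entry.replacement
        if entry.status == "deleted":
            return None
        return acc

    renamed_edges = []
    for a, b in edges:
        ra, rb = resolve(a), resolve(b)
        if ra is None or rb is None:
            for acc, r in ((a, ra), (b, rb)):
                if r is None:
                    log.deleted.append(acc)
            continue
        renamed_edges.append((ra, rb))

    # 2. biotype filter (rescued by HGNC "protein-coding gene" flag)
    def keeps_biotype(acc: str) -> bool:
        entry = entry_for(acc)
        if entry.biotype == "protein_coding":
            return True
        return hgnc_rescue and entry.hgnc_protein_coding

    filtered = []
    for a, b in renamed_edges:
        if keeps_biotype(a) and keeps_biotype(b):
            filtered.append((a, b))
        else:
            for acc in (a, b):
                if not keeps_biotype(acc) and acc not in log.non_coding_removed:
                    log.non_coding_removed.append(acc)

    # 3. merge unreviewed accessions into a reviewed accession of the same gene
    nodes = {acc for e in filtered for acc in e}
    reviewed_by_gene: dict = {}
    for acc in sorted(nodes):
        entry = entry_for(acc)
        if entry.reviewed and len(entry.gene_ids) == 1:
            (gene,) = entry.gene_ids
            reviewed_by_gene.setdefault(gene, acc)
    merge_map = {}
    for acc in sorted(nodes):
        entry = entry_for(acc)
        if not entry.reviewed and len(entry.gene_ids) == 1:
            (gene,) = entry.gene_ids
            target = reviewed_by_gene.get(gene)
            if target is not None and target != acc:
                merge_map[acc] = target
                log.merged.append((acc, target))

    merged_edges = [
        (merge_map.get(a, a), merge_map.get(b, b)) for a, b in filtered
    ]

    node_genes = {}
    for acc in {x for e in merged_edges for x in e}:
        entry = entry_for(acc)
        node_genes[acc] = set(entry.gene_ids)
        if len(entry.gene_ids) > 1:
            log.multi_gene.append(acc)
    return merged_edges, node_genes, log


def build_network(edges, node_genes: dict | None = None) -> nx.Graph:
    """Simple undirected graph: self-loops and duplicate edges collapse."""
    g = nx.Graph()
    if node_genes:
        for acc, genes in node_genes.items():
            g.add_node(acc, gene_ids=frozenset(genes))
    for a, b in edges:
        if a == b:
            continue
        g.add_edge(a, b)
    return g


def resolve_gene_degree(net: nx.Graph, gene_id: str):
    """(accession, degree) of the gene's highest-degree single-gene accession.

    Ties break to the lexicographically smallest accession.  Returns
    ``None`` when the gene has no selectable accession in the network.
    """
    candidates = [
        acc
        for acc, data in net.nodes(data=True)
        if data.get("gene_ids") == frozenset({gene_id})
    ]
    if not candidates:
        return None
    best = min(candidates, key=lambda acc: (-net.degree(acc), acc))
    return best, net.degree(best)


def degree_table(net: nx.Graph, gene_ids) -> tuple:
    """Per-gene degree DataFrame plus the genes absent from the network."""
    rows = {}
    missing = []
    for gene in gene_ids:
        resolved = resolve_gene_degree(net, gene)
        if resolved is None:
            missing.append(gene)
        else:
            acc, deg = resolved
            rows[gene] = {"accession": acc, "degree": deg}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    return df, missing


def read_edge_list(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.itertuples(index=False, name=None))


def read_mapping_table(path) -> dict:
    """Mapping TSV -> accession-keyed :class:`MappingEntry` dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    mapping = {}
    for rec in df.itertuples(index=False):
        mapping[rec.accession] = MappingEntry(
            accession=rec.accession,
            status=rec.status,
            replacement=rec.replacement or None,
            gene_ids=frozenset(v for v in rec.gene_ids.split("|") if v),
            biotype=rec.biotype,
            reviewed=rec.reviewed.lower() in ("true", "1", "yes"),
            hgnc_protein_coding=rec.hgnc_protein_coding.lower()
            in ("true", "1", "yes"),
        )
    return mapping
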