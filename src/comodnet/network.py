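"""Integrative miRNA-protein network assembly and topology scoring.

Differential-expression and coexpression evidence is filtered with
region-specific thresholds, then combined with miRNA->gene target
predictions and protein-protein interactions (PPI, confidence-thresholded)
into one typed graph: miRNA nodes (diamond-style), gene nodes encoding the
measured proteins, and edges of type target_prediction, ppi or coexpression.
Nodes are scored with standard undirected topology metrics and hubs
reported by aggregate rank.

Threshold boundary semantics follow the source operators exactly: strict
``<`` for the differential-expression p cutoffs of miRNAs (0.06 in cortex,
0.05 in midbrain), inclusive ``<=`` for protein p (0.2) and cortex
coexpression p (0.01), strict ``<`` for midbrain coexpression p (0.05),
inclusive ``>=`` for |r| (0.5) and PPI confidence (0.15).
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

REGIONS = ("CTX", "MB")

#: region-specific evidence thresholds (operators noted in the module docstring)
DE_MIRNA_P = {"CTX": 0.06, "MB": 0.05}
DE_PROTEIN_P = 0.2
COEXPR_P = {"CTX": 0.01, "MB": 0.05}
COEXPR_R_MIN = 0.5
PPI_MIN_CONFIDENCE = 0.15


def _check_region(region: str) -> None:
    if region not in REGIONS:
        raise ParameterError(f"unknown region {region!r}; expected one of {REGIONS}")


def filter_de_evidence(
    de_mirna: pd.DataFrame, de_protein: pd.DataFrame, region: str
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the region-specific differential-expression eligibility filters.

    miRNAs are kept iff p < 0.06 (CTX) / p < 0.05 (MB); proteins iff
    p <= 0.2 (both regions). Tables need columns feature_id, p, log2fc.
    """
    _check_region(region)
    mirna = de_mirna[de_mirna["p"] < DE_MIRNA_P[region]].copy()
    protein = de_protein[de_protein["p"] <= DE_PROTEIN_P].copy()
    return mirna, protein


def filter_coexpr_evidence(coexpr: pd.DataFrame, region: str) -> pd.DataFrame:
    """Coexpression-pair eligibility: |r| >= 0.5 and p <= 0.01 (CTX) / p < 0.05 (MB).

    ``coexpr`` needs columns node_a, node_b, r, p.
    """
    _check_region(region)
    strong = coexpr["r"].abs() >= COEXPR_R_MIN
    if region == "CTX":
        sig = coexpr["p"] <= COEXPR_P["CTX"]
    else:
        sig = coexpr["p"] < COEXPR_P["MB"]
    return coexpr[strong & sig].copy()


def assemble_network(
    eligible_mirna: pd.DataFrame,
    eligible_protein: pd.DataFrame,
    targets: pd.DataFrame,
    ppi: pd.DataFrame,
    coexpr_pairs: pd.DataFrame | None = None,
    ppi_min: float = PPI_MIN_CONFIDENCE,
    region: str = "CTX",
) -> nx.Graph:
    """Build the typed integrative graph from eligible evidence.

    Nodes are the eligible miRNAs and the genes of eligible proteins, each
    annotated with kind ("miRNA"/"gene"), regulation direction from the DE
    sign ("up"/"down") and the region tag. Target-prediction edges require
    both endpoints eligible; PPI edges require confidence >= ``ppi_min`` and
    both genes eligible; coexpression edges come from pre-filtered pairs.
    Self-loops are never created.
    """
    if not 0.0 <= ppi_min <= 1.0:
        raise ParameterError("ppi_min must be in [0, 1]")
    g = nx.Graph(region=region)
    for _, row in eligible_mirna.iterrows():
        g.add_node(
            row["feature_id"],
            kind="miRNA",
            regulation="up" if row.get("log2fc", 0.0) >= 0 else "down",
            region=region,
        )
    for _, row in eligible_protein.iterrows():
        g.add_node(
            row["feature_id"],
            kind="gene",
            regulation="up" if row.get("log2fc", 0.0) >= 0 else "down",
            region=region,
        )
    mirna_ids = {n for n, d in g.nodes(data=True) if d["kind"] == "miRNA"}
    gene_ids = {n for n, d in g.nodes(data=True) if d["kind"] == "gene"}
    targets = targets.drop_duplicates(subset=["mirna_id", "gene_id"])
    for _, row in targets.iterrows():
        a, b = row["mirna_id"], row["gene_id"]
        if a in mirna_ids and b in gene_ids and a != b:
            g.add_edge(a, b, type="target_prediction", weight=1.0,
                       provenance=str(row.get("source", "target_table")))
    for _, row in ppi.iterrows():
        a, b = row["gene_a"], row["gene_b"]
        conf = float(row["confidence"])
        if a in gene_ids and b in gene_ids and a != b and conf >= ppi_min:
            if not g.has_edge(a, b):
                g.add_edge(a, b, type="ppi", weight=conf, provenance="ppi_table")
    if coexpr_pairs is not None:
        for _, row in coexpr_pairs.iterrows():
            a, b = row["node_a"], row["node_b"]
            if a in g and b in g and a != b and not g.has_edge(a, b):
                g.add_edge(a, b, type="coexpression", weight=float(row["r"]),
                           provenance="coexpression")
    _assert_edge_types(g)
    return g


def _assert_edge_types(g: nx.Graph) -> None:
    for a, b, d in g.edges(data=True):
        kinds = {g.nodes[a]["kind"], g.nodes[b]["kind"]}
        if d["type"] == "target_prediction" and kinds != {"miRNA", "gene"}:
            raise InputError(f"target edge {a}-{b} must connect miRNA and gene")
        if d["type"] == "ppi" and kinds != {"gene"}:
            raise InputError(f"ppi edge {a}-{b} must connect two genes")
        if a == b:
            raise InputError(f"self-loop at {a}")


def topology_scores(g: nx.Graph) -> pd.DataFrame:
    """Per-node topology metrics on the undirected skeleton.

    degree, betweenness (shortest-path counts normalized to pair fractions),
    closeness (within each connected component), clustering coefficient and
    eccentricity (per component). Empty graphs give an empty table.
    """
    if g.number_of_nodes() == 0:
        return pd.DataFrame(
            columns=["node", "degree", "betweenness", "closeness", "clustering", "eccentricity"]
        )
    degree = dict(g.degree())
    betweenness = nx.betweenness_centrality(g, normalized=True)
    closeness = nx.closeness_centrality(g, wf_improved=False)
    clustering = nx.clustering(g)
    eccentricity: dict = {}
    for comp in nx.connected_components(g):
        eccentricity.update(nx.eccentricity(g.subgraph(comp)))
    nodes = sorted(g.nodes())
    return pd.DataFrame(
        {
            "node": nodes,
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
            "eccentricity": [eccentricity[n] for n in nodes],
        }
    )


#: metric -> True when larger values are more central
_METRIC_ASCENDING = {
    "degree": False,
    "betweenness": False,
    "closeness": False,
    "clustering": False,
    "eccentricity": True,  # smaller eccentricity = closer to the graph centre
}


def hub_report(scores: pd.DataFrame, k: int = 10) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Top-k nodes per metric plus an aggregate rank over all metrics.

    The aggregate is the unweighted mean of per-metric dense ranks (rank 1 =
    most central per that metric); ties in any ordering break
    lexicographically by node ID, so the report is deterministic.
    """
    if k < 1:
        raise ParameterError("k must be >= 1")
    if scores.empty:
        return {m: [] for m in _METRIC_ASCENDING}, scores.assign(aggregate_rank=[])
    scored = scores.set_index("node")
    top: dict[str, list[str]] = {}
    ranks = {}
    for metric, ascending in _METRIC_ASCENDING.items():
        col = scored[metric]
        order = sorted(col.index, key=lambda nd: ((col[nd] if ascending else -col[nd]), nd))
        top[metric] = order[:k]
        ranks[metric] = col.rank(method="dense", ascending=ascending)
    rank_frame = pd.DataFrame(ranks)
    agg = rank_frame.mean(axis=1).rename("aggregate_rank")
    table = scores.merge(agg, left_on="node", right_index=True)
    table = table.sort_values(["aggregate_rank", "node"], kind="stable").reset_index(drop=True)
    return top, table
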