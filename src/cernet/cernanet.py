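"""ceRNA network assembly from correlation-gated pairs.

A candidate triplet (ceRNA, miRNA, mRNA) -- ceRNA being a lncRNA or a
circRNA -- is admitted when the ceRNA-miRNA and mRNA-miRNA pairs are
both negatively coexpressed (SCC < -0.7, p < 0.05) with the *same*
miRNA, and the ceRNA and mRNA are positively coexpressed with
PCC > 0.9 and p < 0.05.  The rendered network contains only
miRNA-incident edges (circRNA-miRNA, lncRNA-miRNA, mRNA-miRNA); the
ceRNA-mRNA correlation is stored as a triplet attribute, not an edge.
All nodes are differentially expressed RNAs and carry their regulation
direction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from cernet.targetlink import (
    EXACT_PERMUTATION_MAX_N,
    CorrelationResult,
    _permutation_p,
    _standardize,
    _t_approx_p,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CeRNATriplet",
    "CeRNANetwork",
    "pearson",
    "build_network",
    "degree_and_hubs",
    "export_network",
    "import_network",
    "triplets_to_frame",
]

PCC_THRESHOLD = 0.9
NET_ALPHA = 0.05


def pearson(x, y, id_a: str = "x", id_b: str = "y", exact: bool = False) -> CorrelationResult:
    """Pearson product-moment correlation with a two-sided p-value.

    p uses the t distribution with n - 2 degrees of freedom; with
    ``exact=True`` (n <= 8) a full permutation enumeration is used
    instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(np.clip(_standardize(x) @ _standardize(y), -1.0, 1.0))
    if exact:
        if n > EXACT_PERMUTATION_MAX_N:
            raise ValueError(f"exact permutation p limited to n <= {EXACT_PERMUTATION_MAX_N}")
        p = _permutation_p(x, y, r)
    else:
        p = _t_approx_p(r, n)
    return CorrelationResult(id_a, id_b, "pearson", r, p, n)


@dataclass
class CeRNATriplet:
    """An admitted ceRNA-miRNA-mRNA triplet with its three correlations."""

    ceRNA_id: str
    ceRNA_layer: str  # "lncRNA" | "circRNA"
    miRNA_id: str
    mRNA_id: str
    scc_ceRNA_miRNA: CorrelationResult
    scc_mRNA_miRNA: CorrelationResult
    pcc_ceRNA_mRNA: CorrelationResult


@dataclass
class CeRNANetwork:
    """Typed ceRNA network: every edge is incident to exactly one miRNA."""

    graph: nx.Graph

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    def edge_count(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    de_sets: dict[str, pd.DataFrame],
    mirna_mrna_pairs: pd.DataFrame,
    cerna_mirna_pairs: pd.DataFrame,
    expression: dict[str, np.ndarray],
    pcc_threshold: float = PCC_THRESHOLD,
    alpha: float = NET_ALPHA,
) -> tuple[list[CeRNATriplet], CeRNANetwork]:
    """Assemble the lncRNA/circRNA-miRNA-mRNA network.

    ``de_sets`` maps layer -> DE record frame (from
    :func:`cernet.diffexpr.call_de`); the pair frames are gated tables
    from :func:`cernet.targetlink.select_negative_pairs` (only rows with
    ``kept`` are used) where ``cerna_mirna_pairs`` additionally carries a
    ``target_layer`` column naming the ceRNA layer.  Features that are
    not DE in their layer are excluded with a log entry.
    """
    de_by_layer = {
        layer: set(df.index[df["is_de"]]) for layer, df in de_sets.items()
    }
    regulation: dict[str, str] = {}
    node_layer: dict[str, str] = {}
    for layer, df in de_sets.items():
        for fid in df.index[df["is_de"]]:
            regulation[fid] = df.loc[fid, "direction"]
            node_layer[fid] = layer

    def _de_ok(fid: str, layer: str) -> bool:
        if fid not in de_by_layer.get(layer, set()):
            logger.warning("%s excluded from network: not DE in layer %s", fid, layer)
            return False
        return True

    mrna_kept = mirna_mrna_pairs[mirna_mrna_pairs["kept"]]
    cerna_kept = cerna_mirna_pairs[cerna_mirna_pairs["kept"]]

    by_mirna_mrna: dict[str, list[pd.Series]] = {}
    for _, row in mrna_kept.iterrows():
        if _de_ok(row["miRNA_id"], "miRNA") and _de_ok(row["target_id"], "mRNA"):
            by_mirna_mrna.setdefault(row["miRNA_id"], []).append(row)

    triplets: list[CeRNATriplet] = []
    for _, crow in cerna_kept.sort_values(["miRNA_id", "target_id"]).iterrows():
        mirna, cerna = crow["miRNA_id"], crow["target_id"]
        clayer = crow["target_layer"]
        if not (_de_ok(mirna, "miRNA") and _de_ok(cerna, clayer)):
            continue
        for mrow in by_mirna_mrna.get(mirna, []):
            mrna = mrow["target_id"]
            if cerna not in expression or mrna not in expression:
                logger.warning("triplet (%s, %s, %s) skipped: expression missing", cerna, mirna, mrna)
                continue
            try:
                x, y = expression[cerna], expression[mrna]
                pcc = pearson(x, y, cerna, mrna, exact=len(x) <= EXACT_PERMUTATION_MAX_N)
            except ValueError:
                continue
            if pcc.coefficient > pcc_threshold and pcc.p_value < alpha:
                triplets.append(
                    CeRNATriplet(
                        ceRNA_id=cerna,
                        ceRNA_layer=clayer,
                        miRNA_id=mirna,
                        mRNA_id=mrna,
                        scc_ceRNA_miRNA=CorrelationResult(
                            mirna, cerna, "spearman", crow["scc"], crow["p_value"], int(crow["n"])
                        ),
                        scc_mRNA_miRNA=CorrelationResult(
                            mirna, mrna, "spearman", mrow["scc"], mrow["p_value"], int(mrow["n"])
                        ),
                        pcc_ceRNA_mRNA=pcc,
                    )
                )

    graph = nx.Graph()
    for t in triplets:
        for fid, layer in (
            (t.ceRNA_id, t.ceRNA_layer),
            (t.miRNA_id, "miRNA"),
            (t.mRNA_id, "mRNA"),
        ):
            graph.add_node(fid, type=layer, regulation=regulation.get(fid, "unknown"))
        graph.add_edge(t.ceRNA_id, t.miRNA_id, edge_type=f"{t.ceRNA_layer}-miRNA")
        graph.add_edge(t.mRNA_id, t.miRNA_id, edge_type="mRNA-miRNA")
    for node, deg in graph.degree():
        graph.nodes[node]["degree"] = deg
    return triplets, CeRNANetwork(graph)


def degree_and_hubs(network: CeRNANetwork, k: int) -> list[tuple[str, int]]:
    """Top-k nodes by degree; ties broken by lexicographic node id."""
    if k < 0:
        raise ValueError("k must be nonnegative")
    if k == 0:
        return []
    ranked = sorted(network.degree.items(), key=lambda item: (-item[1], item[0]))
    return ranked[:k]


# -- export --------------------------------------------------------------------


def export_network(network: CeRNANetwork, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network as GraphML (node attributes kept) or SIF."""
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network.graph, path)
    elif fmt == "sif":
        lines = [
            f"{a}\t{d.get('edge_type', 'interacts')}\t{b}"
            for a, b, d in sorted(network.graph.edges(data=True))
        ]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    else:
        raise ValueError(f"unknown export format {fmt!r} (use 'graphml' or 'sif')")


def import_network(path: str | Path, fmt: str = "graphml") -> CeRNANetwork:
    path = Path(path)
    if fmt == "graphml":
        return CeRNANetwork(nx.read_graphml(path))
    if fmt == "sif":
        graph = nx.Graph()
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            a, edge_type, b = line.split("\t")
            graph.add_edge(a, b, edge_type=edge_type)
        return CeRNANetwork(graph)
    raise ValueError(f"unknown import format {fmt!r}")


def triplets_to_frame(triplets: list[CeRNATriplet]) -> pd.DataFrame:
    rows = [
        {
            "ceRNA_id": t.ceRNA_id,
            "ceRNA_layer": t.ceRNA_layer,
            "miRNA_id": t.miRNA_id,
            "mRNA_id": t.mRNA_id,
            "scc_ceRNA_miRNA": t.scc_ceRNA_miRNA.coefficient,
            "p_ceRNA_miRNA": t.scc_ceRNA_miRNA.p_value,
            "scc_mRNA_miRNA": t.scc_mRNA_miRNA.coefficient,
            "p_mRNA_miRNA": t.scc_mRNA_miRNA.p_value,
            "pcc_ceRNA_mRNA": t.pcc_ceRNA_mRNA.coefficient,
            "p_ceRNA_mRNA": t.pcc_ceRNA_mRNA.p_value,
        }
        for t in triplets
    ]
    cols = [
        "ceRNA_id", "ceRNA_layer", "miRNA_id", "mRNA_id",
        "scc_ceRNA_miRNA", "p_ceRNA_miRNA", "scc_mRNA_miRNA", "p_mRNA_miRNA",
        "pcc_ceRNA_mRNA", "p_ceRNA_mRNA",
    ]
    return pd.DataFrame(rows, columns=cols)
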