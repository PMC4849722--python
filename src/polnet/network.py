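"""Cross-tissue relevance-network inference.

Edges of the normal-tumour (NT) network connect a gene's profile in one
compartment to other genes' profiles in the opposite compartment.  Edge
strength is the Spearman rank correlation across sample pairs; significance
comes from a pairing-destroyed bootstrap null with Benjamini-Hochberg FDR
control, and edges must clear both an absolute-correlation and an FDR cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .data import PairedExpressionDataset

logger = logging.getLogger(__name__)

NORMAL = "normal"
TUMOUR = "tumour"


def _row_ranks(values: np.ndarray) -> np.ndarray:
    """Average ranks per row (ties get the mean of the tied ranks)."""
    return rankdata(values, axis=1, method="average")


def _standardize_rows(ranks: np.ndarray) -> np.ndarray:
    centred = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = centred / norms
    out[~np.isfinite(out)] = np.nan
    return out


def spearman_cross_correlation(ds: PairedExpressionDataset) -> np.ndarray:
    """Spearman correlation of every normal profile with every tumour profile.

    Returns a (genes x genes) matrix whose ``[i, j]`` entry is the rank
    correlation between gene *i* in normal tissue and gene *j* in tumour
    tissue.  Zero-variance profiles yield NaN rows/columns (excluded from
    the network downstream).
    """
    if ds.n_pairs < 3:
        raise ValueError("need >= 3 sample pairs")
    rn = _standardize_rows(_row_ranks(ds.normal.values))
    rt = _standardize_rows(_row_ranks(ds.tumour.values))
    corr = rn @ rt.T
    return np.clip(corr, -1.0, 1.0, out=corr)


@dataclass
class EdgeNullDistribution:
    """Pooled null sample of cross-tissue correlations under broken pairing."""

    null_correlations: np.ndarray
    n_bootstrap: int
    seed: int
    mode: str = "permute"

    @property
    def size(self) -> int:
        return self.null_correlations.size


def bootstrap_null_correlations(
    ds: PairedExpressionDataset,
    n_bootstrap: int = 100,
    seed: int = 0,
    mode: str = "permute",
) -> EdgeNullDistribution:
    """Draw the null distribution of cross-tissue correlations.

    Each iteration destroys the normal-tumour pairing by permuting the
    tumour sample order (``mode="permute"``, the default) and recomputes
    every cross-tissue correlation.  ``mode="resample"`` instead resamples
    patients with replacement; this preserves cross-tissue correlation and
    is provided for diagnostic comparison only.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if mode not in ("permute", "resample"):
        raise ValueError("mode must be 'permute' or 'resample'")
    rng = np.random.default_rng(seed)
    n = ds.n_pairs
    if mode == "permute":
        # ranks are invariant to column permutation, so rank once and
        # permute the rank columns per iteration
        rn = _standardize_rows(_row_ranks(ds.normal.values))
        rt = _standardize_rows(_row_ranks(ds.tumour.values))
        pools = []
        for _ in range(n_bootstrap):
            perm = rng.permutation(n)
            corr = rn @ rt[:, perm].T
            pools.append(corr[np.isfinite(corr)].ravel().astype(np.float32))
    else:
        pools = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            rn = _standardize_rows(_row_ranks(ds.normal.values[:, idx]))
            rt = _standardize_rows(_row_ranks(ds.tumour.values[:, idx]))
            corr = rn @ rt.T
            pools.append(corr[np.isfinite(corr)].ravel().astype(np.float32))
    null = np.concatenate(pools)
    return EdgeNullDistribution(null, n_bootstrap=n_bootstrap, seed=seed, mode=mode)


def edge_significance(
    corr_matrix: np.ndarray, null: EdgeNullDistribution
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical two-sided p and BH q for every cross-tissue pair.

    ``p = (1 + #{|null| >= |r|}) / (1 + N)`` — the pseudocount keeps p > 0.
    BH runs over all finite evaluated pairs.
    """
    if null.size == 0:
        raise ValueError("null distribution is empty")
    abs_null = np.sort(np.abs(null.null_correlations))
    n = abs_null.size
    finite = np.isfinite(corr_matrix)
    p = np.full(corr_matrix.shape, np.nan)
    # number of null values >= |r|  ==  n - searchsorted(left)
    exceed = n - np.searchsorted(abs_null, np.abs(corr_matrix[finite]), side="left")
    p[finite] = (1.0 + exceed) / (1.0 + n)
    q = np.full(corr_matrix.shape, np.nan)
    q[finite] = multipletests(p[finite], method="fdr_bh")[1]
    return p, q


class CrossTissueNetwork:
    """Strictly bipartite network between normal-side and tumour-side nodes.

    Nodes are ``(gene_id, tissue)`` tuples; edges carry the Spearman
    correlation ``r_s`` and the FDR-adjusted ``q``.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self.graph = graph if graph is not None else nx.Graph()
        self._assert_bipartite()

    def _assert_bipartite(self) -> None:
        for u, v in self.graph.edges:
            if u[1] == v[1]:
                raise ValueError(f"within-tissue edge {u} -- {v}")

    # -- accessors ---------------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes_of(self, tissue: str) -> list[tuple[str, str]]:
        return [n for n in self.graph.nodes if n[1] == tissue]

    def degree(self, gene_id: str, tissue: str) -> int:
        node = (gene_id, tissue)
        return self.graph.degree(node) if node in self.graph else 0

    def neighbours(self, gene_id: str, tissue: str) -> set[tuple[str, str]]:
        node = (gene_id, tissue)
        if node not in self.graph:
            return set()
        return set(self.graph.neighbors(node))

    # -- output ------------------------------------------------------------
    def to_edgelist_frame(self):
        import pandas as pd

        rows = []
        for u, v, data in self.graph.edges(data=True):
            normal_node, tumour_node = (u, v) if u[1] == NORMAL else (v, u)
            rows.append(
                {
                    "normal_gene": normal_node[0],
                    "tumour_gene": tumour_node[0],
                    "r_s": data.get("r_s", np.nan),
                    "q": data.get("q", np.nan),
                }
            )
        frame = pd.DataFrame(rows, columns=["normal_gene", "tumour_gene", "r_s", "q"])
        return frame.sort_values(["normal_gene", "tumour_gene"], ignore_index=True)

    def write_edgelist(self, path: str | Path) -> None:
        self.to_edgelist_frame().to_csv(path, sep="\t", index=False)

    def write_graphml(self, path: str | Path) -> None:
        relabelled = nx.relabel_nodes(
            self.graph, {n: f"{n[0]}::{n[1]}" for n in self.graph.nodes}, copy=True
        )
        for node, data in relabelled.nodes(data=True):
            gene, _, tissue = node.rpartition("::")
            data["gene"] = gene
            data["tissue"] = tissue
        nx.write_graphml(relabelled, path)


def build_nt_network(
    corr_matrix: np.ndarray,
    q_matrix: np.ndarray,
    cfg: AnalysisConfig,
    gene_ids: Iterable[str],
    include_self_pairs: bool = False,
) -> CrossTissueNetwork:
    """Keep edges with ``|r_s| > corr_threshold`` and ``q < fdr_max``.

    Rows of ``corr_matrix`` index normal-side genes, columns tumour-side
    genes.  The gene_i-normal <-> gene_i-tumour autocorrelation edge is
    excluded unless ``include_self_pairs`` is set.  Isolated nodes are not
    materialised.
    """
    genes = list(gene_ids)
    if corr_matrix.shape != (len(genes), len(genes)) or q_matrix.shape != corr_matrix.shape:
        raise ValueError("matrices must be (n_genes x n_genes) and conformable")
    with np.errstate(invalid="ignore"):
        keep = (np.abs(corr_matrix) > cfg.corr_threshold) & (q_matrix < cfg.fdr_max)
    keep &= np.isfinite(corr_matrix)
    if not include_self_pairs:
        np.fill_diagonal(keep, False)
    graph = nx.Graph()
    rows, cols = np.nonzero(keep)
    for i, j in zip(rows, cols):
        u = (genes[i], NORMAL)
        v = (genes[j], TUMOUR)
        graph.add_node(u, tissue=NORMAL)
        graph.add_node(v, tissue=TUMOUR)
        graph.add_edge(u, v, r_s=float(corr_matrix[i, j]), q=float(q_matrix[i, j]))
    if graph.number_of_edges() == 0:
        logger.warning("NT network is empty at the configured thresholds")
    return CrossTissueNetwork(graph)


def infer_network(
    ds: PairedExpressionDataset, cfg: AnalysisConfig, seed: int | None = None
) -> tuple[CrossTissueNetwork, np.ndarray, EdgeNullDistribution]:
    """Convenience wrapper: correlations -> bootstrap null -> NT network."""
    seed = cfg.seed if seed is None else seed
    corr = spearman_cross_correlation(ds)
    null = bootstrap_null_correlations(ds, n_bootstrap=cfg.n_bootstrap, seed=seed)
    _, q = edge_significance(corr, null)
    net = build_nt_network(corr, q, cfg, ds.gene_ids)
    return net, corr, null
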