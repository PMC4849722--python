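"""Topology statistics on the NT network.

Community detection (greedy modularity agglomeration), a log-log power-law
fit of the degree distribution, composition tests asking whether a module
or its hubs are skewed toward one tissue, first-neighbour target sets of
polarized genes, and generic overlap / gene-set enrichment tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import NORMAL, TUMOUR, CrossTissueNetwork

logger = logging.getLogger(__name__)

Node = tuple[str, str]


@dataclass
class ModulePartition:
    """Node -> module assignment from greedy modularity maximisation."""

    assignment: dict[Node, int]
    modularity: float
    module_sizes: list[int]
    min_module_size: int

    def members(self, module_id: int) -> list[Node]:
        return sorted(n for n, m in self.assignment.items() if m == module_id)

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def large_modules(self) -> list[int]:
        return [i for i, s in enumerate(self.module_sizes) if s >= self.min_module_size]


def detect_modules(
    net: CrossTissueNetwork, min_module_size: int = 20, seed: int = 0
) -> ModulePartition:
    """Greedy (CNM-style) modularity maximisation over the bipartite graph.

    Starts from singleton communities and merges the pair giving the
    largest modularity increase; the merge tree is cut at its modularity
    maximum.  Tie-breaking and iteration order are deterministic, so the
    partition is reproducible (``seed`` is accepted for interface symmetry
    but the algorithm itself is deterministic).
    """
    graph = net.graph
    if graph.number_of_nodes() < 2:
        raise ValueError("need >= 2 nodes")
    communities = nx.community.greedy_modularity_communities(graph)
    # deterministic module ids: by size descending, then smallest member
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {node: i for i, comm in enumerate(ordered) for node in comm}
    modularity = nx.community.modularity(graph, ordered)
    return ModulePartition(
        assignment=assignment,
        modularity=float(modularity),
        module_sizes=[len(c) for c in ordered],
        min_module_size=min_module_size,
    )


@dataclass
class PowerLawFit:
    slope: float
    r_squared: float
    p: float
    n_bins: int
    evaluable: bool = True


def powerlaw_degree_fit(net: CrossTissueNetwork) -> PowerLawFit:
    """Least-squares line on log10(degree) vs log10(frequency).

    This is the NetworkAnalyzer-style diagnostic fit over non-zero degree
    bins; p is the two-sided t-test of the slope.  It is a descriptive
    check, not rigorous power-law inference.  Graphs with < 5 distinct
    degrees are flagged not evaluable.
    """
    degrees = np.array([d for _, d in net.graph.degree()])
    values, counts = np.unique(degrees[degrees > 0], return_counts=True)
    if values.size < 5:
        return PowerLawFit(np.nan, np.nan, np.nan, int(values.size), evaluable=False)
    fit = stats.linregress(np.log10(values), np.log10(counts))
    return PowerLawFit(
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
        p=float(fit.pvalue),
        n_bins=int(values.size),
    )


@dataclass
class CompositionTest:
    """Tissue composition of a node group against a reference composition."""

    observed_normal: int
    observed_tumour: int
    expected_normal: float
    p: float

    @property
    def group_size(self) -> int:
        return self.observed_normal + self.observed_tumour


def _composition(nodes: Iterable[Node]) -> tuple[int, int]:
    nodes = list(nodes)
    n_normal = sum(1 for _, t in nodes if t == NORMAL)
    return n_normal, len(nodes) - n_normal


def composition_test(group_nodes: Sequence[Node], net: CrossTissueNetwork) -> CompositionTest:
    """Two-sided hypergeometric test of a group's normal/tumour balance
    against the whole network's composition (Fisher exact on the 2x2)."""
    group = list(group_nodes)
    if not group:
        raise ValueError("group must be non-empty")
    all_nodes = set(net.nodes)
    if not set(group) <= all_nodes:
        raise ValueError("group must be a subset of network nodes")
    return _composition_against(group, all_nodes)


def _composition_against(group: Sequence[Node], reference: Iterable[Node]) -> CompositionTest:
    g_normal, g_tumour = _composition(group)
    r_normal, r_tumour = _composition(reference)
    rest_normal = r_normal - g_normal
    rest_tumour = r_tumour - g_tumour
    table = [[g_normal, g_tumour], [rest_normal, rest_tumour]]
    _, p = stats.fisher_exact(table, alternative="two-sided")
    expected = len(group) * r_normal / (r_normal + r_tumour)
    return CompositionTest(
        observed_normal=g_normal,
        observed_tumour=g_tumour,
        expected_normal=float(expected),
        p=float(p),
    )


def hub_composition_test(
    module_nodes: Sequence[Node], net: CrossTissueNetwork, top_hub_k: int = 20
) -> CompositionTest:
    """Composition of the module's top-k hubs against the module itself.

    Hubs are selected by degree; ties break by gene id then tissue so the
    selection is deterministic.
    """
    module = list(module_nodes)
    if len(module) < top_hub_k:
        raise ValueError(f"module size {len(module)} < top_hub_k {top_hub_k}")
    ranked = sorted(module, key=lambda n: (-net.graph.degree(n), n[0], n[1]))
    hubs = ranked[:top_hub_k]
    return _composition_against(hubs, module)


def polarized_targets(
    net: CrossTissueNetwork,
    positive_genes: Iterable[str],
    negative_genes: Iterable[str],
) -> tuple[set[str], set[str]]:
    """First neighbours of polarized genes in the opposite tissue.

    Positively polarized genes drive from their *normal* node, so their
    targets are tumour-side genes; negatively polarized genes drive from
    their *tumour* node onto normal-side genes.
    """
    targets_of_positive: set[str] = set()
    for g in positive_genes:
        targets_of_positive |= {gene for gene, _ in net.neighbours(g, NORMAL)}
    targets_of_negative: set[str] = set()
    for g in negative_genes:
        targets_of_negative |= {gene for gene, _ in net.neighbours(g, TUMOUR)}
    return targets_of_positive, targets_of_negative


@dataclass
class OverlapTest:
    overlap: int
    odds_ratio: float
    p: float


def overlap_test(setA: set, setB: set, universe_size: int) -> OverlapTest:
    """Two-sided Fisher exact test of membership overlap between two sets."""
    union = setA | setB
    if universe_size < len(union):
        raise ValueError("universe smaller than the union of the sets")
    both = len(setA & setB)
    only_a = len(setA) - both
    only_b = len(setB) - both
    neither = universe_size - both - only_a - only_b
    odds, p = stats.fisher_exact([[both, only_a], [only_b, neither]], alternative="two-sided")
    return OverlapTest(overlap=both, odds_ratio=float(odds), p=float(p))


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file (name, description, genes...)."""
    collections: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {raw[:80]!r}")
        collections[fields[0]] = set(fields[2:])
    return collections


def enrichment_test(
    query: set[str],
    collections: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of a query set per term, BH across terms.

    Returns a table (term, term_size, overlap, p, q) sorted by p.
    """
    if not query:
        raise ValueError("query set is empty")
    query = query & universe
    n_universe = len(universe)
    rows = []
    for term, genes in collections.items():
        term_genes = genes & universe
        k = len(query & term_genes)
        # P(X >= k) under hypergeometric
        p = float(stats.hypergeom.sf(k - 1, n_universe, len(term_genes), len(query)))
        rows.append({"term": term, "term_size": len(term_genes), "overlap": k, "p": p})
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
        frame = frame.sort_values(["p", "term"], ignore_index=True)
    return frame


def write_module_assignment(partition: ModulePartition, path: str | Path) -> None:
    rows = [
        {"gene": g, "tissue": t, "module": m}
        for (g, t), m in sorted(partition.assignment.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
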