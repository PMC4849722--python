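"""The polarization index: directional cross-tissue connectivity per gene.

For gene *g*, ``f`` counts the tumour-side genes whose profiles correlate
with *g*'s normal-tissue profile (degree of the normal node) and ``b``
counts the normal-side genes correlating with *g*'s tumour-tissue profile
(degree of the tumour node).  The index

    pol = (f - b) / (f + b + epsilon)

approaches +1 when a gene's normal profile drives a large block of
tumour-side genes with no reverse connectivity (a candidate normal->tumour
signal), and -1 in the symmetric case.  To keep a handful of connections
from producing extreme values, pol is forced to 0 when |f - b| < min_diff.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .network import NORMAL, TUMOUR, CrossTissueNetwork

POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"


def compute_connectivity_counts(
    net: CrossTissueNetwork, genes: Iterable[str] | None = None
) -> dict[str, tuple[int, int]]:
    """Per gene: (f, b) = degrees of its normal and tumour nodes.

    Genes absent from the network get (0, 0).  When ``genes`` is omitted the
    universe is every gene appearing in the network on either side.
    """
    if genes is None:
        genes = sorted({g for g, _ in net.nodes})
    return {g: (net.degree(g, NORMAL), net.degree(g, TUMOUR)) for g in genes}


def polarization_index(
    f: int | np.ndarray,
    b: int | np.ndarray,
    epsilon: float = 1.0,
    min_diff: int = 20,
) -> float | np.ndarray:
    """``(f - b) / (f + b + epsilon)``, zeroed when ``|f - b| < min_diff``."""
    f = np.asarray(f)
    b = np.asarray(b)
    if (f < 0).any() or (b < 0).any():
        raise ValueError("connection counts must be non-negative")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pol = np.where(np.abs(f - b) < min_diff, 0.0, (f - b) / (f + b + epsilon))
    return float(pol) if pol.ndim == 0 else pol


def polarization_table(
    counts: Mapping[str, tuple[int, int]],
    epsilon: float = 1.0,
    min_diff: int = 20,
    pol_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-gene table (gene, f, b, pol, polarized_class).

    Sorted by |pol| descending, then gene id, for a stable deterministic
    ordering.
    """
    genes = list(counts)
    f = np.array([counts[g][0] for g in genes], dtype=int)
    b = np.array([counts[g][1] for g in genes], dtype=int)
    pol = polarization_index(f, b, epsilon=epsilon, min_diff=min_diff)
    pol = np.atleast_1d(pol)
    cls = np.where(pol > pol_threshold, POSITIVE, np.where(pol < -pol_threshold, NEGATIVE, NONE))
    frame = pd.DataFrame(
        {"gene": genes, "f": f, "b": b, "pol": pol, "polarized_class": cls}
    )
    frame = frame.sort_values(
        ["pol", "gene"], key=lambda s: -s.abs() if s.name == "pol" else s, ignore_index=True
    )
    return frame


def classify_polarized(
    table: pd.DataFrame, pol_threshold: float = 0.75
) -> tuple[list[str], list[str]]:
    """Genes with pol strictly above / below the +-threshold.

    Each returned list is ordered by |pol| descending, ties by gene id.
    """
    if not 0.0 < pol_threshold < 1.0:
        raise ValueError("pol_threshold must be in (0, 1)")
    ordered = table.sort_values(
        ["pol", "gene"], key=lambda s: -s.abs() if s.name == "pol" else s
    )
    positive = ordered.loc[ordered["pol"] > pol_threshold, "gene"].tolist()
    negative = ordered.loc[ordered["pol"] < -pol_threshold, "gene"].tolist()
    return positive, negative


def export_polarization_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_polarization_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
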