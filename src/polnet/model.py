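"""Top-level modelling interface.

``CrossTalkModel`` bundles a paired dataset with an analysis configuration;
``fit()`` runs correlation -> bootstrap null -> FDR edge selection ->
polarization and returns a ``CrossTalkResults`` object carrying the NT
network, the per-gene polarization table and the settings that produced
them, with summary, export, simulation and plotting hanging off it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .data import PairedExpressionDataset, filter_genes
from .network import (
    CrossTissueNetwork,
    EdgeNullDistribution,
    bootstrap_null_correlations,
    build_nt_network,
    edge_significance,
    spearman_cross_correlation,
)
from .nullmodels import (
    NullSimulationResult,
    fit_tissue_gaussian,
    null_polarization_fpr,
)
from .polarization import (
    classify_polarized,
    compute_connectivity_counts,
    export_polarization_table,
    polarization_table,
)


class CrossTalkModel:
    """Directional cross-tissue co-expression model for a paired dataset."""

    def __init__(self, dataset: PairedExpressionDataset, config: AnalysisConfig | None = None):
        self.dataset = dataset
        self.config = config if config is not None else AnalysisConfig()

    @classmethod
    def from_files(
        cls,
        normal_path,
        tumour_path,
        pairing_path,
        config: AnalysisConfig | None = None,
        min_expr_quantile: float = 0.0,
        min_var_quantile: float = 0.0,
    ) -> "CrossTalkModel":
        from .data import align_paired_samples, read_expression_matrix, read_pairing_map

        normal = read_expression_matrix(normal_path)
        tumour = read_expression_matrix(tumour_path)
        pairing = read_pairing_map(pairing_path)
        ds = align_paired_samples(normal, tumour, pairing)
        if min_expr_quantile > 0 or min_var_quantile > 0:
            ds, _ = filter_genes(ds, min_expr_quantile, min_var_quantile)
        return cls(ds, config)

    def fit(self, seed: int | None = None) -> "CrossTalkResults":
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        corr = spearman_cross_correlation(self.dataset)
        null = bootstrap_null_correlations(self.dataset, n_bootstrap=cfg.n_bootstrap, seed=seed)
        _, q = edge_significance(corr, null)
        net = build_nt_network(corr, q, cfg, self.dataset.gene_ids)
        counts = compute_connectivity_counts(net, genes=self.dataset.gene_ids)
        table = polarization_table(
            counts, epsilon=cfg.epsilon, min_diff=cfg.min_diff, pol_threshold=cfg.pol_threshold
        )
        return CrossTalkResults(model=self, network=net, polarization=table, null=null, seed=seed)

    def simulate_null(
        self, n_sim: int, seed: int | None = None, ridge: float | None = None
    ) -> NullSimulationResult:
        """Tissue-independent Gaussian null fitted to this dataset."""
        seed = self.config.seed if seed is None else seed
        nm = fit_tissue_gaussian(self.dataset.normal, ridge=ridge)
        tm = fit_tissue_gaussian(self.dataset.tumour, ridge=ridge)
        return null_polarization_fpr(
            nm, tm, self.config, n_sim=n_sim, n_pairs=self.dataset.n_pairs, seed=seed
        )


@dataclasses.dataclass
class CrossTalkResults:
    """Fitted NT network and polarization table with provenance."""

    model: CrossTalkModel
    network: CrossTissueNetwork
    polarization: pd.DataFrame
    null: EdgeNullDistribution
    seed: int

    @property
    def config(self) -> AnalysisConfig:
        return self.model.config

    @property
    def positive_genes(self) -> list[str]:
        return classify_polarized(self.polarization, self.config.pol_threshold)[0]

    @property
    def negative_genes(self) -> list[str]:
        return classify_polarized(self.polarization, self.config.pol_threshold)[1]

    def summary(self) -> str:
        cfg = self.config
        n_normal = len(self.network.nodes_of("normal"))
        n_tumour = len(self.network.nodes_of("tumour"))
        pos, neg = self.positive_genes, self.negative_genes
        lines = [
            "Cross-tissue co-expression model",
            "================================",
            f"sample pairs:          {self.model.dataset.n_pairs}",
            f"genes analysed:        {self.model.dataset.n_genes}",
            f"edge rule:             |r_s| > {cfg.corr_threshold}, FDR < {cfg.fdr_max}"
            f" ({cfg.n_bootstrap} bootstrap permutations)",
            f"NT network:            {self.network.n_edges} edges, "
            f"{n_normal} normal-side / {n_tumour} tumour-side nodes",
            f"polarization:          pol = (f-b)/(f+b+{cfg.epsilon:g}), "
            f"zeroed when |f-b| < {cfg.min_diff}",
            f"polarized (|pol|>{cfg.pol_threshold:g}): "
            f"{len(pos)} positive, {len(neg)} negative",
            f"seed:                  {self.seed}",
        ]
        return "\n".join(lines)

    def plot_polarization(self, ax=None, bins: int = 60):
        """Histogram of the polarization index (trimodal when signal exists)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        ax.hist(self.polarization["pol"], bins=bins, range=(-1, 1), color="steelblue")
        thr = self.config.pol_threshold
        for x in (-thr, thr):
            ax.axvline(x, color="firebrick", linestyle="--", linewidth=1)
        ax.set_xlabel("polarization index")
        ax.set_ylabel("genes")
        return ax

    def detect_modules(self):
        from .topology import detect_modules

        return detect_modules(
            self.network, min_module_size=self.config.min_module_size, seed=self.seed
        )

    def targets(self) -> tuple[set[str], set[str]]:
        from .topology import polarized_targets

        return polarized_targets(self.network, self.positive_genes, self.negative_genes)

    # -- provenance-carrying export ---------------------------------------
    def to_dir(self, outdir, command: str = "fit") -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.network.write_edgelist(outdir / "nt_network.tsv")
        self.network.write_graphml(outdir / "nt_network.graphml")
        export_polarization_table(self.polarization, outdir / "polarization.tsv")
        self.config.to_file(outdir / "config.txt")
        write_manifest(
            outdir,
            command=command,
            config=self.config,
            seed=self.seed,
            inputs={},
        )


def write_manifest(
    outdir, command: str, config: AnalysisConfig, seed: int, inputs: dict[str, str]
) -> None:
    """Run manifest: command, resolved config, input checksums, version, seed."""
    manifest = {
        "command": command,
        "config": config.to_dict(),
        "input_sha256": inputs,
        "version": __version__,
        "seed": int(seed),
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    Path(outdir, "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
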