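"""Synthetic paired-expression, CNV and clinical data with known ground truth.

The paired generator plants directional cross-tissue signals by a latent
factor mechanism: a positively planted gene's *normal* profile shares a
latent driver with a block of tumour-side genes (so its forward count f is
about the block size while its backward count b stays near 0), mimicking a
paracrine driver rather than being painted into a covariance matrix.
Background genes live in within-tissue correlation blocks and are sampled
independently across tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import ExpressionMatrix, PairedExpressionDataset
from .integration import ClinicalTable, CnvDataset


@dataclass
class GroundTruth:
    """Planted structure of a synthetic dataset."""

    planted_positive: list[str] = field(default_factory=list)
    planted_negative: list[str] = field(default_factory=list)
    block_map: dict[str, list[str]] = field(default_factory=dict)
    active_probes: dict[str, dict[str, float]] = field(default_factory=dict)
    survival_effect: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.planted_positive) & set(self.planted_negative):
            raise ValueError("planted positive/negative sets must be disjoint")
        for driver, block in self.block_map.items():
            if not block:
                raise ValueError(f"empty driven block for {driver}")


def generate_paired_dataset(
    n_genes: int = 500,
    n_pairs: int = 50,
    n_pos: int = 10,
    n_neg: int = 10,
    block_size: int = 30,
    driver_strength: float = 0.9,
    within_tissue_blocks: int = 10,
    within_tissue_corr: float = 0.4,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[PairedExpressionDataset, GroundTruth]:
    """Paired matrices with planted directional cross-tissue drivers.

    Layout of the ``n_genes`` genes: the first ``n_pos`` are positively
    planted drivers, the next ``n_neg`` negatively planted, the next
    ``(n_pos + n_neg) * block_size`` are their driven blocks, and the rest
    are background.  Each planted driver and every gene of its driven
    block load a shared latent factor with weight sqrt(driver_strength),
    so their expected cross-tissue correlation is ``driver_strength``.
    Background genes fall into ``within_tissue_blocks`` blocks sharing a
    within-tissue factor with pairwise correlation ``within_tissue_corr``
    (independently per tissue, so they add no cross-tissue signal).
    """
    if not 0.0 < driver_strength < 1.0:
        raise ValueError("driver_strength must be in (0, 1)")
    # A gene contributes two profiles, so a positive driver's tumour-side
    # block and a negative driver's normal-side block can overlay the same
    # genes without interacting (such a gene then has f = b = 1, which the
    # min_diff gate zeroes out).
    n_drivers = n_pos + n_neg
    needed = n_drivers + max(n_pos, n_neg) * block_size
    if needed > n_genes:
        raise ValueError(
            f"infeasible allocation: {n_pos}+{n_neg} drivers with blocks of "
            f"{block_size} need {needed} genes, have {n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    # every profile starts as i.i.d. noise; planted structure overwrites
    normal = rng.standard_normal((n_genes, n_pairs))
    tumour = rng.standard_normal((n_genes, n_pairs))

    load = np.sqrt(driver_strength)
    resid = np.sqrt(1.0 - driver_strength)

    def noisy(shape):
        return rng.standard_normal(shape)

    truth = GroundTruth()
    # planted positive drivers: normal profile shares a latent factor with
    # a tumour-side block; the driver's own tumour profile stays noise
    for d in range(n_pos):
        z = noisy(n_pairs)
        gi = d
        normal[gi] = load * z + resid * noisy(n_pairs)
        start = n_drivers + d * block_size
        block = genes[start : start + block_size]
        for bi in range(start, start + block_size):
            tumour[bi] = load * z + resid * noisy(n_pairs)
        truth.planted_positive.append(genes[gi])
        truth.block_map[genes[gi]] = list(block)
    # planted negative drivers: symmetric (tumour profile drives a
    # normal-side block, overlaying the same gene slots)
    for d in range(n_neg):
        z = noisy(n_pairs)
        gi = n_pos + d
        tumour[gi] = load * z + resid * noisy(n_pairs)
        start = n_drivers + d * block_size
        block = genes[start : start + block_size]
        for bi in range(start, start + block_size):
            normal[bi] = load * z + resid * noisy(n_pairs)
        truth.planted_negative.append(genes[gi])
        truth.block_map[genes[gi]] = list(block)
    # background genes in within-tissue correlation blocks
    background = list(range(n_drivers + max(n_pos, n_neg) * block_size, n_genes))
    if background:
        w_load = np.sqrt(within_tissue_corr)
        w_resid = np.sqrt(1.0 - within_tissue_corr)
        n_blocks = max(within_tissue_blocks, 1)
        factors_n = noisy((n_blocks, n_pairs))
        factors_t = noisy((n_blocks, n_pairs))
        for k, gi in enumerate(background):
            blk = k % n_blocks
            normal[gi] = w_load * factors_n[blk] + w_resid * noisy(n_pairs)
            tumour[gi] = w_load * factors_t[blk] + w_resid * noisy(n_pairs)

    normal *= noise_sd
    tumour *= noise_sd
    samples = [f"p{j:03d}" for j in range(n_pairs)]
    ds = PairedExpressionDataset(
        ExpressionMatrix(genes, samples, normal),
        ExpressionMatrix(genes, samples, tumour),
        samples,
    )
    return ds, truth


def generate_cnv_clinical(
    n_samples: int = 100,
    n_probes: int = 20,
    genes: Sequence[str] = ("gA", "gB", "gC"),
    active_map: Mapping[str, Mapping[str, float]] | None = None,
    gleason_genes: Mapping[str, float] | None = None,
    survival_effect: Mapping[str, tuple[float, float]] | None = None,
    censoring_rate: float = 0.4,
    expr_noise_sd: float = 0.5,
    segment_size: int = 5,
    baseline_hazard: float = 0.1,
    seed: int = 0,
) -> tuple[CnvDataset, ExpressionMatrix, ClinicalTable, GroundTruth]:
    """CNV probes, driven expression, tumour features and survival times.

    CNV log-ratios are segment-wise Gaussian (probes in a segment share a
    sample-level value plus probe noise, giving realistic local
    correlation).  Each gene's expression is the linear combination of its
    active probes (``active_map[gene] = {probe: effect}``) plus noise;
    genes without active probes are pure noise.  The Gleason score is an
    ordinal 6-9 variable cut from a latent monotone combination of
    ``gleason_genes``.  Survival is exponential with log-hazard
    ``log(hr) * 1[expr > cutoff]`` per ``survival_effect[gene] = (hr,
    cutoff)`` and independent uniform censoring calibrated to the stated
    rate.
    """
    if not 0.0 <= censoring_rate <= 1.0:
        raise ValueError("censoring_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = list(genes)
    active_map = {g: dict(v) for g, v in (active_map or {}).items()}
    probe_ids = [f"cnv{i:03d}" for i in range(n_probes)]
    for g, probes in active_map.items():
        if not set(probes) <= set(probe_ids):
            raise ValueError(f"active probes of {g} outside the probe set")

    samples = [f"s{j:03d}" for j in range(n_samples)]
    # segment-wise CNV: consecutive probes share a segment-level value
    n_segments = int(np.ceil(n_probes / segment_size))
    seg_values = rng.normal(0.0, 0.5, size=(n_segments, n_samples))
    cnv = np.empty((n_probes, n_samples))
    chromosome = []
    position = []
    for i in range(n_probes):
        seg = i // segment_size
        cnv[i] = seg_values[seg] + rng.normal(0.0, 0.1, size=n_samples)
        chromosome.append(f"chr{seg + 1}")
        position.append((i % segment_size + 1) * 1000)
    cgh = CnvDataset(probe_ids, chromosome, np.array(position), cnv, samples)

    probe_row = {p: i for i, p in enumerate(probe_ids)}
    expr_values = rng.normal(0.0, expr_noise_sd, size=(len(genes), n_samples))
    for gi, g in enumerate(genes):
        for probe, effect in active_map.get(g, {}).items():
            expr_values[gi] += effect * cnv[probe_row[probe]]
    expr = ExpressionMatrix(genes, samples, expr_values)

    # Gleason: latent monotone combination of the chosen genes
    gleason_genes = dict(gleason_genes or {})
    latent = rng.normal(0.0, 0.5, size=n_samples)
    for g, coef in gleason_genes.items():
        latent += coef * expr_values[genes.index(g)]
    gleason = np.digitize(latent, np.quantile(latent, [0.4, 0.7, 0.9])) + 6
    psa = np.exp(rng.normal(1.5, 0.6, size=n_samples))
    t_stage = rng.integers(1, 4, size=n_samples)

    # survival: exponential with dichotomized-expression log-hazard
    survival_effect = dict(survival_effect or {})
    log_hazard = np.full(n_samples, np.log(baseline_hazard))
    for g, (hr, cutoff) in survival_effect.items():
        high = expr_values[genes.index(g)] > cutoff
        log_hazard += np.log(hr) * high
    hazard = np.exp(log_hazard)
    event_time = rng.exponential(1.0 / hazard)
    time = event_time.copy()
    event = np.ones(n_samples, dtype=int)
    if censoring_rate >= 1.0:
        event[:] = 0
        time = rng.uniform(0, event_time)
    elif censoring_rate > 0:
        cmax = _calibrate_uniform_censoring(hazard, censoring_rate)
        censor_time = rng.uniform(0, cmax, size=n_samples)
        censored = censor_time < event_time
        time = np.where(censored, censor_time, event_time)
        event = (~censored).astype(int)

    clinical = ClinicalTable(
        frame=pd.DataFrame(
            {
                "gleason": gleason,
                "psa": psa,
                "t_stage": t_stage,
                "os_time": time,
                "os_event": event,
                "rfs_time": time,
                "rfs_event": event,
            },
            index=pd.Index(samples, name="sample"),
        )
    )
    truth = GroundTruth(
        active_probes=active_map,
        survival_effect={g: (float(h), float(c)) for g, (h, c) in survival_effect.items()},
    )
    return cgh, expr, clinical, truth


def _calibrate_uniform_censoring(hazard: np.ndarray, rate: float) -> float:
    """Solve for c so that U(0,c) censoring yields the target censored fraction.

    With T ~ Exp(h) and C ~ U(0,c), P(C < T) = (1 - exp(-h c)) / (h c)
    averaged over subjects; the function is monotone in c, so bisect.
    """

    def censored_fraction(c: float) -> float:
        hc = hazard * c
        return float(np.mean((1.0 - np.exp(-hc)) / hc))

    lo, hi = 1e-9, 1.0
    while censored_fraction(hi) > rate and hi < 1e12:
        hi *= 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_fraction(mid) > rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ground_truth_report(
    truth: GroundTruth,
    called_positive: Sequence[str] = (),
    called_negative: Sequence[str] = (),
    called_cnv_edges: Sequence[tuple[str, str]] = (),
    called_survival: Sequence[str] = (),
) -> pd.DataFrame:
    """Sensitivity / FDR of calls against the planted truth, per layer."""
    rows = []

    def layer(name: str, truth_set: set, called: set) -> None:
        tp = len(truth_set & called)
        sens = tp / len(truth_set) if truth_set else np.nan
        fdr = (len(called) - tp) / len(called) if called else 0.0
        rows.append(
            {
                "layer": name,
                "n_true": len(truth_set),
                "n_called": len(called),
                "sensitivity": sens,
                "fdr": fdr,
            }
        )

    layer("polarized_positive", set(truth.planted_positive), set(called_positive))
    layer("polarized_negative", set(truth.planted_negative), set(called_negative))
    true_edges = {
        (g, p) for g, probes in truth.active_probes.items() for p in probes
    }
    layer("cnv_edges", true_edges, set(called_cnv_edges))
    layer("survival", set(truth.survival_effect), set(called_survival))
    return pd.DataFrame(rows)
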