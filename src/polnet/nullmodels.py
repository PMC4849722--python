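"""Validation simulations for the polarization index.

Two counterfactuals establish that extreme polarization values cannot arise
trivially:

1. A multivariate-Gaussian null: each tissue's matrix is fitted by a
   Gaussian preserving its within-tissue correlation structure, then the
   two tissues are sampled *independently*, so every cross-tissue
   correlation is 0 in expectation.  The rate of |pol| calls above the
   threshold under this null is the empirical false-positive rate.

2. A contamination counterfactual: the "tumour" matrix is the normal
   matrix plus signal-dependent Gaussian noise scaled by a factor gamma,
   emulating tumour samples contaminated by normal cells.  Under this model
   f and b rise and fall together, so polarization stays near 0 at every
   gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from .config import AnalysisConfig
from .data import ExpressionMatrix, PairedExpressionDataset
from .network import infer_network
from .polarization import compute_connectivity_counts, polarization_index

logger = logging.getLogger(__name__)


@dataclass
class TissueGaussianModel:
    """Per-tissue multivariate Gaussian (mean vector + regularized covariance)."""

    mean: np.ndarray
    covariance: np.ndarray
    regularization: float
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.covariance.shape != (self.mean.size, self.mean.size):
            raise ValueError("covariance must be square and match the mean")
        if not np.allclose(self.covariance, self.covariance.T):
            raise ValueError("covariance must be symmetric")

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "covariance is not factorable; refit with a larger ridge"
            ) from err

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n samples; returns a (genes x n) matrix."""
        z = rng.standard_normal((self.mean.size, n))
        return self.mean[:, None] + self.cholesky() @ z


def fit_tissue_gaussian(m: ExpressionMatrix, ridge: float | None = None) -> TissueGaussianModel:
    """Row means + sample covariance with a diagonal ridge.

    With far more genes than samples the raw covariance is singular; the
    default ridge is 1e-6 times the mean per-gene variance, just enough to
    guarantee a Cholesky factorisation without distorting the correlation
    structure.
    """
    if m.n_samples < 2:
        raise ValueError("need >= 2 samples to fit a covariance")
    cov = np.cov(m.values, ddof=1)
    cov = np.atleast_2d(cov)
    if ridge is None:
        mean_var = float(np.mean(np.diag(cov)))
        ridge = 1e-6 * mean_var if mean_var > 0 else 1e-6
    if ridge < 0:
        raise ValueError("ridge must be non-negative")
    cov = cov + ridge * np.eye(cov.shape[0])
    return TissueGaussianModel(
        mean=m.values.mean(axis=1),
        covariance=cov,
        regularization=float(ridge),
        gene_ids=list(m.gene_ids),
    )


def simulate_null_dataset(
    normal_model: TissueGaussianModel,
    tumour_model: TissueGaussianModel,
    n_pairs: int,
    seed: int = 0,
) -> PairedExpressionDataset:
    """Sample the two tissues independently (zero expected cross-correlation)."""
    if normal_model.gene_ids != tumour_model.gene_ids:
        raise ValueError("models must cover the same gene set")
    child_n, child_t = np.random.SeedSequence(seed).spawn(2)
    samples = [f"sim{i}" for i in range(n_pairs)]
    normal = ExpressionMatrix(
        list(normal_model.gene_ids),
        samples,
        normal_model.sample(n_pairs, np.random.default_rng(child_n)),
    )
    tumour = ExpressionMatrix(
        list(tumour_model.gene_ids),
        samples,
        tumour_model.sample(n_pairs, np.random.default_rng(child_t)),
    )
    return PairedExpressionDataset(normal, tumour, samples)


@dataclass
class NullSimulationResult:
    """Pooled polarization values under the tissue-independent null."""

    pol_values: np.ndarray
    pol_threshold: float
    n_sim: int
    n_gene_evaluations: int
    n_false_positive: int

    @property
    def fpr(self) -> float:
        """False positives per gene evaluation."""
        return self.n_false_positive / self.n_gene_evaluations


def null_polarization_fpr(
    normal_model: TissueGaussianModel,
    tumour_model: TissueGaussianModel,
    cfg: AnalysisConfig,
    n_sim: int,
    n_pairs: int,
    seed: int = 0,
) -> NullSimulationResult:
    """Repeat null-dataset -> NT network -> polarization; pool pol values.

    The false-positive rate is the fraction of gene evaluations (n_sim x
    n_genes) exceeding ``cfg.pol_threshold`` in absolute value.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(n_sim)
    pols = []
    net_logger = logging.getLogger("polnet.network")
    previous_level = net_logger.level
    net_logger.setLevel(logging.ERROR)  # empty null networks are expected
    try:
        for k in range(n_sim):
            ds = simulate_null_dataset(normal_model, tumour_model, n_pairs, seed=int(seeds[k]))
            net, _, _ = infer_network(ds, cfg, seed=int(seeds[k]))
            counts = compute_connectivity_counts(net, genes=ds.gene_ids)
            f = np.array([counts[g][0] for g in ds.gene_ids])
            b = np.array([counts[g][1] for g in ds.gene_ids])
            pols.append(
                np.atleast_1d(
                    polarization_index(f, b, epsilon=cfg.epsilon, min_diff=cfg.min_diff)
                )
            )
    finally:
        net_logger.setLevel(previous_level)
    pol_values = np.concatenate(pols)
    n_fp = int(np.sum(np.abs(pol_values) > cfg.pol_threshold))
    return NullSimulationResult(
        pol_values=pol_values,
        pol_threshold=cfg.pol_threshold,
        n_sim=n_sim,
        n_gene_evaluations=pol_values.size,
        n_false_positive=n_fp,
    )


@dataclass
class NoiseModel:
    """Signal-dependent measurement noise: sd(I) = sqrt(a^2 + (c*I)^2)."""

    additive_sd: float
    multiplicative_cv: float

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_cv < 0:
            raise ValueError("noise components must be non-negative")

    def sd(self, intensity: np.ndarray) -> np.ndarray:
        return np.sqrt(self.additive_sd**2 + (self.multiplicative_cv * np.abs(intensity)) ** 2)


def estimate_noise_model(
    values: np.ndarray, replicate_groups: list[list[int]]
) -> NoiseModel:
    """Fit the two-component noise model from replicated measurements.

    ``replicate_groups`` lists column indices forming replicate sets.  For
    every gene x group the replicate SD is regressed on the mean intensity
    under sd^2 = a^2 + c^2 * I^2 (ordinary least squares on the squared
    quantities).  Negative components are clipped to zero with a warning;
    if all intensities sit at a single level the two components are not
    identifiable and an additive-only fit is returned.
    """
    means, sds = [], []
    for group in replicate_groups:
        if len(group) < 2:
            raise ValueError("each replicate group needs >= 2 columns")
        block = values[:, group]
        means.append(block.mean(axis=1))
        sds.append(block.std(axis=1, ddof=1))
    intensity = np.concatenate(means)
    sd = np.concatenate(sds)
    x = intensity**2
    y = sd**2
    # the two components are only separable when intensities span a range
    if np.ptp(intensity) < 0.1 * float(np.mean(np.abs(intensity))):
        logger.warning(
            "single intensity level: additive and multiplicative components are "
            "unidentifiable; returning an additive-only fit"
        )
        return NoiseModel(additive_sd=float(np.sqrt(np.mean(y))), multiplicative_cv=0.0)
    slope, intercept = np.polyfit(x, y, 1)
    if intercept < 0 or slope < 0:
        logger.warning("degenerate noise fit (negative component clipped to 0)")
    a2 = max(float(intercept), 0.0)
    c2 = max(float(slope), 0.0)
    return NoiseModel(additive_sd=float(np.sqrt(a2)), multiplicative_cv=float(np.sqrt(c2)))


@dataclass
class ContaminationRun:
    """Synthetic normal/tumour pair built from one tissue plus scaled noise."""

    gamma: float
    synthetic_normal: ExpressionMatrix
    synthetic_tumour: ExpressionMatrix
    pol_distribution: np.ndarray | None = None


def simulate_contamination(
    normal: ExpressionMatrix,
    gamma: float,
    noise: NoiseModel,
    seed: int = 0,
) -> ContaminationRun:
    """Add gamma-scaled signal-dependent noise to one tissue.

    ``synthetic_tumour = normal + gamma * N(0, sd(normal)^2)`` and an
    independent draw gives the synthetic normal.  At gamma=0 the synthetic
    tumour *is* the normal matrix.
    """
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    rng = np.random.default_rng(seed)
    sd = noise.sd(normal.values)
    syn_tumour = normal.values + gamma * rng.standard_normal(normal.values.shape) * sd
    syn_normal = normal.values + gamma * rng.standard_normal(normal.values.shape) * sd
    return ContaminationRun(
        gamma=float(gamma),
        synthetic_normal=ExpressionMatrix(
            list(normal.gene_ids), list(normal.sample_ids), syn_normal
        ),
        synthetic_tumour=ExpressionMatrix(
            list(normal.gene_ids), list(normal.sample_ids), syn_tumour
        ),
    )


def contamination_polarization(
    normal: ExpressionMatrix,
    gamma: float,
    noise: NoiseModel,
    cfg: AnalysisConfig,
    seed: int = 0,
) -> ContaminationRun:
    """Run a contamination pair through the standard pipeline; fill pol values."""
    run = simulate_contamination(normal, gamma, noise, seed=seed)
    ds = PairedExpressionDataset(
        run.synthetic_normal, run.synthetic_tumour, list(normal.sample_ids)
    )
    net_logger = logging.getLogger("polnet.network")
    previous_level = net_logger.level
    net_logger.setLevel(logging.ERROR)  # high-gamma networks are expectedly empty
    try:
        net, _, _ = infer_network(ds, cfg, seed=seed)
    finally:
        net_logger.setLevel(previous_level)
    counts = compute_connectivity_counts(net, genes=ds.gene_ids)
    f = np.array([counts[g][0] for g in ds.gene_ids])
    b = np.array([counts[g][1] for g in ds.gene_ids])
    run.pol_distribution = np.atleast_1d(
        polarization_index(f, b, epsilon=cfg.epsilon, min_diff=cfg.min_diff)
    )
    return run


def _cross_correlations(run: ContaminationRun) -> np.ndarray:
    from .network import spearman_cross_correlation

    ds = PairedExpressionDataset(
        run.synthetic_normal, run.synthetic_tumour, list(run.synthetic_normal.sample_ids)
    )
    corr = spearman_cross_correlation(ds)
    return corr[np.isfinite(corr)].ravel()


def calibrate_gamma(
    normal: ExpressionMatrix,
    noise: NoiseModel,
    target_corr_distribution: np.ndarray,
    gamma_grid: list[float] | np.ndarray,
    seed: int = 0,
) -> float:
    """Pick the grid gamma whose simulated cross-correlation distribution is
    closest (Kolmogorov-Smirnov distance) to the target; ties -> smallest."""
    grid = sorted(float(g) for g in gamma_grid)
    if not grid:
        raise ValueError("gamma grid must be non-empty")
    best_gamma, best_ks = None, np.inf
    for k, gamma in enumerate(grid):
        run = simulate_contamination(normal, gamma, noise, seed=seed + k)
        ks = ks_2samp(_cross_correlations(run), target_corr_distribution).statistic
        if ks < best_ks - 1e-12:  # strict improvement; ties keep the smaller gamma
            best_gamma, best_ks = gamma, ks
    return float(best_gamma)
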