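"""Genetics / clinical integration layer.

Links polarized-gene expression to copy-number variation, tumour features
and outcome: ANOVA probe prioritisation, a spike-and-slab Bayesian
variable-selection regression producing posterior probabilities of
inclusion (PPI) for candidate CNV probes, cis CNV-expression correlation,
ANCOVA against tumour features, and an optimal-cutoff Cox survival screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import ExpressionMatrix
from .survival import cox_binary_fit, logrank_test

logger = logging.getLogger(__name__)


@dataclass
class CnvDataset:
    """Copy-number log-ratios per probe with chromosomal locations."""

    probe_ids: list[str]
    chromosome: list[str]
    position: np.ndarray  # 1-based
    values: np.ndarray  # probes x samples
    sample_ids: list[str]

    def __post_init__(self) -> None:
        n_probes = len(self.probe_ids)
        self.position = np.asarray(self.position, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.chromosome) == n_probes == self.position.size):
            raise ValueError("probe annotation lengths disagree")
        if self.values.shape != (n_probes, len(self.sample_ids)):
            raise ValueError("values shape must be probes x samples")
        # positions must be sorted within each chromosome
        for chrom in set(self.chromosome):
            pos = self.position[[c == chrom for c in self.chromosome]]
            if not np.all(np.diff(pos) >= 0):
                raise ValueError(f"positions not sorted within chromosome {chrom}")

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)
        frame.insert(0, "chromosome", self.chromosome)
        frame.insert(1, "position", self.position)
        return frame

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="probe")

    @classmethod
    def read(cls, path) -> "CnvDataset":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            probe_ids=[str(p) for p in frame.index],
            chromosome=[str(c) for c in frame["chromosome"]],
            position=frame["position"].to_numpy(),
            values=frame.drop(columns=["chromosome", "position"]).to_numpy(dtype=float),
            sample_ids=[str(s) for s in frame.columns[2:]],
        )


@dataclass
class ClinicalTable:
    """Tumour features and survival endpoints per sample.

    ``frame`` is indexed by sample id.  Ordinal features (Gleason score,
    T stage) are listed in ``categorical_features`` and treated as factors
    by the ANOVA ranking; everything else in ``feature_columns`` is
    continuous.  ``survival_endpoints`` maps an endpoint label to its
    (time, event) column pair.
    """

    frame: pd.DataFrame
    feature_columns: list[str] = field(
        default_factory=lambda: ["gleason", "psa", "t_stage"]
    )
    categorical_features: list[str] = field(default_factory=lambda: ["gleason", "t_stage"])
    survival_endpoints: dict[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "survival": ("os_time", "os_event"),
            "recurrence": ("rfs_time", "rfs_event"),
        }
    )

    def __post_init__(self) -> None:
        for label, (tcol, ecol) in list(self.survival_endpoints.items()):
            if tcol not in self.frame.columns or ecol not in self.frame.columns:
                logger.info("endpoint %r missing columns; dropped", label)
                del self.survival_endpoints[label]
                continue
            times = self.frame[tcol].dropna()
            if (times < 0).any():
                raise ValueError(f"negative times in endpoint {label!r}")

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.frame.index]

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample")


def rank_cgh_probes(
    cgh: CnvDataset, clinical: ClinicalTable, top_m: int
) -> list[str]:
    """Rank CNV probes by their strongest clinical association.

    For every probe, each categorical feature gets a one-way ANOVA F-test
    across its levels and each continuous feature a linear-model F-test;
    event indicators of the survival endpoints join as two-level factors.
    A probe's rank statistic is its minimum p across variables; the top
    ``top_m`` probe ids are returned (ties broken by probe id).
    """
    clin = clinical.frame.loc[[s for s in cgh.sample_ids if s in clinical.frame.index]]
    col_idx = [cgh.sample_ids.index(s) for s in clin.index]
    variables: dict[str, tuple[np.ndarray, bool]] = {}
    for feat in clinical.feature_columns:
        if feat in clin.columns:
            variables[feat] = (clin[feat].to_numpy(dtype=float), feat in clinical.categorical_features)
    for label, (_, ecol) in clinical.survival_endpoints.items():
        variables[f"{label}_event"] = (clin[ecol].to_numpy(dtype=float), True)

    min_p = np.full(len(cgh.probe_ids), np.nan)
    for i, probe in enumerate(cgh.probe_ids):
        x = cgh.values[i, col_idx]
        if np.ptp(x) == 0:
            logger.info("probe %r is constant; skipped", probe)
            continue
        best = np.inf
        for values, is_categorical in variables.values():
            ok = np.isfinite(values) & np.isfinite(x)
            if ok.sum() < 3:
                continue
            xv, fv = x[ok], values[ok]
            if is_categorical:
                groups = [xv[fv == lvl] for lvl in np.unique(fv)]
                groups = [g for g in groups if g.size >= 2]
                if len(groups) < 2:
                    continue
                p = stats.f_oneway(*groups).pvalue
            else:
                if np.ptp(fv) == 0:
                    continue
                p = stats.linregress(fv, xv).pvalue
            if np.isfinite(p):
                best = min(best, float(p))
        if np.isfinite(best):
            min_p[i] = best
    order = sorted(
        (i for i in range(len(cgh.probe_ids)) if np.isfinite(min_p[i])),
        key=lambda i: (min_p[i], cgh.probe_ids[i]),
    )
    return [cgh.probe_ids[i] for i in order[:top_m]]


def cis_cnv_correlation(
    cgh: CnvDataset,
    expr: ExpressionMatrix,
    gene_probe_map: Mapping[str, str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Correlate each gene's expression with its own probe's copy number.

    Returns (gene, probe, r, p, significant) using the Pearson correlation
    test; genes without a mapped probe are skipped with a log entry.
    """
    if not gene_probe_map:
        raise ValueError("gene_probe_map is empty")
    shared = [s for s in expr.sample_ids if s in cgh.sample_ids]
    e_idx = [expr.sample_ids.index(s) for s in shared]
    c_idx = [cgh.sample_ids.index(s) for s in shared]
    probe_row = {p: i for i, p in enumerate(cgh.probe_ids)}
    gene_row = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for gene, probe in gene_probe_map.items():
        if gene not in gene_row or probe not in probe_row:
            logger.info("gene %r / probe %r unmapped; skipped", gene, probe)
            continue
        x = cgh.values[probe_row[probe]][c_idx]
        y = expr.values[gene_row[gene]][e_idx]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.info("constant profile for gene %r; skipped", gene)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append(
            {"gene": gene, "probe": probe, "r": float(r), "p": float(p), "significant": p < alpha}
        )
    return pd.DataFrame(rows, columns=["gene", "probe", "r", "p", "significant"])


# ---------------------------------------------------------------------------
# Spike-and-slab Bayesian variable selection
# ---------------------------------------------------------------------------


@dataclass
class SpikeSlabResults:
    """Posterior summaries of the spike-and-slab regression."""

    ppi: np.ndarray  # posterior inclusion probability per covariate
    beta_mean: np.ndarray  # posterior mean coefficients (0 when excluded)
    n_iter: int
    n_burnin: int
    n_updates: int  # accepted state flips across the chain
    split_ppi_diff: float  # max |PPI_first_half - PPI_second_half|
    probe_ids: list[str] | None = None

    @property
    def converged(self) -> bool:
        return self.split_ppi_diff < 0.1

    def summary(self) -> pd.DataFrame:
        ids = self.probe_ids or [f"x{j}" for j in range(self.ppi.size)]
        return pd.DataFrame(
            {"probe": ids, "ppi": self.ppi, "beta_mean": self.beta_mean}
        ).sort_values("ppi", ascending=False, ignore_index=True)


class SpikeSlabRegression:
    """Linear regression with spike-and-slab variable-selection priors.

    Model: ``y = X beta + e``, ``e ~ N(0, sigma^2 I)``; each coefficient is
    exactly zero with prior probability ``1 - pi`` (the spike) or drawn
    from a Gaussian slab ``N(0, tau2 * sigma^2)``; ``sigma^2`` carries an
    inverse-gamma(a0, b0) prior.  Coefficients and the error variance are
    integrated out analytically, so the Gibbs sampler moves only on the
    binary inclusion vector using exact marginal-likelihood ratios — the
    chain targets the same posterior as exhaustive model enumeration.

    Parameters
    ----------
    y : response vector (centred internally).
    X : candidate design matrix (columns standardized internally).
    pi : prior inclusion probability (default 0.1).
    tau2 : slab variance scale relative to sigma^2 (default 1.0).
    a0, b0 : inverse-gamma hyperparameters for sigma^2 (default 0.01).
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        pi: float = 0.1,
        tau2: float = 1.0,
        a0: float = 0.01,
        b0: float = 0.01,
        probe_ids: Sequence[str] | None = None,
        standardize: bool = True,
    ):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if not np.isfinite(y).all() or not np.isfinite(X).all():
            raise ValueError("non-finite values in y or X")
        if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
            raise ValueError("X must be (n x p) with n matching y")
        if y.size <= 3:
            raise ValueError("need more than 3 samples")
        if not 0.0 <= pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if standardize:
            y = y - y.mean()
            X = X - X.mean(axis=0)
            sd = X.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            X = X / sd
        self.y = y
        self.X = X
        self.pi = float(pi)
        self.tau2 = float(tau2)
        self.a0 = float(a0)
        self.b0 = float(b0)
        self.probe_ids = list(probe_ids) if probe_ids is not None else None
        # sufficient statistics: the marginal likelihood of any submodel
        # depends on the data only through these Gram quantities
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def log_marginal(self, gamma: np.ndarray) -> float:
        """log p(y | gamma) up to a gamma-independent constant."""
        idx = np.flatnonzero(gamma)
        k = idx.size
        if k == 0:
            quad = self.yty
            logdet = 0.0
        else:
            A = self.XtX[np.ix_(idx, idx)] + np.eye(k) / self.tau2
            L = np.linalg.cholesky(A)
            u = self.Xty[idx]
            w = np.linalg.solve(L, u)
            quad = self.yty - float(w @ w)
            # |I + tau2 * Xg'Xg| = tau2^k * |A|
            logdet = k * np.log(self.tau2) + 2.0 * float(np.sum(np.log(np.diag(L))))
        return -0.5 * logdet - (self.a0 + self.n / 2.0) * np.log(self.b0 + quad / 2.0)

    def _beta_given(self, gamma: np.ndarray) -> np.ndarray:
        beta = np.zeros(self.p)
        idx = np.flatnonzero(gamma)
        if idx.size:
            A = self.XtX[np.ix_(idx, idx)] + np.eye(idx.size) / self.tau2
            beta[idx] = np.linalg.solve(A, self.Xty[idx])
        return beta

    def fit(
        self, n_iter: int = 5000, n_burnin: int | None = None, seed: int = 0
    ) -> SpikeSlabResults:
        """Gibbs-sample the inclusion vector; PPI_j = posterior mean of gamma_j."""
        if n_burnin is None:
            n_burnin = n_iter // 5
        rng = np.random.default_rng(seed)
        if self.pi >= 1.0:
            gamma = np.ones(self.p, dtype=bool)
            kept = n_iter - n_burnin
            return SpikeSlabResults(
                ppi=np.ones(self.p),
                beta_mean=self._beta_given(gamma),
                n_iter=n_iter,
                n_burnin=n_burnin,
                n_updates=0,
                split_ppi_diff=0.0,
                probe_ids=self.probe_ids,
            )
        if self.pi <= 0.0:
            return SpikeSlabResults(
                ppi=np.zeros(self.p),
                beta_mean=np.zeros(self.p),
                n_iter=n_iter,
                n_burnin=n_burnin,
                n_updates=0,
                split_ppi_diff=0.0,
                probe_ids=self.probe_ids,
            )
        log_prior_odds = np.log(self.pi) - np.log1p(-self.pi)
        gamma = rng.random(self.p) < self.pi
        current_lm = self.log_marginal(gamma)
        gamma_sum = np.zeros(self.p)
        gamma_sum_first = np.zeros(self.p)
        beta_sum = np.zeros(self.p)
        n_updates = 0
        kept = n_iter - n_burnin
        half = kept // 2
        kept_seen = 0
        for it in range(n_iter):
            for j in rng.permutation(self.p):
                flipped = gamma.copy()
                flipped[j] = ~flipped[j]
                flipped_lm = self.log_marginal(flipped)
                if gamma[j]:
                    log_odds = (current_lm - flipped_lm) + log_prior_odds
                else:
                    log_odds = (flipped_lm - current_lm) + log_prior_odds
                p_include = 1.0 / (1.0 + np.exp(-log_odds))
                new_state = rng.random() < p_include
                if new_state != gamma[j]:
                    gamma[j] = new_state
                    current_lm = flipped_lm
                    n_updates += 1
            if it >= n_burnin:
                gamma_sum += gamma
                beta_sum += self._beta_given(gamma)
                if kept_seen < half:
                    gamma_sum_first += gamma
                kept_seen += 1
        ppi = gamma_sum / kept
        ppi_first = gamma_sum_first / max(half, 1)
        ppi_second = (gamma_sum - gamma_sum_first) / max(kept - half, 1)
        return SpikeSlabResults(
            ppi=ppi,
            beta_mean=beta_sum / kept,
            n_iter=n_iter,
            n_burnin=n_burnin,
            n_updates=n_updates,
            split_ppi_diff=float(np.max(np.abs(ppi_first - ppi_second))),
            probe_ids=self.probe_ids,
        )


def bayes_cnv_selection(
    y: np.ndarray,
    X: np.ndarray,
    pi: float = 0.1,
    tau2: float = 1.0,
    n_iter: int = 5000,
    n_burnin: int | None = None,
    seed: int = 0,
    probe_ids: Sequence[str] | None = None,
) -> SpikeSlabResults:
    """Spike-and-slab selection of CNV probes explaining one gene's expression."""
    model = SpikeSlabRegression(y, X, pi=pi, tau2=tau2, probe_ids=probe_ids)
    return model.fit(n_iter=n_iter, n_burnin=n_burnin, seed=seed)


# ---------------------------------------------------------------------------
# ANCOVA on tumour features
# ---------------------------------------------------------------------------


def ancova_tumour_features(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    features: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Joint linear model of each gene's expression on the tumour features.

    Per gene x feature the reported ``correlation`` is the *marginal*
    Pearson correlation with that feature when the feature's term in the
    joint model is significant (p < alpha) and exactly 0 otherwise, so a
    non-zero entry always comes with evidence from the adjusted model.
    """
    import statsmodels.api as sm

    features = list(features) if features is not None else list(clinical.feature_columns)
    clin = clinical.frame
    shared = [s for s in expr.sample_ids if s in clin.index]
    design = clin.loc[shared, features].apply(pd.to_numeric, errors="coerce")
    complete = design.notna().all(axis=1)
    design = design[complete]
    if design.shape[0] < 10:
        raise ValueError("fewer than 10 complete cases")
    # drop collinear features
    X = design.to_numpy(dtype=float)
    keep = []
    for j in range(X.shape[1]):
        cols = keep + [j]
        mat = np.column_stack([np.ones(X.shape[0]), X[:, cols]])
        if np.linalg.matrix_rank(mat) == len(cols) + 1:
            keep.append(j)
        else:
            logger.warning("feature %r is collinear; dropped", features[j])
    used = [features[j] for j in keep]
    Xd = sm.add_constant(X[:, keep])
    sample_pos = {s: i for i, s in enumerate(expr.sample_ids)}
    col_idx = [sample_pos[s] for s in design.index]
    rows = []
    for gi, gene in enumerate(expr.gene_ids):
        y = expr.values[gi, col_idx]
        fit = sm.OLS(y, Xd).fit()
        for fj, feat in enumerate(used):
            p = float(fit.pvalues[fj + 1])
            if p < alpha and np.ptp(X[:, keep[fj]]) > 0 and np.ptp(y) > 0:
                corr = float(stats.pearsonr(y, X[:, keep[fj]])[0])
            else:
                corr = 0.0
            rows.append({"gene": gene, "feature": feat, "correlation": corr, "p": p})
    return pd.DataFrame(rows, columns=["gene", "feature", "correlation", "p"])


# ---------------------------------------------------------------------------
# Optimal-cutoff survival screening
# ---------------------------------------------------------------------------


@dataclass
class CutoffResult:
    cutoff: float
    logrank_p: float
    evaluable: bool = True


def optimal_cutoff(
    expr_g: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    grid_quantiles: tuple[float, float] = (0.1, 0.9),
) -> CutoffResult:
    """Best dichotomising threshold for one gene's expression.

    Every observed expression value between the two quantiles is tried as
    a cutoff (high group = strictly above); the cutoff minimising the
    two-group log-rank p is returned, ties resolved toward the median.
    The minimised p is anti-conservative by construction — it is reported
    as-is, mirroring common practice for outcome-oriented cutoffs.
    """
    expr_g = np.asarray(expr_g, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if event.sum() < 5:
        return CutoffResult(np.nan, np.nan, evaluable=False)
    lo, hi = np.quantile(expr_g, grid_quantiles[0]), np.quantile(expr_g, grid_quantiles[1])
    candidates = np.unique(expr_g[(expr_g >= lo) & (expr_g <= hi)])
    # a cutoff at the maximum leaves the high group empty
    candidates = candidates[candidates < expr_g.max()]
    if candidates.size == 0:
        nearest = expr_g[np.argmin(np.abs(expr_g - lo))]
        if nearest >= expr_g.max():
            return CutoffResult(np.nan, np.nan, evaluable=False)
        candidates = np.array([nearest])
    median = float(np.median(expr_g))
    best: tuple[float, float, float] | None = None  # (p, |c - median|, c)
    for c in candidates:
        group = (expr_g > c).astype(int)
        _, p = logrank_test(time, event, group)
        key = (p, abs(c - median), c)
        if best is None or key < best:
            best = key
    return CutoffResult(cutoff=float(best[2]), logrank_p=float(best[0]))


def survival_screen(
    expr: ExpressionMatrix,
    time: np.ndarray,
    event: np.ndarray,
    endpoint: str = "recurrence",
    grid_quantiles: tuple[float, float] = (0.1, 0.9),
) -> pd.DataFrame:
    """Optimal cutoff -> univariate Cox (Breslow ties) per gene, BH across genes.

    Sign convention: negative beta means higher expression, lower hazard.
    Non-evaluable or non-convergent genes keep NaN statistics and are
    excluded from the BH correction.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    rows = []
    for gi, gene in enumerate(expr.gene_ids):
        x = expr.values[gi]
        cut = optimal_cutoff(x, time, event, grid_quantiles)
        if not cut.evaluable:
            rows.append(
                {"gene": gene, "cutoff": np.nan, "beta": np.nan, "p": np.nan, "converged": False}
            )
            continue
        fit = cox_binary_fit(time, event, (x > cut.cutoff).astype(int))
        rows.append(
            {
                "gene": gene,
                "cutoff": cut.cutoff,
                "beta": fit.beta,
                "p": fit.p,
                "converged": fit.converged,
            }
        )
    frame = pd.DataFrame(rows)
    frame["q"] = np.nan
    ok = frame["p"].notna()
    if ok.any():
        frame.loc[ok, "q"] = multipletests(frame.loc[ok, "p"], method="fdr_bh")[1]
    frame["endpoint"] = endpoint
    return frame


# ---------------------------------------------------------------------------
# Integration network
# ---------------------------------------------------------------------------


def build_integration_network(
    polarization: pd.DataFrame,
    bayes_results: pd.DataFrame,
    ancova_results: pd.DataFrame,
    ppi_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> nx.Graph:
    """Graph linking CNV probes -> polarized genes -> tumour features.

    ``bayes_results`` needs columns (gene, probe, ppi); ``ancova_results``
    needs (gene, feature, correlation, p).  An edge CNV--gene requires
    PPI >= ppi_threshold; gene--feature requires p < p_threshold.  Node
    attributes carry the class (cnv/gene/feature) and, for genes, the
    polarization sign.
    """
    graph = nx.Graph()
    pol_class = dict(zip(polarization["gene"], polarization["polarized_class"]))
    if not bayes_results.empty:
        for _, row in bayes_results.iterrows():
            if row["ppi"] >= ppi_threshold:
                gene, probe = str(row["gene"]), str(row["probe"])
                graph.add_node(probe, kind="cnv")
                graph.add_node(gene, kind="gene", polarized_class=pol_class.get(gene, "none"))
                graph.add_edge(probe, gene, ppi=float(row["ppi"]), relation="cnv")
    if not ancova_results.empty:
        for _, row in ancova_results.iterrows():
            if np.isfinite(row["p"]) and row["p"] < p_threshold:
                gene, feature = str(row["gene"]), str(row["feature"])
                graph.add_node(feature, kind="feature")
                graph.add_node(gene, kind="gene", polarized_class=pol_class.get(gene, "none"))
                graph.add_edge(
                    gene,
                    feature,
                    correlation=float(row["correlation"]),
                    p=float(row["p"]),
                    relation="feature",
                )
    return graph
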