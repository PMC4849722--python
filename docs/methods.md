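# Methods

## Model and assumptions

`polnet` treats paired two-compartment expression data as realisations of
two coupled multivariate processes: a normal-tissue profile matrix N and a
tumour-tissue profile matrix T over the same patients. The working
hypothesis is that a directional paracrine signal manifests as asymmetric
cross-tissue co-expression: the sender gene's profile in the *source*
tissue correlates with many genes in the *receiving* tissue, while its own
profile in the receiving tissue correlates with nothing on the other side.
The method makes no causal claim — it ranks genes by that asymmetry and
leaves mechanism to follow-up work. Assumptions worth keeping in mind:

- correlations are estimated across patients, so inter-patient
  heterogeneity is the signal carrier; the method needs paired samples and
  at least a few dozen pairs to be informative;
- Spearman rank correlation is used throughout (monotone association,
  robust to the heavy tails of log-expression data, usable at small n);
- edges are marginal associations, not partial correlations, which is the
  standard relevance-network trade-off.

## Pipeline parameters

All thresholds live in `AnalysisConfig` and are written next to every
result. Defaults:

| parameter | default | meaning |
|---|---|---|
| `corr_threshold` | 0.75 | minimum \|r_s\| for an NT edge (strict >) |
| `fdr_max` | 0.01 | BH ceiling for edge selection (strict <) |
| `n_bootstrap` | 100 | pairing-destroyed permutations for the edge null |
| `epsilon` | 1 | stabiliser in pol = (f−b)/(f+b+ε) |
| `min_diff` | 20 | pol forced to 0 when \|f−b\| < 20 |
| `pol_threshold` | 0.75 | \|pol\| above which a gene is called polarized |
| `min_module_size` | 20 | modules below this are flagged small |
| `top_hub_k` | 20 | hubs used in the hub composition test |

The edge null destroys the normal↔tumour pairing by permuting the tumour
sample order each iteration. Resampling patients with replacement would
*preserve* cross-tissue correlation and make the null circular, so it is
available only as a diagnostic (`mode="resample"`). Empirical p-values use
a +1 pseudocount in numerator and denominator, so p is never 0 and a
correlation exceeding the entire null sample of size N gets p = 1/(N+1).

The `min_diff` override is applied to the index, not the gene: a gated gene
keeps its (f, b) counts in the output table with pol = 0. Threshold
comparisons are strict on both the correlation and polarization cuts.

## Null models

**Tissue-independent Gaussian null.** Each tissue matrix is fitted by a
multivariate Gaussian (row means, sample covariance). With many more genes
than samples the covariance is singular, so a ridge (default 1e-6 × mean
per-gene variance) is added to the diagonal before Cholesky factorisation;
this is small enough to leave the correlation structure visually and
numerically unchanged while guaranteeing sampling. The two tissues are
sampled from independent random streams, so every cross-tissue correlation
is 0 in expectation while within-tissue structure is preserved. The
false-positive rate is reported per gene evaluation (number of simulated
datasets × genes per dataset); both totals are carried in the result
object because "per simulation" and "per gene" accounting differ by the
gene count.

**Contamination counterfactual.** Measurement noise is modelled with a
two-component form sd(I) = sqrt(a² + (c·I)²) (additive floor plus
multiplicative part), fitted by least squares of replicate variances on
squared mean intensities. Both a "synthetic normal" and a "synthetic
tumour" are the same normal matrix plus independent γ-scaled draws of this
noise, emulating tumour samples that are really contaminated normal
tissue. γ can be calibrated by minimising the Kolmogorov–Smirnov distance
between the synthetic and an observed cross-tissue correlation
distribution (ties resolve to the smaller γ). Because both matrices derive
from the same source, connectivity is symmetric (f ≈ b per gene) at any γ,
and the min_diff gate plus the pol ratio keep the polarized fraction near
zero — which is exactly the point of the counterfactual.

## Topology statistics

Community detection is greedy modularity agglomeration (CNM) on the
undirected bipartite graph, cut at the modularity maximum; module ids are
assigned deterministically (size, then smallest member). On small
structured graphs the greedy optimum coincides with the exhaustive
best-modularity partition, which is how it is tested. The degree
distribution "power-law fit" is the classic log–log least-squares line
over non-zero degree bins with a slope t-test; it is a descriptive
diagnostic with well-known statistical weaknesses (no discreteness
correction, no tail cutoff estimation) and is deliberately not a rigorous
power-law inference. Composition tests (module vs network, hubs vs module)
use the two-sided Fisher exact / hypergeometric test; overlap tests are
two-sided Fisher; gene-set enrichment is one-sided hypergeometric per GMT
term with BH across terms.

## Genetics / clinical integration

**Probe prioritisation.** Each CNV probe is tested against every clinical
variable — one-way ANOVA across levels of ordinal features (Gleason,
T stage), a linear-model F for continuous ones (PSA), and two-level tests
against endpoint event indicators — and ranked by its minimum p across
variables. The min-p rule is a deliberate design choice: the aim is a
permissive prefilter feeding the Bayesian model, not calibrated inference.

**Spike-and-slab regression.** Expression of one gene is regressed on the
candidate probe matrix with β_j = 0 with prior probability 1−π (spike) or
β_j ~ N(0, τ²σ²) (slab), σ² ~ Inv-Gamma(a₀, b₀), columns standardized.
β and σ² are conjugate and integrated out analytically, so the Gibbs
sampler moves only on the binary inclusion vector using exact
marginal-likelihood ratios computed from Gram matrices (an O(k³) solve per
flip, k = current model size). This collapsed sampler targets exactly the
enumeration posterior, which is how it is validated. Defaults π = 0.1,
τ² = 1, a₀ = b₀ = 0.01, 5000 iterations with 20% burn-in; a split-chain
PPI difference above 0.1 flags non-convergence. The posterior inclusion
probability (PPI) threshold for reporting an edge is 0.5 — the median
probability model — and configurable.

**ANCOVA.** Expression is modelled jointly on all tumour features
(numeric/ordinal coding, complete cases, exactly collinear features
dropped with a warning). A feature's reported correlation is the marginal
Pearson correlation when its term in the joint model has p < 0.05 and
exactly 0 otherwise, so every non-zero entry is backed by the adjusted
model.

**Survival screen.** For each gene, every observed expression value
between the 10th and 90th percentile is tried as a dichotomising cutoff;
the cutoff minimising the two-group log-rank p wins, ties resolving toward
the median. The dichotomised indicator then enters a univariate Cox
proportional-hazards fit with the Breslow approximation for ties (Newton
on the partial likelihood; a monotone likelihood is reported as
non-converged rather than as a spurious huge effect). Negative β means
higher expression, lower hazard. BH runs across screened genes. The
minimised log-rank p is anti-conservative by construction — the screen
reports it as such, and the cutoff-selection optimism should be kept in
mind when reading the q-values.

## Synthetic data

`generate_paired_dataset` plants directional signals mechanistically: a
positively planted driver and each gene of its tumour-side block load a
shared latent factor with weight sqrt(driver_strength), so the expected
cross-tissue correlation between driver and block equals driver_strength
while the driver's own tumour profile stays pure noise. Negative drivers
are symmetric. Because every gene contributes two profiles, positive
drivers' tumour-side blocks and negative drivers' normal-side blocks
overlay the same gene slots; such a gene ends up with f = b = 1 and is
silenced by the min_diff gate. Background genes sit in within-tissue
correlation blocks (default pairwise correlation 0.4) sampled
independently per tissue. Defaults — 500 genes, 50 pairs, 10 positive and
10 negative drivers with 30-gene blocks at strength 0.9 — are sized so a
driver's counts (f ≈ 30, b ≈ 0, pol ≈ 0.97) sit clearly above threshold
at 50 pairs and the whole recovery suite runs in seconds on one CPU.

`generate_cnv_clinical` produces segment-wise Gaussian CNV log-ratios
(probes within a segment share a sample-level value, giving local
correlation), expression as a linear combination of each gene's active
probes plus noise, an ordinal Gleason score cut from a latent monotone
combination of chosen genes, and exponential survival with log-hazard
log(HR)·1[expr > cutoff]. Censoring is independent U(0, c) with c solved
numerically so the expected censored fraction equals the requested rate.

What the generators do *not* emulate: probe-level microarray artifacts,
batch effects, non-Gaussian expression marginals, copy-number segmentation
noise, informative censoring, or correlated clinical covariates. Passing
the recovery suite therefore shows the pipeline is correct and calibrated
under its own model assumptions, not that those assumptions hold for any
particular real dataset.

## Numerical and design notes

- Spearman correlations are computed as Pearson correlations of average
  ranks (tie-aware) via one matrix product per tissue; bootstrap
  iterations reuse the precomputed ranks because ranks are invariant to
  column permutation. Null pools are stored as float32.
- Zero-variance profiles yield undefined correlations; they are carried as
  NaN and excluded from edge selection with a log entry.
- The gene filter resolves quantile settings to absolute mean/variance
  thresholds once and reports them; re-applying the resolved thresholds is
  a no-op. Recomputing quantiles on an already-filtered matrix would keep
  shaving the distribution, which is why the resolved-threshold form is
  the one with a stability guarantee.
- Sample alignment orders patients by sorted id, making results invariant
  to input column order. Duplicate gene rows collapse to the
  maximum-variance row by default (mean-collapse available).
- Self-pairs (gene i normal ↔ gene i tumour) are excluded from the NT
  network by default: autocorrelation of a gene with itself across
  tissues is not evidence of cross-talk. A flag restores them for
  diagnostics.
- All stochastic steps take explicit seeds; generators are pure functions
  of their arguments.

## Known limitations

- Relevance networks conflate direct and indirect association; hub genes
  may be correlates of a latent driver rather than senders themselves.
- The polarization index depends on the edge thresholds through f and b;
  very sparse networks gate almost everything to 0 through min_diff.
- The optimal-cutoff survival p-values are optimistically biased; a
  permutation-adjusted variant would be the rigorous alternative and is
  not part of the default screen.
- The spike-and-slab sampler enumerates marginal ratios one coordinate at
  a time; with thousands of highly collinear probes, mixing over
  correlated blocks can be slow and the split-chain diagnostic should be
  checked.
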