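# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions a maintainer needs.

## Panel model and units

A study joins a genes × lines expression matrix (log2 RPKM) with a
drugs × lines IC50 table. IC50s are **molar everywhere internally**;
nanomolar appears only in presentation tables and log10[M] in model
outputs. Joint analyses run on the intersection of line sets; line
identifiers are matched case-sensitively after whitespace stripping (no
fuzzy joins — silent identifier mismatches are the classic pharmacogenomic
bug). Missing expression values are a hard error rather than an imputation
problem: the matrices this pipeline consumes are complete by construction.

Censoring: a measured IC50 above a drug's top tested concentration C is
replaced by C + 1 nM and flagged. The surrogate sorts immediately above
every in-range value, so quartile membership and medians are identical to
treating the measurement as +∞ (a property test asserts this); means are
slightly underestimated, which is accepted and documented in summaries.

## Sensitivity quartiles

For n lines, the top/bottom quartiles hold the q = ⌊n/4⌋ lines with the
lowest/highest IC50s; remainders stay in the middle. Ordering ties are
broken lexicographically by line identifier — ties are measure-zero in
theory but real in rounded data, and a deterministic rule makes every
downstream result reproducible. Quartile assignment depends only on rank,
hence is invariant under any strictly monotone transform of the IC50
scale, which also makes the raw-vs-log question moot.

## Moderated two-group test

Per gene, a pooled two-group comparison of quartile log2 expression with
empirical-Bayes variance shrinkage: posterior variance
s̃² = (d₀s₀² + d s²)/(d₀ + d), moderated t on d₀ + d degrees of freedom.
The prior (d₀, s₀²) is estimated by matching moments of log s² against the
scaled-F sampling model (inverse-trigamma solve); when the observed spread
of log s² does not exceed the sampling term, d₀ = ∞ and all genes share
the common variance. d₀ = 0 (`moderation="off"`) recovers the ordinary
pooled t exactly and serves as a closed-form oracle in tests; the full
estimator is cross-checked against the Bioconductor limma implementation
(agreement to ~1e−8 on a simulated matrix). The effect estimate is the
difference of quartile means of log2 values — a log2 ratio of geometric
means — so |log2fc| ≥ 1 is exactly the 2-fold boundary. Two-sided
p-values throughout; BH adjustment delegates to statsmodels and is tested
against a literal step-up enumeration.

A gene constant within both quartiles has undefined p without moderation
(NaN, and table assembly refuses it); with moderation it gets a finite,
conservative t through the prior variance.

## UFG cascade

Stage 1 keeps genes with p < α_strict (default 0.0025) for exactly one
drug; exclusion is **direction-agnostic** — a gene significant for a
noncognate drug in either direction is dropped, the stricter reading of
drug specificity. Stage 2 keeps |log2fc| ≥ 1 (boundary inclusive) for the
cognate drug. Stage 3 reintroduces the middle quartiles and fits, per
gene and drug, OLS of log10 molar IC50 on expression over the whole panel;
a UFG needs cognate p < 0.05 and noncognate p ≥ 0.05 for both comparators.
Significance thresholds are strict (<) on the significant side and
non-strict (≥) on the exclusion side. Censored IC50s enter regressions at
their surrogate values, consistent with their use in quartile definitions.
Each stage only removes genes, so UFG sets are nested in stage-1 sets and
disjoint between drugs by construction; an empty set is a legitimate
outcome, not an error.

## Network propagation and enrichment

Random walk with restart: fixed point of p = r·s + (1−r)Wp with s uniform
over the seeds present in the graph and W the column-normalised weighted
adjacency. Defaults r = 0.5, L1 tolerance 1e−8 (power iteration, verified
against a direct linear solve to 1e−8 on graphs ≤ 50 nodes). Scores are
nonnegative and sum to 1; isolated nodes receive mass only via restart.
Seeds missing from the graph are recorded in `seeds_dropped` and can never
enter the subnetwork — the propagated interactome is a property of the
graph, not of wishful seed inclusion. The top-K (default 100) nodes by
score, ties broken by gene symbol, induce the subnetwork.

Enrichment: one-sided upper-tail hypergeometric per pathway, each pathway
intersected with the universe first. The default universe is **all graph
nodes**, not all genes in the expression matrix: the query is produced
from the graph, and a larger universe would inflate significance. Pathway
collections are not size-filtered by default. Reported pathways must pass
both p < 0.05 and BH q < 0.1.

## MVR models

Fitted ensembles operate on log2(RPKM); the shipped fixed-coefficient
panels (four-gene eribulin, five-gene vinorelbine, JSON under
`ufgpanel/models/`) take raw RPKM and emit log10[M]. The two families are
deliberately distinct types; no unit conversion is ever applied silently,
because the correct back-transform between them is ambiguous at the
interface and must be the caller's explicit decision.

`EnsembleModel.predict` defaults to calibrated predictions: the raw
member-average passed through the measured-on-predicted OLS line. This
puts predictions on the measured scale but — like any least-squares
predictor — shrinks them toward the panel mean by the factor R² of the
calibration. Consequently predicted quartile means match measured ones
only when the member genes carry most of the response variance; the
analysis drivers show both regimes explicitly. Quartile comparisons use
Welch's t on 25-vs-25 predicted vs measured values with SEM = SD/√q; with
identical vectors the comparison degenerates to t = 0, p = 1.

Subset prioritisation sorts members by descending univariate R² (ties by
symbol) and returns the smallest prefix whose calibration is significant
(p < 0.05) for the cognate drug and nonsignificant for both noncognates;
if no prefix qualifies, the full ensemble is returned flagged
non-drug-specific. The stopping rule is this module's canonical choice
where several were defensible; any fixed k remains directly requestable
via `fit_ensemble`.

## Synthetic data generator

`simulate_panel` draws per-gene baseline means μ_g ~ N(4, 1.5²) and SDs
σ_g ~ LogNormal(log 0.7, 0.15) on the log2 RPKM scale, standard-normal
line effects, a shared latent sensitivity factor f with loading λ = 0.6,
and per-drug response

log10 IC50 = intercept_d + λ f + Σ β_g (x_g − μ_g) + ε η,  ε = 0.25,

followed by censoring at the per-drug assay ceiling (300 nM / 1 µM; default
intercepts −8.8/−8.2/−8.0 log10[M] give an eribulin-most-potent ordering
and a few censored lines per drug). Planted signatures: 10 drug-unique
genes per drug (|β| = 0.15) and 5 shared genes affecting all drugs
(|β| = 0.25), alternating sign so both up- and down-regulated members
occur; planted genes have unit SD.

Members of one signature are **co-regulated**: each loads on a module
factor with fraction `signature_cor` = 0.7 of its variance, signed by its
effect direction. This is both how real transcriptional programs behave
and a mathematical necessity: with independent members, the squared
gene–response correlations share a budget of 1, capping per-gene quartile
separation around 0.6 log2 units for a ten-gene signature — no member
could reach the 2-fold boundary. With the module structure each unique
gene reaches E|log2fc| ≈ 1.5–1.9, strong but not trivial.

The defaults were fixed by a calibration study against the pipeline's own
operating characteristics — null panels (β = 0 everywhere) must yield
empty UFG sets in ≥95% of runs (measured ~99.7%), and planted unique genes
must be recovered with recall ≥ 0.8 (measured ~0.9) — and then frozen.
Noise SDs near-homogeneous across genes (lognormal σ 0.15) are what keeps
the strict-threshold + 2-fold null calibrated at 2000 genes.

Presets: `null_config` removes all planted structure;
`cognate_config` removes the shared signature, lowers the latent loading
to 0.2 and raises the unique effect to 0.2, producing panels where one
drug's signature dominates its response (ensemble calibration R² ≈ 0.95).
The discovery default is intentionally harder: shared and latent
components carry roughly half the response variance, which is what the
specificity cascade needs to be tested against, but which caps ensemble
R² near 0.5 — quartile-mean prediction accuracy is therefore evaluated on
the cognate preset.

What the generator does **not** emulate: real expression covariance and
tissue-of-origin structure, skewed/zero-inflated RPKM distributions,
nonlinear dose–response relationships between expression and potency, and
the identity of any real gene. Passing tests demonstrate that the
pipeline's inferential machinery is correct and calibrated under its own
modelling assumptions — not that those assumptions hold for any given
real panel.

`simulate_graph_and_pathways` draws a stochastic block model (5 modules of
20 nodes; within-module edge probability 0.5, background 0.01) with one
GMT set per module plus 10 random 20-gene decoy sets; designated seed
genes are placed inside module 1. At these densities propagation from ≥6
seeds recovers the host module essentially always, while decoys stay
unenriched.

## Problem sizes and runtime

The reference panel is 100 lines × 2000 genes (the full pipeline runs in
under a second; a `n_genes` override reaches the ~12k-gene scale of real
matrices in a few seconds). Property rates are estimated over 20 panels
(recovery, null calibration) and 100 panels (quartile-mean agreement);
`scripts/acceptance.py` derives every panel seed from its `--seed`
argument.

## Known limitations

- The moderated test assumes a common two-group design across genes;
  no covariates, batch terms or weights.
- Propagation treats the graph as static and undirected; edge confidence
  enters only as a scalar weight.
- The published fixed-coefficient panels are transcriptions; nothing in
  this package can re-derive their coefficients without the original
  expression matrix.
- Calibrated ensemble predictions are conditional means: they understate
  the spread of extreme responders by design (see MVR section).
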