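# Methods

This note documents the statistical procedures `sigperm` implements, the
defaults and tolerances it uses, what the synthetic-data generators do and
do not emulate, and the design choices made where more than one reasonable
convention exists.

## Quantification and filtering

RPKM is computed as `counts · 10⁹ / (length · total)`, with `total` the
column sum of the matrix actually provided. When upstream alignment totals
(all mapped reads, not only gene-assigned ones) are known, they can be
passed explicitly via the `totals` argument; the two conventions differ by
a per-sample constant and only matter for cross-study comparisons.

The detectable-expression filter keeps genes with RPKM strictly greater
than 0.2 in strictly more than 75% of samples (both thresholds
configurable, both strict inequalities). A weaker mode drops only genes
that are zero in every sample; the permutation-test universe uses this
weaker filter so that the universe matches "annotated genes not zero
everywhere". Log₂ transformation uses a pseudocount of 0.01 and centers
each gene on its median; entries that were exactly zero are additionally
flagged (`zero_mask`) so display layers can distinguish "not expressed"
from "low".

Upper-quartile normalization divides each sample by the 75th percentile of
its *nonzero* counts and rescales by the geometric mean of those
percentiles so the matrix keeps its overall magnitude. Note the exact form
of the scale-invariance this buys: multiplying samples by depth factors
changes the output only by the geometric mean of those factors (a single
global constant); relative expression is invariant. The treatment workflow
computes SAM statistics on `log2(UQ + 1)`, the scale on which the
equal-variance assumption behind a pooled standard error is most
reasonable for counts.

## Signature permutation test

Observed statistic: PCA on the signature-restricted matrix (samples are
observations, genes are variables; variables centered, not scaled, because
the input is already log₂ median-centered per gene), followed by a one-way
MANOVA of the first 3 principal components on the group label. The MANOVA
statistic is Pillai's trace with its standard F transform
(`F = (2n+s+1)/(2m+s+1) · (V/s)/(1−V/s)`), chosen for robustness to
covariance heterogeneity among small groups. With a single component it
reduces to the one-way ANOVA F (tested). PCA signs follow a deterministic
convention (largest-magnitude loading positive), so results are exactly
reproducible.

Null: random gene sets of the signature's size drawn uniformly without
replacement from the expressed annotated universe, each scored with the
identical PCA + MANOVA chain. The default p-value is the upper-tail
proportion `#{F_null ≥ F_obs}/n_draws`, ties counted as extreme. Two
variants are kept for auditing: `add_one=True` gives the
`(1+k)/(1+n)` finite-sample correction (recommended when p = 0 is to be
avoided), and `rule="literal"` reports the *lower*-tail proportion, under
which strong separation yields a *large* value — it exists only so either
reading of a "proportion of F greater than" phrasing can be reproduced.
By default the real signature's genes may be resampled into null sets
(`exclude_signature=True` removes them; with thousands of genes the
difference is negligible).

Calibration is a tested property: on no-effect simulations the whole chain
rejects at 5% within the exact binomial band, and the p-values are
uniform, because the observed statistic is exchangeable with the null
draws by construction.

## Hierarchical clustering

Distance is `1 − ρ_Spearman` (average ranks for ties), so profiles
identical up to any strictly monotone transform have distance 0 and exact
rank reversals have distance 2. Constant profiles have undefined rank
correlation and are rejected by name. Agglomeration is the greedy
global-minimum algorithm with complete (max), single (min) or average
linkage; ties break deterministically toward the smallest cluster indices.
The implementation is quadratic per merge — fine for the intended scale
(tens of samples, signature-sized gene sets) — and is verified against
both a brute-force oracle and scipy's linkage on random instances.
Dendrograms export to Newick with ultrametric branch lengths (parent
height minus child height).

## Consensus NMF and rank selection

`nmf_brunet` minimizes the generalized Kullback–Leibler divergence
`D(V‖WH) = Σ V log(V/WH) − V + WH` with the classic multiplicative
updates, uniform random initialization on `(0, max V]`, convergence when
the relative divergence change drops below 1e-6 (max 2000 iterations;
both configurable). Zeros in V are allowed with the `0·log 0 = 0`
convention; WH is floored at 1e-12. The divergence trace is returned and
is non-increasing at every update (asserted in tests with a 1e-10 relative
slack for floating-point accumulation).

Consensus clustering runs the factorization from many random restarts
("iterations" in the sense of the consensus procedure, i.e. restarts —
inner updates always run to tolerance), assigns each sample to its arg-max
row of H (lowest index on ties), and averages co-assignment into the
consensus matrix C. The cophenetic correlation compares the consensus
distances 1−C with the cophenetic distances of the average-linkage
dendrogram built on them. The rank survey repeats this over candidate
ranks on the data (50 restarts by default) and on a randomized baseline in
which every gene row is independently permuted (25 restarts), destroying
sample structure while preserving per-gene marginals.

Rank selection (`select_rank`) takes the last rank before the cophenetic
curve begins to fall, with a 1e-9 tolerance. The tolerance matters: on
strongly structured data several ranks can yield *perfectly* reproducible
consensus (ρ = 1 up to floating-point noise), and a bare argmax would be
decided by that noise; treating exact ties as a plateau and stopping at
the first genuine drop recovers the planted rank reliably. The
corresponding recovery test plants three sample blocks under multiplicative
log-normal noise (sdlog 0.8) — with noiseless blocks the task is
degenerate because every rank is stable.

## Rank statistics

All exact modes enumerate the full permutation null and define the
two-sided p as the doubled smaller tail, capped at 1; ties receive half
credit inside the statistic, and tail comparisons use a 1e-9 buffer so
exactly tied statistics count as extreme.

* **Mann–Whitney**: U counts pairs with a > b (+½ for ties). Exact when
  both groups have ≤ 8 values — enumeration over all C(n, n₁) splits, so
  ties are handled without approximation; otherwise the normal
  approximation with tie correction (scipy). Identical groups give
  p = 1 exactly in exact mode.
* **Jonckheere–Terpstra**: JT sums the pairwise Mann–Whitney counts over
  ordered group pairs; ordered levels always come from the declared
  design ordering, never from the data. Exact enumeration of all group
  assignments up to total n = 12; beyond that the normal approximation
  with the Hollander–Wolfe tie-corrected variance.
* **Spearman**: average-rank ρ; exact p for n ≤ 9 without ties by
  enumerating all n! rank permutations (the null distribution is cached
  per n), otherwise the t approximation with n − 2 df.

Benjamini–Hochberg adjustment is the standard step-up procedure
(statsmodels), input order preserved, `q ≥ p` and monotone in p.

## Factorial synergy test

Per gene, the 2×2 model `y ~ A + B + A·B` is fit by least squares; the
interaction coefficient measures synergy beyond additivity. With
`moderated=True` (default) residual variances are shrunk toward a
consensus via an empirical-Bayes update: the marginal distribution of the
log sample variances is matched to a scaled-F model by digamma/trigamma
moment inversion, giving a prior df d₀ and prior variance s₀²; posterior
variances `(d₀s₀² + df·s²)/(d₀ + df)` feed t statistics with df + d₀
degrees of freedom. This is a limma-style moderation — the shrinkage
target and prior df are estimated from the data, but the exact hyperparameter
estimator of that package is not reproduced. P-values are reported
unadjusted, matching the convention of testing a small pre-declared gene
panel. The unmoderated path equals ordinary two-way ANOVA (tested against
statsmodels).

## SAM-ranked GSEA

The SAM statistic `d = (x̄₁ − x̄₂)/(s + s₀)` uses the pooled two-sample
standard error s and a fudge constant s₀ that prevents low-variance genes
from dominating. s₀ defaults to the median of the per-gene standard
errors (a percentile is configurable); the full coefficient-of-variation
minimization of the original SAM procedure is intentionally not
implemented, and the resolved s₀ is recorded in the result. Genes are
ranked by descending d with lexicographic tie-breaking.

The enrichment score is the classic unweighted running sum: +1/k at set
genes, −1/(N−k) elsewhere; ES is the running-sum value of maximal
magnitude (first index on ties, with a 1e-12 tolerance so algebraically
equal peaks resolve identically regardless of summation order). Unweighted
ES depends only on ranks, its increments sum to zero exactly, and a set
occupying the top k of the list scores exactly 1. A weighted mode
(|d|^exponent) is available but not default — the maximal-excursion form
is the unweighted statistic.

The null permutes *gene labels* (the gene-to-score assignment), not
phenotypes: one shared permutation per iteration, every pathway rescored
from it, preserving the correlation structure between overlapping
pathways. A phenotype-permutation mode exists for comparison. Normalized
scores divide ES by the mean |null ES| of matching sign for that pathway.
All three significance levels are then computed on |NES| with the
permutation count as denominator:

* nominal p — fraction of that pathway's null |NES| at or above the
  observed |NES| (two-sided; uniform under the null);
* FDR q — pooled-null estimator across the analyzed pathways, clipped to
  [0, 1] and made monotone in |NES|;
* family-wise p — maxT: the fraction of permutations whose *family-wide
  maximum* |NES| reaches the pathway's observed |NES|.

Working throughout on |NES| makes the three levels mutually consistent:
FWER p ≥ nominal p for every pathway by construction, and a family of one
collapses to the nominal p. Direction (up/down) is reported separately as
the sign of ES. The leading-edge ("core enrichment") subset contains the
set members at or before the running-sum maximum for positive ES, and the
members past the minimum — toward the bottom of the list — for negative
ES; for a contiguous top-k or bottom-k set this is the entire set.

## Synthetic data

The generators emulate the *structure* the analyses assume, not any real
dataset: negative-binomial counts with variance `μ + φμ²` (default
dispersion φ = 0.15), per-gene relative abundances log-normal (sdlog 1.2),
log-normal library sizes (default mean 2×10⁷, CV 0.3), uniform gene
lengths 500–5000 nt, four groups CB/NPB/CP/BC of sizes 3/3/8/9, and a
41-gene signature whose means are multiplied by 2^log2fc (default 1.0) in
the designated group only. Gene-set universes draw uniform random sets
(default 100 sets of 15–100 genes) and always include the planted
signature as a named, flagged set. The dormancy assay uses a Gaussian
copula with `r = 2 sin(πρ/6)` so the *population Spearman* correlation
equals the requested ρ. The factorial generator produces Gaussian
log-expression with configurable main and interaction effects.

Everything is a pure function of (config, seed), and the ground truth
(signature members, per-group fold changes, set memberships, labels) is
serialized alongside. What the generators do **not** model: isoform
structure, GC/length bias, outlier samples, batch effects, correlated
genes beyond the planted programs, or library-preparation artifacts.
Passing recovery tests therefore demonstrates correctness and calibration
of the *procedures* under their stated assumptions, not robustness to all
features of real RNA-seq.

## Problem sizes used in the checks

The simulation-based checks run at desk scale, chosen to keep the full
suite to a few minutes while leaving the conclusions unchanged:
2000-gene universes with 500 null draws for the calibration (200
datasets) and power (100 datasets) studies of the signature test; 100
null datasets at 500 gene-label permutations for family-wise error
control; 20 seeds at the full 2000 permutations for treatment-workflow
recovery; 30/10 restarts over ranks 2–5 and 20 seeds for the NMF survey.
The workflows themselves default to the full-scale parameters (5000
signature draws, 2000 permutations, 13,850 genes).

## Known limitations

* The negative-binomial DE route of dedicated count-model packages is out
  of scope; differential expression here is the Mann–Whitney/BH route,
  which at n = 8 vs 9 has little power below ~4-fold effects.
* FDR q-values follow the pooled-null estimator and can be conservative
  for small pathway families.
* The permutation-test universe should contain the signature's genes; if
  the signature is much more variable than the universe average, the test
  is anti-conservative in the way any random-set null is.
* Exact-mode thresholds (Mann–Whitney 8 per group, trend test 12 total,
  Spearman 9 pairs) are enumeration-feasibility bounds; immediately above
  them the normal/t approximations are still small-sample approximations.
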