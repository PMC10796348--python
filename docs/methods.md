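# Methods

## Model

A bulk tumour sample with purity λ_T mixes tumour and normal cells; its
somatic-SNV VAF distribution decomposes into Beta-distributed clusters — the
clonal cluster (cancer-cell fraction c = 1, every tumour cell carries the
mutation) and optional subclones (c < 1) — plus a power-law tail of neutral
within-clone passengers. A matched normal contaminated by a fraction λ_N of
tumour cells shows the same clonal mutations at a VAF scaled down by λ_N.
For a mutation with cancer-cell fraction c on a segment with minor/major
allele copies (m, M), present in μ copies, in a sample with tumour cell
fraction λ:

    E[VAF] = c · μ · λ / (λ(m + M) + 2(1 − λ))

Tumour cells contribute m + M chromosome copies at the locus, admixed normal
cells two. Inverting at c = 1 gives the purity equation ρ = 2v / (μ + v(2 −
m − M)); the read-fraction conversion η = λ(m+M) / (λ(m+M) + 2 − 2λ) follows
from the same copy-count argument and is the identity for diploid genomes.

The estimator never observes λ directly; it reconstructs the clonal VAF
summaries v_T (mean tumour VAF of the selected clonal mutations) and v_N
(mixing-weighted Binomial success probability in the normal) and pushes both
through the same equation with the same karyotype — contaminating cells in
the normal are tumour cells, so the tumour karyotype applies to both
conversions. This is the one consistent reading and is documented here
because the alternative (treating the normal as diploid in the read-fraction
conversion) would silently disagree in non-diploid genomes.

## Fitting choices

**Tumour mixture (Pareto tail + Betas).** EM with exact weighted M-steps:
Beta components are updated by damped Newton on the weighted Beta
log-likelihood in (a, b) with backtracking (the objective is evaluated from
sufficient statistics, O(1) per step); the update never decreases the
objective, so the whole loop is a monotone generalised EM. The Pareto
Type-I scale is fixed at the minimum retained VAF (its MLE is the sample
minimum; fixing it removes a non-smooth parameter) and the shape has the
closed-form weighted MLE. Beta parameters are bounded: mean in [1e-3,
1−1e-3], precision in [10, 5000] to prevent degenerate spikes. Model search:
k = 1..3 Beta clusters × tail on/off, each with 5 EM restarts (k-means
initialisation for the means, jittered on restarts ≥ 1), convergence |Δ log
L| < 1e-8 or 500 iterations. Input VAFs are sorted internally so the fit is
exactly permutation invariant; responsibilities are re-evaluated in input
order.

**Model selection.** ICL = −2 log L + p·log n + entropy(z), minimised, with
p counting 2 per Beta, 1 for the tail shape, components−1 for the mixing
proportions, and entropy(z) = −Σ z log z ≥ 0 (0·log 0 := 0). The entropy
term penalises poorly separated clusterings on top of the BIC penalty; with
the opposite sign the score would reward duplicated overlapping components
(an entropy bonus of up to n·log 2 against a parameter penalty of ~3·log n)
and model selection would collapse, so the separation-penalising sign is
used.

**Normal Binomial mixture.** EM with the closed-form M-step, k = 1..3
selected by the same ICL construction. Mutations with zero alternate reads
in the normal are retained: at ~30x, Binomial sampling produces many zero
counts even under genuine contamination, and the mixing proportions weight
their contribution to v_N = Σ πᵢ pᵢ. Success probabilities are clipped to
[1e-9, 1−1e-9]; all-zero input yields p ≈ 0 (TIN ≈ 0), which is a valid
result, not an error.

**Clonal-cluster guard (SNV-only mode).** The 60/20 rule: rank chromosomes
by the cluster's mutation count, find the smallest prefix covering >60% of
the cluster, and reject when that prefix is <20% of the chromosomes carrying
at least one SNV in the dataset. The greedy prefix is exact here — for a
fixed subset size, coverage is maximised by the largest counts — and the
tests check it against exhaustive subset search. The denominator counts
chromosomes with data rather than a fixed 24 so the rule behaves on sparse
(exome-like) inputs. Clusters are walked in decreasing-mean order; in
CNA-aware mode the rule is skipped entirely because the karyotype filter
already removes CNA confounding.

**Clonal mutation threshold.** z₊ starts at 0.9 and decreases in 0.01 steps
until ≥150 mutations are selected or the floor 0.5 is reached; the set grows
monotonically as the threshold drops. The fixed step and floor make the
dynamic cutoff deterministic.

**Joint confirmation.** Mean-field variational Bayes for the bivariate
Binomial mixture with Beta(1,1) priors on per-cluster success probabilities
and a sparse symmetric Dirichlet (α₀ = 1e-2) on the weights; convergence
|ΔELBO| < 1e-8 or 1000 iterations. CAVI is run from k-means initialisations
with 1..10 starting components and the highest final ELBO wins: the sparse
prior empties near-empty components, but merging two half-clusters of one
population is vanishingly slow under coordinate ascent, so the ELBO ladder
is what makes the cluster count genuinely automatic. Components with
expected weight <1% are pruned. If ≥80% of the clonal mutations occupy one
joint cluster, its posterior-mean (θ_t, θ_n) give alternative TIT/TIN
estimates; deviations >0.03 read fraction are flagged. The check is advisory
and never overrides the primary estimates, because its input shares the
false-negative bias of the upstream caller.

## Pipeline policy

Quality floor before deconvolution: tumour VAF ≥ 0.05 and tumour depth ≥ 10
(low-VAF noise destabilises the tail fit). Sex chromosomes are excluded in
SNV-only mode, where hemizygosity violates the implied diploid assumption;
with CNA data the karyotype filter handles them. If the most prevalent
karyotype is unsupported (not in {1:0, 1:1, 2:0, 2:1, 2:2}) or leaves fewer
than 50 SNVs, the run falls back to SNV-only mode with a reason code rather
than failing. Mutation multiplicity defaults to μ = 1 for all supported
karyotypes: clonal mutations in amplified genomes typically predate the
amplification on one allele, and a single-copy assumption is the
conservative choice. ρ estimates are clipped to [0, 1] with an explicit
flag.

Classification uses read-fraction units with strict inequalities: TIT <
0.25 → CANNOT_ESTIMATE, else TIN > 0.01 → FAIL, else PASS (a sample at
exactly 1% passes). A clonal/total mutation ratio of 1 (no clonal/subclonal
separation achieved) adds a reliability warning but does not by itself fail
the sample. Stage failures on valid inputs (too few mutations, all clusters
rejected, unreadable files) map to CANNOT_ESTIMATE with reason codes.

## Synthetic data

The generator is a read-count-level stand-in for BAM-mixing experiments:
depths are Poisson around the target coverages (defaults 100x tumour / 30x
normal, the design coverages of clinical WGS), alternate reads are
Binomial(depth, E[VAF]) with E[VAF] from the closed form above. The default
architecture is a clonal cluster of 400 SNVs, two subclones (cancer-cell
fractions 0.45 and 0.22, 150 SNVs each) and a neutral tail of 250 SNVs with
cancer-cell fractions from a Pareto(shape 2) truncated to (0.1, 1] — a
typical mid-burden WGS architecture at the scale of the worked examples
(~1000 informative SNVs). Karyotypes are assigned by genome-fraction
weights, with every karyotype spread across all 22 autosomes so cluster
geometry is chromosomally uniform as in real WGS. The optional censoring
step drops variants whose observed normal VAF exceeds a threshold,
reproducing caller-side subtraction and its TIN-underestimation bias.

Ground-truth read fractions are converted with the most prevalent simulated
karyotype — the same convention the estimator reports under — so
estimate-versus-truth comparisons are unit-consistent in mixed-karyotype
genomes.

What the simulator does not model: sequencing error and strand artefacts,
depth variation with local copy number, mapping bias, germline leakage,
subclonal copy-number events, and caller-specific filtering other than the
censoring step. A green recovery test therefore establishes that the
estimator inverts its own generative assumptions at realistic depths and
architectures, not that it is robust to every artefact of real pipelines.

## Validation series

The recovery experiments simulate 30 pairs with injected TIN evenly spread
(with seeded within-bin scatter) over 0–25% read fraction and purity uniform
in [0.5, 0.95]; genomes are diploid-dominant (85% 1:1) for the
haematological-like series and 70%+ non-diploid ({2:1, 2:0, 2:2, 1:0} at
75% total weight) for the CNA-heavy series, run CNA-aware. Estimated TIN
(read fraction) is regressed on the injected truth and R² reported. Series
size and per-case SNV counts are desk-scale choices to keep a full run in
minutes on one CPU.

## Known limitations

* Pure Binomial components in the normal fit: overdispersed (Beta-Binomial)
  counts are not modelled and would widen the contamination peak.
* One karyotype per run: mixed-karyotype estimation and subclonal CNAs are
  out of scope; unsupported dominant karyotypes fall back to the diploid
  assumption on all SNVs.
* The 60/20 guard needs multi-chromosome data to have any power; datasets
  confined to one chromosome pass it vacuously.
* Very high contamination degrades the input itself (clonal variants are
  subtracted by the caller before the estimator sees them); the censoring
  model reproduces the direction of that bias but not caller-specific
  magnitudes.
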