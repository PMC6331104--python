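# Methods

This note documents the models and procedures implemented in `toxrank`,
the defaults and why they were chosen, what the synthetic data generator
does and does not emulate, and the numerical conventions.

## Differential-expression screen (`toxrank.de`)

Per compound, gene expression y (log2) over samples is modelled as a
polynomial of unit-scaled time t with treatment-group structure:

    y = β0 + Σ_p βp t^p + Σ_dose [ γ_d 1_d + Σ_p γ_dp 1_d t^p ] + ε

with p = 1..d, d = min(max_degree, #timepoints − 1) (default cap 3,
cubic), one indicator 1_d per non-control dose level present in the data
(a missing dose arm simply contributes no columns), and iid Gaussian ε.
Time is scaled to unit range purely for conditioning.

*Step 1* fits this full model by OLS per gene and F-tests it against the
intercept-only null — "does the gene change over time in any group, or
depend on treatment at all?" The per-gene p-values are BH-adjusted across
genes and cut at `global_fdr` (default 0.01). The intercept-only null was
chosen over a time-only null because the screen's purpose is sensitivity:
genes with any temporal or treatment structure proceed to step 2, which
then separates treatment from shared drift.

*Step 2* prunes the full model by two-way backward stepwise regression at
the per-coefficient threshold α = 0.05/n, n the full model's coefficient
count: repeatedly drop the least significant coefficient above α, after
each drop re-admit any excluded variable that would be significant
(a visited-set guard prevents add/remove cycles; the intercept is never
dropped). A gene is **selected** iff it passed step 1, the pruned model
retains at least one treatment-related coefficient (dose indicator or
dose×time interaction — a time-only model does not distinguish treatment
from control), and the pruned model's R² ≥ `r2_min` (default 0.6, i.e.
at least 60% of expression variance explained).

Degenerate inputs are absorbed, not raised: a zero-variance gene receives
p = 1 and R² = 0; aliased design columns are handled by pseudo-inverse
fitting and eliminated by the stepwise pass (their t-tests are
uninformative, p ≈ 1); groups with fewer than two replicates trigger a
warning only. The model p-value reported for ranking ("adjusted model
p-value") is the F-test of the pruned model against intercept-only. A
`denoise` hook (identity by default) lets real-data users insert a noise-
removal step before fitting.

## Extended partial ranking (`toxrank.ranking`)

Selected genes are ordered by adjusted-model R² (descending), ties broken
by adjusted-model p-value (ascending), remaining ties by midrank. All
non-selected genes share a single bottom rank. Two conventions for that
shared rank are provided:

* `midrank` (default): the average of the positions the block spans,
  (n_sel + 1 + N)/2. This conserves the rank sum N(N+1)/2 exactly, which
  keeps MEAN aggregation unbiased and makes rank-sum conservation a
  testable invariant of every downstream ranking.
* `max`: the shared rank is N. Exposed because "the same lowest rank" is
  also a defensible reading; aggregation behaviour differs mainly for
  RRA, whose extreme order-statistic channels are inert when the bottom
  block sits at r = 1.

## Rank aggregation (`toxrank.aggregate`)

All methods consume the gene × compound matrix of normalized ranks
r = rank/N ∈ (0,1]; every output resolves ties by midrank, so each
consensus rank vector sums to N(N+1)/2.

* **MEAN** ranks by the average normalized rank. A significance level is
  attached via the Irwin–Hall CDF of the rank sum (exact alternating-sum
  formula for m ≤ 50 lists, evaluated on the lower half via the symmetry
  F(s) = 1 − F(m−s) to avoid catastrophic cancellation; normal
  approximation N(m/2, m/12) beyond) and BH-adjusted across genes. Ranks
  are computed from the mean itself: the p and q transforms are monotone,
  but BH adjustment introduces tie plateaus that would corrupt the
  ranking's tie structure without changing its order.
* **NC** counts the lists in which the gene is modulated (outside the
  bottom block) and ranks descending.
* **RRA** computes p_k = P(U₍ₖ₎ ≤ r₍ₖ₎) = Beta(k, m−k+1) CDF for each
  order k of the gene's sorted ranks, takes ρ = min_k p_k and reports the
  Bonferroni score min(1, m·ρ). Ranking uses the uncapped product m·ρ for
  the same tie-structure reason as MEAN (the cap would tie all weak genes
  at 1).
* **STUART** evaluates the joint probability Q that m uniform order
  statistics fall below the gene's sorted ranks, via the scaled Steck
  recursion w_k = Σ_{j<k} (−1)^{k−1−j} C(k,j) w_j b_{j+1}^{k−j}, w_0 = 1,
  Q = w_m. Binomial coefficients replace explicit factorials so the
  recursion stays finite at large m; cancellation is benign for the list
  counts used here (m ≤ ~60). A flag removes the m! scaling (reporting
  the raw simplex volume); the ranking is invariant to it.
* **BIRRA** starts from the rank-average consensus, takes the top ⌈πN⌉
  genes (prior π = 0.05) as putative positives, and scores each list by
  cumulative-bin Bayes factors (50 bins, pseudo-count 1):
  BF_{c,b} = [(pos ≤ b) + 1]/(πN + 1) ÷ [(neg ≤ b) + 1]/((1−π)N + 1).
  Log Bayes factors are made monotone non-increasing across bins by a
  running maximum from the last bin, summed over lists per gene, and the
  consensus is re-ranked; iteration stops when the rank vector is stable
  or after 10 iterations. These internals (cumulative bins, smoothing,
  monotonization, convergence test) follow the published description of
  the method; the contract is recovery behaviour, not bit-equivalence
  with any particular implementation.
* **AR** is the per-gene median of the five ranks above, re-ranked. It
  requires all five inputs and names any missing one.

Rank matrices assemble their columns in sorted label order so float
summations — and therefore entire pipelines — are invariant to the order
in which lists are supplied.

## Literature arm (`toxrank.literature`)

For each gene with ≥ 1 annotated abstract, a one-tailed (enrichment)
Fisher exact test compares its abstracts against a topic abstract set
within a declared universe: p = P(X ≥ a) for X ~ Hypergeometric(U, |T|,
|G|). The universe is a declared count (the background is all abstracts,
not an enumerable local set); a switch restricts it to abstracts
annotated to ≥ 1 gene. Candidates must satisfy BH-FDR q ≤ 0.05, support
≥ 3 topic abstracts, and possess a one-to-one ortholog in the partner
taxon; the pre-ortholog selection is also reported. Executing literature
queries is out of scope — the package consumes pre-resolved abstract-id
sets; the query strings for the two organ topics are documented in
`TOPIC_QUERIES`.

## Orthology and probesets (`toxrank.orthology`)

Probesets mapping to more than one gene are discarded; among several
probesets for one gene the largest interquartile range across all samples
wins (linear-interpolation quartiles; exact IQR ties break to the
lexicographically smallest probeset id, for deterministic builds).
One-to-one orthologs are homolog groups with exactly one member in each
of the two taxa; rankings and gene sets are translated through these
pairs, dropping (and counting) unpaired genes.

## Evaluation (`toxrank.evaluate`)

ROC curves traverse tied rank blocks as single straight segments; the
trapezoidal area equals the midrank-corrected Mann–Whitney statistic, so
AUC(r) + AUC(reverse r) = 1 holds exactly. Spearman's rho is the Pearson
correlation of midrank vectors with the large-sample t approximation for
its p-value; constant rankings return NaN. Rankings are combined by rank
sums (ascending head = consistently perturbed genes) or differences
(ascending head = first-system-specific genes; the combination is exactly
antisymmetric). `top_k` includes a tied block that straddles the boundary
in full and reports the realized size.

## Synthetic data (`toxrank.simulate`)

The generator emulates a single-dose toxicogenomics design: per compound,
samples at {control, low, middle, high} × timepoints × replicates.
Defaults describe the study conditions used throughout the tests: 2,000
genes, 20 compounds of which 16 toxic, 100 planted toxicity genes,
responsiveness 0.6, effect size 2.0 log2 units, noise SD 0.5, timepoints
(3, 9, 12, 24) h, 3 replicates.

A responsive gene g in compound c receives
baseline_g ± magnitude · w(dose) · g(t) + N(0, noise_sd), with dose
weights w = (0, ⅓, ⅔, 1) and the saturating profile
g(t) = (1 − e^{−t/τ})/(1 − e^{−t_max/τ}). Only the existence of dose- and
time-dependent signal matters for testing, not its exact shape. The time
scale τ defaults to 1 h — an acute induction largely saturated by the
first 3 h measurement. This choice is deliberate: with the fixed dose
weights, effect 2.0 and noise 0.5, the share of expression variance a
correct model can explain peaks near 0.69, and slower profiles push the
adjusted-model R² of genuinely responsive genes under the 0.6 selection
floor, making the screen's nominal sensitivity (≈ 0.9 per responsive
gene-compound pair at these settings) unreachable.

Two forms of heterogeneity make the recovery problem realistic rather
than separable:

* **Per-gene sensitivity.** Each planted gene's response probability is
  Beta-distributed around the configured mean responsiveness
  (concentration 5), so some planted genes respond in most toxic
  compounds and others in few — as gene sensitivities differ in real
  panels. Setting responsiveness to 0 or 1 disables the heterogeneity.
* **Off-target responders.** Every compound — toxic or not — additionally
  modulates its own set of non-planted genes (count log-uniform in
  (30, 300) by default, magnitudes 0.5–1.5 × effect size). Real compounds
  perturb hundreds of genes of which only some are toxicity-related; this
  produces the heterogeneous differentially-expressed set sizes that
  penalize rank averaging, and it turns the non-toxic compounds into
  non-empty but toxicity-uninformative (outlier) rankings — the input
  robust aggregation exists to tolerate. `off_target_range=(0, 0)`
  restores fully signal-free compounds for null calibration.

The generator does **not** emulate probe-level microarray physics, batch
effects, normalization artifacts, gene-gene correlation, or compound
similarity structure. Passing recovery tests therefore demonstrates that
the pipeline's inference and aggregation machinery works as specified on
data satisfying its model assumptions — not that any particular organ or
compound conclusion transfers to real arrays.

The literature generator gives every gene 1 + Poisson(4) background
abstracts (each a topic abstract at the background rate, default
|T|/U = 300/20,000, settable to 0); a configurable fraction of planted
genes additionally receives 3–6 topic abstracts, the support the
selection filter requires. Abstract ids within a gene are distinct. A
companion homolog-table generator pairs ~90% of genes one-to-one with a
partner taxon and places the rest in non-one-to-one groups.

All generators are deterministic per seed; the pipeline fans a single
global seed out to per-stage sub-seeds, and re-running any stage with the
same configuration is byte-identical (floats are written with 12
significant digits).

## Problem sizes used in the checks

The acceptance computations use 10⁶ Monte-Carlo draws per order-statistic
check; exhaustive hypergeometric enumeration over universes up to 200;
null calibration on 500-gene × 10-list uniform matrices with 50
replicates plus one 2,000-gene signal-free screen; end-to-end recovery at
the default study scale above; and 20 replicate literature simulations
for false-selection control. These sizes were chosen so each quantity's
Monte-Carlo error is well below the margins being asserted while the
whole recomputation stays in the half-minute range.

## Known limitations

* The two-step screen is not bit-compatible with the original
  reference implementation of the two-step regression tool; its contracts
  here are calibration (FDR control on null genes) and recovery, and the
  step-1 null (intercept-only vs time-only) is a documented choice.
* RRA inherits a structural weakness on extended partial rankings: the
  shared bottom block makes the k = m order-statistic channel identical
  (and extreme) for every gene, so genes with few detections collapse
  into one tie. Its recovery AUC accordingly sits well below the other
  robust methods on partial rankings; this is a property of the method,
  reproduced rather than repaired.
* NC and AR rankings are count-valued and heavily tied; rank-uniformity
  diagnostics based on continuous statistics (per-decile chi-square) do
  not apply to them, and their null behaviour is covered by
  exchangeability/permutation properties instead.
* Fisher testing treats abstracts as exchangeable units; citation bias,
  annotation depth and abstract age are not modelled.
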