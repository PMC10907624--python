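# Methods

`combnet` implements a patient-oriented strategy for designing two-drug
combination therapies from an ex vivo drug-response screen, as used in
functional precision medicine for acute myeloid leukemia (AML). The premise
is that drugs fall into response-behavior classes — sets of compounds that
inhibit the same patient samples — and that combining one drug from each of
two distinct classes covers complementary patient subpopulations and
non-overlapping toxicity mechanisms. The package builds the drug classes
from screen data, corroborates them with orthogonal evidence (protein
targets, chemical structure), selects low-toxicity/high-efficacy candidates,
and evaluates candidate pairs with synergy reference models and proportion
tests.

## Pipeline model

**Normalization.** Raw cell-death readouts are min–max normalized to an
inhibition rate `R = (x − min)/(max − min) ∈ [0, 1]` (1 = highest
sensitivity). The scope of min/max is global by default — one comparable
scale across the screen — with a per-drug option. The equation does not
itself fix the scope; global was chosen because the point of the
normalization is cross-experiment comparability.

**Complete submatrix.** Screens have missing cells; the network stage
requires a complete matrix. `extract_complete_submatrix` greedily deletes
the row or column with the largest *fraction* of missing cells (absolute
counts are incomparable between rows and columns of different lengths; ties
go to the larger absolute count, then — under `max_area` — to the deletion
leaving more cells), followed by a restoration pass that re-adds any deleted
line no longer covering a missing cell. The result is complete and maximal
(no single deleted row/column can be restored), but not globally optimal;
on exhaustively enumerable 8×8 instances it retains ≥ 80% of the optimal
cell count in our tests. Maximum complete submatrix extraction is NP-hard in
general, so a documented heuristic is the deliberate choice.

**Bipartite network and projection.** The matrix A defines a weighted
bipartite graph (samples, drugs) with ω(s_i, d_j) = a_ij; exact-zero edges
are dropped by default (they cannot affect any projection weight). The
one-mode drug projection uses w_ij = Σ_k a_ik·a_jk — the off-diagonal of
AᵀA — so two drugs are similar when they strongly inhibit the same samples.
Note this is a raw inner product: it mixes response *level* and *pattern*,
which is why the synthetic generator plants block-structured (not merely
mean-shifted) profiles; see below.

**Median filter and communities.** Only edges strictly above the median of
all projected edge weights are kept (midpoint convention for even counts —
the strict inequality means an all-equal network loses every edge). Louvain
weighted-modularity maximization (resolution 1.0, seeded) on the filtered
network yields the drug communities. The number of communities is not forced
to two; drugs isolated by the filter become singletons. Community ids are
renumbered 1..k by decreasing size for determinism.

**Target corroboration.** Given a drug → protein-target map, each protein P
is scored S(P) = ln(f1/f2), the log-ratio of *distinct* drugs targeting it
in clusters 1 and 2. PPT1 = {S > ln 2}, PPT2 = {S < ln 0.5}; thresholds are
strict (f1=4, f2=2 sits exactly at ln 2 and is excluded). The log base is
irrelevant to membership since the thresholds are log(2)/log(0.5) in the
same base; natural log is used. For zero counts S is undefined; the default
policy assigns such proteins to the evident set (f2=0 → PPT1) with a ±inf
sentinel score, and a pseudocount (0.5) variant is available. Exclusive sets
G1/G2 require ≥ 3 drugs from the focal cluster and ≤ 2 from the other.
Enrichment of protein sets is a generic upper-tail hypergeometric test over
user-supplied annotation terms (GMT format) with Benjamini–Hochberg FDR and
fold enrichment (k/n)/(K/N); no live pathway databases are queried.

**Chemical corroboration.** Drugs are compared by Dice similarity
S = 2c/(a+b) on binary fingerprints (ECFP via the optional rdkit adapter,
radius 2 / 2048 bits, or any bit set). The homogeneity test asks whether
inter-cluster pairs are less similar than intra-cluster pairs: one-sided
Welch t and Mann–Whitney tests are reported per intra group and pooled.
Pairwise similarities sharing a drug are dependent, which both tests ignore
and which makes them anti-conservative; a label-permutation p-value on the
difference of group means is therefore computed alongside and is the
calibrated variant (exact under exchangeability). All three are reported.

**Selection.** Per drug, efficacy = mean normalized inhibition over patient
samples, toxicity = mean over healthy samples. Candidates must beat both
grand means (efficacy above average AND toxicity below average); survivors
are ranked by efficacy − toxicity (ties by id; efficacy-only ranking is an
option), capped at ⌈5% × n_drugs⌉ overall and then at 4 per cluster. With
four drugs per cluster, exhaustive pairing yields 16 inter-cluster and
6 + 6 intra-cluster combinations.

**Synergy models.** On a dose–response surface (monotherapy ladders +
combination grid, default doses 1, 10, 100, 1000, 10000 nM), each reference
model predicts the no-interaction combination response:
HSA max(y_a, y_b); Bliss y_a + y_b − y_a·y_b; Loewe the y solving
x_a/D_a(y) + x_b/D_b(y) = 1, with D(y) inverting a 4-parameter logistic
(Hill) fit of each monotherapy, solved by bracketed root finding (xtol
1e-10; a y unreachable by the shallower drug is clamped to
min(e_max) and flagged); ZIP a Bliss-form expectation on the *fitted*
monotherapy curves compared against the combination surface smoothed by
conditional Hill refits along each dose axis (the lower asymptote of each
slice is pinned to the partner drug's fitted effect combined with the
baseline by independence), with the delta averaged over the two fitting
directions — an approximation to the full two-way potency-shift fit,
recorded in result flags when the conditional fits fall back to raw data.
Scores are 100 × mean excess (observed − expected) over combination cells,
positive = synergy. HSA/Bliss use observed monotherapies; Loewe/ZIP the
fitted curves. The combination ratio CR = combo / max(single agents) (> 1 =
added benefit; cells with a zero best single agent are excluded and
counted). DSS is a simplified drug-sensitivity score: 100 × the trapezoidal
area of max(response − 0.1, 0) over log10 dose, normalized by the maximal
attainable area — the exact published DSS variants are not reproduced.

**Evaluation.** For a set of labeled combinations, the proportion test asks
whether inter-cluster combinations enrich the high-benefit corner beyond a
null probability p0 = 0.33: a success is efficacy above the third quartile
of *all* combination efficacies and toxicity below the first quartile of all
toxicities (type-7 linear-interpolation quantiles, computed once over the
pooled set). The test is the exact binomial tail of k successes in n
inter-cluster trials (normal approximation available); the same machinery
runs on synergy scores and CR (high on patient material, low on healthy).
Note an arithmetic consequence of the pooled-quantile convention: at most
⌈n_total/4⌉ records can exceed Q3, so with 16 inter of 28 total the
achievable significance is bounded (min p ≈ 0.26 at k = 7); the convention
is kept because it is the unambiguous reading of the thresholds, and the
reported p-values are honest under it.

## Synthetic data: what it emulates and what it does not

The generators produce every input the pipeline consumes, at the statistical
structure the analysis assumes, so the whole method is testable hermetically.

* **Screen** (`simulate_screen`): patient samples split into two responder
  blocks; cluster-g drugs respond at `base_response + profile_separation ×
  noise_sd` (defaults 0.05 + 6 × 0.08 = 0.53) on block g and at the 0.05
  baseline elsewhere, plus a per-drug potency offset (SD 0.02) and truncated
  Gaussian noise. This block structure — each drug class effective in its
  own patient subpopulation — is exactly the structure the raw inner-product
  projection detects, and it makes inter-cluster combinations genuinely
  better: the Bliss union of complementary profiles inhibits every sample.
  A mere mean-shift between clusters would not survive submatrix extraction
  (the inner product conflates level with pattern, and subset imbalance can
  invert the intra/inter weight ordering). Healthy-sample responses are a
  per-drug attenuation factor ~ Uniform(0, `healthy_attenuation`) times the
  drug's patient-level mean: drugs with low draws are the low-toxicity ones.
  Missing cells are i.i.d. (`missing_rate`); the real screen's missingness
  mechanism is unknown and is certainly more structured (plate layouts),
  so i.i.d. is a convention, and at 20% it is punishing: the maximal
  complete submatrix of a 50 × 40 screen is only ~12 × 12.
* **Target map**: proteins split into two pools; each target of a cluster-g
  drug comes from pool g with probability `bias` (default 0.9; 0.5 = no
  structure, 1.0 = exclusive pools).
* **Fingerprints**: each cluster has a random density-0.5 seed pattern;
  members flip every bit with probability q = (1 − √(2s − 1))/2, making the
  expected intra-cluster Dice exactly s (default 0.8) while inter-cluster
  Dice stays at 0.5, the independent-fingerprint baseline. Targets s < 0.5
  fall back to unstructured fingerprints of density s, with a warning.
* **Surfaces**: monotherapies follow specified Hill curves exactly (plus
  optional replicate noise); combination cells equal a chosen null model's
  expectation (Bliss independence, HSA max, dose-additive sham self-pair, or
  capped response-additivity) plus a planted `shift_delta`, truncated to
  [0, 1]. A noise-free surface therefore scores exactly zero under its own
  model — the basis of the null-model acceptance checks — and truncation
  means a planted shift is only recovered exactly while the shifted
  expectation stays within [0, 1].

What passing tests on these generators shows: the algebra, the statistics,
and the end-to-end plumbing are correct, and the pipeline recovers planted
structure at realistic signal-to-noise. What they do not show: performance
on real screens, whose noise is not Gaussian or i.i.d., whose missingness is
structured, whose drug classes are neither two nor disjoint, and whose
toxicity is not a scalar attenuation.

## Key parameters

| Parameter | Default | Meaning |
|---|---|---|
| normalization scope | global | one min–max over the whole screen |
| Louvain resolution / seed | 1.0 / 0 | modularity granularity; reproducibility |
| PPT thresholds | ±ln 2 | preferential-targeting score cutoffs (strict) |
| G-set bounds | ≥3 in / ≤2 out | exclusive target sets |
| selection fraction / cap | 5% / 4 per cluster | candidate-drug rule |
| dose grid | 1–10⁴ nM, half-log ×2 | five-dose combination design |
| p0 | 0.33 | proportion-test null success probability |
| DSS activity threshold | 0.10 | inhibition floor for the sensitivity AUC |
| screen spec | 40+10 samples, 20+20 drugs, d=6, σ=0.08, 20% missing | default study conditions |

The demonstration configuration `pipeline.screen_scale_config()` scales the
screen to ~200 samples × 624 drugs with 1% missingness, the regime where the
complete submatrix retains a few hundred drugs, the 5% rule yields ~12
candidates, and a 4-per-cluster selection with 16 + 12 combinations emerges.

## Numerical choices and degenerate inputs

* Hill fits run in log10-EC50 parameterization with box bounds (effects in
  [0, 1], slope in [0.05, 20], EC50 within ±3 decades of the dose range);
  constant responses yield a flagged degenerate fit rather than an error.
* Loewe inversion brackets y inside the intersection of both drugs'
  achievable ranges; single-agent dose pairs (x = 0) short-circuit to the
  monotherapy response.
* Quantiles are type-7 (linear interpolation) throughout; with 28
  combination records Q1/Q3 depend on this convention, so it is fixed and
  stated.
* All randomness flows from explicit integer seeds (NumPy `default_rng`);
  pipeline child seeds are derived deterministically from the master seed.
  The pipeline run report embeds a manifest sufficient to reproduce a run
  bit-identically.
* Degenerate statistical inputs (zero-variance similarity groups, empty
  selections, a sample class deleted by extraction, single-cluster
  selections) degrade gracefully: the affected stage is skipped or reports
  p = 1 with a flag, and the manifest records why.

## Known limitations

* The greedy submatrix heuristic is not optimal; on adversarial patterns it
  can be arbitrarily far from the maximum (tests bound it only on small
  random instances).
* The median edge filter can fragment a dominant cluster when cluster sizes
  are very unbalanced (it then cuts into the large cluster's weakest
  internal edges); at the default small-screen conditions this puts planted-
  partition recovery at ~95%, with failures concentrated in replicates where
  i.i.d. missingness leaves a ~12×12 submatrix or deletes one responder
  block entirely.
* ZIP is a documented approximation (conditional refits, two-direction
  average), not the full potency-shift model; no numeric parity with any
  web service is claimed.
* The t/Wilcoxon homogeneity p-values ignore pairwise dependence; use the
  permutation p-value for inference.
* Efficacy/toxicity are scalar summaries; no dose optimization, no cell
  subpopulation modeling, no mutation covariates.
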