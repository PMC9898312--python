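# Methods

This note describes the statistical model behind `pathnet`, the defaults it
ships with, the design choices that were genuinely open, and what the
synthetic studies do and do not demonstrate.

## Gene-wise statistic and its shape

The per-gene input is a differential-expression p-value p_i ∈ (0, 1] per
condition (e.g. time point after a stress treatment). The gene-wise
statistic is t_i = −log₁₀(p_i). Exact zeros are clamped to a floor
(default 10⁻³⁰⁰) with a logged warning rather than rejected, since upstream
tools occasionally emit them. Under a global null (p ~ Uniform), t_i is
exponential with mean 1/ln 10, so the genome-wide score distribution is
right-skewed even without signal; true expression change pushes the right
tail further out. Distribution asymmetry is summarised by the population
moment skewness g₁ = m₃ / m₂^{3/2} with no small-sample correction —
sample sizes here are in the thousands, where the correction is
negligible; the brute-force moment definition is what the tests pin down.

Single-gene significance uses a strict cut t_i > τ (default τ = 3, i.e.
p < 10⁻³): genes sitting exactly on the line are not flagged.

## Competitive test

The hypergeometric over-representation test asks whether the candidate
list is concentrated inside a pathway relative to the measured universe.
The background is always made self-consistent before testing: pathways are
intersected with the score table's gene universe (L = genes measured in the
condition), the candidate list is restricted to that universe (M), and the
pathway size (S = N_G) and overlap (g = N_FT) are counted inside it. The
p-value is the exact upper tail P(X ≥ g) of Hypergeometric(L, S, M),
evaluated with scipy's log-space survival function; g = 0 returns exactly 1.
Because the resolved background is an analysis choice with no single right
answer on real data, L and M are logged per condition in the run manifest.

## Self-contained tests

SUMSTAT and SUMSQ score a pathway by ES = Σ t_i and Σ t_i² over its
members, ignoring genes outside the set except as permutation material.
Since only gene-level summary statistics are available (no per-sample
expression), the null is gene-label resampling: B uniformly random gene
sets of the same size drawn without replacement from the score universe.
Nulls are cached per (condition, set size) and shared across pathways of
equal size — the distribution is identical, and the cache is what makes
200-pathway runs cheap. Each cached draw yields both statistics at once.

Three quantities are reported per pathway:

* **p_empirical** — the add-one estimator (1 + #{ES_null ≥ ES}) / (B + 1),
  never zero, floor 1/(B+1);
* **normalized_ES** — z = (ES − mean(ES_null)) / sd(ES_null) (sample sd);
* **p_asymptotic** — the standard-normal upper tail of z.

**Calling rule.** The significance call uses p_empirical, except when fewer
than 10 permutations reach the observed ES: an empirical estimate with b
exceedances has relative error of order 1/√b, so below b = 10 the estimate
cannot support decisions at thresholds like 10⁻⁴, and the asymptotic
normal-tail p takes over (reported in the `p_value` column alongside both
ingredients). This is how the package reconciles a strict genome-wide
threshold of 10⁻⁴ with finite permutation budgets; it is the package's own
resolution of an ambiguity inherent in reporting permutation p-values far
below 1/B. The asymptotic tail is approximate for skewed nulls, so
borderline sub-resolution calls should be read with that caveat; both raw
quantities are always in the output.

A pathway identical to the whole universe has a degenerate (constant)
null; its z is reported as missing and the call falls back to the
empirical p (which is 1 by construction).

**Multiple testing.** BH and Bonferroni adjustments (via statsmodels) are
attached per method × condition table. Following the study design this
implements, the primary call is the raw threshold 10⁻⁴; the BH-at-0.05
column is reported alongside, not used for the consensus.

**Consensus.** Per method, a pathway is a consensus hit when it passes the
threshold in every condition (configurable to "any condition"). Pairwise
method intersections are emitted; the hypergeometric ∩ SUMSTAT set is the
one the downstream network step consumes, mirroring the workflow this
package reimplements.

## Permutation engine

All randomness flows from one non-negative integer seed. Per-(condition,
set size) streams are derived with numpy `SeedSequence` spawn keys
(seed, crc32(condition label), size), so results are independent of
pathway iteration order and bitwise reproducible across processes. Subsets
are drawn by keeping the first k distinct values of an over-sampled
with-replacement draw — by exchangeability this is exactly uniform over
k-subsets — in O(B·k log k) per size instead of the O(B·L) of shuffling
the whole universe, which is what keeps 50-study power simulations inside
minutes. Member scores are summed in sorted gene-index order so floating
results do not depend on set iteration order.

## Network analysis

The reference interactome is a weighted undirected edge list (functional
log-likelihood scores). Duplicate edges keep the maximum weight; self-loops
are dropped with a warning; gene identifiers are lower-cased and stripped
everywhere, because Glyma-style identifiers are case-inconsistent across
sources.

The analysis network keeps the candidate genes found in the reference plus
every non-candidate adjacent to at least `min_seed_links` candidates
(default 2), recruited as *intermediate* connector genes; candidates absent
from the reference are reported, not silently dropped. This recruitment
rule is a deliberate, parameterised approximation of proprietary
"functional module" expansion tools whose exact algorithms are not
published: it reproduces their connector-hub behaviour (a recruited gene
must tie together at least two candidates) while staying auditable.

Centrality is plain degree — the incident-edge count in the analysis
network, unweighted, because the workflow's published degree ranges are
integers and weights enter only the edge list. The dense core is the set
of nodes whose degree lies in a band (default [20, 30]); band membership
uses parent-network degrees, never degrees recomputed on the induced
subgraph. Low-degree nodes (default degree ≤ 2) can be collapsed into a
single labelled meta-node for display exports; the meta-node records its
members and never participates in key-gene selection. **Key genes** are
the union, over all method-specific networks, of band members that are
candidates; provenance (which network contributed which gene) is kept.

## Group comparisons

Key genes, remaining candidates, intermediates and all remaining genes
partition the universe (candidate status outranks intermediate; key ⊆
candidate is enforced). Pairs of groups are compared one-sidedly on mean
score with a label-permutation test (default 10,000 resamples, add-one p),
chosen over the t-test as the primary method because score distributions
are heavily right-skewed; Welch's t is available as the asymptotic
cross-check. The per-gene two-proportion z table applies the pooled
z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)) to the proportion of conditions in
which a gene clears the single-gene line versus the genome-wide background
proportion — one concrete instantiation of a "binomial proportions"
summary, chosen because it is computable from the pipeline's own outputs.

## Synthetic studies: what they emulate

`SyntheticTruth` defaults describe one study: a 5,000-gene universe, 200
pathways with log-uniform sizes on [6, 300] (log-uniform so the 6–1500
analysis range is spanned without giant sets dominating), 10 planted
enriched pathways, a 144-gene candidate list with prioritisation scores
above the cutoff 42, 4 conditions, and a 300-node interactome with 5
planted hub candidates.

* **Scores.** Background p ~ Uniform(0,1); members of planted pathways
  p ~ Beta(a, 1) with a = 0.1 (stochastically smaller than uniform; the
  planted −log₁₀ scores are exponential with mean 1/(a ln 10) ≈ 4.3).
  Planting is identical across conditions by default, because the
  consensus step requires multi-condition persistence; a `late_onset_ids`
  option keeps chosen pathways null in the first condition to mimic
  responses that switch on later.
* **Candidates.** Planted pathways are chosen among pathways of moderate
  size (window [20, 80]) and each contributes 12 members to the candidate
  list, the remainder drawn from the background. Twelve per pathway makes
  the competitive overlap unambiguous (hypergeometric tail ≲ 5×10⁻⁶ at
  these L, M, S) while keeping 10 planted pathways within a 144-gene list.
* **Network.** The background is preferential attachment truncated at
  degree 15 (attachment weight degree+1 among nodes below the cap,
  m = 3 links per node, mean degree ≈ 7). The truncation is essential:
  untruncated preferential attachment regularly produces background nodes
  above degree 30 at n = 300, which would make the degree band
  meaningless. Planted hubs are wired to a target degree inside [20, 28];
  every recruited background neighbour is guaranteed a second candidate
  link so that seeding recovers it; non-hub candidates are pinned to
  low-degree positions (≤ ~16 after all wiring). Construction therefore
  guarantees band recovery is exactly the planted hub set.

**What passing does not show.** The generator draws gene scores
independently given membership — real expression data have strong
gene–gene correlation within pathways, which inflates self-contained null
variance and would make the reported calibrations optimistic on real data
(the permutation scheme is correlation-naive by design). Pathway
memberships overlap naturally, so a "null" pathway sharing members with a
planted one carries genuine signal; recovery statistics count it as null
regardless. Real annotation bias, identifier mismatch rates, and the
upstream derivation of p-values are out of scope.

## Numerical and degenerate-input choices

* Empirical-p tie comparison uses a relative 10⁻⁹ tolerance so exact ties
  survive summation-order rounding.
* A null sd at rounding-noise level (≤ 10⁻¹² relative) is treated as zero
  variance and raises, rather than producing astronomical z-scores.
* Hypergeometric tail probabilities are floored at the smallest positive
  double to keep them in (0, 1].
* Ranked outputs sort by calling p-value with normalised-ES and pathway-id
  tie-breaks (mergesort), so output files are stable.
* All result tables are written with fixed float formats; a rerun with the
  same configuration and seed is byte-identical.

## Problem sizes used in the shipped studies

The validation suite runs the calibration study at B = 2,000 with one
condition (20 seeds), the power study at B = 2,000 with four conditions
(50 seeds), and the acceptance script one planted pipeline plus a
five-seed null calibration at B = 1,000 — sizes chosen to keep a full
validation run in the minutes range on a single core while leaving the
Monte-Carlo error of every asserted quantity well inside its asserted
band. The package default for production runs remains B = 10,000.

## Known limitations

* SUMSQ is substantially noisier than SUMSTAT when scores are
  exponential-tailed: ES_SUMSQ of a k-member pathway has coefficient of
  variation ≈ √(20/k)/2 under the planted model, so small genuinely
  enriched pathways can draw unremarkable observed scores. In the shipped
  power study SUMSQ accordingly fails to place every planted pathway above
  every null pathway in most replicates, while SUMSTAT and the
  hypergeometric test succeed — consistent with the large sensitivity gap
  between the two self-contained statistics in the study this package
  reimplements.
* The asymptotic normal tail used below the empirical resolution is
  approximate for skewed nulls (see the calling rule above).
* Degree is the only centrality; betweenness/eigenvector measures and
  community detection are out of scope, as is re-deriving interaction
  weights from evidence.
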