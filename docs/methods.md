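# Methods

## Scope and data model

The pipeline analyzes hospital-discharge records, one row per
hospitalization: demographics (sex, age, insurance, admission route,
treatment outcome, length of stay, hospital bed size), a discharge year, a
principal ICD-10 diagnosis, and a possibly empty list of additional ICD-10
diagnoses. A *comorbidity* is any additional diagnosis; the principal
diagnosis is never an item.

Eligibility rules, applied in order with per-rule removal counts: age ≥ 19
years at discharge; discharge year 2006–2016; principal diagnosis in one of
the seven mental-disorder subgroups (F00–F03, F10–F19, F20–F29, F30–F39,
F40–F48, F50–F59, F60–F69). Organic mental disorders other than dementia
(F04–F09), mental retardation (F70–F79), disorders of psychological
development (F80–F89), childhood-onset disorders (F90–F98), unspecified
mental disorder (F99) and all non-F principals are excluded.

## Block classification

Comorbidity codes are reduced to their 3-character category (letter + two
digits; subdivision digits are ignored, so I10.0 and I10 are equivalent) and
mapped to ICD-10 intermediate blocks — contiguous closed category ranges
under the lexicographic (letter, category) order, which lets blocks span a
letter boundary (X85–Y09). The default table is the full ICD-10 block list
with the F00–F09 range split into F00–F03 (dementia) and F04–F09, giving 255
pairwise-disjoint blocks; it is a plain CSV (`start,end,label`) and fully
replaceable, e.g. by a national modification's block list at a different
granularity. Codes falling outside every block are dropped from the
patient's transaction but tallied, never silently lost: silent loss would
corrupt support denominators invisibly.

## Transactions and mining

Each stratum patient contributes one transaction: the set of *distinct*
blocks covering their additional diagnoses. Patients without comorbidities
contribute empty transactions that still count in the stratum size n, so
every support is a fraction of the whole stratum. (Diagnosis-level summaries
such as the mean comorbidity count per patient deliberately do not
deduplicate by block.)

Frequent itemsets come from a from-scratch levelwise Apriori: size-k
candidates are prefix-joins of frequent (k−1)-sets, pruned by downward
closure, counted exactly by enumerating the size-k subsets of each
transaction (cheap: comorbidity transactions are short, ~1–3 items).
An itemset is frequent when count/n ≥ min_support and count ≥ 1; the second
condition matters only at min_support = 0, where zero-count sets are still
excluded. An exhaustive enumerator (`brute_force_frequent`, universes ≤ 20
items) serves as the independent oracle in the test suite.

Rules have a single-item consequent (itemset size ≤ 3, hence antecedents of
1–2 items) and are selected by support ≥ 0.01, confidence ≥ 0.1, lift > 1
(strict). The support floor of 0.01 is a deliberate tightening of "support
> 0": over ~250 candidate items, a strictly positive floor is
computationally and statistically indiscriminate, and every reported rule
of the reference analysis has support ≥ 0.010. All thresholds are
parameters (CLI flags or YAML config).

The ranking key is the IS (interest-support) scale, implemented as
√(support × lift), equivalently the cosine P(AB)/√(P(A)P(B)). Ties break by
descending support, then lexicographic rule label, making the order total
and deterministic. All filtering and ranking use full-precision values;
rounding (half away from zero, 3 decimals for metrics, 2 for percentages)
happens only at output boundaries — IS is computed from unrounded support,
which matters at the third decimal.

## Descriptive statistics

Comorbidity-by-characteristic contingency tables use Pearson's chi-square
*without* continuity correction (the convention the reference tables follow,
including for 2×2); df = (r−1)(c−1). Group-mean comparisons from summary
statistics use Welch's unequal-variance t with Welch–Satterthwaite degrees
of freedom, signed as (group-1 mean − group-2 mean)/SE with group order
(with comorbidity, without). Both wrap scipy.stats. The frequent-block table
counts each patient at most once per block and reports blocks above a
percentage floor (default 1%).

## Synthetic cohort generator

The generator emulates the structure the analysis assumes, not the source
registry itself:

- **Subgroup mix** — categorical over the seven strata; defaults are the
  reference cohort's observed shares (e.g. mood disorders 0.3175).
- **Comorbidity blocks** — each block is a Bernoulli indicator with the
  reference cohort's observed marginal prevalence (35 blocks ≥ 1%, e.g.
  hypertensive diseases 0.1106); blocks are independent except planted
  pairs. A planted pair (A, B; target lift L) is drawn from the 2×2 law
  P11 = L·pA·pB, P10 = pA − P11, P01 = pB − P11, P00 = 1 − pA − pB + P11,
  feasible iff L·pA·pB ≤ min(pA, pB) and P00 ≥ 0 (checked before any
  generation). This keeps the marginals exact and gives closed forms:
  support = L·pA·pB, confidence(A→B) = L·pB, lift = L, IS = L·√(pA·pB).
  Pairs must be disjoint so the closed forms stay exact; higher-order
  dependence can be composed qualitatively from overlapping pairs but has
  no closed form here.
- **Code emission** — a present block is emitted as its start code (block
  membership is all that matters downstream), nudged to the next category
  when it would collide with the principal code. Principal codes are fixed
  representatives per subgroup (F03, F10, F20, F31, F41, F51, F60).
- **Demographics** — drawn independently of everything else from the
  reference cohort's marginal proportions; age ~ Normal(48.3, 17.7²)
  truncated to [19, 99] and rounded; length of stay ~ rounded
  lognormal(μ=2.8, σ=1.1) (median ≈ 16 days with a heavy tail, mean ≈ 36);
  year uniform on 2006–2016.
- **Reproducibility** — one named `numpy` Generator seeded from the
  mandatory config seed; no global state. Same seed ⇒ byte-identical CSV.

`calibrate_marginals` rescales all prevalences by a common factor so the
expected number of comorbid blocks per patient (the sum of prevalences,
under independence) hits a target such as the reference mean of 1.42
comorbidities; it refuses factors that push any prevalence above 1 or miss
the target by more than 5%.

For recovery tests, `lift_standard_error` gives the delta-method standard
error of the empirical lift of a planted pair: treating the 2×2 cell counts
as multinomial(n) and propagating through log lift, Var(log L̂) =
(Σᵢ pᵢgᵢ² − (Σᵢ pᵢgᵢ)²)/n with g = ∂log L/∂p, and SE(L̂) ≈ L·sd(log L̂).
Planted lifts of 1–10 at pA = pB = 0.1, n = 20,000 are recovered within
3 SE; unplanted pairs are consistent with lift 1.

What passing these tests does **not** show: real discharge data have
higher-order dependence among comorbidities, demographic–comorbidity
coupling, within-block code structure, and survey design effects (cluster
sampling, hospital-size truncation) that the generator deliberately omits.
Recovery results validate the mining machinery, not any clinical claim.

## Network export

A ranked rule table is exported as a bipartite directed graph: item vertices
(block id + label) and one vertex per rule (rank-ordered ids r1, r2, …,
carrying numeric `support` and `lift` for downstream sizing/coloring), with
edges antecedent-item → rule → consequent-item. Rule-as-vertex was chosen
over item-to-item edges because 2-antecedent rules have no faithful
item-edge representation. GraphML output is deterministic (items
alphabetical, rules by rank) and written atomically (temp file + rename),
as are all CLI outputs. Layout and plotting aesthetics are out of scope.

## Numerical and edge-case conventions

- Support/confidence denominators must be positive; zero marginal supports
  make lift undefined and raise.
- Empty strata raise, naming the stratum.
- Rule induction requires the frequent collection to be closed downward and
  raises on a missing subset count rather than recomputing it.
- Chi-square rejects tables smaller than 2×2 or with a zero marginal.
- `brute_force_frequent` refuses universes above 20 items (2²⁰ subsets).

## Validation problem sizes

The test suite validates the miner against exhaustive enumeration on 200+
random transaction sets of up to 12 items, and parameter recovery on
synthetic cohorts of n = 20,000 (the reference cohort's order of magnitude);
the full suite runs in well under a minute.
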