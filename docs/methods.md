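# Methods

This note describes the statistical model, procedures, and numerical
choices implemented in `willis-concord`, together with their assumptions
and known limitations.

## 1. Variant classification

Each individual is described by six segment diameters in millimetres:
left/right A1 (anterior cerebral, precommunicating), left/right P1
(posterior cerebral, precommunicating), and left/right posterior
communicating artery (PcomA). A diameter of `0.0` means the segment is
absent (an informative value); a blank/NaN means the measurement is
missing, and classification refuses to run on incomplete records
(`MissingDataError`). All comparisons are strict inequalities.

Rules (all thresholds tunable via `ClassificationRules`):

| Parameter | Default | Meaning |
|---|---|---|
| `hypoplasia_threshold_mm` | 0.8 mm | a segment at or below this is hypoplastic/absent |
| `a1_asymmetry_fraction` | 0.33 | relative A1 difference \|L−R\|/max(L,R) above this is asymmetric |
| `fetal_excess_fraction` | 0.10 | PcomA more than (1+f)× the ipsilateral P1 is fetal |

- **A1 asymmetry**: \|L−R\|/max(L,R) > 0.33. If both A1s are absent the
  ratio is undefined and a `ClassificationError` is raised rather than
  guessing.
- **Incomplete PcomA**: either PcomA < 0.8 mm.
- **Fetal posterior circulation**: on either side, PcomA > 1.1 × P1.
- **Classical**: none of the above fired *and* all six diameters
  > 0.8 mm.

The non-classical variants may co-occur (a profile is a set); classical
is mutually exclusive with everything and the data model enforces that.
A profile may also be empty (no variant fired but some non-PcomA segment
≤ 0.8 mm, e.g. symmetric hypoplastic A1s); see §7.

## 2. Concordance

For outcome *v* and a reference proband carrying *v*, an FDR is
concordant if their profile contains *v*. For the composite "any
variation" outcome the reference proband must have a non-empty profile
and an FDR is concordant if the profiles intersect. Family concordance
is the events/trials pair over the family's imaged FDRs. When pooling
families, the default is the pooled proportion Σevents/Σtrials (each
FDR weighted equally); an unweighted mean of family proportions is
available as `method="family_mean"` but gives small families outsized
influence and is not used by the pipeline.

## 3. Matched resampling design

For each outcome, the index arm is the set of families whose proband
carries that outcome; it is fixed across iterations. In each iteration
every index family draws, uniformly with replacement, a comparison
family from the pool of families whose proband's profile is **disjoint**
from the index proband's (default `pool_rule="disjoint"`; a weaker
`"not-identical"` rule is available). The comparison family's FDRs are
scored against the *index* proband; the comparison proband is never
counted (they are discordant by construction and would bias the
comparison arm downward). One matching per iteration is shared across
all outcomes so outcome-specific results come from the same draws.

Each (index, comparison) pair forms a stratum of two binomials. The
common odds ratio is fitted by exact conditional logistic regression
(§4). Over `n_iterations = 1001` iterations (odd, so the median is an
actual iteration's value), the reported summary per outcome is the
median OR, the componentwise medians of the CI bounds (the median-lower
and median-upper bounds generally come from different iterations — this
is a summary band, not a single fitted interval), and the median pooled
concordances per arm. Iterations where the fit does not converge
(separation) are excluded from the medians; if fewer than half of the
iterations converge the run raises `AggregationError` rather than
reporting a fragile summary. Outcomes with no index families are
omitted from the output.

Randomness: `numpy.random.SeedSequence(seed).spawn(n_iterations)` gives
each iteration an independent substream, so results are bit-reproducible
for a given seed and independent of execution order.

## 4. Exact conditional logistic events/trials model

Stratum *s* has index events/trials (a, n₁) and comparison events/trials
(c, n₂), t = a + c. Conditioning on t eliminates the stratum's nuisance
intercept and yields Fisher's noncentral hypergeometric likelihood in
β = ln ψ:

P(A = a | t) = C(n₁, a) C(n₂, t − a) e^{βa} / Σ_u C(n₁, u) C(n₂, t − u) e^{βu},

with u ranging over max(0, t − n₂) … min(n₁, t). Strata with t = 0 or
t = n₁ + n₂ are uninformative (the conditional distribution is
degenerate) and contribute exactly zero to the log-likelihood, score,
and information; they are filtered out, and their presence or absence
provably cannot change the estimate (asserted exactly in the tests).

Numerics:

- Log-domain throughout: binomial weights via `gammaln`, normalisation
  via `logsumexp`; conditional moments via a vectorised softmax over the
  (padded, rectangular) support arrays. No factorials or raw
  exponentials are formed.
- Newton–Raphson from β = 0 on the score Σ(a − E[U]) with information
  ΣVar[U]; convergence at |score| < 1e-8 or |Δβ| < 1e-10, max 50
  iterations (the concave likelihood makes this generous).
- Separation: if the observed total event count in the index arm equals
  its attainable maximum (or minimum) over informative strata, the MLE
  is +∞ (−∞); the fit reports `converged=False` with infinite `beta_hat`
  instead of iterating to a spurious finite value.
- Wald 95% CI: β̂ ± z/√I(β̂) with z = 1.959964 (the conventional
  4-significant-digit normal quantile, matching standard meta-analysis
  software) — the same z is used everywhere a 95% interval appears.

The implementation was verified against a brute-force oracle (direct
summation of the likelihood with `math.comb` plus dense grid search over
β, step 1e-4) exhaustively for every non-separated single-stratum
configuration up to 6 trials, and against an independent
binary-expansion fit with `statsmodels` `ConditionalLogit`.

## 5. Fixed-effects meta-analysis

Groups enter as (OR, 95% CI) triples. The standard error is back-derived
from the interval width on the log scale, se = (ln hi − ln lo)/(2z),
which assumes the interval was Wald-symmetric in log-OR. Pooling is
inverse-variance fixed effects; heterogeneity is Cochran's Q with
df = k − 1 and Higgins I² = max(0, (Q − df)/Q) × 100, banded as
mild/moderate (≤ 60%) or substantial (> 60%).

Limitation: when the per-group inputs are themselves rounded to one
decimal (as printed tables are), the pooled CI bounds can move by up to
about half a unit in the printed decimal relative to pooling the
unrounded values. The test suite therefore asserts agreement with
published pooled rows to one unit of the printed decimal; the point
estimates and I² agree exactly after rounding.

## 6. Synthetic cohort generator

The generator emulates the *statistical structure* of a family cohort
with CoW imaging, not vascular biology:

- **Family sizes** (imaged FDRs per family) are drawn from an empirical
  distribution whose default is
  {1: 76, 2: 25, 3: 6, 4: 4, 5: 4, 6: 3, 7: 2, 11: 1, 14: 1}
  over 122 families — expectation 237/122 ≈ 1.943 FDRs per family.
- **Marginal prevalences** default to classical 0.18, A1 asymmetry 0.22,
  incomplete PcomA 0.62, fetal PC 0.26.
- **Familial aggregation**: per non-classical variant *v*, each family
  draws a random intercept b ~ N(0, σ_v²) and every member carries *v*
  with probability expit(logit(p_v) + b). `familial_sd` defaults to σ = 0
  for every variant — the null, so that effects in analyses of generated
  cohorts are opt-in rather than baked in.
- **Classical** is derived, not drawn: a member with no non-classical
  variant is classical with probability p_classical / Π_v(1 − p_v)
  (the conditional probability that reproduces the marginal prevalence);
  parameters making that ratio ≥ 1 are rejected (`ParameterError`).
  Members that are neither classical nor variant-carrying get the empty
  profile — interpreted as "complete circle failing the classical
  criteria" (e.g. borderline-hypoplastic but symmetric A1s).
- The first member of each family is the proband; members are exchangeable
  by construction, so this is an arbitrary designation, as in the null.
- **Diameter emission** (optional): each profile is rendered to six
  diameters by constructive sampling (e.g. fetal side: P1 ~ U(1, 2) mm,
  PcomA = P1 × U(1.2, 1.6); incomplete side: PcomA ~ U(0, 0.75) mm;
  empty profile: symmetric A1s ~ U(0.3, 0.75) mm) and verified by
  running the classifier on the result; a profile that fails to render
  in 100 attempts raises `GenerationError` (does not occur with the
  shipped rules). This guarantees simulate → emit → classify is the
  identity.

Not emulated: correlations *between* variants beyond what the classical
derivation induces, measurement error, modality differences,
ascertainment bias, and pedigree structure finer than "proband + FDRs".

The package's own calibration checks (in the test suite) use 200
replicate null cohorts of 122 families with 21 resampling iterations
each — enough replication to pin the null median OR near 1.0 and CI
coverage near 95% while staying fast — and 12 replicate cohorts per σ
level for the monotonicity-in-σ check, which compares medians across
replicates because a single cohort's median OR is noisy.

## 7. Design decisions

- **Disjoint pool rule by default**: the comparison proband should not
  share *any* variant with the index proband, so every comparison-arm
  concordance is with an unrelated configuration; "not-identical" is
  offered for sensitivity analyses but admits partial overlap.
- **Families whose proband has an empty profile** are excluded from the
  resampling analysis (with a logged warning): they can anchor no
  outcome, including "any variation".
- **Exclusion filters** for imaging-quality workflows: records imaged
  with DSA only, CTA with slice thickness > 1 mm, or flagged poor
  quality are dropped; families then lose eligibility if the proband was
  excluded or no FDR remains, and the pipeline logs each drop with its
  reason.
- **CSV round-trips are bit-exact**: results are written with
  `repr(float)` formatting and read with `float_precision="round_trip"`;
  provenance (group label, iterations, seed, pool rule) is stored as
  `#`-prefixed header comments.

## 8. Known limitations

- The Wald CI is poor in near-separated strata configurations; the
  >50%-convergence guard and median-of-iterations reporting mitigate but
  do not remove this.
- Meta-analysis from rounded printed inputs carries the rounding
  propagation described in §5.
- XLSX input is implemented (via `openpyxl`, with `column_map` renaming)
  but exercised only on synthetic files in the test suite, not on any
  external workbook.
- The componentwise-median CI band has no formal coverage guarantee; it
  summarises the distribution of per-iteration Wald intervals.
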