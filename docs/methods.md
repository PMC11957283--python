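# Methods

## The scoring model

The Health Index condenses eight ordinal necropsy/histopathology
parameters into one bounded score. Each parameter takes a score in
{0, 1, 2, 3} and a weight; the weighted sum is normalized by the maximum
achievable sum for the animal's taxon and inverted so that 1 means healthy:

    HI = 1 − Σᵢ scoreᵢ · wᵢ / HImax

Parameter scores and weights:

| parameter | score source | weight |
|---|---|---|
| body | external body condition, excellent→cachectic | 1 (seabird, marine mammal) / 2 (sea turtle) |
| systemic_macro | count of affected systems at necropsy | max weight class of affected systems (1–3) |
| cutaneous | focal→diffuse non-anthropogenic skin lesions | 1 |
| organized | count of systems with old, resolved lesions | scheme-dependent (below) |
| systemic_histo | count of affected systems on histopathology | max weight class of affected systems (1–3) |
| parasitosis | severity of parasite-associated tissue lesions | 1 |
| lymphoid_depletion | lymphocyte loss in lymphoid organs | 2 |
| thyroid | severity of thyroid alterations | 2 |

Count-scored parameters map 0 systems → 0, 1–3 → 1, 4–6 → 2, and more
than 6 (read as ≥ 7, bounded by the 10 defined systems) → 3. Weight
classes rank each system's importance for short-term homeostasis:
1 — reproductive, musculoskeletal, lympho-hematopoietic; 2 — digestive,
respiratory, urinary; 3 — nervous, endocrine, cardiovascular. When several
systems are affected the *highest* class applies. The integumentary system
appears in the ten-system vocabulary but in no weight group; it is
assigned class 1 here, on the reasoning that skin disease already has a
dedicated parameter. An empty system set is given weight 1 by convention,
which is immaterial because its score (and hence value) is 0.

### The two scheme variants

Summing the per-parameter printed weights (organized lesions at weight 1)
gives maxima of 42 for seabirds/marine mammals and 45 for sea turtles, yet
the stated maxima are 48 and 51. The default `paper_consistent` scheme
reconciles this by giving the organized-lesions parameter — the only other
parameter scored by a count of affected systems — the same system-dependent
weights (1–3) as the two systemic-conditions parameters, which reproduces
48/51 exactly. This is the minimal mechanically consistent change, but it
is an interpretation, not settled text: alternative reconciliations (e.g.
cutaneous or parasitosis at weight 3) would also close the 6-point gap.
The `literal_weights` variant (organized fixed at 1, maxima 42/45) is kept
behind `ScoringScheme.literal_weights()` / `--scheme literal` so users can
score under either reading. Both variants keep the sea-turtle maximum
exactly 3 above the seabird maximum (max body score 3 × the weight
difference of 1).

### Missing data

All eight parameters must be assessed. Any missing parameter makes the
result indeterminable (`determinable=False`, `hi=None`, with the missing
parameters listed); a partial HI is never emitted, because dropping a
parameter from the numerator but not the denominator can only raise the
apparent health. Decomposition state (carcass code) is carried on records
but never enters the score; filtering to fresh carcasses (code 2) is an
I/O concern, on by default in `read_records` and the `score` subcommand,
because advanced decomposition makes several parameters unassessable or
unreliable.

### Numerics

HI is computed in double precision and serialized to 4 decimals; the
scoring core is exact integer arithmetic until the final division, so test
comparisons use absolute tolerance 1e-9. Ordinal scores outside 0–3,
unknown organ systems, and unknown taxa are validation errors (rejected at
I/O with row-level diagnostics, or raised by `compute_hi`), never coerced.

## Cohort statistics

- **Summaries** report n, arithmetic mean, sample standard deviation
  (n − 1 denominator; a singleton group reports 0 with `sd_defined=False`
  rather than failing), min, max, and skewness.
- **Skewness** is the Fisher–Pearson standardized moment coefficient
  g1 = m3 / m2^{3/2} with population (n) moments, the form the g1 symbol
  denotes. It is undefined (error, or NaN inside summaries) for n < 3 or
  zero variance.
- **HI categories**: the five printed bands <0.20, 0.20–0.39, 0.40–0.59,
  0.60–0.79, 0.80–1.0 are implemented as half-open intervals
  [0, 0.20), [0.20, 0.40), [0.40, 0.60), [0.60, 0.80), [0.80, 1.0] — HI is
  continuous, so two-decimal labels are read as interval edges, with the
  top bin closed.
- **Kruskal–Wallis** uses the tie-corrected H (mid-ranks; correction
  1 − Σ(t³−t)/(N³−N)) with a χ²(k−1) p-value, delegated to
  `scipy.stats.kruskal`. The degenerate all-values-identical case returns
  H = 0, p = 1 instead of erroring.
- **Dunn's post hoc test** is implemented in-package (no maintained
  reference implementation is among the dependencies): for each pair,
  z is the mean-rank difference over
  sqrt((N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/nᵢ + 1/nⱼ)) with two-sided
  normal p-values. The default reports *raw* p-values (the convention
  matched by "p < 0.05"-style reporting); Bonferroni and Holm adjustments
  are available and delegated to `statsmodels.stats.multitest`.
- **Parameter contributions** average each parameter's weighted value per
  HI category; body-score values are divided by the taxon maximum (3 or 6)
  first, since body score is the only taxon-weighted parameter.

## The synthetic cohort generator

No public per-record generative model exists for stranding necropsy data,
so validation uses a latent-trait simulator of the package's own design.
Each animal draws a morbidity level m ~ Beta(a, b) on [0, 1]; defaults
Beta(2, 5) make morbidity right-skewed (most carcasses moderately ill),
which produces the bounded, *left*-skewed HI distributions (g1 < 0) seen
in real cohorts. Observables derive from m:

- **Ordinal parameters** use a cumulative-threshold model: the category is
  the number of thresholds (defaults 0.25/0.5/0.8, per parameter) at or
  below m, then with probability `ordinal_noise` (default 0.1) the
  category shifts ±1 (equal odds; shifts off the 0–3 range are dropped, so
  boundary categories keep that mass).
- **System sets** include each of the 10 systems independently with
  probability `system_inclusion_base · m` (default base 1.2, clipped to
  [0, 1]), halved for weight-3 systems (`weight3_factor=0.5`) — critical-
  system involvement is rarer than digestive or musculoskeletal findings.
- **Vet ratings** threshold m at cutpoints 0.35/0.65 into good/fair/poor,
  then move to an adjacent category with probability `vet_noise`
  (default 0.15), emulating inter-rater disagreement.
- **Taxon mix** defaults to 61% seabirds, 34% sea turtles, 5% marine
  mammals, the approximate composition of a large multi-year
  beach-monitoring cohort; `missing_rate` (default 0) knocks out
  individual parameters to exercise the indeterminable path.

All randomness flows through one `numpy` generator seeded from
`SimConfig.seed`; identical configs give identical cohorts. Under the
defaults the simulated HI has mean ≈ 0.70 with g1 ≈ −0.66 and Spearman
correlation ≤ −0.8 between latent morbidity and computed HI; a cohort of
n = 300 separates the three rating groups under Kruskal–Wallis at α = 0.05
with power above 0.9.

What the simulator does *not* emulate: species-specific pathology profiles,
correlations between specific parameters beyond the shared latent trait,
decomposition codes other than fresh, and spatial/temporal stranding
structure. Passing simulation tests therefore show that the pipeline
recovers a monotone latent health signal and separates rating groups under
a plausible noise model — not that real cohorts meet these effect sizes.

## Test and validation sizes

Scoring is cross-checked against an independently coded brute-force
evaluation over all 4⁵ ordinal combinations crossed with structured small
system sets, and the analytic HImax against brute-force maximization over
an enumerated record space (extreme scores × {empty, 7-with-critical,
all-10} system sets, plus seeded random records in the acceptance script).
Rank statistics are cross-checked against from-scratch rank-sum oracles on
seeded instances with pooled N ≤ 12, where ranks are enumerable by hand.
Stochastic properties use fixed seed lists: Spearman recovery on n = 2000
cohorts, and rating-separation power over 200 replicates of n = 300.

## Known limitations

- The 48/51 reconciliation is an interpretation (see above); results under
  `literal_weights` differ by a constant rescaling of the denominator plus
  the organized-lesions weighting.
- Whether the sea-turtle body weight of 2 applies to all reptiles is
  assumed, not stated; the taxon vocabulary is fixed at three labels.
- Dunn p-values assume large-sample normality of mean-rank differences;
  at very small group sizes they are approximate.
- The loose benchmark reader (`read_hi_table`) expects the user to supply
  the externally distributed raw-HI table and silently drops non-numeric
  or out-of-range HI cells; it is for benchmark summaries only.
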