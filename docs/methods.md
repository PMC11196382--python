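# Methods

## Scope and data model

The package operates on four delimited-text table kinds (UTF-8, header row,
comma or tab): plot surveys (plot × species: count, mean height in cm,
percent cover), stage-structured censuses (site × year: total, adult,
juvenile, seedling), paired soil–trait samples, and the result tables it
writes. Validation is total: every malformed input raises exactly one typed
error (schema, validation, parameter or configuration), and the CLI maps
these to exit codes 1/2.

Census cells may be missing ("—", parsed as absent — the stage-sum
invariant applies only when all three stages are recorded) or censored
("<200", parsed as an upper bound rather than a count, because historical
surveys of rare plants often report only a ceiling).

## Importance values

IV = (RA + RH + RC)/3 per species per plot, each component in percent of
the plot total, so IVs sum to 100 within a plot. Relative height uses the
per-species mean height (plant height is what field protocols record per
species); no weighting of height by abundance is applied. The cross-plot
summary uses the population-SD standard error, se = sd_n/√n, because that
is the convention under which the replicated survey table's printed
"Mean ± SE" column is recovered (e.g. IVs 16.66, 1.67, 29.51, 25.07 give
SE 5.31 under sd_n but 6.13 under sd_{n−1}); a `se_convention="sample"`
switch is provided. Species absent from a plot carry IV 0 into summaries.
The "IV > 1 %" cut used to shortlist dominant species is a display filter
only and is never applied before niche computations.

## Niche metrics and the convention split

Levins breadth uses proportions normalized within the species
(p = IV/ΣIV), giving the interpretable range [1, number of plots]. Shannon
breadth defaults to p = IV/100 without renormalization. This asymmetric
pairing is deliberate: recomputation across all 13 rows of the replicated
table shows the printed Levins column is reproduced only under
normalization and the printed Shannon column only under IV/100. The
`consistent-normalized` mode applies normalization to both when internal
consistency matters more than replication.

Pianka overlap is computed directly on IV vectors (the index is invariant
to per-species rescaling, so normalization is immaterial). Zeros are
detected as |O| < 1e-12 — an exact zero occurs precisely when two species
share no plot — never by rounding to 0.00. The overlap census applies its
threshold inclusively (≥): on the replicated published matrix, which
contains exactly one printed 0.50 cell, the inclusive count is 43 of 78 and
the strict count 42; only the inclusive rule matches the published report.

### Known irreproducibilities of the printed tables

Three cell-level checks against the published tables fail by small margins
and are expected to fail: the source computed breadths, overlaps and means
from unrounded importance values, while only 2-decimal IVs are printed.
Concretely: three printed Levins cells differ by 0.006–0.015 from values
recomputed from the printed IVs; five printed overlap cells differ by
0.005–0.10, including one printed 0.00 between two species that share a
plot with positive IVs (an impossible exact zero, evidently a typo); and
one printed mean (6.03) differs by 0.01 from the mean of its own printed
row (6.02). The affected tests assert the intended ±0.005 agreement
faithfully and fail on exactly those cells; all other cells (73/78
overlaps, 24/26 breadths, 25/26 summaries) agree.

## Demography

Aggregation sums counts; stage percentages are rounded half-up to 2
decimals (the convention of the printed tables; two printed parentheticals
are themselves misrounded by one final digit and are compared against
unrounded values within ±0.01). Decline flags compare the two most recent
surveys per site. Against a censored previous value the default policy is
pessimistic — a latest count below the bound is flagged as decline,
matching how a drop from "<200" to 15–30 plants is read in practice — with
an optimistic policy available that never flags against a bound. The
overall flag compares aggregate totals over sites present in both of the
two latest survey years; sites first surveyed in the latest year are
excluded so that discovering a new subpopulation cannot mask or fake a
trend.

## Red-list rule engine

Criteria C and D are encoded from the v3.1 category thresholds
(C: CR < 250, EN < 2500, VU < 10000 mature individuals; D: CR < 50,
EN < 250, VU(D1) < 1000), with strict inequalities so categories flip
exactly at 250/2500/10000 and 50/250/1000. Subcriterion 2 attaches when
continuing decline is asserted; conditions a(i) (largest subpopulation ≤
50/250/1000 by category), a(ii) (≥ 90/95/100 % of mature individuals in one
subpopulation) are evaluated only when the optional inputs are present, and
b (extreme fluctuation) is an asserted boolean — the package does not
attempt the order-of-magnitude fluctuation test on short census series.
Criteria A, B and E need data (rates over three generations, range
geometry, quantitative PVA) that this data model does not carry and are out
of scope. PSESP cutoffs (default: < 5000 mature, < 5 populations) are
policy configuration, not biology, and are exposed as such.

## Redundancy analysis

Both matrices are column-standardized (z-score by default — traits span
counts to centimetres and soil variables span pH units to mg/kg; centring
only is available). Y is regressed on X by least squares; the SVD of the
fitted values gives the constrained axes, with eigenvalues s²/(n−1) and
explained percentages relative to the total variance of standardized Y.
Because fitted values and residuals are orthogonal, constrained plus
residual eigenvalues equal the total variance to machine precision — this
is asserted at 1e-9. The fit requires n_samples > n_explanatory (a
saturated design with an orthonormal basis of the centred sample space is
legal and reduces RDA to PCA of Y, which is the spectral cross-check used
in the tests); the permutation F-test additionally requires residual
degrees of freedom n − k − 1 > 0. Rank deficiency raises an error naming
the dependent columns. Eigenvalues are independently cross-checked against
the vegan implementation in R on a small random matrix.

Forward selection is greedy on added explained variance, with lexicographic
tie-breaking; all variables are selected (no α-to-enter), producing a full
explanation-rate table whose contribution column — added variance over the
variance explainable by the full X — sums to 100. Significance of each
addition uses pseudo-F = added/(residual/(n−k−1)) with permutation of
reduced-model residuals, p = (1 + #{F* ≥ F})/(n_perm + 1), n_perm = 999 by
default (permutation floor 0.001), exactly reproducible under a fixed seed.

The p-value attached to a *selected* variable is the max of several
candidate statistics and is therefore anticonservative under the null —
a property of all stepwise procedures. For that reason the type-I-error
simulation tests the marginal, single-variable permutation test, whose p is
uniform under exchangeability: 200 null replicates (all effects zero,
n = 60, n_perm = 99) must reject at 5 % within three binomial standard
errors. Parameter recovery runs 100 seeded simulations at the default
effect sizes and requires organic matter to be selected first in at least
95 of them.

## Synthetic generators

Each generator consumes one integer seed driving a single
`numpy.random.default_rng` stream; no global state.

*Community*: 62 species × 4 plots by default, per-species Bernoulli plot
occupancy 0.5 (conditioned on ≥ 1 occupied plot), counts as rounded
lognormals (log-mean 1, log-sd 1 — heavy-tailed, matching importance values
spanning ~0.8 to ~30 %), truncated-normal heights around 30 ± 12 cm, and
per-plot Dirichlet cover fractions scaled to percent. *Census*: totals
decline by binomial thinning at the requested expected rate; stages are
multinomial with default fractions 23/72/5 % (adult/juvenile/seedling, the
juvenile-dominated, recruitment-limited structure of the motivating
census). *Soil–traits*: 60 samples by default; organic matter uniform over
≈44–118 g/kg (the span of the motivating site means), pH in a narrow
slightly-alkaline band (7.9 ± 0.15), eleven nuisance soil variables at
realistic baselines; every trait loads positively (loadings 0.6–1.4) on one
latent axis driven by standardized OM (effect +1 SD/SD by default) and pH
(−0.4), plus weak random nuisance effects (sd 0.05) and noise (sd 0.5).
Effects are parameterized on the standardized scale because traits span
three orders of magnitude in raw units; since the ordination z-scores
everything, this changes nothing downstream.

What the generators deliberately do not emulate: spatial or temporal
autocorrelation, site-level blocking of soils, observation error in counts,
and trait integer-ness. Passing recovery tests therefore show the methods
work when their assumptions hold, not that field data meet those
assumptions.

## Problem sizes and numerics

Default analyses run in seconds on one core: the full 13-variable forward
selection with 999 permutations on 60 samples takes under ten seconds; the
test-suite simulations use 99–199 permutations and stop selection early
where only the order matters. Table replication rounds half-up to 2
decimals; all replication comparisons are made on unrounded values at
±0.005 (±0.01 for census percents). Degenerate inputs — all-zero plots,
all-zero IV rows, constant columns under z-scoring, single-year censuses,
empty year selections — raise typed errors rather than NaNs.
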