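# Methods

This note documents the statistical procedures, the conventions behind
them, the synthetic-data model, and the choices made where the design was
genuinely open.

## Inputs and name matching

The unit of analysis is the canonical binomial of a regional checklist.
Accession and survey taxon labels are matched **exactly** against those
binomials after whitespace/case normalization, optionally routed through a
user-supplied `old_name → accepted_name` synonym table; no fuzzy matching
and no external taxonomic backbone are used. Infraspecific names (var.,
subsp., f.) are folded into the parent binomial and counted in the load
report. Accession rows whose taxon cannot be resolved are retained,
flagged `UNRESOLVED`, excluded from every statistic, and always counted
(`resolved + unresolved + skipped == input rows` is asserted at load
time). Rows with unparseable dates are skipped and listed.

Determination qualifiers follow standard floristic usage: *aff.* marks a
record reliable only to genus; *cf.* is a tentative determination
attributed to the suggested species; *sp.*/bare genus names are
indeterminate genus members; single tokens ending in `-aceae` are
family-level determinations.

"Threatened" means IUCN classes VU, EN, CR, EW or EX; "endemic" (for the
priority index and the core-barcode contrast) means the regional or local
endemism class.

## Coverage and evenness

A taxon is *covered* when at least one resolved accession of a marker in
the chosen set (default: all ten regions) maps into it. Proportions are
kept at full precision internally and rounded only at report time — whole
percent for checklist-coverage tables, one decimal for survey summaries.

Pielou's evenness for a marker at a taxonomic level is
`J = (−Σ pᵢ ln pᵢ) / ln S` with `0·ln 0 := 0`. **All** `S` checklist taxa
at the level enter the denominator, including taxa with zero sequences.
Many ecology texts use only observed taxa; the all-taxa convention is
deliberate here because the statistic is meant to measure how evenly
sequencing effort covers the *whole flora*, not the sequenced subset. `J`
is undefined (reported as absent) when `S < 2` or no sequences exist.

Known inconsistency: with the checklist size as denominator, per-marker
species percentages differ by a few tenths of a percent from some
published figures for this kind of table, whose denominator is not
recoverable; the checklist-size convention is used throughout and the
percentages are treated as descriptive only.

## Survey coverage

Per survey and level L ∈ {species, genus, family}, coverage is the number
of individuals whose determination is usable at L (match level ≥ L) and
whose matched taxon is covered, divided by **all** individuals in the
survey. Records not identifiable at L (at species level: *aff.*, *sp.*,
family-level and unknown determinations) stay in the denominator, so
species-level coverage is conservative; their share is reported separately
as `proportion_unidentified`. This construction makes coverage monotone
non-decreasing from species to genus to family, which the tests assert for
every survey.

Across-survey summaries report mean, median, range, and a 95 % CI of the
mean by seeded percentile bootstrap (10,000 resamples; default seed
20180101, overridable). The bootstrap was chosen because per-survey
coverages are bounded proportions with no distributional form worth
assuming.

## Representation flags

For each family (or genus), `delta = share of checklist species − share of
barcoded species`; deltas sum to zero by construction (asserted to 1e-12).
A Cauchy distribution is fitted to the deltas by numerical maximum
likelihood (scipy), initialized at (median, IQR/2); an all-identical
sample raises a degenerate-fit error. The "confidence intervals" used for
flagging are **central quantile intervals of the fitted distribution**,
`location ± scale·tan(π(q − ½))`, not sampling CIs of the MLE — flagging
which taxa fall in the tails only makes sense as distribution quantiles.
Flags are two-sided: beyond the 95 % interval → strongly under/over;
between the 90 % and 95 % bounds → under/over; else typical. Positive
delta = underrepresented (more flora share than barcode share). The whole
procedure is location-scale equivariant, which the tests check.

## Priority index

`P = p₁ + p₂ + p₃ ∈ [0, 3]` per family, where `p₁` is the fraction of the
family's species without any barcode, `p₂` the fraction of its
*threatened* species without barcodes, and `p₃` the same for its *endemic*
species. Components with empty denominators (no threatened/endemic
species) are 0. This reading of the component definitions is an
assumption — the exact published formula for the latter two components is
not recoverable — and is isolated in a single function
(`representation._priority_components`) for easy revision. Ranked reports
break ties alphabetically by family. Priority is defined at family level
only. Tree annotation writes `[&P=…]` comments on tips via dendropy and
reports families missing on either side without failing.

## Accumulation and saturation

Accessions are binned by trimester (calendar quarter, January-anchored —
the natural reading of quarterly grouping) because sequence archives
release accessions in bursts. For taxon series, a taxon accumulates at
the quarter of its *first* accession of any of the ten regions. Fits
default to starting at 1995Q3, after the sparse earliest years.

Sequence growth: `N(t) = N₀ e^{rt}` by nonlinear least squares
(scipy `curve_fit`); doubling time `ln 2 / r`. Taxon growth: logistic
`N(t) = a/(1 + c e^{bt})` with `a` **fixed** at the known checklist total,
free parameters (b, c) only, initialized at `c = a/N(t₀) − 1, b = −0.05`,
with bounds enforcing the growth convention `c > 0, b < 0` (the formula
admits mirrored parameterizations). Noise-free generated series are
recovered to machine precision; seeded noisy series recover `b` within
10 % (tested).

Saturation is the quarter where the fitted curve reaches `a − 0.5` — the
last whole taxon, matching the "100 % of taxa" reading rather than an
arbitrary 99 % threshold — solved in closed form
`t* = ln((0.5/(a − 0.5))/c)/b` and converted back to a calendar year.
Projected years on synthetic data validate the machinery only; real-data
projections require the real accession time series.

## Endemism regression

The response is the number of **distinct** marker regions with ≥ 1
sequence per species (0–10 for the full set) — not the raw sequence
count, which is dominated by a few massively resequenced species. The
model is NB2 negative binomial regression (`Var = μ + μ²/θ`, θ by MLE via
statsmodels) on the distribution-class factor with the widespread class
as reference. In this saturated one-way design fitted group means equal
observed group means (asserted to 1e-4). Significance is a likelihood
ratio test against the intercept-only NB model; `df_model` = number of
class contrasts, with residual df (n − #classes) reported alongside as is
conventional. A θ estimate above 50 raises an equidispersion flag
(Poisson-like data). The rbcL/matK contrast is presence/absence, so it
uses binomial logistic regression (endemic vs other) with its own LRT.

## Synthetic-data model

The generators are first-class, tested code; their defaults are the study
conditions:

| parameter | default | rationale |
|---|---|---|
| species / genera / families / orders | 2097 / 508 / 107 / 36 | regional tree-flora scale |
| threatened fraction | 227/2097 | exact-quota draw |
| local / regional endemics | 237/2097, 493/2097 | exact-quota draws |
| Eastern South-American endemics | 0.30 | not published; a plausible middle class |
| coverage by class | 0.74 / 0.62 / 0.42 / 0.30 | yields 1,214 barcoded species (58 %) with the endemism gradient |
| accessions, local batch | 12,104 (1,611 local, dated 2016-01-16) | library scale; fixed-date local campaign |
| growth rate | 0.063 per trimester from 1993-12 | doubling ≈ every 2.75 y |
| allocation skew (Zipf) | 0.9 | top species > 500 sequences at this scale |
| abundance bias γ | 0.8 | see below |
| surveys × individuals | 135 × 2000 | ≈ 270,000 individuals |
| abundance σ (lognormal) | 1.5 | standard species-abundance choice |
| qualifier fraction | 0.015 | ≈ the typical 1–2 % unidentified share |

Structure: species are assigned to genera (and genera to families,
families to orders) by Zipf-skewed partitions, so a few groups are
species-rich and some are monospecific. Composition counts use
exact-quota sampling rather than Bernoulli draws so fixtures hit their
target totals exactly. Barcoded species are selected per class by
weighted sampling without replacement with weight `abundance^γ`
(Efraimidis–Spirakis keys): sequencing campaigns and herbaria sample
common species first. γ = 0.8 was calibrated once, analytically, so the
expected individual-weighted coverage of the default flora is ≈ 0.89; it
is a generating condition, not a fitted quantity. GenBank submission
times are drawn by inverse-CDF sampling from the exponential-growth
density; markers follow a GenBank-like frequency mix (ITS, rbcL,
psbA-trnH, matK, trnL dominant) with an rbcL/matK/ITS mix for the local
batch. Surveys draw multinomial individuals from lognormally perturbed
regional abundances; at generation time the realized mean coverage is
checked against the analytic expectation (barcoded species' share of
abundance mass) to within 0.03.

What the generator does **not** emulate: spatial structure among surveys,
phylogenetic signal in coverage or abundance, taxonomic synonym churn,
misidentification, sequence quality, or any correlation between endemism
and abundance. Passing tests therefore demonstrate that the machinery is
correct under the stated statistical structure, not that real libraries
behave this way; real-data headline values (coverage percentages, LRT
statistics, saturation years) are expected to differ.

## Numerical conventions and edge cases

- `0·ln 0 := 0` throughout; J absent when undefined, never NaN.
- Cauchy fit requires ≥ 3 distinct-spread values; exponential fit ≥ 3
  points; logistic fit ≥ 4 points and `a ≥ max N`.
- Degenerate inputs (constant series, zero-spread deltas, zero-individual
  surveys, empty checklists) raise typed errors rather than returning
  garbage.
- All randomness (generators, bootstrap) flows from explicit integer
  seeds via `numpy.random.default_rng`; equal seeds give byte-identical
  outputs, which the pipeline tests assert on full report bundles.
- Test and acceptance runs use a ~5× scaled-down flora (400 species,
  2,400 accessions, 25 surveys) for module tests and the full-scale
  bundle in the acceptance script; both complete in seconds.

## Known limitations

- Exact-match name resolution will undercount coverage for floras with
  heavy synonymy unless a synonym table is supplied.
- The priority-index component definitions for threatened/endemic species
  are an interpretation (see above).
- Whether representation flagging should be one- or two-sided is not
  settled; two-sided is implemented.
- Genus-level priority scores are intentionally not computed.
- No rarefaction, discrimination-success analysis, or live database
  querying; sequence records themselves are out of scope — the package
  consumes accession *metadata*.
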