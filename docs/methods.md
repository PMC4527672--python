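# Methods

## Data model

A cohort is a set of subjects — species ∈ {human, bonobo, chimp_central,
chimp_west, rhesus}, environment ∈ {wild_born, captive_born}, sex, optional
age and weight — plus a sparse mapping (subject, biomarker) → measurement.
A measurement is exact, below-censored (`<b`, value under the assay's lower
limit of quantification) or above-censored (`>u`). *Missing* is a distinct
state from censored: a marker not determined in a group is absent from the
mapping and excluded from every test, whereas a censored value participates
with its ordinal information.

Groups are (species, environment) strata with short labels; the default
vocabulary is Rh-DE, B-CD, B-DE, Ch-CG, Ch-SL, Ch-DE, H-DE (species
abbreviation plus ISO 3166 country of origin). The label↔stratum mapping
must be bijective; humans are carried in the captive_born stratum purely to
satisfy that bijection — environments are pooled within species in every
cross-species test, so the choice has no analytical effect.

Files are tab-separated with a declared (never sniffed) layout, long or
wide. Censoring is encoded in the value cell as `<x`/`>x`, optional
whitespace after the sign. Parsing is locale-independent: decimal point
only, and a cell like `1,234` is a hard error rather than a silent
misread. Write→read is the identity, including censor tokens, which makes
cohorts safely archivable as plain text.

## Censored ordering and the rank-sum test

All statistics operate on the censored total preorder

    below(b) < exact(x ≥ b),   exact(x ≤ u) < above(u),

with censored values at one bound forming a tie block and an exact value
equal to a bound ranking above the below-block (it was quantified; the
censored ones were not). This is the only ordering consistent with what a
censored report asserts, and it makes rank statistics well-defined without
imputing numbers. The two-sided Wilcoxon rank-sum test then applies with
midranks and the tie-corrected variance. Implementation detail: the
censored keys are reduced to dense integer codes; for tie-free pooled
samples of total n ≤ 25 the exact permutation distribution is used
(scipy's enumeration), otherwise the normal approximation without
continuity correction. Both the method switch ("auto"/"exact"/
"asymptotic"), the threshold, and the continuity correction are
configurable because published analyses rarely pin down their software's
variant. The inlined asymptotic path reproduces
`scipy.stats.mannwhitneyu(method="asymptotic")` to float precision (a test
asserts this); it exists because the scipy entry point's input validation
dominated runtime in simulation loops.

Two groups falling entirely into one tie block (e.g. all `<1.71`) are a
*degenerate* comparison: p = 1 with a flag, not an error — this happens
routinely for heavily censored markers and must not abort a screen.

Exactness near the significance threshold: by full enumeration of the 8v8
null, the asymptotic p tracks the exact p within 0.009 wherever p ≤ 0.1;
mid-distribution the two can differ by up to ~0.046 because the exact
two-sided p is discrete with atoms up to 0.041. Decisions at α = 0.01 are
therefore insensitive to the variant for balanced medium samples, but exact
agreement of *large* p-values between variants should not be expected.

## Censored quantiles

Quantiles use plotting positions h = q(n+1−a−b)+a−1 over the censored
ordering; the default family is a = b = 1 (linear interpolation of order
statistics, the common type 7), with the other standard continuous families
selectable. Interpolation only happens between two exact order statistics.
If either bracketing value is censored the censored bound itself is
returned (rendered `<b`/`>u`) — no number between `<1.71` and 2.0 is
defensible. Two *different* censored values at the quantile position (mixed
bounds, e.g. `<1.71` next to `<2.5`) raise an error demanding explicit
bound harmonization rather than guessing. Group summaries report n, median,
2.5th/97.5th percentiles and range; the table renderer prints percentiles
for groups with n ≥ 20 and the plain range for smaller groups, matching
clinical reference-table convention.

## Lineage assignment cascade

Candidate lineages are evaluated in leaf-first order (human, bonobo,
chimp_central, chimp_west, then the chimpanzee and great-ape clades) against
the fixed cladogram ((human,(bonobo,(chimp_central,chimp_west))),rhesus);
other topologies can be supplied as newick with named internal nodes. For
each candidate L, with environments pooled within species:

1. pooled L vs pooled ingroup-complement significant;
2. every sibling-level comparison inside the complement non-significant
   (for L = human: bonobos vs chimpanzees);
3. L vs outgroup significant;
4. L vs each complement taxon individually significant.

The first candidate passing all conditions is the category; if several pass
(never observed at these effect sizes, but possible in principle) the
assignment is flagged ambiguous and resolved to the first in order, keeping
the cascade deterministic. Markers passing no candidate are
non-lineage-specific; markers lacking measurements in some species are "not
classifiable", a separate outcome. No outgroup-specific category exists —
polarizing a change onto the outgroup branch would require a second, more
distant outgroup.

Open design points and their defaults:

- **Complement taxon resolution.** "Each species individually" is read at
  species level (chimpanzee subspecies pooled), with a subspecies-resolved
  mode available (`lineage_scope="subspecies"`).
- **Full polarity.** The literal rule only requires L-vs-outgroup
  significance; `full_polarity=True` additionally requires the complement
  NOT to differ from the outgroup.
- **Strict environment mode** additionally requires significance against
  every (species, environment) stratum of the complement; off by default.

The cascade uses only ranks, so assignments are invariant under any
strictly increasing per-marker transform (property-tested) and a shift
shared by the whole ingroup can resolve to the great-ape clade or to
nothing, but never to a single tip (polarity sanity, simulation-tested).

## Environment and sex screens

The environment screen tests wild vs captive conspecifics per marker:
bonobos B-CD vs B-DE; chimpanzees by default subspecies-matched (Ch-SL vs
Ch-DE, both West African), with a pooled-wild alternative (Ch-SL+Ch-CG vs
Ch-DE) selectable. Markers absent from either environment of a species are
untested for that species and never flagged. The robust lineage set is the
lineage-specific markers minus the flagged ones; the complementary report
lists each excluded marker with the species driving the flag.

The sex screen compares males vs females per marker within each group —
wild- and captive-born conspecifics are never pooled in a sex test — and
reports the per-group percentage of significantly different markers. The
percentage denominator defaults to markers actually testable in that group
(both sexes measured); a total-panel denominator is selectable since
published percentages are ambiguous when markers are not analyzed in some
groups.

## Subsampling divergence analysis

For a pair of groups, draw k = 8 subjects per side without replacement,
run the censoring-aware rank-sum per marker, pool p-values over draws and
markers, and compare pooled distributions between group pairs with the same
rank-sum test. Exhaustive enumeration of 8-subsets is infeasible
(C(50,8) ≈ 5.4×10⁸), so draws are seeded random subsamples, n_draws = 1000
by default; the whole procedure is bit-reproducible from the seed. The four
default pairs are {B-CD, B-DE} × {Ch-SL, Ch-DE}: if environment dominates
species signal, the wild–wild pair shows the highest p-values (least
divergence). Degenerate tests are recorded as p = 1 with a flag; draws
leaving one side empty for a marker are skipped and logged.

Note that the null distribution of the pooled p-values is uniform only up
to the discreteness of the 8v8 exact test; its exact Kolmogorov offset from
U[0,1] is 0.081 (enumerated in the test oracle), which is the right
baseline when judging "approximately uniform".

## Synthetic cohorts

The generator draws value = exp(Normal(log-baseline + species shift +
sex shift + captivity shift, σ)) per subject × marker and censors at the
assay bounds, storing `<lloq`/`>uloq` exactly as an analyzer would report.
Log-normality reflects the right-skewed, positive, multiplicative character
of clinical-chemistry markers; a heavier-tailed alternative can be emulated
by enlarging σ. Default design: the study's group sizes (Rh-DE 20, B-CD 50,
B-DE 11, Ch-CG 121, Ch-SL 76, Ch-DE 19, H-DE 312) and sex splits; ages and
weights are generated for schema completeness but not used by the analysis.

Shipped scenarios (σ = 0.5 log-units throughout):

- **null** — 20 markers, no effects; calibrates false-positive behaviour.
- **human_specific_shift** — a bilirubin-like marker: baseline median at
  the LLOQ 1.71 (apes ≈ 86% censored), rhesus shifted −0.5 (≈ 98%
  censored), humans +1.22 (median ≈ 3.4, ≈ 8% censored); plus 4 null
  markers.
- **bonobo_specific_shift** — one marker +1.0 in bonobos.
- **environment_confounded** — a human-shifted marker that also carries a
  +0.8 captivity shift in the apes; the cascade calls it human-specific and
  the environment screen must flag and remove it.
- **environment_only** — no species effects; captivity shifts of +0.8
  (bonobo) and +0.5 (chimpanzee) on every marker, producing the
  wild–wild-least-divergent ordering in the subsampling analysis.

Effect sizes are fixed constants chosen so the cascade recovers planted
categories in ≥ 95% of replicates at the default group sizes (the recovery
rate is itself measured by the test suite). What the generator does *not*
model: correlations between markers (the analysis treats markers
independently anyway), age/weight effects, assay-specific antibody affinity
differences between species, and batch effects. Passing tests on synthetic
cohorts therefore demonstrate the statistical machinery and its operating
characteristics, not the biological claims of any particular dataset.

## Calibration facts used by the tests

Simulation tests compare Monte-Carlo rates against oracle-derived
expectations, not against nominal α blindly: by exact enumeration of the
null U distribution, the asymptotic two-sided test at nominal α = 0.01 has
true size 0.00853 at n = 50 vs 11 and 0.00931 at n = 76 vs 19. Null-screen
flag counts are asserted against these exact sizes (times the marker
count) within 3 Monte-Carlo SE, and the sizes themselves are asserted to
lie within [α/2, 1.5α].

## Problem sizes

The test suite runs its deep simulations at: 500 null replicates for screen
calibration and the cascade's family-wise false-assignment rate; 200
replicates per planted-shift recovery rate; 20 replicates × 250 draws for
the divergence ordering; 200 draws × 20 markers for null uniformity. The
acceptance script uses 100–150 replicates per quantity. These sizes give
Monte-Carlo SEs comfortably below the asserted margins.

## Known limitations

- The censored ordering assumes a single LLOQ per marker per comparison;
  assays with drifting limits need bound harmonization first (mixed bounds
  at a quantile position raise rather than guess).
- No Tobit/likelihood modelling of censored values — ranks only, by design.
- No multiple-testing correction by default (α = 0.01 per test, matching
  the screening character of the analysis); Bonferroni/BH adjustment is
  available as a utility for users who want it.
- The subsampling analysis approximates "all pairwise comparisons" by
  seeded random draws; with n_draws ≫ C(11,8) = 165 for the smallest group,
  draws necessarily repeat subjects heavily, which pools into the intended
  distribution but makes draws non-independent — compared distributions are
  interpreted descriptively, via their rank-sum comparison, not as i.i.d.
  samples.
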