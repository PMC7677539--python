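# Methods

## Data model and filtering

A *bioactivity record* links a compound, a single-protein target, and the
document that reported the measurement, with the document's publication
year. The analysis set is defined by five filters applied together:
publication year inside an inclusive window (default 1998–2017), target
organism (`Homo sapiens`), target type (`SINGLE PROTEIN`), assay confidence
strictly greater than 8 (so only the top confidence score, 9, survives the
default), and presence of standard units. Filtering is idempotent and an
empty result is a warning, not an error — downstream stages accept empty
sets.

Targets are assigned to one of six families by case-insensitive substring
search on the flattened ("/" -joined) protein-class description path, using
the fixed keyword order `kinase`, `7tm1`, `transcription factor`,
`protease`, `ion channel`, `transporter` (mapping to kinases, GPCRs,
nuclear receptors, proteases, ion channels, transporters). First match
wins, which makes the assignment a deterministic total function even for a
path mentioning two keywords; no match means `other`. Records whose target
has no annotation row stay in the all-target analyses but are excluded from
family/GO/disease aggregations — disease trends across *all* targets
deliberately span more than the six families.

Disease associations carry a curation score in [0, 1]; associations with
score ≥ 0.3 (inclusive) are retained at load time. Scores outside [0, 1]
are treated as a fatal validation error rather than clamped, because they
indicate a malformed table.

## Trend estimation

For each annotation the yearly count of one of five measures (raw
bioactivity count, distinct compounds, distinct documents, distinct
targets, drug-efficacy annotation pairs) is divided by the same measure
over a reference population and expressed in percent. The default
reference population is the entire filtered set; a `six-families`
denominator mode restricts it to records of the six families, which is the
natural base for comparing drug-efficacy annotation shares among the
families. Years in which the reference population is empty are omitted
from the percent series (fitting treats them as missing); a zero count in a
populated year is an honest 0% and participates in the fit.

The percent series is fitted by Huber M-estimation with tuning constant
c = 1.345, solved by iteratively reweighted least squares from the OLS
start, with the residual scale re-estimated each iteration as
`median(|r|) / Φ⁻¹(3/4)`. The scale factor is carried at full precision
(1.482602218505602): with the rounded 1.4826 the fixed point differs from
the reference M-estimator implementations at the 1e-6 level, which matters
for oracle agreement. Convergence is declared when the largest coefficient
change drops below 1e-8 (50 iterations maximum; the fit reports
non-convergence but still returns the last iterate). Years are centered at
the series start, so the intercept is the fitted percent in the first year
and the slope is in percentage points per year. A residual spread of
exactly zero (an exact line, or fewer than three distinct residual values
straddling zero) short-circuits to OLS, which is the IRLS limit there.
Fewer than three distinct years is a refused input, not a degenerate fit.

Significance uses a robust Wald test: the squared ratio of the slope to its
M-estimator standard error, referred to F(1, n − 2). The standard error
follows Huber's large-sample covariance at the converged fit —
`k² · Σψ(r/s)²·s² / ((n−p)·mean(ψ′)²) · (XᵀX)⁻¹` with the finite-sample
correction `k = 1 + p·var(ψ′)/(n·mean(ψ′)²)` — the same form the standard
R/statsmodels robust-regression summaries use, so the p-value can be
cross-checked against an independent implementation. Simulated type-I error
at α = 0.05 on 20-year Gaussian nulls sits near 0.04–0.05 (the acceptance
script recomputes it). For an exact line the p-value is 0 when the slope is
materially nonzero and 1 when the line is flat, with "materially" meaning
relative to the data scale at 1e-12.

A trend is *reported* when p ≤ 0.05 and |slope| ≥ 0.25 pp/year (both
boundaries inclusive). Reported trends are ordered by descending slope with
alphabetical tie-break. Note the statistical consequence of a sharp slope
gate: an annotation whose true slope sits exactly on the gate is reported
in only about half of replicated universes, because the fitted slope is
unbiased and lands on either side with equal probability. Detection (the
p-value condition alone) is still near-certain at realistic counts.

## Class decomposition

A selected GO or disease trend is decomposed by grouping its targets'
records on the class name at a chosen depth of the class path; the default
`auto` depth takes each target's most specific named class, since the
informative classes (JAK-type kinase classes, receptor subfamilies) sit
below family level and path lengths vary. Each class's yearly count is
expressed as percent of that year's total bioactivities, so the displayed
blocks plus the bucket sum exactly to the annotation's overall percent
series. The display rule is evaluated per year: a class is shown iff its
share is at least 30% of the year's largest class share (boundary
inclusive — "less than 30%" defines the bucketed side), so the largest
class is always shown and a class can be shown in some years and bucketed
(into `X_targets`) in others. A depth beyond a target's path length falls
back to its deepest level with a one-time warning.

## Cross-source disease trends

`Dt` is the target-derived document series of a disease: per year, the sum
over the disease's targets of each target's distinct-document count. This
literal summation double-counts a document shared by two targets of the
disease; a `dedupe_documents` switch counts distinct documents over the
union instead. The literal reading is the default because the quantity is
defined as a sum of per-target publication counts; the deduplicated series
is never larger, and the tests pin that ordering.

`Dp` is an external per-disease yearly literature count. A disease enters
the analysis when it has external data in at least 10 distinct years
(boundary inclusive) and appears in the store. In `normalized` mode each
series is divided by its own source's yearly grand total; `absolute` mode
(the default for the causality report) uses raw counts.

Agreement is the squared Pearson correlation over common years (undefined,
and flagged as missing, for constant series). Granger causality is tested
in both directions at lag 1 by default (the lag the analysis is usually
run at; configurable and recorded in the output): for x → y, the F-test of
the restricted autoregression of y against the unrestricted one including
x's lags, `F = ((RSSᵣ − RSSᵤ)/L)/(RSSᵤ/(T − 2L − 1))` on F(L, T − 2L − 1)
with T usable observations. Lagged regression is ill-defined across gaps,
so the test runs on the longest contiguous run of common years and reports
its length. Collinear lag matrices yield flagged missing p-values.
p-values are reported raw, one pair per disease; a Benjamini–Hochberg
column is emitted alongside for users who want an FDR view.

Two permutation nulls calibrate observed r²: *within-series* shuffling
permutes the disease's own Dp across years (1000 reps by default; for
exchangeable series the null mean is exactly 1/(n−1), ≈ 0.053 at n = 20),
while *across-diseases* shuffling draws other diseases' whole Dp series
(500 draws, with replacement when fewer diseases exist, which is logged).
Because every literature count series shares the secular growth of
publication volume, the across-diseases null can sit far above the
within-series null — reproducing that contrast is one of the acceptance
checks.

## Synthetic universes

The generator emulates exactly the structure the analysis consumes, not
the marginal distributions of any real database. A universe is a 20-year
panel (1998–2017) with a fixed yearly total of bioactivities (default
5000/year, the scale at which slope-recovery experiments are run; the
small shared test universe uses 2000/year to keep the suite fast). Each
injected trend specifies an annotation kind (GO term, disease, or a
family's own share), a baseline share, and a slope in pp/year; yearly
counts are drawn *multinomially* over the trends plus a background
annotation, because the analysis normalizes to the yearly total and the
generator must induce that compositional coupling (independent Poisson
counts would not). Share paths are clamped to [0, 1] and a yearly sum
above 1 is a configuration error naming the offending year.

Each trend owns disjoint dedicated targets carrying exactly one
annotation, so every downstream aggregation recovers the generated counts
exactly and the truth manifest (slopes, baselines, realized counts,
per-target family/class/TDL assignments) is checkable stage by stage.
Records are grouped into synthetic documents of about 20 measurements and
compounds are drawn from per-trend pools, giving non-degenerate
distinct-document and distinct-compound series. Disease scores for
injected trends are drawn from a Beta(2, 2) law rescaled to [0.3, 1] so the
score filter keeps them; decoy associations spanning [0, 1] exercise the
filter. TDL categories cycle Tclin/Tchem/Tbio/Tdark over each group's
targets. Everything is a deterministic function of (config, seed).

What the generator does **not** emulate: compound promiscuity, assay size
distributions, annotation sparsity, correlated annotations sharing targets,
or real class hierarchies. Passing parameter-recovery tests therefore shows
the pipeline's arithmetic and statistics are right under the stated noise
model, not that real extracts are this clean.

Coupled series for causality testing: the driver is a rounded, positive
AR(1) around mean 100 (φ = 0.7, innovation sd 20 — count-like magnitudes
with visible autocorrelation), the response is an affine lag-L function of
the driver plus Gaussian noise, floored at zero. The driver is simulated
with L pre-sample values so the coupling holds over every returned year.
External count tables share a common multiplicative yearly growth (default
4%/year) with log-normal disease levels and year noise, plus a grand total
dominated by a background term — the ingredients the across-diseases
shuffle contrast needs.

## Pipeline and reproducibility

`run_pipeline` executes filter → aggregate → fit → select → decompose →
causality → shuffle from one serializable config, writing CSV outputs and
a JSON run manifest (package version, config incl. seeds, per-stage row
counts, dropped-row report). Outputs are written to a temporary directory
and moved into place only on success, so a failed run leaves no partial
outputs; re-running an identical config byte-identically reproduces every
table (pinned by test). Stage outputs are not content-hash cached: runs at
package scale are cheap and a cache would add an invalidation surface with
no benefit the tests could lock down.

Problem sizes used by the test suite and the acceptance script — 200 seeds
for slope recovery at 5000 bioactivities/year, 1000 replicates for the
type-I simulations, 500 seeds for Granger power, 1000/500 reps for the two
shuffle schemes — are chosen so every Monte-Carlo interval is comfortably
narrower than the asserted band while the whole suite runs in well under a
minute on one core.

## Known limitations

- Trends are straight lines in share space; no autocorrelation adjustment,
  changepoints, or shrinkage across annotations. That is the method being
  implemented, not an oversight, but slopes on strongly autocorrelated
  shares should be read descriptively.
- The Granger test assumes contiguous yearly sampling and stationary-ish
  count series; no differencing or stationarity pre-tests are applied, and
  raw counts of growing literatures are not stationary.
- Closely related disease annotations (subtypes, synonyms) are deliberately
  not merged, so disease trends are not independent of one another.
- The multinomial noise model makes annotation shares negatively coupled
  within a year; generators with strong annotation overlap (one target
  carrying many annotations) are out of scope.
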