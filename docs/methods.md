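# Methods

## Setting and data model

The unit of analysis is the province-year. A panel carries, for each of the
31 provincial administrative units of mainland China (Hong Kong, Macao and
Taiwan excluded) and each year of a study window (default 2009–2018
inclusive), the year-end population (persons), the land area (km², constant
over years), and counts of up to four TCM-hospital resource types:
institutions and beds (physical resources), health technicians and
practicing (assistant) physicians (human resources). Provinces are
partitioned into eastern (11), central (8) and western (12) macro-regions;
Chongqing belongs to the western group, and "Xizang"/"Tibet" are accepted
as spellings of the same unit. Densities (per 10,000 people or per
10,000 km²) are always derived from counts, never stored, so population
and area remain the only unit-bearing inputs.

Whether populations are year-end resident or registered counts is a
property of the source, not of the method; the package does not assume
either, and the CSV contract leaves room for a free-text provenance note.

## Lorenz/Gini

For a set of units with base amounts `b_i > 0` (population or area) and
resource amounts `r_i ≥ 0`, units are sorted ascending by density `r_i/b_i`
(ties kept in input order), cumulative shares are accumulated, and the
origin (0,0) is prepended so the sum below spans every segment. The Gini
coefficient is the trapezoid form

    G = 1 − Σ_i (x_{i+1} − x_i)(y_{i+1} + y_i).

Sorting before cumulation is essential — without it the formula is not a
Gini — and the implementation treats it as part of the definition. The
trapezoid form is algebraically identical to the weighted pairwise
mean-difference form `Σ_i Σ_j w_i w_j |d_i − d_j| / (2μ)` with `w` the base
shares, `d` the densities and `μ = Σ w_i d_i`; the test suite checks this
equivalence to 1e−10 on thousands of random instances, plus scale,
permutation and replication invariance, and the closed-form limits `G = 0`
(equal densities) and `G = (n−1)/n` (single holder, equal bases).

Gini values are classified on contiguous bands with cut points
0.2/0.3/0.4/0.5; 0.4 and 0.5 are the conventional warning lines. Regional
tables compute one Gini per region per year across that region's provinces;
a national mode over all 31 provinces is also available.

## Agglomeration degrees

HRAD (share of the resource over share of land area), PAD (same for
population) and their ratio are pure arithmetic on sums. Regional values
are always computed from summed counts, populations and areas — never by
averaging provincial degrees — because only that construction preserves the
exact identities: the area-weighted mean of HRAD (or PAD) over any
partition is 1, and HRAD/PAD equals the unit's per-capita density over the
whole's. The ratio column in report tables is recomputed from unrounded
HRAD and PAD, not copied.

The theoretical fairness criterion (HRAD = 1, or HRAD/PAD = 1) is never hit
exactly on data, so qualitative labels use a band of ±0.05 around 1
(configurable): below → under-served, above → over-concentrated.

## Growth rates

Two definitions of the average annual growth rate are implemented: the
endpoint CAGR `100·((v_k/v_1)^{1/(k−1)} − 1)` (default) and the arithmetic
mean of year-on-year percentage changes. They agree to first order for
small yearly changes (tested). Published yearbook-style headline growth
rates are often not reproducible from rounded table values by either
definition, so report tables record which mode produced their footer row in
the run metadata rather than claiming comparability.

## Synthetic yearbook generator

The generator emulates the statistical shape of the yearbook panels:

- **Populations**: log-normal, median 4.0e7 persons, log-sd 0.5 — the
  right-skewed spread of provincial populations (a few very large coastal
  provinces, small western ones). Each province gets a growth rate drawn
  from N(0.5 %, 0.3 %) truncated at 0, so populations never shrink and
  national totals are monotone whenever resource growth factors are ≥ 1.
- **Areas**: log-normal, median 2.0e5 km², log-sd 1.0, drawn once and held
  fixed (land does not change). The wide dispersion is what makes
  area-based Gini and HRAD values much more extreme than population-based
  ones, as on real data.
- **Densities**: per-capita densities per resource are log-normal with
  dispersion σ (`inequality_level`), median-parameterised so σ = 0
  collapses every province onto the national density. Because the 31
  provinces are a census of units rather than an i.i.d. sample, densities
  are drawn as a jittered stratified quantile sample: stratum midpoints
  `(i − 1 + U_i)/n` are jittered, mapped through the log-normal quantile
  function, and assigned to provinces in random order. Marginals are
  exactly log-normal while each panel's cross-section spans the full
  distribution, so the realized Gini is centred on the closed form
  `G = 2Φ(σ/√2) − 1` instead of carrying the ~`G/n`-sized downward bias of
  an i.i.d. draw through the plug-in estimator. `calibrate_sigma` inverts
  the closed form exactly (`σ = √2·Φ⁻¹((1+G)/2)`).
- **Levels and growth**: first-year national densities per 10,000 people
  (institutions 0.025, beds 3.2, technicians 2.1, physicians 1.25) and
  yearly growth factors (1.05/1.11/1.09/1.06) are set to the magnitudes of
  the published 2009→2018 regional series, so synthetic tables look like
  yearbook tables at a glance.
- **Counts** are density × population, rounded half-to-even
  (deterministic, negligible bias at these magnitudes). The rounding can
  be disabled (`integer_counts=False`) for degenerate-dispersion checks
  where rounding noise would mask exact equality.
- Optional per-region density offsets mimic an eastern-skewed geography;
  they are off by default so statistical tests see an exchangeable model.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring provinces, migration, correlation between population size and
per-capita provision, or the name-level magnitudes of actual provinces.
Passing recovery tests therefore shows the estimators are correct under
the generative model, not that real yearbook values are reproduced.

Note one consequence of the model: σ controls per-capita density
dispersion only, so σ = 0 zeroes the population-based Gini but not the
area-based one (which reflects the population-vs-area mismatch). A fully
degenerate panel additionally needs zero population/area dispersion.

## Pipeline and report conventions

`run_pipeline` loads (or generates) a panel and writes six CSV tables plus
`run_log.json` (config digest, seed, growth mode, table row counts). Table
writes are atomic (temp file + rename) and partially written tables are
removed on failure; stage errors carry the stage name. Display rounding
follows yearbook convention — densities and shares 2 decimals, HRAD/PAD/
ratio 3, Gini 4 — and can be disabled (`round_for_display=False`) to get
full-precision tables; internal computation is always full precision.
Missing resource cells are written as empty fields, never zeros, so a
zero-resource province stays distinguishable from absent data. Column
order puts physical resources before human resources.

CSV round trips are exact: floats are written with shortest-round-trip
formatting and read back with correctly rounded parsing, so
`read_panel(write_panel(p))` reproduces `p` bit for bit.

## Problem sizes used in the checks

Oracle-equivalence checks run on thousands of random instances with up to
12 units; parameter-recovery checks generate 200 replicate 31 × 10 panels
per target Gini (0.1/0.2/0.4) and compare the mean national
population-based Gini (averaged over the four resources in the reference
year) with the calibration target within ±0.02, the Monte-Carlo band at
that replication. These sizes were chosen as the smallest at which the
Monte-Carlo error is clearly below the tolerances being certified.

## Known limitations

- The Gini here is the plug-in (population) statistic with no small-sample
  correction and no confidence intervals; with ~8–12 units per region a
  within-region Gini carries noticeable finite-sample variability.
- Agglomeration degrees are scale-free but not decomposable; no
  Theil/Atkinson decompositions or concentration indices against income
  rank are provided.
- The classification bands are conventions, not inferential statements.
- Geographic rendering (choropleths) is out of scope; tables are the
  output surface.
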