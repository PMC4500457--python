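# Methods

This note documents the models, conventions and design choices behind
`linneangap`, in the order the pipeline runs them.

## Data model

A *description record* is one new-species publication event: species
identifier, calendar year, article, journal (with optional 2-year impact
factor), family, ordered author list with ages at publication (nullable),
and the first author's country/state plus the type locality's ecoregion
(nullable). A *survey dataset* adds the window `[window_start,
window_end]`, the count of species described before the window
(`pre_window_species`, counted from `pre_window_start`, default 1758 — the
start of binominal nomenclature), and optionally a per-family count of all
valid species.

Conventions:

- Species identifiers are unique: one description per valid species.
  Re-descriptions and synonymy resolution are out of scope.
- A partial final survey year is treated as a full sampling period; all
  analyses bin by calendar year, so a window 1990–2014 always has m = 25
  periods, and zero-count years are kept.
- Author ages are opportunistic. Age-dependent statistics use the subset
  with known ages; the no-ages case returns an empty result with a warning
  rather than an error.
- Files are single UTF-8 CSVs (TSV via a dialect flag): leading `#`
  metadata lines, a mandatory header, and the author list nested as
  `id:age;id:age` (empty age = unknown). This keeps a dataset portable as
  one file without a relational schema.

### The survey-margins fixture

The packaged fixture holds the printed marginal totals of the 1990–2014
Neotropical Siluriformes survey (595 species / 402 articles / 252 authors /
43 journals / 1,452 pre-window species, plus the printed per-family counts:
Loricariidae 285, Trichomycteridae 129, Nematogenyidae 0). The underlying
record table was never published, so `margins_to_dataset` fabricates one
deterministically from a seed: marginal totals are reproduced *exactly*
(this is what the downstream estimators consume), while the per-year
allocation, article composition and the remaining 181 species' family
labels are synthetic and seed-dependent. Quantities that depend only on
marginals (rates, family shares, the Jackknife2 chain) are therefore exact;
per-year quantities (the accumulation curve's shape) are not claims about
the real survey.

## Bibliometrics

- Rates divide by window years (species/year), distinct articles
  (species/article) and distinct authors (articles/author). Display
  rounding is one decimal; full precision is kept internally.
- Journal relative weight: `w_j = 100 · (d_j/D) · (d_j/T_j)` with `d_j`
  describing papers in journal j, `D` all describing papers and `T_j` the
  journal's total output. The second factor rewards journals whose output
  is *concentrated* on descriptions independently of their size. `T_j`
  requires an auxiliary journal-output table; without it the weight is
  reported as unavailable rather than guessed.
- Spearman correlation is computed on mean ranks with the large-sample
  p-value (scipy's implementation behind the module surface); constant
  inputs raise a degenerate-input error instead of returning NaN.
- Age groups are decade bins 20–29 … 80–89, with ages taken at each
  publication (one author can contribute to several bins over a career).
  *Production* counts (species, known-age coauthor) pairs per bin;
  *productivity per author* divides by all distinct authors in the
  dataset, *productivity per group* by distinct authors observed in the
  bin — the two divisor conventions a survey report quotes.
- Family sampling classification: the "theoretical line" is the
  origin-anchored proportionality line with slope
  Σ described / Σ valid over the families with known valid counts. Below
  the line (described < slope · valid) = well sampled, above = low
  sampled, equal within a relative tolerance (default 1e-9) = on the line.
  The line's construction is a design choice; proportional allocation is
  the natural null for "equal description effort per valid species".
- Impact-factor stratification (width 0.3 up to 6.7) is a plotting
  convenience only; correlations always use unbinned values.

## Breakpoint regression

The cumulative curve is fitted as two *independent* least-squares segments
in a shared calendar-year coordinate — quadratic before the breakpoint and
linear after, by default (both degrees are parameters). The breakpoint
(first year of the second segment) is chosen by exhaustive scan over all
splits leaving at least `max(3, degree+1)` points per segment, minimising
`SSE_pre + SSE_post`; SSE differences below round-off (1e-9 relative to
the response's sum of squares) count as ties, which go to the earliest
year. There is no continuity constraint: the two printed segment models of
the motivating survey are independent fits, and a free jump lets the
breakpoint absorb genuine regime shifts.

Numerics: segments are solved via `numpy.polynomial.Polynomial.fit`, which
rescales the abscissa internally, so fits are invariant under shifting all
years by a constant; reported coefficients are converted back to the
calendar-year power basis (lowest order first). Predictions use the
scaled-domain representation. `cumulative_at_breakpoint` is the observed
running total at the last pre-segment year — the inventory size when the
new regime began.

## Richness extrapolation

With years as sampling units, description data make every species a
singleton: Q1 = S_obs, Q2 = 0. Jackknife2,

    S_jack2 = S_obs + Q1(2m−3)/m − Q2(m−2)²/(m(m−1)),

then collapses to `3·S_obs·(m−1)/m`, a pure (and admittedly strong)
singleton extrapolation — appropriate here precisely because the sampled
"community" is the pool of species still being discovered. Jackknife1 and
Chao2 are companions for sensitivity reporting; Chao2 uses the
bias-corrected denominator `2(Q2+1)` so it stays finite at Q2 = 0, but on
all-singleton data its `Q1(Q1−1)` term makes it explode quadratically —
report it for contrast, not as an estimate.

The bootstrap SE resamples the m period columns with replacement
(duplicated years count as distinct units), recomputes S_obs/Q1/Q2 on the
species present in the draw and re-applies the estimator; default 1,000
seeded randomizations.

The *richness budget* adds the pre-window described count to the
extrapolated in-window pool: `K = estimate + pre_window`, `described =
pre_window + S_obs`, `remaining = K − described`, with `remaining/K` the
undescribed fraction. On the packaged margins this chain gives
1713.6 + 1452 = 3165.6 total, 1118.6 remaining, 35%.

## Logistic projection

Cumulative descriptions are modelled as a population with carrying
capacity K:

    N(t) = K / (1 + (K/N0 − 1) e^(−r t)),

with t counted from t0 (default: the last observed year). Because N(t)
only reaches K asymptotically, "inventory complete" is crossing `f·K`;
the default `f = 0.995` makes the completion year

    t = (1/r) · ln[(K/N0 − 1) · f/(1−f)]

finite and well-inside the century scale the projections address. f is a
parameter and every report prints it — any such threshold is a convention,
not a fact about the fauna.

Two accounting conventions exist for N0 and are explicit in the API
(`n0_mode`): `window_only` starts the projection from the species
described within the survey window (the convention of the motivating
survey, which pairs N0 = 595 with a K that *includes* the pre-window
backlog), and `described_total` starts from everything described by t0.
`window_only` is the default; it is the convention under which the
published scenario completion years are reproduced. Mixing bases is
conservative (a smaller N0 delays completion), and the choice is reported
in every scenario suite.

The *sigmoidicity score* of a scenario is

    1 − |y_infl − y_mid| / ((y_c − y_start)/2),  clipped to [0, 1],

where y_infl is the inflection year (N = K/2), y_c the completion year,
y_start the first observed year and y_mid their midpoint. It rewards
scenarios whose joined observed + projected curve has its steepest growth
centrally — the classic shape of a completed inventory. Scenario selection
is this documented heuristic's argmax; the suite reports all scores rather
than asserting a single "right" r.

## Synthetic data

The generator emulates the structure of the motivating survey with
defaults fixed once: window 1990–2014; change-point 2004; pre-change
annual intensity `0.923·i + 4.35` (i = years since 1990, the increments of
the survey's printed quadratic cumulative segment, ≈4→17 species/year);
post-change constant intensity 39.92 species/year (the printed linear
slope); family probabilities led by Loricariidae 0.48 and Trichomycteridae
0.22; Zipf-ranked journals (s = 1.1) over the survey's ten most frequent
titles; articles of 1–4 species (the printed per-article range); mean team
size 1.2 growing by 0.07 authors/year (≈2.9 by 2014); author ages from a
three-component normal mixture (30±4, 44±7, 58±7; weights 0.35/0.45/0.20)
with birth years fixed at first appearance so authors age consistently.
Annual counts are Poisson draws from the piecewise intensity; a separate
logistic discovery-process generator produces counts as stochastically
rounded increments of N(t) (integer counts, continuous model in
expectation).

What the generator does *not* emulate: real coauthorship networks,
nomenclatural acts (synonymies, re-descriptions), geographic structure,
or year-to-year autocorrelation beyond the intensity trend. Passing tests
show the pipeline recovers known structure from data of this form — not
that real surveys satisfy the model.

## Problem sizes and determinism

Test and example runs use the survey's own scale (hundreds of records,
25 periods), 50-seed replication for change-point recovery, 1,000-matrix
sweeps for estimator equality and 100–10,000 bootstrap replicates —
seconds on one core. All randomness flows through
`numpy.random.default_rng` seeds; the same seed yields byte-identical
record files and pipeline reports (reports carry no timestamps for this
reason).

## Known limitations

- Jackknife2 on pure description data is the singleton closed form; its
  validity rests on years being exchangeable sampling units of a closed
  pool, which accelerating effort strains. The breakpoint analysis is the
  package's own caveat to that assumption.
- The journal weight needs an external journal-output table that most
  users will not have; it degrades to frequencies, not to a guess.
- A single breakpoint only; no confidence interval on the breakpoint year.
- The projection treats K as known; propagating the Jackknife2 SE into
  completion years is a natural extension hook, not implemented.
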