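# linneangap

Estimate how many species of a taxon remain undescribed — and how long a
complete inventory will take — from the taxon's own description record.

Taxonomists describing a fauna leave a paper trail: each new species has a
publication year, journal, family, author team. `linneangap` treats that
trail as an ecological survey of the undescribed pool and runs the full
chain of analyses a description-effort study needs:

- **Bibliometrics** — description rates (species/year, species/article,
  articles/author), journal and family frequencies, journal relative
  weight, Spearman correlations, author-age production/productivity, and a
  family sampling classification against a proportional-effort line.
- **Breakpoint regression** — the cumulative description curve is fitted as
  two independent least-squares segments (quadratic, then linear) with the
  change-point chosen by exhaustive total-SSE scan, to date shifts in
  description effort.
- **Richness extrapolation** — each calendar year is a sampling unit and a
  species "occurs" in its description year, giving a binary incidence
  matrix; the second-order jackknife
  `S_jack2 = S_obs + Q1(2m−3)/m − Q2(m−2)²/(m(m−1))`
  extrapolates the total pool (Jackknife1 and bias-corrected Chao2 as
  companions, bootstrap SE over resampled years). Adding species described
  before the survey window yields total richness K and the
  remaining-to-describe fraction — the taxon's Linnean shortfall.
- **Logistic projection** — cumulative descriptions grow toward K as
  `N(t) = K / (1 + (K/N0 − 1)e^(−rt))`; for each growth rate r the year of
  crossing `f·K` (default f = 0.995) has the closed form
  `t = (1/r)·ln[(K/N0 − 1)·f/(1−f)]`, and a sigmoidicity score flags the
  scenario whose joined observed + projected curve looks most like a
  completed inventory.
- **Synthetic surveys** — a seeded generator produces record tables with a
  known change-point, skewed family/journal structure, rising team sizes
  and author-age mixtures, so every stage is testable with known truth.

The package ships the marginal totals of a published survey of Neotropical
freshwater catfishes (Siluriformes) described 1990–2014 (595 species, 402
articles, 252 authors, 43 journals, 1,452 species described before 1990)
and can expand them deterministically into a record table with exactly
those marginals.

## Worked example

```python
from linneangap import (
    siluriformes_margins, margins_to_dataset, build_incidence,
    jackknife2, richness_budget, accumulation_curve, project_scenarios,
)

dataset = margins_to_dataset(siluriformes_margins(), seed=1)
matrix = build_incidence(dataset)
budget = richness_budget(jackknife2(matrix), dataset)
print(f"{matrix.S_obs} species over {matrix.m} years -> "
      f"Jack2 pool {jackknife2(matrix).estimate:.1f}")
print(f"K = {budget.K_total:.1f}, remaining {budget.remaining:.1f} "
      f"({100 * budget.remaining_fraction:.0f}%)")

suite = project_scenarios(budget, accumulation_curve(dataset))
for s in suite.scenarios:
    print(f"r = {s.r:4.2f}: complete in {s.completion_year:.0f} "
          f"(sigmoidicity {s.sigmoidicity:.2f})")
```

prints

```
595 species over 25 years -> Jack2 pool 1713.6
K = 3165.6, remaining 1118.6 (35%)
r = 0.05: complete in 2149 (sigmoidicity 0.67)
r = 0.10: complete in 2082 (sigmoidicity 0.84)
r = 0.20: complete in 2048 (sigmoidicity 0.92)
r = 0.30: complete in 2036 (sigmoidicity 0.76)
r = 0.40: complete in 2031 (sigmoidicity 0.65)
r = 0.50: complete in 2027 (sigmoidicity 0.56)
```

Every described species is a singleton (it "occurs" only in its
description year), so Jackknife2 collapses to `3·S_obs·(m−1)/m = 1713.6`;
with the 1,452 pre-window species the total is ~3,166, of which 35% remain
undescribed. Higher assumed description effort r completes the inventory
sooner; the mid-grid rates give the most sigmoid joined curve.

The `examples/` directory has one narrative script per capability;
`linneangap --help` exposes the same stages as a thin CLI
(`fixture`, `simulate`, `summarize`, `accumulate`, `richness`, `project`,
`report`).

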