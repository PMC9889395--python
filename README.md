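# mesobloom

Analysis pipeline for quantifying how viral infection of a coccolithophore
(*Emiliania huxleyi*) bloom redirects carbon, built around mesocosm
time-series data: recursive production–loss models for transparent
exopolymer particles (TEP) and particulate inorganic carbon (PIC), an
infected-cell production multiplier, Bray–Curtis community turnover and
divergence statistics, growth-rate kinetics, dilution-method grazing and
viral-lysis rates, and the assay-level conversions (ddPCR, cell carbon
budgets, carbohydrate-microarray normalization) that feed them.

It is intended for plankton ecologists and biogeochemists analysing
enclosure ("bag") experiments in which several replicate blooms develop
different degrees of infection by the *E. huxleyi*-specific virus EhV, and
for anyone who needs a tested implementation of the underlying estimators
on their own data.  A synthetic-data module generates complete in-silico
experiments with the study's statistical structure, so every stage is
testable without any data download.

## The central model

A bulk extracellular carbon pool C(t) (TEP, PIC, POC or CSP) accumulates
contributions from phytoplankton producers and loses a fixed fraction *d*
per day to degradation and sinking:

    C(t) = (1 − d)·C(t−1) + a_E·E(t) + a_N·N(t) + a_P·P(t)

with closed form C(t) = Σ_{t′≤t} (1−d)^{t−t′} Σ_i a_i X_i(t′).  E, N, P are
the abundances of *E. huxleyi*, naked nanophytoplankton and
picophytoplankton (cells/mL); a_i is the per-cell daily production.  For
PIC the single driver is the positive part of the day-to-day *E. huxleyi*
increment — calcite only accumulates through newly built coccoliths.
Fitting solves a non-negative least-squares problem (a_i ≥ 0, no
intercept) at each *d* on a grid (default 0–0.5, step 0.0025) and keeps
the *d* maximizing R².

To resolve infected from bystander cells, the *E. huxleyi* term is split
into a bystander fraction producing *T* per cell (*T* and *d* fixed from
the least-infected uncovered bags) and an infected fraction f(t) (measured
by single-molecule FISH) producing *I·T* per cell; the multiplier *I* is
chosen on a grid (0–10, step 0.05) minimizing squared deviation from the
observed pool.

Community statistics follow the companion conventions: Bray–Curtis
similarity 1 − Σ|x−y|/Σ(x+y); turnover fitted as
BC(t) = (1−BC∞)·e^{−k(t−t′)} + BC∞ with floor BC∞ = 0.05; cosine k-means
over smoothed mean taxon profiles with silhouette model selection (k =
2–12); Mann–Whitney differential-abundance screens with Bonferroni
correction; dilution-method rates k = ln(C_t/C_0)/t, g = (k_d−k_1)/(1−x),
µ = g (+ v) + k_1.

## Worked example

Simulate a noise-free 7-bag, 24-day experiment and run the full pipeline:

```bash
mesobloom simulate --seed 1 --noise-cv 0 --out-dir sim
mesobloom run-all --data-dir sim --out-dir results
```

which prints

```
wrote synthetic experiment (7 bags x 24 days) to sim
pipeline complete; summary in results/summary.json
infected-cell TEP multiplier I = 4
```

`results/carbon_fits.csv` holds one row per (bag, model) with the shared
loss fraction *d*, per-cell rates and R²; `summary.json` additionally
records the cluster selection, turnover rates, per-bag divergence, growth
rates and the metric-versus-viral-load regressions.  The printed `I = 4`
is the infected-cell TEP multiplier recovered from the two-subpopulation
scan: infected cells in this simulated experiment secrete four times the
TEP of their uninfected bystanders, the generator's planted value.

The worked carbon budget is available directly:

```bash
mesobloom budget
```

```
cell volume: 65.4498 um^3
cell carbon: 14398 fg C/cell
cell loss:   19050 cells/mL/day
carbon flux: 274281 pg C/mL/day (274.281 ug C/L/day)
```

i.e. a 2.5-µm-radius *E. huxleyi* cell carries ~14.4 pg C, and the demise
from 57,000 to 18,900 cells/mL over two days releases ~274 µg C per litre
per day.

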