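# Methods

This note records the models, conventions and design choices behind the
package, in the spirit of a model-description appendix: what is computed,
under which assumptions, and what the synthetic experiments do and do not
establish about real data.

## Production–loss models for extracellular carbon pools

TEP, POC and CSP are modeled as a single bulk pool fed by three producer
groups and drained by a constant daily loss fraction:

    C(t) = (1 − d)·C(t−1) + a_E·E(t) + a_N·N(t) + a_P·P(t),

equivalently C(t) = Σ_{t′=0..t} (1−d)^{t−t′}[a_E E(t′) + a_N N(t′) + a_P P(t′)].

Both evaluations are implemented (`forward_tep(..., closed_form=True)`)
and must agree to 1e-10 relative — this dual-formula identity is the
primary correctness oracle for the kernel.  Producer abundances enter at
the same day *t* (using *t−1* gives equivalent fits, since it only shifts
the kernel by one lag).  The pool starts from the day-0 producer term;
an observed day-0 offset can be supplied instead where real series begin
mid-bloom.

PIC uses a single driver, the positive part of the *E. huxleyi* increment
max(E(t) − E(t−1), 0) (with max(E(0), 0) on the first day): calcite is
only added through newly built coccoliths, so host demise freezes the
modeled pool rather than draining it (loss still acts through *d*).

**Fitting.**  For fixed *d* the model is linear in the rates, so each
candidate *d* is solved by non-negative least squares (active-set NNLS,
no intercept, a_i ≥ 0) against the d-discounted kernels, and the *d*
maximizing R² (equivalently minimizing SSE) is selected; ties break
toward smaller *d*.  The default grid runs 0–0.5 in steps of 0.0025,
bracketing both regimes of interest (fast TEP turnover near 0.12/day,
slow PIC dissolution near 0.0075/day).  R² is 1 − SS_res/SS_tot about the
observed mean and is flagged undefined for an all-zero observation.
Joint fits share one *d* across bags while keeping per-bag rates
(`fit_production_model_global`), reflecting that the loss process is a
property of the water treatment, not of the bag.

**Units.**  Rates carry pool units per (cell/mL) per day: µg XG eq/L for
TEP (numerically pg XG eq per cell per day), µmol/L for PIC (numerically
1e-3 pmol per cell per day held as µmol L⁻¹ (cell mL⁻¹)⁻¹), µg C/L for
POC, µg BSA eq/L for CSP.

## Infected-cell production multiplier

Within an infected bag, the *E. huxleyi* population is partitioned into a
bystander fraction 1 − f(t) producing *T* per cell and an infected
fraction f(t) producing *I·T*.  *T* and *d* come from a baseline fit to
the least-infected uncovered bags; f(t) is the smFISH infected-fraction
series, linearly interpolated onto the model day grid and clipped to
[0, 1].  The prediction is the plain model evaluated on the effective
series E(t)·[(1 − f) + I·f]; at *I* = 1 it reduces exactly to the
baseline model (identity-checked).  *I* is scanned over 0–10 in steps of
0.05, minimizing the summed squared deviation from the observed pool.
The scan step, not stated by any source, is fine enough that the
recovered optimum is grid-exact on noise-free data; f ≡ 0 makes *I*
unidentifiable and raises an error naming the condition.

## Community statistics

* **Bray–Curtis similarity** 1 − Σ|x−y|/Σ(x+y), written out rather than
  delegated so the definition is explicit; it is cross-checked against
  the SciPy dissimilarity in the tests.
* **Turnover**: for each bag, the similarity between the composition at a
  start day t′ and every later day t is fitted by
  BC(t) = (1 − BC∞)·e^{−k(t−t′)} + BC∞ with *k* ≥ 0 and the floor fixed
  at BC∞ = 0.05 (the empirical level at which between-day similarity
  plateaus, maintained by taxa present in every sample; configurable).
  The decaying-exponent convention is used throughout — it is the only
  reading under which similarity declines from 1 toward the floor.  The
  solver is bounded nonlinear least squares warm-started from the
  log-linearized slope, and inverts exactly synthesized curves to 1e-6.
  Since "turnover time" is ambiguous between 1/k and a half-life, the
  fit exposes both `e_folding_days` and `half_life_days` and reports *k*
  itself as the primary quantity.
* **Clustering**: per-taxon profiles are averaged across bags, smoothed
  with a width-2 moving average (trailing-biased centered window;
  shrinking windows at the boundaries keep the series length), then
  L2-normalized so Euclidean k-means orders identically to cosine
  distance.  Candidate counts 2–12 are scored by the cosine silhouette;
  the maximal positive score wins.  Seed 0 and 10 restarts by default —
  determinism given the seed is part of the contract.
* **Divergence**: mean Bray–Curtis distance from a focal bag to all other
  bags at the end day, normalized by the same quantity at each of the
  bloom-onset start days {11, 12, 13}; reported as mean ± sd over start
  days.  Under a bag-exchangeable null the statistic is 1.  For 18S
  matrices the *E. huxleyi* rows should be removed first (the most
  infected bag otherwise diverges trivially through host collapse).
* **Differential abundance**: two-sided Mann–Whitney U (normal
  approximation with tie correction) of the focal bag's demise-phase
  values against all other bags pooled, Bonferroni-corrected across
  tested taxa.  Bonferroni is the default because the screening step
  reports only a handful of taxa and a conservative bound is appropriate;
  the method is switchable in the config.
* **Trait aggregation**: per bloom phase (mixed bloom days 0–9, growth
  10–17, demise 18–23), annotated taxa's relative abundances are summed
  per trophic mode, renormalized over annotated taxa, and averaged over
  samples; heterotroph sub-modes (osmotroph/saprotroph/other) are
  reported as shares within heterotrophy.

## Kinetics

Growth rates are OLS slopes of ln(abundance) against day, repeated with
the window start shifted by −0.5, 0, +0.5 days (snapping to the nearest
twice-daily sample), reported as mean ± sd of the n = 3 fits.  Zero or
missing abundances are dropped, not imputed — the log transform demands
positivity, and an error is raised if fewer than three points remain.
Named window presets encode the per-variable fitting conventions
(thraustochytrids until their maximum; free-living bacteria after day 15;
2–20 µm bacteria after day 10; with per-bag overrides for the early-
demise bags), all overridable.  The biomass-ratio rate is the OLS slope
of log(thraustochytrid:bacteria biomass) from day 10 to the ratio's
maximum; for exact exponentials it equals the difference of the two
growth rates.  Viral-load correlations come in a stratified mode (one
simple regression per cover class) and a pooled mode with an additive
cover-class intercept; both are exposed because the covariate structure
behind "corrected for cover" admits either reading, and they coincide
when the cover classes share an intercept.

## Dilution method

Apparent growth is k = ln(C_t/C_0)/t.  (A published variant prints
ln(C_t − C_0)/t, which is dimensionally inconsistent; the package
implements the standard ratio form and keeps the literal form behind
`literal_log_difference=True` purely for auditing.)  Grazing is
g = (k_d − k_1)/(1 − x) with k_d from the 20% dilution in 0.45-µm
filtrate and k_1 from the nutrient-amended 100% treatment; intrinsic
growth is µ = g + k_1 with the *unamended* k_1.  The ±nutrient 100%
treatments are compared by paired t-test at α = 0.1 and pooled when not
different (zero-variance ties are resolved analytically: all-equal pairs
pool, constant nonzero differences do not).  Viral lysis is the analogous
rate from the paired 100-kDa (virus-free) dilution,
v = (k_TFF − k_FSW)/(1 − x), retained only when those treatments differ
at α; when retained, µ = g + v + k_1.  The synthetic bottle generator is
constructed as the exact inverse of these equations (FSW filtrate passes
viruses, so lysis is undiluted there; TFF dilutes both grazing and
lysis), so noise-free round trips recover (µ, g, v) to machine precision.

## Assay conversions

ddPCR concentrations (copies/µL reaction) convert to cells/mL seawater
through reaction volume × template dilution ÷ filtered volume ÷
copies-per-cell; the copy number derives from genome size via
round(10^(0.6607·log10 G + 0.7508)) — 64 copies for a 40-Mb genome.
Biomass factors: thraustochytrids 1.65e-10 g C/cell, bacterioplankton
1e-14 g C/cell.  The *E. huxleyi* budget treats the cell as a 2.5-µm
sphere at 220 fg C/µm³; carbon values are *truncated* to integer
femtograms (14,398 fg), and the demise flux inherits the same truncation,
reproducing the reference chain 19,050 cells/mL/day → 274,281 pg
C/mL/day.  A negative loss (growing population) is clamped to zero flux
with a warning.  Microarray signals are scaled so the data-set maximum is
100 and zeroed below 5 arbitrary units, after replicate averaging.

## Synthetic experiments

The generator emulates the *statistical structure* of a 7-bag, 24-day
twin-bloom mesocosm: a pico/nano mixed bloom peaking near day 5; an
*E. huxleyi* bloom rising logistically to ~5.7e4 cells/mL (20% lower in
covered bags) and peaking near day 17; exponential demise whose depth
scales from 30% (no virus — nutrient-driven demise) to 90% of peak in the
most infected bag; biomass-associated viral load spanning three orders of
magnitude across bags and rising through demise; bacteria increasing
tenfold during the first-bloom demise with a viral-load-dependent
secondary rise; thraustochytrids appearing only after the host peak with
viral-load-dependent growth; ciliates increasing late in low-virus bags.
Infection fractions follow a scaled logistic through the demise phase,
reaching the per-bag maximum (0.10 and 0.25 in the two smFISH-monitored
bags; exactly zero in the baseline bags) on the final day.  Bulk
chemistry is produced by the package's own forward kernels — with
infected cells producing at `infection_multiplier` (default 4) times the
per-cell rate — plus mean-preserving multiplicative lognormal noise
(default CV 0.1, abundances being positive and roughly log-scaled).
Twice-daily abundance samples (integer days + 0.5-day offsets) exist
solely to support the ±0.5-day shifted growth-rate fits; daily analyses
use the morning sample.

Default per-cell rates are mid-range literature-plausible values: TEP
4.75 pg XG eq/cell/day (so that a fourfold infected rate reproduces the
~19 pg/day scale of infected cells), PIC 1.5e-3 µmol L⁻¹ (cell mL⁻¹)⁻¹
(≈1.5 pmol/cell/day), POC 5 pg C/cell/day (within the 4–6 pg C/cell
range typical of the species), with loss fractions 0.12/day (TEP),
0.0075/day (PIC).

Composition matrices plant six Gaussian-bump succession clusters at
staggered centers (five taxa each, ~4-day spacing, sd 1.8 days) plus,
optionally, an enriched/depleted differential pair in the highest-virus
bag during demise; columns are renormalized to 1 and all taxa carry
trophic annotations.  With the differential pair present the pair
legitimately forms a seventh profile cluster, so planted-6-cluster
recovery uses `differential_bag=None`.

What the generator does **not** emulate: hydrodynamics, nutrient
dynamics, mechanistic virus–host population coupling, compositional
count noise (reads are treated as proportions with lognormal
perturbation), or day-to-day autocorrelated measurement error.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's own assumptions — identifiability, grid-exactness, oracle
agreement — not robustness to real-data misspecification.

A structural consequence worth knowing: because bulk chemistry is
generated *with* the infection multiplier, a plain pooled fit across all
bags (shared *d*) is slightly biased low on synthetic data (the extra
infected-cell TEP is absorbed into the loss term).  The baseline-bags fit
and the two-subpopulation scan recover the generating parameters exactly;
this mirrors the motivation for the infected-subpopulation model in the
first place.

## Numerical conventions and degenerate inputs

Moving averages use shrinking windows at boundaries (length-preserving);
even widths bias the window one point to the left, so width 2 averages
each point with its predecessor.  Replicate measurement rows are averaged
on read; conflicting units are an error.  Measurement tables round-trip
through CSV losslessly (17 significant digits).  Composition
normalization is idempotent; zero-sum samples are an error naming the
sample.  All-zero turnover decay, identical cluster profiles, f ≡ 0
infection, zero modeled pools and zero-variance predictors are each
detected and either flagged or raised explicitly rather than returning
silently wrong numbers.

## Problem sizes

The default experiment is 7 bags × 24 days (168 chemistry observations
per pool), 32 taxa × 168 composition samples; the d-grid has 201 points
and the I-grid 201 points.  The full test suite, including 100 noisy
differential-screen replicates and 1,000 kernel-equivalence instances,
runs in well under a minute on a single core.
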