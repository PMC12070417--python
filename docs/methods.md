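# Methods

`fticrdom` characterizes dissolved organic matter (DOM) from centroided
negative-mode ESI FT-ICR MS peak lists.  This note records the models,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer
would want to know.

## Scope and data model

The ingestion boundary is a centroided peak list — CSV rows of (m/z,
intensity) — plus a manifest carrying per-spectrum metadata (site,
collection date, sample/blank type, acquisition date).  Everything
upstream (transients, apodization, peak picking into centroids) is
instrument-vendor territory and is out of scope, as are isotopologue
patterns, multiply charged ions and adducts other than [M−H]⁻.

The chemical universe is neutral CHNOS molecules.  Phosphorus is
excluded deliberately: P-containing molecules ionize poorly in
negative-mode ESI of natural organic matter and admitting P inflates
false assignments; the aromaticity-index denominator's P term is
therefore always zero.

Element constants ship in one plain-text table
(`src/fticrdom/data/elements.tsv`): monoisotopic masses (IUPAC 2021)
for all mass-spectrometric arithmetic, conventional standard atomic
weights for bulk elemental-analysis (weight-percent) arithmetic, and
the electron rest mass.  The electron is included in [M−H]⁻ m/z by
default (neutral − H atom + e⁻ ≈ −1.00728 Da); at sub-ppm mass accuracy
its 0.55 mDa matters (≈1.4 ppm at m/z 400), but a flag disables it for
comparison with tools that omit it.

## Molecular indices

For a formula with counts C, H, N, O, S (C ≥ 1):

* **DBE** = 1 + C − H/2 + N/2 (classical valence form; O and S are
  divalent and contribute nothing).  **DBE/C** normalizes per carbon.
* **NOSC** = 4 − (4C + H − 3N − 2O − 2S)/C (LaRowe & Van Cappellen
  form), equivalently 2(O/C) − H/C + 3(N/C) + 2(S/C); −4 for methane,
  0 for carbohydrates.
* **AI** = (1 + C − O − S − H/2)/(C − O − S − N) (Koch & Dittmar),
  clamped to 0 when the numerator is negative or the denominator
  non-positive, following the original convention.  The modified
  variant (AImod) replaces O with O/2 in both numerator and
  denominator, treating half the oxygen as carboxyl-like.

Bulk metrics mirror the per-formula forms on elemental-analysis molar
ratios: **C_ox** = 2(O/C) − H/C + 3(N/C) and **OR** = 1 − C_ox/4 by
default, with a nitrogen-corrected OR variant (+3/4·N/C) selectable.
For a sulfur-free stoichiometry C_ox equals NOSC identically; the test
suite asserts this cross-module consistency to 1e−9.

## Peak filtering

Order of operations: m/z window → prominence → noise threshold.

* **Window**: closed interval, default [100, 700] Th; "100 to 700" is
  read inclusively and boundary peaks are retained.
* **Prominence**: retain peaks at ≥ 0.01% (default) of the base peak,
  where the base peak is defined on the *windowed* list, before the
  noise cut.
* **Noise threshold** `exp(mode + k·sigma)`, default k = 3, estimated
  from the log-intensity distribution.  The noise population dominates
  by count and is taken symmetric in log intensity, with signal
  contaminating only the right tail.  The mode is located in two
  passes: a Freedman–Diaconis histogram of all log intensities (lightly
  smoothed with a moving average whose window stays well below the bin
  count), then a refined histogram of the observations at or below the
  coarse mode's neighborhood — the second pass matters because signal
  stretches the overall IQR and would otherwise force over-coarse
  bins.  The spread is then estimated from the signal-free left side as
  sigma = (mode − median{x ≤ mode})/0.6745, the half-normal median
  relation.  Quantiles of the sub-mode data were chosen over the
  histogram's half-maximum width because they average thousands of
  observations rather than a handful of Poisson-noisy bin heights;
  across simulation scenarios this roughly triples the precision of
  sigma (relative sd ~4% vs ~12% at 10⁴ peaks).  Degenerate inputs
  (all intensities equal, fewer than `min_peaks`=50 peaks) raise.

## Internal recalibration

FT-ICR mass error grows with m/z, so error is modeled in relative (ppm)
space as a degree-2 polynomial of m/z.

* **Reference series**: all CHO-only formulas in the constraint sub-box
  with DBE in a configured set, ion m/z inside the window.  The
  configured default set is {−1, 0, 1}; DBE −1 is impossible for a
  neutral CHO molecule, so infeasible entries are logged and the
  feasible members {0, 1} are enumerated (~1,300 calibrants over
  100–700 Th).  An ion-formula DBE convention is not offered; the
  neutral convention with the logged-unreachable rule keeps the
  configuration honest and the chemistry valid.
* **Matching**: all (peak, reference) pairs within `match_tol_ppm`
  (default 1.0 ppm) are ranked by |error| and accepted greedily with
  each peak and each reference used at most once.  Fewer than 3 matches
  raises.  The tolerance is exposed as a config knob and a diagnostic
  plot (`plot_error_model`) supports the error-distribution inspection
  by which such thresholds are conventionally predetermined.
* **Fit**: least squares of ppm error against the matched references'
  *theoretical* m/z (conditioned via a scaled-domain polynomial fit,
  converted back to plain coefficients).  Fitting against theoretical
  rather than observed m/z makes drift that is polynomial in true m/z
  exactly recoverable; evaluating the model at observed m/z during
  correction perturbs predictions only at O(ppm²).  If a fit fails to
  improve the matched-pair RMS (degenerate second-order cases) the
  model falls back to the zero polynomial, so correction never degrades
  and `rms_ppm_after ≤ rms_ppm_before` holds unconditionally.
* **Correction**: calibrated m/z = m/z / (1 + e(m/z)/10⁶); intensities
  untouched; the raw m/z is kept alongside.

In the orchestrated pipeline a blank whose filtered spectrum yields
fewer than 3 reference matches reuses the same-day sample's model: the
blank shares the acquisition's drift, and sparse methanol blanks often
lack the CHO series.  Samples have no such fallback; their calibration
failure aborts the run.

## Formula assignment

Candidates for a peak are all neutral formulas in the constraint box —
C 1–90, H 4–200, O 1–26, N 0–2, S 0–1 — whose [M−H]⁻ mass lies within
±0.5 ppm (default) of the calibrated m/z, optionally restricted to
integer DBE ≥ 0 (default on).  The enumerator iterates the
(N, S, O, C) grid (~14,000 cells, precomputed and cached) and solves
the residual-mass window for the hydrogen count in closed form; this is
exactly the brute-force candidate set — the test suite and the
acceptance script verify equality against an exhaustive sweep of the
~2.8 million-formula box on 1,000+ random masses — at ~100× the speed.

The best candidate is chosen by a deterministic, configurable tie-break:
smallest |ppm error|, then fewest heteroatoms (N+S), then lowest DBE,
then Hill string (a total order).  The order mirrors common practice in
DOM assignment; no nitrogen-rule/parity filter is applied by default
because deprotonated even-electron ions complicate parity arguments (an
optional DBE-integrality flag covers the chemically meaningful part).
Unassigned peaks are retained with an empty formula, and the number of
in-tolerance candidates is recorded per peak so assignment ambiguity is
visible in the output rather than hidden.

**Blank subtraction**: a formula detected in a blank at a prominence
strictly above 20% (default) of the blank's own base peak is removed
from every sample acquired on the blank's day.  Prominence attaches to
the blank detection (not the sample's intensity), the inequality is
strict ("more than 20%"), and same-day matching uses the acquisition
date.  Samples without a same-day blank pass through with a warning;
every removal is logged (sample, formula, blank, blank prominence).

## Compound classes, diversity, summaries

Class assignment is a first-match-wins walk over an ordered rule table
in (O/C, H/C, N/C) space, shipped as editable YAML with schema
validation.  The default table transcribes the MSCC stoichiometric
criteria (Rivas-Ubach et al. 2018) for the six classes: nucleotide,
amino sugar, peptide, carbohydrate, lipid, oxy-aromatic phytochemical;
N-containing classes precede N-free ones so the N/C bounds resolve
overlaps deterministically; anything else is "unclassified".  The
nucleotide rule's P/C condition is dropped with the element model's
exclusion of phosphorus.

Diversity on relative intensities of distinct formulas: richness
(count), Shannon–Wiener −Σp·ln p (nats), Gini–Simpson 1 − Σp².

Per-sample summaries collapse peaks sharing a formula (intensities
summed), then average m/z, element counts, NOSC, AI and DBE/C, and
compute class percentages.  Default weighting is **count-based**
(every formula equal), with intensity weighting selectable; the choice
is recorded in the output because the two conventions coexist in the
DOM literature and differ materially when intensity distributions are
skewed.  Diversity always uses relative intensities.

## Cross-sample comparison

Presence/absence is defined on assigned formulas after blank
subtraction; intensity plays no role because compounds are counted,
not weighed.  A formula is unique to a group (sample, site, or calendar
month of collection) when present in at least one member and absent
from every sample outside the group.  Merging groups can only preserve
or increase pooled uniqueness; group-unique plus shared equals total
distinct formulas (both are property-tested).  A fixed month→season
lookup (Winter = Dec–Feb, etc.) ships for seasonal aggregation.
Regressions of unique-compound counts against composition metrics are
OLS via statsmodels, reported as slope, intercept, adjusted R² and the
two-sided slope p-value; fewer than 3 points or zero predictor variance
raises rather than returning nonsense.

## Synthetic data: what it emulates and what it does not

The generator provides ground-truthed inputs under the study-like
default conditions: 500 formulas per library in m/z 100–700, mixed
70% CHO / 20% CHNO / 10% CHNOS, sampled inside the constraint box by
drawing C, O and an integer DBE (0–15) and deriving H (guaranteeing
valid parity and DBE ≥ 0); log-normal signal intensities
(ln I ~ N(6, 1)); 1,000 noise peaks per spectrum, uniform in m/z with
ln I ~ N(2, 0.3) — two log-sigmas below the signal so the threshold
estimator has a recoverable target; quadratic relative mass drift with
coefficients (0.1, 10⁻³, 10⁻⁶) ppm (≈0.66 ppm at m/z 400, a plausible
uncalibrated FT-ICR drift that exceeds the 0.5 ppm assignment tolerance,
so assignment genuinely requires calibration); and blanks sharing a
seeded 5% contaminant subset of the library.  Bulk elemental-analysis
records are mass balances of formula mixtures in standard atomic
weights with optional Gaussian noise.

Not emulated: per-peak stochastic mass error (drift is a deterministic
function of m/z, so recalibration residuals are numerically tiny rather
than instrument-realistic), isotope clusters, peak shape, space-charge
effects, chemically structured intensity covariance, and per-sample
presence variation (every sample emits the full library; uniqueness
fixtures are constructed directly in tests).  Passing end-to-end tests
therefore demonstrates correctness of the algorithms under their model
assumptions, not instrument-grade performance on real spectra.

## Determinism and provenance

All randomness flows from the single config seed; no stage draws
ambient entropy, and no output embeds a timestamp, so a rerun with
identical inputs is byte-identical (this is itself a test).  Every
output CSV carries a provenance header: package version, SHA-256 of the
canonicalized config, seed.

## Problem sizes in tests

The test suite and acceptance script run at desk scale: 150–500-formula
libraries, 1,000–2,000 noise peaks, 1,000-mass enumeration sweeps
against a fully materialized 2.8 M-formula brute-force box, and 2–3
sample campaigns — sizes at which every check completes in seconds
while the quantities being verified (recovery rates, coefficient
errors, survival fractions) are statistically meaningful.

## Known limitations

* Single charge, single adduct ([M−H]⁻) only.
* The class-boundary table is a stoichiometric heuristic; boundary
  compounds are classified by fiat of rule order.
* The pure-noise survival fraction behind the k·sigma threshold is an
  extreme-tail statistic; even with the quantile spread estimator its
  run-to-run scatter is a few hundredths of a percent at 10⁴ peaks.
* Blank subtraction removes a formula from a sample entirely; there is
  no partial (intensity-difference) subtraction.
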