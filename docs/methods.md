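# Methods

## Scope and data model

The package calibrates analyte content of living mealworm larvae from
near-infrared absorbance spectra on a uniform 1100–2100 nm grid.
Analytes are crude fat (g/100 g fresh weight, Soxhlet reference), the
eight fatty acids C12:0, C14:0, C16:0, C16:1, C18:0, C18:1ω9, C18:2ω6
and C18:3ω3 (relative % of total fatty acids, dry-matter basis, from
GC-FID peak-area normalisation), and the class sums SFA/MUFA/PUFA.
Spectra and reference chemistry travel as plain wide CSV; samples are
joined by explicit id, never by row order. Replicate scans are averaged
arithmetically before calibration. Missing absorbance values are
rejected rather than imputed. Spectra are assumed to be absorbance; a
log10(1/R) helper covers reflectance exports.

## Pretreatments

Five composable transforms, applied in the listed order of a recipe
such as `msc+mc`:

* **MSC** — each spectrum s is regressed on the calibration-mean
  reference by least squares, s ≈ a + b·ref, and corrected to
  (s − a)/b. The reference is stored at fit time; validation and
  prediction spectra are corrected against it, never against their own
  mean. A spectrum with |b| < 1e-12 (flat against the reference) is a
  hard error naming the row. MSC is exactly idempotent on the affine
  scatter family a + b·shape it is designed to invert; with per-sample
  band variation on top, a second pass moves points by orders of
  magnitude less than the first correction but not to machine zero —
  the tests distinguish these regimes.
* **Detrend** — per-spectrum least-squares polynomial baseline removal
  in wavelength; order defaults to 2 (the classic quadratic detrend).
  Wavelengths are rescaled to [−1, 1] before building the Vandermonde
  basis for conditioning. Detrend is a projection (idempotent).
* **Mean centering** — calibration column means are stored and
  subtracted from every set.
* **SG derivatives** — Savitzky–Golay first/second derivatives via
  `scipy.signal.savgol_filter`, window 11 and polynomial order 2 by
  default, with the grid step passed through so units are AU/nm and
  AU/nm². The original study names the derivative pretreatments without
  smoothing parameters, so these defaults are explicit package choices
  and both are exposed in the step configuration. Edge points use the
  truncated-window polynomial fit (`mode="interp"`).

No pretreatment ever sees validation responses or spectra during
fitting; a test asserts fitted state is bit-identical when validation
data change.

## PLS1 and model selection

PLS1 by NIPALS with deflation; for a single response each component is
a single pass, but a guarded convergence loop (tol 1e-12, max 500
iterations) remains. The regression vector is b = W(P′W)⁻¹q; predictions
are in original units via the stored x/y centering. At n_lv = rank(X)
the predictions coincide with ordinary least squares, which the tests
use as an oracle alongside an independently coded NIPALS recursion and
scikit-learn's PLSRegression as an external cross-check.

Latent variables are selected by minimising RMSECV under a cap of 10
(the conventional complexity limit; the published fatty-acid models all
use 8, and a forced `n_lv` mode supports that workflow). The default CV
scheme is venetian blinds with 10 splits; contiguous blocks and
leave-one-out are available. Within each fold the full-rank NIPALS
decomposition is computed once and truncated per LV count, which is
exactly equivalent to refitting (components are extracted
sequentially); if deflation exhausts a rank-deficient fold the curve is
flat beyond the rank. Per-LV cumulative explained response variance is
reported alongside for transparency, since RMSECV minimisation is the
package's reading of the (ambiguously worded) original selection rule.
Ties go to the smaller model.

## Evaluation and best-model choice

RMSEC/RMSEP are plain root mean square errors; R² is 1 − SSE/SST about
the observed mean of the same set (so R²_P, RMSEP and RPD are mutually
consistent; a squared-correlation reading would differ below reporting
precision on well-behaved models but is not used). RPD divides the
validation-set reference SD (n−1 denominator) by RMSEP — the
validation, not calibration, SD: this is the convention under which the
published RPD values reproduce arithmetically from the published SDs
and RMSEPs. R²_F is the squared Pearson correlation between a fatty
acid's relative concentration and total fat on the validation samples.
The best row per analyte ranks by RPD descending, ties broken by lower
RMSEP, then fewer latent variables. Reports display 3 decimals for
R²/RMSE and 2 for RPD; stored values keep full precision. A perfect fit
(RMSEP = 0) reports an infinite RPD rather than failing.

## Composition and husbandry arithmetic

GC peak areas normalise to percentages by area/total·100. Class sums
use a data-driven classification map (SFA: C12:0, C14:0, C16:0, C18:0;
MUFA: C16:1, C18:1ω9; PUFA: C18:2ω6, C18:3ω3); "not detected" is
modelled as absence and contributes zero. A QC routine compares
recomputed class sums against printed table values and returns
discrepancies instead of failing — the bundled case-study table
contains five printed sums inconsistent with their own printed
components (CF20 SFA by 3.0 points; GP4 SFA, HPF5 MUFA, PPF5 MUFA and
PPF5 PUFA by 0.3–0.9), which the QC surfaces as notes.

Growth metrics operate on group totals plus counts: LWGpL divides total
gain by survivors; SGR uses mean per-larva weights (equal to the
total-weight ratio when counts are equal), natural logs, per day ×100;
FCR and ECI are exact reciprocals (ECI = 100/FCR), enforced as a
property. "Feed consumed" is expected as offered − residual − frass;
the supplemental carrot moisture source is excluded from feed by
convention. Weights are mg internally.

Diets are two-component linear mixtures: each nutrient of the blend is
the mass-fraction-weighted mean. `solve_inclusion` inverts for a target
level; `solve_component_values` recovers the two component levels from
two published mixtures (a 2×2 solve). The bundled 10/15/20% coconut and
flaxseed rows are mutually consistent under one solved component pair
(CF20's 68.6% inclusion reproduces to 0.1 point); the 5% rows are not,
and are excluded from the consistency identity.

## Synthetic data generator

The generator emulates the feeding trial at its true scale: 15 diet
groups, 8 samples each, split 80/40 with every group in both sets.

* **Fat**: truncated normal per group, SD 0.4 g/100 g within groups.
  Group means span 7.6–16.1 g/100 g; the three published group values
  (CF15 16.1, CF20 15.9, PPF6 7.6) are used directly and the remaining
  twelve are fixed plausible values ordered by dietary fat and protein
  (coconut/flaxseed high, protein-rich diets low), giving a pooled
  spread close to the reported calibration summary (range 7.4–16.2,
  SD 2.3).
* **Fatty acids**: Dirichlet draws centred on each group's measured
  mean profile with concentration κ = 8000, i.e. within-group SDs of a
  few tenths of a percentage point, matching the reported duplicate
  SDs; profiles renormalise to 100.
* **Spectra**: clean spectrum = linear baseline + Σ constituents
  (concentration × Gaussian bands). Fat carries bands at 1205/1727/1797
  nm; water (~62 ± 2% proxy) and protein (~19 ± 1.5%) carry the
  1454/1930 nm bands and are sampled independently of fat. Individual
  fatty acids contribute weak bands near the lipid region scaled by
  absolute content (relative % × fat/100) — except palmitoleic (C16:1)
  and stearic (C18:0), which get no bands, reproducing the regime in
  which those two acids are honestly unpredictable. Band widths
  (σ 24–65 nm) make visually broad NIR features; amplitudes put total
  absorbance near 0.3–0.7 AU.
* **Artefacts**: per-spectrum additive offset a ~ U(−0.05, 0.05) AU and
  multiplicative slope b ~ U(0.8, 1.2) (large enough that MSC
  materially matters), plus white noise with SD 0.002 AU.
* **Seeding**: one global seed expands through `numpy.SeedSequence
  .spawn` into child seeds for reference chemistry, spectra and the
  split, so each stage is independently reproducible and equal seeds
  give byte-identical CSV output.

What passing tests on this generator show: that the pipeline recovers a
band-linked constituent through realistic scatter and noise, honours
the calibration/validation separation, and degrades monotonically with
noise. What they do not show: performance on real larvae — the
generator has no instrument line-shape, no Kubelka–Munk scattering
physics, no wavelength-dependent noise, and its band model is far
cleaner than a living, moving sample. Synthetic figures of merit (e.g.
fat R²_P ≈ 0.999, RPD ≈ 29 on the canonical fixture) are therefore
upper bounds of pipeline correctness, not predictions of instrument
performance.

## Numerical choices and degenerate inputs

NIPALS tolerance 1e-12; rank deficiency and zero-variance responses are
hard errors. Wavelength grids must be strictly increasing, uniform to
1e-9 nm and within 1100–2100 nm; mismatched grids are refused at every
seam, and saved models embed a grid hash so the prediction command
refuses foreign spectra. CSV I/O is comma-separated, dot-decimal UTF-8
with 12 significant digits, making write∘read an identity to 1e-12.
Profiles above 100.5% total, negative areas/percentages, zero
survivors, non-positive weights or durations, and singular mixing
systems all raise typed errors.

## Known limitations

Wavelength resampling between instruments is out of scope (grids must
match exactly). PLS2, SIMPLS, outlier ellipses (Hotelling T²/Q) and
variable selection are not implemented. The husbandry module does not
model instars or ANOVA-style group comparisons. The acceptance script's
synthetic figures are self-checks of the pipeline, not reproductions of
instrument-grade statistics.
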