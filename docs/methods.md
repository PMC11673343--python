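# Methods

## Quantification model

The pipeline operates on co-registered three-channel sections: N-terminus
(aa 34–45), phospho-Ser129 and C-terminus (aa 118–123) α-synuclein antibody
channels plus a tissue mask. All headline statistics are area-based set
algebra on binary masks — no intensity-based colocalization coefficients are
computed, because the quantities of interest are *where each antibody
detects pathology*, not how correlated the intensities are.

Per section, the three masks are decomposed into the seven disjoint Venn
compartments; pathology load is the union as a percentage of the tissue
area, and the total / unique epitope percentages are compartment sums as
percentages of the union. On an empty union (control tissue) the
percentages-of-union are reported as 0 with a `zero_union` flag instead of
erroring, so control sections flow through cohort tables. Areas are carried
in pixels and convertible to µm² via `pixel_size_um²`; all statistics run on
percentages, so the unit choice cannot affect results.

Mass-balance invariants (`unique ≤ total` per epitope, `Σ total ≥ 100` when
the union is nonempty, `Σ unique ≤ 100`, exact integer conservation of the
compartment partition) are asserted at `QuantRecord`/`VennAreas`
construction — every pipeline run re-checks them, not just the test suite.

## Segmentation

Each channel is processed as: background subtraction → Otsu threshold on
the histogram of tissue pixels → threshold floor → strictly-greater-than
mask → small-object removal.

- **Background subtraction.** `max(0, image − G_σ(image))` with reflective
  boundaries; σ defaults to 50 px, large against aggregate diameters
  (≲ 45 px) so aggregates survive the subtraction while slow illumination
  and autofluorescence gradients are removed. When a tissue mask is
  available the background is the normalized masked Gaussian
  `G(image·mask)/G(mask)`: an unmasked estimate is dragged toward zero by
  off-tissue glass near the boundary, which would leave a spurious positive
  halo along the tissue edge (on control sections this halo alone can
  segment as several percent of tissue).
- **Otsu.** Implemented on explicit histograms (256 bins over the observed
  tissue-pixel range) with the convention fixed for bit-exactness: classes
  are bins ≤ t versus > t, ties broken by the smallest t, foreground is
  strictly greater than the mapped threshold value. Degenerate (single-bin)
  histograms yield an empty mask plus an `empty_channel` QC flag rather than
  an error: absent staining — common for pS129 in MSA — must flow through
  quantification as zero area.
- **Threshold floor.** The applied threshold is `max(otsu, floor)` with
  floor default 50 intensity units (post-subtraction scale). Rationale: Otsu
  always finds *some* split, so on a channel containing only noise it
  segments noise; the floor encodes the requirement that pathology must be
  brighter than the monomeric/background signal seen in neurologically
  normal tissue. 50 ≈ 3.5× the residual noise SD of the default camera
  model (Poisson at background 150 plus read noise 6) and a factor ≥ 10
  below true signal after subtraction.
- **QC.** Per-channel flags (`floor_applied`, `empty_channel`,
  `foreground_cap_exceeded` above 30 % foreground/tissue) plus a CSV report
  and overlay thumbnails replace operator-based visual confirmation of the
  segmentation.
- **Tissue mask.** Estimated from summed-channel autofluorescence (heavy
  Gaussian smoothing, Otsu or fixed threshold, closing + hole fill, keep
  the largest components covering ≥ 99 % of foreground); a supplied
  precomputed mask always takes precedence, and flat sections raise an
  error directing the user to supply one.

## Synthetic sections

The simulator emulates 20x slide-scanned tissue at 0.325 µm/px (an assumed,
config-recorded value — typical for 20x scanners; the quantification is
scale-free). Default field 512×512 px with a smoothed-random tissue blob
(low-frequency Gaussian noise field thresholded at 55 % coverage, closed,
hole-filled, largest component kept).

Aggregate classes combine a shape model, a truncated-normal size in µm, a
per-epitope composition rule and an abundance weight:

| shape | construction |
|---|---|
| punctate | disk |
| neurite | smoothed random-walk polyline, 1–2 px wide |
| shell_body | disk with an annular rim (thickness 15 % of radius, ≥ 1.5 px); core and rim carry different membership vectors |
| filament_web | 5–12 chord-like smoothed curves inside a cell envelope; each filament carries one membership vector drawn from the class's choices |
| irregular_cluster | union of overlapping disks around a nuclear void |

Preset catalogues encode the disease taxonomies: the PD preset is dominated
by N-terminus-exclusive classes (lysosomal punctate, perinuclear, glial
clusters) plus pS129-only neurites and shelled Lewy bodies (all-epitope core,
pS129/C-terminus rim); MSA presets carry shelled glial cytoplasmic
inclusions (rim exclusively C-terminus-positive, and half of them with a
pS129-negative core), N-terminus-only punctate neuronal inclusions, and —
dominant in the inferior-olive preset — filament-web neuronal inclusions
whose filaments are individually N- or C-terminus-exclusive and never
pS129-positive. The control preset places no aggregates.

Placement requires each object to lie fully inside tissue without touching
a previously placed object (bounded retries; failures are warned and
counted), which guarantees the ground-truth invariants: disjoint
per-aggregate pixel sets, all foreground inside tissue. Filament fragments
below 6 px (created when a filament crosses an earlier one) are discarded so
the truth contains no sub-resolution shards.

Per-class counts are the deterministic largest-remainder apportionment of
the total aggregate count over abundance weights; between-case variability
in cohorts comes solely from per-class log-normal weight multipliers
(σ = 0.3 by default), chosen so that a zero-dispersion cohort has exactly
reproducible class counts and case *i* is bit-identical to a single-section
run at seed `base_seed + i`.

Rendering: per-channel constant intensity on member pixels (≈ 1100–1800 DN,
16-bit) plus tissue-confined background (150 DN), Gaussian PSF (σ = 0.8 px,
matching a slightly under-sampled 20x/0.8 NA acquisition), Poisson shot
noise (gain 1) and Gaussian read noise (SD 6), quantized to the configured
bit depth. With PSF, noise and background all zero, the image support equals
the truth masks exactly — the basis of the exact-recovery tests.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: intra-aggregate intensity texture, out-of-focus
haze and section-thickness effects, spectral bleed-through (an off-by-default
mixing step exists but no unmixing is implemented), staining-intensity
variation between cases, and anatomically realistic aggregate spatial
clustering. Recovery tolerances met on simulated cohorts bound algorithmic
error, not biological or staining variability. Simulated pathology loads
(≈ 3–14 % depending on preset) are deliberately denser than whole-region
post-mortem values so that per-section percentages are stable on 512² desk-
scale fields; the percentage-of-union measures are invariant to this choice.

## Cohort statistics

Measurements are long-format rows (case, group, region, measure, value);
one record per section, with case-level means taken before cohort statistics
when multiple sections share a case. The battery:

- **Normality routing:** Shapiro–Wilk per group; the parametric branch is
  taken only when *every* group has p ≥ 0.05 (the routing rule is recorded
  in output metadata). Constant samples route non-parametric.
- **Pearson correlation** from the closed form, p from the t-transform with
  n − 2 df; correlations are reported unadjusted, with a clearly-labelled
  Holm-adjusted column emitted as an extension.
- **Repeated-measures one-way ANOVA** across regions within a disease:
  complete cases only (dropped cases logged), F = MS_region/MS_error from
  the two-way subject×region decomposition, df (k−1), (k−1)(n−1);
  sphericity is assumed (no Greenhouse–Geisser correction). Tukey pairwise
  p-values from the studentized-range distribution with
  q = |Δmean|/√(MS_error/n); at k = 2 the Tukey p equals the ANOVA p.
- **Two-group comparison:** pooled-variance Student's t (Welch is
  deliberately not the default; the pooled form is the plain "unpaired
  t-test") or Mann–Whitney U with the tie-corrected, continuity-corrected
  normal approximation; U + U′ = n_x·n_y is reported.

Implementation notes: Shapiro–Wilk and Mann–Whitney come from scipy.stats;
Pearson, the pooled t, the RM-ANOVA sums of squares and the Tukey p are
computed from their closed forms. The test suite pins all six procedures to
reference values frozen from R 4.3.3 (shapiro.test, cor.test, t.test with
var.equal, wilcox.test with exact=FALSE, aov with a subject error stratum,
emmeans Tukey pairs) within 1e-6, cross-checks the RM-ANOVA against
pingouin, and confirms U by brute-force pair counting.

## Numerical conventions and degenerate inputs

- Row-major rasters, 0-based indices; masks stored 0/255 in single-channel
  TIFF; channel order (Nterm, pS129, Cterm) everywhere.
- Connected components: 8-connectivity by default (configurable 4);
  component order is scan order. Per-component exclusivity labels use
  ε = 0.05: a component is X-exclusive iff coverage[X] ≥ 1 − ε and both
  other coverages ≤ ε.
- CSV writers emit full-precision `repr` floats in a fixed row order, so
  identical inputs produce byte-identical files and values survive a parse
  round-trip beyond 12 significant digits.
- Empty tissue → error; empty union → zeros + flag; single-value summary
  slices report SD 0 with an `n = 1` flag; RM-ANOVA with zero error mean
  square reports F = 0, p = 1 when the region effect is also zero.

## Problem sizes

Default validation sizes — 512×512 px sections, 40–45 aggregates, 10 cases
per cohort — were chosen so that per-section percentages are stable (worst
observed per-section recovery error ≈ 3.3 percentage points on unique
fractions, ≈ 9 % relative on load, against tolerances of 5 points / 20 %)
while a full five-preset validation sweep completes in about a minute.

## Known limitations

- The per-epitope threshold floor is expressed in post-subtraction
  intensity units and must be re-tuned if acquisition gain differs greatly
  from the default camera model.
- Tissue estimation relies on tissue autofluorescence in the summed
  channels; sections with no background signal require an explicit mask.
- The RM-ANOVA assumes sphericity and complete cases; heavily unbalanced
  designs should use a mixed model, which is out of scope.
- Percentages-of-union are ratios of correlated quantities; their per-case
  SDs are reported descriptively, not propagated.
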