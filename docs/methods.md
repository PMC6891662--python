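# Methods

This note documents the models, procedures, and design choices behind
`immunoquant`, in the spirit of a methods appendix: what each pipeline
assumes, which parameters matter, and what the synthetic benchmarks do and
do not demonstrate.

## Bead-encapsulation scoring

### Grading scheme

Each bead receives two grades. The area fraction *A* = covered degrees /
360 is binned into five grades (0–4), and the thickness ratio
*T* = (√(Area/π) − R)/R into seven (0–6). The printed bin definitions share
endpoints ("0–0.25", "0.25–0.5", …), so an edge convention is required:
grade 0 is reserved for a value of exactly zero (the stated
"no encapsulation" case) and the remaining bins are lower-exclusive /
upper-inclusive, e.g. *A* ∈ (0.25, 0.5] → grade 2. Thickness ratios above
the last bin edge (2.0) clamp to grade 6, which preserves the index's
[0, 10] bound.

Two further interpretation choices, both explicit in the code:

- "Area" in the *T* formula is the total bead-plus-capsule footprint.
  The alternative (capsule-only area) would give *T* = −1 for a bare bead,
  which the grading table ("0, T = 0") contradicts. *T* is floored at 0 so
  segmentation jitter on bare beads cannot produce negative ratios.
- The encapsulation index Σ(*P*·T-grade + *P*·A-grade) uses fractional *P*
  (not ×100): only with fractional *P* does the index stay within [0, 10],
  the range containing all published values of this statistic. The index is
  then algebraically the per-bead mean of (area grade + thickness grade),
  which the tests exploit as an independent oracle.
- The encapsulation *rate* is reported as the fraction of beads with any
  capsule (area grade ≥ 1). This is an interpretation — the term appears in
  published summaries without a printed definition — and is flagged as such
  here.

### Image measurement

The renderer and the assay stain both make the bead brighter than the
capsule, which is brighter than background. Segmentation classifies
intensities into three bands with 1-D Lloyd (k-means) iterations
initialised at the 0.1/50/99.9 percentiles; this is robust to the capsule
band being a small minority of pixels, where histogram-threshold methods
(Otsu) can drop or split it. The middle band is accepted as a real capsule
only when the three band means are separated by more than 6× the largest
within-band spread — a unimodal population split at its own mean separates
by only ~1.6σ, so bead-only images correctly degrade to two-band
segmentation with an empty capsule mask. The bead circle is the
equivalent-area circle of the largest bead-band component.

Angular coverage is measured on the circle of directions around the bead
centre (counter-clockwise from the +x axis, 0-based (row, col) pixel
coordinates): a direction is covered when a capsule-classified pixel centre
lies beyond the bead radius at that angle. Rather than sampling integer-
degree rays — which quantises by up to ±3° on thin annuli — each capsule
pixel at distance r contributes its angular extent 2·asin(0.5/r), and the
union of extents is accumulated on a 0.1° grid. On noiseless renders this
recovers the true arc within ±2° and the thickness ratio within ±0.005.

Pixel size defaults to 1 μm/px. *A*, *T*, the grades, and the index are
scale-invariant, so calibration only affects reported absolute areas.

## Cellular assays

Hemocytes are segmented by Otsu thresholding of the DIC channel with
nuclei-seeded watershed splitting (seeds from the nuclei channel; regions
under 50 px discarded). Per cell the pipeline computes area, perimeter,
circularity 4πA/P², and a convexity-defect count — the number of
connected components of (convex hull − silhouette) with ≥ 10 px, which
counts the concave gaps between pseudopod arms.

Spreading is classified as circularity < c₀ OR defects ≥ d₀ with defaults
c₀ = 0.6, d₀ = 3. The morphological criteria used in the original assays
are cited to earlier literature and not restated, so these thresholds are
explicit configuration, calibrated once against the synthetic renderer's
spread/round silhouettes (a rendered 5-armed star scores circularity ≈ 0.4
with 4–6 defects; a disk scores ≈ 1.0 with 0). The spreading percentage
counts only plasmatocytes and granulocytes — the two spreading-competent
classes — in both numerator and denominator. On synthetic fields the type
labels come from ground truth (matched by nearest centroid); on real images
a size/shape typing heuristic would be low-confidence and is deliberately
not built in.

Engulfed bacteria are counted as local maxima of the (Gaussian-smoothed,
σ = 1 px) bacteria channel above the midpoint between background and
maximum, assigned to the cell label at the peak; a spot outside every cell
mask counts for no cell. Engulfment is thus approximated by 2-D containment,
matching how fluorescence-microscopy counting is done; no internalisation
test is attempted.

Relative F-actin fluorescence divides each replicate's intensity by the
blank's mean intensity; groups are reported as mean ± SE of the ratios.

## Docking post-processing

The lowest-energy conformer per ligand is selected (ties broken by lowest
conformer id) and converted by the standard Boltzmann relation
K_i = exp(ΔG/RT), R = 1.98720×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K — the
relation AutoDock-family engines print alongside their energies. Applied to
the bundled seven-ligand fatty-acid panel, this reproduces the published
inhibition constants to within ~1% for six ligands and ~5% for linolenic
acid; the residuals are consistent with the panel energies being rounded to
two decimals before publication. Ranking by ΔG and by K_i coincide because
the map is strictly monotone. Running the docking engine, grid generation,
and pose geometry are out of scope; the input is a plain energy table.

## Statistics

One-way fixed-effects ANOVA accumulates SS_between and SS_within directly
and takes p from the upper tail of F(k−1, N−k); Tukey–Kramer pairwise
comparisons use q = |mᵢ−mⱼ| / √(MSW/2·(1/nᵢ+1/nⱼ)) against
studentized-range quantiles at α = 0.05. Levene's statistic is reported
alongside as a homogeneity diagnostic but never gates the analysis —
reporting, not silent branching. Degenerate inputs (zero within-group
variance, unequal means) yield F = ∞ with p reported as the smallest
positive float and a `degenerate` flag. The chi-square test is uncorrected
Pearson by default — appropriate for the hundreds-to-thousands of cells
these assays count per arm — with Yates' correction behind a flag.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed) via a single
per-call `numpy` Generator; identical calls are byte-identical.

- **Beads**: a bright disk (default radius 40 px at 1 μm/px, consistent
  with <150 μm beads at modest magnification) with a concentric annular
  capsule arc of controllable angular extent and thickness. Intensity bands
  are background/capsule/bead = 10/110/220 on a 0–255 scale; additive
  Gaussian noise with stated sd ("5% noise" = sd 11, 5% of the bead band).
  Real capsules are irregular, not concentric annuli; concentricity is kept
  by default so the analytic area/angle oracles (annulus area 3πR² for a
  full ring at thickness ratio 1, etc.) hold exactly.
- **Hemocyte fields**: non-overlapping cells (body radius 8–12 px), round
  cells as disks, spread cells as 4–6-armed star silhouettes
  (r(θ) = r₀(1 + 0.55·cos kθ)), nuclei as small central disks, engulfed
  bacteria as radius-2 spots ≥ 7 px apart inside the silhouette with count
  k ~ 1 + Poisson(mean − 1) for phagocytic cells. The shifted Poisson is a
  modelling choice; assay counts are only reported as "one or more".
- **Fluorescence readings**: lognormal replicates with the requested mean
  and CV (positive by construction; CV = 0 degenerates to the exact mean),
  four replicates per group by default, plus a blank group.
- **Docking tables**: per-ligand conformer energies uniform in a stated
  interval (default ten conformers), with the per-ligand minimum recorded
  as ground truth.

Passing the recovery benchmarks therefore shows the pipelines are correct
on well-separated intensity bands, circular beads, and non-touching cells
with Gaussian noise. It does **not** show robustness to uneven
illumination, point-spread blur, touching or overlapping cells, irregular
capsule boundaries, or out-of-focus debris — real-image performance must be
validated separately. No photorealistic or PSF modelling is attempted.

## Benchmark scales and tolerances

The default test suite uses the assay's own scales: cohorts of 10 beads ×
5 replicates (index recovered within ±0.5 at 5% noise; noiseless per-bead
coverage ±2°, thickness ±0.05), 400–500-cell fields (spreading and
phagocytosis percentages within the 99% binomial CI of ground truth;
per-cell engulfed counts ≥ 95% exact), ANOVA/χ² against brute-force
sum-of-squares and Σ(O−E)²/E oracles at 1e-10, and a 2000-replicate null
simulation whose type-I error at α = 0.05 must land in [0.04, 0.06].

## Known limitations

- Cell typing (plasmatocyte vs granulocyte) is not inferred from images.
- A bead touching the image border yields a flagged partial measurement,
  not an extrapolated one.
- The spot counter undercounts when bacteria lie closer than ~5 px
  (plateaus merge); the generator enforces 7 px separation, real clumps
  would need deconvolution.
- Thickness grading of very thin capsules (< ~0.05 ratio) is limited by
  rasterisation: a sub-pixel annulus may render no capsule pixels at all.
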