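# Methods

This note records how the pipeline's quantities are defined, what the
synthetic data emulate, and the numerical choices that shape the results.

## RI-window segmentation

A voxel belongs to a compartment iff its refractive index falls in the
compartment's half-open window: whole cell [1.348, 1.44), post-acrosomal
region + midpiece [1.37, 1.39), nucleus [1.39, 1.44). The half-open
convention resolves the shared 1.39 bound deterministically in favour of the
nucleus, making the two sub-windows adjacent and disjoint; the same windows
are applied to every cell, fresh or frozen. Voxels at or above 1.44 belong
to no window; they are counted in a QC field and logged, never silently
reassigned. For single-cell fields, cleaning reduces the whole-cell mask to
its largest connected component (26-connectivity by default, 6 available)
and intersects the sub-region masks with it; ties between equal-sized
components break on the smallest flattened voxel index. Cleaning can be
switched off for multi-cell fields.

## Morphometry

* **Volume** is voxel count × voxel volume. No partial-volume weighting is
  attempted; accuracy comes from resolution and (in synthetic studies) from
  the unbiasedness argument below.
* **Surface area** is the area of the marching-cubes iso-surface at the 0.5
  level of the binary mask. The mask is first smoothed with a 1-voxel
  Gaussian: the raw binary iso-surface carries staircase facets that
  overestimate a smooth surface by ≈ 9% independent of resolution, whereas
  the smoothed field recovers a digitized r = 2 µm sphere's area to < 1%.
  Objects so small that smoothing pushes the field entirely below the level
  fall back to the raw mask, keeping a surface defined for any non-empty
  mask. The smoothing sigma is exposed as a parameter.
* **Sphericity** is π^(1/3)(6V)^(2/3)/A, 1 for a sphere. Discretization can
  push it marginally above 1; tests allow +2%.
* **Projection area** is the occupied-pixel count of the max-projection
  along a chosen axis (optical z axis by default) × pixel area.
* **Dry mass** converts RI excess over the medium via the specific
  refractive increment α, default 0.185 µm³/pg — the standard protein
  value, configurable because lipid-rich compartments have lower α.
  Noise can push in-mask voxels below the medium RI; their negative
  contributions are clipped to zero (logged), keeping dry mass non-negative
  and exactly additive over disjoint masks.
* **Concentration** is dry mass / volume; for a homogeneous region it
  reduces to (RI − RI_medium)/α independent of size.

## The freezability index

FI_HT = V_frozen / V_fresh × 100 per donor × extender × region, where both
volumes are **sample means over cells**, not per-cell ratios: different
spermatozoa are imaged in the fresh and frozen arms, so no per-cell pairing
exists at analysis time. Values above 100% are legal (swelling). The
motility counterpart is post/pre motility × 100 (a `delta` mode returning
percentage-point loss is provided; the ratio is the default because it
mirrors the volumetric definition). Cooler calls: *good* if every region's
FI_HT ≥ 90%, *poor* if any region < 80% (the bound associated with
substantial structural shrinkage), *intermediate* otherwise; both thresholds
are configurable, and calls can be pooled across extenders (default) or per
extender.

## Kinematics

VCL is summed step length over duration, VSL net displacement over duration,
VAP the length of the smoothed path over duration. Smoothing is a centred
moving average (default 5 frames) whose half-width shrinks symmetrically at
the track ends; endpoints are untouched, which makes VSL ≤ VAP exact and
keeps VAP ≤ VCL up to numerical noise. The immotile rule ("average velocity
below 10 µm/s") reads the average velocity as VAP, the common CASA
convention; a config knob switches it to VCL since the convention is not
universal. Progressive requires VAP > 30 µm/s **and** STR > 80%. Tracks
with VAP = 0 (STR undefined) are immotile. Population summaries report TM
(% non-immotile), PM (% progressive) and velocity means over motile tracks.

The track simulator draws a class per track (immotile / motile /
progressive), a speed from the class distribution, and evolves a heading by
Gaussian turning noise per frame (persistent random walk); immotile cells
only jitter in place. Default classes (progressive 45 ± 8 µm/s, low turning;
motile 30 ± 4 µm/s, strong turning; immotile 0.08 µm jitter) are chosen to
be well separated relative to the 10/30 µm/s thresholds, so generative
labels are recoverable (> 95%) and estimated TM tracks the generative motile
fraction. Default capture: 25 fps for 1 s. Real CASA tracks carry
segmentation dropouts, collisions and drift that the simulator does not
model, so passing tests validate the estimators, not tracking robustness.

## Synthetic phantoms and cohorts

A phantom is an ellipsoidal nucleus, a cylindrical midpiece abutting it, and
a thin cylindrical tail, aligned along the optical axis in a uniform medium
(RI 1.337, PBS-like; it must stay below 1.348 so background never enters the
whole-cell window). Compartment RIs (nucleus 1.415, midpiece 1.380, tail
1.360) sit centred in their windows with ≥ 5σ margin at the default additive
Gaussian RI noise (sd 0.002), so window labels are pure by construction; the
tail lies inside the whole-cell window but outside both sub-windows,
mirroring how tails appear only in whole-cell renderings. No speckle or
reconstruction artifacts are modelled. Default sampling pitch is
(0.11, 0.11, 0.22) µm — the instrument's lateral/axial resolution used as
the voxel size — on a 64³ grid, the problem size used for study-scale runs
throughout. Default geometry (nucleus semiaxes 0.6 × 1.6 × 2.9 µm, midpiece
4.2 × r0.45 µm, tail 1.8 × r0.18 µm) is equine-like for head and midpiece
but with a foreshortened tail: a real ~35 µm flagellum cannot fit a
single-cell grid, and the tail never enters a reported region, so only the
whole-cell volume carries a small, arm-consistent offset.

Two rendering details matter numerically:

* **Sub-voxel placement.** Each render translates the phantom by a seeded
  uniform sub-voxel offset. Under uniform translation the voxel count is an
  unbiased volume estimator; with a fixed centred placement the
  few-voxel-thick midpiece shows a radius-dependent digitization bias of
  several percent that does not cancel between fresh and frozen arms and
  visibly distorts FI_HT. With the jitter, cohort-mean FI_HT matches
  generative truth to a few tenths of a point.
* **Junction grace.** The ellipsoid is thinner than one voxel near its
  apex, so a cylinder starting exactly at the apex can voxelize into a
  separate component — which largest-component cleaning would then delete.
  The midpiece is therefore painted with one axial voxel of grace into the
  nucleus tip, and the nucleus is painted last so its voxels are untouched.

Cryo-induced dehydration is modelled as an isotropic per-region volume
scaling: factor f multiplies linear dimensions by f^(1/3), so region volume
scales exactly by f (no shape model for contraction is assumed). Cohorts
default to 11 donors × (fresh INRA96 reference + Spectrum Duo Red, BotuCrio,
INRA Freeze, HF-20) × 40 cells. Donor baselines are log-normal (sd 0.08 on
volume) with log-normal per-cell jitter (sd 0.03), the product truncated to
±30% so every cell fits the default grid. Each donor's per-cell base specs
are shared between arms (generation is paired; analysis remains unpaired),
so degenerate zero-variance shrinkage reproduces exactly. Extender effects
(mean ± sd of the volume factor) encode the qualitative pattern of the
phenomenon being modelled: the midpiece is most affected — worst under the
fast-freezing Spectrum Duo Red (0.55 ± 0.08), mildest under slow-cooled
INRA Freeze (0.85 ± 0.06) — while the nucleus is nearly stable (0.95–0.97).
Donors 2 and 4 are designated good coolers drawing ≈ 0.98 ± 0.02 in every
region under every extender. Fixation effects on RI are not modelled.

On the generator's analytic ground-truth volumes, aggregated FI_HT equals
100·f to floating-point rounding; through the rendered pipeline it matches
at the voxelization tolerance (mean absolute error < 2 percentage points at
40 cells/sample).

## Statistics

Percentages (TM, PM, FI) are arcsine-square-root transformed before ANOVA;
volumes are analysed untransformed. Because FI_HT can exceed 100%, the
transform used inside the ANOVA/pairwise helpers clips to [0, 100] with a
logged warning; the bare transform stays strict. Normality is checked on
within-group-centred residuals (Shapiro–Wilk) and variance homogeneity with
Levene's test; failures are logged but do not stop the ANOVA, which has no
documented fallback in this workflow. One factor uses the classic one-way
decomposition; multiple factors use an additive fixed-effects OLS model
(interaction by flag) with type-II sums of squares — both one-way-per-
variable and factorial analyses are therefore available, since the choice
is genuinely open. The Bonferroni family is all pairwise level contrasts of
one factor for one response (raw pooled-variance t-tests × family size,
capped at 1). Numerical routines (F, Shapiro–Wilk, Levene, OLS) are
delegated to scipy/statsmodels; this package contributes the transforms,
family definitions and orchestration. Report tables are five-number
box-plot summaries (median, quartiles, 1.5-IQR whiskers) per donor and per
extender, written deterministically.

## Known limitations

* Phantoms are geometric idealizations: no acrosome compartment (the three
  windows define three regions), no bent or coiled tails, no reconstruction
  artifacts, no RI gradients within a compartment. Passing tests show the
  estimators are correct on such data, not that the windows segment real
  tomograms of any particular species correctly.
* Whether the midpiece window would also capture tail voxels in real data
  is untested here; phantoms place the tail outside both sub-windows by
  construction.
* Surface areas of thin cylinders (sub-5-voxel radii) remain several
  percent off at the default pitch; volume, the quantity the freezability
  analysis relies on, is unbiased under the sub-voxel jitter.
* The statistics stage implements fixed-effects models only; no
  mixed-effects or repeated-measures structure.
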