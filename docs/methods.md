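# Methods

## The fellow-eye difference construct

A raw anterior-elevation export gives, for one eye, the height of the
corneal front surface above the plane tangent to the apex, sampled on a
141 × 141 lattice at 0.1 mm pitch (14 × 14 mm, apex at index (70, 70)).
Grid index (row i, col j) maps to physical coordinates
x = (j − 70)·0.1 mm (rightward), y = (70 − i)·0.1 mm (upward); row 0 is
the top of the map. The package treats the two eyes' exports as directly
comparable (same apex-tangent reference); no apex re-registration or
iterative-closest-point alignment is applied — the method is raw
corresponding-point subtraction.

Fellow eyes are mirror images, so the left-eye grid is flipped about its
vertical axis (column reversal, x → −x; a row reversal would model an
up–down flip with no anatomical meaning) and the right-eye grid is
subtracted: `D = flip(L) − R`. Positive values mean the left cornea is
more elevated at the mirrored location. Missing cells (NaN) propagate:
a difference cell is missing iff either source cell is. Two exact
identities follow from the algebra and are enforced by tests: flipping
is an involution, and swapping the eyes' roles yields `−flip(D)`.

## Zones and features

Peripheral samples are frequently corrupted (limbus, eyelids, nose
shadow, extrapolation), so analysis is restricted to concentric central
zones of 2.0, 3.0, 4.0, 5.0 and 6.0 mm diameter. A cell belongs to a
zone when its center satisfies x² + y² ≤ r² (inclusive boundary); this
rule gives exactly 317, 709, 1257, 1961 and 2821 points for the five
zones — the lattice-point counts inside circles of radius 10, 15, 20,
25, 30 grid units — and it is the only boundary convention that does.
The mask comparison is done in integer grid units so boundary cells are
never lost to floating-point round-off.

Per zone, the flattened valid values yield 17 features. Conventions
where more than one definition exists:

* **skewness** — Fisher–Pearson third standardized moment,
  bias-uncorrected; **kurtosis** — excess fourth standardized moment
  (−3), bias-uncorrected. Both are defined as 0 for constant input
  (0/0 moment ratio resolved to zero).
* **SD** — sample standard deviation (ddof = 1): it is used as a
  dispersion feature, not a standard error of the mean.
* **absolute mean / median** — mean (median) of |values|. The
  alternative reading |mean| is available as
  `zones.signed_mean_abs` for comparison.
* **central 95% range** — P97.5 − P2.5 with linear-interpolation
  percentiles.
* **volumes** — neg_volume = |Σ negative values|·a, pos_volume =
  (Σ positive values)·a with cell area a = 0.01 mm², so the unit is
  µm·mm² (10⁻³ mm³) and the quantity is the geometric gap volume where
  one cornea sits below / above its fellow. total_volume is their sum,
  volume_diff the absolute difference (an intraindividual asymmetry
  measure).

Missing cells are excluded from all statistics; `n_valid` is carried per
zone so under-covered cases can be filtered. A single-valued zone
reports its dispersion features as 0 with a warning; an empty zone is an
error. Pair matching rejects cases where either eye has fewer than 2680
valid points inside the 6.0 mm zone (95% of its 2821 cells) — a
coverage floor for downstream statistics.

## Pattern rule

The qualitative colormap taxonomy (flat / tilt / cone / 4-leaf /
irregular) is operationalized with a least-squares fit of the masked
zone values (default zone 6.0 mm) on six surfaces over the zone disk:
piston 1, tilt ρcosθ and ρsinθ, defocus 2ρ² − 1, astigmatism ρ²cos2θ
and ρ²sin2θ, with ρ the radial coordinate normalized to the zone
radius. Coefficients are reported as zone-edge amplitudes in µm; group
energies (tilt, defocus, astigmatism, residual) are evaluated on the
actual grid samples, so the slight non-orthogonality of the basis on
the discrete lattice is accounted for exactly.

Decision rule: FLAT when the zone RMS is ≤ 2.0 µm (central differences
of well-matched fellow corneas are of the order of a few µm); otherwise
the leading component group must carry ≥ 60% of the non-piston energy
with the residual ≤ 35% to be labelled TILT / CONE / FOUR_LEAF;
anything else — including the degenerate case of an above-threshold map
whose energy is essentially all piston — is IRREGULAR. Defocus sign is
ignored for CONE: either cornea may be the steeper one. All thresholds
are configurable; they are operational package choices for a taxonomy
originally defined by visual inspection, not measured constants, and
their correspondence to expert visual assignments on clinical maps is
untested.

## Clustering

Features are z-scored by default (centroids are back-reported in
original units as per-cluster means), zero-variance columns dropped
with a warning, and clusters renumbered in descending size so cluster 0
is always the largest. k-means uses k-means++ initialisation (seeded)
followed by an explicit Lloyd loop; the within-cluster SSE is recorded
every iteration and asserted non-increasing, and an emptied cluster is
re-seeded at the point farthest from its center. EM is a
full-covariance Gaussian mixture at fixed k. Row order of the input
table does not affect the result (rows are canonically sorted before
fitting). Per-cluster summaries report mean ± SD per feature with a
one-way ANOVA across clusters; when every group has zero variance the
ANOVA is reported as degenerate rather than as a numeric p-value.

## Bilateral categories

Cases with a QS error code in either eye are excluded. The remaining
cases are categorized by the worse eye's KKS: both normal →
bilateral-normal; worse = possible → KS-abnormal; worse = stage 1–2 →
KCN-1-2; worse = stage 3–4 → KCN-3-4. The worse-eye rule is the minimal
rule consistent with the category names and is deliberately isolated in
a single function so an alternative recode table can be swapped in. It
is symmetric in the two eyes and monotone in severity. Interocular
scalar differences are absolute OD−OS differences; an astigmatism
difference ≥ 1.0 D flags anisoastigmatism.

## Synthetic cohort generator

The generator is the test substrate standing in for cohort data that is
not publicly available. The base cornea is a sphere of radius 7.8 mm (a
typical anterior radius of curvature); elevation is the sag
1000·(R − √(R² − x² − y²)) µm, 0 at the apex, missing beyond the
sphere's footprint (as the corners of real exports are). A spherical
base — rather than a biconic — is the simplest surface whose mirrored
pair subtracts to exactly zero, which isolates the injected asymmetry;
it does not attempt physiological realism of corneal shape or of
keratoconus morphology.

Asymmetry is injected into the left eye only (which eye carries it is
irrelevant by the eye-swap antisymmetry): TILT is a plane through the
apex, CONE a centered Gaussian bump, FOUR_LEAF a ρ²cos2θ saddle, MIXED
a seeded Dirichlet-weighted sum. Tilt and astigmatism amplitudes are
parameterized as the field's value at the 6.0 mm zone edge (3 mm from
the apex) so modes of equal amplitude are visually comparable.

Defaults, chosen once as realistic study conditions:

| parameter | default | rationale |
| --- | --- | --- |
| base_radius | 7.8 mm | typical anterior corneal radius |
| noise_sd | 1.0 µm | typical central Scheimpflug elevation repeatability |
| cone_sigma | 1.5 mm | paracentral cone footprint; its disk projection over the 6 mm zone is defocus-dominated (≈94% of non-piston energy), matching the radially-growing-gap reading of the cone pattern |
| dropout_fraction | 0.02 | sporadic missing samples of real exports |
| amplitude ranges | 15–40 µm (single-mode cohorts); 5–15 / 30–80 µm (moderate / large severity) | clearly supra-threshold vs. the 2 µm flat RMS, spanning subtle to advanced asymmetry |
| peripheral_artifact_amplitude | 0 (off) | artifacts are injected explicitly in robustness checks |

Noise is i.i.d. Gaussian per cell. Real Scheimpflug noise is spatially
correlated and heteroscedastic (worse peripherally); i.i.d. noise is a
documented simplification, so passing recovery tests demonstrate the
machinery's correctness under controlled conditions, not clinical
classification performance. Peripheral artifacts are confined strictly
outside the 6.0 mm mask (using the complement of the mask itself, so
boundary cells are never touched), which is what makes the
artifact-invariance guarantee exact.

## Rendering

Difference maps are displayed with the spectral diverging palette
(negative dark red, zero bright yellow, positive dark blue) on a
symmetric scale clipped at ±70 µm, cropped to the 6.0 mm zone, missing
cells transparent. Rendering is a deterministic function of the map and
configuration.

## Problem sizes and numerics

The validation suite uses 1000 pair-identity trials, 100 antisymmetry
pairs, 100 oracle vectors (10–3000 values each), 500-case cohorts for
pattern and cluster recovery, and a 50-case end-to-end pipeline run —
sizes at which every stochastic check is far from its decision
boundary while the whole suite runs in seconds. Zonal statistics agree
with the independent brute-force oracle to ~10⁻¹² relative; the
identity checks (flip involution, mirror-pair zero, eye-swap
antisymmetry, artifact invariance) hold exactly in floating point
because they involve only negation, permutation and identical-operand
subtraction. File round-trips are exact to 5×10⁻⁵ µm (4 decimal
places written).

## Known limitations

* The grids of the two eyes are assumed apex-co-referenced; systematic
  reference-plane differences between exports would appear as piston or
  tilt in every difference map.
* Pattern thresholds are operational choices, untested against expert
  visual labels on clinical data.
* The synthetic generator does not simulate posterior surface,
  pachymetry, spatially correlated noise, or realistic ectasia
  morphology; cohort-level published statistics are not reproducible
  without the original non-public data.
* The exact device recode table for bilateral categories is not public;
  the worse-eye rule is an assumption (isolated for replacement).
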