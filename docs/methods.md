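# Methods

## Phantom model

A spermatozoon is modelled as three compartments threaded on a common
medial axis, each optically uniform:

| compartment | geometry | default dimensions | default RI |
| --- | --- | --- | --- |
| head | triaxial ellipsoid, flattened in z | 9.053 × 4.954 × 2.477 µm (HO means; thickness = width/2) | 1.3514 |
| midpiece | cylinder + coaxial core | length 13.926 µm, radius 0.40 µm, core radius 0.25 µm | 1.3629 (core 1.3731) |
| tail | linearly tapered filament | length 46.415 µm, radius 0.35 → 0.10 µm | 1.3580 |

Compartments join with flat cuts perpendicular to the axis, so each
rasterized volume converges to its closed form (ellipsoid, cylinder, cone
frustum) and calibration functions can hit published volumes exactly:
`calibrate_head_axes` solves the ellipsoid semi-axes for a target volume
and aspect ratios in closed form; `scale_to_cell_volume` scales the
flagellar radii to a target whole-cell volume. A sub-voxel axial rod
keeps the tapering ellipsoid tip 26-connected to the midpiece (volume
impact below one voxel layer). The axis can be bent with constant
curvature in the x–y plane; the default is straight.

Head and flagellum lengths are published means; radii and head thickness
are not published anywhere we know of, so the values above are
anatomically plausible stand-ins and are plain dataclass fields. The head
RI implies ≈76 fg/µm³ at the default increment, matching the published
head concentration; the midpiece core sits mid-RI-III, reproducing the
reported confinement of dense (mitochondria-associated) material to the
midpiece; the tail RI is placed in RI-II because the published band table
reports no detectable RI-III in the tail (the published *tail
concentration*, 153.5 fg/µm³, would imply an RI inside RI-III — the two
published numbers are not simultaneously reproducible with a uniform tail,
and we follow the band structure).

Populations are sampled per-parameter from truncated normals (±4 SD and
physical bounds: positive lengths, RI ≥ medium, width ≥ thickness), with
one seeded stream per (group, parameter). Default group statistics are
the published HO/KN 2D means ± SDs at n = 30 cells/group (five bulls ×
six cells, modelled as one flat sample, as in the original analysis).
The generator emulates idealized, noise-free, piecewise-uniform cells; it
does not emulate intra-compartment RI texture, acrosomal cavities,
curvature variation along the flagellum, or instrument noise, so passing
recovery tests validate the measurement chain, not robustness to real
biological variability.

## Forward model and reconstruction

First-order (Rytov) scattering only: the 2D spectrum of the complex
Rytov phase equals the Ewald-sphere cap (kz = √((n_m k₀)² − k⊥²)) of the
3D potential spectrum, shifted by the illumination wavevector and cropped
at the detection NA. Illumination directions are snapped to the FFT
frequency grid to avoid plane-wave leakage. The same discrete cap
(nearest-voxel rounding) is used in the forward and inverse directions,
so reconstruction tests probe the missing-cone/regularization behaviour,
not gridding interpolation error. Multiply-hit frequency voxels are
averaged. Validity requires max Δn ≲ 0.05 (warned, not rejected).

Default optics: λ = 0.532 µm, NA_illum = NA_det = 1.2, n_m = 1.337
(phosphate-buffered saline), 30 azimuthal angles on the maximum-NA cone.
The Lauer-criterion metadata at these defaults is lateral
λ/(2(NA_i + NA_d)) = 110.8 nm and axial λ/((n_m − √(n_m² − NA_d²)) +
(n_m − √(n_m² − NA_i²))) = 355.9 nm, i.e. the instrument-class (110, 360)
nm pair.

Off-axis holograms place the sample field against a tilted plane-wave
reference with a diagonal carrier at 1/3 of camera Nyquist, snapped to
the camera frequency grid (an off-grid carrier delta leaks percent-level
error into the sideband). The camera is oversampled 3× relative to the
tomogram grid: sideband separability at full illumination NA requires
|f_c − f_illum| > 2·NA/λ *and* carrier + signal band below Nyquist, which
a 2× grid cannot satisfy. Demodulation crops the sideband (radius
NA_det/λ around the known illumination frequency), unwraps the phase
(scikit-image), and aligns the free 2π offset to the illumination ramp.
Optional intensity noise is Gaussian at a stated SNR (dB); default off.

Missing-cone correction is a Gerchberg–Papoulis iteration: clamp the
real-space potential to V ≥ 0 (n ≥ n_m, matching the physical
non-negative-contrast prior), restore measured frequency voxels, repeat.
Defaults: 100 iterations, early stop at relative RI change < 1e-4,
divergence declared after three consecutive growing steps. The output RI
map is real, so measured spectrum voxels are preserved up to the
Hermitian projection of the (slightly non-Hermitian) gridded data —
a few 1e-3 relative on the weak-sphere fixture.

Reconstruction quality fixtures run at 64³–128³ voxels of 0.1 µm; the
weak sphere (Δn = 0.01, r = 2 µm) reconstructs with in-cell RMSE ≈ 0.001
and far-background error < 0.001. "Background" excludes a shell of one
lateral resolution length around the object: a band-limited system cannot
reproduce a step to ±0.001 at the boundary voxel itself. The axial
elongation of the uncorrected reconstruction is demonstrated on a
point-like bead (r = 0.15 µm), where the PSF, not the object, dominates
the FWHM (ratio ≈ 2).

## Morphometry

**Medial axis.** The segmented cell is skeletonized; the axis is the
longest geodesic through the skeleton graph, smoothed by a spline
(raw skeleton chains overestimate arclength through lattice effects) and
extended along its end tangents to the sub-voxel mask boundary (the
medial axis of an ellipse stops at the vertex curvature centres, well
short of the tip).

**Boundaries.** The head/midpiece boundary is seeded where the axial
width profile falls below 25% of the maximum head width; the reported
head length and width come from a least-squares ellipse fit to the
profile up to that crossing. The bare threshold crossing under-measures
an ellipsoidal head by ~1.5% (it cuts the far vertex); the fit removes
that bias and makes head length/width recovery limited only by
rasterization (≈0.1%). The 25% labelling rule must exceed the
midpiece-to-head width ratio (~16% at defaults) — configurable. The
midpiece/tail boundary is where the dense (RI-III) core ends: in 3D the
largest axis-projected arclength of core voxels; in 2D the steepest
sustained drop of the on-axis phase profile (the projected optical path
steps down where the core ends), refined by the centroid of the gradient
dip and falling back to a configurable default midpiece length (13 µm)
when no core signature exists. Masks with no recognisable long axis
(principal-axis aspect < 1.3) cannot be oriented and are rejected;
compact head-only objects in 2D are measured by principal-axis extents.

**2D segmentation.** Otsu's threshold capped at 5% of the maximum phase:
a sperm phase image is strongly bimodal in the head but the tail signal
is an order of magnitude weaker, and plain Otsu can amputate the
flagellum. Small gaps are closed morphologically (a real instrument's
diffraction blur closes them physically). Widths are measured by
sub-pixel interpolation of 0.5-crossings along perpendicular profiles.

**Surface area.** Marching cubes on the (hole-filled, for outer surfaces)
binary mask at physical spacing, followed by Taubin non-shrinking mesh
smoothing (50 iterations): volume-domain Gaussian smoothing cannot serve
both curved surfaces (needs σ ≈ 1 voxel) and faceted fixtures (any σ
erodes cube edges beyond tolerance), whereas Taubin leaves planar facets
invariant and removes the staircase bias on spheres to <1%. Per-band
sub-region areas mesh the band mask itself without hole filling —
internal surfaces count, the only convention under which band areas may
exceed the enclosing region's outer area, as the published band tables
show.

**Densitometry.** C = Δn/α with α = 0.19 mL/g (the common value for
protein/nucleic-acid mixtures; configurable), medium RI 1.337. These
defaults reproduce the correspondence between the published RI band
limits and band concentrations. Region dry mass is mean concentration ×
volume (= per-voxel sum by construction); RI values are quantized to 4
decimals before banding so the printed band edges tile without gaps.
Regions with fewer than 10 voxels in a band are reported undetectable.

The published head sphericity (0.67) differs from ψ computed from the
published head volume and area (≈0.70), and the published head dry mass
(6.496 pg) from concentration × volume (≈7.15 pg); the original
aggregation conventions are unknown, and the package does not force
agreement — its own measurements are self-consistent by construction.

## Statistics

Two-sided pooled-variance Student t-tests (the classical choice for this
kind of table; not Welch), sample SDs with n−1, the cell as the
replication unit, no bull-level nesting, no multiple-testing correction
by default (optional Holm). At the published head-width means/SDs and
n = 30/group the exact power at α = 0.01 is 0.89, so seeded replication
studies recover the published P < 0.01 in ≈90% of runs — a property of
the published effect size, not of the implementation.

## Problem sizes

Test fixtures use 0.05–0.2 µm voxels on grids up to 128³ (reconstruction)
and ~45 × 110 × 800 voxels (full-cell phantoms at 0.1 µm); population
simulations use 2–30 cells per group. These sizes were chosen so the full
validation suite completes in minutes on a single CPU while keeping
every voxelization error at least a factor of two inside the stated
tolerances.
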