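# Methods

`craniodot` estimates how scalp measurement locations correspond to the
underlying cortex — the question every NIRS/fNIRS and DOT study must answer
before interpreting its signals anatomically — and how that correspondence
changes with head growth. This note documents the models, the synthetic
data the package runs on, the numerical choices, and the limits of what the
tests demonstrate.

## Head phantoms

The synthetic-data generator produces nested-ellipsoid segmented head
volumes with seven tissue labels (air, scalp, skull, CSF, grey matter,
white matter, other). Real 9- or 10-label segmentations are accepted by
mapping extra labels onto this set through the label-name table. Each
voxel is classified by the radius of its centre relative to the
direction-dependent shell boundaries, so shell thicknesses are exact radial
quantities and the concentric-sphere benchmark has analytically known
geometry.

An `AgeProfile` controls:

| parameter | units | default (packaged range) | role |
|---|---|---|---|
| `semi_axes_mm` | mm | 44–72 (half-width; y = 1.25x, z = 0.95x) | overall head size |
| `scalp_mm`, `skull_mm`, `csf_mm` | mm | 2.6–6.0 / 2.6–6.5 / 2.6–4.0 | shell thicknesses |
| `gm_mm` | mm | 3.0 | cortical ribbon thickness |
| `ap_gap_gradient_mm` | mm | 0 | extra anterior CSF (nasion pole), tapering to 0 at the inion |
| `inferior_gap_gradient_mm` | mm | 2.0–4.5 | extra gap toward the head base (face/neck soft-tissue stand-in) |
| `hemispheric_asymmetry_mm` | mm | 0 | signed one-sided deepening of the GM surface |
| `perturb_amplitude_mm`, `perturb_order` | mm, – | 0, 6 | low-order sinusoidal GM ripple (gyrification stand-in) |

The eight packaged profiles (`2wk` … `adult`) have monotone sizes and
thicknesses. They are plausible-scale configuration defaults chosen once to
emulate infant-to-adult growth — not anatomical measurements — and the
resulting scalp-to-cortex distances (about 8 mm at two weeks to about
16 mm in the adult, frontal/vertex region) sit in the range reported by
the virtual-electrode literature. The inferior gap gradient exists because
on real heads the lowest electrode ring (around the face and ears) is
farthest from the cortex; a latitude-uniform shell stack cannot reproduce
that ordering, so the generator encodes it explicitly. All shell
thicknesses in the packaged profiles stay at or above 2.6 mm so that every
shell remains 6-connected-closed on the default 2 mm grid.

Fiducials (Nz, Iz, Vz, LPA, RPA, plus unused mastoids) are the analytic
extreme points of the scalp ellipsoid. The atlas is an angular-sector
parcellation about the brain centroid: six lobar-style coarse sectors
(frontal, occipital, left/right temporal, parietal/central, cerebellum)
refined by a fixed longitude-by-colatitude grid into 30–48 sublobar
sectors, each nested in exactly one coarse sector. A rotation parameter
shifts the sector boundaries to emulate region borders that move with age.

## Montage construction

The 81 standard 10-10 positions are built from the fiducials alone: the
surface is cut by planes, the resulting closed curves are traced as
polylines (0.5-degree angular sampling, sub-voxel boundary bisection), and
positions are placed at arc-length fractions — the midline sagittal curve
Nz–Vz–Iz at 10% steps; the lowest circumference through the preauricular
points; the second circumference through Fpz/T7/Oz/T8; and one traced row
curve per coronal level. Because the voxelized boundary is a ~half-voxel
sawtooth around the true surface, traced radii are smoothed with a Gaussian
kernel matched to the voxel/arc-resolution ratio before arc lengths are
measured, and point snapping averages a small angular neighbourhood; the
voxel-face boundary is an unbiased estimator of the true surface, so these
estimates track it to a fraction of a voxel without per-phantom bias.

The 10-5 superset (358 locations) and the channel sets (251 source–detector
pairs at the 10-10 level and the same 251 combinations at half span at the
10-5 level) come from a frozen, versioned layout table
(`craniodot._layout`). The published totals fix the enumeration only up to
its counts, and a parity argument shows no left–right symmetric rule can
produce them (every symmetric enumeration of this layout yields even
counts; 251 and 277 are odd). The shipped table is therefore generated by
an explicit deterministic recipe — along-curve triples (122), midline
junction pairs (4), strict layout diagonals (74) and the first 51 wide
diagonals in a canonical ordering for channels; channel half-edge midpoints
merged where layout diagonals cross, plus shortest-arc supplementary pairs
for the 10-5 set — and calibrated so the counts hold. 10-5 midpoint names
follow a systematic convention (row-pair tokens and `h` column suffixes,
e.g. `FFC3h`), since the original naming is not standardized. All final
locations keep at least 0.3 of the nominal inter-electrode step apart on
the ideal layout (0.2 after clustering), far above the half-voxel
deduplication threshold on every packaged head.

Electrode groupings follow the name structure: group 1 = midline (z)
curve; group 2 = lowest circumference (9/10 indices with N1/N2, I1/I2);
group 3 = second circumference (7/8 indices with Fp1/Fp2, O1/O2); group 4 =
the enclosed remainder (11/18/18/34 electrodes). Hemisphere follows name
parity rather than coordinate sign so asymmetric heads do not flip labels;
the frontal vs central/posterior split follows the name prefix (N/F/A
prefixes vs C/T/P/O/I).

## Photon transport

The Monte Carlo engine is a survival-weighted voxel random walk: step
lengths drawn from `exp(-mu_t s)`, exact DDA traversal of voxel boundaries,
weight multiplied by the albedo `mu_s/mu_t` at each interaction with the
absorbed share bookkept, Henyey–Greenstein scattering (with a trig-free
isotropic draw when `g = 0`), continuous track-length fluence tally
(weight x path length per voxel, normalised per launched photon and voxel
volume, units mm^-2), termination on crossing into air, and Russian
roulette below weight 1e-4 with survival probability 0.1. Boundaries are
index-matched by default; a specular Fresnel reflection at the air boundary
(using the axis-aligned face normal) is available behind a flag. The weight
ledger (absorbed + escaped + roulette net = launched) closes to float
precision and is asserted at 1e-6.

Randomness is counter-based: each photon's stream is a splitmix64 sequence
seeded from (run seed, photon index), so fluence volumes are bit-reproducible
and independent of execution order.

Validation compares shell-averaged fluence in a homogeneous medium
(`mu_a = 0.01/mm`, `mu_s' = 1.0/mm`) against the infinite-medium diffusion
closed form `exp(-mu_eff r) / (4 pi D r)`; with 1e6 photons the two agree
within a few percent at r = 5–20 mm (the suite asserts 15%). The
anisotropic path is validated directly against the HG distribution's first
two moments, plus conservation and decay checks; a full diffusion
comparison at `g = 0.9`, `mu_s = 10/mm` converges the same way but needs
roughly tenfold more compute, so the routine suite exercises it at reduced
photon counts.

Default optical properties are configuration, not reproduction: they are
plausible ~800 nm tissue coefficients expressed in reduced-scattering form
(`g = 0`, `mu_s` set to a typical `mu_s'`), which leaves diffuse transport
beyond one transport mean free path unchanged while keeping desk-scale
runs affordable. Anisotropic tables can be supplied wherever properties are
accepted.

## Distance estimators

* **Scalp projection** — march from the scalp position toward the
  brain-mask centroid in quarter-voxel steps; the first brain-mask entry,
  refined by bisection to 0.05 mm, is the cortical intersection.
  "Closest intersection" is read as first-entry-along-ray; a
  global-nearest-surface-voxel variant is available behind a flag.
* **Direct DOT** — the brain voxel with maximum single-optode fluence
  inside a 15 mm sphere; distance from the electrode to that voxel centre.
* **S-D channel DOT** — the voxel with maximum PMDF (voxelwise product of
  source and detector fluence) inside the sphere; distance from the
  channel's scalp location (the centre electrode, the point equidistant
  from source and detector).

The search sphere is centred on the cortical projection point of the
location by default; centring on the raw scalp location is a flag, since
both conventions appear in the literature and they cannot both be exact.
Argmax ties break toward the scalp position, then by lowest linear index.
Distances are measured to voxel centres; no sub-voxel peak interpolation is
attempted (quantization is at most half a voxel). Where several channels
share a centre electrode, the reported per-location S-D distance is the
mean over those channels, with the shortest-separation channel's peak as
the location's cortical anchor for ROI mapping.

## ROI mapping and consistency

For each location and method, the atlas regions of the brain voxels inside
the 15 mm sphere at the method's cortical anchor are tabulated as
percentages of the in-mask **brain** voxel count (the full-mask denominator
is a flag). All regions are recorded in machine-readable output; the 25%
threshold (boundary-inclusive) applies only to derived views. Cross-age
consistency compares the thresholded region sets across profiles:
identical non-empty sets = consistent, non-empty intersection = partial,
empty intersection = discrepant. These classes are monotone non-improving
in the threshold. Channel specificity divides each region's summed PMDF by
the total in-brain PMDF.

## Pipeline and problem sizes

`run_pipeline` executes phantom → montage/channels → projections → fluence →
PMDF → distances → look-up tables per profile, then cross-profile
summaries, ordering checks, and the consistency report; a failing profile
is recorded and the others continue. Per-optode seeds derive from
(master seed, profile, optode name) via SHA-256, so adding optodes never
perturbs others. Summaries are descriptive (cell means/SDs/counts);
no inferential statistics are computed.

Routine runs use 2 mm voxels and 8,000–10,000 photons per optode. On these
phantoms a photon walk terminates quickly (small heads, absorbing tissue),
so all 81 electrodes of all eight profiles simulate in about a minute, and
profile-mean Monte Carlo noise (< 0.2 mm) stays well below the 0.5–2.5 mm
spacing between adjacent profiles. The anterior-gradient recovery check
uses 1 mm voxels so face quantization stays inside its ±1 mm band. The
1e6-photon diffusion validation is the single most expensive test (about
1–2 minutes).

## What passing tests do and do not show

The phantoms exercise every geometric and probabilistic mechanism of the
analysis — shell ordering, montage combinatorics, projection geometry,
transport physics, mask bookkeeping, cross-age classification — under known
ground truth. They do not contain cortical folding, a real interhemispheric
fissure, anisotropic skull structure, or realistic atlas anatomy, so
passing tests validate the machinery and its scaling behaviour, not the
specific millimetre values or region assignments one would obtain on real
MRI-derived head models. Orderings that on real heads arise from anatomy
the phantom lacks (e.g. midline electrodes being deeper than the second
circumference) are reported by `check_orderings` but not asserted.

## Known limitations

* Star-shaped-surface assumption in the scalp tracer (valid for the
  phantoms and typical heads; not for arbitrary topologies).
* Voxel transport only; no mesh-based variant, time gates or frequency
  domain.
* The Fresnel option reflects off axis-aligned voxel faces, which
  overestimates specularity on oblique surfaces.
* The layout table reproduces the published enumeration's counts, not its
  (unpublished) exact membership.
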