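# Methods

This note documents the models, conventions and numerical choices behind
`osteoquant`, in the order the pipeline runs them.

## Coordinate and geometry conventions

All volumes are `(depth, width, slices)` arrays with physical coordinates
`index * voxel_mm + origin_mm`; axis 0 points away from the transducer, so
"lowest depth" is the smallest row index. The stabilizing shell is a rigid
cylinder (axis point at the rostral endcap center, unit axis direction,
outer radius R, length L). In-plane polar angle θ is measured from the ray
pointing at the transducer, positive toward increasing lateral coordinate;
the half visible to the probe is |θ| < π/2. All markers use the shell's
**outer** surface, consistent with deposits forming on the shell exterior.

The cylinder is fitted to rim landmarks by initializing the axis with the
point cloud's principal direction and refining (axis direction, in-plane
axis offset, R) with Levenberg–Marquardt on the radial residuals
Σ(dist-to-axis − R)². Collinear or coplanar landmark sets are rejected —
a coplanar set does not constrain a cylinder. Axis orientation is made
deterministic by pointing it toward increasing slice index.

## Ultrasound surface detection

Bone interfaces are thin bright (hyperechoic) ridges. Detection is local
*phase symmetry* from a quadrature filter pair: a single-scale,
single-orientation 3-D log-Gabor band-pass (radial transfer
`exp(−(log(f/f₀))²/(2 log²σᵣ))`, zero DC) restricted to the frequency
half-space along the depth axis with a Gaussian angular spread. The inverse
transform's real part is the even (symmetric) response, its imaginary part
the odd response, and

    sym = max(even − |odd| − T, 0) / (E + ε),   E = √(even² + odd²).

Two deliberate choices here:

- **Polarity.** The measure is polarity-sensitive (`even`, not `|even|`).
  Full-wave rectification also fires on the dark side lobes that any
  band-pass response develops around a bright ridge, which manifests as
  striped false surfaces about half a wavelength above the true one and a
  systematic shallow bias of the extracted profile. Bone is bright; only
  positive even symmetry counts.
- **Noise floor.** `T = noise_k · mean(E)` rather than a median-based
  estimate: in sparse scenes most voxels carry no signal, the median energy
  is ≈ 0, and the contrast normalization would then amplify numerically
  tiny filter leakage into full-strength responses in empty regions. The
  mean tracks the volume's overall energy scale in both sparse and
  speckle-filled volumes. ε is relative to mean energy, which makes the
  response exactly invariant to global positive rescaling of the input.

The volume is reflect-padded by two wavelengths before the FFT; without the
padding, circular convolution wraps the bright skin band onto the far depth
border and produces border detections.

Defaults: center wavelength 4 voxels' physical size (must be ≥ 2 voxels),
bandwidth ratio σᵣ = 0.55 (≈ 2 octaves), angular spread π/4 rad so surfaces
tilted up to ~45° off the beam still respond, `noise_k` = 2, ε = 10⁻³.

Preprocessing is depth-gain compensation plus a 3×3×1 median filter. The
gain curve (target mean / per-depth mean) is smoothed with a 1.5 mm
Gaussian before application and clipped to [1/10, 10]: an unsmoothed
per-row equalization imprints kinks at ridge-onset rows that the
level-surface detector reports as a false horizontal interface.

Binarization thresholds the response at its 98th percentile (bone surfaces
are sparse; a percentile is robust to global gain). Cleanup removes, in
order: components touching the lateral/longitudinal image borders; all
voxels shallower than `skin_band_mm` (set to skin depth plus two
wavelengths of ringing clearance when driven from the phantom pipeline);
voxels within `shell_exclusion_mm` of the fitted shell surface inside its
axial extent — these delineate the bare shell, while genuine deposit
surfaces sit a full deposit thickness above it; an optional user-supplied
exclusion mask (e.g. vessel lumina — the package deliberately does not
guess an automatic vessel detector); and finally 26-connected components
smaller than `min_component_voxels`. Cleanup only ever removes voxels.

## CT segmentation

The bone/soft-tissue threshold is estimated per scan from the defect zone —
the axial range where native bone is absent — so cortical bone cannot bias
it. Intensities are sampled from a radial band outside the shell's outer
surface (defaults: 0–8 mm beyond R, excluding the shell wall), and an Otsu
threshold (between-class variance over a 256-bin histogram) is applied to
the Gaussian-smoothed volume (σ = 0.3 mm, sub-voxel: suppresses noise
without eroding ≥ 1 mm deposits), followed by the same area opening.

Otsu tie-breaking: when several candidate bin edges tie (an exact plateau,
as happens whenever the inter-class range contains no samples — e.g. a
noise-free two-valued image), the threshold is the plateau midpoint. This
places the cut between the classes instead of hugging the lower one, which
matters for exactly two-valued inputs; with noisy data the argmax is unique
and the rule never engages.

## Per-slice morphometry

US masks are thin detection bands: each slice is skeletonized, spur
branches shorter than `prune_len_px` (default 5) ending at a junction are
pruned (open arcs are never pruned — they are the surface itself), and the
lowest-depth skeleton pixel per image column is kept, resolving
partial-occlusion ambiguity. The skeleton centerline places the surface at
the middle of the band, which is where the symmetric response is centered.
CT masks are solid bulk; skeletonizing them would yield the medial axis
(halving NBB), so their surface is the outer envelope — the shallowest
foreground pixel per column (`thin=False`).

The profile is smoothed with a cubic smoothing spline in the penalized
least-squares convention

    p · Σ residual² + (1 − p) · ∫ f″²,

so p = 1 interpolates; the default p = 0.5 weighs fidelity and roughness
equally under this convention. (A bare "smoothing parameter" is meaningless
without fixing the convention; this one is the form in which 0.5 is a
documented midpoint.) The solver maps p to the equivalent penalty
λ = (1−p)/p; it needs at least 5 support points, so runs of up to 4
detected columns pass through unsmoothed (logged). Fitting is per
contiguous run; gaps wider than `max_gap_columns` (default 3) split runs
rather than being bridged.

Marker construction per slice: curve points are converted to polar
coordinates about the shell cross-section center and clipped to ρ ≥ R —
NBB is deposited bulk, so curve excursions inside the shell cannot count
negative; a curve crossing the circle contributes only its outside lobes.
The region polygon is [curve → radial drop → shell arc back → radial rise]
and its area is the shoelace sum (arc discretized at 5 mrad). The perimeter
is split with a contact tolerance of one in-plane voxel diagonal ("on the
shell" needs a numeric tolerance on a grid): per deposit interval, NBC is
the projected arc R·Δθ and NBS the curve polyline plus the two radial
closure segments; exposed shell arcs *between* deposit intervals are added
to NBS, and only when deposits flank the gap on both sides within the
detected lateral extent — the bulk-fill assumption presumes bone on both
sides.

Slices with no detected bone and slices outside 5–95% of the shell length
are excluded; retained slices are labeled proximal (5–35%), middle
(35–65%) or distal (65–95%), with half-open boundaries toward distal.
Normalizations: NBB by FOV area in percent (the full B-mode frame, the
natural configurable choice when no crop is defined); NBS by π·R as a plain
ratio; NBC by π·R in percent — matching the units the three markers are
conventionally reported in.

The mean absolute distance between two surface reconstructions is the
*symmetric* mean of per-point nearest-neighbor distances (average of the
two directed means over the profile point clouds, KD-tree queries in mm);
the directed/symmetric choice is a convention, flagged here because only
the symmetric form is order-independent. Comparisons are made after
restricting both masks to the intersection of their bone-bearing
lateral/slice extents.

## Statistics

Bland-Altman limits use the fixed 1.96 normal multiplier and the n−1
sample SD — the convention that reproduces published worked examples of
this analysis at printed precision. The t-test is two-tailed Student's,
paired across slices by default (slices are matched between scans and
modalities); an unpaired variant is available behind
`StatsConfig(paired=False)`. Repeated-scan markers are averaged slice-wise
before cross-modality comparison. Sheep-level clustering is deliberately
not modeled: slices are pooled, matching how such markers are normally
reported.

## The phantom: what it emulates and what it does not

The generator renders geometric interfaces plus noise, not wave physics.
It emulates exactly the image properties the pipeline consumes: a bright
ridge at the first bone-or-shell interface along each probe ray, acoustic
shadow beneath it (nothing deeper is visible), multiplicative speckle with
mean 1 and configurable SNR (gamma-distributed), a bright skin band; and
for CT, a high-intensity bone compartment, a radio-lucent shell wall close
to soft-tissue intensity, and additive Gaussian noise. Deposits are angular
sectors of constant radial thickness with closed-form per-slice markers
(`true_slice_morphometry`), which is what makes end-to-end accuracy
testable.

It does **not** model refraction, deflection or sound-speed artifacts (real
error sources for bone surface profiles), curved or tapered anatomy,
partially mineralized tissue with intermediate echogenicity, or irregular
deposit shapes. Passing tests therefore demonstrate that the *computational
chain* is unbiased and internally consistent at realistic noise levels —
not that in-vivo accuracy matches the phantom numbers.

Default scene: shell radius 10 mm and desk-scale length 20 mm on a
256×256×120 grid at 0.2 mm isotropic spacing (resolving a 2 mm deposit
with 10 voxels; a clinical-scale 7 cm shell is accepted by configuration
but needs a correspondingly longer grid, since the scene validates that the
shell fits the slice extent). Slice spacing is uniform — an idealization of
freehand cine sweeps, whose true inter-frame spacing is irregular. Speckle
SNR 5 and CT noise SD 20 (2/3 of the soft/shell contrast step) are the
default noise conditions; accuracy checks use SNR 4 as the stress level.
The analysis volumes in tests and the reproduction script are 160×144×60
at 0.2 mm — large enough that a quantified scan spans ~45 slices while the
whole two-scan study runs in seconds.

## Known limitations

- Steep surface segments (|θ| ≳ 60°) lose up to one image column of angular
  extent at each deposit end; NBC on near-vertical flanks carries a
  corresponding discretization error.
- Co-registration between US and CT is accepted as an input rigid
  transform; the package does not register images.
- Markers are 2-D per-slice quantities; volumetric (3-D) analogues are out
  of scope.
- The vessel-lumen exclusion is a user-supplied mask, not an automatic
  detector.
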