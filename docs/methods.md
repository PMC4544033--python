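# Methods

`vimtrace` quantifies the endogenous vimentin network of cultured cells
from live-cell chromobody fluorescence. This note documents the models
and procedures the package implements, the choices that were genuinely
open, and what the built-in simulator does and does not emulate.

## The segments-per-cell readout

Vimentin forms a branching cytoplasmic filament network. The package's
central statistic decomposes that network into *fiber segments* —
maximal branchpoint-free pieces of the skeletonized network — and
normalizes their number by the cell count:

    segments per cell = (total fiber segments over all fields of a
                         condition) / (total segmented nuclei)

This is a pooled population-level ratio, not a mean of per-field
ratios; the two coincide only when weighted by per-field nuclei counts
(an identity covered by a property test). Pooling is the default
because the statistic's denominator is the entire imaged cell
population; the unweighted mean of field ratios is available via
`segments_per_cell_table(..., pooled=False)`.

Relative (drug-response) series divide each condition's segments per
cell by the untreated control *at the same time point*; the control is
therefore 1.0 everywhere and the normalization is invariant to any
global rescaling of a time point's raw measurements.

### Fiber segmentation

1. **Ridge enhancement.** Multi-scale Hessian tubeness: at each scale
   σ ∈ {1, 2, 3} px the image is smoothed with a Gaussian of that σ and
   the response is `max(0, −λ_min) · σ²`, where λ_min is the smaller
   eigenvalue of the Hessian. Bright curvilinear structures curve
   steeply downward across the ridge, so λ_min is large and negative on
   filaments and ≈ 0 on flat background; σ² makes responses comparable
   across scales. The per-pixel maximum over scales is used. Boundary
   handling is reflective — zero padding would fabricate ridges at the
   field border.
2. **Thresholding.** Otsu's method on the response values above their
   median (the tubeness histogram is strongly right-skewed), with a
   robust noise floor of `median + 6 × 1.4826·MAD`. The floor matters in
   near-empty fields (e.g. after vimentin knock-down): with no real
   foreground, Otsu bisects the noise distribution and, unguarded, fills
   the mask with speckle. Connected components under 30 px are removed.
3. **Skeletonization and graph construction.** Topology-preserving
   thinning to a 1-px skeleton; terminal branches shorter than 3 px are
   pruned (thinning artifacts). Skeleton pixels with ≥ 3 8-connected
   skeleton neighbours are branchpoint pixels; 8-adjacent branchpoint
   pixels merge into one node cluster so thick junctions are not
   double-counted. Removing the node pixels splits the skeleton into
   branch-free edges; every skeleton pixel belongs to exactly one edge
   or one node (a conservation property that is tested). Edge length is
   polyline arc length (√2 per diagonal step) times the pixel size.
4. **Decomposition.** Every edge of length ≥ 1 µm is one fiber segment;
   branchpoint-free cycles count once. Spur length and the minimum
   segment length are configuration knobs — no published value exists
   for either, so the defaults are declared, not reconstructed. The
   3-px spur default was chosen over a longer one because aggressive
   pruning removes genuine short arms in dense networks and makes the
   measured count sub-linear in the true density, which would bias fold
   changes downward.

On synthetic ground truth the measured/true segment-count ratio stays
within ~5 % of unity from 0.3 to 30 true segments per cell, which is
what makes ratio readouts (fold changes, dose responses) accurate even
though the absolute count carries small systematic errors (occasional
fiber crossings add segments; merged parallel fibers remove them).

### Nuclei counting

Gaussian smoothing (1 µm) → Otsu threshold → hole filling → watershed
on the Euclidean distance transform, seeded at its local maxima (min
separation 10 px) → area filter 30–500 µm². Counting is invariant to
intensity offset and gain because only the histogram shape enters.
Border-touching nuclei are **kept** by default: the statistic divides by
the population, it does not do per-cell morphometry; a `keep_border`
flag exposes the alternative. Defaults are declared values at 0.325
µm/px; none are published.

### Aggregate (granule) classification

Bright puncta are detected with a multi-scale Laplacian-of-Gaussian
blob detector and kept when the peak exceeds the local annulus median
by ≥ 100 intensity units (offset-invariant). Each punctum is assigned
to the nearest segmented nucleus within 30 µm, and a cell is
*aggregate-positive* when it carries ≥ 3 puncta. The positive-fraction
comparison between constructs uses the 2×2 Pearson chi-squared test
without continuity correction (hundreds of cells per group); condition
means use the two-tailed pooled-variance Student's t-test. The ≥ 3
threshold and the 30 µm radius are declared defaults.

## FRAP recovery analysis

Raw traces carry the mean intensity of the bleached region, a cell-free
background region, and the whole cell, at 294 ms intervals with 5
prebleach and 145 postbleach frames. Double normalization corrects for
background and for the total loss of fluorescence caused by imaging:

    I_norm(t) = (roi(t) − bg(t)) / (roi_pre − bg_pre)
              × (whole_pre − bg_pre) / (whole(t) − bg(t))

with `*_pre` prebleach means, so the prebleach level is 1 by
construction and any common rescaling of the three channels cancels.
The whole-*cell* trace is used for the loss correction (whole-image
would also be defensible; it is not what the trace schema carries).

The recovery model is a single exponential

    I(t) = I0 + (A − I0) · (1 − e^(−k t)),     t½ = ln 2 / k

where `A` is the end value of the normalized intensity (the mobile
fraction) and `I0` the residual bleach depth. `I0` is a *fitted*
parameter (bounds −0.2…0.95, with A ∈ [0, 1.2], k ∈ (0, 10] s⁻¹):
fixing it at the first postbleach sample makes small-amplitude
recoveries ill-posed — a single-frame error of the order of the noise
moves the global least-squares optimum onto the k → 0 ridge, where the
fitted plateau is pure extrapolation. The optimizer (trust-region
least squares, tolerances 1e-10) is multi-started over several rate
guesses and the lowest-residual solution kept. A solution pinned at a
parameter bound means plateau and rate are not identifiable from that
trace (typically: the recovery never levels off within the ~43 s
window); such fits are flagged `converged=False` and excluded from
group summaries. Tests verify that the converged fit's residual is
never worse than a dense grid search over the offset-fixed model class.

Binding kinetics: for a 1:1 interaction the equilibrium dissociation
constant is `K_D = k_off / k_on`, reported in nM. The package reports
the computed ratio; no rounding to externally printed affinities is
attempted.

## The synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated; its defaults are fixed and the treatment regimes are encoded
as ground-truth density multipliers.

**Fields.** 0.325 µm/px (40× class), two channels, 16-bit with
saturation clipping, Gaussian PSF σ 0.35 µm, Poisson shot noise at unit
gain plus Gaussian read noise (σ 3). Nuclei are rotated ellipses
(semi-major 4–6.5 µm, dart-thrown with a configurable pairwise-overlap
budget, default non-overlapping). Fibers are correlated random walks
(von Mises turning, κ = 300, 1 px steps, 8–20 µm long) that nucleate on
a perinuclear annulus 0.5–3 µm outside the nucleus with stratified,
outward headings — reproducing the radially organised perinuclear cage
of chromobody-labelled vimentin and keeping dense networks measurable
rather than an isotropic tangle. A branch event (p = 0.02 per step)
terminates the current polyline and spawns a continuation plus a side
branch at ±60°, so each logged polyline is exactly one
branchpoint-delimited segment: the generator's truth and the pipeline's
readout share one segment definition. Per cell the number of segments
is Poisson with mean `fibers_per_cell` (baseline 3 — a weak but present
network in untreated cells; induction/knock-down regimes multiply it).
A diffuse unbound-chromobody pool (15 % of fiber intensity over the
cell body) and optional Poisson-per-cell granules (Gaussian spots, σ
0.5 µm, placed 1.2–3 nucleus radii from the centre, resampled to stay
in the field) complete the fiber channel. Every rendered primitive is
logged; identical (config, seed) pairs are byte-identical.

**FRAP traces.** Latent recovery `bleach_depth + (A − bleach_depth)(1 −
e^(−kt))` scaled by an acquisition-bleaching envelope `e^(−rt)` that
also decays the whole-cell trace, plus i.i.d. Gaussian noise per
channel; defaults follow the acquisition protocol above.

**What it does not emulate.** 3-D structure, realistic optics (Airy
PSF, spectral bleed-through), cell motility, intensity heterogeneity
along a filament, filament bundling/thickness variation, and any
photophysics beyond single-exponential acquisition bleaching. Passing
tests therefore demonstrate that the measurement chain is unbiased and
monotone *for curvilinear networks of known topology under realistic
CCD noise* — not that it reproduces any particular instrument's output
on real cells.

## Problem sizes used in validation

Validation conditions use 512×512 px fields with 8 cells per field and
20 fields per condition (160 pooled nuclei, comfortably above the
100-cell floor the pooled statistic warns at). The vimentin knock-down
arm carries only ~0.3 segments per cell, so it uses 60 fields: at 20
fields its pooled count (~50 segments) would fluctuate by ~14 % from
generator sampling alone, swamping the quantity under test. Aggregate
regimes use 16 cells per field × 20 fields (320 cells per construct);
their per-cell granule rates (4.3, 1.75, 1.28) are the Poisson rates
whose P(N ≥ 3) equals the regime's target positive fraction. FRAP
validation uses 10 traces per regime at 3 % noise, mirroring typical
group sizes for such experiments.

## Known limitations

- Absolute segment counts are resolution- and parameter-dependent
  (threshold floor, spur length, minimum segment length); only ratios
  between conditions processed with one parameter set are comparable.
- Fiber crossings are split at the crossing point: a dense isotropic
  mesh would be over-segmented. The radial-geometry simulation regime
  deliberately keeps crossings rare, as they are in perinuclear cages.
- The watershed splits nuclei reliably up to ~30 % pairwise overlap;
  beyond that, under-segmentation grows and the 5 % count guarantee no
  longer holds.
- FRAP fitting assumes a single kinetic component; reaction–diffusion
  models and two-component recoveries are out of scope, and traces
  whose recovery does not level off within the acquisition window are
  reported as non-identifiable rather than extrapolated.
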