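# vimtrace

High-content quantification of the endogenous vimentin filament network
from live-cell chromobody fluorescence.

Vimentin is the canonical mesenchymal intermediate filament and a
marker of epithelial–mesenchymal transition (EMT). A
chromobody — a vimentin-specific nanobody fused to GFP — makes the
endogenous network visible in living cells without tagging vimentin
itself, which opens the door to time-lapse, dose–response phenotypic
screens. The bottleneck is turning images of a dense, branching
filament network into a number. `vimtrace` implements that readout,
plus the companion kinetic analyses, for people building or validating
such screens: image analysts, assay developers, and anyone who needs a
fully synthetic, ground-truthed testbed for filament-network
segmentation.

## The readout

The filament channel is enhanced with a multi-scale Hessian tubeness
operator, thresholded, thinned to a one-pixel skeleton, and split at
branchpoints (skeleton pixels with ≥ 3 neighbours) into individual
**fiber segments**. Nuclei counted from the Hoechst channel give the
denominator:

    segments per cell = Σ fiber segments / Σ segmented nuclei

pooled over all fields of a condition. Treatment responses are
expressed as fold changes or as values relative to the untreated
control at the same time point. Aggregate-prone constructs are
quantified as the fraction of cells carrying ≥ 3 bright puncta
(chi-squared-tested between constructs).

FRAP (fluorescence recovery after photobleaching) traces are
double-normalized — background-corrected and corrected for total loss
of fluorescence during imaging — and fitted with the single-exponential
recovery I(t) = A·(1 − e^(−kt)) (with a fitted residual bleach-depth
offset), giving the mobile fraction A and half-time t½ = ln 2 / k. For
1:1 binding kinetics, K_D = k_off / k_on.

Because no public dataset accompanies this kind of assay, the package
ships a first-class synthetic-data module: two-channel fields with
elliptical nuclei and perinuclear branching filament networks of known
topology (every fiber, nucleus and granule is logged as ground truth),
with PSF blur, Poisson shot noise and Gaussian read noise; and FRAP
traces with known plateau, rate, bleach depth and acquisition
bleaching. All measurement code is validated against this ground truth.

## Worked example

```python
import math
from vimtrace import (SimulationConfig, generate_field, segment_fibers,
                      segment_nuclei, FrapSimParams, simulate_frap_trace,
                      normalize_frap, fit_recovery, kd_from_rates)

# a field of 8 cells with a strongly induced network (~21 segments/cell)
cfg = SimulationConfig(field_shape=(512, 512), n_nuclei=8,
                       fibers_per_cell=21.0, seed=42)
img, truth = generate_field(cfg)
segments, graph, mask = segment_fibers(img.fiber_channel,
                                       pixel_size=cfg.pixel_size)
nuclei = segment_nuclei(img.nuclear_channel, pixel_size=cfg.pixel_size)
print(f"true segments:     {truth.true_segment_count}")
print(f"measured segments: {segments.total_count}")
print(f"segments per cell: {segments.total_count / nuclei.nuclei_count:.2f}")

# a fast, high-mobility FRAP recovery with 3% noise
p = FrapSimParams(plateau=0.841, k=math.log(2) / 3.9, noise_sd=0.03)
fit = fit_recovery(normalize_frap(simulate_frap_trace(p, seed=1)))
print(f"FRAP plateau A = {fit.A:.3f}, t1/2 = {fit.t_half:.2f} s")
print(f"K_D = {kd_from_rates(4.75e5, 1.76e-2):.1f} nM")
```

prints

```
true segments:     169
measured segments: 171
segments per cell: 21.38
FRAP plateau A = 0.828, t1/2 = 3.98 s
K_D = 37.1 nM
```

The measured segment count tracks the generator's ground truth within a
few percent, the FRAP fit recovers the generating plateau/half-time
within the noise, and the affinity is the printed-rate ratio in nM.

A command-line pipeline wraps the same functions
(`vimtrace simulate | segment | quantify | frap | all`), configured by a
single YAML file with a root seed; every run writes tidy CSV tables and
a manifest (config hash, seed, versions) that reconstructs it exactly:

```
vimtrace all --config examples/induction.yaml --seed 1 --out run1
```

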