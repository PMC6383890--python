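# Methods

`micest` implements the quantitative chain of a CEST-MRI neuroinflammation
experiment: multi-pool saturation-transfer simulation, WASSR-based B0
mapping and correction, MTR asymmetry quantification at 0.6 ppm, microglial
soma morphometry on Iba-1 histology, LCModel-table quality control, and
paired LPS-vs-vehicle group statistics. This note records the models, the
parameters that matter, the numerical choices, what the synthetic data do
and do not emulate, and the known limitations.

## Bloch-McConnell model

Magnetization of N exchanging proton pools under a constant-amplitude
(hard) saturation pulse follows the linear system `dM/dt = A M + b`, where
`M` stacks (Mx, My, Mz) per pool. `A` carries transverse/longitudinal
relaxation (R2 = 1/T2, R1 = 1/T1), off-resonance precession at
`2*pi*f_ppm*(delta_i - Delta)` rad/s (with `f_ppm = B0 * 42.577` Hz/ppm;
400.2 Hz/ppm at 9.4 T), RF nutation at `omega_1 = 2*pi*42.577*B1[uT]`
rad/s, and two-site exchange between water and each solute. Exchange uses
the solute-to-water rate `k` with the detailed-balance reverse rate `f*k`
(`f` = solute equilibrium fraction), so net flux vanishes at thermal
equilibrium — asserted by a test on the assembled matrix.

Two solution modes:

- **steady_state** — the fixed point `-A^{-1} b`, the continuous-wave
  limit. For a single pool this reduces exactly to the textbook CW result
  `Z = (1 + (2*pi*df*T2)^2) / (1 + (2*pi*df*T2)^2 + omega_1^2*T1*T2)`,
  which the package also ships as an independent closed-form oracle.
- **time_evolved** — the exact propagation
  `M(t) = M_ss + expm(A t)(M_eq - M_ss)` over the pulse duration. Because
  the system is linear time-invariant under a hard pulse, the matrix
  exponential is the exact solution; no adaptive ODE integration (and hence
  no stiffness failure mode) is involved. A deliberately naive fixed-step
  RK4 integrator lives in the test suite as an independent cross-check.

Offsets are simulated independently from thermal equilibrium; readout and
inter-offset recovery are not modeled. Shaped pulses, B1 inhomogeneity and
super-Lorentzian macromolecular lineshapes are out of scope.

### Default pool set (9.4 T)

The shipped `data/default_pools.yaml` is a plausible parameterization, not
a measured one: water (T1 1.8 s, T2 40 ms), a hydroxyl solute at +0.6 ppm
with k = 600 1/s (the slow-to-intermediate exchange regime of myoinositol
-OH protons; T1 1.0 s, T2 10 ms), and a broad macromolecular pool at
-2.4 ppm (T2 0.5 ms, fraction 0.001, k 40 1/s). The hydroxyl fraction
(0.0037324) was calibrated once, by root-finding, so that the simulated
MTR asymmetry at 0.6 ppm under the standard schedule (1.6 s, 0.9 uT,
steady-state mode) equals 8.2% — the scale of the in vivo vehicle-side
contrast — and the phantom lesion multiplier (1.4079) raises it to 10.7%,
the in vivo LPS-side level in responder animals. These two anchors define
the synthetic study conditions and are frozen.

## Synthetic data

All generators are pure functions of (spec, seed); identical inputs give
bit-identical outputs, and each returns a ground-truth bundle sufficient to
score the downstream pipeline.

**CEST/WASSR phantom.** Default geometry follows the acquisition protocol:
128 x 128 matrix over a 20 x 20 mm field of view; two non-overlapping
1.25 x 1.25 mm ROIs ("LPS" lesion at (6.25, 10) mm, "PBS" control at
(13.75, 10) mm — 8 x 8 pixel windows at full resolution). CEST offsets are
the symmetric 0.2-ppm comb over +/-4 ppm (41 points; the protocol's "40
offsets" is geometrically ambiguous, so the offset list is explicit and
configurable); WASSR uses 35 uniform offsets in +/-1 ppm (spacing unstated
in the protocol; uniform chosen). Each voxel's z-spectrum is the
Bloch-McConnell solution with the voxel's hydroxyl-fraction multiplier and
with the offset axis shifted by a smooth polynomial B0 field (optionally
plus a localized Gaussian "susceptibility artifact" bump). Noise is
additive Gaussian on magnitude images (Rician behind a flag; at the SNR
simulated, reference intensity 1000 with sd 1%, the Gaussian approximation
is accurate and keeps oracles analytic). Phantom spectra default to
steady-state mode: it is exact against the closed-form oracle, an order of
magnitude faster than voxelwise matrix exponentials, and the asymmetry
calibration above was performed in the same mode, so generator and truth
are self-consistent.

The phantom does not emulate: anatomy, partial volume, readout point-spread,
scanner drift, or B1 variation. Passing tests therefore demonstrate
correctness of the processing chain under the stated physics, not
robustness to those real-data effects.

**Histology slides.** Dark elliptical somata (default 50 per 512 x 512
frame at 0.46 um/px; area ~ Normal(40, 8) um^2, the scale of quiescent
microglial somata at 20x) on an uneven bright background (linear gradient
plus a smooth sinusoidal modulation), with thin 1-px processes radiating
from each soma as distractors. Ground truth is the rasterized ellipse area
only; processes must be rejected by the segmenter's size filter.

**Metabolite tables.** LCModel-style rows (concentration, %SD, linewidth,
SNR) for eight metabolites per spectrum, two spectra (LPS/PBS) per subject.
Baselines give mI/tCr = 0.70 (mI 5.6, Cr 4.0, PCr 4.0); the default
LPS-side mI effect is +17.1%, i.e. 0.82/0.70 - 1, matching the responder
contrast. Linewidths draw from Normal(12.9, 0.8) Hz and SNR from
Normal(8.9, 0.6) — the reported cohort-level spectral quality. Injectable
violations (linewidth > 25 Hz, %SD > 10%) exercise the QC gates.

**Synthetic cohort.** Six effect subjects (lesion fraction multiplier
1.4079, soma shift +10 um^2, mI effect +17.1%) and six nulls, with 4%
between-subject variability on the base hydroxyl fraction. The two
hemisphere slides of one slice share the same soma field and differ only by
the activation area shift, so the per-slice soma-size difference isolates
the effect (and is exactly zero for nulls). Cohort runs use a 32 x 32
phantom grid and 256 x 256 slides with 5 slices per subject — problem sizes
chosen so a 12-subject study completes in seconds while every ROI retains
multiple voxels; the full-resolution defaults remain available per phantom.

## WASSR B0 mapping

Per voxel, the normalized WASSR spectrum is interpolated with a natural
cubic spline onto a 0.001-ppm grid and the maximum-symmetry center is found
by brute force over candidate centers at 0.005-ppm spacing within the
search range (default +/-0.3 ppm), scoring each candidate by the mean
squared difference between the spectrum and its mirror image about the
candidate, evaluated only where both mirror partners fall inside the
sampled range (no extrapolation; at least 25 dense points of overlap). The
discrete minimum is refined by a parabolic fit through its neighbors.
Candidates whose minimum sits on the search boundary, and voxels with
non-finite data, are flagged invalid. The estimator is translation
equivariant and unbiased on symmetric spectra across T1/T2 (both asserted).

The subject-level B0 gate compares the two ROI mean shifts (medians behind
a flag): the subject passes when |difference| <= 0.05 ppm; an ROI with no
valid voxel is "unmeasurable" and fails.

## Z-spectrum processing and MTR asymmetry

Processing order is fixed: normalize by the reference image (voxels at or
below the intensity threshold are masked) -> natural cubic spline onto a
0.01-ppm grid anchored at 0 (so +/-0.6 ppm are grid points) -> translate
the frequency axis by the voxel's shift and resample on the original grid,
dropping offsets that leave the sampled support -> evaluate

    MTR_asym(dw) = 100 * (M_sat(-dw) - M_sat(+dw)) / M_0   [percent].

No smoothing is applied (a smoothing parameter exists in the API, default
off), and no Lorentzian line fitting is attempted: with hydroxyl lines
merged into the water dip a Lorentzian decomposition is ill-posed, which is
why asymmetry analysis is used at 0.6 ppm. The asymmetry map evaluates the
per-voxel spline at the two shifted readout points directly (vectorized
across voxels); a test verifies it equals the per-voxel composition of the
three steps above.

### Known limitation: interpolation-limited round-trip accuracy

With 0.2-ppm sampling, cubic-spline interpolation of the exchange line
(k = 600 1/s gives ~0.24 ppm half-width at 9.4 T, amplitude ~8% M0 at the
calibrated fraction) carries a sub-grid-position-dependent bias of up to
~0.24 percentage points in the asymmetry readout: it vanishes when the B0
shift is a multiple of the sampling step and peaks near half-grid shifts.
(Errors from the symmetric direct-saturation dip cancel between the two
readout points to < 0.01 pp.) A second term of similar size enters through
the WASSR estimate: the asymmetry readout has ~150 pp/ppm sensitivity to
shift error on the steep z-spectrum flanks at +/-0.6 ppm, and the
maximum-symmetry estimator carries a ~0.001-0.0015 ppm spline-induced bias
of its own (35 offsets at ~0.059 ppm spacing against a ~0.07 ppm half-width
dip). The measured pipeline-level worst case of the full round trip
(simulate with shift -> WASSR -> correct -> asymmetry vs the unshifted
analysis) is ~0.5 pp over |shift| <= 0.3 ppm, noiseless. A sweep across
interpolant families (higher-order B-splines, PCHIP/Akima, Floater-Hormann
rational, transformed-domain and analytic-baseline-residual splines) shows
this is information-limited by the acquisition schedule, not by the choice
of spline; the property test bounds the residual at 0.6 pp. Within-study
comparisons are affected far less than absolute values, because the bias is
shared between the two ROIs of a subject when their B0 values are close —
which is exactly what the 0.05-ppm homogeneity gate enforces.

## Morphometry

Segmentation: mean-filter blur (3 px) -> local background as a 95-px mean
-> foreground where the blurred image falls more than 30% below the local
background -> 8-connected components -> physical size filter 10-150 um^2
(rejecting 1-px-wide processes and clumps). The blur window and threshold
were tuned on held-out synthetic slides for unbiased area recovery (~1%
median-area error at 100% detection); all are configuration. The manual
correction step of interactive workflows is externalized as a
`drop_regions` list, keeping runs reproducible. ROI statistics use the
centroid rule, so tangent ROIs partition somata without double counting.
The activation marker is the per-slice difference in median soma area
(LPS - PBS), summarized per animal as median and IQR; the responder call
("Iba1+") requires the difference to exceed a configurable threshold
(default 0 um^2) on a strict majority of slices — a documented surrogate
for expert judgment, not a validated classifier.

## MRS QC and statistics

Spectra with linewidth > 25 Hz are excluded whole; metabolites with
Cramér-Rao bound >= 10 %SD are excluded individually; surviving
concentrations are expressed relative to total creatine (Cr + PCr, both of
which must pass QC or the spectrum's ratios are unmeasurable). Every
exclusion carries a machine-readable reason code.

Paired LPS-vs-vehicle outcomes are described as median (IQR, 25th-75th
percentile, linear interpolation) and tested with a paired t-test plus the
Wilcoxon signed-rank test — the paired-design analogue of the rank-sum test
named in the protocol; the two-sample rank-sum p-value is reported
alongside, labeled, so the ambiguity is surfaced rather than hidden. Fewer
than 3 pairs yields descriptives only. All-zero differences report p = 1.
No multiple-testing correction is applied. ROI outcomes default to the
voxel mean ("average contrast"); a median variant exists. Group statistics
are computed within the supplied responder labels (the design's gold
standard), with the soma-rule classification reported against them.

Calibration is verified by simulation: on 2000 null cohorts (n = 6 pairs,
normal noise) the paired t rejects at 5.25% (nominal 5%), and its power at
a 2.5-pp effect with unit noise matches a brute-force normal-theory
simulation within sampling error.
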