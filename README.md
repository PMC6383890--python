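# micest

Quantitative CEST-MRI analysis for neuroinflammation imaging: multi-pool
Bloch-McConnell z-spectrum simulation, WASSR B0 mapping and correction, MTR
asymmetry quantification at 0.6 ppm, microglial soma morphometry on Iba-1
histology, LCModel metabolite-table quality control, and paired
LPS-vs-vehicle study statistics — with seeded synthetic-data generators that
provide ground truth for every stage.

## Who this is for

Preclinical MR groups using chemical exchange saturation transfer (CEST) to
image glial metabolites — in particular myoinositol, whose six hydroxyl
protons exchange with bulk water at k ≈ 600 s⁻¹ about 0.6 ppm from the water
resonance. At that offset the contrast is small, sits on the shoulder of the
direct water-saturation dip, and is exquisitely sensitive to B0: a
quantitative pipeline needs simulation to choose saturation parameters,
per-voxel water-frequency referencing (WASSR), strict B0 quality gates, and
paired statistics. `micest` packages that chain end to end, together with
the histology morphometry (soma-size differences) used to define responder
groups in an intracerebral LPS challenge design.

## The model and the contrast

N proton pools (water; exchanging solutes; an optional broad macromolecular
pool) under a hard saturation pulse obey the coupled Bloch-McConnell
equations `dM/dt = A M + b`; the package solves them exactly (matrix
exponential for finite pulses, linear fixed point for the CW limit). The
contrast metric is the magnetization transfer ratio asymmetry

```
MTR_asym(Δω) = 100 · (M_sat(−Δω) − M_sat(+Δω)) / M_0   [%]
```

evaluated at Δω = 0.6 ppm after each voxel's z-spectrum has been
spline-interpolated and re-centered on its true water frequency, which is
estimated per voxel from a WASSR acquisition by the maximum-symmetry
algorithm.

## Worked example

Simulate a two-pool z-spectrum at 9.4 T under the standard schedule
(1.6 s, 0.9 µT, 41 offsets in ±4 ppm) and quantify the hydroxyl contrast:

```python
import numpy as np
from micest import PoolParameters, SaturationPulse, ScannerContext, simulate_zspectrum
from micest.zspec import interpolate_spectrum, mtr_asym

ctx = ScannerContext()  # 9.4 T
pools = [
    PoolParameters("water", t1=1.8, t2=0.040),
    PoolParameters("hydroxyl", t1=1.0, t2=0.010, shift=0.6,
                   fraction=0.0037324, k_exchange=600.0),
]
pulse = SaturationPulse(b1=0.9, duration=1.6)
offsets = np.linspace(-4.0, 4.0, 41)
z = simulate_zspectrum(pools, pulse, offsets, ctx, mode="steady_state")
asym = mtr_asym(interpolate_spectrum(z), delta_ppm=0.6)
print(f"Z(-0.6 ppm) = {z.values[offsets.searchsorted(-0.6)]:.4f}")
print(f"Z(+0.6 ppm) = {z.values[offsets.searchsorted(0.6)]:.4f}")
print(f"MTR_asym(0.6 ppm) = {asym:.2f}%")
```

prints

```
Z(-0.6 ppm) = 0.4616
Z(+0.6 ppm) = 0.3780
MTR_asym(0.6 ppm) = 8.35%
```

The water signal at +0.6 ppm is depressed relative to −0.6 ppm because
saturation applied at the hydroxyl resonance is transferred to water by
exchange; 8.35% is the resulting asymmetry contrast for a hydroxyl pool
fraction of 0.37% — the package's calibrated control-tissue level.

A full synthetic study (12 subjects, 6 with an elevated lesion-side
hydroxyl fraction, a +10 µm² soma-size shift and elevated mI/tCr) runs end
to end in seconds:

```python
from micest import CohortSpec, run_study
res = run_study(CohortSpec(seed=7))
print(res.summary())
```

The report shows LPS-side MTR_asym ≈ 10.6% vs vehicle ≈ 8.3% with paired-t
p < 0.05 in the effect group only, a ≈ +9 µm² soma-size difference there,
null results in the control group, and 12/12 responder classification. The
same drivers exist on the command line (`micest simulate / synth / wassr /
cest / morpho / stats / run-study`).

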