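# bptsim

A desk-scale simulator and signal-processing toolkit for **Beat Pilot Tone
(BPT)** motion sensing in MRI.

Pilot-tone methods track patient motion by transmitting an RF tone into the
scanner bore and watching how the receiver coil array's pickup of that tone
changes as the body moves. A conventional pilot tone (PT) must sit near the
Larmor frequency (~127.8 MHz at 3 T). BPT removes that restriction: two
tones at arbitrary microwave frequencies f1, f2 are transmitted, and a
second-order nonlinearity in the receive preamplifiers mixes them into an
intermodulation product at

    f_BPT = m f2 + n f1,   e.g.  2527.8 MHz − 2400 MHz = 127.8 MHz,

which lands inside the receiver bandwidth — within each k-space readout
line, but outside the band occupied by the MR image — and is extracted as a
per-line navigator. Because the bore acts as a circular waveguide (TE11
cutoff ≈ 251 MHz for a 70 cm bore), microwave tones above cutoff form
standing waves whose local sampling by each coil makes the beat signal far
more motion sensitive, and more spatially diverse, than a sub-cutoff PT.

`bptsim` implements this mechanism end to end on synthetic data:

| module | what it does |
|---|---|
| `bptsim.em_bore` | analytic circular-waveguide bore: mode cutoffs (Bessel roots), propagation/evanescence, modal standing-wave fields, coil flux Φ = ∫H·dA by adaptive Gauss–Legendre quadrature, isotropic exposure estimate P/(4πr²) |
| `bptsim.receiver_chain` | intermodulation frequency algebra, output-referred IP2 slope-2 power law `P_IMD = P1 + P2 − IP2`, memoryless polynomial nonlinearity, intercept-point fitting, the conjugate flux product `conj(Φ1)·Φ2` |
| `bptsim.kspace` | synthetic multicoil raw acquisitions (HDF5), tones embedded with a continuous phase clock, exact single-frequency matched-filter extraction, image-band-preserving notch |
| `bptsim.sigproc` | percent modulation (x/mean − 1)·100, zero-group-delay Butterworth filtering, Savitzky–Golay smoothing, inter-coil phase extraction, accelerometer→displacement double integration, repeat alignment, per-coil linear artifact correction |
| `bptsim.motion_analysis` | frame averaging, PCA calibration/projection, multicoil OLS regression with Pearson-r reporting, max-margin separating plane, MIMO channel stacking |
| `bptsim.scenarios` | seeded experiment generators: coil translation sweeps, cradle-step vibration ring-downs, respiratory/bulk/cardiac (dBCG) physiology, 2-antenna × 22-coil MIMO head-motion calibration/inference |
| `bptsim.io`, `bptsim.cli` | HDF5/CSV/JSON plumbing, run manifests, and the `bpt` command line |

## Worked example

```python
import numpy as np
import bptsim as b
from bptsim.scenarios import ScenarioConfig, gen_translation_sweep, count_peaks

fc = b.mode_cutoff("TE", 1, 1, 0.35)
print(f"TE11 cutoff: {fc/1e6:.1f} MHz")
spec = b.imd_frequency(1, -1, b.TonePair(2400e6, 2527.8e6))
print(f"beat frequency: {spec.frequency/1e6:.1f} MHz")
print(f"power density: {b.isotropic_power_density(100, 10):.2g} mW/cm^2")

cfg = ScenarioConfig(kind="translation_sweep", seed=1, params={"n_repeats": 1})
res = gen_translation_sweep(cfg)
n = res.unique_offsets.size
for label in ("pt_127.8MHz", "bpt_2463.9MHz"):
    env = np.abs(res.envelopes[label][:n, 0])
    pm, _ = b.percent_modulation(env)
    print(f"{label}: peaks={count_peaks(env)}  "
          f"modulation range [{pm.min():.0f}, {pm.max():.0f}] %")
```

prints

```
TE11 cutoff: 251.0 MHz
beat frequency: 127.8 MHz
power density: 0.08 mW/cm^2
pt_127.8MHz: peaks=0  modulation range [-28, 36] %
bpt_2463.9MHz: peaks=2  modulation range [-99, 81] %
```

Reading the output: the 127.8 MHz pilot tone is below the bore's 251 MHz
waveguide cutoff, so its field decays monotonically along the bore — a
10 cm coil translation produces a peakless, moderate modulation. The
2400/2527.8 MHz beat tone rides on standing waves (guide wavelength
≈ 12.6 cm), so the same translation crosses interference nulls: several
envelope peaks and nearly full-depth modulation, i.e. much higher motion
sensitivity per millimeter of travel. Transmitting 100 mW from 10 cm away
deposits at most 0.08 mW/cm² — well under the 5 mW/cm² FCC limit.

The same pipeline runs from the shell:

```bash
bpt modes --radius 0.35 --list 5      # lowest waveguide modes
bpt imd --f1 2400 --f2 2527.8         # intermodulation products
bpt simulate physio.yaml --out run/   # synthesize a scenario
bpt analyze run/acquisition.h5 --out report/
```

`bpt analyze` extracts every declared tone, converts envelopes to percent
modulation (excluding low-mean coils), reports the dominant respiratory
rate and PC scores, and writes `report.json` plus CSV traces; every output
directory carries a manifest (config hash, seed, package version) so runs
are exactly reproducible.

## Documentation

See `docs/methods.md` for the physical model, its assumptions, parameter
defaults, and known limitations.
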