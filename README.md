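# clm — correlation light-field microscopy

`clm` is a simulation and reconstruction toolkit for **correlation
light-field microscopy** (CLM), a volumetric imaging scheme for thick
biological samples that refocuses out-of-focus planes in post-processing
*without* the resolution penalty of conventional light-field microscopy.
It is aimed at optics and biomedical-imaging researchers who want to design,
sanity-check or reanalyze a CLM experiment on a desk-scale computer.

## The idea

A conventional microscope (objective, tube lens, camera `D_a`) is augmented
with a beam splitter and a relay lens that image the **objective pupil** onto
a second camera `D_b`.  The sample is illuminated with chaotic
(pseudo-thermal) light, and both cameras record many short frames, each one
an independent speckle realization.  The covariance of intensity
fluctuations

```
Γ(ρa, ρb) = ⟨ΔI_a(ρa) ΔI_b(ρb)⟩
```

is a 4D light field: each pupil pixel `ρb` labels a viewpoint on the lens
(`ρ_O = −ρb/M_L`), and shift-and-sum over viewpoints,

```
Σ_ref(ρa) = Σ_b Γ((f_O/f) ρa + (1 − f_O/f)(M/M_L) ρb, ρb)  ∼  F²(−ρa/M),
```

refocuses the sample plane at distance `f` from the objective.  Unlike a
microlens-based light-field camera, no spatial pixels are sacrificed for
directional information, so the lateral resolution stays at the diffraction
limit `Δx₀ = 0.61 λ/NA₀` while the refocusing range grows **quadratically**
with the detail size (`3.3 a²/λ`, independent of the numerical aperture).

The package provides, module by module:

| module            | contents |
|-------------------|----------|
| `clm.config`      | instrument description (`OpticalConfig`, `DetectorSpec`) |
| `clm.optics`      | scalar wave-optics engine: chaotic source, angular-spectrum propagation, thin lenses, paired-frame formation |
| `clm.phantoms`    | seeded test objects: triple slits, the two-plane 3D target, random granule volumes |
| `clm.correlation` | plain and differential (variance-minimizing) estimators of the 4D correlation |
| `clm.refocus`     | shift-and-sum refocusing, perspective views, depth maps |
| `clm.geometry`    | closed-form geometrical-optics oracle of Γ and the circle-of-confusion formulas |
| `clm.metrics`     | design formulas (resolution, DOF, viewpoint multiplicity) and the 10 %-visibility resolution criterion |
| `clm.io` / `clm.cli` | TIFF/JSON frame stacks, HDF5 correlation containers, YAML run configs, `clm` command line |

## Worked example

Refocus a triple-slit mask (center-to-center 22.1 µm, slit width 11 µm)
placed 250 µm beyond the focal plane, from 2000 simulated frame pairs:

```python
import numpy as np
from clm import (OpticalConfig, FrameStack, estimate_gamma, refocus,
                 visibility, simulate_arrays, triple_slit, ThickSample)

config = OpticalConfig()                       # 532 nm, NA0 = 0.23, M = 4.17
dx = config.band_limit_spacing                 # 1.156 um sample-plane grid
n = 256
mask = triple_slit(22.1e-6, fov=n * dx, spacing=dx)   # d = 22.1 um, width d/2
sample = ThickSample(planes=((250e-6, mask),))        # 250 um past focus

ia, ib, ca, cb = simulate_arrays(sample, config, 2000, seed=1,
                                 sim_size=n, bin_a=2, bin_b=16)
gamma = estimate_gamma(FrameStack(ia, ib, ca, cb))

expected = np.array([-22.1e-6, 0.0, 22.1e-6]) * config.magnification
ref = refocus(gamma, config.objective_focal + 250e-6, config)
prof = ref.values.mean(axis=0)
rep = visibility(prof / prof.max(), expected, coords=ca)
print(f"refocused visibility: {rep.visibility:.2f}  resolved: {rep.resolved}")
```

prints

```
refocused visibility: 0.61  resolved: True
```

i.e. the slits — unresolvable in the raw correlation image (visibility 0.08
on the same data) — are recovered at 61 % visibility, far above the 10 %
threshold that generalizes the Rayleigh criterion to defocused images.

The design-tradeoff table for a 24.8 µm detail and a 5-cell light-field
camera:

```console
$ clm metrics --a 24.8e-6 --n-u 5
config d9519a4b55fe006c  M = 4.167  Dx0 = 1.411 um
technique    res (um)  DOF@res (um)  DOF ext (um)  axial (um)   views
standard         1.41          6.13         107.8      107.83     1.0
lightfield       7.05        153.36         539.1      107.83     5.0
clm              1.41          6.13        3815.1      107.83    17.6
```

CLM keeps the 1.41 µm diffraction-limited resolution of the standard
microscope while extending the refocusing range to 3.8 mm — 35 axial
planes — where the light-field camera must trade resolution (7 µm) for its
0.54 mm range.

The same pipeline is scriptable from the shell:

```bash
clm simulate --config run.yaml --frames 2000 --seed 1 --out stack/
clm correlate --in stack/ --estimator plain --out gamma.h5
clm refocus --gamma gamma.h5 --z -1250e-6 --z 1250e-6 --out refocused.tif
clm viewpoint --gamma gamma.h5 --rho-b 1e-3,0 --patch 10 --out view.tif
clm depthmap --gamma gamma.h5 --z-min -5e-4 --z-max 5e-4 --steps 11 --out z.tif
```

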