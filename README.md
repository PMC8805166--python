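# spirestore

Restoration of noisy and masked X-ray single-particle diffraction
patterns, and what restored patterns buy you downstream.

In single-particle imaging at X-ray free-electron lasers, each detector
frame is a Poisson-noisy, partially masked sampling of a particle's
far-field diffraction intensities at an unknown orientation.  This package
implements the full computational pipeline of a restoration study around
that problem:

* **Forward simulation** of diffraction from atomic coordinates (PDB),
  geometric shapes (sphere with its closed-form factor, cube,
  icosahedron) and pseudo-protein point clouds, on an exact Ewald-sphere
  pixel map, with per-pattern Poisson corruption controlled by an
  intensity factor f (counts ~ Poisson(f * I), I max-normalized);
* **Missing-data masks**: central stripes, circular beamstops and a
  deterministic AGIPD-like module-gap layout (widest vertical band
  14 px at 128 px);
* **Log-scale normalization** I_hat = log(1+cI)/log(1+cI_max) onto [0, 1]
  and its exact inverse;
* **Binary-filter benchmark**: constrain the autocorrelation (inverse FFT
  of the intensities) to its true support and transform back — a matched
  low-pass denoiser that is deliberately fragile to masks;
* **U-Net restorer** (pure NumPy, explicit backprop, Adam, pixel-mean
  binary cross-entropy) for joint denoising and inpainting of normalized
  patterns;
* **Evaluation**: linearized MSE, PSNR = −10·log₁₀(MSE) at unit peak,
  central-speckle size, mask/speckle ratio, and best-case real-space
  reconstruction from true phases;
* **EMC orientation recovery** (expand–maximize–compress) with Poisson and
  Gaussian likelihoods and the blurred variant for data-starved regimes,
  plus gauge-aligned rotation-error scoring.

## Worked example

Simulate a small dataset, corrupt it at f = 10, denoise with the binary
filter and with a desk-scale U-Net, and compare errors:

```python
import numpy as np
import spirestore as sp
from spirestore.datasets import DatasetSpec, build_dataset
from spirestore.preprocess import NormalizedPattern, linearize

geo = sp.DetectorGeometry(photon_energy=8.0, distance=0.15,
                          pixel_size=400e-6, n_side=128)
ds = build_dataset(DatasetSpec(n_patterns=300, intensity_factors=(10.0,),
                               geometry=geo, bin_factor=2, seed=7))

# Poisson noise floor: E[(K/f - I)^2] = mean(I)/f
mse_noisy = np.mean((ds.noisy[10.0]/10 - ds.noiseless)**2)
print(f"noisy MSE {mse_noisy:.2e}  predicted {ds.noiseless.mean()/10:.2e}")

# train the desk-scale U-Net on the training split
from spirestore.unet import UNet, desk_config, train
cfg = desk_config(seed=1)
restorer = train(UNet(cfg), *ds.training_pairs(10.0, "train"), cfg)
out = restorer.restore(ds.training_pairs(10.0, "test")[0])
test = ds.splits()["test"]
mse_unet = np.mean([
    np.mean((linearize(NormalizedPattern(out[i], 1.0, 10.0))
             - ds.noiseless[k])**2)
    for i, k in enumerate(test)])
print(f"U-Net test MSE {mse_unet:.2e}")
```

prints (seeds as above, one CPU core, ~3 minutes):

```
noisy MSE 1.47e-03  predicted 1.47e-03
U-Net test MSE 1.54e-04
```

The first line verifies the Poisson variance law — the linearized noise
floor equals mean(I)/f exactly.  The second shows the trained restorer
cutting the error of the noisy input by ~10× at this desk scale (the
published full-scale training, with 9900 patterns at 128 px and 20 epochs,
reaches far larger factors; the desk preset trades accuracy for minutes of
CPU).

A thin CLI wraps the same functions: `spirestore simulate`, `maskgen`,
`train`, `restore`, `evaluate`, `orient` (see `spirestore --help`).

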