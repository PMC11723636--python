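# dualrecon

Hybrid dual-domain deep-learning reconstruction of undersampled multi-coil
cardiac MR images, with the full supporting stack needed to study it without
any external data: multi-coil simulation from cardiac-like phantoms,
variable-density Cartesian undersampling, Walsh adaptive coil combination,
classical baselines (zero-filled, compressed sensing, single-domain U-Net),
and SSIM / PSNR / RMSE evaluation.

## The method

Accelerated MRI acquires only a subset of phase-encode lines; the
zero-filled inverse transform of such data is aliased.  Compressed sensing
recovers the image by solving

    y* = argmin_y  ‖x − E∘F(S y)‖₂² + λ‖T(y)‖₁

with undersampling operator `E`, Fourier encoding `F`, coil sensitivities
`S` and a sparsifying transform `T`.  Deep-learning reconstruction instead
learns the inverse mapping from (undersampled, fully sampled) training
pairs.  Single-domain networks operate in either the image or the k-space
domain and miss the coupling between the two; this package implements the
dual-domain alternative: two small U-Nets, one interpolating composite
k-space (K-Net) and one removing aliasing in the image domain (I-Net),
cascaded in either order —

* **KI-Net**: K-Net → IFFT → MCDC → I-Net → MCDC
* **IK-Net**: I-Net → MCDC → FFT → K-Net → IFFT → MCDC

— where **MCDC** (multi-coil data consistency) projects the current
composite image onto the coils via sensitivity maps, re-imposes every
acquired k-space sample per coil, and adaptively recombines.  The networks
are trained incrementally (stage 1 alone, then frozen while stage 2 trains
on its MCDC-corrected outputs) on coil-combined composites, which keeps the
models independent of the number of receiver coils.  Sensitivity maps come
from the Walsh eigen-method (or the simulation ground truth); simulated
coils use Biot-Savart fields of circular surface loops.

See `docs/methods.md` for assumptions, defaults and numerical details.

## Worked example

Train the IK cascade on the standard synthetic benchmark (200 cardiac-like
64×64 phantoms, 8 simulated coils, acceleration factor 2) and score it on 20
held-out phantoms against zero-filled reconstruction:

```python
import numpy as np
from dualrecon.benchmark import make_benchmark, desk_train_config, desk_unet_config
from dualrecon.cascade import train_cascade, reconstruct
from dualrecon.baselines import zero_filled
from dualrecon.metrics import ssim, psnr, rmse

bm = make_benchmark(seed=1, af=2.0)
model = train_cascade(bm.train, "IK", desk_train_config(seed=1),
                      desk_unet_config(seed=1), af=2.0)

scores = {"zf": [], "ik": []}
for acq, maps, ref in zip(bm.test_acquired, bm.test_maps, bm.test_references):
    scores["zf"].append([ssim(zero_filled(acq, maps), ref)])
    out = reconstruct(acq, maps, model)
    scores["ik"].append([ssim(out, ref), psnr(out, ref), rmse(out, ref)])
```

On this benchmark the run prints (means over the 20 test images):

```
SSIM zf 0.9423 ik 0.9761 | PSNR zf 35.45 ik 40.58 | RMSE zf 0.0191 ik 0.0100
```

i.e. the trained cascade removes most of the aliasing the zero-filled
reconstruction leaves behind: structural similarity to the fully sampled
reference rises from 0.942 to 0.976, peak SNR gains ~5 dB, and the
magnitude RMSE halves.  The same study at larger image sizes, more epochs
and wider networks only changes the budget, not the code paths.

A command-line interface wraps the same pipeline:

```bash
dualrecon simulate --out data.h5 --n-volumes 15 --n-frames 20 --shape 64 --n-coils 8
dualrecon train --order ik --af 2 --data data.h5 --out ckpt/model --base-filters 8
dualrecon reconstruct --method ik --data data.h5 --model ckpt/model --out recon.h5
dualrecon evaluate --recon recon.h5 --data data.h5 --method ik --af 2 \
    --out-csv per_image.csv --out-json summary.json
```

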