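"""Reference reconstructors: zero-filled, CS (ISTA + wavelets), single-domain U-Net.

The compressed-sensing solver minimizes

    J(y) = 1/2 * sum_i || M F (S_i y) - x_i ||_2^2  +  lambda * || W y ||_1

by proximal gradient descent (ISTA): a gradient step on the multi-coil data
term followed by soft-thresholding of the orthonormal wavelet coefficients by
``step * lambda``.  With unit-RSS sensitivity maps, a unitary FFT and a
sampling projection, the forward operator has unit norm, so any step <= 1
guarantees a monotonically non-increasing objective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .coils import AcquiredData, adaptive_combine
from .networks import UNet, forward_inet
from .synthetic import SensitivityMaps
from .transforms import fft2c, ifft2c

__all__ = ["CSConfig", "zero_filled", "cs_reconstruct", "unet_single_domain"]


@dataclass(frozen=True)
class CSConfig:
    """ISTA settings: wavelet sparsity ``db4`` at ``levels`` scales by default."""

    lam: float = 1e-3
    wavelet: str = "db4"
    levels: int = 3
    n_iter: int = 50
    step: float = 1.0
    tol: float = 1e-9

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if not 0 < self.step <= 1:
            raise ValueError("step must be in (0, 1] for guaranteed descent")


def zero_filled(acquired: AcquiredData, maps: SensitivityMaps) -> np.ndarray:
    """Adaptive combination of the per-coil inverse transforms of zero-filled k-space."""
    return adaptive_combine(acquired.coil_images(), maps)


def _wavelet_l1(coeff_arr: np.ndarray) -> float:
    return float(np.sum(np.abs(coeff_arr)))


def _soft(x: np.ndarray, t: float) -> np.ndarray:
    """Complex soft-thresholding: shrink magnitudes by ``t``."""
    mag = np.abs(x)
    scale = np.maximum(mag - t, 0.0) / np.where(mag > 0, mag, 1.0)
    return x * scale


def cs_reconstruct(acquired: AcquiredData, maps: SensitivityMaps,
                   config: CSConfig = CSConfig()) -> tuple[np.ndarray, list[float]]:
    """CS-MRI reconstruction by ISTA; returns the final iterate and objective trace."""
    mask2d = acquired.mask.to_2d(acquired.shape[0]).astype(float)
    b = acquired.coil_kspace_acq
    S = maps.maps

    def forward(y):
        return np.stack([mask2d * fft2c(S[i] * y) for i in range(S.shape[0])])

    def adjoint(k):
        return np.sum(np.conj(S) * np.stack([ifft2c(mask2d * k[i])
                                             for i in range(S.shape[0])]), axis=0)

    wav = pywt.Wavelet(config.wavelet)

    def analyze(y):
        coeffs = pywt.wavedec2(y, wav, mode="periodization", level=config.levels)
        return pywt.coeffs_to_array(coeffs)

    def synthesize(arr, slices):
        coeffs = pywt.array_to_coeffs(arr, slices, output_format="wavedec2")
        return pywt.waverec2(coeffs, wav, mode="periodization")

    y = adjoint(b)  # zero-filled start
    trace: list[float] = []
    for it in range(config.n_iter):
        resid = forward(y) - b
        y = y - config.step * adjoint(resid)
        arr, slices = analyze(y)
        if config.lam > 0:
            arr = _soft(arr, config.step * config.lam)
            y = synthesize(arr, slices)
        obj = 0.5 * float(np.sum(np.abs(forward(y) - b) ** 2)) + config.lam * _wavelet_l1(
            analyze(y)[0])
        if not np.isfinite(obj):
            raise FloatingPointError(f"CS objective diverged at iteration {it}")
        if trace and abs(trace[-1] - obj) <= config.tol * max(1.0, abs(trace[-1])):
            trace.append(obj)
            break
        trace.append(obj)
    return y, trace


def unet_single_domain(acquired: AcquiredData, maps: SensitivityMaps,
                       trained_inet: UNet) -> np.ndarray:
    """Conventional single-domain baseline: one image-domain pass, no MCDC."""
    return forward_inet(zero_filled(acquired, maps), trained_inet)


def train_single_domain_unet(dataset, train_config, unet_config) -> UNet:
    """Train the image-domain baseline on (zero-filled, fully sampled) pairs.

    Uses the same volume-wise 80/20 split and optimizer settings as the
    cascade stages but involves no data-consistency operation.
    """
    from .cascade import _pack_pairs, _split_by_volume
    from .networks import build_unet, UNetConfig
    from .nn.train import train_network

    x, y = _pack_pairs(dataset.zf_image, dataset.label_image)
    tr, va = _split_by_volume(dataset.volume_index, train_config.val_fraction,
                              train_config.seed)
    net = build_unet(UNetConfig(**{**vars(unet_config), "seed": train_config.seed + 7}))
    train_network(net, x[tr], y[tr], x[va], y[va],
                  lr0=train_config.lr0, lr_factor=train_config.lr_factor,
                  lr_patience=train_config.lr_patience,
                  early_patience=train_config.early_patience,
                  batch_size=train_config.batch_size,
                  max_epochs=train_config.max_epochs, seed=train_config.seed + 7)
    return net
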