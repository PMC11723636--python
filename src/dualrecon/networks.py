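"""Network-facing API: complex channel packing and domain-tagged inference.

Complex 2-D arrays enter the (real-valued) U-Net as two channels — channel 0
the real part, channel 1 the imaginary part — and are normalized per example
to unit maximum magnitude before packing; the scale is reapplied on the way
out.  ``forward_knet`` and ``forward_inet`` are the same operation on
k-space and image arrays respectively; the distinction is the domain of the
data (and of the training labels), not the architecture.
"""

from __future__ import annotations

import numpy as np

from .nn.unet import UNet, UNetConfig, build_unet, load_model, save_model

__all__ = [
    "UNetConfig",
    "UNet",
    "build_unet",
    "save_model",
    "load_model",
    "complex_to_channels",
    "channels_to_complex",
    "normalize_scale",
    "forward_knet",
    "forward_inet",
]


def complex_to_channels(z: np.ndarray) -> np.ndarray:
    """Pack a complex 2-D array into a (2, H, W) float array (real, imag)."""
    z = np.asarray(z)
    if z.ndim != 2:
        raise ValueError(f"expected a 2-D array, got ndim={z.ndim}")
    return np.stack([z.real, z.imag]).astype(np.float32 if z.itemsize <= 8 else np.float64)


def channels_to_complex(t: np.ndarray) -> np.ndarray:
    """Inverse of :func:`complex_to_channels`."""
    t = np.asarray(t)
    if t.ndim != 3 or t.shape[0] != 2:
        raise ValueError(f"expected a (2, H, W) array, got shape {t.shape}")
    return t[0] + 1j * t[1]


def normalize_scale(z: np.ndarray) -> float:
    """Per-example normalization constant: the maximum magnitude (1 if zero)."""
    s = float(np.max(np.abs(z)))
    return s if s > 0 else 1.0


def _net_apply(z: np.ndarray, net: UNet) -> np.ndarray:
    s = normalize_scale(z)
    t = complex_to_channels(np.asarray(z) / s)[None]
    out = net.forward(t, training=False)[0]
    return channels_to_complex(np.asarray(out, dtype=np.float64)) * s


def forward_knet(k_in: np.ndarray, net: UNet) -> np.ndarray:
    """Run the k-space subnetwork: k-space in, interpolated k-space out."""
    return _net_apply(k_in, net)


def forward_inet(img_in: np.ndarray, net: UNet) -> np.ndarray:
    """Run the image subnetwork: aliased image in, de-aliased image out."""
    return _net_apply(img_in, net)
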