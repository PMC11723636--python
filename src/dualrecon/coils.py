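"""Coil operations: Walsh adaptive combination and multi-coil data consistency.

The Walsh method estimates per-pixel coil sensitivities as the principal
eigenvector of the local inter-coil sample correlation matrix; combining the
coil images with the conjugate of those (unit root-sum-of-squares) maps is the
matched-filter "adaptive" combine.  Multi-coil data consistency (MCDC)
projects a composite image back to coil k-space, re-imposes every acquired
sample, and recombines — it is the deterministic glue between the learned
subnetworks of the cascades.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .synthetic import SensitivityMaps
from .transforms import SamplingMask, fft2c, ifft2c, undersample

__all__ = [
    "AcquiredData",
    "acquire",
    "walsh_maps",
    "estimate_maps_from_center",
    "adaptive_combine",
    "dc_single",
    "mcdc",
]


@dataclass(frozen=True)
class AcquiredData:
    """Measured (zero-filled) per-coil k-space plus the mask that produced it."""

    coil_kspace_acq: np.ndarray  # (n_coils, nx, ny), zero off-mask
    mask: SamplingMask

    @property
    def n_coils(self) -> int:
        return self.coil_kspace_acq.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.coil_kspace_acq.shape[1:]

    def coil_images(self) -> np.ndarray:
        """Zero-filled per-coil images."""
        return np.stack([ifft2c(k) for k in self.coil_kspace_acq])


def acquire(coil_kspace: np.ndarray, mask: SamplingMask) -> AcquiredData:
    """Retrospectively undersample fully sampled coil k-space."""
    acq = np.stack([undersample(k, mask) for k in coil_kspace])
    return AcquiredData(coil_kspace_acq=acq, mask=mask)


def walsh_maps(coil_images: np.ndarray, block_size: int = 7) -> SensitivityMaps:
    """Estimate sensitivity maps by the Walsh adaptive-array method.

    For every pixel the ``n_coils x n_coils`` sample correlation matrix
    ``R_ij = <c_i conj(c_j)>`` is averaged over a ``block_size``-square
    neighborhood; the sensitivity vector is the principal eigenvector of R,
    phase-referenced to coil 0 and normalized to unit root-sum-of-squares.
    """
    coil_images = np.asarray(coil_images)
    if coil_images.ndim != 3:
        raise ValueError("coil_images must be (n_coils, nx, ny)")
    n_coils, nx, ny = coil_images.shape
    if block_size < 1 or block_size % 2 == 0:
        raise ValueError(f"block_size must be odd and >= 1, got {block_size}")
    if block_size > min(nx, ny):
        raise ValueError(
            f"block_size {block_size} exceeds image size {(nx, ny)}"
        )

    # local correlation matrices via box filtering of the coil outer products
    corr = np.empty((nx, ny, n_coils, n_coils), dtype=complex)
    for i in range(n_coils):
        for j in range(i, n_coils):
            prod = coil_images[i] * np.conj(coil_images[j])
            sm = (uniform_filter(prod.real, size=block_size)
                  + 1j * uniform_filter(prod.imag, size=block_size))
            corr[..., i, j] = sm
            if i != j:
                corr[..., j, i] = np.conj(sm)

    # principal eigenvector per pixel (eigh returns ascending eigenvalues)
    _, vecs = np.linalg.eigh(corr.reshape(-1, n_coils, n_coils))
    v = vecs[:, :, -1]  # (pixels, n_coils)
    # phase-reference to coil 0 for a deterministic combined phase
    ref = v[:, 0]
    phase = np.where(np.abs(ref) > 0, ref / np.where(np.abs(ref) > 0, np.abs(ref), 1.0), 1.0)
    v = v * np.conj(phase)[:, None]
    norm = np.sqrt(np.sum(np.abs(v) ** 2, axis=1))
    v = v / np.where(norm > 0, norm, 1.0)[:, None]
    maps = v.T.reshape(n_coils, nx, ny)
    return SensitivityMaps(maps=maps)


def estimate_maps_from_center(acquired: AcquiredData, block_size: int = 7) -> SensitivityMaps:
    """Walsh maps from the fully sampled central band (self-calibration).

    Only the autocalibration lines are kept before the inverse transform, so
    the estimate uses data available at inference time on real acquisitions.
    """
    mask = acquired.mask
    n_center = int(round(mask.center_fraction * mask.ny))
    if n_center == 0:
        raise ValueError("mask has no fully sampled center band to calibrate from")
    dc = mask.ny // 2
    lo = dc - n_center // 2
    band = np.zeros(mask.ny)
    band[lo:lo + n_center] = 1.0
    lowres = np.stack([ifft2c(k * band[None, :]) for k in acquired.coil_kspace_acq])
    return walsh_maps(lowres, block_size=block_size)


def adaptive_combine(coil_images: np.ndarray, maps: SensitivityMaps) -> np.ndarray:
    """Matched-filter coil combination ``sum_i conj(S_i) c_i``.

    With unit-RSS maps no denominator is needed and
    ``adaptive_combine(expand_to_coils(m, S), S) == m`` exactly.
    """
    coil_images = np.asarray(coil_images)
    if coil_images.shape != maps.maps.shape:
        raise ValueError(
            f"coil image stack {coil_images.shape} does not match maps {maps.maps.shape}"
        )
    return np.sum(np.conj(maps.maps) * coil_images, axis=0)


def dc_single(k_est: np.ndarray, acq: np.ndarray, mask: SamplingMask,
              weight: float = 1.0) -> np.ndarray:
    """Single-coil data consistency.

    Hard replacement (``weight=1``, the default): acquired values at sampled
    positions, the estimate elsewhere.  ``0 < weight < 1`` blends
    ``weight * acq + (1 - weight) * k_est`` at sampled positions.
    """
    k_est = np.asarray(k_est)
    acq = np.asarray(acq)
    if k_est.shape != acq.shape:
        raise ValueError(f"shape mismatch: {k_est.shape} vs {acq.shape}")
    m2 = mask.to_2d(k_est.shape[0]).astype(float)
    return k_est * (1.0 - weight * m2) + weight * m2 * acq


def mcdc(composite: np.ndarray, maps: SensitivityMaps, acquired: AcquiredData,
         weight: float = 1.0) -> np.ndarray:
    """Multi-coil data consistency on a composite image.

    Pipeline: project to coils with the sensitivity maps, transform each coil
    to k-space, re-impose the acquired samples per coil, transform back, and
    adaptively recombine.
    """
    composite = np.asarray(composite)
    if maps.n_coils != acquired.n_coils:
        raise ValueError(
            f"maps have {maps.n_coils} coils but acquisition has {acquired.n_coils}"
        )
    if composite.shape != maps.shape:
        raise ValueError(
            f"composite shape {composite.shape} does not match maps {maps.shape}"
        )
    corrected = np.empty_like(maps.maps)
    for i in range(maps.n_coils):
        k = fft2c(maps.maps[i] * composite)
        k = dc_single(k, acquired.coil_kspace_acq[i], acquired.mask, weight=weight)
        corrected[i] = ifft2c(k)
    return adaptive_combine(corrected, maps)
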