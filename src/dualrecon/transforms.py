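"""Centered orthonormal Fourier transforms and 1-D variable-density sampling masks.

Every module in the package routes k-space <-> image conversions through
:func:`fft2c` / :func:`ifft2c` so that a single convention (DC at the grid
center, unitary normalization) holds package-wide.  Undersampling removes whole
phase-encode lines (the second array axis); the frequency-encode axis (first
axis) is always fully sampled, as in Cartesian 2-D cine acquisitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "fft2c",
    "ifft2c",
    "SamplingMask",
    "vd_mask",
    "undersample",
    "save_mask",
    "load_mask",
]


def _check_2d(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x)
    if x.ndim != 2:
        raise ValueError(f"{name} must be a 2-D array, got ndim={x.ndim}")
    return x


def fft2c(image: np.ndarray) -> np.ndarray:
    """Centered, unitary 2-D FFT (image -> k-space).

    DC ends up at index ``(Nx//2, Ny//2)``; Parseval holds exactly up to
    floating-point roundoff.
    """
    image = _check_2d(image, "image")
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Centered, unitary 2-D inverse FFT (k-space -> image)."""
    kspace = _check_2d(kspace, "kspace")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(kspace), norm="ortho"))


@dataclass(frozen=True)
class SamplingMask:
    """Binary 1-D variable-density phase-encode sampling pattern.

    Attributes
    ----------
    lines:
        Binary vector of length ``ny``; ``lines[j] == 1`` means phase-encode
        line ``j`` is acquired.
    af_nominal:
        Requested acceleration factor; the number of sampled lines is exactly
        ``round(ny / af_nominal)``.
    center_fraction:
        Fraction of ``ny`` around DC that is always fully sampled (the
        self-calibration band used for sensitivity estimation).
    sigma:
        Width of the Gaussian sampling density, as a fraction of ``ny``.
    seed:
        Seed of the line draw; the mask is a pure function of its parameters.
    """

    lines: np.ndarray
    af_nominal: float
    center_fraction: float
    sigma: float
    seed: int

    @property
    def ny(self) -> int:
        return self.lines.shape[0]

    @property
    def n_sampled(self) -> int:
        return int(self.lines.sum())

    @property
    def af_achieved(self) -> float:
        return self.ny / self.n_sampled

    def to_2d(self, nx: int) -> np.ndarray:
        """Broadcast to an ``(nx, ny)`` array, constant along frequency encode."""
        return np.broadcast_to(self.lines[None, :], (nx, self.ny)).astype(self.lines.dtype)


def _center_band(ny: int, center_fraction: float) -> np.ndarray:
    """Indices of the fully sampled band around DC (index ny//2)."""
    n_center = int(round(center_fraction * ny))
    if n_center == 0:
        return np.empty(0, dtype=int)
    dc = ny // 2
    lo = dc - n_center // 2
    return np.arange(lo, lo + n_center)


def vd_mask(
    ny: int,
    af_nominal: float,
    center_fraction: float = 1.0 / 16.0,
    sigma: float = 0.15,
    seed: int = 0,
) -> SamplingMask:
    """Draw a 1-D variable-density Gaussian sampling mask.

    The central ``center_fraction * ny`` lines are always acquired; the
    remaining budget of ``round(ny / af_nominal) - n_center`` lines is drawn
    without replacement from the off-center lines with probability
    proportional to ``exp(-d^2 / (2 (sigma*ny)^2))`` where ``d`` is the
    distance (in lines) from DC.  The total line count is enforced exactly so
    the achieved acceleration is reproducible.
    """
    if not 1 < af_nominal <= ny:
        raise ValueError(f"af_nominal must be in (1, ny={ny}], got {af_nominal}")
    if not 0 <= center_fraction <= 0.5:
        raise ValueError(f"center_fraction must be in [0, 0.5], got {center_fraction}")
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    n_keep = int(round(ny / af_nominal))
    center = _center_band(ny, center_fraction)
    if n_keep < math.ceil(center_fraction * ny) or n_keep < center.size:
        raise ValueError(
            "infeasible sampling budget: center band has "
            f"{center.size} lines but only {n_keep} lines may be sampled "
            f"(ny={ny}, af={af_nominal}, center_fraction={center_fraction})"
        )

    lines = np.zeros(ny, dtype=np.uint8)
    lines[center] = 1
    n_extra = n_keep - center.size
    if n_extra > 0:
        candidates = np.flatnonzero(lines == 0)
        d = candidates - ny // 2
        w = np.exp(-(d.astype(float) ** 2) / (2.0 * (sigma * ny) ** 2))
        p = w / w.sum()
        rng = np.random.default_rng(seed)
        chosen = rng.choice(candidates, size=n_extra, replace=False, p=p)
        lines[chosen] = 1
    return SamplingMask(
        lines=lines,
        af_nominal=float(af_nominal),
        center_fraction=float(center_fraction),
        sigma=float(sigma),
        seed=int(seed),
    )


def undersample(kspace: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Zero-fill ``kspace`` outside the sampled phase-encode lines."""
    kspace = _check_2d(kspace, "kspace")
    if kspace.shape[1] != mask.ny:
        raise ValueError(
            f"kspace has {kspace.shape[1]} phase-encode lines, mask has {mask.ny}"
        )
    return kspace * mask.lines[None, :]


def save_mask(mask: SamplingMask, path: str | Path) -> None:
    """Serialize a mask (line vector plus parameters) as JSON."""
    payload = {
        "lines": mask.lines.astype(int).tolist(),
        "af_nominal": mask.af_nominal,
        "center_fraction": mask.center_fraction,
        "sigma": mask.sigma,
        "seed": mask.seed,
    }
    Path(path).write_text(json.dumps(payload))


def load_mask(path: str | Path) -> SamplingMask:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no mask file at {path}")
    payload = json.loads(path.read_text())
    return SamplingMask(
        lines=np.asarray(payload["lines"], dtype=np.uint8),
        af_nominal=payload["af_nominal"],
        center_fraction=payload["center_fraction"],
        sigma=payload["sigma"],
        seed=payload["seed"],
    )
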