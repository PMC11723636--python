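"""Image-quality metrics against the coil-combined fully sampled reference.

All metrics operate on magnitude images after normalizing both to the
reference maximum (so the dynamic range is 1): RMSE of the magnitudes, PSNR
``20 log10(peak / rmse)`` with peak 1 after normalization, and mean SSIM with
an 11x11 Gaussian window (sigma 1.5) and the canonical constants K1=0.01,
K2=0.03.  The reference must itself be the adaptive coil combination of the
fully sampled coil images, so reconstruction and evaluation share a single
reference definition.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["rmse", "psnr", "ssim", "EvalReport", "evaluate"]


def _norm_pair(test: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    test, ref = np.abs(np.asarray(test)), np.abs(np.asarray(ref))
    if test.shape != ref.shape:
        raise ValueError(f"shape mismatch: {test.shape} vs {ref.shape}")
    peak = ref.max()
    if peak == 0:
        raise ValueError("reference image is identically zero")
    return test / peak, ref / peak


def rmse(test: np.ndarray, ref: np.ndarray) -> float:
    """Root mean squared error of magnitudes, reference normalized to max 1."""
    t, r = _norm_pair(test, ref)
    return float(np.sqrt(np.mean((t - r) ** 2)))


def psnr(test: np.ndarray, ref: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical magnitudes."""
    e = rmse(test, ref)
    if e == 0:
        return math.inf
    return 20.0 * math.log10(1.0 / e)


def ssim(test: np.ndarray, ref: np.ndarray) -> float:
    """Mean structural similarity (Gaussian window 11x11, sigma 1.5, range 1)."""
    t, r = _norm_pair(test, ref)
    return float(structural_similarity(
        t, r, data_range=1.0, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03))


@dataclass
class EvalReport:
    """Per-image metric rows plus mean +/- std summaries for one method/AF."""

    method: str
    af: float
    per_image: list[dict] = field(default_factory=list)

    @property
    def n_images(self) -> int:
        return len(self.per_image)

    def _finite(self, key: str) -> np.ndarray:
        vals = np.array([row[key] for row in self.per_image], dtype=float)
        return vals[np.isfinite(vals)]

    def summary(self) -> dict[str, tuple[float, float]]:
        """Mean and std per metric; non-finite PSNR entries are excluded."""
        out = {}
        for key in ("ssim", "psnr_db", "rmse"):
            vals = self._finite(key)
            out[key] = (float(vals.mean()), float(vals.std())) if vals.size else (
                math.nan, math.nan)
        return out

    def to_csv(self, path: str | Path) -> None:
        with open(Path(path), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=["image_id", "ssim", "psnr_db", "rmse"])
            writer.writeheader()
            writer.writerows(self.per_image)

    def to_dict(self) -> dict:
        s = self.summary()
        return {
            "method": self.method,
            "af": self.af,
            "n_images": self.n_images,
            "summary": {k: {"mean": v[0], "std": v[1]} for k, v in s.items()},
        }


def save_comparison_panel(recon: np.ndarray, ref: np.ndarray, path,
                          error_gain: float = 5.0, method: str = "") -> None:
    """Qualitative panel: reference | reconstruction | amplified error map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t, r = _norm_pair(recon, ref)
    fig, axes = plt.subplots(1, 3, figsize=(9, 3))
    for ax, img, title in zip(axes, (r, t, error_gain * np.abs(t - r)),
                              ("reference", method or "reconstruction",
                               f"{error_gain:g}x error")):
        ax.imshow(img, cmap="gray", vmin=0, vmax=1)
        ax.set_title(title, fontsize=9)
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(Path(path), dpi=120)
    plt.close(fig)


def evaluate(recon_set, ref_set, method: str, af: float,
             image_ids=None) -> EvalReport:
    """Score a list of reconstructions against aligned references."""
    recon_set, ref_set = list(recon_set), list(ref_set)
    if len(recon_set) != len(ref_set):
        raise ValueError(
            f"{len(recon_set)} reconstructions vs {len(ref_set)} references"
        )
    if image_ids is None:
        image_ids = list(range(len(recon_set)))
    report = EvalReport(method=method, af=af)
    import warnings

    for iid, rec, ref in zip(image_ids, recon_set, ref_set):
        p = psnr(rec, ref)
        if not math.isfinite(p):
            warnings.warn(f"image {iid}: identical to reference; PSNR is infinite "
                          "and excluded from summary means")
        report.per_image.append(
            {"image_id": iid, "ssim": ssim(rec, ref), "psnr_db": p,
             "rmse": rmse(rec, ref)})
    return report
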