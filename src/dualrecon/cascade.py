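"""Dual-domain cascades: KI-Net and IK-Net with interleaved MCDC.

KI order: the k-space subnetwork interpolates the composite zero-filled
k-space; its inverse transform passes through MCDC, the image subnetwork
removes residual aliasing, and a final MCDC re-imposes the measurements.
IK order runs the image subnetwork first and the k-space subnetwork second.

Training is incremental: subnetwork 1 is trained alone against its domain's
fully sampled labels, then frozen while every training example is propagated
through it (plus MCDC and the domain transform) to build the inputs on which
subnetwork 2 is trained.  With pass-through subnetworks both cascades reduce
exactly to repeated MCDC of the zero-filled input, which cleanly separates
the learned part from the deterministic part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coils import AcquiredData, acquire, adaptive_combine, mcdc
from .networks import (UNet, UNetConfig, build_unet, complex_to_channels,
                       forward_inet, forward_knet, normalize_scale)
from .nn.train import TrainHistory, train_network
from .synthetic import MultiCoilData, SensitivityMaps
from .transforms import fft2c, ifft2c, vd_mask

__all__ = [
    "PassThrough",
    "TrainConfig",
    "CascadeModel",
    "TrainingSet",
    "make_training_set",
    "make_stage2_inputs",
    "ki_reconstruct",
    "ik_reconstruct",
    "reconstruct",
    "train_cascade",
]


class PassThrough:
    """Identity stand-in for a subnetwork; isolates the deterministic MCDC path."""

    def forward(self, x, training: bool = False):
        return x


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by both cascade stages.

    MSE loss minimized by RMSProp, initial learning rate 1e-3 reduced by a
    factor of 0.1 after 10 epochs without validation improvement, early
    stopping after ``early_patience`` stale epochs, 80/20 train/validation
    split (by volume, to avoid leakage between temporally adjacent frames).
    """

    lr0: float = 1e-3
    lr_factor: float = 0.1
    lr_patience: int = 10
    early_patience: int = 20
    val_fraction: float = 0.2
    batch_size: int = 8
    max_epochs: int = 30
    seed: int = 0


@dataclass
class CascadeModel:
    """An ordered pair of trained subnetworks plus the MCDC wiring."""

    order: str  # "KI" or "IK"
    subnet1: UNet | PassThrough
    subnet2: UNet | PassThrough
    maps_policy: str = "true_maps"  # or "walsh_from_center"
    af: float = 2.0
    histories: tuple[TrainHistory, TrainHistory] | None = None

    def __post_init__(self):
        if self.order not in ("KI", "IK"):
            raise ValueError(f"order must be 'KI' or 'IK', got {self.order!r}")

    @property
    def subnet_domains(self) -> tuple[str, str]:
        return ("k", "image") if self.order == "KI" else ("image", "k")


@dataclass
class TrainingSet:
    """Flattened 2-D training examples built from fully sampled volumes."""

    acquired: list[AcquiredData]
    maps: list[SensitivityMaps]
    zf_image: np.ndarray       # (N, H, W) complex zero-filled composites
    zf_kspace: np.ndarray
    label_image: np.ndarray    # (N, H, W) complex fully sampled composites
    label_kspace: np.ndarray
    volume_index: np.ndarray   # (N,) volume of origin, for the split

    @property
    def n_examples(self) -> int:
        return self.zf_image.shape[0]


def make_training_set(volumes: list[MultiCoilData], af: float, mask_seed: int = 0,
                      center_fraction: float = 1.0 / 16.0, sigma: float = 0.15,
                      per_frame_masks: bool = False) -> TrainingSet:
    """Undersample volumes and flatten slice x frame into independent examples.

    One mask per (volume, AF, seed) by default; ``per_frame_masks`` draws a
    fresh mask for every frame instead.
    """
    if not volumes:
        raise ValueError("empty volume list")
    acq_list, maps_list, vol_idx = [], [], []
    zf_i, zf_k, lb_i, lb_k = [], [], [], []
    for v, vol in enumerate(volumes):
        ny = vol.shape[1]
        mask = vd_mask(ny, af, center_fraction, sigma, seed=mask_seed + 7919 * v)
        for t in range(vol.n_frames):
            m = mask
            if per_frame_masks:
                m = vd_mask(ny, af, center_fraction, sigma,
                            seed=mask_seed + 7919 * v + 104729 * (t + 1))
            acq = acquire(vol.frame_kspace(t), m)
            label = adaptive_combine(vol.frame_images(t), vol.maps)
            zf = adaptive_combine(acq.coil_images(), vol.maps)
            acq_list.append(acq)
            maps_list.append(vol.maps)
            vol_idx.append(v)
            zf_i.append(zf)
            zf_k.append(fft2c(zf))
            lb_i.append(label)
            lb_k.append(fft2c(label))
    return TrainingSet(
        acquired=acq_list,
        maps=maps_list,
        zf_image=np.stack(zf_i),
        zf_kspace=np.stack(zf_k),
        label_image=np.stack(lb_i),
        label_kspace=np.stack(lb_k),
        volume_index=np.asarray(vol_idx),
    )


# ---------------------------------------------------------------------------
# Inference graphs
# ---------------------------------------------------------------------------

def _zero_filled_composite(acquired: AcquiredData, maps: SensitivityMaps) -> np.ndarray:
    return adaptive_combine(acquired.coil_images(), maps)


def ki_reconstruct(acquired: AcquiredData, maps: SensitivityMaps,
                   model: CascadeModel) -> np.ndarray:
    """KI-Net inference: K-Net -> IFFT -> MCDC -> I-Net -> MCDC."""
    if model.order != "KI":
        raise ValueError(f"ki_reconstruct requires a KI-order model, got {model.order}")
    zf = _zero_filled_composite(acquired, maps)
    k1 = forward_knet(fft2c(zf), model.subnet1)
    img1 = mcdc(ifft2c(k1), maps, acquired)
    img2 = forward_inet(img1, model.subnet2)
    return mcdc(img2, maps, acquired)


def ik_reconstruct(acquired: AcquiredData, maps: SensitivityMaps,
                   model: CascadeModel) -> np.ndarray:
    """IK-Net inference: I-Net -> MCDC -> FFT -> K-Net -> IFFT -> MCDC."""
    if model.order != "IK":
        raise ValueError(f"ik_reconstruct requires an IK-order model, got {model.order}")
    zf = _zero_filled_composite(acquired, maps)
    img1 = forward_inet(zf, model.subnet1)
    k1 = fft2c(mcdc(img1, maps, acquired))
    img2 = ifft2c(forward_knet(k1, model.subnet2))
    return mcdc(img2, maps, acquired)


def reconstruct(acquired: AcquiredData, maps: SensitivityMaps,
                model: CascadeModel) -> np.ndarray:
    """Dispatch to the model's cascade order."""
    if model.order == "KI":
        return ki_reconstruct(acquired, maps, model)
    return ik_reconstruct(acquired, maps, model)


# ---------------------------------------------------------------------------
# Incremental training
# ---------------------------------------------------------------------------

def _pack_pairs(inputs: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Channel-pack complex pairs, normalizing each pair by the input's max magnitude."""
    xs, ys = [], []
    for z_in, z_lb in zip(inputs, labels):
        s = normalize_scale(z_in)
        xs.append(complex_to_channels(z_in / s))
        ys.append(complex_to_channels(z_lb / s))
    return (np.stack(xs).astype(np.float32), np.stack(ys).astype(np.float32))


def _split_by_volume(volume_index: np.ndarray, val_fraction: float,
                     seed: int) -> tuple[np.ndarray, np.ndarray]:
    vols = np.unique(volume_index)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(vols)
    n_val = max(1, int(round(val_fraction * vols.size)))
    val_vols = set(perm[:n_val].tolist())
    is_val = np.array([v in val_vols for v in volume_index])
    return np.flatnonzero(~is_val), np.flatnonzero(is_val)


def make_stage2_inputs(dataset: TrainingSet, subnet1, order: str) -> np.ndarray:
    """Propagate every example through the frozen stage-1 network plus MCDC.

    Returns the complex stage-2 inputs (k-space arrays for IK order, images
    for KI order); deterministic given the stage-1 weights.
    """
    out = np.empty_like(dataset.zf_image)
    for i in range(dataset.n_examples):
        if order == "KI":
            img = ifft2c(forward_knet(dataset.zf_kspace[i], subnet1))
            out[i] = mcdc(img, dataset.maps[i], dataset.acquired[i])
        else:
            img = forward_inet(dataset.zf_image[i], subnet1)
            out[i] = fft2c(mcdc(img, dataset.maps[i], dataset.acquired[i]))
    return out


def train_cascade(dataset: TrainingSet, order: str, train_config: TrainConfig,
                  unet_config: UNetConfig, af: float = 2.0) -> CascadeModel:
    """Two-stage incremental training of a KI or IK cascade.

    Stage 1 trains subnetwork 1 on (zero-filled, fully sampled) pairs in its
    own domain; stage 2 freezes it, rebuilds every input through subnetwork 1
    and MCDC (with the simulation's true maps), and trains subnetwork 2
    against its domain's fully sampled labels.
    """
    if order not in ("KI", "IK"):
        raise ValueError(f"order must be 'KI' or 'IK', got {order!r}")
    if dataset.n_examples == 0:
        raise ValueError("empty dataset")
    tr, va = _split_by_volume(dataset.volume_index, train_config.val_fraction,
                              train_config.seed)
    if tr.size == 0 or va.size == 0:
        raise ValueError("train/validation split produced an empty side")

    kw = dict(lr0=train_config.lr0, lr_factor=train_config.lr_factor,
              lr_patience=train_config.lr_patience,
              early_patience=train_config.early_patience,
              batch_size=train_config.batch_size,
              max_epochs=train_config.max_epochs)

    # stage 1
    if order == "KI":
        in1, lb1 = dataset.zf_kspace, dataset.label_kspace
    else:
        in1, lb1 = dataset.zf_image, dataset.label_image
    x1, y1 = _pack_pairs(in1, lb1)
    net1 = build_unet(UNetConfig(**{**vars(unet_config), "seed": train_config.seed}))
    hist1 = train_network(net1, x1[tr], y1[tr], x1[va], y1[va],
                          seed=train_config.seed, **kw)

    # stage 2: frozen stage-1 outputs become stage-2 inputs
    in2 = make_stage2_inputs(dataset, net1, order)
    lb2 = dataset.label_image if order == "KI" else dataset.label_kspace
    x2, y2 = _pack_pairs(in2, lb2)
    net2 = build_unet(UNetConfig(**{**vars(unet_config), "seed": train_config.seed + 1}))
    hist2 = train_network(net2, x2[tr], y2[tr], x2[va], y2[va],
                          seed=train_config.seed + 1, **kw)

    return CascadeModel(order=order, subnet1=net1, subnet2=net2,
                        maps_policy="true_maps", af=af,
                        histories=(hist1, hist2))
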