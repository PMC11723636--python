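"""The package's standard synthetic benchmark.

One fixed recipe shared by the test-suite and the reproduction script:
cardiac-like 64x64 phantoms expanded to 8 simulated receiver coils,
variable-density undersampled at a requested acceleration factor.  The
training pool holds 200 single-frame volumes and the held-out test pool 20,
with disjoint seeds; networks use 8 base filters so the whole study runs on
one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import TrainConfig, TrainingSet, make_training_set
from .coils import AcquiredData, acquire, adaptive_combine
from .networks import UNetConfig
from .synthetic import (CoilGeometry, MultiCoilData, SensitivityMaps,
                        biot_savart_maps, make_cine_volume)

__all__ = ["Benchmark", "make_benchmark", "desk_unet_config", "desk_train_config"]


@dataclass
class Benchmark:
    """Training set plus held-out test volumes (with their references)."""

    train: TrainingSet
    test_acquired: list[AcquiredData]
    test_maps: list[SensitivityMaps]
    test_references: list[np.ndarray]
    af: float


def desk_unet_config(seed: int = 0) -> UNetConfig:
    return UNetConfig(base_filters=8, seed=seed)


def desk_train_config(seed: int = 0, max_epochs: int = 30) -> TrainConfig:
    return TrainConfig(max_epochs=max_epochs, seed=seed)


def make_benchmark(
    seed: int = 0,
    af: float = 2.0,
    n_train: int = 200,
    n_test: int = 20,
    shape: tuple[int, int] = (64, 64),
    n_coils: int = 8,
) -> Benchmark:
    """Build the standard benchmark; seeds of test phantoms are disjoint
    from training seeds, and test masks use their own seed stream."""
    geometry = CoilGeometry.default(n_coils, shape[0])
    maps = biot_savart_maps(geometry, shape)

    train_vols = [
        make_cine_volume(shape, seed=(seed * 1_000_003 + i) % 2 ** 31, n_coils=n_coils,
                         geometry=geometry, maps=maps)
        for i in range(n_train)
    ]
    train = make_training_set(train_vols, af=af, mask_seed=(seed * 31 + 1) % 2 ** 20)

    test_acq, test_maps, test_refs = [], [], []
    from .transforms import vd_mask

    for j in range(n_test):
        vol = make_cine_volume(shape, seed=(seed * 1_000_003 + n_train + 500 + j) % 2 ** 31,
                               n_coils=n_coils, geometry=geometry, maps=maps)
        mask = vd_mask(shape[1], af, seed=(seed * 37 + 100_000 + j) % 2 ** 31)
        acq = acquire(vol.frame_kspace(0), mask)
        test_acq.append(acq)
        test_maps.append(maps)
        test_refs.append(adaptive_combine(vol.frame_images(0), maps))
    return Benchmark(train=train, test_acquired=test_acq, test_maps=test_maps,
                     test_references=test_refs, af=af)
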