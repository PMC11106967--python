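"""Desk-scale phantom experiments: the full pipeline at CPU-friendly size.

These functions wire the pipeline stages together on synthetic phantoms:
normalise -> crop to the pot interior -> tile -> train -> predict ->
evaluate.  They are the backbone of the examples, the end-to-end tests
and the results-reproduction script.

Scaled-down study design
------------------------
The full-scale protocol (64-voxel tiles, batch 64, thousands of epochs)
is impractical on a single CPU, so the desk-scale experiments shrink the
problem while keeping every mechanism intact: 96^3 phantoms, a
``base_width=4`` network, all non-overlapping 24-voxel training tiles of
the pot-cropped volume, batches of 9 tiles (so each soft-Dice step mixes
root, soil and air context), 50 epochs, and a larger constant learning
rate appropriate for the much shorter schedule.  Tiled inference still
uses the standard 64-voxel tiles with 8-voxel overlap margins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import MetricsReport, evaluate_volumes, psnr
from .model import SegModelConfig, VoxResNet, build_model, predict_volume, restore_volume
from .synthetic_data import NoiseSpec, apply_noise, generate_phantom, tiny_spec
from .tiling import plan_tiles
from .training import LossCurve, TrainConfig, train
from .volume_io import (
    CTVolume,
    LabelVolume,
    crop_center,
    find_histogram_peaks,
    rescale_to_gray8,
    to_unit,
)

__all__ = [
    "desk_model_config",
    "desk_train_config",
    "normalize_volume",
    "crop_pair",
    "tile_dataset",
    "SegmentationResult",
    "RestorationResult",
    "run_segmentation_experiment",
    "run_restoration_experiment",
]

#: desk-scale learning rates, chosen once for the 50-epoch schedule by a
#: short stability pilot (the full-scale rates assume thousands of epochs)
DESK_SEG_LR = 1e-2
DESK_RESTO_LR = 3e-3
#: restoration demo degradation: heavy noise on a binned short scan, so
#: the noisy baseline leaves the restorer real headroom
DESK_RESTO_SIGMA = 5000.0
#: training-tile side at desk scale; must be divisible by 4
DESK_TILE = 24
#: tiles per batch: each soft-Dice step sees root, soil and air context
DESK_BATCH = 9
#: crop radius in voxels: just inside the phantom pot wall, mirroring the
#: full protocol's 9-cm crop of a 10-cm-radius pot
DESK_CROP_VOX = 40


def desk_model_config(head: str = "sigmoid") -> SegModelConfig:
    """Reduced architecture for CPU-scale runs.

    Segmentation enables deep supervision: with only ~200 optimisation
    steps the auxiliary coarse-stage outputs markedly stabilise training
    (they shorten the gradient path to the encoder), and multi-level
    fused outputs are how the original voxel-wise residual architecture
    was described.  The restoration trunk stays single-output.
    """
    return SegModelConfig(
        base_width=4,
        num_voxres_blocks=(1, 1, 1, 1),
        head=head,
        deep_supervision=(head == "sigmoid"),
    )


def desk_train_config(task: str, seed: int, epochs: int = 50) -> TrainConfig:
    lr = DESK_SEG_LR if task == "segmentation" else DESK_RESTO_LR
    return TrainConfig(
        task=task, learning_rate=lr, batch_size=DESK_BATCH, epochs=epochs,
        seed=seed,
    )


def normalize_volume(raw: CTVolume) -> CTVolume:
    """Peak-anchored rescale to gray8, then to the unit interval."""
    return to_unit(rescale_to_gray8(raw, find_histogram_peaks(raw)))


def crop_pair(
    vol: CTVolume,
    label: LabelVolume,
    crop_vox: int = DESK_CROP_VOX,
    trim_multiple: int | None = None,
) -> tuple[CTVolume, LabelVolume]:
    """Crop both members of an aligned volume/label pair to the pot interior.

    With ``trim_multiple`` the cropped plane is further trimmed (centred)
    to the largest multiple of that value, so a lattice of training tiles
    covers the analysis volume exactly — voxels no training tile ever saw
    would otherwise leak into the evaluation.
    """
    r_mm = crop_vox * vol.voxel_size_mm
    vol_c = crop_center(vol, r_mm)
    lab_as_vol = CTVolume(
        label.data.astype(np.float32), "unit", voxel_size_mm=vol.voxel_size_mm
    )
    lab_c = crop_center(lab_as_vol, r_mm)
    out_v, out_l = vol_c.data, lab_c.data > 0.5
    if trim_multiple:
        H, W, D = out_v.shape
        sw = (W // trim_multiple) * trim_multiple
        sd = (D // trim_multiple) * trim_multiple
        w0, d0 = (W - sw) // 2, (D - sd) // 2
        out_v = out_v[:, w0 : w0 + sw, d0 : d0 + sd]
        out_l = out_l[:, w0 : w0 + sw, d0 : d0 + sd]
    return (
        vol_c.with_data(out_v),
        LabelVolume(out_l, voxel_size_mm=vol.voxel_size_mm),
    )


def tile_dataset(
    data: np.ndarray,
    target: np.ndarray,
    tile: int = DESK_TILE,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """All non-overlapping training tiles of an aligned (input, target) pair.

    Full coverage matters: air, the soil surface and plain soil texture
    must all appear in training, or the network never learns to reject
    them at prediction time.
    """
    H, W, D = data.shape
    return [
        (data[i : i + tile, j : j + tile, k : k + tile],
         target[i : i + tile, j : j + tile, k : k + tile])
        for i in range(0, H - tile + 1, tile)
        for j in range(0, W - tile + 1, tile)
        for k in range(0, D - tile + 1, tile)
    ]


@dataclass
class SegmentationResult:
    curve: LossCurve
    holdout: MetricsReport
    net: VoxResNet

    @property
    def loss_ratio(self) -> float:
        """Final-epoch mean loss over epoch-1 mean loss."""
        return self.curve.losses[-1] / self.curve.losses[0]


@dataclass
class RestorationResult:
    curve: LossCurve
    psnr_noisy: float
    psnr_restored: float
    net: VoxResNet


def _phantom_pair(
    seed: int, sigma: float, binning: bool = False
) -> tuple[CTVolume, CTVolume, LabelVolume]:
    """One phantom (noisy, clean, label) at the given noise level."""
    clean, label = generate_phantom(tiny_spec(seed=seed))
    if sigma > 0 or binning:
        noisy = apply_noise(
            clean, NoiseSpec(gaussian_sigma=sigma, binning=binning, seed=seed + 1)
        )
    else:
        noisy = clean
    return noisy, clean, label


def _normalize_against_clean(noisy: CTVolume, clean: CTVolume) -> CTVolume:
    """Rescale a noisy series member with the clean member's anchors.

    Members of an aligned scan series share geometry; heavy noise can
    wash out the noisy member's own bimodality, so the anchors come from
    the clean (long-scan) volume — the same volume that provides the
    ground truth.
    """
    peaks = find_histogram_peaks(clean)
    return to_unit(rescale_to_gray8(noisy, peaks))


def run_segmentation_experiment(
    seed: int = 0,
    sigma: float = 0.0,
    epochs: int = 50,
    binning: bool = False,
    train_phantom_seed: int | None = None,
    holdout_phantom_seed: int | None = None,
) -> SegmentationResult:
    """Train the desk-scale segmentation network on one noisy phantom and
    evaluate on a held-out phantom from the same specification.

    The training and held-out phantoms differ only in their generator
    seeds; both are degraded with the same noise level.
    """
    tseed = train_phantom_seed if train_phantom_seed is not None else seed + 101
    hseed = holdout_phantom_seed if holdout_phantom_seed is not None else seed + 907
    train_noisy, train_clean, train_label = _phantom_pair(tseed, sigma, binning)
    hold_noisy, hold_clean, hold_label = _phantom_pair(hseed, sigma, binning)

    xt, lt = crop_pair(
        _normalize_against_clean(train_noisy, train_clean), train_label,
        trim_multiple=DESK_TILE,
    )
    xh, lh = crop_pair(
        _normalize_against_clean(hold_noisy, hold_clean), hold_label,
        trim_multiple=DESK_TILE,
    )

    dataset = tile_dataset(xt.data, lt.data)
    net = build_model(desk_model_config(), seed=seed)
    net, curve = train(net, dataset, desk_train_config("segmentation", seed, epochs))

    pred = predict_volume(net, xh, plan_tiles(xh.shape))
    return SegmentationResult(
        curve=curve, holdout=evaluate_volumes(pred, lh), net=net
    )


def run_restoration_experiment(
    seed: int = 0,
    sigma: float = DESK_RESTO_SIGMA,
    epochs: int = 50,
    binning: bool = True,
) -> RestorationResult:
    """Noise2Clean at desk scale: learn short-scan -> long-scan mapping on
    one phantom, then restore a held-out phantom and compare PSNR.

    Both PSNR values are measured on the unit intensity scale against the
    held-out clean volume.
    """
    tseed, hseed = seed + 101, seed + 907
    train_clean, train_label = generate_phantom(tiny_spec(seed=tseed))
    hold_clean, hold_label = generate_phantom(tiny_spec(seed=hseed))
    train_noisy = apply_noise(
        train_clean, NoiseSpec(gaussian_sigma=sigma, binning=binning, seed=tseed + 1)
    )
    hold_noisy = apply_noise(
        hold_clean, NoiseSpec(gaussian_sigma=sigma, binning=binning, seed=hseed + 1)
    )

    # anchor both members of each pair on the clean volume's histogram so
    # the mapping is pure denoising, not an intensity shift
    def unit_pair(noisy, clean):
        peaks = find_histogram_peaks(clean)
        return (
            to_unit(rescale_to_gray8(noisy, peaks)),
            to_unit(rescale_to_gray8(clean, peaks)),
        )

    xt_noisy, xt_clean = unit_pair(train_noisy, train_clean)
    xh_noisy, xh_clean = unit_pair(hold_noisy, hold_clean)
    xt_noisy, _ = crop_pair(xt_noisy, train_label, trim_multiple=DESK_TILE)
    xt_clean, _ = crop_pair(xt_clean, train_label, trim_multiple=DESK_TILE)
    xh_noisy, _ = crop_pair(xh_noisy, hold_label, trim_multiple=DESK_TILE)
    xh_clean, _ = crop_pair(xh_clean, hold_label, trim_multiple=DESK_TILE)

    dataset = tile_dataset(xt_noisy.data, xt_clean.data)
    net = build_model(desk_model_config(head="none"), seed=seed)
    net, curve = train(net, dataset, desk_train_config("restoration", seed, epochs))

    restored = restore_volume(net, xh_noisy, plan_tiles(xh_noisy.shape))
    return RestorationResult(
        curve=curve,
        psnr_noisy=psnr(xh_noisy.data, xh_clean.data, max_val=1.0),
        psnr_restored=psnr(restored.data, xh_clean.data, max_val=1.0),
        net=net,
    )
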