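"""Synthetic root-in-soil phantoms with known voxel labels.

The generator emulates the salient statistics of a pot of granular
calcined-clay substrate scanned by X-ray CT:

* a bimodal air/soil intensity histogram (air layer above the soil
  surface and outside the pot cylinder; granular soil texture inside);
* crown roots that start near the top centre and grow downward as biased
  3-D random walks, rasterised as tubes of known radius — the exact
  Boolean label volume comes for free;
* scan-time-dependent degradation: additive Gaussian noise plus an
  optional 3x3 in-plane binning blur, perfectly aligned with the clean
  volume so noisy/clean pairs can train a Noise2Clean restorer.

Roots are rendered darker than soil by default (water-filled tissue in a
dry granular matrix attenuates less); the contrast sign is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .volume_io import CTVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "generate_phantom",
    "apply_noise",
    "make_scan_series",
    "tiny_spec",
    "demo_spec",
]

_RAW_MAX = 65535


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensity parameters of one phantom.

    Intensities are raw16 means; ``soil_texture_sigma`` is the granular
    intensity variation of the substrate.  ``downward_bias`` in [0, 1]
    weights the growth direction toward +H (1 = straight down when
    tortuosity is 0); ``tortuosity`` scales per-step angular jitter.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 0.3
    n_roots: int = 3
    root_radius_vox: tuple[float, float] = (2.0, 3.0)
    step_length_vox: float = 1.0
    downward_bias: float = 0.8
    tortuosity: float = 0.25
    air_level: float = 2000.0
    soil_level: float = 20000.0
    root_level: float = 9000.0
    soil_texture_sigma: float = 1200.0
    air_gap_frac: float = 0.1
    pot_radius_frac: float = 0.95
    lateral_branch_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_roots < 0:
            raise ValueError("n_roots must be >= 0")
        if self.root_radius_vox[0] < 1:
            raise ValueError("root radius must be >= 1 voxel")
        if not self.air_level < min(self.root_level, self.soil_level):
            raise ValueError("air must be the darkest phase")
        if self.root_level == self.soil_level:
            raise ValueError("root/soil contrast must be nonzero")
        if 2 * max(self.root_radius_vox) >= min(self.shape):
            raise ValueError("roots cannot fit in the volume")


@dataclass(frozen=True)
class NoiseSpec:
    """Scan-time-dependent degradation parameters."""

    gaussian_sigma: float = 0.0
    binning: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


def tiny_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """96^3 preset used for CPU-scale tests and examples."""
    return replace(PhantomSpec(shape=(96, 96, 96), seed=seed), **overrides)


def demo_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """192^3 preset for slightly richer demonstrations."""
    return replace(
        PhantomSpec(shape=(192, 192, 192), n_roots=6, seed=seed), **overrides
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        return np.array([1.0, 0.0, 0.0])
    return v / n


def _walk_centerline(
    spec: PhantomSpec,
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
) -> list[np.ndarray]:
    """Grow one root as a biased random walk; returns centreline points."""
    H, W, D = spec.shape
    cw, cd = (W - 1) / 2.0, (D - 1) / 2.0
    pot_r = spec.pot_radius_frac * min(W, D) / 2.0
    pos = start.astype(float)
    d = _unit(direction)
    points = [pos.copy()]
    max_steps = int(3 * H / spec.step_length_vox)
    for _ in range(max_steps):
        jitter = spec.tortuosity * rng.standard_normal(3)
        pull = spec.downward_bias * np.array([1.0, 0.0, 0.0])
        d = _unit(d + jitter + pull * 0.5)
        pos = pos + d * spec.step_length_vox
        if pos[0] >= H - 1:
            break
        if (pos[1] - cw) ** 2 + (pos[2] - cd) ** 2 > (pot_r - 1) ** 2:
            break
        points.append(pos.copy())
    return points


def _stamp_tube(
    label: np.ndarray, points: list[np.ndarray], radius: float
) -> None:
    """Mark every voxel within ``radius`` of any centreline point."""
    H, W, D = label.shape
    r = int(np.ceil(radius))
    offs = np.arange(-r, r + 1)
    oz, oy, ox = np.meshgrid(offs, offs, offs, indexing="ij")
    for p in points:
        c = np.round(p).astype(int)
        ball = (
            (oz + (c[0] - p[0])) ** 2
            + (oy + (c[1] - p[1])) ** 2
            + (ox + (c[2] - p[2])) ** 2
        ) <= radius**2
        zz, yy, xx = np.nonzero(ball)
        z = c[0] + zz - r
        y = c[1] + yy - r
        x = c[2] + xx - r
        ok = (
            (z >= 0) & (z < H) & (y >= 0) & (y < W) & (x >= 0) & (x < D)
        )
        label[z[ok], y[ok], x[ok]] = True


def _granular_texture(
    rng: np.random.Generator, shape, sigma: float, grain_vox: float = 1.2
) -> np.ndarray:
    """Spatially correlated zero-mean noise mimicking substrate grains."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), grain_vox)
    sd = noise.std()
    if sd > 0:
        noise *= sigma / sd
    return noise


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelVolume]:
    """Generate one clean raw16 phantom and its exact Boolean root label."""
    rng = np.random.default_rng(spec.seed)
    H, W, D = spec.shape
    cw, cd = (W - 1) / 2.0, (D - 1) / 2.0
    air_gap = max(1, int(round(spec.air_gap_frac * H)))
    pot_r = spec.pot_radius_frac * min(W, D) / 2.0

    # soil background with granular texture
    vol = spec.soil_level + _granular_texture(
        rng, spec.shape, spec.soil_texture_sigma
    )

    # roots: biased random walks rasterised as tubes
    label = np.zeros(spec.shape, dtype=bool)
    for _ in range(spec.n_roots):
        radius = rng.uniform(*spec.root_radius_vox)
        jw = rng.uniform(-0.15, 0.15) * W
        jd = rng.uniform(-0.15, 0.15) * D
        start = np.array([float(air_gap), cw + jw, cd + jd])
        # initial tilt scales with tortuosity so a tortuosity-0 root is a
        # perfectly vertical tube
        direction = np.array(
            [
                1.0,
                spec.tortuosity * rng.normal(0, 0.8),
                spec.tortuosity * rng.normal(0, 0.8),
            ]
        )
        points = _walk_centerline(spec, rng, start, direction)
        _stamp_tube(label, points, radius)
        if spec.lateral_branch_prob > 0:
            for p in points[:: max(1, int(2 * spec.step_length_vox))]:
                if rng.random() < spec.lateral_branch_prob:
                    side = np.array(
                        [0.3, rng.normal(0, 1.0), rng.normal(0, 1.0)]
                    )
                    branch = _walk_centerline(
                        replace(spec, downward_bias=0.2), rng, p, side
                    )
                    _stamp_tube(label, branch[: len(branch) // 2], radius / 2)

    vol[label] = spec.root_level + 0.2 * spec.soil_texture_sigma * (
        rng.standard_normal(int(label.sum()))
    )

    # air above the soil surface and outside the pot cylinder
    w = np.arange(W) - cw
    d = np.arange(D) - cd
    outside = (w[:, None] ** 2 + d[None, :] ** 2) > pot_r**2
    air_sigma = 0.1 * spec.soil_texture_sigma
    air = spec.air_level + air_sigma * rng.standard_normal(spec.shape)
    vol[:air_gap] = air[:air_gap]
    vol[:, outside] = air[:, outside]
    label[:air_gap] = False
    label[:, outside] = False

    data = np.clip(np.round(vol), 0, _RAW_MAX).astype(np.uint16)
    return (
        CTVolume(data, "raw16", voxel_size_mm=spec.voxel_size_mm),
        LabelVolume(label, voxel_size_mm=spec.voxel_size_mm),
    )


def apply_noise(clean: CTVolume, noise: NoiseSpec) -> CTVolume:
    """Degrade a clean phantom: optional binning blur, then Gaussian noise.

    The output stays voxel-aligned with the input (no geometric change).
    Binning is emulated as a 3x3 in-plane box blur — the resolution cost
    of merging detector pixels — and is applied *before* the noise:
    binning degrades resolution, while the noise of a short scan is
    observed on top of the binned image.  Blurring after adding noise
    would average the noise away and invert the scan-time quality trend
    the series is meant to emulate.
    """
    if noise.gaussian_sigma == 0 and not noise.binning:
        return clean.with_data(clean.data.copy())
    data = clean.data.astype(np.float64)
    if noise.binning:
        data = ndimage.uniform_filter(data, size=(1, 3, 3), mode="nearest")
    if noise.gaussian_sigma > 0:
        rng = np.random.default_rng(noise.seed)
        data = data + rng.normal(0.0, noise.gaussian_sigma, size=data.shape)
    out = np.clip(np.round(data), 0, _RAW_MAX).astype(np.uint16)
    return clean.with_data(out)


def make_scan_series(
    spec: PhantomSpec,
    sigmas: list[float],
    binning_flags: list[bool] | None = None,
) -> tuple[list[CTVolume], LabelVolume]:
    """One clean phantom degraded at several noise levels, sharing a label.

    Mirrors a scan-time series of the same pot: all volumes are aligned
    and the single ground-truth label applies to every member.
    """
    if binning_flags is None:
        binning_flags = [False] * len(sigmas)
    if len(sigmas) != len(binning_flags):
        raise ValueError("sigmas and binning_flags must have equal length")
    clean, label = generate_phantom(spec)
    seeds = np.random.SeedSequence([spec.seed, 9173]).generate_state(
        max(1, len(sigmas))
    )
    series = [
        apply_noise(
            clean,
            NoiseSpec(
                gaussian_sigma=s, binning=b, seed=int(seeds[i]) % (2**31 - 1)
            ),
        )
        for i, (s, b) in enumerate(zip(sigmas, binning_flags))
    ]
    return series, label
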