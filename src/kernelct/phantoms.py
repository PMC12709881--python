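"""Deterministic kernel-like CT phantoms with known ground truth.

A phantom is a nested-ellipsoid "seed": a bright pericarp rim on the
outside, a vitreous-endosperm shell (label 2) under it, and a starchy
core (label 1) at the centre, embedded in a dim uniform background.
The image is built from crisp per-region mean intensities, then
Gaussian-blurred and corrupted with additive Gaussian noise — emulating
the two properties that make real kernel CT hard: small intensity
contrast between the two endosperm classes and blurred inter-class
boundaries.  The labels are the *pre-blur* crisp regions, so ground
truth stays exact while the image carries the ambiguity.

Default intensities (background 20, starchy 150, vitreous 180, pericarp
220) put the endosperm contrast gap at 30 gray levels: visually faint
but learnable at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io_formats import CTVolume, LabelVolume, DEFAULT_VOXEL_EDGE_UM


@dataclass
class PhantomSpec:
    """Geometry, intensity and noise parameters of one phantom kernel.

    ``shell_fraction`` and ``core_fraction`` are radial fractions of the
    outer ellipsoid: normalized radius r < core_fraction is starchy
    core, core_fraction <= r < shell_fraction is vitreous shell, and
    shell_fraction <= r <= 1 is pericarp (seed but not endosperm).
    """

    shape: tuple[int, int, int] = (64, 96, 96)
    semi_axes_um: tuple[float, float, float] = (24 * 27.0, 36 * 27.0, 32 * 27.0)
    shell_fraction: float = 0.92
    core_fraction: float = 0.62
    intensity_bg: float = 20.0
    intensity_starchy: float = 150.0
    intensity_vitreous: float = 180.0
    intensity_pericarp: float = 220.0
    noise_sd: float = 8.0
    blur_sigma: float = 1.2
    seed: int = 0
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM
    center: tuple[float, float, float] | None = None

    @property
    def contrast_gap(self) -> float:
        """Absolute endosperm intensity contrast |vitreous − starchy|."""
        return abs(self.intensity_vitreous - self.intensity_starchy)

    @property
    def semi_axes_vox(self) -> tuple[float, float, float]:
        return tuple(a / self.voxel_edge_um for a in self.semi_axes_um)  # type: ignore[return-value]

    def validate(self) -> None:
        if not (0.0 < self.core_fraction < self.shell_fraction <= 1.0):
            raise ValueError(
                f"need 0 < core_fraction < shell_fraction <= 1, got "
                f"core={self.core_fraction}, shell={self.shell_fraction}"
            )
        for name in ("intensity_bg", "intensity_starchy", "intensity_vitreous", "intensity_pericarp"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise ValueError(f"{name}={v} outside [0, 255]")
        if self.noise_sd < 0 or self.blur_sigma < 0:
            raise ValueError("noise_sd and blur_sigma must be >= 0")
        if min(self.shape) < 1:
            raise ValueError(f"empty shape {self.shape}")
        if min(self.semi_axes_vox) <= 0:
            raise ValueError("semi-axes must be positive")


@dataclass
class PhantomTruth:
    """Exact ground-truth bookkeeping emitted alongside a phantom."""

    seed_count: int
    starchy_count: int
    vitreous_count: int
    pericarp_count: int
    centroid: tuple[float, float, float]
    bbox: tuple[int, int, int, int, int, int]  # half-open (z0,z1,y0,y1,x0,x1)
    spec: PhantomSpec

    @property
    def analytic_seed_volume_vox(self) -> float:
        """(4/3)π·a·b·c of the outer ellipsoid, in voxel units."""
        a, b, c = self.spec.semi_axes_vox
        return 4.0 / 3.0 * np.pi * a * b * c


def _normalized_radius(shape, center, semi_axes_vox) -> np.ndarray:
    zz, yy, xx = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]),
        indexing="ij",
    )
    cz, cy, cx = center
    az, ay, ax = semi_axes_vox
    return np.sqrt(((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)


def generate_kernel_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelVolume, PhantomTruth]:
    """Generate one kernel phantom; identical output for identical seed."""
    spec.validate()
    center = spec.center if spec.center is not None else tuple((s - 1) / 2.0 for s in spec.shape)
    r = _normalized_radius(spec.shape, center, spec.semi_axes_vox)

    seed_mask = r <= 1.0
    core = r < spec.core_fraction
    shell = (r >= spec.core_fraction) & (r < spec.shell_fraction) & seed_mask
    pericarp = seed_mask & ~core & ~shell

    labels = np.zeros(spec.shape, dtype=np.uint8)
    labels[core] = 1
    labels[shell] = 2

    image = np.full(spec.shape, spec.intensity_bg, dtype=np.float64)
    image[pericarp] = spec.intensity_pericarp
    image[shell] = spec.intensity_vitreous
    image[core] = spec.intensity_starchy
    if spec.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.blur_sigma)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = image + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    idx = np.nonzero(seed_mask)
    if idx[0].size == 0:
        raise ValueError("phantom seed does not intersect the volume; enlarge shape or shrink axes")
    centroid = tuple(float(np.mean(ax)) for ax in idx)
    bbox = (
        int(idx[0].min()), int(idx[0].max()) + 1,
        int(idx[1].min()), int(idx[1].max()) + 1,
        int(idx[2].min()), int(idx[2].max()) + 1,
    )
    truth = PhantomTruth(
        seed_count=int(seed_mask.sum()),
        starchy_count=int(core.sum()),
        vitreous_count=int(shell.sum()),
        pericarp_count=int(pericarp.sum()),
        centroid=centroid,  # type: ignore[arg-type]
        bbox=bbox,
        spec=spec,
    )
    ct = CTVolume(data=image, voxel_edge_um=spec.voxel_edge_um,
                  source_id=f"phantom-seed{spec.seed}")
    lab = LabelVolume(data=labels, voxel_edge_um=spec.voxel_edge_um)
    return ct, lab, truth


def generate_batch_scene(
    specs: Sequence[PhantomSpec],
    spacing_vox: int = 12,
) -> tuple[CTVolume, list[PhantomTruth]]:
    """Composite several phantoms side-by-side along x on a dim background.

    The analogue of several kernels glued to a foam board and scanned in
    one pass.  Ground-truth centroids and bounding boxes are returned in
    scene coordinates for testing batch splitting.

    Raises if the kernels would overlap at the requested spacing (each
    phantom occupies its own x-band, so disjointness is guaranteed by
    construction; a negative spacing triggers the error).
    """
    if not specs:
        raise ValueError("need at least one phantom spec")
    if spacing_vox < 0:
        raise ValueError(f"kernels would overlap: spacing_vox={spacing_vox} < 0")
    truths = []
    bg = float(np.mean([s.intensity_bg for s in specs]))
    z_max = max(s.shape[0] for s in specs)
    y_max = max(s.shape[1] for s in specs)
    x_off = spacing_vox
    total_x = spacing_vox + sum(s.shape[2] + spacing_vox for s in specs)
    scene = np.full((z_max, y_max, total_x), bg)
    for i, spec in enumerate(specs):
        ct, _, truth = generate_kernel_phantom(spec)
        z0 = (z_max - spec.shape[0]) // 2
        y0 = (y_max - spec.shape[1]) // 2
        sl = (slice(z0, z0 + spec.shape[0]), slice(y0, y0 + spec.shape[1]),
              slice(x_off, x_off + spec.shape[2]))
        scene[sl] = np.maximum(scene[sl], ct.data.astype(np.float64))
        b = truth.bbox
        truths.append(PhantomTruth(
            seed_count=truth.seed_count,
            starchy_count=truth.starchy_count,
            vitreous_count=truth.vitreous_count,
            pericarp_count=truth.pericarp_count,
            centroid=(truth.centroid[0] + z0, truth.centroid[1] + y0, truth.centroid[2] + x_off),
            bbox=(b[0] + z0, b[1] + z0, b[2] + y0, b[3] + y0, b[4] + x_off, b[5] + x_off),
            spec=truth.spec,
        ))
        x_off += spec.shape[2] + spacing_vox
    for a, b in zip(truths, truths[1:]):
        if a.bbox[5] > b.bbox[4]:
            raise ValueError("kernels overlap at the requested spacing")
    ct = CTVolume(data=np.clip(np.rint(scene), 0, 255).astype(np.uint8),
                  voxel_edge_um=specs[0].voxel_edge_um,
                  source_id=f"batch-scene-{len(specs)}")
    return ct, truths


#: parameter ranges the training-set sampler draws from by default;
#: chosen to span faint-contrast, blurred, noisy kernels around the defaults
DEFAULT_SPEC_RANGES: Mapping[str, tuple[float, float]] = {
    "semi_axis_y_vox": (30.0, 44.0),
    "semi_axis_x_vox": (26.0, 40.0),
    "core_fraction": (0.45, 0.72),
    "shell_fraction": (0.85, 0.96),
    "intensity_starchy": (140.0, 160.0),
    "contrast_gap": (22.0, 38.0),
    "noise_sd": (4.0, 10.0),
    "blur_sigma": (0.8, 1.6),
    "center_jitter_frac": (-0.08, 0.08),
}


def make_training_set(
    n: int,
    spec_ranges: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    side: int = 128,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Sample ``n`` paired (image, label) central phantom slices.

    Images are float32 in [0, 1] of shape (side, side); labels uint8 in
    {0, 1, 2}.  Deterministic under ``seed``.  Each sample is the
    central axial slice of a thin 3D phantom whose parameters are drawn
    uniformly from ``spec_ranges``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_SPEC_RANGES)
    if spec_ranges:
        for k, v in spec_ranges.items():
            if k not in ranges:
                raise ValueError(f"unknown spec range {k!r}")
            lo, hi = v
            if lo > hi:
                raise ValueError(f"invalid range for {k}: {v}")
            ranges[k] = (float(lo), float(hi))
    rng = np.random.default_rng(seed)
    pairs = []
    zdim = 9
    for i in range(n):
        draw = {k: rng.uniform(*ranges[k]) for k in ranges}
        ay = min(draw["semi_axis_y_vox"], side / 2 - 2)
        ax = min(draw["semi_axis_x_vox"], side / 2 - 2)
        jitter_y = draw["center_jitter_frac"] * side
        jitter_x = rng.uniform(*ranges["center_jitter_frac"]) * side
        edge = DEFAULT_VOXEL_EDGE_UM
        spec = PhantomSpec(
            shape=(zdim, side, side),
            # large z semi-axis: the central slice cuts near the equator
            semi_axes_um=(max(ay, ax) * 3 * edge, ay * edge, ax * edge),
            shell_fraction=draw["shell_fraction"],
            core_fraction=min(draw["core_fraction"], draw["shell_fraction"] - 0.08),
            intensity_starchy=draw["intensity_starchy"],
            intensity_vitreous=min(draw["intensity_starchy"] + draw["contrast_gap"], 255.0),
            noise_sd=draw["noise_sd"],
            blur_sigma=draw["blur_sigma"],
            seed=int(rng.integers(0, 2**31 - 1)),
            voxel_edge_um=edge,
            center=((zdim - 1) / 2.0,
                    (side - 1) / 2.0 + jitter_y,
                    (side - 1) / 2.0 + jitter_x),
        )
        ct, lab, _ = generate_kernel_phantom(spec)
        mid = zdim // 2
        image = ct.data[mid].astype(np.float32) / 255.0
        label = lab.data[mid].copy()
        pairs.append((image, label))
    return pairs
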