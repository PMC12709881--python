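"""Raw batch-scan slices → model-ready single-kernel inputs and labels.

The stages mirror how the scans are prepared for segmentation:

1. intensity clamping to a [min_val, max_val] window,
2. contrast enhancement (percentile linear stretch by default, CLAHE as
   a named alternative),
3. remapping of raw annotation gray values onto the class codes
   {0 background, 1 starchy, 2 vitreous},
4. Canny-edge-based splitting of a multi-kernel batch scan into
   per-kernel crops,
5. aspect-preserving resize + zero-pad of a crop to the square side the
   network consumes, intensities rescaled to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure, feature, transform

from .io_formats import CTVolume
from .phenotype import otsu_threshold


@dataclass(frozen=True)
class PixelClampSpec:
    """Intensity clamping window; defaults pass 8-bit data unchanged."""

    min_val: float = 0
    max_val: float = 255

    def __post_init__(self) -> None:
        if self.min_val > self.max_val:
            raise ValueError(f"min_val {self.min_val} > max_val {self.max_val}")


@dataclass(frozen=True)
class KernelCrop:
    """One kernel's sub-volume cut out of a batch scan.

    ``bbox`` is a 0-based, half-open (z0, z1, y0, y1, x0, x1) index
    range into the source volume; ``kernel_index`` orders kernels
    left-to-right by centroid x.
    """

    image: np.ndarray
    bbox: tuple[int, int, int, int, int, int]
    kernel_index: int

    def __post_init__(self) -> None:
        z0, z1, y0, y1, x0, x1 = self.bbox
        if not (z1 > z0 >= 0 and y1 > y0 >= 0 and x1 > x0 >= 0):
            raise ValueError(f"empty or negative bbox {self.bbox}")
        if self.kernel_index < 0:
            raise ValueError("kernel_index must be >= 0")


def clamp_pixels(image: np.ndarray, spec: PixelClampSpec = PixelClampSpec()) -> np.ndarray:
    """Clamp every value into [min_val, max_val]; shape and dtype-kind preserved.

    Idempotent: clamping twice equals clamping once.
    """
    arr = np.asarray(image)
    return np.clip(arr, spec.min_val, spec.max_val)


def enhance_contrast(
    image: np.ndarray,
    method: str = "stretch",
    *,
    p_low: float = 1.0,
    p_high: float = 99.0,
    clip_limit: float = 0.01,
) -> np.ndarray:
    """Increase the contrast of an 8-bit grayscale image.

    ``"stretch"`` (default) maps the [p_low, p_high] percentile window
    linearly onto [0, 255] — a monotone non-decreasing intensity map.
    ``"clahe"`` applies contrast-limited adaptive histogram
    equalization.  A constant image is returned unchanged (there is no
    contrast to stretch).
    """
    arr = np.asarray(image, dtype=np.float64)
    if method == "stretch":
        lo, hi = np.percentile(arr, [p_low, p_high])
        if hi <= lo:  # constant (or near-constant) image
            return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        out = (arr - lo) / (hi - lo) * 255.0
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    if method == "clahe":
        if arr.max() == arr.min():
            return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
        eq = exposure.equalize_adapthist(arr.astype(np.uint8), clip_limit=clip_limit)
        return np.clip(np.rint(eq * 255.0), 0, 255).astype(np.uint8)
    raise ValueError(f"unknown contrast method {method!r} (choose 'stretch' or 'clahe')")


def remap_labels(raw_label_image: np.ndarray, mapping: dict[int, int]) -> np.ndarray:
    """Remap raw annotation gray values onto class codes {0, 1, 2}.

    Raw masks come off annotation tools with arbitrary gray values
    (e.g. starchy painted 255, vitreous 128); this truncates them to the
    8-bit code scheme.  Every distinct value present must be covered by
    ``mapping`` and every target must be a legal class code.
    """
    arr = np.asarray(raw_label_image)
    present = np.unique(arr)
    unmapped = [int(v) for v in present if int(v) not in mapping]
    if unmapped:
        raise ValueError(f"unmapped label value(s) {unmapped} present in image")
    bad_targets = sorted({t for t in mapping.values() if t not in (0, 1, 2)})
    if bad_targets:
        raise ValueError(f"mapping targets {bad_targets} outside class codes {{0,1,2}}")
    out = np.zeros(arr.shape, dtype=np.uint8)
    for src in present:
        out[arr == src] = mapping[int(src)]
    return out


def _slice_foreground(sl: np.ndarray, canny_sigma: float) -> np.ndarray:
    """Canny edges → morphological closing → hole fill, one slice.

    Canny high threshold defaults to the slice's Otsu threshold with
    low = 0.5·high — parameter-free on bright-object/dark-background
    scans.
    """
    if sl.max() == sl.min():
        return np.zeros(sl.shape, dtype=bool)
    high = float(otsu_threshold(sl))
    low = 0.5 * high
    edges = feature.canny(sl.astype(np.float64), sigma=canny_sigma,
                          low_threshold=low, high_threshold=high)
    closed = ndimage.binary_closing(edges, structure=np.ones((5, 5)))
    return ndimage.binary_fill_holes(closed)


def split_batch_scan(
    volume: CTVolume,
    expected_kernels: int = 3,
    *,
    canny_sigma: float = 1.5,
    min_size_frac: float = 0.001,
    pad_frac: float = 0.05,
) -> list[KernelCrop]:
    """Split a batch scan of several kernels into per-kernel crops.

    Per-slice Canny edge maps are closed and filled, the filled
    foreground is labelled as 3D 26-connected components, components are
    ranked by voxel count, and the largest ``expected_kernels`` are each
    cut out with a tight bounding box padded by ``pad_frac`` of its
    longer side (clipped at volume edges).  Crops are ordered
    left-to-right by centroid x; equal-size ties break toward the
    smaller centroid x.
    """
    if expected_kernels < 1:
        raise ValueError("expected_kernels must be >= 1")
    data = volume.data
    fg = np.zeros(data.shape, dtype=bool)
    for z in range(data.shape[0]):
        fg[z] = _slice_foreground(data[z], canny_sigma)

    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n_comp = ndimage.label(fg, structure=structure)
    min_size = max(1, int(min_size_frac * data.size))
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n_comp + 1))
    keep = [(int(sz), i + 1) for i, sz in enumerate(sizes) if sz >= min_size]
    if len(keep) < expected_kernels:
        raise ValueError(
            f"expected {expected_kernels} kernels but found {len(keep)} "
            f"components above the minimum-size filter"
        )
    centroids = ndimage.center_of_mass(fg, labeled, index=[lab for _, lab in keep])
    ranked = sorted(
        zip(keep, centroids),
        key=lambda t: (-t[0][0], t[1][2]),  # by size desc, tie → smaller centroid x
    )[:expected_kernels]
    ranked.sort(key=lambda t: t[1][2])  # final order: left-to-right by centroid x

    crops = []
    for idx, ((_, lab), _c) in enumerate(ranked):
        zz, yy, xx = np.nonzero(labeled == lab)
        bounds = []
        for ax_idx, ax in enumerate((zz, yy, xx)):
            lo, hi = int(ax.min()), int(ax.max()) + 1
            bounds.append((lo, hi))
        longest = max(hi - lo for lo, hi in bounds)
        pad = int(round(pad_frac * longest))
        bbox = []
        for (lo, hi), extent in zip(bounds, data.shape):
            bbox.extend((max(0, lo - pad), min(extent, hi + pad)))
        z0, z1, y0, y1, x0, x1 = bbox
        crops.append(KernelCrop(
            image=data[z0:z1, y0:y1, x0:x1].copy(),
            bbox=(z0, z1, y0, y1, x0, x1),
            kernel_index=idx,
        ))
    return crops


def standardize_for_model(crop: KernelCrop | np.ndarray, side: int = 256) -> np.ndarray:
    """Resize + zero-pad a crop to ``side``×``side``, intensities in [0, 1].

    Each slice is resized aspect-preservingly so its longer side equals
    ``side``, then centred on a zero canvas.  A 2D array is treated as a
    single slice and returned as 2D.
    """
    image = crop.image if isinstance(crop, KernelCrop) else np.asarray(crop)
    squeeze = image.ndim == 2
    if squeeze:
        image = image[None]
    if image.size == 0:
        raise ValueError("empty crop")
    h, w = image.shape[1:]
    scale = side / max(h, w)
    nh, nw = max(1, int(round(h * scale))), max(1, int(round(w * scale)))
    out = np.zeros((image.shape[0], side, side), dtype=np.float32)
    y0 = (side - nh) // 2
    x0 = (side - nw) // 2
    for z in range(image.shape[0]):
        sl = image[z].astype(np.float64) / 255.0
        resized = transform.resize(sl, (nh, nw), order=1, anti_aliasing=scale < 1,
                                   preserve_range=True)
        out[z, y0:y0 + nh, x0:x0 + nw] = np.clip(resized, 0.0, 1.0)
    return out[0] if squeeze else out
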