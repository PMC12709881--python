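"""Readers and writers for the containers the pipeline touches.

Two in-memory containers carry everything: :class:`CTVolume` (a stack of
8-bit grayscale CT slices with its physical voxel edge length) and
:class:`LabelVolume` (an aligned integer mask with class codes
0 = background, 1 = starchy endosperm, 2 = vitreous endosperm).

Slice stacks on disk are directories of BMP/PNG files, one file per axial
slice, ordered by natural (numeric-aware) filename sort so that
``slice_2`` precedes ``slice_10``.  Label volumes travel as NIfTI-1
(``.nii`` / ``.nii.gz``) or as indexed-PNG stacks.

NIfTI orientation codes are deliberately ignored: arrays are taken in
stored order with z as the slowest axis.  Scanner exports in this
pipeline are never reoriented, and silently applying an affine would
desynchronise image and label stacks.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np

#: Physical edge length of a voxel in micrometres used when the caller
#: does not override it.  Overridable everywhere it is consumed.
DEFAULT_VOXEL_EDGE_UM = 27.0

VALID_LABELS = (0, 1, 2)

_SLICE_EXTENSIONS = (".png", ".bmp", ".PNG", ".BMP")


@dataclass
class CTVolume:
    """A 3D stack of grayscale CT slices.

    Parameters
    ----------
    data
        3D array of intensities on the 8-bit scale [0, 255], axes ordered
        (z, y, x) — slice, row, column.
    voxel_edge_um
        Physical edge length of one (cubic) voxel in micrometres.
    source_id
        Free-text provenance tag (directory name, variety code, ...).
    """

    data: np.ndarray
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"CTVolume data must be 3D with positive extents, got shape {self.data.shape}"
            )
        if self.voxel_edge_um <= 0:
            raise ValueError(f"voxel_edge_um must be > 0, got {self.voxel_edge_um}")
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities must lie in [0, 255], found range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class LabelVolume:
    """A 3D integer mask aligned to a :class:`CTVolume`.

    Class codes: 0 background (including pericarp), 1 starchy endosperm,
    2 vitreous endosperm.
    """

    data: np.ndarray
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError(
                f"LabelVolume data must be 3D with positive extents, got shape {self.data.shape}"
            )
        if self.voxel_edge_um <= 0:
            raise ValueError(f"voxel_edge_um must be > 0, got {self.voxel_edge_um}")
        _check_label_codes(self.data)
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.data.shape)  # type: ignore[return-value]

    def class_mask(self, code: int) -> np.ndarray:
        """Binary mask of one class code."""
        return self.data == code

    def class_counts(self) -> dict[int, int]:
        """Voxel count per class code present in the volume."""
        values, counts = np.unique(self.data, return_counts=True)
        return {int(v): int(c) for v, c in zip(values, counts)}


@dataclass
class PhenotypeRecord:
    """One kernel's internal-structure phenotypes.

    Volumes in μm³, bounding-box dimensions in μm, ratios dimensionless.
    ``V`` is the whole-seed volume (pericarp and germ included), ``VV``
    and ``SV`` the vitreous- and starchy-endosperm volumes, so
    ``VV/V + SV/V < 1`` in general.
    """

    kernel_id: str
    V: float
    VV: float
    SV: float
    VV_over_V: float
    SV_over_V: float
    length: float
    width: float
    thickness: float
    group: str = "other"

    #: column order of the CSV schema
    FIELDS = (
        "kernel_id", "V", "VV", "SV", "VV_over_V", "SV_over_V",
        "length", "width", "thickness", "group",
    )

    def __post_init__(self) -> None:
        if self.VV < 0 or self.SV < 0:
            raise ValueError("endosperm volumes must be non-negative")
        if self.V + 1e-9 < self.VV + self.SV:
            raise ValueError(
                f"seed volume V={self.V} smaller than VV+SV={self.VV + self.SV}: "
                "endosperm must be contained in the seed"
            )
        if not (self.length >= self.width >= self.thickness):
            raise ValueError("bounding-box dims must satisfy length >= width >= thickness")


def _check_label_codes(data: np.ndarray) -> None:
    bad = np.setdiff1d(np.unique(data), VALID_LABELS)
    if bad.size:
        raise ValueError(f"illegal class code {int(bad[0])} (allowed: 0, 1, 2)")


def natural_sort_key(name: str) -> tuple:
    """Sort key splitting digit runs so 'slice_2' < 'slice_10'."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def _list_slice_files(directory: Path) -> list[Path]:
    files = [p for p in directory.iterdir() if p.suffix in _SLICE_EXTENSIONS and p.is_file()]
    return sorted(files, key=lambda p: natural_sort_key(p.name))


def _to_gray(img: np.ndarray) -> np.ndarray:
    """Collapse a color slice to single-channel luminance (ITU-R 601)."""
    if img.ndim == 2:
        return img
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(np.float64)
        gray = rgb @ np.array([0.299, 0.587, 0.114])
        return np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported slice array shape {img.shape}")


def read_slice_stack(
    directory_path: str | Path,
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM,
) -> CTVolume:
    """Read a directory of BMP/PNG slices into a :class:`CTVolume`.

    Slices are stacked along z in natural filename order.  Color inputs
    are converted to luminance.

    Raises
    ------
    FileNotFoundError
        If the directory contains no slice files ("no slices found").
    ValueError
        If slice dimensions are inconsistent, naming the offending file.
    """
    directory = Path(directory_path)
    files = _list_slice_files(directory)
    if not files:
        raise FileNotFoundError(f"no slices found in {directory}")
    slices = []
    ref_shape: tuple[int, int] | None = None
    for f in files:
        img = _to_gray(np.asarray(iio.imread(f)))
        if ref_shape is None:
            ref_shape = img.shape
        elif img.shape != ref_shape:
            raise ValueError(
                f"inconsistent slice shape: {f.name} is {img.shape}, expected {ref_shape}"
            )
        slices.append(img)
    data = np.stack(slices, axis=0)
    return CTVolume(data=data, voxel_edge_um=voxel_edge_um, source_id=directory.name)


def write_slice_stack(volume: CTVolume, directory_path: str | Path, prefix: str = "slice") -> list[Path]:
    """Write a CTVolume as zero-padded 8-bit PNG slices; returns the paths."""
    directory = Path(directory_path)
    directory.mkdir(parents=True, exist_ok=True)
    width = max(4, len(str(volume.n_slices)))
    paths = []
    data = np.clip(np.rint(volume.data), 0, 255).astype(np.uint8)
    for z in range(volume.n_slices):
        p = directory / f"{prefix}_{z:0{width}d}.png"
        iio.imwrite(p, data[z])
        paths.append(p)
    return paths


def read_label_volume(
    path: str | Path,
    voxel_edge_um: float = DEFAULT_VOXEL_EDGE_UM,
) -> LabelVolume:
    """Read a label volume from NIfTI or an indexed-PNG stack directory.

    Any value outside {0, 1, 2} raises rather than being clamped: a bad
    code means the mask was produced by something other than this
    pipeline's conventions and must not be silently reinterpreted.
    """
    p = Path(path)
    if p.is_dir():
        files = _list_slice_files(p)
        if not files:
            raise FileNotFoundError(f"no slices found in {p}")
        data = np.stack([np.asarray(iio.imread(f)) for f in files], axis=0)
    else:
        if not p.exists():
            raise FileNotFoundError(f"label volume not found: {p}")
        img = nib.load(str(p))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D label volume, got shape {arr.shape} in {p}")
        # stored order, z slowest: NIfTI stores x fastest, so transpose
        data = np.ascontiguousarray(arr.T)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.rint(data)):
            raise ValueError(f"non-integer label values in {p}")
        data = np.rint(data).astype(np.int64)
    _check_label_codes(data)
    return LabelVolume(data=data.astype(np.uint8), voxel_edge_um=voxel_edge_um)


def write_label_volume(labels: LabelVolume, path: str | Path) -> Path:
    """Write a LabelVolume to NIfTI (``.nii``/``.nii.gz``) or a PNG stack directory."""
    p = Path(path)
    if p.suffix in (".nii", ".gz"):
        affine = np.diag([labels.voxel_edge_um / 1000.0] * 3 + [1.0])  # mm units
        # transpose back to NIfTI's x-fastest storage so read∘write is identity
        img = nib.Nifti1Image(labels.data.T.astype(np.uint8), affine)
        p.parent.mkdir(parents=True, exist_ok=True)
        nib.save(img, str(p))
    else:
        p.mkdir(parents=True, exist_ok=True)
        width = max(4, len(str(labels.data.shape[0])))
        for z in range(labels.data.shape[0]):
            iio.imwrite(p / f"label_{z:0{width}d}.png", labels.data[z])
    return p


def write_phenotype_table(records: Sequence[PhenotypeRecord], path: str | Path) -> Path:
    """Write phenotype records as CSV (header always present).

    Columns: kernel_id, V, VV, SV, VV_over_V, SV_over_V, length, width,
    thickness, group.  Volumes μm³, dimensions μm, ratios dimensionless.
    """
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PhenotypeRecord.FIELDS)
        for rec in records:
            writer.writerow([
                rec.kernel_id,
                *(format(getattr(rec, k), ".10g") for k in PhenotypeRecord.FIELDS[1:-1]),
                rec.group,
            ])
    return p


def read_phenotype_table(path: str | Path) -> list[PhenotypeRecord]:
    """Read back a phenotype CSV written by :func:`write_phenotype_table`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(PhenotypeRecord(
                kernel_id=row["kernel_id"],
                **{k: float(row[k]) for k in PhenotypeRecord.FIELDS[1:-1]},
                group=row["group"],
            ))
    return records
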