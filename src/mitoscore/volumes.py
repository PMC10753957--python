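"""Data model and I/O for 3D label and probability volumes.

Volumes are stored with axes ordered (z, y, x) — the thick, anisotropic
serial-section axis first — and carry a physical voxel spacing in nm in the
same order.  The serial-section EM convention of 8 x 8 x 30 nm voxels is the
default spacing (z, y, x) = (30, 8, 8) when a file carries no metadata.

Label volumes use 0 for background and positive integers for instance ids;
ids need not be consecutive.  Probability volumes are floats in [0, 1],
voxel-aligned with their companion label volume.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile
from scipy import ndimage

#: MitoEM-convention spacing in nm, (z, y, x).
DEFAULT_SPACING_NM = (30.0, 8.0, 8.0)

#: default HDF5 dataset name
DEFAULT_DATASET = "main"


@dataclass(frozen=True)
class LabelVolume:
    """3D integer instance-label grid with physical voxel spacing.

    Parameters
    ----------
    grid
        3D integer array, axes (z, y, x).  0 is background; positive
        integers are instance ids.
    spacing_nm
        Physical voxel edge lengths in nm, ordered (z, y, x).
    """

    grid: np.ndarray
    spacing_nm: tuple[float, float, float] = DEFAULT_SPACING_NM

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        if grid.ndim != 3:
            raise ValueError(f"label grid must be 3D, got shape {grid.shape}")
        if not np.issubdtype(grid.dtype, np.integer):
            raise TypeError(f"label grid must be integer-typed, got {grid.dtype}")
        if grid.size and grid.min() < 0:
            raise ValueError("label grid contains negative ids")
        spacing = tuple(float(s) for s in self.spacing_nm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing_nm}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing_nm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def ids(self) -> np.ndarray:
        """Sorted array of instance ids present (background excluded)."""
        u = np.unique(self.grid)
        return u[u != 0]

    def mask(self, instance_id: int) -> np.ndarray:
        """Boolean support of one instance."""
        return self.grid == instance_id


@dataclass(frozen=True)
class ProbVolume:
    """3D float probability grid in [0, 1], axes (z, y, x)."""

    grid: np.ndarray
    spacing_nm: tuple[float, float, float] = DEFAULT_SPACING_NM

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=np.float64)
        if grid.ndim != 3:
            raise ValueError(f"probability grid must be 3D, got shape {grid.shape}")
        if grid.size and (grid.min() < 0.0 or grid.max() > 1.0):
            raise ValueError("probability values must lie in [0, 1]")
        spacing = tuple(float(s) for s in self.spacing_nm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing_nm}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "spacing_nm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class InstanceIndex:
    """Per-instance voxel counts and bounding boxes for one label volume.

    Bounding boxes are half-open voxel intervals ((z0, z1), (y0, y1), (x0, x1))
    with 0-based indices, matching array-slicing semantics.
    """

    ids: list[int] = field(default_factory=list)
    sizes: dict[int, int] = field(default_factory=dict)
    bboxes: dict[int, tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = field(
        default_factory=dict
    )

    def __len__(self) -> int:
        return len(self.ids)


def build_index(vol: LabelVolume) -> InstanceIndex:
    """Count voxels and locate bounding boxes for every instance."""
    ids = vol.ids()
    index = InstanceIndex(ids=[int(i) for i in ids])
    if len(ids) == 0:
        return index
    counts = np.bincount(vol.grid.ravel())
    slices = ndimage.find_objects(vol.grid)
    for i in ids:
        index.sizes[int(i)] = int(counts[i])
        sl = slices[i - 1]
        index.bboxes[int(i)] = tuple((s.start, s.stop) for s in sl)
    return index


def relabel_consecutive(vol: LabelVolume) -> tuple[LabelVolume, dict[int, int]]:
    """Relabel instance ids to 1..K in first-occurrence scan order.

    Background stays 0; the voxel support of each instance is unchanged.
    Returns the relabeled volume and the old -> new id mapping.
    """
    flat = vol.grid.ravel()
    nz = flat != 0
    # first-occurrence order of the nonzero labels
    old_ids = flat[nz]
    _, first_idx = np.unique(old_ids, return_index=True)
    ordered = old_ids[np.sort(first_idx)]
    mapping = {int(old): new for new, old in enumerate(ordered, start=1)}
    if not mapping:
        return LabelVolume(vol.grid.copy(), vol.spacing_nm), {}
    lut = np.zeros(int(flat.max()) + 1, dtype=np.int64)
    for old, new in mapping.items():
        lut[old] = new
    return LabelVolume(lut[vol.grid], vol.spacing_nm), mapping


# ---------------------------------------------------------------------------
# I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _read_sidecar_spacing(path: Path) -> tuple[float, float, float] | None:
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "spacing_nm" in meta:
            return tuple(float(s) for s in meta["spacing_nm"])
    return None


def _as_volume(data: np.ndarray, spacing) -> LabelVolume | ProbVolume:
    if data.ndim != 3:
        raise ValueError(f"expected 3D data, got shape {data.shape}")
    if np.issubdtype(data.dtype, np.integer) or data.dtype == bool:
        return LabelVolume(data.astype(np.int64, copy=False), spacing)
    return ProbVolume(data, spacing)


def read_volume(
    path: str | Path,
    dataset: str | None = None,
    spacing_nm: tuple[float, float, float] | None = None,
) -> LabelVolume | ProbVolume:
    """Read a 3D volume from HDF5 (``.h5``/``.hdf5``) or multi-page TIFF.

    Integer data yields a :class:`LabelVolume`, float data a
    :class:`ProbVolume`.  Spacing is taken from, in order: the ``spacing_nm``
    argument, a file attribute / sidecar JSON (``{"spacing_nm": [z, y, x]}``),
    or the 30 x 8 x 8 nm serial-section default (with a warning).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    file_spacing: tuple[float, float, float] | None = None
    if suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "r") as f:
            keys = list(f.keys())
            name = dataset
            if name is None:
                if len(keys) == 1:
                    name = keys[0]
                elif DEFAULT_DATASET in keys:
                    name = DEFAULT_DATASET
                else:
                    raise ValueError(
                        f"{path} holds datasets {keys}; specify one explicitly"
                    )
            if name not in f:
                raise KeyError(f"dataset {name!r} not found in {path}")
            ds = f[name]
            data = ds[()]
            if "spacing_nm" in ds.attrs:
                file_spacing = tuple(float(s) for s in ds.attrs["spacing_nm"])
    elif suffix in {".tif", ".tiff"}:
        data = tifffile.imread(path)
        file_spacing = _read_sidecar_spacing(path)
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")

    spacing = spacing_nm or file_spacing or _read_sidecar_spacing(path)
    if spacing is None:
        warnings.warn(
            f"{path.name}: no spacing metadata; assuming {DEFAULT_SPACING_NM} nm (z, y, x)",
            stacklevel=2,
        )
        spacing = DEFAULT_SPACING_NM
    return _as_volume(np.asarray(data), spacing)


def write_volume(
    vol: LabelVolume | ProbVolume,
    path: str | Path,
    dataset: str = DEFAULT_DATASET,
) -> None:
    """Write a volume to HDF5 or TIFF; spacing is stored as metadata.

    Integer grids round-trip bit-exactly through :func:`read_volume`.
    """
    path = Path(path)
    if vol.grid.size == 0:
        raise ValueError("refusing to write an empty (0-voxel) volume")
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    suffix = path.suffix.lower()
    if isinstance(vol, LabelVolume):
        data = vol.grid.astype(np.int64, copy=False)
    else:
        data = vol.grid.astype(np.float32, copy=False)
    if suffix in {".h5", ".hdf5"}:
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=data, compression="gzip")
            ds.attrs["spacing_nm"] = np.asarray(vol.spacing_nm, dtype=np.float64)
    elif suffix in {".tif", ".tiff"}:
        tifffile.imwrite(path, data, photometric="minisblack")
        _sidecar_path(path).write_text(
            json.dumps({"spacing_nm": list(vol.spacing_nm)})
        )
    else:
        raise ValueError(f"unsupported volume format: {path.suffix}")
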