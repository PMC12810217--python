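"""Voxel-based muscle morphometry.

Muscles are represented as labelled sets of integer grid voxels on an
anisotropic MRI grid (default 1.17 x 1.17 x 5.0 mm; the k axis indexes
trans-axial slices), each voxel carrying a fat fraction (FF) in percent of
the total 1H signal.  The module computes muscle volume from the voxel
count, mean fat fraction, the peripheral-shell / centre partition (end
slices plus a two-voxel outer ring on the slices in between), composite
muscle-group aggregates, lean volume and a high-fat exclusion flag, and
reads/writes the tabular voxel-export format (one row per voxel: three
coordinates plus the fat-fraction value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import ndimage

DEFAULT_VOXEL_DIMS = (1.17, 1.17, 5.0)
#: In-plane shell ring thickness in voxels ("two voxels or 2.34 mm").
DEFAULT_SHELL_THICKNESS = 2
#: Muscles whose mean FF reaches this are excluded from group statistics.
DEFAULT_EXCLUSION_FF = 25.0


class MorphometryError(ValueError):
    """Invalid voxel map or operation on one."""


class VoxelTableParseError(MorphometryError):
    """Malformed voxel-table file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MuscleVoxelMap:
    """A muscle segmentation: voxel grid indices with per-voxel fat fraction.

    Parameters
    ----------
    ijk:
        Integer array of shape (n, 3); 0-based grid indices, k is the
        trans-axial slice axis.
    ff:
        Fat fraction per voxel, percent of total 1H signal, in [0, 100].
    voxel_dims:
        Voxel edge lengths (dx, dy, dz) in mm; dz is the slice thickness.
    """

    ijk: np.ndarray
    ff: np.ndarray
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    muscle_name: str = ""
    subject_id: str = ""
    group: str = ""
    extra: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ijk = np.asarray(self.ijk, dtype=np.int64).reshape(-1, 3)
        ff = np.asarray(self.ff, dtype=float).reshape(-1)
        object.__setattr__(self, "ijk", ijk)
        object.__setattr__(self, "ff", ff)
        if len(ijk) != len(ff):
            raise MorphometryError("ijk and ff lengths differ")
        if len(ijk) and (ijk < 0).any():
            raise MorphometryError("grid indices must be non-negative")
        if len(ijk):
            uniq = np.unique(ijk, axis=0)
            if len(uniq) != len(ijk):
                raise MorphometryError("duplicate voxel coordinates")
        if len(ff) and ((ff < 0) | (ff > 100)).any():
            raise MorphometryError("fat fraction outside [0, 100]")
        dims = tuple(float(d) for d in self.voxel_dims)
        if len(dims) != 3 or any(d <= 0 for d in dims):
            raise MorphometryError("voxel_dims must be three positive lengths")
        object.__setattr__(self, "voxel_dims", dims)

    def __len__(self) -> int:
        return len(self.ff)

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_dims
        return dx * dy * dz

    @property
    def n_slices(self) -> int:
        if not len(self):
            return 0
        k = self.ijk[:, 2]
        return int(len(np.unique(k)))


@dataclass(frozen=True)
class RegionPartition:
    """Disjoint shell/centre split of a voxel map (index arrays into the map)."""

    shell_idx: np.ndarray
    centre_idx: np.ndarray

    def __post_init__(self):
        shell = np.asarray(self.shell_idx, dtype=np.int64)
        centre = np.asarray(self.centre_idx, dtype=np.int64)
        object.__setattr__(self, "shell_idx", shell)
        object.__setattr__(self, "centre_idx", centre)
        if np.intersect1d(shell, centre).size:
            raise MorphometryError("shell and centre overlap")

    @property
    def n_shell(self) -> int:
        return len(self.shell_idx)

    @property
    def n_centre(self) -> int:
        return len(self.centre_idx)


@dataclass(frozen=True)
class MuscleSummary:
    """Per-muscle morphometry results (the Tables 2-4 style variables)."""

    muscle_name: str
    subject_id: str
    group: str
    volume_ml: float
    ff_mean_pct: float
    ff_shell_pct: float
    ff_centre_pct: float
    lean_volume_ml: float
    excluded: bool
    n_voxels: int = 0
    n_shell: int = 0
    n_centre: int = 0

    def __post_init__(self):
        if self.volume_ml < 0:
            raise MorphometryError("negative volume")
        if self.lean_volume_ml > self.volume_ml + 1e-9:
            raise MorphometryError("lean volume exceeds volume")


def muscle_volume(m: MuscleVoxelMap) -> float:
    """Muscle volume in ml: voxel count times voxel size (1 ml = 1000 mm^3)."""
    if not len(m):
        warnings.warn("empty voxel map: volume is 0 ml", stacklevel=2)
        return 0.0
    return len(m) * m.voxel_volume_mm3 / 1000.0


def mean_fat_fraction(m: MuscleVoxelMap, region: np.ndarray | None = None) -> float:
    """Unweighted mean FF (%) over the whole map or a voxel-index subset.

    All voxels have equal volume, so the unweighted mean over voxels is the
    volume-weighted tissue mean.
    """
    if region is None:
        vals = m.ff
    else:
        region = np.asarray(region)
        if region.dtype == bool:
            region = np.flatnonzero(region)
        if len(region) and (region.min() < 0 or region.max() >= len(m)):
            raise MorphometryError("region indices outside map")
        vals = m.ff[region]
    if not len(vals):
        raise MorphometryError("mean fat fraction of an empty region")
    return float(vals.mean())


def _slice_mask(ij: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense 2-D boolean mask of one slice plus the offset of its bbox."""
    lo = ij.min(axis=0)
    shape = ij.max(axis=0) - lo + 1
    mask = np.zeros(shape, dtype=bool)
    mask[ij[:, 0] - lo[0], ij[:, 1] - lo[1]] = True
    return mask, lo


def shell_centre_partition(
    m: MuscleVoxelMap,
    thickness: int = DEFAULT_SHELL_THICKNESS,
    connectivity: str = "chebyshev",
) -> RegionPartition:
    """Split a muscle into its peripheral shell and central region.

    The shell contains every voxel of the most proximal and most distal
    occupied slices, plus, on the slices in between, an outer ring of
    ``thickness`` voxels (default 2 voxels = 2.34 mm in-plane).  A voxel
    belongs to the ring when its in-plane distance to the nearest
    non-muscle grid cell is <= ``thickness``; ``connectivity`` selects the
    distance: "chebyshev" (8-connected, default) or "cityblock"
    (4-connected).  Background is any grid cell not in this muscle's own
    voxel set — neighbouring muscles do not shield the shell.
    """
    if not len(m):
        raise MorphometryError("cannot partition an empty map")
    if thickness < 1:
        raise MorphometryError("shell thickness must be >= 1 voxel")
    if connectivity == "chebyshev":
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == "cityblock":
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    else:
        raise MorphometryError(f"unknown connectivity {connectivity!r}")

    k = m.ijk[:, 2]
    kmin, kmax = int(k.min()), int(k.max())
    is_shell = (k == kmin) | (k == kmax)
    for ks in np.unique(k):
        if ks == kmin or ks == kmax:
            continue
        sel = np.flatnonzero(k == ks)
        ij = m.ijk[sel, :2]
        mask, lo = _slice_mask(ij)
        # erosion by `thickness` removes voxels within that distance of
        # background; border_value=0 treats everything off-grid as background
        interior = ndimage.binary_erosion(
            mask, structure=structure, iterations=thickness, border_value=0
        )
        ring = ~interior[ij[:, 0] - lo[0], ij[:, 1] - lo[1]]
        is_shell[sel[ring]] = True
    return RegionPartition(np.flatnonzero(is_shell), np.flatnonzero(~is_shell))


def lean_volume(volume_ml: float, ff_pct: float) -> float:
    """Lean volume: total volume times the water fraction (100 - FF)/100."""
    if not 0 <= ff_pct <= 100:
        raise MorphometryError("fat fraction outside [0, 100]")
    if volume_ml < 0:
        raise MorphometryError("negative volume")
    return volume_ml * (100.0 - ff_pct) / 100.0


def high_fat_exclusion(ff_mean_pct: float, threshold_pct: float = DEFAULT_EXCLUSION_FF) -> bool:
    """Flag a muscle for exclusion when its mean FF reaches the threshold.

    Muscles averaging 25-40% fat are outliers relative to the surrounding
    musculature and are dropped from group statistics; the boundary is
    inclusive (FF == threshold excludes).
    """
    return bool(ff_mean_pct >= threshold_pct)


def composite_muscles(maps: Sequence[MuscleVoxelMap], name: str = "composite") -> MuscleVoxelMap:
    """Sum several muscle matrices of one subject into a composite map.

    The composite is the union of the voxel sets; its volume is the sum of
    the member volumes and its mean FF the voxel-count-weighted mean of the
    member means (the matrices are summed first, the mean taken over the
    union).  Member segmentations must be disjoint and share grid geometry.
    """
    if not maps:
        raise MorphometryError("no maps to compose")
    first = maps[0]
    for m in maps[1:]:
        if m.voxel_dims != first.voxel_dims:
            raise MorphometryError("voxel_dims differ between member muscles")
        if m.subject_id != first.subject_id:
            raise MorphometryError("member muscles belong to different subjects")
    ijk = np.concatenate([m.ijk for m in maps])
    ff = np.concatenate([m.ff for m in maps])
    if len(np.unique(ijk, axis=0)) != len(ijk):
        raise MorphometryError("member muscles overlap; segmentations must be disjoint")
    return MuscleVoxelMap(
        ijk=ijk,
        ff=ff,
        voxel_dims=first.voxel_dims,
        muscle_name=name,
        subject_id=first.subject_id,
        group=first.group,
    )


def summarize(
    m: MuscleVoxelMap,
    shell_thickness: int = DEFAULT_SHELL_THICKNESS,
    exclusion_ff: float = DEFAULT_EXCLUSION_FF,
    connectivity: str = "chebyshev",
) -> MuscleSummary:
    """Compute all per-muscle morphometry variables in one pass."""
    vol = muscle_volume(m)
    part = shell_centre_partition(m, thickness=shell_thickness, connectivity=connectivity)
    ff_mean = mean_fat_fraction(m)
    ff_shell = mean_fat_fraction(m, part.shell_idx)
    # a map can be all shell (e.g. single slice); report NaN centre then
    ff_centre = (
        mean_fat_fraction(m, part.centre_idx) if part.n_centre else float("nan")
    )
    return MuscleSummary(
        muscle_name=m.muscle_name,
        subject_id=m.subject_id,
        group=m.group,
        volume_ml=vol,
        ff_mean_pct=ff_mean,
        ff_shell_pct=ff_shell,
        ff_centre_pct=ff_centre,
        lean_volume_ml=lean_volume(vol, ff_mean),
        excluded=high_fat_exclusion(ff_mean, exclusion_ff),
        n_voxels=len(m),
        n_shell=part.n_shell,
        n_centre=part.n_centre,
    )


# ---------------------------------------------------------------------------
# Voxel-table I/O
#
# TSV dialect: optional metadata lines '# key: value' (a YAML mapping once
# the '# ' prefixes are stripped), then a header 'i<TAB>j<TAB>k<TAB>ff',
# then one row per voxel.  FF is written in percent with 0.1 precision.
# Raw grey-value exports (0-1000, FF% = value/10) are read with
# grey_values=True.
# ---------------------------------------------------------------------------

_HEADER = "i\tj\tk\tff"


def write_voxel_table(m: MuscleVoxelMap, path: str | Path) -> None:
    """Write a voxel map as the tabular TSV export (FF at 0.1% precision)."""
    path = Path(path)
    meta = {
        "voxel_dims_mm": list(m.voxel_dims),
        "muscle": m.muscle_name,
        "subject_id": m.subject_id,
        "group": m.group,
    }
    lines = [f"# {k}: {v}" for k, v in meta.items()]
    lines.append(_HEADER)
    for (i, j, k), f in zip(m.ijk, m.ff):
        lines.append(f"{i}\t{j}\t{k}\t{f:.1f}")
    path.write_text("\n".join(lines) + "\n")


def read_voxel_table(path: str | Path, grey_values: bool = False) -> MuscleVoxelMap:
    """Read a voxel-table TSV into a :class:`MuscleVoxelMap`.

    With ``grey_values=True`` the ff column is an integer grey value in
    [0, 1000] and is converted to percent by dividing by 10.
    """
    path = Path(path)
    meta: dict = {}
    meta_lines: list[str] = []
    ijk: list[tuple[int, int, int]] = []
    ff: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                meta_lines.append(line.lstrip("#").strip())
                continue
            if not header_seen:
                if line.strip() != _HEADER.replace("\t", "\t"):
                    cols = line.split("\t")
                    if [c.strip() for c in cols] != ["i", "j", "k", "ff"]:
                        raise VoxelTableParseError(
                            f"expected header {_HEADER!r}, got {line!r}", lineno
                        )
                header_seen = True
                continue
            cols = line.split("\t")
            if len(cols) != 4:
                raise VoxelTableParseError(f"expected 4 columns, got {len(cols)}", lineno)
            try:
                i, j, k = (int(c) for c in cols[:3])
            except ValueError as exc:
                raise VoxelTableParseError(f"bad grid index: {exc}", lineno) from None
            try:
                val = float(cols[3])
            except ValueError:
                raise VoxelTableParseError(f"bad ff value {cols[3]!r}", lineno) from None
            if grey_values:
                if not val.is_integer() or not 0 <= val <= 1000:
                    raise VoxelTableParseError(
                        f"grey value {cols[3]} outside integer range 0-1000", lineno
                    )
                val /= 10.0
            elif not 0 <= val <= 100:
                raise VoxelTableParseError(f"ff {val} outside [0, 100]", lineno)
            ijk.append((i, j, k))
            ff.append(val)
    if meta_lines:
        try:
            parsed = yaml.safe_load("\n".join(meta_lines))
            if isinstance(parsed, dict):
                meta = parsed
        except yaml.YAMLError:
            meta = {}
    dims = meta.get("voxel_dims_mm", list(DEFAULT_VOXEL_DIMS))
    try:
        return MuscleVoxelMap(
            ijk=np.asarray(ijk, dtype=np.int64).reshape(-1, 3),
            ff=np.asarray(ff, dtype=float),
            voxel_dims=tuple(dims),
            muscle_name=str(meta.get("muscle", "")),
            subject_id=str(meta.get("subject_id", "")),
            group=str(meta.get("group", "")),
        )
    except MorphometryError as exc:
        raise VoxelTableParseError(str(exc)) from exc


def maps_from_nifti(
    ff_path: str | Path,
    label_path: str | Path,
    label_names: dict[int, str] | None = None,
    subject_id: str = "",
    grey_values: bool = False,
) -> list[MuscleVoxelMap]:
    """Import muscle maps from a dense fat-fraction volume plus label volume.

    ``ff_path`` is a NIfTI image whose intensities are FF in percent (or raw
    0-1000 grey values with ``grey_values=True``); ``label_path`` is a paired
    integer volume with one label per muscle (0 = background).  Voxel
    dimensions are taken from the image header.
    """
    import nibabel as nib

    ff_img = nib.load(str(ff_path))
    lab_img = nib.load(str(label_path))
    ff_data = np.asanyarray(ff_img.dataobj, dtype=float)
    labels = np.asanyarray(lab_img.dataobj).astype(np.int64)
    if ff_data.shape != labels.shape:
        raise MorphometryError("fat-fraction and label volumes have different shapes")
    dims = tuple(float(z) for z in ff_img.header.get_zooms()[:3])
    if grey_values:
        ff_data = ff_data / 10.0
    maps = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        idx = np.argwhere(labels == lab)
        name = (label_names or {}).get(int(lab), f"label_{int(lab)}")
        maps.append(
            MuscleVoxelMap(
                ijk=idx,
                ff=ff_data[labels == lab],
                voxel_dims=dims,
                muscle_name=name,
                subject_id=subject_id,
            )
        )
    return maps
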