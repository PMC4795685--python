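"""Binary voxel masks on a regular grid and the set primitives built on them.

A delineated structure (a clinical target volume drawn slice by slice on CT)
is represented as a 3-D boolean occupancy lattice plus voxel geometry: the
per-axis voxel edge length in mm and the physical coordinate of the center of
voxel (0, 0, 0).  All comparisons in this package are voxelwise, so every
mask taking part in a comparison must live on an identical grid; there is no
resampling.  Volume is voxel count times voxel volume — no partial-volume
weighting — which makes every overlap index an exact integer-arithmetic
computation.

Array axis convention: ``occupancy[x, y, z]``, 0-based indices, ``z`` the
craniocaudal (slice) axis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: spacing components closer than this (mm) are considered the same grid
SPACING_ATOL_MM = 1e-6

MM3_PER_CC = 1000.0


class GridMismatchError(ValueError):
    """Two masks do not share dimensions/spacing/origin and cannot be compared."""


@dataclass(frozen=True)
class VoxelMask:
    """A binary occupancy volume on a regular grid.

    Parameters
    ----------
    occupancy
        3-D boolean array; ``occupancy[x, y, z]`` is True where the structure
        is present.
    spacing
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all > 0.
    origin
        Physical coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    label
        Free-text structure name, e.g. ``"CTV"``.
    """

    occupancy: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.ndim != 3 or min(occ.shape) < 1:
            raise ValueError(f"occupancy must be 3-D with all dims >= 1, got shape {occ.shape}")
        if occ.dtype != np.bool_:
            occ = occ > 0.5
        object.__setattr__(self, "occupancy", occ)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be three positive lengths in mm, got {self.spacing}")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.occupancy.shape  # type: ignore[return-value]

    @property
    def grid_key(self) -> tuple:
        """Hashable signature of the grid: (shape, spacing, origin).

        Spacing and origin are rounded to the grid-equality tolerance so that
        numerically equal grids compare equal.
        """
        q = round(-np.log10(SPACING_ATOL_MM))
        return (
            self.shape,
            tuple(round(s, q) for s in self.spacing),
            tuple(round(o, q) for o in self.origin),
        )

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def voxel_count(self) -> int:
        """Number of occupied voxels."""
        return int(np.count_nonzero(self.occupancy))

    def physical_volume_mm3(self) -> float:
        return self.voxel_count() * self.voxel_volume_mm3

    def volume_cc(self) -> float:
        """Structure volume in cubic centimetres (the clinical reporting unit)."""
        return self.physical_volume_mm3() / MM3_PER_CC

    def is_empty(self) -> bool:
        return not bool(self.occupancy.any())

    def with_label(self, label: str) -> "VoxelMask":
        return replace(self, label=label)

    def same_grid(self, other: "VoxelMask") -> bool:
        return self.grid_key == other.grid_key

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VoxelMask):
            return NotImplemented
        return self.same_grid(other) and bool(np.array_equal(self.occupancy, other.occupancy))

    def __hash__(self) -> int:  # frozen dataclass with an array field
        return hash(self.grid_key)


def _require_same_grid(a: VoxelMask, b: VoxelMask, op: str) -> None:
    if not a.same_grid(b):
        raise GridMismatchError(
            f"{op}: masks are on different grids: {a.grid_key} vs {b.grid_key}; "
            "resampling is not supported — inputs must share a grid"
        )


def intersect(a: VoxelMask, b: VoxelMask) -> VoxelMask:
    """Voxels occupied in both masks (Cn ∩ CR)."""
    _require_same_grid(a, b, "intersect")
    return replace(a, occupancy=a.occupancy & b.occupancy, label=f"({a.label}&{b.label})")


def union(a: VoxelMask, b: VoxelMask) -> VoxelMask:
    """Voxels occupied in either mask (Cn ∪ CR)."""
    _require_same_grid(a, b, "union")
    return replace(a, occupancy=a.occupancy | b.occupancy, label=f"({a.label}|{b.label})")


def difference(a: VoxelMask, b: VoxelMask) -> VoxelMask:
    """Voxels occupied in ``a`` but not in ``b`` (Cn − CR)."""
    _require_same_grid(a, b, "difference")
    return replace(a, occupancy=a.occupancy & ~b.occupancy, label=f"({a.label}-{b.label})")


def shift(mask: VoxelMask, offset: Sequence[int]) -> VoxelMask:
    """Translate the occupancy by an integer voxel offset.

    Voxels pushed outside the lattice are dropped with a logged warning;
    spacing and origin are unchanged.
    """
    off = tuple(int(o) for o in offset)
    if len(off) != 3:
        raise ValueError(f"offset must be an integer triple, got {offset!r}")
    before = mask.voxel_count()
    out = np.zeros_like(mask.occupancy)
    src = []
    dst = []
    for n, o in zip(mask.shape, off):
        src.append(slice(max(0, -o), min(n, n - o)))
        dst.append(slice(max(0, o), min(n, n + o)))
    if all(s.stop > s.start for s in src):
        out[tuple(dst)] = mask.occupancy[tuple(src)]
    shifted = replace(mask, occupancy=out)
    clipped = before - shifted.voxel_count()
    if clipped:
        logger.warning("shift by %s clipped %d voxel(s) off the lattice", off, clipped)
    return shifted


# -- I/O ---------------------------------------------------------------------

def read_mask(path: str | Path, label: str = "") -> VoxelMask:
    """Read a binary mask from NIfTI (.nii/.nii.gz), NRRD (.nrrd) or voxel CSV.

    Volumetric values > 0.5 are treated as occupied.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        return _read_nifti(path, label)
    if suffixes.endswith(".nrrd"):
        return _read_nrrd(path, label)
    if suffixes.endswith(".csv"):
        return read_voxel_csv(path, label=label)
    raise ValueError(f"unrecognized mask format: {path}")


def write_mask(mask: VoxelMask, path: str | Path) -> None:
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        _write_nifti(mask, path)
    elif suffixes.endswith(".nrrd"):
        _write_nrrd(mask, path)
    elif suffixes.endswith(".csv"):
        write_voxel_csv(mask, path)
    else:
        raise ValueError(f"unrecognized mask format: {path}")


def _read_nifti(path: Path, label: str) -> VoxelMask:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    return VoxelMask(data > 0.5, spacing=tuple(float(z) for z in zooms), origin=origin,
                     label=label or path.stem)


def _write_nifti(mask: VoxelMask, path: Path) -> None:
    import nibabel as nib

    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


def _read_nrrd(path: Path, label: str) -> VoxelMask:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)  # (z, y, x)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return VoxelMask(
        np.transpose(data, (2, 1, 0)) > 0.5,
        spacing=tuple(float(s) for s in img.GetSpacing()),
        origin=tuple(float(o) for o in img.GetOrigin()),
        label=label or path.stem,
    )


def _write_nrrd(mask: VoxelMask, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.transpose(mask.occupancy.astype(np.uint8), (2, 1, 0)))
    img.SetSpacing(mask.spacing)
    img.SetOrigin(mask.origin)
    sitk.WriteImage(img, str(path))


def read_voxel_csv(
    path: str | Path,
    shape: Optional[tuple[int, int, int]] = None,
    spacing: Optional[tuple[float, float, float]] = None,
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
    label: str = "",
) -> VoxelMask:
    """Read the plain-text voxel dialect: ``x,y,z`` header then occupied-index triples.

    Optional ``# shape=..`` / ``# spacing=..`` / ``# origin=..`` comment lines
    before the header pin the grid; otherwise shape is inferred as max index + 1
    and spacing defaults to 1 mm isotropic.  Explicit arguments override both.
    """
    path = Path(path)
    meta: dict[str, tuple[float, ...]] = {}
    rows: list[tuple[int, int, int]] = []
    header_seen = False
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(shape|spacing|origin)\s*=\s*(.+)", line)
            if m:
                meta[m.group(1)] = tuple(float(v) for v in m.group(2).split(","))
            continue
        if not header_seen:
            if [c.strip().lower() for c in line.split(",")] != ["x", "y", "z"]:
                raise ValueError(f"{path}:{ln}: expected header 'x,y,z', got {line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise ValueError(f"{path}:{ln}: expected three comma-separated indices")
        rows.append(tuple(int(p) for p in parts))  # type: ignore[arg-type]
    if not header_seen:
        raise ValueError(f"{path}: missing 'x,y,z' header line")
    if shape is None:
        if "shape" in meta:
            shape = tuple(int(v) for v in meta["shape"])  # type: ignore[assignment]
        elif rows:
            shape = tuple(int(max(r[i] for r in rows)) + 1 for i in range(3))  # type: ignore[assignment]
        else:
            raise ValueError(f"{path}: empty mask with no '# shape=' line — grid unknown")
    if spacing is None:
        spacing = tuple(meta.get("spacing", (1.0, 1.0, 1.0)))  # type: ignore[assignment]
    if "origin" in meta:
        origin = tuple(meta["origin"])  # type: ignore[assignment]
    occ = np.zeros(shape, dtype=bool)
    for r in rows:
        occ[r] = True
    return VoxelMask(occ, spacing=spacing, origin=origin, label=label or path.stem)


def write_voxel_csv(mask: VoxelMask, path: str | Path) -> None:
    path = Path(path)
    lines = [
        "# shape=%d,%d,%d" % mask.shape,
        "# spacing=%g,%g,%g" % mask.spacing,
        "# origin=%g,%g,%g" % mask.origin,
        "x,y,z",
    ]
    xs, ys, zs = np.nonzero(mask.occupancy)
    lines.extend(f"{x},{y},{z}" for x, y, z in zip(xs, ys, zs))
    path.write_text("\n".join(lines) + "\n")


# -- observer collections ----------------------------------------------------

MaskKey = tuple[str, str, str]  # (observer_id, case_id, round_id)


@dataclass
class ObserverSet:
    """Masks keyed by (observer_id, case_id, round_id), all on one grid.

    One observer may optionally be designated the reference; in that role it
    must own a mask for every (case, round) being compared.
    """

    masks: dict[MaskKey, VoxelMask] = field(default_factory=dict)
    reference_observer: Optional[str] = None

    def __post_init__(self) -> None:
        for key, mask in self.masks.items():
            self._check_grid(key, mask)

    @property
    def grid_key(self) -> Optional[tuple]:
        for mask in self.masks.values():
            return mask.grid_key
        return None

    def _check_grid(self, key: MaskKey, mask: VoxelMask) -> None:
        gk = self.grid_key
        if gk is not None and mask.grid_key != gk:
            raise GridMismatchError(
                f"mask {key} is on grid {mask.grid_key}, set is on {gk}"
            )

    def add(self, observer_id: str, case_id: str, round_id: str, mask: VoxelMask) -> None:
        key = (str(observer_id), str(case_id), str(round_id))
        if key in self.masks:
            raise ValueError(f"duplicate mask key {key}")
        self._check_grid(key, mask)
        self.masks[key] = mask

    def get(self, observer_id: str, case_id: str, round_id: str) -> VoxelMask:
        return self.masks[(str(observer_id), str(case_id), str(round_id))]

    def observers(self, case_id: Optional[str] = None, round_id: Optional[str] = None) -> list[str]:
        seen: dict[str, None] = {}
        for (o, c, r) in self.masks:
            if (case_id is None or c == str(case_id)) and (round_id is None or r == str(round_id)):
                seen.setdefault(o)
        return list(seen)

    def cases(self) -> list[str]:
        seen: dict[str, None] = {}
        for (_, c, _) in self.masks:
            seen.setdefault(c)
        return list(seen)

    def rounds(self, case_id: Optional[str] = None) -> list[str]:
        seen: dict[str, None] = {}
        for (_, c, r) in self.masks:
            if case_id is None or c == str(case_id):
                seen.setdefault(r)
        return list(seen)

    def select(self, case_id: str, round_id: str,
               exclude: Sequence[str] = ()) -> dict[str, VoxelMask]:
        """Observer → mask mapping for one (case, round), in insertion order."""
        out: dict[str, VoxelMask] = {}
        for (o, c, r), mask in self.masks.items():
            if c == str(case_id) and r == str(round_id) and o not in exclude:
                out[o] = mask
        return out

    def __len__(self) -> int:
        return len(self.masks)

    def __iter__(self) -> Iterator[tuple[MaskKey, VoxelMask]]:
        return iter(self.masks.items())

    def validate_reference(self) -> None:
        if self.reference_observer is None:
            raise ValueError("no reference observer designated")
        ref = self.reference_observer
        for (_, c, r) in list(self.masks):
            if (ref, c, r) not in self.masks:
                raise ValueError(
                    f"reference observer {ref!r} has no mask for case {c!r}, round {r!r}"
                )

    @classmethod
    def from_manifest(cls, manifest_path: str | Path) -> "ObserverSet":
        """Load a set from a manifest CSV.

        Columns: ``observer_id,case_id,round_id,path,role`` with role in
        {observer, reference}; paths are resolved relative to the manifest.
        """
        import pandas as pd

        manifest_path = Path(manifest_path)
        df = pd.read_csv(manifest_path, dtype=str)
        required = {"observer_id", "case_id", "round_id", "path", "role"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"{manifest_path}: manifest missing columns {sorted(missing)}")
        obs_set = cls()
        for row in df.itertuples(index=False):
            role = str(row.role).strip().lower()
            if role not in {"observer", "reference"}:
                raise ValueError(f"{manifest_path}: unknown role {row.role!r}")
            mask_path = Path(str(row.path))
            if not mask_path.is_absolute():
                mask_path = manifest_path.parent / mask_path
            mask = read_mask(mask_path)
            obs_set.add(str(row.observer_id), str(row.case_id), str(row.round_id), mask)
            if role == "reference":
                if obs_set.reference_observer not in (None, str(row.observer_id)):
                    raise ValueError(
                        f"{manifest_path}: conflicting reference observers "
                        f"{obs_set.reference_observer!r} and {row.observer_id!r}"
                    )
                obs_set.reference_observer = str(row.observer_id)
        return obs_set
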