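"""The five delineation-comparison indices for an ordered (test, reference) pair.

With Cn the contour under test, CR the reference contour, Vn and VR their
physical volumes:

====================  =================================  =============
index                 definition                         optimal value
====================  =================================  =============
volume ratio (VR)     Vn / VR                            1
common volume (CV)    100 · |Cn ∩ CR| / |CR|   [%]       100
additional vol. (AV)  100 · |Cn − CR| / |Cn|   [%]       0
volume overlap (VO)   |Cn ∩ CR| / |Cn ∪ CR|  (Jaccard)   1
Dice coeff. (DSC)     2 |Cn ∩ CR| / (|Cn| + |CR|)        1
====================  =================================  =============

CV is referenced to CR and AV to Cn, so those two are deliberately asymmetric
in the pair order; VO and DSC are symmetric.  The five share one intersection
and satisfy exact algebraic identities (DSC = 2·VO/(1+VO);
CV/100 = VR·(1−AV/100); DSC = 2·(CV/100)/(1+VR)) that the test suite asserts.

An index whose denominator is empty raises :class:`UndefinedIndexError` rather
than returning a sentinel — an empty clinical contour signals an upstream
data error.
"""

from __future__ import annotations

from dataclasses import dataclass

from .mask_core import VoxelMask, _require_same_grid

OPTIMAL_VALUES = {"vr": 1.0, "cv": 100.0, "av": 0.0, "vo": 1.0, "dsc": 1.0}
INDEX_NAMES = tuple(OPTIMAL_VALUES)

CSV_COLUMNS = (
    "test_id", "reference_id", "case_id", "round_id",
    "vr", "cv", "av", "vo", "dsc", "test_volume_cc", "reference_volume_cc",
)


class UndefinedIndexError(ValueError):
    """An index denominator is empty (empty test, reference, or union)."""


@dataclass(frozen=True)
class IndexSet:
    """All five indices for one ordered (test, reference) mask pair."""

    vr: float
    cv: float
    av: float
    vo: float
    dsc: float
    test_id: str = ""
    reference_id: str = ""
    case_id: str = ""
    round_id: str = ""
    test_volume_cc: float = float("nan")
    reference_volume_cc: float = float("nan")

    def value(self, index_name: str) -> float:
        if index_name not in INDEX_NAMES:
            raise KeyError(f"unknown index {index_name!r}; expected one of {INDEX_NAMES}")
        return getattr(self, index_name)

    def to_row(self, digits: int = 4) -> dict:
        row = {c: getattr(self, c) for c in CSV_COLUMNS}
        for k in ("vr", "cv", "av", "vo", "dsc", "test_volume_cc", "reference_volume_cc"):
            row[k] = round(float(row[k]), digits)
        return row


def _counts(test: VoxelMask, reference: VoxelMask) -> tuple[int, int, int]:
    _require_same_grid(test, reference, "index computation")
    n = test.voxel_count()
    r = reference.voxel_count()
    i = int((test.occupancy & reference.occupancy).sum())
    return n, r, i


def volume_ratio(test: VoxelMask, reference: VoxelMask) -> float:
    """Vn/VR by physical volume; optimal 1."""
    _require_same_grid(test, reference, "volume_ratio")
    if reference.is_empty():
        raise UndefinedIndexError(
            f"volume_ratio: reference contour {reference.label!r} is empty")
    return test.physical_volume_mm3() / reference.physical_volume_mm3()


def common_volume_pct(test: VoxelMask, reference: VoxelMask) -> float:
    """Percentage of the reference covered by the test contour; optimal 100."""
    n, r, i = _counts(test, reference)
    if r == 0:
        raise UndefinedIndexError(
            f"common_volume_pct: reference contour {reference.label!r} is empty")
    return 100.0 * i / r


def additional_volume_pct(test: VoxelMask, reference: VoxelMask) -> float:
    """Percentage of the test contour lying outside the reference; optimal 0."""
    n, r, i = _counts(test, reference)
    if n == 0:
        raise UndefinedIndexError(
            f"additional_volume_pct: test contour {test.label!r} is empty")
    return 100.0 * (n - i) / n


def volume_overlap(test: VoxelMask, reference: VoxelMask) -> float:
    """Jaccard index |Cn∩CR|/|Cn∪CR|; optimal 1."""
    n, r, i = _counts(test, reference)
    u = n + r - i
    if u == 0:
        raise UndefinedIndexError("volume_overlap: both contours are empty")
    return i / u


def dice(test: VoxelMask, reference: VoxelMask) -> float:
    """Dice similarity coefficient 2|Cn∩CR|/(|Cn|+|CR|); optimal 1."""
    n, r, i = _counts(test, reference)
    if n + r == 0:
        raise UndefinedIndexError("dice: both contours are empty")
    return 2.0 * i / (n + r)


def all_indices(
    test: VoxelMask,
    reference: VoxelMask,
    test_id: str = "",
    reference_id: str = "",
    case_id: str = "",
    round_id: str = "",
) -> IndexSet:
    """Compute all five indices from a single shared intersection count."""
    n, r, i = _counts(test, reference)
    if r == 0:
        raise UndefinedIndexError(
            f"vr/cv: reference contour {reference.label or reference_id!r} is empty")
    if n == 0:
        raise UndefinedIndexError(
            f"av: test contour {test.label or test_id!r} is empty")
    return IndexSet(
        vr=n / r,  # equal spacing on a shared grid: count ratio == volume ratio
        cv=100.0 * i / r,
        av=100.0 * (n - i) / n,
        vo=i / (n + r - i),
        dsc=2.0 * i / (n + r),
        test_id=test_id or test.label,
        reference_id=reference_id or reference.label,
        case_id=case_id,
        round_id=round_id,
        test_volume_cc=test.volume_cc(),
        reference_volume_cc=reference.volume_cc(),
    )
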