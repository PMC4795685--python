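"""Vote-threshold consensus ("common") contours from a multi-observer set.

Instead of electing one observer as the reference, a common contour is built
by voxelwise voting: a voxel belongs to the consensus when at least
``threshold_count`` observers delineated it.  The study design this mirrors
used 9 of 14 physicians; the default here generalizes that count to
``ceil(9/14 · N)`` observers, preserving the ≈64 % fraction, which yields
exactly 9 when N = 14.  Threshold 1 is the union of all contours, threshold N
their intersection, and the consensus volume is monotone non-increasing in
the threshold.

By default each observer's own contour participates in the consensus it is
compared against ("also comprising" semantics).  Because self-inclusion
inflates agreement, a leave-one-out option rebuilds the consensus without the
observer being scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .indices import IndexSet, all_indices
from .mask_core import ObserverSet, VoxelMask

#: fraction of observers that must vote for a voxel, absent an explicit count
DEFAULT_VOTE_FRACTION = 9 / 14


class InsufficientObserversError(ValueError):
    """Fewer than two observer contours are available for the (case, round)."""


class InvalidConsensusSpecError(ValueError):
    """threshold_count is outside 1..number of contributing observers."""


class UndefinedConsensusError(ValueError):
    """No voxel reaches the vote threshold."""


@dataclass(frozen=True)
class ConsensusSpec:
    """Rule producing a common contour for one (case, round).

    ``threshold_count=None`` resolves to ``ceil(9/14 · N)`` for N contributing
    observers.
    """

    case_id: str
    round_id: str
    threshold_count: Optional[int] = None
    leave_one_out: bool = False

    def resolve_threshold(self, n_observers: int) -> int:
        if self.threshold_count is None:
            t = math.ceil(DEFAULT_VOTE_FRACTION * n_observers)
        else:
            t = int(self.threshold_count)
        if not 1 <= t <= n_observers:
            raise InvalidConsensusSpecError(
                f"threshold_count {t} outside 1..{n_observers} contributing observers"
            )
        return t


def vote_map(obs_set: ObserverSet, case_id: str, round_id: str,
             exclude: tuple[str, ...] = ()) -> np.ndarray:
    """Per-voxel count of observers whose contour covers that voxel."""
    masks = obs_set.select(case_id, round_id, exclude=exclude)
    if len(masks) < 2:
        raise InsufficientObserversError(
            f"need >= 2 observer contours for case {case_id!r} round {round_id!r}, "
            f"found {len(masks)}"
        )
    votes = np.zeros(next(iter(masks.values())).shape, dtype=np.int32)
    for mask in masks.values():
        votes += mask.occupancy
    return votes


def common_contour(obs_set: ObserverSet, spec: ConsensusSpec,
                   exclude: tuple[str, ...] = ()) -> VoxelMask:
    """Mask of voxels delineated by at least ``threshold_count`` observers."""
    masks = obs_set.select(spec.case_id, spec.round_id, exclude=exclude)
    votes = vote_map(obs_set, spec.case_id, spec.round_id, exclude=exclude)
    threshold = spec.resolve_threshold(len(masks))
    template = next(iter(masks.values()))
    return replace(
        template,
        occupancy=votes >= threshold,
        label=f"consensus>={threshold}/{len(masks)}",
    )


def compare_to_consensus(obs_set: ObserverSet, spec: ConsensusSpec) -> list[IndexSet]:
    """Score every observer contour of (case, round) against the common contour.

    With ``leave_one_out`` the consensus is rebuilt for each observer with that
    observer's vote removed (same threshold count).
    """
    masks = obs_set.select(spec.case_id, spec.round_id)
    if len(masks) < 2:
        raise InsufficientObserversError(
            f"need >= 2 observer contours for case {spec.case_id!r} "
            f"round {spec.round_id!r}, found {len(masks)}"
        )
    # pin the vote count on the full set so leave-one-out keeps the same rule
    spec = replace(spec, threshold_count=spec.resolve_threshold(len(masks)))
    if not spec.leave_one_out:
        consensus = common_contour(obs_set, spec)
        if consensus.is_empty():
            raise UndefinedConsensusError(
                f"consensus for case {spec.case_id!r} round {spec.round_id!r} is empty "
                f"at threshold {spec.resolve_threshold(len(masks))}; lower the threshold"
            )
    results = []
    for observer_id, mask in masks.items():
        if spec.leave_one_out:
            ref = common_contour(obs_set, spec, exclude=(observer_id,))
            if ref.is_empty():
                raise UndefinedConsensusError(
                    f"leave-one-out consensus excluding {observer_id!r} is empty; "
                    "lower the threshold"
                )
        else:
            ref = consensus
        results.append(
            all_indices(mask, ref, test_id=observer_id, reference_id=ref.label,
                        case_id=spec.case_id, round_id=spec.round_id)
        )
    return results
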