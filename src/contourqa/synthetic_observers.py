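"""Synthetic ground truth and multi-observer, multi-round contour simulation.

The clinical delineations behind the study this package operationalizes were
never deposited, so the pipeline ships a simulator that emulates their
statistical structure: one organ-like ground-truth structure per case, N
observers (default 14) each drawing one contour per case per round, and a
second round with reduced disagreement to reproduce the harmonization effect
of guideline agreement.

Noise model
-----------
Observer contours are produced by radially displacing the truth boundary in
cylindrical coordinates, slice by slice:

    r_obs(θ, z) = r_truth(θ, z) + bias_o + ε(θ, z)

* ``bias_o ~ Normal(0, sigma_sys_mm)`` is an observer-specific systematic
  over/under-contouring tendency, drawn once per (observer, case); round 2
  carries the same bias scaled by ``round2_scale``.
* ``ε`` is a zero-mean Gaussian random field with SD ``sigma_rand_mm``,
  smoothed over angle (Gaussian kernel, SD 30°) and lightly across slices,
  giving smooth contour disagreement rather than voxel salt-and-pepper.
* Craniocaudal extent disagreement — the classic apex/base problem — is a
  separate channel: each end of the structure is extended or trimmed by
  ``round(Normal(0, extent_sigma_slices))`` slices.

``round2_scale < 1`` shrinks all three SDs in round 2, emulating
post-guideline harmonization; ``round2_scale = 1`` is the null of no change.

Case presets mirror the three clinical scenarios of the study design:
``lowrisk`` (compact ellipsoid, low noise — baseline Dice ≈ 0.83), ``nodal``
(elongated curved nodal-chain structure, high noise — baseline Dice ≈ 0.58)
and ``postop`` (small post-operative bed, extent noise dominant).  Noise
magnitudes are a calibration choice pinned to those baseline Dice levels, not
measured clinical quantities.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np

from .mask_core import ObserverSet, VoxelMask, write_mask

ROUND_1 = "1"
ROUND_2 = "2"


@dataclass(frozen=True)
class TruthSpec:
    """Analytic ground-truth shape: an ellipsoid or a curved elliptical chain.

    ``family="ellipsoid"``: semi-axes (a, b, c) mm about the grid center.
    ``family="chain"``: constant elliptical cross-section (a, b) mm extruded
    over ±c mm with an in-plane sinusoidal center drift of ``drift_amp_mm`` —
    a stand-in for an elongated nodal-chain target.
    """

    family: str = "ellipsoid"
    semi_axes_mm: tuple[float, float, float] = (25.0, 22.0, 24.0)
    drift_amp_mm: float = 0.0

    def __post_init__(self) -> None:
        if self.family not in ("ellipsoid", "chain"):
            raise ValueError(f"unknown truth family {self.family!r}")
        if min(self.semi_axes_mm) <= 0:
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes_mm}")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition knobs for one simulated case."""

    n_observers: int = 14
    grid_shape: tuple[int, int, int] = (56, 56, 40)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.5)
    truth: TruthSpec = field(default_factory=TruthSpec)
    sigma_sys_mm: float = 2.4          #: SD of per-observer systematic radial bias
    sigma_rand_mm: float = 2.4         #: SD of the random radial boundary noise
    extent_sigma_slices: float = 0.7   #: SD of apex/base over/under-extension
    round2_scale: float = 1.0          #: multiplier on all three SDs in round 2
    seed: int = 0
    angle_bins: int = 72
    angle_smooth_deg: float = 30.0
    z_smooth_slices: float = 1.0

    def __post_init__(self) -> None:
        if self.n_observers < 2:
            raise ValueError("n_observers must be >= 2")
        if min(self.sigma_sys_mm, self.sigma_rand_mm, self.extent_sigma_slices) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0 < self.round2_scale <= 1:
            raise ValueError("round2_scale must be in (0, 1]")

    def round_scale(self, round_id: str) -> float:
        return self.round2_scale if str(round_id) == ROUND_2 else 1.0


#: per-case presets; noise SDs calibrated to the baseline Dice ranges above
PRESETS: dict[str, dict] = {
    "lowrisk": dict(
        truth=TruthSpec("ellipsoid", (25.0, 22.0, 24.0)),
        sigma_sys_mm=2.4, sigma_rand_mm=2.4, extent_sigma_slices=0.7,
    ),
    "nodal": dict(
        truth=TruthSpec("chain", (16.0, 13.0, 34.0), drift_amp_mm=12.0),
        sigma_sys_mm=4.0, sigma_rand_mm=4.0, extent_sigma_slices=1.0,
    ),
    "postop": dict(
        truth=TruthSpec("ellipsoid", (17.0, 15.0, 16.0)),
        sigma_sys_mm=3.0, sigma_rand_mm=3.0, extent_sigma_slices=1.8,
    ),
}

#: default three-case study: case id -> preset name
DEFAULT_STUDY_CASES: dict[str, str] = {"1": "lowrisk", "2": "nodal", "3": "postop"}


def preset_config(name: str, **overrides) -> SimConfig:
    """A SimConfig for one of the named case presets."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return SimConfig(**{**PRESETS[name], **overrides})


def _substream(seed: int, *labels: str) -> np.random.Generator:
    """Deterministic child generator keyed by stable string hashing."""
    key = tuple(zlib.crc32(lab.encode()) for lab in labels)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# -- truth geometry ----------------------------------------------------------

def _slice_params(config: SimConfig) -> dict[int, tuple[float, float, float, float]]:
    """Per-slice analytic cross-section: z -> (cx, cy, ax, ay) in mm."""
    nx, ny, nz = config.grid_shape
    dx, dy, dz = config.spacing_mm
    cx0, cy0, cz0 = (nx - 1) * dx / 2, (ny - 1) * dy / 2, (nz - 1) * dz / 2
    a, b, c = config.truth.semi_axes_mm
    out = {}
    for iz in range(nz):
        z = iz * dz - cz0
        if abs(z) > c:
            continue
        if config.truth.family == "ellipsoid":
            s = np.sqrt(max(0.0, 1.0 - (z / c) ** 2))
            ax, ay = a * s, b * s
            cx, cy = cx0, cy0
        else:  # chain: constant cross-section, drifting center
            ax, ay = a, b
            cx = cx0 + config.truth.drift_amp_mm * np.sin(np.pi * (z + c) / (2 * c))
            cy = cy0
        if ax < min(dx, dy) / 4:  # vanishing polar cap: no voxels
            continue
        out[iz] = (cx, cy, ax, ay)
    return out


def make_truth(config: SimConfig) -> VoxelMask:
    """Rasterize the analytic ground-truth structure onto the config grid.

    The shape must fit the grid with at least a 2-voxel margin on every axis;
    the rasterized volume is within 10% of the analytic volume at default
    spacing.
    """
    nx, ny, nz = config.grid_shape
    dx, dy, dz = config.spacing_mm
    params = _slice_params(config)
    if not params:
        raise ValueError("truth shape produces no voxels on this grid")
    occ = np.zeros(config.grid_shape, dtype=bool)
    xs = np.arange(nx)[:, None] * dx
    ys = np.arange(ny)[None, :] * dy
    for iz, (cx, cy, ax, ay) in params.items():
        occ[:, :, iz] = ((xs - cx) / ax) ** 2 + ((ys - cy) / ay) ** 2 <= 1.0
    # margin precondition: no truth voxel within 2 voxels of any grid face
    ix, iy, iz_idx = np.nonzero(occ)
    if (ix.min() < 2 or iy.min() < 2 or iz_idx.min() < 2
            or ix.max() > nx - 3 or iy.max() > ny - 3 or iz_idx.max() > nz - 3):
        raise ValueError(
            "truth shape does not fit the grid with a 2-voxel margin; "
            "enlarge grid_shape or shrink the truth"
        )
    return VoxelMask(occ, spacing=config.spacing_mm, label=f"truth:{config.truth.family}")


# -- observer simulation -----------------------------------------------------

def _gauss_kernel(sigma: float) -> np.ndarray:
    if sigma <= 0:
        return np.array([1.0])
    half = max(1, int(np.ceil(4 * sigma)))
    x = np.arange(-half, half + 1)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    return w / w.sum()


def _smooth_field(rng: np.random.Generator, n_slices: int, config: SimConfig) -> np.ndarray:
    """Unit-variance smooth noise field on (slice, angle-bin)."""
    raw = rng.standard_normal((n_slices, config.angle_bins))
    deg_per_bin = 360.0 / config.angle_bins
    ka = _gauss_kernel(config.angle_smooth_deg / deg_per_bin)
    kz = _gauss_kernel(config.z_smooth_slices)
    # circular convolution over angle
    out = np.empty_like(raw)
    half = len(ka) // 2
    padded = np.concatenate([raw[:, -half:], raw, raw[:, :half]], axis=1) if half else raw
    for j in range(config.angle_bins):
        out[:, j] = padded[:, j:j + len(ka)] @ ka
    # reflected convolution over slices
    if len(kz) > 1:
        hz = len(kz) // 2
        pz = np.pad(out, ((hz, hz), (0, 0)), mode="reflect")
        out = np.stack([pz[i:i + len(kz), :].T @ kz for i in range(n_slices)])
    # renormalize to unit marginal variance (separable kernels)
    factor = np.sqrt((ka ** 2).sum() * (kz ** 2).sum())
    return out / factor


def _radius_profiles(truth: VoxelMask, config: SimConfig) -> dict[int, tuple[float, float, np.ndarray]]:
    """Empirical per-slice boundary: z -> (cx, cy, r_truth per angle bin) in mm.

    r_truth(θ) is the max radius of occupied voxel centers in the bin plus a
    half in-plane voxel (the cell boundary); empty bins are filled by circular
    linear interpolation.
    """
    dx, dy, _ = truth.spacing
    nb = config.angle_bins
    half_vox = (dx + dy) / 4.0
    profiles = {}
    for iz in range(truth.shape[2]):
        sl = truth.occupancy[:, :, iz]
        if not sl.any():
            continue
        ix, iy = np.nonzero(sl)
        x, y = ix * dx, iy * dy
        cx, cy = float(x.mean()), float(y.mean())
        r = np.hypot(x - cx, y - cy)
        theta = np.arctan2(y - cy, x - cx)
        bins = ((theta + np.pi) / (2 * np.pi) * nb).astype(int) % nb
        prof = np.full(nb, -1.0)
        np.maximum.at(prof, bins, r)
        empty = prof < 0
        if empty.any():
            if empty.all():
                prof[:] = 0.0
            else:
                idx = np.arange(nb)
                good = idx[~empty]
                # circular linear interpolation across empty bins
                prof[empty] = np.interp(idx[empty], good, prof[good], period=nb)
        profiles[iz] = (cx, cy, prof + half_vox)
    return profiles


def simulate_observer(
    truth: VoxelMask,
    config: SimConfig,
    observer_id: str,
    round_id: str,
    rng: np.random.Generator,
    bias_mm: Optional[float] = None,
) -> VoxelMask:
    """One observer's contour: truth boundary radially displaced by bias + noise.

    ``bias_mm`` is the observer's systematic radial bias before round scaling;
    if None it is drawn from ``rng`` (Normal(0, sigma_sys_mm)).  Round-2 SDs
    and bias are multiplied by ``round2_scale``.  A perturbation that
    annihilates the mask is resampled up to 10 times.
    """
    if truth.is_empty():
        raise ValueError("truth mask is empty")
    scale = config.round_scale(round_id)
    if bias_mm is None:
        bias_mm = float(rng.normal(0.0, config.sigma_sys_mm))
    bias = bias_mm * scale
    sigma_rand = config.sigma_rand_mm * scale
    extent_sigma = config.extent_sigma_slices * scale

    profiles = _radius_profiles(truth, config)
    z_occupied = sorted(profiles)
    z_lo, z_hi = z_occupied[0], z_occupied[-1]
    nx, ny, nz = truth.shape
    dx, dy, _ = truth.spacing
    nb = config.angle_bins
    xs = np.arange(nx)[:, None] * dx
    ys = np.arange(ny)[None, :] * dy

    for _attempt in range(10):
        # apex/base extent channel: extend (copy end profile) or trim slices
        d_lo = int(np.rint(rng.normal(0.0, extent_sigma))) if extent_sigma > 0 else 0
        d_hi = int(np.rint(rng.normal(0.0, extent_sigma))) if extent_sigma > 0 else 0
        lo = max(0, z_lo - max(0, d_lo))
        hi = min(nz - 1, z_hi + max(0, d_hi))
        z_slices = [z for z in range(lo, hi + 1)
                    if not (d_lo < 0 and z < z_lo - d_lo) and not (d_hi < 0 and z > z_hi + d_hi)]
        if not z_slices:
            continue
        noise = _smooth_field(rng, len(z_slices), config) * sigma_rand
        occ = np.zeros(truth.shape, dtype=bool)
        for k, iz in enumerate(z_slices):
            cx, cy, prof = profiles[min(max(iz, z_lo), z_hi)]
            r_target = prof + bias + noise[k]
            r_vox = np.hypot(xs - cx, ys - cy)
            theta = np.arctan2(ys - cy, xs - cx)
            b = ((theta + np.pi) / (2 * np.pi) * nb).astype(int) % nb
            occ[:, :, iz] = r_vox <= r_target[b]
        if occ.any():
            return VoxelMask(occ, spacing=truth.spacing, origin=truth.origin,
                             label=f"obs{observer_id}_r{round_id}")
    raise RuntimeError(
        f"observer {observer_id!r} round {round_id!r}: perturbation annihilated "
        "the mask in 10 consecutive attempts; reduce the noise SDs"
    )


def simulate_case(
    config: SimConfig,
    case_id: str = "1",
    rounds: tuple[str, ...] = (ROUND_1, ROUND_2),
    obs_set: Optional[ObserverSet] = None,
) -> ObserverSet:
    """All observer contours for one case, both rounds, deterministic in seed.

    Observer 1 is designated the reference observer (the study elected one
    participant's contours as reference for every case and round).
    """
    truth = make_truth(config)
    if obs_set is None:
        obs_set = ObserverSet()
    observers = [f"obs{k:02d}" for k in range(1, config.n_observers + 1)]
    if obs_set.reference_observer is None:
        obs_set.reference_observer = observers[0]
    for observer_id in observers:
        bias_rng = _substream(config.seed, "bias", case_id, observer_id)
        bias = float(bias_rng.normal(0.0, config.sigma_sys_mm))
        for round_id in rounds:
            # the reference participant delineates consistently across rounds:
            # same noise substream, so their round-2 contour differs only by
            # the round-2 scale.  Without this, the reference's own re-draw
            # would shift every paired difference in the same direction.
            if observer_id == obs_set.reference_observer:
                rng = _substream(config.seed, "noise", case_id, observer_id)
            else:
                rng = _substream(config.seed, "noise", case_id, observer_id, round_id)
            mask = simulate_observer(truth, config, observer_id, round_id, rng,
                                     bias_mm=bias)
            obs_set.add(observer_id, case_id, round_id, mask)
    return obs_set


def simulate_study(
    config: SimConfig,
    cases: Optional[Mapping[str, str]] = None,
) -> tuple[ObserverSet, "pd.DataFrame"]:  # noqa: F821
    """The full multi-case, two-round study plus its manifest table.

    ``cases`` maps case id -> preset name (default: the three-case design).
    Per-case truth geometry and noise SDs come from the preset; observer
    count, grid, round2_scale and seed come from ``config``.
    """
    import pandas as pd

    if cases is None:
        cases = DEFAULT_STUDY_CASES
    obs_set = ObserverSet()
    rows = []
    for case_id, preset_name in cases.items():
        case_cfg = preset_config(
            preset_name,
            n_observers=config.n_observers,
            grid_shape=config.grid_shape,
            spacing_mm=config.spacing_mm,
            round2_scale=config.round2_scale,
            seed=config.seed,
        )
        simulate_case(case_cfg, case_id=case_id, obs_set=obs_set)
    for (observer_id, case_id, round_id), _mask in obs_set:
        rows.append({
            "observer_id": observer_id, "case_id": case_id, "round_id": round_id,
            "path": f"{case_id}_{observer_id}_r{round_id}.nii.gz",
            "role": "reference" if observer_id == obs_set.reference_observer else "observer",
        })
    manifest = pd.DataFrame(rows, columns=["observer_id", "case_id", "round_id", "path", "role"])
    return obs_set, manifest


def write_study(obs_set: ObserverSet, manifest, out_dir: str | Path,
                config: Optional[SimConfig] = None) -> Path:
    """Write volumes + manifest CSV (+ resolved config JSON) to a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_key = {(r.observer_id, r.case_id, r.round_id): r.path
              for r in manifest.itertuples(index=False)}
    for key, mask in obs_set:
        write_mask(mask, out_dir / by_key[key])
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    if config is not None:
        cfg = dataclasses.asdict(config)
        (out_dir / "sim_config.json").write_text(json.dumps(cfg, indent=2) + "\n")
    return out_dir / "manifest.csv"
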