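"""Semi-automated compartment segmentation of reconstructed volumes.

The tools mirror a typical volume-analysis workstation workflow:
gray-value thresholding between histogram valleys, seeded region growing
with a running-mean homogeneity criterion, externally supplied rough ROI
and manual masks, and component-filtered vessel extraction.  All
operations are deterministic (no RNG).
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phantom import LABELS, MERGED_LABELS
from .recon import ReconVolume

log = logging.getLogger(__name__)

ALL_CODES = {**LABELS, **MERGED_LABELS}
_CODE_NAMES = {v: k for k, v in ALL_CODES.items()}


@dataclass
class SegmentationResult:
    """Compartment label volume plus per-compartment provenance tags."""

    labels: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)
    voxel_size: float = 0.0075
    flags: dict[str, object] = field(default_factory=dict)

    def count(self, name: str) -> int:
        return int(np.count_nonzero(self.labels == ALL_CODES[name]))


def _as_array(volume) -> np.ndarray:
    return volume.data if isinstance(volume, ReconVolume) else np.asarray(volume)


def validate_bounds(bounds: dict[str, tuple[float, float]]) -> None:
    """Reject overlapping half-open [lo, hi) threshold intervals."""
    items = sorted(bounds.items(), key=lambda kv: kv[1][0])
    for (name_a, (lo_a, hi_a)), (name_b, (lo_b, hi_b)) in zip(items, items[1:]):
        if hi_a > lo_b:
            raise ValueError(
                f"ambiguous_thresholds: intervals for {name_a!r} and {name_b!r} overlap"
            )
    for name, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"ambiguous_thresholds: empty interval for {name!r}")


def threshold_segment(volume, bounds: dict[str, tuple[float, float]],
                      voxel_size: float | None = None) -> SegmentationResult:
    """Assign each voxel to the compartment whose [lo, hi) interval holds its value."""
    data = _as_array(volume)
    validate_bounds(bounds)
    labels = np.zeros(data.shape, dtype=np.uint8)
    for name, (lo, hi) in bounds.items():
        labels[(data >= lo) & (data < hi)] = ALL_CODES[name]
    vx = voxel_size if voxel_size is not None else getattr(volume, "voxel_size", 0.0075)
    return SegmentationResult(
        labels=labels,
        provenance={name: "threshold" for name in bounds},
        voxel_size=vx,
    )


def region_grow(volume, seeds: list[tuple[tuple[int, int, int], str]],
                tol: float, voxel_size: float | None = None) -> SegmentationResult:
    """Seeded 6-connected region growing with a running-mean criterion.

    A voxel joins a region when |value - running region mean| <= tol; the
    mean is updated incrementally.  The frontier is processed in
    lexicographic voxel order, and regions are grown sequentially in seed
    order, so a voxel reachable from two seeds belongs to the
    earlier-seeded region.
    """
    data = _as_array(volume)
    if tol <= 0:
        raise ValueError("tol must be > 0")
    labels = np.zeros(data.shape, dtype=np.uint8)
    shape = data.shape
    neighbors = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    for seed, name in seeds:
        seed = tuple(int(s) for s in seed)
        if any(s < 0 or s >= n for s, n in zip(seed, shape)):
            raise ValueError(f"seed {seed} out of bounds for grid {shape}")
        code = ALL_CODES[name]
        if labels[seed] != 0:
            continue  # claimed by an earlier region
        total = 0.0
        count = 0
        frontier = [seed]
        in_frontier = {seed}
        while frontier:
            vox = heapq.heappop(frontier)
            in_frontier.discard(vox)
            if labels[vox] != 0:
                continue
            value = float(data[vox])
            if count > 0 and abs(value - total / count) > tol:
                continue
            labels[vox] = code
            total += value
            count += 1
            for dz, dy, dx in neighbors:
                nb = (vox[0] + dz, vox[1] + dy, vox[2] + dx)
                if (
                    0 <= nb[0] < shape[0]
                    and 0 <= nb[1] < shape[1]
                    and 0 <= nb[2] < shape[2]
                    and labels[nb] == 0
                    and nb not in in_frontier
                ):
                    heapq.heappush(frontier, nb)
                    in_frontier.add(nb)
    vx = voxel_size if voxel_size is not None else getattr(volume, "voxel_size", 0.0075)
    return SegmentationResult(
        labels=labels,
        provenance={name: "region_grow" for _, name in seeds},
        voxel_size=vx,
    )


def apply_roi_and_manual(auto: SegmentationResult,
                         roi_masks: dict[str, np.ndarray] | None = None,
                         manual_masks: dict[str, np.ndarray] | None = None,
                         ) -> SegmentationResult:
    """Constrain automatic labels to rough ROIs; manual masks override.

    Mirrors the workstation practice of defining coarse regions of
    interest first and refining inside them; conflicts between a manual
    mask and automatic labels of another compartment are resolved in favor
    of the manual mask (counted and logged).
    """
    labels = auto.labels.copy()
    provenance = dict(auto.provenance)
    if roi_masks:
        for name, mask in roi_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != labels.shape:
                raise ValueError(f"ROI mask shape mismatch for {name!r}")
            code = ALL_CODES[name]
            labels[(labels == code) & ~mask] = 0
    conflicts = 0
    if manual_masks:
        for name, mask in manual_masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != labels.shape:
                raise ValueError(f"manual mask shape mismatch for {name!r}")
            code = ALL_CODES[name]
            conflicts += int(np.count_nonzero(mask & (labels != 0) & (labels != code)))
            labels[mask] = code
            provenance[name] = "manual"
    if conflicts:
        log.info("manual masks overrode %d automatically labeled voxels", conflicts)
    return SegmentationResult(
        labels=labels,
        provenance=provenance,
        voxel_size=auto.voxel_size,
        flags={**auto.flags, "manual_conflicts": conflicts},
    )


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_vessels(volume, threshold: float, min_component: int = 60,
                    roi: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Extract the vessel tree as below-threshold 26-connected components.

    Vessel lumina are darker than parenchyma; thresholding from below,
    linking with 26-connectivity (permissive for thin structures) and
    dropping components smaller than ``min_component`` voxels separates
    the contiguous tree from isolated tubule voids and noise.
    Returns (mask, number of retained components).
    """
    data = _as_array(volume)
    if not (data.min() <= threshold <= data.max()):
        raise ValueError("threshold outside data range")
    mask = data < threshold
    if roi is not None:
        mask &= np.asarray(roi, dtype=bool)
    comp, n_comp = ndimage.label(mask, structure=_CONN26)
    if n_comp == 0:
        return mask, 0
    sizes = np.bincount(comp.ravel())
    keep = np.flatnonzero(sizes >= min_component)
    keep = keep[keep != 0]
    out = np.isin(comp, keep)
    return out, int(len(keep))
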