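"""Synthetic paired kidney phantoms (contralateral control vs ischemia-reperfusion).

The phantom is a nested-ellipsoid kidney embedded in a paraffin block:
a cortex shell around the outer stripe of the outer medulla (OSOM), the
inner stripe (ISOM) and the inner medulla (IM) core, plus a branching
vessel tree rooted at a hilum point and scattered tubule voids.  Each
compartment carries a refractive-index decrement delta, an absorption
index beta and a linear diffusion coefficient epsilon (dark-field
scattering, 1/mm), with within-compartment Gaussian texture.

The ischemia-reperfusion (I/R) phantom is derived from its control
counterpart (same seed, same grid): the outer compartments shrink until a
target tissue-volume fraction is retained, the inner medulla is nearly
preserved, the vessel tree is pruned to a target volume fraction, and
tubule voids are strongly reduced.  Compartment delta means collapse onto
a single value so the gray-value histogram merges into one peak.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

# Compartment label codes shared across the pipeline.
LABELS = {
    "background": 0,
    "cortex": 1,
    "osom": 2,
    "isom": 3,
    "im": 4,
    "vessel": 5,
    "tubule_void": 6,
}
# Merged classes used by segmentation reports (cortex vs OSOM is not
# value-separable in the control; OSOM vs ISOM is not separable after I/R).
MERGED_LABELS = {"cortex_osom": 7, "osom_isom": 8, "tissue": 9}
TISSUE_CODES = (1, 2, 3, 4)

#: delta is dimensionless; the scale (1e-7) is typical of soft tissue vs
#: paraffin at ~19 keV and keeps the differential phase below the wrap limit.
DELTA_SCALE = 1e-7
#: beta scale chosen so a ~0.5 mm specimen transmits ~80% at 19 keV.
BETA_SCALE = 2e-9

_RELATIVE_CONTROL = {
    "background": 1.00,
    "cortex": 1.05,
    "osom": 1.05,
    "isom": 1.10,
    "im": 1.15,
    "vessel": 0.90,
    "tubule_void": 0.95,
}
_RELATIVE_IR = {
    "background": 1.00,
    "cortex": 1.08,
    "osom": 1.08,
    "isom": 1.08,
    "im": 1.08,
    "vessel": 0.90,
    "tubule_void": 0.95,
}


def default_delta_means(condition: str) -> dict[str, float]:
    rel = _RELATIVE_CONTROL if condition == "control" else _RELATIVE_IR
    return {k: v * DELTA_SCALE for k, v in rel.items()}


def default_beta_means(condition: str) -> dict[str, float]:
    rel = _RELATIVE_CONTROL if condition == "control" else _RELATIVE_IR
    return {k: v * BETA_SCALE for k, v in rel.items()}


def default_epsilon_means(condition: str) -> dict[str, float]:
    # Dark-field scattering lives at tubule-to-tissue interfaces: a small
    # parenchymal baseline plus an elevated 1-voxel rim around each void.
    base = 0.05 if condition == "control" else 0.03
    eps = {k: 0.0 for k in LABELS}
    for k in ("cortex", "osom", "isom", "im"):
        eps[k] = base
    eps["tubule_rim"] = 1.0 if condition == "control" else 0.6
    return eps


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic kidney.

    ``condition`` selects control or ischemia-reperfusion ("ir"); the I/R
    phantom internally rebuilds its control counterpart (same seed, same
    grid) to calibrate shrinkage and vessel-pruning targets.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size: float = 0.0075  # mm
    condition: str = "control"
    compartment_delta_means: dict[str, float] | None = None
    compartment_beta_means: dict[str, float] | None = None
    compartment_epsilon_means: dict[str, float] | None = None
    texture_sd: float = 0.01
    shrink_total: float = 0.46
    vessel_retain: float = 0.18
    im_retain: float = 0.95
    n_tubule_voids: int = 90
    ir_tubule_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.condition not in ("control", "ir"):
            raise ValueError(f"unknown condition {self.condition!r}")
        gs = tuple(int(g) for g in self.grid_shape)
        object.__setattr__(self, "grid_shape", gs)
        if len(gs) != 3 or any(g < 8 for g in gs):
            raise ValueError("grid_too_small: grid_shape must be 3 axes, all >= 8")
        if min(gs) < 16:
            # four nested shells plus background need headroom
            raise ValueError("grid_too_small: need >= 16 voxels per axis for 4 nested shells")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if not (0.0 < self.shrink_total <= 1.0):
            raise ValueError("shrink_total must lie in (0, 1]")
        if not (0.0 < self.vessel_retain <= 1.0):
            raise ValueError("vessel_retain must lie in (0, 1]")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")
        if self.compartment_delta_means is None:
            object.__setattr__(
                self, "compartment_delta_means", default_delta_means(self.condition)
            )
        if self.compartment_beta_means is None:
            object.__setattr__(
                self, "compartment_beta_means", default_beta_means(self.condition)
            )
        if self.compartment_epsilon_means is None:
            object.__setattr__(
                self, "compartment_epsilon_means", default_epsilon_means(self.condition)
            )
        self._validate_delta_structure()

    def _validate_delta_structure(self) -> None:
        d = self.compartment_delta_means
        if self.condition == "control":
            if not (d["im"] > d["isom"] > d["cortex"]):
                raise ValueError("control requires delta(IM) > delta(ISOM) > delta(cortex)")
            if abs(d["osom"] - d["cortex"]) >= self.texture_sd * d["cortex"]:
                raise ValueError("control requires delta(OSOM) within one texture SD of cortex")
        else:
            tissue = [d[k] for k in ("cortex", "osom", "isom", "im")]
            sd = self.texture_sd * float(np.mean(tissue))
            if max(tissue) - min(tissue) > sd:
                raise ValueError("ir requires merged compartment delta means (<= 1 texture SD apart)")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        payload = json.loads(text)
        payload["grid_shape"] = tuple(payload["grid_shape"])
        return cls(**payload)


@dataclass
class PhantomVolumes:
    """Label map plus delta/beta/epsilon property volumes on one grid."""

    labels: np.ndarray
    delta: np.ndarray
    beta: np.ndarray
    epsilon: np.ndarray
    voxel_size: float
    spec: PhantomSpec

    def __post_init__(self):
        shapes = {self.labels.shape, self.delta.shape, self.beta.shape, self.epsilon.shape}
        if len(shapes) != 1:
            raise ValueError("labels/delta/beta/epsilon must share one grid")

    def compartment_count(self, name: str) -> int:
        return int(np.count_nonzero(self.labels == LABELS[name]))

    def tissue_count(self) -> int:
        return int(np.count_nonzero(np.isin(self.labels, TISSUE_CODES)))


# ---------------------------------------------------------------------------
# geometry helpers

# Organ semi-axes as fractions of (half-grid - margin), per axis (z, y, x):
# a kidney-like ellipsoid, elongated along the rotation axis.
_ORGAN_FRACTIONS = (0.90, 0.80, 0.68)
# Outer-boundary scale of each shell relative to the organ surface.
_SHELL_SCALES = {"osom_outer": 0.80, "isom_outer": 0.66, "im_outer": 0.48}


def _ellipsoid_r2(shape, center, semi_axes):
    """Squared normalized ellipsoid radius for every voxel."""
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - center[0]) / semi_axes[0]) ** 2
        + ((yy - center[1]) / semi_axes[1]) ** 2
        + ((xx - center[2]) / semi_axes[2]) ** 2
    )


def _build_shells(shape, center, organ_axes, outer_scale, im_axes):
    """Label volume of nested compartment shells (no vessels/voids yet)."""
    labels = np.zeros(shape, dtype=np.uint8)
    organ = np.asarray(organ_axes) * outer_scale
    r2 = _ellipsoid_r2(shape, center, organ)
    labels[r2 <= 1.0] = LABELS["cortex"]
    r2 = _ellipsoid_r2(shape, center, organ * _SHELL_SCALES["osom_outer"])
    labels[r2 <= 1.0] = LABELS["osom"]
    r2 = _ellipsoid_r2(shape, center, organ * _SHELL_SCALES["isom_outer"])
    labels[r2 <= 1.0] = LABELS["isom"]
    r2 = _ellipsoid_r2(shape, center, im_axes)
    labels[r2 <= 1.0] = LABELS["im"]
    return labels


def _vessel_tree_segments(organ_axes, center, rng):
    """Centerline segments of a bifurcating vessel tree in voxel coordinates.

    Returns a list of (p0, p1, radius) ordered root-first so that pruning a
    suffix keeps the tree connected.
    """
    segments = []
    root_len = 0.52 * organ_axes[2]
    root_radius = 3.4
    hilum = np.array([center[0], center[1], center[2] - 0.92 * organ_axes[2]])
    direction = np.array([0.0, 0.0, 1.0])

    queue = [(hilum, direction, 0)]
    n_generations = 4
    while queue:
        p0, d, gen = queue.pop(0)
        length = root_len * (0.72 ** gen)
        radius = root_radius * (0.82 ** gen)
        # small deterministic jitter so branches spread through the organ
        jitter = rng.normal(scale=0.12, size=3)
        d = d + jitter
        d = d / np.linalg.norm(d)
        p1 = p0 + d * length
        segments.append((p0.copy(), p1.copy(), radius))
        if gen + 1 < n_generations:
            # bifurcate: rotate the direction by +/- ~35 degrees about a
            # random axis perpendicular to d
            axis = np.cross(d, rng.normal(size=3))
            axis = axis / max(np.linalg.norm(axis), 1e-12)
            for sign in (+1.0, -1.0):
                angle = sign * np.deg2rad(35.0 + rng.normal(scale=4.0))
                child = _rotate_about(d, axis, angle)
                queue.append((p1, child, gen + 1))
    return segments


def _detour_around(segments, center, axes, margin=1.10):
    """Bend vessel segments around an ellipsoidal exclusion zone.

    The macroscopic renal vessels arc around the inner medulla rather than
    piercing it; endpoints (and, where needed, segment midpoints, splitting
    the segment in two) inside the margin ellipsoid are pushed radially to
    its surface.  Shared endpoints move identically, keeping the tree
    connected.
    """
    guard = np.asarray(axes) * margin

    def push(p):
        u = (p - center) / guard
        r = float(np.linalg.norm(u))
        if r >= 1.0 or r < 1e-9:
            return p
        return center + (u / r) * guard

    out = []
    for p0, p1, radius in segments:
        p0n, p1n = push(p0), push(p1)
        mid = 0.5 * (p0n + p1n)
        mid_n = push(mid)
        if np.any(mid_n != mid):
            out.append((p0n, mid_n, radius))
            out.append((mid_n, p1n, radius))
        else:
            out.append((p0n, p1n, radius))
    return out


def _rotate_about(v, axis, angle):
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def _rasterize_segments(shape, segments, inside_mask, radius_scale=1.0, length_budget=None):
    """Rasterize capsule segments into a boolean mask, clipped to inside_mask.

    length_budget truncates the tree (root-first) after a cumulative
    centerline length; the segment straddling the cutoff is shortened.
    """
    mask = np.zeros(shape, dtype=bool)
    used = 0.0
    for p0, p1, radius in segments:
        seg_len = float(np.linalg.norm(p1 - p0))
        if length_budget is not None:
            if used >= length_budget:
                break
            if used + seg_len > length_budget:
                frac = (length_budget - used) / seg_len
                p1 = p0 + (p1 - p0) * frac
                seg_len *= frac
        used += seg_len
        r = radius * radius_scale
        lo = np.floor(np.minimum(p0, p1) - r - 1).astype(int)
        hi = np.ceil(np.maximum(p0, p1) + r + 1).astype(int) + 1
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        pts = (zz - p0[0], yy - p0[1], xx - p0[2])
        d = p1 - p0
        dd = float(np.dot(d, d))
        t = (pts[0] * d[0] + pts[1] * d[1] + pts[2] * d[2]) / max(dd, 1e-12)
        t = np.clip(t, 0.0, 1.0)
        dist2 = (
            (pts[0] - t * d[0]) ** 2 + (pts[1] - t * d[1]) ** 2 + (pts[2] - t * d[2]) ** 2
        )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= dist2 <= r * r
    mask &= inside_mask
    return mask


def _scatter_voids(labels, n_voids, rng, exclude=None):
    """Small ellipsoidal tubule voids placed in cortex/OSOM/ISOM.

    ``exclude`` masks out a forbidden zone (the vessel tree and a safety
    margin): tubule lumina do not abut the macroscopic vasculature.
    """
    host = np.isin(labels, (LABELS["cortex"], LABELS["osom"], LABELS["isom"]))
    if exclude is not None:
        host &= ~exclude
    idx = np.flatnonzero(host)
    if idx.size == 0 or n_voids == 0:
        return np.zeros(labels.shape, dtype=bool)
    picks = rng.choice(idx, size=min(n_voids, idx.size), replace=False)
    centers = np.column_stack(np.unravel_index(picks, labels.shape))
    mask = np.zeros(labels.shape, dtype=bool)
    for c in centers:
        radii = rng.uniform(1.2, 2.0, size=3)
        lo = np.maximum(np.floor(c - radii - 1).astype(int), 0)
        hi = np.minimum(np.ceil(c + radii + 1).astype(int) + 1, labels.shape)
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        r2 = (
            ((zz - c[0]) / radii[0]) ** 2
            + ((yy - c[1]) / radii[1]) ** 2
            + ((xx - c[2]) / radii[2]) ** 2
        )
        mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= r2 <= 1.0
    mask &= host
    return mask


# ---------------------------------------------------------------------------
# assembly


def _assemble_labels(spec: PhantomSpec, outer_scale: float, im_scale: float,
                     vessel_budget: float | None):
    """Build the full label volume for one shrink/prune configuration.

    All randomness restarts from spec.seed so every bisection trial (and
    every repeated call) is bit-reproducible.
    """
    shape = spec.grid_shape
    center = np.array([(n - 1) / 2.0 for n in shape])
    half = np.array([(n / 2.0) - 2.0 for n in shape])
    organ_axes = np.asarray(_ORGAN_FRACTIONS) * half
    im_axes = organ_axes * _SHELL_SCALES["im_outer"] * im_scale

    labels = _build_shells(shape, center, organ_axes, outer_scale, im_axes)

    rng_tree = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    segments = _vessel_tree_segments(organ_axes, center, rng_tree)
    if outer_scale != 1.0:
        segments = [
            (center + (p0 - center) * outer_scale, center + (p1 - center) * outer_scale, r)
            for p0, p1, r in segments
        ]
    segments = _detour_around(segments, center, im_axes, margin=1.3)
    organ_mask = labels > 0

    n_voids = spec.n_tubule_voids
    if spec.condition == "ir" or vessel_budget is not None:
        n_voids = max(0, int(round(spec.n_tubule_voids * spec.ir_tubule_fraction)))
    vessels = _rasterize_segments(shape, segments, organ_mask, length_budget=vessel_budget)

    rng_voids = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    vessel_zone = ndimage.binary_dilation(vessels, iterations=6)
    voids = _scatter_voids(labels, n_voids, rng_voids, exclude=vessel_zone)
    labels[voids] = LABELS["tubule_void"]
    labels[vessels] = LABELS["vessel"]
    return labels, segments


def _tree_length(segments) -> float:
    return float(sum(np.linalg.norm(p1 - p0) for p0, p1, _ in segments))


def _bisect(fn, lo, hi, target, rel_tol=0.005, max_iter=40):
    """Find scalar x in [lo, hi] with monotone fn(x) ~ target (voxel counts)."""
    f_lo, f_hi = fn(lo), fn(hi)
    if not (min(f_lo, f_hi) <= target <= max(f_lo, f_hi)):
        # fall back to nearest endpoint
        return lo if abs(f_lo - target) < abs(f_hi - target) else hi
    increasing = f_hi >= f_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = fn(mid)
        if abs(f_mid - target) <= rel_tol * target:
            return mid
        if (f_mid < target) == increasing:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_phantom(spec: PhantomSpec) -> PhantomVolumes:
    """Generate a voxelized kidney phantom (control or ischemia-reperfusion).

    The I/R phantom rebuilds its control counterpart (same seed/grid) and
    calibrates, by bisection on the shell scale and the vessel-tree length
    budget, the retained tissue fraction (``shrink_total``, tolerance 0.5%),
    the inner-medulla retention (``im_retain``) and the vessel retention
    (``vessel_retain``, tolerance 1%).
    """
    if spec.condition == "control":
        labels, _ = _assemble_labels(spec, outer_scale=1.0, im_scale=1.0, vessel_budget=None)
        return _fill_properties(spec, labels)

    control_spec = dataclasses.replace(
        spec,
        condition="control",
        compartment_delta_means=None,
        compartment_beta_means=None,
        compartment_epsilon_means=None,
    )
    c_labels, c_segments = _assemble_labels(
        control_spec, outer_scale=1.0, im_scale=1.0, vessel_budget=None
    )
    c_tissue = int(np.count_nonzero(np.isin(c_labels, TISSUE_CODES)))
    c_vessels = int(np.count_nonzero(c_labels == LABELS["vessel"]))

    c_im = int(np.count_nonzero(c_labels == LABELS["im"]))
    tissue_target = spec.shrink_total * c_tissue
    vessel_target = spec.vessel_retain * c_vessels
    im_target = spec.im_retain * c_im
    total_length = _tree_length(c_segments)

    # The three targets interact (vessels and the inner-medulla boundary
    # both carve tissue), so bisect each in turn and iterate to a joint fix.
    scale = spec.shrink_total ** (1.0 / 3.0)
    im_scale = spec.im_retain ** (1.0 / 3.0)
    budget = total_length * spec.vessel_retain / 0.7

    def counts_for(s, ims, bud):
        labels, _ = _assemble_labels(spec, s, ims, bud)
        return labels

    for _ in range(2):
        s_min = _SHELL_SCALES["im_outer"] * im_scale / _SHELL_SCALES["isom_outer"] + 0.02

        def tissue_count(s):
            labels = counts_for(s, im_scale, budget)
            return int(np.count_nonzero(np.isin(labels, TISSUE_CODES)))

        scale = _bisect(tissue_count, s_min, 1.0, tissue_target, rel_tol=0.003)

        def im_count(ims):
            labels = counts_for(scale, ims, budget)
            return int(np.count_nonzero(labels == LABELS["im"]))

        im_scale = _bisect(im_count, 0.7 * im_scale, min(1.3 * im_scale, 1.0),
                           im_target, rel_tol=0.01)

        def vessel_count(bud):
            labels = counts_for(scale, im_scale, bud)
            return int(np.count_nonzero(labels == LABELS["vessel"]))

        budget = _bisect(vessel_count, 0.0, total_length, vessel_target, rel_tol=0.005)

    labels, _ = _assemble_labels(spec, scale, im_scale, budget)
    return _fill_properties(spec, labels)


def _fill_properties(spec: PhantomSpec, labels: np.ndarray) -> PhantomVolumes:
    """Per-voxel delta/beta/epsilon = compartment mean x (1 + texture noise)."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    shape = labels.shape

    # The paraffin embedding block is a cylinder inscribed in the grid
    # (axis = rotation axis): everything the beam sees must stay inside the
    # field of view under rotation.  Outside the block: vacuum.
    cy, cx = (shape[1] - 1) / 2.0, (shape[2] - 1) / 2.0
    yy, xx = np.ogrid[: shape[1], : shape[2]]
    r_block = min(shape[1], shape[2]) / 2.0 - 2.0
    block = ((yy - cy) ** 2 + (xx - cx) ** 2 <= r_block * r_block)[None, :, :]

    def textured(mean_map, extra_rim=None):
        out = np.zeros(shape, dtype=np.float64)
        for name, code in LABELS.items():
            out[labels == code] = mean_map.get(name, 0.0)
        if extra_rim is not None:
            rim_mask, rim_value = extra_rim
            out[rim_mask] = rim_value
        noise = rng.normal(0.0, spec.texture_sd, size=shape)
        out = np.clip(out * (1.0 + noise), 0.0, None)
        out *= block
        return out

    void_mask = labels == LABELS["tubule_void"]
    rim = ndimage.binary_dilation(void_mask) & np.isin(labels, TISSUE_CODES)
    eps_means = spec.compartment_epsilon_means
    delta = textured(spec.compartment_delta_means)
    beta = textured(spec.compartment_beta_means)
    epsilon = textured(eps_means, extra_rim=(rim, eps_means.get("tubule_rim", 0.0)))
    return PhantomVolumes(
        labels=labels,
        delta=delta,
        beta=beta,
        epsilon=epsilon,
        voxel_size=spec.voxel_size,
        spec=spec,
    )
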