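"""Rigid registration of embryo point clouds and spatial averaging.

Nuclei from several embryos are pooled into one reference frame by rigid
(rotation + translation, optional isotropic scale) alignment, then
per-nucleus attributes (expression class, relative-level index) are
averaged over local neighbourhoods.  The default neighbourhood radius is
11 µm, which for ~10 µm nuclei corresponds to about 14 nearest
neighbours — the count of the first two coordination shells of a perfect
body-centred cubic lattice (8 at sqrt(3)/2 of the cell side plus 6 at
one cell side).

Also provides ablation-ROI bookkeeping: counting nuclei inside a
registered ROI and per-voxel overlap frequencies of ROIs across embryos.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "PointCloud",
    "RigidTransform",
    "RegistrationResult",
    "NeighborhoodMap",
    "register_point_clouds",
    "average_neighborhood",
    "count_nuclei_in_roi",
    "roi_overlap_map",
]


@dataclass
class PointCloud:
    """3D points (µm) with optional per-point named attributes."""

    points_um: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    embryo_id: str | None = None

    def __post_init__(self) -> None:
        self.points_um = np.atleast_2d(np.asarray(self.points_um, dtype=float))
        if self.points_um.ndim != 2 or self.points_um.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points_um.shape}")
        if not np.all(np.isfinite(self.points_um)):
            raise ValueError("point coordinates must be finite")
        for name, arr in self.attributes.items():
            arr = np.asarray(arr)
            if len(arr) != len(self.points_um):
                raise ValueError(
                    f"attribute {name!r} has {len(arr)} values for {len(self.points_um)} points"
                )
            self.attributes[name] = arr

    def __len__(self) -> int:
        return len(self.points_um)

    def transformed(self, transform: "RigidTransform") -> "PointCloud":
        return PointCloud(transform.apply(self.points_um), dict(self.attributes), self.embryo_id)


@dataclass
class RigidTransform:
    """Proper rigid transform ``p -> scale * R @ p + t`` (µm).

    The rotation must be orthonormal with determinant +1 (within 1e-8);
    scale defaults to 1 (pure rigid motion).
    """

    rotation: np.ndarray
    translation_um: np.ndarray
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation_um = np.asarray(self.translation_um, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError(f"rotation must be 3x3, got {self.rotation.shape}")
        err = np.max(np.abs(self.rotation @ self.rotation.T - np.eye(3)))
        if err > 1e-8:
            raise ValueError(f"rotation not orthonormal (max deviation {err:.2e})")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation has determinant -1 (reflection)")
        if self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return self.scale * pts @ self.rotation.T + self.translation_um

    def inverse(self) -> "RigidTransform":
        r_inv = self.rotation.T
        return RigidTransform(
            r_inv, -r_inv @ self.translation_um / self.scale, 1.0 / self.scale
        )

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """The transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.scale * self.rotation @ other.translation_um + self.translation_um,
            self.scale * other.scale,
        )

    def rotation_angle_deg(self, other: "RigidTransform" | None = None) -> float:
        """Rotation angle, relative to ``other`` if given (identity otherwise)."""
        r = self.rotation if other is None else self.rotation @ other.rotation.T
        c = (np.trace(r) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation_um": self.translation_um.tolist(),
            "scale": self.scale,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation_um"]),
                   float(d.get("scale", 1.0)))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms_um: float
    residuals_um: np.ndarray
    converged: bool = True
    n_iterations: int = 0
    mode: str = "landmark"


def _kabsch(moving: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Closed-form least-squares rigid alignment of matched point pairs."""
    mu_m = moving.mean(axis=0)
    mu_f = fixed.mean(axis=0)
    x = moving - mu_m
    y = fixed - mu_f
    if np.linalg.matrix_rank(x, tol=1e-9 * max(1.0, np.abs(x).max())) < 3:
        raise ValueError("degenerate geometry: centred points have rank < 3")
    h = x.T @ y
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_f - r @ mu_m
    return RigidTransform(r, t)


def register_point_clouds(
    moving: PointCloud,
    fixed: PointCloud,
    mode: str = "landmark",
    max_iterations: int = 50,
    tolerance_um: float = 1e-8,
) -> RegistrationResult:
    """Estimate the rigid transform mapping ``moving`` onto ``fixed``.

    ``landmark`` mode assumes matched correspondences (same length, same
    order) and solves the least-squares rigid alignment in closed form
    (Kabsch).  ``icp`` mode iterates nearest-neighbour matching plus the
    closed-form update until the mean residual changes by less than
    ``tolerance_um`` or ``max_iterations`` is reached; non-convergence
    is flagged on the result, not raised.
    """
    mov = moving.points_um
    fix = fixed.points_um
    if len(mov) < 4 or len(fix) < 4:
        raise ValueError("registration needs at least 4 points per cloud")

    if mode == "landmark":
        if len(mov) != len(fix):
            raise ValueError(
                f"landmark mode needs matched correspondences: {len(mov)} vs {len(fix)} points"
            )
        tf = _kabsch(mov, fix)
        res = np.linalg.norm(tf.apply(mov) - fix, axis=1)
        return RegistrationResult(tf, float(np.sqrt(np.mean(res**2))), res, True, 0, "landmark")

    if mode != "icp":
        raise ValueError(f"unknown registration mode {mode!r}; use 'landmark' or 'icp'")

    tree = cKDTree(fix)
    tf = RigidTransform.identity()
    prev_mean = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        cur = tf.apply(mov)
        dists, idx = tree.query(cur)
        tf = _kabsch(mov, fix[idx])
        mean_res = float(np.mean(np.linalg.norm(tf.apply(mov) - fix[idx], axis=1)))
        if abs(prev_mean - mean_res) < tolerance_um:
            converged = True
            break
        prev_mean = mean_res
    res = tree.query(tf.apply(mov))[0]
    return RegistrationResult(
        tf, float(np.sqrt(np.mean(res**2))), res, converged, n_iter, "icp"
    )


# ---------------------------------------------------------------------------
# neighbourhood averaging
# ---------------------------------------------------------------------------

@dataclass
class NeighborhoodMap:
    """Attribute values averaged over local neighbourhoods of a reference.

    ``values`` is NaN wherever ``support`` (neighbour count) is zero.
    """

    points_um: np.ndarray
    values: np.ndarray
    support: np.ndarray
    radius_um: float
    attribute: str


def average_neighborhood(
    reference: PointCloud,
    pooled: PointCloud,
    attribute: str,
    radius_um: float = 11.0,
) -> NeighborhoodMap:
    """Average a pooled-cloud attribute around every reference point.

    For each reference point the value is the mean of the attribute over
    pooled points strictly within ``radius_um``.  Pooled points exactly
    coincident with the reference point are excluded, so a cloud pooled
    with itself does not average each nucleus into its own neighbourhood.
    """
    if attribute not in pooled.attributes:
        raise KeyError(
            f"unknown attribute {attribute!r}; pooled cloud has {sorted(pooled.attributes)}"
        )
    vals = np.asarray(pooled.attributes[attribute], dtype=float)
    tree = cKDTree(pooled.points_um)
    out_vals = np.full(len(reference), np.nan)
    out_support = np.zeros(len(reference), dtype=int)
    for i, p in enumerate(reference.points_um):
        idx = tree.query_ball_point(p, radius_um)
        if not idx:
            continue
        d = np.linalg.norm(pooled.points_um[idx] - p, axis=1)
        keep = [j for j, dj in zip(idx, d) if 0.0 < dj < radius_um]
        if not keep:
            continue
        out_support[i] = len(keep)
        out_vals[i] = float(np.mean(vals[keep]))
    return NeighborhoodMap(reference.points_um.copy(), out_vals, out_support,
                           float(radius_um), attribute)


# ---------------------------------------------------------------------------
# ablation ROIs
# ---------------------------------------------------------------------------

def count_nuclei_in_roi(points_um: np.ndarray, roi: tuple) -> int:
    """Count points inside an axis-aligned box (µm).

    ``roi = (lo, hi)`` with 3-vectors; bounds are inclusive on the low
    edge and exclusive on the high edge.  A zero-volume ROI warns and
    returns 0.
    """
    pts = np.atleast_2d(np.asarray(points_um, dtype=float))
    lo = np.asarray(roi[0], dtype=float)
    hi = np.asarray(roi[1], dtype=float)
    if np.any(hi <= lo):
        warnings.warn("ROI has zero (or negative) volume; count is 0", stacklevel=2)
        return 0
    if pts.size == 0:
        return 0
    inside = np.all((pts >= lo) & (pts < hi), axis=1)
    return int(inside.sum())


def roi_overlap_map(
    rois: list,
    spacing_um: tuple[float, float, float],
    origin_um: np.ndarray | None = None,
    shape: tuple[int, int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel count of how many registered ROIs cover each voxel.

    ``rois`` are axis-aligned boxes ``(lo, hi)`` in µm (already
    registered to the common frame) or boolean masks sharing one grid.
    For boxes, a voxel counts as covered when its centre falls inside
    (low-inclusive, high-exclusive); the grid defaults to the bounding
    box of the union of ROIs.  Returns ``(counts, origin_um)``.
    """
    if not rois:
        raise ValueError("need at least one ROI")
    if isinstance(rois[0], np.ndarray) and rois[0].dtype == bool:
        counts = np.zeros(rois[0].shape, dtype=int)
        for m in rois:
            if m.shape != counts.shape:
                raise ValueError("boolean ROI masks must share one grid")
            counts += m.astype(int)
        return counts, np.zeros(3)

    spacing = np.asarray(spacing_um, dtype=float)
    boxes = [(np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)) for lo, hi in rois]
    if origin_um is None:
        origin_um = np.min([lo for lo, _ in boxes], axis=0)
    origin_um = np.asarray(origin_um, dtype=float)
    if shape is None:
        top = np.max([hi for _, hi in boxes], axis=0)
        shape = tuple(
            max(int(np.ceil((t - o) / s)), 1) for t, o, s in zip(top, origin_um, spacing)
        )
    counts = np.zeros(shape, dtype=int)
    centres = [origin_um[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)]
    for lo, hi in boxes:
        idx = [
            (centres[a] >= lo[a]) & (centres[a] < hi[a])
            for a in range(3)
        ]
        counts[np.ix_(*idx)] += 1
    return counts, origin_um
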