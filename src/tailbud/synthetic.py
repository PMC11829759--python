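"""Synthetic phantoms with attached ground truth.

Generates every input the analysis pipeline consumes, so the whole chain
is testable without any imaging data:

* 3-channel nuclear stacks: ~10 µm Gaussian-tapered ellipsoidal nuclei
  packed in an ellipsoidal (tailbud-like) domain, with opposing
  dorsoventral expression gradients of two genes, a co-expression band,
  optional ablated regions rendered as pyknotic debris, and a
  ground-truth label image plus nucleus table;
* 3D cell tracks with diffusive, persistent, ballistic or confined step
  statistics and the per-kind ground-truth MSD exponent;
* embryo point clouds related to a reference cloud by known rigid
  transforms plus isotropic jitter;
* tail polylines (spinal cord + paraxial mesoderm) whose per-somite
  segment lengths are known exactly.

Every generator is a pure function of its spec including the seed:
identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .morphometry import MeasuredPolyline
from .registration import PointCloud, RigidTransform
from .stack import ImageStack3D
from .tracks import Track, TrackSet

__all__ = [
    "EmbryoPhantomSpec",
    "TrackSimSpec",
    "generate_nuclear_stack",
    "generate_tracks",
    "generate_point_clouds",
    "generate_tail_polylines",
    "bcc_lattice",
]

# amplitude floor of an expressed gene relative to its maximum, so that
# in-band nuclei are unambiguously above background
_EXPR_FLOOR = 0.3
# intensity profile: exp(-rho^2 / (2 * sigma^2)) in normalised ellipsoid
# coordinates rho (rho = 1 at the nominal surface)
_TAPER_SIGMA = 0.5


@dataclass
class EmbryoPhantomSpec:
    """Parameters of a tailbud-like nuclear phantom.

    ``gradient_axis`` is the dorsoventral direction (unit vector, zyx
    order); the gradient coordinate g runs 0 -> 1 across the domain
    along it.  ``coexpression_band`` is the g-interval where both genes
    are on.  ``min_separation_factor`` times the nucleus diameter is the
    minimum centre-to-centre distance (>= 0.8; raise it to guarantee
    non-touching nuclei).
    """

    shape_voxels: tuple[int, int, int] = (40, 120, 120)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_nuclei: int = 50
    nucleus_diameter_um: float = 10.0
    gradient_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    coexpression_band: tuple[float, float] = (0.4, 0.6)
    noise_sd: float = 0.0
    ablation_box_um: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None
    seed: int = 0
    min_separation_factor: float = 0.8

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape_voxels):
            raise ValueError("shape_voxels must be positive")
        if any(s <= 0 for s in self.voxel_size_um):
            raise ValueError("voxel_size_um must be positive")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if self.nucleus_diameter_um <= 0:
            raise ValueError("nucleus_diameter_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.min_separation_factor < 0.8:
            raise ValueError("min_separation_factor must be >= 0.8")
        lo, hi = self.coexpression_band
        if not (0 <= lo < hi <= 1):
            raise ValueError("coexpression_band must be an interval within [0, 1]")
        axis = np.asarray(self.gradient_axis, dtype=float)
        if not math.isclose(float(np.linalg.norm(axis)), 1.0, rel_tol=1e-6):
            raise ValueError("gradient_axis must be a unit vector")


def _true_class(g: float, band: tuple[float, float]) -> str:
    lo, hi = band
    if g < lo:
        return "sox2_only"
    if g > hi:
        return "tbxta_only"
    return "double_positive"


def _expression_amplitudes(g: float, band: tuple[float, float]) -> tuple[float, float]:
    """Per-nucleus channel amplitudes: sox2 decreases with g, tbxta increases."""
    lo, hi = band
    amp_sox2 = (_EXPR_FLOOR + (1 - _EXPR_FLOOR) * (1.0 - g)) if g <= hi else 0.0
    amp_tbxta = (_EXPR_FLOOR + (1 - _EXPR_FLOOR) * g) if g >= lo else 0.0
    return amp_sox2, amp_tbxta


def generate_nuclear_stack(
    spec: EmbryoPhantomSpec,
) -> tuple[ImageStack3D, np.ndarray, pd.DataFrame]:
    """Render a 3-channel phantom stack with full ground truth.

    Returns ``(stack, labels, truth)`` where the stack carries channels
    ``nuclear``, ``sox2``, ``tbxta``; ``labels`` is the ground-truth 3D
    label image (0 background); and ``truth`` has one row per nucleus:
    centre (µm), semi-axes, rendered volume, channel amplitudes,
    gradient coordinate, true expression class and an ``ablated`` flag
    (ablated nuclei are removed from the label image and replaced by
    small bright pyknotic fragments in the nuclear channel).
    """
    rng = np.random.default_rng(spec.seed)
    spacing = np.asarray(spec.voxel_size_um)
    shape = tuple(spec.shape_voxels)
    extent = np.asarray(shape) * spacing  # physical size, µm
    radius = spec.nucleus_diameter_um / 2.0
    min_sep = spec.min_separation_factor * spec.nucleus_diameter_um

    # -- place centres inside the inscribed ellipsoid (tailbud-like domain)
    centres: list[np.ndarray] = []
    semi = extent / 2.0 - radius  # centre must keep the nucleus inside
    if np.any(semi <= 0) and spec.n_nuclei > 0:
        raise ValueError(
            f"domain {extent} µm too small for nuclei of diameter "
            f"{spec.nucleus_diameter_um} µm"
        )
    mid = extent / 2.0
    attempts = 0
    max_attempts = 500 * max(spec.n_nuclei, 1)
    while len(centres) < spec.n_nuclei and attempts < max_attempts:
        attempts += 1
        cand = mid + (rng.random(3) * 2 - 1) * semi
        if np.sum(((cand - mid) / semi) ** 2) > 1.0:
            continue
        if centres and np.min(
            np.linalg.norm(np.asarray(centres) - cand, axis=1)
        ) < min_sep:
            continue
        centres.append(cand)
    if len(centres) < spec.n_nuclei:
        raise RuntimeError(
            f"infeasible packing: placed only {len(centres)} of {spec.n_nuclei} "
            f"nuclei at >= {min_sep:.1f} µm separation in a {extent} µm domain; "
            f"reduce n_nuclei to <= {len(centres)} or enlarge the domain"
        )

    axis = np.asarray(spec.gradient_axis, dtype=float)
    proj = np.array([float(np.dot(c, axis)) for c in centres]) if centres else np.array([])
    span = float(np.dot(extent, np.abs(axis)))
    gs = proj / span if span > 0 else proj

    nuclear = np.zeros(shape, dtype=np.float64)
    sox2 = np.zeros(shape, dtype=np.float64)
    tbxta = np.zeros(shape, dtype=np.float64)
    labels = np.zeros(shape, dtype=np.int32)

    box = spec.ablation_box_um
    rows = []
    for i, (c, g) in enumerate(zip(centres, gs)):
        nucleus_id = i + 1
        semi_axes = radius * rng.uniform(0.9, 1.05, size=3)
        amp_s, amp_t = _expression_amplitudes(g, spec.coexpression_band)
        ablated = bool(box is not None and np.all(
            (c >= np.asarray(box[0])) & (c < np.asarray(box[1]))
        ))
        volume = 0.0
        if not ablated:
            volume = _render_ellipsoid(
                c, semi_axes, spacing,
                targets=((nuclear, 1.0), (sox2, amp_s), (tbxta, amp_t)),
                labels=labels, label_id=nucleus_id,
            )
        else:
            _render_debris(c, radius, spacing, nuclear, rng)
        rows.append(
            {
                "id": nucleus_id,
                "z_um": c[0], "y_um": c[1], "x_um": c[2],
                "semi_z_um": semi_axes[0], "semi_y_um": semi_axes[1],
                "semi_x_um": semi_axes[2],
                "volume_um3": volume,
                "amp_sox2": amp_s, "amp_tbxta": amp_t,
                "gradient_coord": g,
                "expr_class": _true_class(g, spec.coexpression_band),
                "ablated": ablated,
            }
        )

    truth = pd.DataFrame(
        rows,
        columns=[
            "id", "z_um", "y_um", "x_um", "semi_z_um", "semi_y_um", "semi_x_um",
            "volume_um3", "amp_sox2", "amp_tbxta", "gradient_coord",
            "expr_class", "ablated",
        ],
    )

    voxels = np.stack([nuclear, sox2, tbxta])
    if spec.noise_sd > 0:
        # additive Gaussian on a Poisson-like signal-dependent scale
        sd = spec.noise_sd * np.sqrt(1.0 + voxels)
        voxels = np.clip(voxels + rng.normal(size=voxels.shape) * sd, 0.0, None)
    stack = ImageStack3D(
        voxels.astype(np.float32), spec.voxel_size_um, ("nuclear", "sox2", "tbxta")
    )
    return stack, labels, truth


def _render_ellipsoid(
    centre_um, semi_axes_um, spacing, targets, labels=None, label_id=0
) -> float:
    """Paint a Gaussian-tapered ellipsoid; returns its labelled volume (µm³).

    With ``labels=None`` only the intensity is painted (debris fragments).
    """
    shape = np.asarray(targets[0][0].shape)
    c_vox = centre_um / spacing
    half = 1.4 * semi_axes_um / spacing
    lo = np.maximum(np.floor(c_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(c_vox + half).astype(int) + 1, shape)
    if np.any(lo >= hi):
        return 0.0
    grids = np.meshgrid(
        *[(np.arange(l, h) - cv) * s / a
          for l, h, cv, s, a in zip(lo, hi, c_vox, spacing, semi_axes_um)],
        indexing="ij",
    )
    rho2 = sum(g**2 for g in grids)
    profile = np.exp(-rho2 / (2 * _TAPER_SIGMA**2))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    for vol, amp in targets:
        if amp > 0:
            vol[sl] += amp * profile
    if labels is None:
        return 0.0
    mask = (rho2 <= 1.0) & (labels[sl] == 0)
    labels[sl][mask] = label_id
    return float(mask.sum() * np.prod(spacing))


def _render_debris(centre_um, radius_um, spacing, nuclear, rng) -> None:
    """Pyknotic fragments: 1-3 µm bright blobs scattered near the centre."""
    n_frag = int(rng.integers(3, 7))
    for _ in range(n_frag):
        offset = rng.normal(scale=0.4 * radius_um, size=3)
        frag_r = rng.uniform(0.5, 1.5)  # µm radius -> 1-3 µm diameter
        _render_ellipsoid(
            centre_um + offset, np.full(3, frag_r), spacing,
            targets=((nuclear, 1.5),),
        )


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

_TRACK_KINDS = ("diffusive", "persistent", "ballistic", "confined")


@dataclass
class TrackSimSpec:
    """Parameters of a simulated track ensemble.

    The ground-truth MSD exponent is 1 for diffusive motion, 2 for
    ballistic motion and < 1 for confined motion; persistent motion
    interpolates between 1 and 2 depending on ``persistence``.
    """

    kind: str = "diffusive"
    n_tracks: int = 200
    n_steps: int = 100
    step_sd_um: float = 1.0
    frame_interval_s: float = 30.0
    persistence: float = 0.7
    speed_um_per_frame: float = 1.0
    confinement_radius_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}; use one of {_TRACK_KINDS}")
        if self.n_steps < 10:
            raise ValueError(f"n_steps must be >= 10, got {self.n_steps}")
        if self.n_tracks < 1:
            raise ValueError("n_tracks must be positive")
        if not 0 <= self.persistence <= 1:
            raise ValueError("persistence must be in [0, 1]")


def generate_tracks(spec: TrackSimSpec) -> TrackSet:
    """Simulate 3D tracks at uniform frame intervals.

    * diffusive: i.i.d. Gaussian steps of sd ``step_sd_um`` per axis;
    * ballistic: constant random velocity of magnitude
      ``speed_um_per_frame`` plus additive positional noise of sd
      ``step_sd_um`` per axis (0 for noiseless straight lines);
    * persistent: AR(1)-correlated steps with parameter ``persistence``;
    * confined: diffusive steps reflected at a sphere of radius
      ``confinement_radius_um`` around the start.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_steps
    t = np.arange(n + 1) * spec.frame_interval_s
    frames = np.arange(n + 1)
    true_alpha = {"diffusive": 1.0, "ballistic": 2.0,
                  "persistent": float("nan"), "confined": float("nan")}[spec.kind]
    tracks = []
    for i in range(spec.n_tracks):
        start = rng.uniform(0, 100, size=3)
        if spec.kind == "diffusive":
            steps = rng.normal(scale=spec.step_sd_um, size=(n, 3))
            pos = start + np.concatenate([[np.zeros(3)], np.cumsum(steps, axis=0)])
        elif spec.kind == "ballistic":
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            pos = start + np.outer(frames, direction) * spec.speed_um_per_frame
            if spec.step_sd_um > 0:
                pos = pos + rng.normal(scale=spec.step_sd_um, size=pos.shape)
        elif spec.kind == "persistent":
            steps = np.empty((n, 3))
            steps[0] = rng.normal(scale=spec.step_sd_um, size=3)
            innov_sd = spec.step_sd_um * math.sqrt(max(1 - spec.persistence**2, 0.0))
            for k in range(1, n):
                steps[k] = spec.persistence * steps[k - 1] + rng.normal(
                    scale=innov_sd, size=3
                )
            pos = start + np.concatenate([[np.zeros(3)], np.cumsum(steps, axis=0)])
        else:  # confined
            pos = np.empty((n + 1, 3))
            pos[0] = start
            r_conf = spec.confinement_radius_um
            for k in range(1, n + 1):
                cand = pos[k - 1] + rng.normal(scale=spec.step_sd_um, size=3)
                disp = cand - start
                d = np.linalg.norm(disp)
                if d > r_conf:
                    cand = start + disp / d * (2 * r_conf - d)  # reflect inwards
                    d2 = np.linalg.norm(cand - start)
                    if d2 > r_conf:  # huge step: clamp to the boundary
                        cand = start + (cand - start) / d2 * r_conf
                pos[k] = cand
        tracks.append(
            Track(id=i, frames=frames.copy(), t_s=t.copy(), xyz_um=pos,
                  true_alpha=true_alpha)
        )
    return TrackSet(tracks, {"kind": spec.kind, "true_alpha": true_alpha,
                             "spec": spec})


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def generate_point_clouds(
    n_embryos: int,
    n_points: int,
    transform_ranges: dict | None = None,
    noise_sd_um: float = 0.0,
    seed: int = 0,
) -> tuple[PointCloud, list[tuple[PointCloud, RigidTransform]]]:
    """Reference cloud plus embryo clouds under known rigid transforms.

    Each embryo cloud equals the reference mapped by its recorded
    transform plus isotropic Gaussian jitter of sd ``noise_sd_um``.
    ``transform_ranges`` bounds the draws:
    ``{"rotation_deg": max_angle, "translation_um": max_abs_component}``.
    Returns ``(reference, [(cloud, true_transform), ...])``.
    """
    if n_points < 4:
        raise ValueError(f"n_points must be >= 4, got {n_points}")
    ranges = {"rotation_deg": 30.0, "translation_um": 20.0}
    if transform_ranges:
        ranges.update(transform_ranges)
    rng = np.random.default_rng(seed)
    ref_pts = rng.uniform(0, 100, size=(n_points, 3))
    if np.linalg.matrix_rank(ref_pts - ref_pts.mean(axis=0)) < 3:
        raise ValueError("degenerate reference cloud: points are coplanar")
    reference = PointCloud(ref_pts, embryo_id="reference")
    out = []
    for i in range(n_embryos):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = rng.uniform(0, np.radians(ranges["rotation_deg"]))
        rot = Rotation.from_rotvec(axis * angle).as_matrix()
        trans = rng.uniform(-ranges["translation_um"], ranges["translation_um"], size=3)
        tf = RigidTransform(rot, trans)
        pts = tf.apply(ref_pts)
        if noise_sd_um > 0:
            pts = pts + rng.normal(scale=noise_sd_um, size=pts.shape)
        out.append((PointCloud(pts, embryo_id=f"embryo_{i}"), tf))
    return reference, out


def bcc_lattice(n_cells: int = 4, cell_side: float = 1.0) -> np.ndarray:
    """Points of a body-centred cubic lattice, (n_cells+1)^3 corners plus
    n_cells^3 body centres, conventional cell side ``cell_side``.

    An interior site of this lattice has 8 neighbours at
    ``sqrt(3)/2 * cell_side`` and 6 at ``cell_side``: 14 points within
    any radius strictly between the second and third coordination shells.
    """
    idx = np.arange(n_cells + 1)
    corners = np.stack(np.meshgrid(idx, idx, idx, indexing="ij"), axis=-1).reshape(-1, 3)
    cidx = np.arange(n_cells) + 0.5
    centres = np.stack(np.meshgrid(cidx, cidx, cidx, indexing="ij"), axis=-1).reshape(-1, 3)
    return np.vstack([corners, centres]) * cell_side


# ---------------------------------------------------------------------------
# tail polylines
# ---------------------------------------------------------------------------

def generate_tail_polylines(
    n_somites: int,
    somite_lengths_um,
    sc_profile=None,
    psm_length_um: float = 150.0,
    curvature_sd_deg: float = 5.0,
    seed: int = 0,
) -> tuple[MeasuredPolyline, MeasuredPolyline]:
    """Spinal-cord and paraxial-mesoderm polylines with exact lengths.

    The paraxial-mesoderm polyline has one chord per somite whose length
    reproduces ``somite_lengths_um`` exactly, followed by a PSM stretch
    of total length ``psm_length_um`` (0 to omit it); landmarks sit at
    every somite boundary and at the PSM start/end.  ``sc_profile`` is a
    list of spinal-cord segment lengths (defaults to the somite lengths).
    Headings wander by ``curvature_sd_deg`` per segment so the lines are
    gently curved rather than straight.
    """
    somite_lengths_um = [float(v) for v in somite_lengths_um]
    if len(somite_lengths_um) != n_somites:
        raise ValueError(
            f"n_somites={n_somites} but {len(somite_lengths_um)} somite lengths given"
        )
    if any(v <= 0 for v in somite_lengths_um):
        raise ValueError("somite lengths must be positive")
    rng = np.random.default_rng(seed)

    def _chain(segment_lengths, extra_psm: float) -> MeasuredPolyline:
        pts = [np.zeros(2)]
        heading = 0.0
        landmarks = [0]
        for length in segment_lengths:
            heading += math.radians(rng.normal(scale=curvature_sd_deg))
            pts.append(pts[-1] + length * np.array([math.cos(heading), math.sin(heading)]))
            landmarks.append(len(pts) - 1)
        if extra_psm > 0:
            n_sub = 4
            for _ in range(n_sub):
                heading += math.radians(rng.normal(scale=curvature_sd_deg))
                pts.append(
                    pts[-1] + (extra_psm / n_sub)
                    * np.array([math.cos(heading), math.sin(heading)])
                )
            landmarks.append(len(pts) - 1)
        return MeasuredPolyline(np.asarray(pts), tuple(landmarks))

    pm = _chain(somite_lengths_um, psm_length_um)
    pm.tissue = "paraxial_mesoderm"
    sc_lengths = [float(v) for v in (sc_profile if sc_profile is not None else somite_lengths_um)]
    sc = _chain(sc_lengths, 0.0)
    sc.tissue = "spinal_cord"
    return sc, pm
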