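"""Cell-track motion metrics.

Consumes time-ordered 3D positions per cell (TrackMate/Mastodon-style
CSV exports or in-memory tracks) and derives the statistics used to
classify migratory behaviour on a diffusive-to-directional spectrum:

* the time-averaged mean squared displacement (MSD) and its log-log
  exponent alpha (alpha ~ 1 diffusive, > 1 directional, ~ 2 ballistic);
* a directionality call at a configurable alpha threshold (default 1.1,
  strict);
* corrected straightness (net over path length, scaled by the square
  root of the duration in frames to correct for duration bias);
* mean angular alignment (mean cosine of the turning angle between
  consecutive steps);
* signed dorsoventral displacement and the per-embryo fraction of
  ventrally displaced tracks near a reference point (default cutoff
  60 µm);
* reporter-intensity dynamics (z-scored start intensity and mean
  per-frame intensity change).

Frame gaps of up to two missing frames are accepted on input; lag pairs
spanning a gap are skipped, never interpolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Track",
    "TrackSet",
    "read_tracks",
    "select_tracks",
    "msd_curve",
    "msd_exponent",
    "classify_directional",
    "straightness_corrected",
    "mean_angular_alignment",
    "dv_displacement",
    "ventral_fraction",
    "intensity_dynamics",
    "compute_track_metrics",
]


@dataclass
class Track:
    """One cell's time-ordered samples.

    ``frames`` are integer frame indices (gaps allowed), ``t_s`` the
    matching times in seconds, ``xyz_um`` an ``(n, 3)`` position array.
    """

    id: int
    frames: np.ndarray
    t_s: np.ndarray
    xyz_um: np.ndarray
    intensity: np.ndarray | None = None
    parent_id: int | None = None
    true_alpha: float | None = None  # ground truth, set by simulators

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.xyz_um = np.asarray(self.xyz_um, dtype=float)
        if self.xyz_um.shape != (len(self.frames), 3):
            raise ValueError(
                f"track {self.id}: xyz shape {self.xyz_um.shape} != ({len(self.frames)}, 3)"
            )
        if np.any(np.diff(self.t_s) <= 0):
            raise ValueError(f"track {self.id}: times not strictly increasing")
        if self.intensity is not None:
            self.intensity = np.asarray(self.intensity, dtype=float)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def start_time_s(self) -> float:
        return float(self.t_s[0])


@dataclass
class TrackSet:
    tracks: list[Track] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    def __getitem__(self, i: int) -> Track:
        return self.tracks[i]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for tr in self.tracks:
            for i in range(len(tr)):
                row = {
                    "id": tr.id,
                    "frame": int(tr.frames[i]),
                    "t": tr.t_s[i],
                    "x": tr.xyz_um[i, 2],
                    "y": tr.xyz_um[i, 1],
                    "z": tr.xyz_um[i, 0],
                }
                if tr.intensity is not None:
                    row["intensity"] = tr.intensity[i]
                if tr.parent_id is not None:
                    row["parent_id"] = tr.parent_id
                rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reading exports
# ---------------------------------------------------------------------------

_COLUMN_DIALECTS = {
    "id": ("id", "track_id", "trackid"),
    "t": ("t", "time", "t_s", "position_t"),
    "frame": ("frame",),
    "x": ("x", "position_x", "x_um"),
    "y": ("y", "position_y", "y_um"),
    "z": ("z", "position_z", "z_um"),
    "intensity": ("intensity", "mean_intensity"),
    "parent": ("parent_id", "parent"),
}


def _find_column(df: pd.DataFrame, key: str) -> str | None:
    lower = {c.lower(): c for c in df.columns}
    for cand in _COLUMN_DIALECTS[key]:
        if cand in lower:
            return lower[cand]
    return None


def read_tracks(
    source: str | Path | pd.DataFrame,
    max_frame_gap: int = 2,
    frame_interval_s: float | None = None,
) -> TrackSet:
    """Read a track table into a :class:`TrackSet`.

    Accepts the generic ``id/t/x/y/z`` layout and the common tracker
    export layout (``TRACK_ID``, ``POSITION_X/Y/Z``, ``POSITION_T`` or
    ``FRAME``), case-insensitively; an intensity column and a parent
    (division-linkage) column are carried through when present.
    Non-numeric header rows, as emitted by some exporters, are dropped.

    Tracks with non-monotone times raise, as do frame gaps of more than
    ``max_frame_gap`` missing frames (two, matching the linking setting
    the tables come from).
    """
    if isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = source.copy()
    if df.empty:
        return TrackSet([])

    id_col = _find_column(df, "id")
    t_col = _find_column(df, "t")
    frame_col = _find_column(df, "frame")
    xyz_cols = [_find_column(df, k) for k in ("x", "y", "z")]
    missing = [
        name
        for name, col in zip(("id", "time/frame", "x", "y", "z"),
                             (id_col, t_col or frame_col, *xyz_cols))
        if col is None
    ]
    if missing:
        raise ValueError(f"track table missing mandatory column(s): {', '.join(missing)}")
    int_col = _find_column(df, "intensity")
    par_col = _find_column(df, "parent")

    # drop exporter unit/header rows that are not numeric
    num_cols = [c for c in (id_col, t_col, frame_col, *xyz_cols, int_col) if c]
    for c in num_cols:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    df = df.dropna(subset=[c for c in (id_col, *xyz_cols) if c])

    # establish frame indices
    if frame_col is not None:
        df["_frame"] = df[frame_col].round().astype(int)
        if t_col is not None:
            df["_t"] = df[t_col].astype(float)
        else:
            dt = frame_interval_s if frame_interval_s else 1.0
            df["_t"] = df["_frame"] * dt
    else:
        times = np.sort(df[t_col].unique())
        diffs = np.diff(times)
        diffs = diffs[diffs > 0]
        dt = frame_interval_s or (float(diffs.min()) if diffs.size else 1.0)
        df["_t"] = df[t_col].astype(float)
        df["_frame"] = np.round(df["_t"] / dt).astype(int)

    tracks = []
    for tid, grp in df.groupby(id_col, sort=True):
        # samples must arrive time-ordered within each track
        if np.any(np.diff(grp["_t"].to_numpy()) <= 0):
            raise ValueError(f"track {tid}: non-monotone times")
        t = grp["_t"].to_numpy()
        gaps = np.diff(grp["_frame"].to_numpy()) - 1
        if gaps.size and gaps.max() > max_frame_gap:
            raise ValueError(
                f"track {tid}: frame gap of {int(gaps.max())} missing frames "
                f"exceeds the permitted {max_frame_gap}"
            )
        xyz = np.column_stack(
            [grp[xyz_cols[2]].to_numpy(), grp[xyz_cols[1]].to_numpy(), grp[xyz_cols[0]].to_numpy()]
        )  # stored (z, y, x)
        parent = None
        if par_col is not None and not grp[par_col].isna().all():
            parent = int(pd.to_numeric(grp[par_col], errors="coerce").dropna().iloc[0])
        tracks.append(
            Track(
                id=int(tid),
                frames=grp["_frame"].to_numpy(),
                t_s=t,
                xyz_um=xyz,
                intensity=grp[int_col].to_numpy() if int_col else None,
                parent_id=parent,
            )
        )
    return TrackSet(tracks)


def select_tracks(
    tracks: TrackSet,
    start_window_s: tuple[float, float] = (0.0, 600.0),
    min_length: int = 10,
) -> TrackSet:
    """Keep tracks starting within a time window and long enough to fit.

    The default window is the first 10 minutes of the recording.
    """
    lo, hi = start_window_s
    kept = [t for t in tracks if lo <= t.start_time_s <= hi and len(t) >= min_length]
    return TrackSet(kept, dict(tracks.metadata))


# ---------------------------------------------------------------------------
# MSD
# ---------------------------------------------------------------------------

def msd_curve(track: Track, max_lag_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged MSD over frame lags 1..floor(max_lag_fraction*(n-1)).

    ``MSD(tau) = mean over t of ||r(t+tau) - r(t)||^2`` using every
    available pair; pairs spanning missing frames are skipped.  Returns
    ``(lags_frames, msd_um2)``; lags with no available pair carry NaN.
    """
    n = len(track)
    if n < 10:
        raise ValueError(f"track {track.id}: need >= 10 samples for an MSD curve, have {n}")
    max_lag = int(math.floor(max_lag_fraction * (n - 1)))
    max_lag = max(max_lag, 1)
    f0 = track.frames - track.frames[0]
    index = {int(f): i for i, f in enumerate(f0)}
    lags = np.arange(1, max_lag + 1)
    msd = np.full(max_lag, np.nan)
    for k, tau in enumerate(lags):
        d2 = [
            np.sum((track.xyz_um[index[f + tau]] - track.xyz_um[i]) ** 2)
            for f, i in index.items()
            if (f + tau) in index
        ]
        if d2:
            msd[k] = float(np.mean(d2))
    return lags, msd


def msd_exponent(lags: np.ndarray, msd: np.ndarray) -> tuple[float, float]:
    """Least-squares slope of log MSD vs log lag, with its R^2.

    Lags with zero or undefined MSD are dropped; fewer than three
    remaining points make the exponent undefined (NaN, NaN).
    """
    lags = np.asarray(lags, dtype=float)
    msd = np.asarray(msd, dtype=float)
    ok = np.isfinite(msd) & (msd > 0)
    if ok.sum() < 3:
        return (float("nan"), float("nan"))
    lx, ly = np.log(lags[ok]), np.log(msd[ok])
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return (float(slope), float(r2))


def track_alpha(track: Track, max_lag_fraction: float = 0.5) -> tuple[float, float]:
    """Convenience: fit the MSD exponent of a single track."""
    return msd_exponent(*msd_curve(track, max_lag_fraction))


def classify_directional(alpha: float, threshold: float = 1.1) -> bool | None:
    """Directional iff alpha strictly exceeds the threshold.

    Undefined alpha (NaN) propagates as ``None``.
    """
    if alpha is None or (isinstance(alpha, float) and math.isnan(alpha)):
        return None
    return bool(alpha > threshold)


# ---------------------------------------------------------------------------
# other per-track statistics
# ---------------------------------------------------------------------------

def straightness_corrected(track: Track) -> float:
    """Net-over-path straightness scaled by sqrt(duration in frames).

    The sqrt factor corrects the duration bias of plain straightness
    (long random tracks look less straight).  A stationary track (zero
    path length) returns 0 by convention.
    """
    if len(track) < 2:
        raise ValueError(f"track {track.id}: need >= 2 samples")
    steps = np.diff(track.xyz_um, axis=0)
    path = float(np.sum(np.linalg.norm(steps, axis=1)))
    if path == 0:
        return 0.0
    net = float(np.linalg.norm(track.xyz_um[-1] - track.xyz_um[0]))
    duration = float(track.frames[-1] - track.frames[0])
    return net / path * math.sqrt(duration)


def mean_angular_alignment(track: Track) -> float:
    """Mean cosine of the turning angle between consecutive steps.

    +1 for perfectly straight motion, -1 for perfect reversals, ~0 for
    an isotropic random walk.  Zero-length steps are skipped; if every
    step has zero length the value is undefined (NaN).
    """
    if len(track) < 3:
        raise ValueError(f"track {track.id}: need >= 3 samples")
    steps = np.diff(track.xyz_um, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    cosines = []
    for i in range(len(steps) - 1):
        if norms[i] == 0 or norms[i + 1] == 0:
            continue
        cosines.append(float(np.dot(steps[i], steps[i + 1]) / (norms[i] * norms[i + 1])))
    return float(np.mean(cosines)) if cosines else float("nan")


def dv_displacement(track: Track, dv_axis: Sequence[float]) -> float:
    """Signed end-minus-start displacement along the DV axis (ventral +)."""
    axis = np.asarray(dv_axis, dtype=float)
    if not math.isclose(float(np.linalg.norm(axis)), 1.0, rel_tol=1e-6):
        raise ValueError(f"dv_axis must be a unit vector, |axis| = {np.linalg.norm(axis)}")
    return float(np.dot(track.xyz_um[-1] - track.xyz_um[0], axis))


def ventral_fraction(
    tracks: Iterable[Track],
    dv_axis: Sequence[float],
    reference_point_um: Sequence[float],
    cutoff_um: float = 60.0,
) -> tuple[float, int]:
    """Fraction of ventrally displaced tracks starting near a reference.

    Eligible tracks start strictly within ``cutoff_um`` of the reference
    point (e.g. the ablation centre).  Returns ``(fraction, n_eligible)``;
    no eligible tracks gives ``(nan, 0)``.
    """
    ref = np.asarray(reference_point_um, dtype=float)
    disp = [
        dv_displacement(t, dv_axis)
        for t in tracks
        if np.linalg.norm(t.xyz_um[0] - ref) < cutoff_um
    ]
    if not disp:
        return (float("nan"), 0)
    return (float(np.mean(np.asarray(disp) > 0)), len(disp))


def intensity_dynamics(
    track: Track, embryo_mean: float, embryo_sd: float
) -> tuple[float, float]:
    """Z-scored start intensity and mean per-frame intensity change.

    ``start_z = (I_first - mean) / sd``; the mean change is the mean of
    successive intensity differences, equal to
    ``(I_last - I_first) / (n - 1)`` for gap-free tracks.  A
    single-sample track has undefined change (NaN).
    """
    if track.intensity is None:
        raise ValueError(f"track {track.id}: no intensity data")
    if embryo_sd <= 0:
        raise ValueError("embryo intensity sd must be positive")
    start_z = float((track.intensity[0] - embryo_mean) / embryo_sd)
    if len(track) < 2:
        return (start_z, float("nan"))
    change = float(np.mean(np.diff(track.intensity)))
    return (start_z, change)


# ---------------------------------------------------------------------------
# batch metrics
# ---------------------------------------------------------------------------

def compute_track_metrics(
    tracks: TrackSet,
    dv_axis: Sequence[float] | None = None,
    reference_point_um: Sequence[float] | None = None,
    alpha_threshold: float = 1.1,
    max_lag_fraction: float = 0.5,
    embryo_intensity_stats: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-track metrics table for a whole track set.

    Columns: alpha, fit_r2, straightness_corrected,
    mean_angular_alignment, directional, and — when axis/reference/
    intensity inputs are supplied — dv_displacement_um,
    start_distance_um, start_intensity_z, mean_intensity_change.
    """
    rows = []
    for tr in tracks:
        try:
            alpha, r2 = track_alpha(tr, max_lag_fraction)
        except ValueError:
            alpha, r2 = float("nan"), float("nan")
        row: dict = {
            "id": tr.id,
            "n_samples": len(tr),
            "alpha": alpha,
            "fit_r2": r2,
            "straightness_corrected": straightness_corrected(tr) if len(tr) >= 2 else float("nan"),
            "mean_angular_alignment": mean_angular_alignment(tr) if len(tr) >= 3 else float("nan"),
            "directional": classify_directional(alpha, alpha_threshold),
        }
        if dv_axis is not None:
            row["dv_displacement_um"] = dv_displacement(tr, dv_axis)
        if reference_point_um is not None:
            row["start_distance_um"] = float(
                np.linalg.norm(tr.xyz_um[0] - np.asarray(reference_point_um, dtype=float))
            )
        if embryo_intensity_stats is not None and tr.intensity is not None:
            z, change = intensity_dynamics(tr, *embryo_intensity_stats)
            row["start_intensity_z"] = z
            row["mean_intensity_change"] = change
        rows.append(row)
    return pd.DataFrame(rows)
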