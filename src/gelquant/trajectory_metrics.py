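"""Per-cell migration statistics from particle-tracking exports.

Four measures are computed for every tracked cell, following common
single-particle-tracking practice for cells embedded in 3D collagen:

* mean instantaneous speed between consecutive observed frames (μm/min),
* a static/motile classification from total path length against a
  threshold of 1.5 cell diameters,
* the anomalous-diffusion exponent α, i.e. the log-log slope of the
  time-averaged mean-squared displacement (MSD) versus time lag
  (α = 1 Brownian, α < 1 subdiffusive/confined, α > 1 superdiffusive),
* directional persistence, net displacement divided by total path length.

Per-cell metrics are then aggregated into per-condition cohort summaries
(percent static, mean speed, mean α, percent persistence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Trajectory",
    "MSDCurve",
    "TrackMetrics",
    "AnalysisParams",
    "CohortSummary",
    "read_tracks",
    "mean_speed",
    "path_length",
    "net_displacement",
    "persistence",
    "classify_static",
    "msd_curve",
    "alpha_exponent",
    "compute_track_metrics",
    "summarize_cohort",
]


@dataclass
class Trajectory:
    """One cell's time-ordered positions.

    Parameters
    ----------
    track_id:
        Identifier carried through to the metrics table.
    frame_interval:
        Time between consecutive frames, in minutes.
    positions:
        ``(n, d)`` array of positions in μm, ``d`` in {2, 3}.
    frames:
        Strictly increasing integer frame indices; gaps mark frames in
        which the tracker lost the cell.
    """

    track_id: str
    frame_interval: float
    positions: np.ndarray
    frames: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] not in (2, 3):
            raise ValueError("positions must be an (n, 2) or (n, 3) array")
        if len(self.positions) < 2:
            raise ValueError("a trajectory needs at least 2 positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.frames is None:
            self.frames = np.arange(len(self.positions))
        self.frames = np.asarray(self.frames, dtype=int)
        if len(self.frames) != len(self.positions):
            raise ValueError("frames and positions disagree in length")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_points(self) -> int:
        return len(self.positions)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]

    @property
    def times_min(self) -> np.ndarray:
        """Observation times in minutes, relative to the first frame."""
        return (self.frames - self.frames[0]) * self.frame_interval


@dataclass
class MSDCurve:
    """Time-averaged mean-squared displacement per time lag."""

    lags_min: np.ndarray  # time lags, minutes, strictly increasing
    msd_um2: np.ndarray  # μm² per lag
    n_pairs: np.ndarray  # displacement pairs contributing per lag

    def __post_init__(self) -> None:
        self.lags_min = np.asarray(self.lags_min, dtype=float)
        self.msd_um2 = np.asarray(self.msd_um2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)

    @property
    def is_defined(self) -> bool:
        return len(self.lags_min) > 0


@dataclass
class AnalysisParams:
    """Tunable constants of the trajectory pipeline.

    ``static_threshold`` defaults to 1.5 × the 50 μm nominal cell
    diameter used for tracking, i.e. 75 μm of total path over the
    acquisition.  ``max_lag_fraction`` restricts the MSD fit to short
    lags where the time average over a single short track is reliable.
    """

    cell_diameter: float = 50.0  # μm
    static_threshold: float = field(default=None)  # type: ignore[assignment]
    min_track_frames: int = 10
    max_lag_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.static_threshold is None:
            self.static_threshold = 1.5 * self.cell_diameter
        if self.static_threshold <= 0:
            raise ValueError("static_threshold must be positive")
        if not 0 < self.max_lag_fraction <= 0.5:
            raise ValueError("max_lag_fraction must be in (0, 0.5]")


@dataclass
class TrackMetrics:
    """The four migration measures for a single track."""

    track_id: str
    mean_speed: float  # μm/min
    path_length: float  # μm, sum of step lengths
    net_displacement: float  # μm, |end - start|
    persistence: float  # in [0, 1]
    alpha: float  # MSD log-log slope; NaN when undefined
    is_static: bool


@dataclass
class CohortSummary:
    """Per-condition aggregate of track metrics."""

    condition_label: str
    n_tracks: int
    percent_static: float
    mean_instant_speed: float  # μm/min
    mean_alpha: float  # NaN when no track has a defined α
    percent_persistence: float  # 100 × mean persistence


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_CSV_REQUIRED = ("track_id", "frame", "x_um", "y_um")


def read_tracks(
    path: str | Path,
    dialect: str = "csv",
    frame_interval: float = 10.0,
) -> list[Trajectory]:
    """Read tracker output into trajectories.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``"csv"`` for the plain table (columns ``track_id``, ``frame``,
        ``x_um``, ``y_um``, optional ``z_um``) or ``"trackmate_xml"``
        for the TrackMate track export (``<Tracks>`` with ``<particle>``
        / ``<detection>`` elements).
    frame_interval:
        Minutes per frame for the CSV dialect; the XML dialect carries
        its own ``frameInterval`` attribute and ignores this argument
        when that attribute is present.

    Single-point tracks are dropped with a warning (two positions are
    the minimum for any of the migration measures).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_tracks_csv(path, frame_interval)
    if dialect == "trackmate_xml":
        return _read_trackmate_xml(path, frame_interval)
    raise ValueError(f"unknown dialect: {dialect!r}")


def _read_tracks_csv(path: Path, frame_interval: float) -> list[Trajectory]:
    df = pd.read_csv(path)
    missing = [c for c in _CSV_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    coord_cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in df.columns else [])
    for col in coord_cols + ["frame"]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {bad[0]}"
            )
        df[col] = numeric
    trajectories = []
    for track_id, group in df.groupby("track_id", sort=False):
        group = group.sort_values("frame")
        if len(group) < 2:
            warnings.warn(
                f"track {track_id!r} has fewer than 2 points; skipped",
                stacklevel=2,
            )
            continue
        trajectories.append(
            Trajectory(
                track_id=str(track_id),
                frame_interval=frame_interval,
                positions=group[coord_cols].to_numpy(dtype=float),
                frames=group["frame"].to_numpy(dtype=int),
            )
        )
    return trajectories


def _read_trackmate_xml(path: Path, frame_interval: float) -> list[Trajectory]:
    tree = etree.parse(str(path))
    root = tree.getroot()
    if root.tag != "Tracks":
        raise ValueError(f"{path}: expected <Tracks> root, got <{root.tag}>")
    interval = float(root.get("frameInterval", frame_interval))
    trajectories = []
    for i, particle in enumerate(root.iterfind("particle")):
        rows = []
        for det in particle.iterfind("detection"):
            try:
                t = int(float(det.get("t")))
                x = float(det.get("x"))
                y = float(det.get("y"))
                z = float(det.get("z", "0"))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"{path}: malformed <detection> in particle {i}: {exc}"
                ) from exc
            rows.append((t, x, y, z))
        if len(rows) < 2:
            warnings.warn(f"particle {i} has fewer than 2 detections; skipped",
                          stacklevel=2)
            continue
        rows.sort(key=lambda r: r[0])
        arr = np.array(rows, dtype=float)
        positions = arr[:, 1:4]
        if np.allclose(positions[:, 2], 0.0):
            positions = positions[:, :2]  # planar export
        trajectories.append(
            Trajectory(
                track_id=f"Track_{i}",
                frame_interval=interval,
                positions=positions,
                frames=arr[:, 0].astype(int),
            )
        )
    return trajectories


# ---------------------------------------------------------------------------
# Per-track measures
# ---------------------------------------------------------------------------


def _step_lengths(traj: Trajectory) -> np.ndarray:
    return np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)


def path_length(traj: Trajectory) -> float:
    """Total path length in μm (sum of step lengths between observations)."""
    return float(_step_lengths(traj).sum())


def net_displacement(traj: Trajectory) -> float:
    """Straight-line distance from first to last position, μm."""
    return float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))


def mean_speed(traj: Trajectory) -> float:
    """Mean instantaneous speed in μm/min.

    Each consecutive pair of *observed* frames contributes one speed,
    step length divided by the actual elapsed time — so a step spanning
    a tracking gap of k frames is divided by k·frame_interval rather
    than being mistaken for a single-frame jump.
    """
    steps = _step_lengths(traj)
    dt = np.diff(traj.frames) * traj.frame_interval
    return float(np.mean(steps / dt))


def persistence(traj: Trajectory) -> float:
    """Net displacement over total path length, in [0, 1].

    A path of zero total length has no maintained direction and is
    assigned persistence 0.
    """
    total = path_length(traj)
    if total == 0.0:
        return 0.0
    return net_displacement(traj) / total


def classify_static(traj: Trajectory, params: AnalysisParams) -> bool:
    """True when total path length is strictly below the static threshold."""
    return path_length(traj) < params.static_threshold


def msd_curve(
    traj: Trajectory,
    params: AnalysisParams | None = None,
    max_lag: int | None = None,
    min_pairs: int = 3,
) -> MSDCurve:
    """Time-averaged MSD over increasing time lags.

    For each lag of ℓ frames (ℓ = 1 … ``max_lag``, by default
    ``floor(max_lag_fraction · n_observations)``), the squared
    displacement is averaged over every pair of observed frames exactly
    ℓ frames apart; pairs straddling a tracking gap simply do not exist
    at that lag.  Lags with fewer than ``min_pairs`` contributing pairs
    are dropped (``min_pairs=1`` keeps every computable lag, e.g. for
    very short tracks).  An empty curve (``is_defined`` False) marks
    tracks too short to support the estimate.
    """
    params = params or AnalysisParams()
    n = traj.n_points
    if n < 3:
        return MSDCurve(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    if max_lag is None:
        max_lag = int(np.floor(params.max_lag_fraction * n))
    max_lag = max(max_lag, 0)

    # dense (frame-indexed) position array with NaN at missing frames
    span = traj.frames[-1] - traj.frames[0] + 1
    dense = np.full((span, traj.ndim), np.nan)
    dense[traj.frames - traj.frames[0]] = traj.positions

    lags, msds, counts = [], [], []
    for lag in range(1, min(max_lag, span - 1) + 1):
        disp = dense[lag:] - dense[:-lag]
        sq = np.einsum("ij,ij->i", disp, disp)
        valid = np.isfinite(sq)
        if valid.sum() < min_pairs:
            continue
        lags.append(lag * traj.frame_interval)
        msds.append(sq[valid].mean())
        counts.append(int(valid.sum()))
    return MSDCurve(np.array(lags), np.array(msds), np.array(counts))


def alpha_exponent(msd: MSDCurve) -> float:
    """Anomalous-diffusion exponent: OLS slope of log(MSD) vs log(lag).

    Zero or negative MSD values cannot enter the log fit and are
    dropped; NaN is returned when fewer than 3 points remain.
    """
    if not msd.is_defined:
        return float("nan")
    keep = msd.msd_um2 > 0
    if keep.sum() < 3:
        return float("nan")
    slope, _ = np.polyfit(np.log(msd.lags_min[keep]), np.log(msd.msd_um2[keep]), 1)
    return float(slope)


def compute_track_metrics(
    traj: Trajectory,
    params: AnalysisParams | None = None,
) -> TrackMetrics:
    """All four migration measures for one track.

    α is reported as NaN (not an exception) for tracks shorter than
    ``min_track_frames`` or without enough positive MSD points, so a
    batch containing static or short tracks still completes.
    """
    params = params or AnalysisParams()
    if traj.n_points >= params.min_track_frames:
        alpha = alpha_exponent(msd_curve(traj, params))
    else:
        alpha = float("nan")
    return TrackMetrics(
        track_id=traj.track_id,
        mean_speed=mean_speed(traj),
        path_length=path_length(traj),
        net_displacement=net_displacement(traj),
        persistence=persistence(traj),
        alpha=alpha,
        is_static=classify_static(traj, params),
    )


def summarize_cohort(
    metrics: Sequence[TrackMetrics],
    condition_label: str,
) -> CohortSummary:
    """Aggregate per-track metrics into one condition row.

    Mean speed and persistence average over all tracks (static cells
    included); mean α averages over tracks where the exponent is
    defined and is NaN when none is.
    """
    if len(metrics) == 0:
        raise ValueError("cannot summarize an empty cohort")
    alphas = np.array([m.alpha for m in metrics])
    defined = np.isfinite(alphas)
    return CohortSummary(
        condition_label=condition_label,
        n_tracks=len(metrics),
        percent_static=100.0 * np.mean([m.is_static for m in metrics]),
        mean_instant_speed=float(np.mean([m.mean_speed for m in metrics])),
        mean_alpha=float(alphas[defined].mean()) if defined.any() else float("nan"),
        percent_persistence=100.0 * float(np.mean([m.persistence for m in metrics])),
    )


def metrics_table(metrics: Sequence[TrackMetrics]) -> pd.DataFrame:
    """Per-track metrics as a DataFrame (one row per track)."""
    return pd.DataFrame([vars(m) for m in metrics])
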