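"""Cell-migration track metrics and neurosphere radial outgrowth.

A track is a time-ordered sequence of (t, x, y) samples for one cell.  Five
motility statistics are derived per track:

* displacement      -- Euclidean distance from first to last position, um
* duration          -- elapsed time, min
* path length       -- sum of per-frame Euclidean displacements, um
  (identical to the cumulative distance reported by tracking tools)
* track velocity    -- displacement / duration, um/min
* mean instantaneous speed -- mean of per-interval speeds, um/min
* persistence       -- displacement / path length, dimensionless in [0, 1]
  (1 for straight-line motion; 0 by convention for a stationary track)

Missing frames are treated as single longer intervals, never interpolated,
which keeps the statistics well defined for manually curated tracks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "t_min", "x_um", "y_um"]


@dataclass
class Track:
    """One cell's trajectory: strictly increasing times, positions in um."""

    track_id: int | str
    t_min: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    frame: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (self.t_min.shape == self.x_um.shape == self.y_um.shape):
            raise ValueError("t, x, y must have equal length")
        if self.t_min.size < 2:
            raise ValueError("a track needs at least 2 samples")
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.t_min.size


@dataclass
class TrackMetrics:
    track_id: int | str
    displacement_um: float
    duration_min: float
    path_length_um: float
    velocity_um_min: float
    mean_instantaneous_speed_um_min: float
    cumulative_distance_um: float
    persistence: float
    stationary: bool


def track_metrics(track: Track) -> TrackMetrics:
    """The five motility statistics of one track (closed-form, no smoothing)."""
    dx = np.diff(track.x_um)
    dy = np.diff(track.y_um)
    dt = np.diff(track.t_min)
    step = np.hypot(dx, dy)

    displacement = float(np.hypot(track.x_um[-1] - track.x_um[0],
                                  track.y_um[-1] - track.y_um[0]))
    duration = float(track.t_min[-1] - track.t_min[0])
    path = float(step.sum())
    stationary = path == 0.0
    persistence = 0.0 if stationary else displacement / path
    return TrackMetrics(
        track_id=track.track_id,
        displacement_um=displacement,
        duration_min=duration,
        path_length_um=path,
        velocity_um_min=displacement / duration,
        mean_instantaneous_speed_um_min=float(np.mean(step / dt)),
        cumulative_distance_um=path,
        persistence=persistence,
        stationary=stationary,
    )


def metrics_table(tracks: list[Track]) -> pd.DataFrame:
    """Per-track metrics as a DataFrame, one row per track."""
    rows = [track_metrics(t).__dict__ for t in tracks]
    return pd.DataFrame(rows)


def radial_outgrowth(initial_radius_um: float, radii_um) -> np.ndarray:
    """Neurosphere radial outgrowth normalized to the initial sphere radius.

    ``radii_um`` holds the radius of the furthest migrated cell at each
    imaged timepoint; the result is the elementwise ratio to the initial
    radius (1.0 means no outgrowth)."""
    if initial_radius_um <= 0:
        raise ValueError("initial radius must be positive")
    radii = np.asarray(radii_um, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    return radii / initial_radius_um


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_ALIASES = {
    "track_id": {"track_id", "track", "track no", "track n", "trackid", "id"},
    "frame": {"frame", "slice", "slice n", "frame n", "t_index"},
    "t_min": {"t_min", "t", "time", "time_min", "t (min)"},
    "x_um": {"x_um", "x", "x (um)", "x [um]", "x_px", "x (px)"},
    "y_um": {"y_um", "y", "y (um)", "y [um]", "y_px", "y (px)"},
}


def _map_columns(columns) -> dict[str, str] | None:
    lowered = {c.strip().lower(): c for c in columns}
    mapping = {}
    for canon, names in _ALIASES.items():
        hit = next((lowered[n] for n in names if n in lowered), None)
        if hit is None and canon in ("track_id", "x_um", "y_um"):
            return None
        if hit is not None:
            mapping[canon] = hit
    return mapping


def read_tracks_csv(path, pixel_size_um: float | None = None,
                    frame_interval_min: float | None = None) -> list[Track]:
    """Read tracks from CSV.

    The native dialect has the header ``track_id,frame,t_min,x_um,y_um``.  A
    tracking-tool export dialect is also accepted: up to 3 preamble rows
    before the header, coordinate columns in pixels (converted with
    ``pixel_size_um``), and a missing time column reconstructed from the
    frame index and ``frame_interval_min``.
    """
    df = None
    for skip in range(4):
        try:
            cand = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
        except Exception:
            continue
        mapping = _map_columns(cand.columns)
        if mapping is not None:
            df = cand.rename(columns={v: k for k, v in mapping.items()})
            break
    if df is None:
        raise ValueError(f"{path}: no recognizable track header in the first 4 rows")

    if "t_min" not in df.columns:
        if "frame" not in df.columns or frame_interval_min is None:
            raise ValueError("no time column; provide frame_interval_min to "
                             "reconstruct time from the frame index")
        df["t_min"] = df["frame"].astype(float) * frame_interval_min
    if pixel_size_um is not None:
        df["x_um"] = df["x_um"].astype(float) * pixel_size_um
        df["y_um"] = df["y_um"].astype(float) * pixel_size_um

    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("t_min")
        tracks.append(Track(
            track_id=tid,
            t_min=sub["t_min"].to_numpy(float),
            x_um=sub["x_um"].to_numpy(float),
            y_um=sub["y_um"].to_numpy(float),
            frame=sub["frame"].to_numpy() if "frame" in sub.columns else None,
        ))
    return tracks


def write_tracks_csv(tracks: list[Track], path) -> None:
    """Write tracks in the native dialect ``track_id,frame,t_min,x_um,y_um``."""
    frames = []
    for t in tracks:
        frame = t.frame if t.frame is not None else np.arange(t.n_samples)
        frames.append(pd.DataFrame({
            "track_id": t.track_id, "frame": frame,
            "t_min": t.t_min, "x_um": t.x_um, "y_um": t.y_um,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")
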