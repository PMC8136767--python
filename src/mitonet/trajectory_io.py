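"""Trajectory containers and I/O for particle-tracking data.

Mitochondrial trajectories arrive either as TrackMate XML exports or as a
plain track CSV (``track_id,frame,time_s,x_um,y_um``).  Both are parsed into
a :class:`TrackSet`, the common currency between experiment, simulation and
every statistics module.  Coordinates are stored in micrometres; pixel data
must pass through :func:`apply_pixel_scale` first, because every distance
threshold used downstream (1.6 um colocalization, 4 um boundary region) is
metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

#: Canonical column order of the track CSV dialect.
COLUMNS = ["track_id", "frame", "time_s", "x_um", "y_um"]

#: Tolerance (um) for points nominally outside the declared region
#: (tracker jitter near the crop boundary).
REGION_TOLERANCE_UM = 0.5


class TrackParseError(ValueError):
    """A track file could not be parsed."""


class NoTracksError(TrackParseError):
    """The file contains no tracks."""


@dataclass
class TrackSet:
    """A collection of time-stamped 2D trajectories with identity.

    Parameters
    ----------
    data
        Long-format table with columns ``track_id, frame, time_s, x_um,
        y_um``; one row per organelle per frame.
    frame_interval_s
        Seconds between consecutive frames.  Required metadata: the
        experimental videos do not carry it implicitly, and all time-based
        statistics use ``time_s``, never frame counts.
    region_width_um, region_height_um
        Bounding region of the field of view / simulation cell, if known.
    provenance
        Free-text label (experiment id, preset name, fixture kind).
    max_gap
        Largest number of skipped frames tolerated inside a trajectory
        (default 2, matching typical gap-closing tracker settings).
    """

    data: pd.DataFrame
    frame_interval_s: float = 1.0
    region_width_um: float | None = None
    region_height_um: float | None = None
    provenance: str = ""
    max_gap: int = 2

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise TrackParseError(f"TrackSet missing columns: {missing}")
        df = df.loc[:, COLUMNS].copy()
        df["frame"] = df["frame"].astype(np.int64)
        for c in ("time_s", "x_um", "y_um"):
            df[c] = df[c].astype(float)
        df = df.sort_values(["track_id", "frame"], kind="mergesort").reset_index(drop=True)
        self.data = df
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        if not np.isfinite(df[["x_um", "y_um", "time_s"]].to_numpy()).all():
            raise TrackParseError("non-finite coordinates or times in TrackSet")
        if (df["frame"] < 0).any():
            raise TrackParseError("negative frame indices")
        dup = df.duplicated(subset=["track_id", "frame"])
        if dup.any():
            pair = df.loc[dup.idxmax(), ["track_id", "frame"]].tolist()
            raise TrackParseError(f"duplicate (track_id, frame) entry: {pair}")
        gaps = df.groupby("track_id", sort=False)["frame"].diff().dropna()
        if (gaps <= 0).any():
            raise TrackParseError("frame indices must strictly increase within a track")
        if (gaps > self.max_gap + 1).any():
            raise TrackParseError(
                f"trajectory gap exceeds max_gap={self.max_gap} skipped frames"
            )
        if self.region_width_um is not None:
            lo, hi = -REGION_TOLERANCE_UM, self.region_width_um + REGION_TOLERANCE_UM
            if ((df["x_um"] < lo) | (df["x_um"] > hi)).any():
                raise TrackParseError("x coordinate outside declared region")
        if self.region_height_um is not None:
            lo, hi = -REGION_TOLERANCE_UM, self.region_height_um + REGION_TOLERANCE_UM
            if ((df["y_um"] < lo) | (df["y_um"] > hi)).any():
                raise TrackParseError("y coordinate outside declared region")

    # -- convenience ---------------------------------------------------
    @property
    def track_ids(self) -> list:
        return list(dict.fromkeys(self.data["track_id"]))

    @property
    def n_tracks(self) -> int:
        return self.data["track_id"].nunique()

    @property
    def frames(self) -> np.ndarray:
        """Sorted unique frame indices present in the data."""
        return np.sort(self.data["frame"].unique())

    @property
    def duration_s(self) -> float:
        if len(self.data) == 0:
            return 0.0
        return float(self.data["time_s"].max() - self.data["time_s"].min())

    def trajectories(self):
        """Yield ``(track_id, frame-ordered DataFrame)`` per trajectory."""
        for tid, g in self.data.groupby("track_id", sort=False):
            yield tid, g

    def positions_at(self, frame: int) -> pd.DataFrame:
        """Rows of all organelles present in one frame."""
        return self.data[self.data["frame"] == frame]

    def time_window(self, window_s: float) -> "TrackSet":
        """Restrict to frames with ``time_s`` within ``[t0, t0 + window_s]``."""
        if len(self.data) == 0:
            return replace(self, data=self.data.copy())
        t0 = self.data["time_s"].min()
        sub = self.data[self.data["time_s"] <= t0 + window_s].copy()
        return replace(self, data=sub)

    def __eq__(self, other) -> bool:  # identity = same points + metadata
        if not isinstance(other, TrackSet):
            return NotImplemented
        a = self.data.sort_values(["track_id", "frame"]).reset_index(drop=True)
        b = other.data.sort_values(["track_id", "frame"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        if list(map(str, a["track_id"])) != list(map(str, b["track_id"])):
            return False
        num = ["frame", "time_s", "x_um", "y_um"]
        return bool(
            np.allclose(a[num].to_numpy(float), b[num].to_numpy(float),
                        rtol=0, atol=1e-9)
            and np.isclose(self.frame_interval_s, other.frame_interval_s)
        )


def empty_trackset(frame_interval_s: float = 1.0, **meta) -> TrackSet:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                       zip(COLUMNS, [object, np.int64, float, float, float])})
    return TrackSet(df, frame_interval_s=frame_interval_s, **meta)


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------

def read_track_csv(path, frame_interval_s: float = 1.0, **meta) -> TrackSet:
    """Read the plain track CSV dialect.

    Mandatory columns: ``track_id, frame, x_um, y_um``; ``time_s`` is
    optional and filled as ``frame * frame_interval_s`` when absent.
    Row order is irrelevant; the result is grouped by track and frame.
    """
    df = pd.read_csv(path)
    mandatory = {"track_id", "frame", "x_um", "y_um"}
    missing = sorted(mandatory - set(df.columns))
    if missing:
        raise TrackParseError(f"track CSV missing mandatory columns: {missing}")
    if "time_s" not in df.columns or df["time_s"].isna().all():
        df["time_s"] = df["frame"].astype(float) * frame_interval_s
    elif df["time_s"].isna().any():
        fill = df["frame"].astype(float) * frame_interval_s
        df["time_s"] = df["time_s"].fillna(fill)
    return TrackSet(df, frame_interval_s=frame_interval_s, **meta)


def write_track_csv(tracks: TrackSet, path) -> None:
    """Write the CSV dialect; round-trips losslessly through read_track_csv.

    Floats are written at full repr precision so write/read reproduces the
    coordinates bit-for-bit.
    """
    tracks.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# TrackMate XML
# ---------------------------------------------------------------------------

def parse_trackmate_xml(path, frame_interval_s: float = 1.0, **meta) -> TrackSet:
    """Parse a TrackMate model XML (spots + tracks) or track export XML.

    Two dialects are supported:

    * the full model file with ``<AllSpots>`` and ``<AllTracks>`` sections,
      where trajectories are reassembled from the edge list of each
      ``<Track>`` (spots never referenced by an edge are dropped, with a
      logged count);
    * the simplified "export tracks" file, ``<Tracks>`` of ``<particle>``
      elements, each a list of ``<detection t= x= y=>`` spots.

    Spot positions are taken in the file's spatial units: apply
    :func:`apply_pixel_scale` afterwards if they are pixels.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        if exc.msg and "Document is empty" in exc.msg:
            raise NoTracksError(f"no tracks in {path}: file is empty") from exc
        raise TrackParseError(f"malformed TrackMate XML {path}: {exc}") from exc
    root = tree.getroot()

    if root.tag == "Tracks" or root.find(".//particle") is not None:
        return _parse_simple_tracks(root, frame_interval_s, meta, path)
    return _parse_model_tracks(root, frame_interval_s, meta, path)


def _parse_simple_tracks(root, frame_interval_s, meta, path) -> TrackSet:
    rows = []
    for tid, particle in enumerate(root.iter("particle")):
        for det in particle.iter("detection"):
            t = float(det.get("t"))
            rows.append((f"track_{tid}", int(round(t)), t * frame_interval_s,
                         float(det.get("x")), float(det.get("y"))))
    if not rows:
        raise NoTracksError(f"no tracks in {path}")
    df = pd.DataFrame(rows, columns=COLUMNS)
    return TrackSet(df, frame_interval_s=frame_interval_s, **meta)


def _parse_model_tracks(root, frame_interval_s, meta, path) -> TrackSet:
    spots = {}
    for spot in root.iter("Spot"):
        sid = spot.get("ID")
        try:
            frame = int(float(spot.get("FRAME", spot.get("POSITION_T"))))
            x = float(spot.get("POSITION_X"))
            y = float(spot.get("POSITION_Y"))
        except (TypeError, ValueError) as exc:
            raise TrackParseError(
                f"malformed <Spot ID={sid!r}> in {path}: missing position") from exc
        t = spot.get("POSITION_T")
        time_s = float(t) if t is not None else frame * frame_interval_s
        spots[sid] = (frame, time_s, x, y)

    track_elems = list(root.iter("Track"))
    if not track_elems:
        raise NoTracksError(f"no tracks in {path}: no <Track> section")

    rows = []
    linked = set()
    for track in track_elems:
        tid = track.get("TRACK_ID", track.get("name", ""))
        members = set()
        for edge in track.iter("Edge"):
            members.add(edge.get("SPOT_SOURCE_ID"))
            members.add(edge.get("SPOT_TARGET_ID"))
        members.discard(None)
        linked |= members
        for sid in members:
            if sid not in spots:
                raise TrackParseError(
                    f"<Edge> in track {tid} references unknown spot {sid} in {path}")
            frame, time_s, x, y = spots[sid]
            rows.append((f"track_{tid}", frame, time_s, x, y))
    n_unlinked = len(spots) - len(linked)
    if n_unlinked:
        logger.info("parse_trackmate_xml: dropped %d unlinked spots", n_unlinked)
    if not rows:
        raise NoTracksError(f"no tracks in {path}: tracks contain no edges")
    df = pd.DataFrame(rows, columns=COLUMNS)
    return TrackSet(df, frame_interval_s=frame_interval_s, **meta)


# ---------------------------------------------------------------------------
# Unit handling
# ---------------------------------------------------------------------------

def apply_pixel_scale(raw: TrackSet, pixels_per_um: float) -> TrackSet:
    """Convert a pixel-coordinate TrackSet to micrometres.

    Divides all coordinates (and the declared region, if any) by
    ``pixels_per_um``; e.g. the standard video scale of 5.0 pixels/um maps
    (5, 10) px to (1, 2) um.
    """
    if not pixels_per_um > 0:
        raise ValueError(f"pixels_per_um must be positive, got {pixels_per_um}")
    df = raw.data.copy()
    df["x_um"] = df["x_um"] / pixels_per_um
    df["y_um"] = df["y_um"] / pixels_per_um
    scale = lambda v: None if v is None else v / pixels_per_um
    return replace(raw, data=df,
                   region_width_um=scale(raw.region_width_um),
                   region_height_um=scale(raw.region_height_um))
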