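import numpy as np
import pandas as pd
import pytest

from mitonet.trajectory_io import COLUMNS, TrackSet


def trackset_from_rows(rows, dt=1.0, **meta) -> TrackSet:
    """Build a TrackSet from (track_id, frame, x, y) tuples; time = frame * dt."""
    df = pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])
    df["time_s"] = df["frame"] * dt
    return TrackSet(df[COLUMNS], frame_interval_s=dt, **meta)


@pytest.fixture
def single_track():
    """One track moving +2 um/frame along x for 3 frames."""
    return trackset_from_rows([("a", 0, 0.0, 0.0), ("a", 1, 2.0, 0.0),
                               ("a", 2, 4.0, 0.0)])


@pytest.fixture
def trackmate_model_xml(tmp_path):
    """Write a minimal TrackMate model XML and return its path.

    Spots are (id, frame, x, y); edges are (source, target) per track.
    """

    def _write(spots, tracks, name="model.xml"):
        spot_xml = "".join(
            f'<Spot ID="{sid}" FRAME="{f}" POSITION_T="{float(f)}" '
            f'POSITION_X="{x}" POSITION_Y="{y}" />'
            for sid, f, x, y in spots)
        track_xml = "".join(
            '<Track TRACK_ID="%d">%s</Track>' % (
                tid, "".join(f'<Edge SPOT_SOURCE_ID="{a}" SPOT_TARGET_ID="{b}" />'
                             for a, b in edges))
            for tid, edges in tracks.items())
        xml = (f"<TrackMate><Model><AllSpots><SpotsInFrame>{spot_xml}"
               f"</SpotsInFrame></AllSpots><AllTracks>{track_xml}"
               f"</AllTracks></Model></TrackMate>")
        path = tmp_path / name
        path.write_text(xml)
        return path

    return _write
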