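"""Windowed re-analysis: connectivity at matched observation horizons.

Because encounter networks are historical, connectivity statistics depend
on how long a system is observed; physical spacing does not.  This driver
rebuilds the networks of the four illustrative systems within windows of
2, 39, 97 and 193 s (anchored at capture start) and reports mean degree
and InterMitoMean per window — the comparison used to contrast clustered
and dispersed populations whose ranking changes with observation time.
Writes results/windowed_table.csv.
"""

from pathlib import Path

from mitonet.pipeline import windowed_compare
from mitonet.trajectory_io import read_track_csv

ROOT = Path(__file__).resolve().parents[1] / "results"
WINDOWS = (2.0, 39.0, 97.0, 193.0)
PRESETS = ("NM9", "NM10", "NM11", "NM12")


def main() -> None:
    track_sets = {name: read_track_csv(ROOT / "tracks" / f"{name}.csv")
                  for name in PRESETS}
    table = windowed_compare(track_sets, list(WINDOWS))
    out = ROOT / "windowed_table.csv"
    table.to_csv(out, index=False)
    piv = table.pivot(index="label", columns="window_s", values="mean_degree")
    print("mean degree by observation window (s):")
    print(piv.round(3).to_string())
    print("\nInterMitoMean stays window-stable while degree accumulates:")
    piv2 = table.pivot(index="label", columns="window_s",
                       values="inter_mito_mean_um")
    print(piv2.round(2).to_string())
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
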