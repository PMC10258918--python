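"""Optional validation on measured migration data.

The experimental two-channel time series (e.g. the public gap-closure
recordings of blood and lymphatic endothelial cells) are not bundled; when
such data is available as a centroid table (columns x,y,channel,timepoint —
the output of segmenting each frame and taking per-cell mask centroids),
this script runs the standard boundary-fractality analysis on it and
reports the per-frame table plus the final fractal value.

Usage:
    python scripts/validate_experimental.py --points cells.csv \
        --width 1024 --height 1024 [--contact-frame 16 | --contact-threshold 8] \
        --out report.json [--frames-csv frames.csv]
"""

import argparse
import json
from pathlib import Path

from cellfract import RunConfig, analyze, load_point_table
from cellfract.boundary import BoundaryConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--points", type=Path, required=True, help="centroid CSV")
    ap.add_argument("--width", type=int, required=True)
    ap.add_argument("--height", type=int, required=True)
    ap.add_argument("--compression", type=float, default=2.0)
    ap.add_argument("--n-neighbors", type=int, default=1)
    ap.add_argument("--contact-threshold", type=float, default=None)
    ap.add_argument("--contact-frame", type=int, default=None,
                    help="override automatic contact detection (e.g. the 8 h frame)")
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--frames-csv", type=Path, default=None)
    args = ap.parse_args()

    series = load_point_table(args.points, (args.width, args.height))
    config = RunConfig(
        boundary=BoundaryConfig(n_neighbors=args.n_neighbors, compression=args.compression),
        contact_threshold=args.contact_threshold,
        contact_frame=args.contact_frame,
    )
    table = analyze(series, config)
    if args.frames_csv:
        table.to_csv(args.frames_csv, index=False)

    report = {
        "t0": int(table.attrs["t0"]),
        "f_final": float(table.attrs["f_final"]),
        "n_frames_analyzed": int(len(table)),
        "mean_r_squared": float(table["r_squared"].mean()),
    }
    args.out.write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
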