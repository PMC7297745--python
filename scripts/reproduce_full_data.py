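#!/usr/bin/env python
"""Optional: reproduce the published herd/troop network summaries.

This script requires two externally deposited data sets (roughly 1e7 fixes in
total; the full run takes hours on one core):

* calves: radio-telemetry RTLS fixes for 70 feedlot beef calves over 24 h,
  available in the supplement of https://doi.org/10.1016/j.epidem.2018.08.003
* baboons: GPS fixes for an olive-baboon troop, Movebank Data Repository
  deposit https://doi.org/10.5441/001/1.kn0816jn

Download them yourself and pass the CSV paths.  For the calves it builds the
"precise" (SpTh = 0) and "expected" (SpTh = 0.56 m) fullBody / head.head /
head.posterior networks on the 10-s grid and prints their density, node
degree, contact duration and per-capita sum contacts.  For the baboons it
projects the subset onto a plane, derives 100-m/120-degree visual-field
triangles at 1-s resolution and prints the visual-network summaries
(mean visible individuals per second, mean visual bout duration, daily
degree).

Example:
    python scripts/reproduce_full_data.py calves --input calves.csv \
        --start 1462147200 --end 1462233600
    python scripts/reproduce_full_data.py baboons --input baboons.csv \
        --start 1343880000 --end 1344916800
"""

import argparse
import json
import sys

import polycontact as pc


def run_calves(args) -> None:
    fixes = pc.read_fixes(args.input, coordinate_system_hint="planar")
    fixes, _ = pc.filter_duplicates(fixes)
    grid = pc.GridSpec(interval=10, start=args.start, end=args.end)
    fixes = pc.aggregate_time(fixes, grid)
    model = pc.load_model(args.model or "calf")
    states = pc.estimate_heading(fixes, immobility_threshold=0.1)
    series = pc.derive_polygons(fixes, states, model)

    from itertools import combinations_with_replacement

    pairings = {
        "fullBody": list(combinations_with_replacement(sorted(model.parts), 2)),
        "head.head": [("head", "head")],
        "head.posterior": [("head", "posterior")],
    }
    out = {}
    for spth, label in ((0.0, "precise"), (0.56, "expected")):
        for net_name, pairing in pairings.items():
            dist = pc.pairwise_distances(series, pairing)
            flags = pc.detect_contacts(dist, spth)
            bouts = pc.extract_bouts(flags, grid)
            net = pc.build_network(bouts, nodes=sorted(fixes["id"].unique()))
            out[f"{label}.{net_name}"] = pc.network_metrics(net)
    print(json.dumps(out, indent=1))


def run_baboons(args) -> None:
    cmap = {
        "individual_id": "individual-local-identifier",
        "time": "timestamp",
        "x": "location-long",
        "y": "location-lat",
    }
    fixes = pc.read_fixes(args.input, column_map=cmap)
    fixes = pc.project_to_plane(fixes, "centroid")
    fixes, _ = pc.filter_duplicates(fixes)
    grid = pc.GridSpec(interval=1, start=args.start, end=args.end)
    fixes = pc.aggregate_time(fixes, grid)
    model = pc.load_model(args.model or "visual_100m_120deg")
    states = pc.estimate_heading(fixes, immobility_threshold=0.0)
    series = pc.derive_polygons(fixes, states, model)
    net = pc.build_visual_network(series, fixes, spth=args.spth, grid=grid)
    print(json.dumps(pc.network_metrics(net, grid=grid), indent=1))


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    sub = parser.add_subparsers(dest="dataset", required=True)
    for name in ("calves", "baboons"):
        p = sub.add_parser(name)
        p.add_argument("--input", required=True)
        p.add_argument("--start", type=int, required=True, help="window start, epoch s")
        p.add_argument("--end", type=int, required=True, help="window end, epoch s")
        p.add_argument("--model", default=None)
    sub.choices["baboons"].add_argument("--spth", type=float, default=0.109)
    args = parser.parse_args()
    if args.dataset == "calves":
        run_calves(args)
    else:
        run_baboons(args)


if __name__ == "__main__":
    sys.exit(main())
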