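#!/usr/bin/env python
"""Full two-state pipeline: stiff vs floppy hinge, delta-LRCC recovery.

Runs the config-driven pipeline end to end on two synthetic states that
differ only in hinge stiffness, then summarises the delta-LRCC profile:
the stiff state must show enhanced cross-domain communication
(nonnegative stiff-minus-floppy deltas for residues with cross-domain
partners beyond the reference distance).

Writes the full result bundle under results/two_state_run/.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from allocomm.pipeline import RunConfig, run_pipeline
from allocomm.tables import read_matrix

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-frames", type=int, default=2000)
    args = parser.parse_args()
    out = ROOT / "results" / "two_state_run"

    def state(label, sigma):
        return {
            "label": label,
            "synthetic": {
                "model_kind": "hinge",
                "n_residues": 60,
                "n_frames": args.n_frames,
                "parameters": {"split_index": 30, "hinge_angle_sigma": sigma, "jitter_sigma": 0.5},
            },
        }

    cfg = RunConfig.from_dict(
        {
            "seed": args.seed,
            "output_dir": str(out),
            "delta_grid": [20, 30, 40, 50, 60, 70],
            "states": [state("stiff", 2.0), state("floppy", 15.0)],
        }
    )
    manifest = run_pipeline(cfg)
    print(f"pipeline wrote {len(manifest['outputs'])} outputs under {out}")

    rel = pd.read_csv(out / "compare_stiff_vs_floppy" / "delta_lrcc_delta50.tsv", sep="\t")
    deltas = rel["delta_lrcc"].to_numpy()
    dist = read_matrix(out / "state_stiff" / "mean_distances.tsv")
    split = 30
    cross = np.zeros(60, dtype=bool)
    cross[:split] = (dist[:split, split:] > 50).any(axis=1)
    cross[split:] = (dist[split:, :split] > 50).any(axis=1)
    frac = (deltas[cross] >= 0).mean()
    print(
        f"delta-LRCC at 50 A: {cross.sum()} cross-domain residues, "
        f"{frac:.0%} with the designed (stiff >= floppy) ordering, "
        f"mean delta {deltas[cross].mean():.3f}"
    )


if __name__ == "__main__":
    main()
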