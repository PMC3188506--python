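#!/usr/bin/env python
"""Generate the four synthetic ensemble models and tabulate their basic
fluctuation statistics.

Each generator has a known ground truth: rigid-body ensembles have zero
communication propensity (CP), iid jitter tends to CP = 2 sigma^2 and
RMSF = sigma sqrt(3), the GNM realises a prescribed covariance, and the
hinge concentrates distance variance in cross-block pairs. The table
written here is the raw material the later analyses interpret.

Writes results/ensemble_summary.tsv and an example multi-model PDB.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

import allocomm as ac
from allocomm.synthetic import SyntheticModelSpec, sample_ensemble
from allocomm.trajectory_io import write_ensemble_pdb

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-frames", type=int, default=2000)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)

    specs = [
        SyntheticModelSpec("rigid_body", 40, args.n_frames, args.seed),
        SyntheticModelSpec("iid_jitter", 40, args.n_frames, args.seed + 1, {"jitter_sigma": 0.5}),
        SyntheticModelSpec("gnm", 40, args.n_frames, args.seed + 2, {"gnm_cutoff": 7.5, "gnm_scale": 0.25}),
        SyntheticModelSpec(
            "hinge", 40, args.n_frames, args.seed + 3,
            {"split_index": 20, "hinge_angle_sigma": 10.0, "jitter_sigma": 0.5},
        ),
    ]
    rows = []
    for spec in specs:
        ens = sample_ensemble(spec)
        ref = ens.coords.mean(axis=0)
        aligned = ac.superpose_ensemble(ens, ref)
        flex = ac.flexibility_profile(aligned, ref)
        cp = ac.communication_propensity(ens).values
        off = ~np.eye(ens.n_residues, dtype=bool)
        rows.append(
            {
                "model": spec.model_kind,
                "n_frames": ens.n_frames,
                "mean_rmsf_A": flex.rmsf_per_residue.mean(),
                "max_rmsf_A": flex.rmsf_per_residue.max(),
                "mean_cp_A2": cp[off].mean(),
                "max_cp_A2": cp[off].max(),
            }
        )
        if spec.model_kind == "hinge":
            write_ensemble_pdb(ens.select(range(40)).with_coords(ens.coords[:10]), OUT / "hinge_example.pdb")
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "ensemble_summary.tsv", sep="\t", index=False, float_format="%.5g")
    print(df.to_string(index=False))
    print("\nrigid-body CP is exactly zero; iid jitter CP ~ 2 sigma^2 = 0.5 A^2;")
    print("the hinge's max CP is dominated by cross-block pairs.")


if __name__ == "__main__":
    main()
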