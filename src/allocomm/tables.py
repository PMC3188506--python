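"""Delimited-table writers for matrices and per-residue profiles.

All outputs are tab-separated with a header row; floats are printed with
a fixed format so that identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .communication import (
    CommunicationPropensityMatrix,
    CommunicationThreshold,
    LRCCProfile,
    MeanDistanceMatrix,
    PeakClusterSet,
    RelativeLRCCProfile,
)
from .ensemble import ResidueTopology

FLOAT_FMT = "%.10g"


def write_matrix(values: np.ndarray, path: str | Path) -> None:
    """Square matrix as a headerless TSV (row per residue)."""
    pd.DataFrame(np.asarray(values)).to_csv(
        path, sep="\t", header=False, index=False, float_format=FLOAT_FMT
    )


def read_matrix(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)


def _residue_frame(topology: ResidueTopology) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue_index": np.arange(len(topology)),
            "chain": topology.chain_ids.astype(str),
            "residue_id": topology.residue_ids,
        }
    )


def write_profile(
    profile: LRCCProfile, topology: ResidueTopology, path: str | Path
) -> None:
    df = _residue_frame(topology)
    df["density"] = profile.densities
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_relative_profile(
    rel: RelativeLRCCProfile, topology: ResidueTopology, path: str | Path
) -> None:
    df = _residue_frame(topology)
    df["delta_lrcc"] = rel.deltas
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def write_threshold_report(
    thr: CommunicationThreshold, topology: ResidueTopology, path: str | Path
) -> None:
    df = _residue_frame(topology)
    df["neighbor_mean_cp"] = thr.per_residue_means
    df["n_terms"] = thr.terms_per_residue
    with open(path, "w") as fh:
        fh.write(f"# threshold\t{FLOAT_FMT % thr.value}\n")
        fh.write(f"# window\t{thr.window}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def write_peaks(peaks: PeakClusterSet, path: str | Path) -> None:
    rows = [
        {
            "start_index": c.start,
            "stop_index": c.stop,
            "extent": c.extent,
            "mean_density": c.mean_density,
        }
        for c in peaks.clusters
    ]
    pd.DataFrame(rows, columns=["start_index", "stop_index", "extent", "mean_density"]).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FMT
    )


def write_series(values: np.ndarray, name: str, path: str | Path, index_name: str = "frame") -> None:
    df = pd.DataFrame({index_name: np.arange(len(values)), name: np.asarray(values)})
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
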