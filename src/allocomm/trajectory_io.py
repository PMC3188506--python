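"""Reading, superposing and writing conformational ensembles.

Standard structural formats (PDB, DCD, XTC) go through MDAnalysis; the
delimited frame/residue/x/y/z table goes through pandas. Everything is
reduced to the Calpha trace on input — all communication and essential-
dynamics statistics in this package are Calpha statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .ensemble import CoordinateEnsemble, ResidueTopology

logger = logging.getLogger(__name__)

_TABLE_SUFFIXES = {".csv", ".tsv", ".txt", ".dat", ".table"}


@dataclass(frozen=True)
class ResidueSelection:
    """Restrict an ensemble to chains and/or author residue-id ranges.

    ``chains`` of None keeps all chains; ``residue_range`` of None keeps all
    residues. The range is inclusive on both ends.
    """

    chains: tuple[str, ...] | None = None
    residue_range: tuple[int, int] | None = None

    def mask(self, topology: ResidueTopology) -> np.ndarray:
        keep = np.ones(len(topology), dtype=bool)
        if self.chains is not None:
            keep &= np.isin(topology.chain_ids.astype(str), list(self.chains))
        if self.residue_range is not None:
            lo, hi = self.residue_range
            keep &= (topology.residue_ids >= lo) & (topology.residue_ids <= hi)
        return keep


def _mda():
    # MDAnalysis import deferred: it is slow and noisy at import time.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _ca_atoms(universe):
    """One Calpha per residue, preferring altloc '' or 'A'; residues without
    a Calpha are skipped with a warning."""
    atoms = []
    skipped = 0
    for res in universe.residues:
        cas = [a for a in res.atoms if a.name == "CA"]
        if len(cas) > 1:
            try:
                cas = [a for a in cas if a.altLoc in ("", "A")] or cas
            except AttributeError:
                pass
        if not cas:
            skipped += 1
            logger.warning(
                "residue %s %s%s has no Calpha; skipped",
                res.resname,
                getattr(res, "segid", ""),
                res.resid,
            )
            continue
        atoms.append(cas[0])
    if not atoms:
        raise ValueError("no Calpha atoms found in structure")
    if skipped:
        logger.warning("%d residue(s) without Calpha skipped; indices shift", skipped)
    return atoms


def _chain_of(atom) -> str:
    for attr in ("chainID", "segid"):
        val = getattr(atom, attr, "")
        if val:
            return str(val)[0]
    return "A"


def _topology_from_atoms(atoms) -> ResidueTopology:
    return ResidueTopology(
        residue_ids=np.array([a.resid for a in atoms]),
        chain_ids=np.array([_chain_of(a) for a in atoms], dtype=object),
        residue_names=np.array([a.resname for a in atoms], dtype=object),
        segment_labels=np.array(
            [str(getattr(a, "segid", "") or "") for a in atoms], dtype=object
        ),
    )


def read_reference_structure(path: str | Path) -> tuple[ResidueTopology, np.ndarray]:
    """Read a PDB reference structure down to its Calpha trace.

    Returns the residue topology and an N x 3 coordinate array (angstrom) in
    file residue order. Residues lacking a Calpha are skipped (warning);
    a structure with zero Calpha atoms is a fatal error.
    """
    mda = _mda()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    atoms = _ca_atoms(u)
    coords = np.array([a.position for a in atoms], dtype=float)
    return _topology_from_atoms(atoms), coords


def _read_table_ensemble(path: Path, label: str) -> CoordinateEnsemble:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"frame", "chain", "residue_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"table {path} lacks columns: {sorted(missing)}")
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]]
    keys = list(zip(first["chain"].astype(str), first["residue_id"].astype(int)))
    coords = np.empty((len(frames), len(keys), 3))
    for f_i, f in enumerate(frames):
        sub = df[df["frame"] == f]
        if len(sub) != len(keys):
            raise ValueError(
                f"frame {f} has {len(sub)} residues, frame {frames[0]} has {len(keys)}"
            )
        sub = sub.set_index(
            [sub["chain"].astype(str), sub["residue_id"].astype(int)]
        )
        coords[f_i] = sub.loc[keys, ["x", "y", "z"]].to_numpy(dtype=float)
    topology = ResidueTopology(
        residue_ids=np.array([k[1] for k in keys]),
        chain_ids=np.array([k[0] for k in keys], dtype=object),
        residue_names=np.array(["UNK"] * len(keys), dtype=object),
    )
    return CoordinateEnsemble(topology=topology, coords=coords, label=label)


def read_ensemble(
    reference: str | Path | None,
    trajectory: str | Path,
    selection: ResidueSelection | None = None,
    label: str = "",
) -> CoordinateEnsemble:
    """Read a Calpha conformational ensemble.

    ``trajectory`` may be a DCD or XTC file (``reference`` PDB required as
    topology), a multi-model PDB (``reference`` optional), or a delimited
    table with header ``frame,chain,residue_id,x,y,z`` (comma or tab,
    auto-detected). ``selection`` restricts residues before any statistic
    is computed downstream.
    """
    trajectory = Path(trajectory)
    if trajectory.suffix.lower() in _TABLE_SUFFIXES:
        ens = _read_table_ensemble(trajectory, label)
    else:
        mda = _mda()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory.suffix.lower() == ".pdb" and reference is None:
                u = mda.Universe(str(trajectory))
            else:
                if reference is None:
                    raise ValueError(
                        f"{trajectory.suffix} trajectories need a reference PDB topology"
                    )
                try:
                    u = mda.Universe(str(reference), str(trajectory))
                except Exception as exc:  # noqa: BLE001
                    raise ValueError(
                        f"trajectory {trajectory} is inconsistent with reference "
                        f"{reference}: {exc}"
                    ) from exc
        atoms = _ca_atoms(u)
        idx = [a.ix for a in atoms]
        topology = _topology_from_atoms(atoms)
        coords = np.array(
            [u.atoms.positions[idx] for _ in u.trajectory], dtype=float
        )
        ens = CoordinateEnsemble(topology=topology, coords=coords, label=label)
    if selection is not None:
        keep = selection.mask(ens.topology)
        ens = ens.select(np.flatnonzero(keep))
    return ens


def kabsch_rotation(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares proper rotation R (det +1) and translation mapping
    ``mobile`` onto ``target``: R @ (x - mobile_mean) + target_mean."""
    mob_mean = mobile.mean(axis=0)
    tgt_mean = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tgt_mean, mobile - mob_mean)
    return rot.as_matrix(), mob_mean, tgt_mean


def superpose_ensemble(
    ensemble: CoordinateEnsemble,
    reference: np.ndarray,
    selection: Sequence[int] | np.ndarray | None = None,
) -> CoordinateEnsemble:
    """Least-squares superpose every frame onto ``reference`` over a residue
    subset, removing rigid-body translation and rotation.

    Only proper rotations (determinant +1) are applied — a mirror-image
    frame keeps a positive residual rather than being reflected. Returns a
    new ensemble; the input is untouched.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (ensemble.n_residues, 3):
        raise ValueError("reference shape must match ensemble residues")
    if selection is None:
        sel = np.arange(ensemble.n_residues)
    else:
        sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise ValueError("superposition needs at least 3 selected residues")
    ref_sel = reference[sel]
    centered = ref_sel - ref_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected residues are collinear; rotation underdetermined")
    out = np.empty_like(ensemble.coords)
    for f in range(ensemble.n_frames):
        frame = ensemble.coords[f]
        rot, mob_mean, tgt_mean = kabsch_rotation(frame[sel], ref_sel)
        out[f] = (frame - mob_mean) @ rot.T + tgt_mean
    return ensemble.with_coords(out)


def write_reference_pdb(
    topology: ResidueTopology, coords: np.ndarray, path: str | Path
) -> None:
    """Write a Calpha-only PDB for a topology + single coordinate set."""
    _write_pdb_models(topology, np.asarray(coords, dtype=float)[None, :, :], path)


def write_ensemble_pdb(ensemble: CoordinateEnsemble, path: str | Path) -> None:
    """Write an ensemble as a multi-model Calpha PDB."""
    _write_pdb_models(ensemble.topology, ensemble.coords, path)


def _build_universe(topology: ResidueTopology, n_frames: int):
    mda = _mda()
    n = len(topology)
    chains = topology.chain_ids.astype(str)
    uniq_chains, seg_index = np.unique(chains, return_inverse=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=n,
            n_residues=n,
            n_segments=len(uniq_chains),
            atom_resindex=np.arange(n),
            residue_segindex=seg_index,
            trajectory=True,
        )
        u.add_TopologyAttr("name", ["CA"] * n)
        u.add_TopologyAttr("type", ["C"] * n)
        u.add_TopologyAttr("element", ["C"] * n)
        u.add_TopologyAttr("resname", topology.residue_names.astype(str))
        u.add_TopologyAttr("resid", topology.residue_ids)
        u.add_TopologyAttr("segid", uniq_chains.tolist())
        u.add_TopologyAttr("chainID", chains.tolist())
        u.add_TopologyAttr("occupancy", np.ones(n))
        u.add_TopologyAttr("tempfactor", np.zeros(n))
    return u


def _write_pdb_models(topology, coords: np.ndarray, path: str | Path) -> None:
    mda = _mda()
    from MDAnalysis.coordinates.memory import MemoryReader

    u = _build_universe(topology, coords.shape[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.load_new(np.ascontiguousarray(coords), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=len(topology), multiframe=coords.shape[0] > 1) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_ensemble_dcd(ensemble: CoordinateEnsemble, path: str | Path) -> None:
    """Write an ensemble's coordinates as a DCD trajectory (pair it with a
    reference PDB from :func:`write_reference_pdb` for reading back)."""
    mda = _mda()
    from MDAnalysis.coordinates.memory import MemoryReader

    u = _build_universe(ensemble.topology, ensemble.n_frames)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.load_new(np.ascontiguousarray(ensemble.coords), format=MemoryReader)
        with mda.Writer(str(path), n_atoms=ensemble.n_residues) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def write_annotated_structure(
    reference_pdb: str | Path,
    topology: ResidueTopology,
    values: np.ndarray,
    out_path: str | Path,
) -> None:
    """Write a copy of ``reference_pdb`` with a per-residue scalar in the
    B-factor column.

    Values are scaled linearly to 0–99.99 (the PDB column range); the scale
    and offset are recorded in a REMARK so the original scores can be
    recovered. Residues not covered by ``topology``/``values`` get 0.00.
    Lets molecular viewers colour structures by LRCC, RMSF, etc.
    """
    values = np.asarray(values, dtype=float)
    if values.shape != (len(topology),):
        raise ValueError("values length must equal topology size")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite annotation values")
    vmin = float(values.min())
    vmax = float(values.max())
    span = vmax - vmin
    if span > 0:
        scaled = (values - vmin) / span * 99.99
    else:
        scaled = np.zeros_like(values)
    lookup = {
        (str(c), int(r)): s
        for c, r, s in zip(topology.chain_ids, topology.residue_ids, scaled)
    }
    lines_out = [
        f"REMARK   3 B-FACTOR = (SCORE - {vmin:.6g}) * {99.99 / span if span > 0 else 0.0:.6g}\n",
        f"REMARK   3 SCORE RANGE {vmin:.6g} TO {vmax:.6g}\n",
    ]
    with open(reference_pdb) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 66:
                chain = line[21].strip() or "A"
                try:
                    resid = int(line[22:26])
                except ValueError:
                    resid = None
                b = lookup.get((chain, resid), 0.0) if resid is not None else 0.0
                line = f"{line[:60]}{b:6.2f}{line[66:]}"
                if not line.endswith("\n"):
                    line += "\n"
            lines_out.append(line)
    with open(out_path, "w") as fh:
        fh.writelines(lines_out)
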