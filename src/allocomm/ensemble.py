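"""Core in-memory containers: residue topology and coordinate ensembles."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ResidueTopology:
    """Per-residue identity for the Calpha trace of one (possibly multi-chain)
    molecule.

    ``residue_index`` is implicit: position 0..N-1 in the arrays below. All
    chains of a complex are concatenated into this single index space;
    ``segment_labels`` may keep monomer/domain identity (e.g. "receiver",
    "activator") for intra- vs inter-monomer analyses.
    """

    residue_ids: np.ndarray  # author-assigned residue numbers, int
    chain_ids: np.ndarray  # single-character chain labels, str
    residue_names: np.ndarray  # 3-letter codes, str
    segment_labels: np.ndarray | None = None  # optional free-text tags

    def __post_init__(self) -> None:
        object.__setattr__(self, "residue_ids", np.asarray(self.residue_ids, dtype=int))
        object.__setattr__(self, "chain_ids", np.asarray(self.chain_ids, dtype=object))
        object.__setattr__(
            self, "residue_names", np.asarray(self.residue_names, dtype=object)
        )
        n = len(self.residue_ids)
        if len(self.chain_ids) != n or len(self.residue_names) != n:
            raise ValueError("topology arrays must have equal length")
        if self.segment_labels is not None:
            seg = np.asarray(self.segment_labels, dtype=object)
            if len(seg) != n:
                raise ValueError("segment_labels length mismatch")
            object.__setattr__(self, "segment_labels", seg)
        keys = set(zip(self.chain_ids.tolist(), self.residue_ids.tolist()))
        if len(keys) != n:
            raise ValueError("(chain_id, residue_id) pairs must be unique")

    def __len__(self) -> int:
        return len(self.residue_ids)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def subset(self, indices: np.ndarray) -> "ResidueTopology":
        """Topology restricted to ``indices`` (order preserved, re-indexed)."""
        idx = np.asarray(indices, dtype=int)
        return ResidueTopology(
            residue_ids=self.residue_ids[idx],
            chain_ids=self.chain_ids[idx],
            residue_names=self.residue_names[idx],
            segment_labels=None
            if self.segment_labels is None
            else self.segment_labels[idx],
        )

    @classmethod
    def simple_chain(cls, n: int, chain_id: str = "A", start_id: int = 1) -> "ResidueTopology":
        """A single chain of ``n`` alanines numbered consecutively — the
        default topology for synthetic ensembles."""
        return cls(
            residue_ids=np.arange(start_id, start_id + n),
            chain_ids=np.array([chain_id] * n, dtype=object),
            residue_names=np.array(["ALA"] * n, dtype=object),
        )


@dataclass
class CoordinateEnsemble:
    """F frames x N residues x 3 Cartesian Calpha coordinates, in angstrom."""

    topology: ResidueTopology
    coords: np.ndarray  # (F, N, 3)
    frame_times: np.ndarray | None = None  # ps, optional
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, N, 3)")
        if self.coords.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError(
                f"coords have {self.coords.shape[1]} residues but topology has "
                f"{len(self.topology)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in ensemble")
        if self.frame_times is not None:
            self.frame_times = np.asarray(self.frame_times, dtype=float)
            if len(self.frame_times) != self.coords.shape[0]:
                raise ValueError("frame_times length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    def select(self, indices: Sequence[int] | np.ndarray) -> "CoordinateEnsemble":
        """Ensemble restricted to a residue subset (new object)."""
        idx = np.asarray(indices, dtype=int)
        return CoordinateEnsemble(
            topology=self.topology.subset(idx),
            coords=self.coords[:, idx, :].copy(),
            frame_times=None if self.frame_times is None else self.frame_times.copy(),
            label=self.label,
        )

    def with_coords(self, coords: np.ndarray) -> "CoordinateEnsemble":
        return CoordinateEnsemble(
            topology=self.topology,
            coords=coords,
            frame_times=None if self.frame_times is None else self.frame_times.copy(),
            label=self.label,
        )


@dataclass
class AtomSelectionFrames:
    """All-atom coordinates for a named set of atoms across frames.

    Supports contact criteria that need side-chain atoms rather than the
    Calpha trace. ``labels`` holds (chain_id, residue_id, atom_name) tuples,
    one per atom column of ``coords``.
    """

    labels: list[tuple[str, int, str]]
    coords: np.ndarray  # (F, M, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (F, M, 3)")
        if self.coords.shape[1] != len(self.labels):
            raise ValueError("labels/coords atom count mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def find_atoms(
        self,
        chain_id: str | None,
        residue_id: int,
        atom_names: Sequence[str] | None,
    ) -> np.ndarray:
        """Column indices of atoms matching (chain, residue, any of names).

        ``chain_id`` of None matches any chain; ``atom_names`` of None
        matches all atoms of the residue.
        """
        out = []
        names = None if atom_names is None else {a.upper() for a in atom_names}
        for k, (ch, rid, an) in enumerate(self.labels):
            if chain_id is not None and ch != chain_id:
                continue
            if rid != residue_id:
                continue
            if names is not None and an.upper() not in names:
                continue
            out.append(k)
        return np.asarray(out, dtype=int)
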