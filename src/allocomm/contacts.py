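"""Occupancy of declared interface contacts (salt bridges, hydrogen bonds).

A contact is declared between two atoms or atom groups; its per-frame
distance is the minimum over cross-pair atom distances, and its occupancy
is the fraction of frames in which the distance criterion (and, when
hydrogens are present, an optional angle criterion) is satisfied.

Default geometric criteria (conventional values, exposed in config):
hydrogen bond — donor–acceptor heavy-atom distance <= 3.5 A, D-H...A
angle >= 120 deg when explicit hydrogens exist; salt bridge — minimum
charged-group heavy-atom (side-chain N/O) distance <= 4.0 A; generic —
user-supplied cutoff (e.g. ring-centroid <= 5.5 A for stacking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import AtomSelectionFrames

logger = logging.getLogger(__name__)

DEFAULT_CUTOFFS = {"hydrogen_bond": 3.5, "salt_bridge": 4.0, "generic": 4.5}
CONTACT_KINDS = tuple(DEFAULT_CUTOFFS)


@dataclass(frozen=True)
class ContactGroup:
    """One side of a contact: a residue and (optionally) specific atoms."""

    chain_id: str | None
    residue_id: int
    atom_names: tuple[str, ...] | None = None  # None = all atoms of residue


@dataclass(frozen=True)
class ContactSpec:
    """A named geometric contact between two atom groups."""

    contact_id: str
    group_a: ContactGroup
    group_b: ContactGroup
    kind: str = "generic"
    distance_cutoff: float | None = None  # A; None = kind default
    angle_cutoff: float | None = None  # degrees, hydrogen bonds only
    hydrogen_name: str | None = None  # explicit H atom on the donor side

    def __post_init__(self) -> None:
        if self.kind not in CONTACT_KINDS:
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.distance_cutoff is not None and self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be > 0")

    @property
    def cutoff(self) -> float:
        return (
            self.distance_cutoff
            if self.distance_cutoff is not None
            else DEFAULT_CUTOFFS[self.kind]
        )


@dataclass
class OccupancyTable:
    """Rows of (contact_id, state_label, occupancy, mean distance, frames)."""

    rows: pd.DataFrame

    COLUMNS = ("contact_id", "state_label", "occupancy", "mean_distance", "n_frames")

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"occupancy table lacks columns {sorted(missing)}")
        occ = self.rows["occupancy"]
        if ((occ < 0) | (occ > 1)).any():
            raise ValueError("occupancy must lie in [0, 1]")


def _resolve(frames: AtomSelectionFrames, group: ContactGroup, contact_id: str) -> np.ndarray:
    idx = frames.find_atoms(group.chain_id, group.residue_id, group.atom_names)
    if idx.size == 0:
        raise ValueError(
            f"contact {contact_id!r}: no atoms match chain={group.chain_id} "
            f"residue={group.residue_id} names={group.atom_names}"
        )
    return idx


def contact_distance_series(
    frames: AtomSelectionFrames, spec: ContactSpec
) -> np.ndarray:
    """Per-frame minimum distance (angstrom) between the two atom groups."""
    ia = _resolve(frames, spec.group_a, spec.contact_id)
    ib = _resolve(frames, spec.group_b, spec.contact_id)
    a = frames.coords[:, ia, :]  # (F, Ma, 3)
    b = frames.coords[:, ib, :]  # (F, Mb, 3)
    diff = a[:, :, None, :] - b[:, None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return dist.min(axis=(1, 2))


def _angle_series(frames: AtomSelectionFrames, spec: ContactSpec) -> np.ndarray | None:
    """D-H...A angle per frame (degrees), or None when no hydrogen exists."""
    if spec.hydrogen_name is None:
        return None
    ih = frames.find_atoms(spec.group_a.chain_id, spec.group_a.residue_id, [spec.hydrogen_name])
    if ih.size == 0:
        return None
    ia = _resolve(frames, spec.group_a, spec.contact_id)
    ib = _resolve(frames, spec.group_b, spec.contact_id)
    # use the first donor heavy atom and the per-frame nearest acceptor atom
    d = frames.coords[:, ia[0], :]
    h = frames.coords[:, ih[0], :]
    b = frames.coords[:, ib, :]
    dist_hb = np.sqrt(((b - h[:, None, :]) ** 2).sum(axis=-1))
    acc = b[np.arange(frames.n_frames), dist_hb.argmin(axis=1)]
    v1 = d - h
    v2 = acc - h
    cos = (v1 * v2).sum(axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.rad2deg(np.arccos(np.clip(cos, -1.0, 1.0)))


def occupancy(
    frames: AtomSelectionFrames,
    spec: ContactSpec,
    state_label: str = "",
    series: np.ndarray | None = None,
) -> pd.DataFrame:
    """One occupancy-table row: the fraction of frames satisfying the
    contact's distance (and optional angle) criterion.

    ``series`` may supply a precomputed distance series to avoid
    recomputation. An angle criterion without hydrogen coordinates degrades
    to distance-only with a warning.
    """
    if series is None:
        series = contact_distance_series(frames, spec)
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ValueError("need at least 1 frame")
    ok = series <= spec.cutoff
    if spec.angle_cutoff is not None:
        angles = _angle_series(frames, spec)
        if angles is None:
            logger.warning(
                "contact %s: angle criterion requested but no hydrogen present; "
                "applying distance-only",
                spec.contact_id,
            )
        else:
            ok &= angles >= spec.angle_cutoff
    return pd.DataFrame(
        [
            {
                "contact_id": spec.contact_id,
                "state_label": state_label,
                "occupancy": float(ok.mean()),
                "mean_distance": float(series.mean()),
                "n_frames": int(series.size),
            }
        ]
    )


def occupancy_table(
    frames: AtomSelectionFrames,
    specs: Sequence[ContactSpec],
    state_label: str = "",
) -> OccupancyTable:
    """Occupancy rows for a declared contact list, one state."""
    rows = pd.concat(
        [occupancy(frames, s, state_label=state_label) for s in specs],
        ignore_index=True,
    )
    return OccupancyTable(rows=rows)


def compare_occupancies(table_a: OccupancyTable, table_b: OccupancyTable) -> pd.DataFrame:
    """Per-contact occupancy difference a - b over the shared contact ids."""
    a = table_a.rows.set_index("contact_id")
    b = table_b.rows.set_index("contact_id")
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("the two occupancy tables share no contact ids")
    out = pd.DataFrame(
        {
            "contact_id": shared,
            "occupancy_a": a.loc[shared, "occupancy"].to_numpy(),
            "occupancy_b": b.loc[shared, "occupancy"].to_numpy(),
        }
    )
    out["delta"] = out["occupancy_a"] - out["occupancy_b"]
    return out
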