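"""Communication propensity, efficiency threshold, and LRCC profiles.

The communication propensity (CP) of a residue pair is the variance, over
an ensemble, of the Calpha–Calpha distance between them:

    CP_ij = < (d_ij - <d_ij>)^2 >        (angstrom^2, population average)

Pairs whose distance fluctuates little communicate perturbations
efficiently. The efficiency threshold is the average CP between sequence
neighbours (|i - j| <= window, same chain), on the assumption that
covalently connected neighbourhoods communicate well; a pair is
"efficient" iff CP_ij <= threshold. The Long-Range Communication
Capability (LRCC) of residue i at reference distance delta is the
fraction of all other residues that communicate efficiently with i from a
mean distance greater than delta; profile differences between two states
(mutant minus wild type, say) localise gains and losses of long-range
communication (delta-LRCC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import CoordinateEnsemble

logger = logging.getLogger(__name__)


def _check_square_symmetric(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(values, values.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    return values


@dataclass
class MeanDistanceMatrix:
    """Time-averaged inter-residue Calpha distances <d_ij>, angstrom."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_square_symmetric(self.values, "mean distance matrix")
        if (self.values < 0).any():
            raise ValueError("distances must be >= 0")

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass
class CommunicationPropensityMatrix:
    """CP_ij = variance over frames of the inter-residue distance, angstrom^2."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = _check_square_symmetric(self.values, "CP matrix")
        if (self.values < -1e-12).any():
            raise ValueError("CP must be >= 0")
        self.values = np.clip(self.values, 0.0, None)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n_residues(self) -> int:
        return self.values.shape[0]


@dataclass
class CommunicationThreshold:
    """Global efficiency threshold: the mean neighbour-window CP.

    ``per_residue_means[i]`` averages CP_ij over the sequence neighbours
    j in i-window..i+window (same chain, j != i, window truncated at
    termini); ``value`` is the mean of those per-residue averages.
    ``terms_per_residue`` records m, the number of neighbour terms each
    residue contributed.
    """

    value: float
    window: int
    per_residue_means: np.ndarray
    terms_per_residue: np.ndarray

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class EfficiencyMatrix:
    """Boolean pair matrix: True where CP_ij <= threshold (diagonal False)."""

    values: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if not (self.values == self.values.T).all():
            raise ValueError("efficiency matrix must be symmetric")
        np.fill_diagonal(self.values, False)


@dataclass
class LRCCProfile:
    """Per-residue fraction of efficient partners beyond ``reference_distance``."""

    densities: np.ndarray
    reference_distance: float
    state_label: str = ""

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        if ((self.densities < 0) | (self.densities > 1)).any():
            raise ValueError("densities must lie in [0, 1]")


@dataclass
class RelativeLRCCProfile:
    """Elementwise LRCC difference between two states, in [-1, 1].

    Positive values mean enhanced long-range communication in state A
    relative to state B.
    """

    deltas: np.ndarray
    state_a: str
    state_b: str
    reference_distance: float


@dataclass
class PeakCluster:
    start: int  # first residue_index, inclusive
    stop: int  # last residue_index, inclusive
    mean_density: float

    @property
    def extent(self) -> int:
        return self.stop - self.start + 1


@dataclass
class PeakClusterSet:
    clusters: list[PeakCluster] = field(default_factory=list)
    cutoff: float = float("nan")  # density threshold used

    def __len__(self) -> int:
        return len(self.clusters)

    def member_indices(self) -> np.ndarray:
        out = [np.arange(c.start, c.stop + 1) for c in self.clusters]
        return np.concatenate(out) if out else np.array([], dtype=int)


def pairwise_distances(frame: np.ndarray) -> np.ndarray:
    diff = frame[:, None, :] - frame[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _distance_moments(ensemble: CoordinateEnsemble) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance (population, 1/F) of all pair distances over frames.

    Accumulates per frame to keep memory at O(N^2) regardless of F.
    """
    n = ensemble.n_residues
    s1 = np.zeros((n, n))
    s2 = np.zeros((n, n))
    for f in range(ensemble.n_frames):
        d = pairwise_distances(ensemble.coords[f])
        s1 += d
        s2 += d * d
    f = ensemble.n_frames
    mean = s1 / f
    var = np.clip(s2 / f - mean * mean, 0.0, None)
    # variances below 1e-9 A^2 are cancellation noise (a rigid ensemble is
    # exactly rigid); snap them to zero so thresholds behave degenerately
    var[var < 1e-9] = 0.0
    return mean, var


def mean_distance_matrix(ensemble: CoordinateEnsemble) -> MeanDistanceMatrix:
    """Arithmetic mean over frames of every Calpha–Calpha distance."""
    mean, _ = _distance_moments(ensemble)
    return MeanDistanceMatrix(values=mean)


def communication_propensity(ensemble: CoordinateEnsemble) -> CommunicationPropensityMatrix:
    """CP_ij: population variance over frames of the distance d_ij.

    Invariant under any per-frame rigid transform of the whole molecule,
    so superposition is unnecessary (and harmless).
    """
    _, var = _distance_moments(ensemble)
    return CommunicationPropensityMatrix(values=var)


def communication_threshold(
    cp: CommunicationPropensityMatrix,
    window: int = 4,
    chain_ids: np.ndarray | None = None,
) -> CommunicationThreshold:
    """Average CP between sequence neighbours, the global efficiency cutoff.

    For each residue i the CP values to neighbours j in i-window..i+window
    (j != i) are averaged; the window truncates at chain termini and never
    crosses a chain boundary (``chain_ids``, one label per residue, defaults
    to a single chain). The threshold is the mean of the per-residue
    averages over all residues.
    """
    values = cp.values
    n = values.shape[0]
    if n < 2:
        raise ValueError("need at least 2 residues")
    if chain_ids is None:
        chain_ids = np.zeros(n, dtype=object)
    chain_ids = np.asarray(chain_ids, dtype=object)
    per_res = np.zeros(n)
    terms = np.zeros(n, dtype=int)
    for i in range(n):
        lo = max(0, i - window)
        hi = min(n - 1, i + window)
        js = [j for j in range(lo, hi + 1) if j != i and chain_ids[j] == chain_ids[i]]
        terms[i] = len(js)
        per_res[i] = values[i, js].mean() if js else 0.0
    return CommunicationThreshold(
        value=float(per_res.mean()),
        window=window,
        per_residue_means=per_res,
        terms_per_residue=terms,
    )


def efficient_pairs(
    cp: CommunicationPropensityMatrix, threshold: CommunicationThreshold | float
) -> EfficiencyMatrix:
    """Pairs communicating efficiently: CP_ij <= threshold (equality counts)."""
    thr = threshold.value if isinstance(threshold, CommunicationThreshold) else float(threshold)
    if thr < 0:
        raise ValueError("threshold must be >= 0")
    eff = cp.values <= thr
    np.fill_diagonal(eff, False)
    return EfficiencyMatrix(values=eff, threshold=thr)


def lrcc_profile(
    eff: EfficiencyMatrix,
    dist: MeanDistanceMatrix,
    delta: float,
    state_label: str = "",
) -> LRCCProfile:
    """LRCC density: fraction of the other N-1 residues that communicate
    efficiently with residue i from a mean distance greater than ``delta``.

    The gating distance is the trajectory-mean <d_ij> (self-consistent with
    CP's averaging); pass a single-frame "ensemble" distance matrix to gate
    on a reference structure instead.
    """
    if delta <= 0:
        raise ValueError("delta must be > 0")
    n = dist.n_residues
    if eff.values.shape != (n, n):
        raise ValueError("efficiency and distance matrices disagree in size")
    # ties at the reference distance are excluded; the 1e-9 A tolerance
    # keeps exact geometric boundaries stable against rounding
    qualifying = eff.values & (dist.values - delta > 1e-9)
    np.fill_diagonal(qualifying, False)
    densities = qualifying.sum(axis=1) / (n - 1)
    return LRCCProfile(densities=densities, reference_distance=float(delta), state_label=state_label)


def relative_lrcc(a: LRCCProfile, b: LRCCProfile) -> RelativeLRCCProfile:
    """delta-LRCC = profile(a) - profile(b), elementwise.

    Positive values mean state ``a`` (conventionally the mutant or perturbed
    state) communicates better over long range at this delta.
    """
    if len(a.densities) != len(b.densities):
        raise ValueError("profiles have different residue counts")
    if a.reference_distance != b.reference_distance:
        raise ValueError(
            f"profiles computed at different deltas: "
            f"{a.reference_distance} vs {b.reference_distance}"
        )
    return RelativeLRCCProfile(
        deltas=a.densities - b.densities,
        state_a=a.state_label,
        state_b=b.state_label,
        reference_distance=a.reference_distance,
    )


def detect_peak_clusters(
    profile: LRCCProfile, z_cut: float = 1.0, min_run: int = 3
) -> PeakClusterSet:
    """Contiguous residue runs whose LRCC density exceeds mean + z_cut * SD.

    Runs shorter than ``min_run`` are discarded. These clusters are the
    candidates for allosterically coupled structural elements. A flat
    (zero-variance) profile yields no clusters.
    """
    d = profile.densities
    if len(d) < min_run:
        raise ValueError("profile shorter than min_run")
    sd = d.std()
    if sd == 0:
        logger.info("flat LRCC profile: no peak clusters")
        return PeakClusterSet(clusters=[], cutoff=float(d.mean()))
    cutoff = d.mean() + z_cut * sd
    above = d > cutoff
    clusters: list[PeakCluster] = []
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                clusters.append(
                    PeakCluster(start=start, stop=i - 1, mean_density=float(d[start:i].mean()))
                )
            start = None
    return PeakClusterSet(clusters=clusters, cutoff=float(cutoff))
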