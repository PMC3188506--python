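"""Essential dynamics: coordinate covariance, PCA, correlation maps,
and flexibility (RMSD/RMSF) profiles.

The 3N x 3N covariance of centered Calpha coordinates (after rigid-body
motion is removed by superposition) is diagonalised; the leading
eigenvectors are the essential modes — the dominant collective motions —
and projections of the trajectory onto them give the per-frame amplitude
of each mode. The N x N dynamic cross-correlation map normalises the
trace of each 3x3 inter-residue covariance block by the residue
fluctuation magnitudes, giving values in [-1, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .ensemble import CoordinateEnsemble

logger = logging.getLogger(__name__)


@dataclass
class CoordinateCovariance:
    """Covariance of centered Calpha coordinates (3N x 3N, angstrom^2),
    population-normalised, plus the ensemble-mean structure."""

    matrix: np.ndarray
    mean_structure: np.ndarray  # (N, 3)
    n_frames_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")

    @property
    def n_residues(self) -> int:
        return self.mean_structure.shape[0]

    def residue_block(self, i: int, j: int) -> np.ndarray:
        return self.matrix[3 * i : 3 * i + 3, 3 * j : 3 * j + 3]


@dataclass
class ResidueCorrelationMap:
    """Dynamic cross-correlation map, N x N in [-1, 1]."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if ((self.matrix < -1 - 1e-9) | (self.matrix > 1 + 1e-9)).any():
            raise ValueError("correlations must lie in [-1, 1]")
        self.matrix = np.clip(self.matrix, -1.0, 1.0)


@dataclass
class EssentialModes:
    """Eigenpairs of the coordinate covariance, eigenvalues descending.

    ``eigenvectors[:, k]`` is the k-th mode (3N, orthonormal); the sign is
    fixed so that each mode's largest-magnitude component is positive.
    ``mean_structure`` is carried along so trajectories can be projected.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    mean_structure: np.ndarray

    @property
    def cumulative_variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return np.cumsum(self.eigenvalues) / total


@dataclass
class FlexibilityProfile:
    """Per-frame RMSD to a reference and per-residue RMSF about the mean."""

    rmsd_per_frame: np.ndarray
    rmsf_per_residue: np.ndarray


def subsample_frames(n_frames: int, count: int) -> np.ndarray:
    """Indices of ``count`` evenly spaced frames out of ``n_frames``."""
    if count >= n_frames:
        return np.arange(n_frames)
    return np.unique(np.linspace(0, n_frames - 1, count).round().astype(int))


def _warn_if_unsuperposed(coords: np.ndarray, mean: np.ndarray) -> None:
    # Heuristic: optimal rotation of a handful of frames onto the mean
    # should be near-identity if rigid-body motion was removed.
    idx = np.linspace(0, coords.shape[0] - 1, min(5, coords.shape[0])).astype(int)
    mean_c = mean - mean.mean(axis=0)
    worst = 0.0
    for f in idx:
        frame_c = coords[f] - coords[f].mean(axis=0)
        rot, _ = Rotation.align_vectors(mean_c, frame_c)
        worst = max(worst, np.rad2deg(rot.magnitude()))
    if worst > 5.0:
        logger.warning(
            "ensemble appears unsuperposed (net frame rotation up to %.1f deg); "
            "covariance will mix rigid-body and internal motion",
            worst,
        )


def coordinate_covariance(
    ensemble: CoordinateEnsemble,
    n_snapshots: int | None = None,
    stride: int | None = None,
) -> CoordinateCovariance:
    """Population covariance of centered coordinates over the (sub)sampled
    frames.

    ``n_snapshots`` picks that many evenly spaced frames (e.g. 500, the
    conventional snapshot count for a production trajectory); ``stride``
    takes every stride-th frame. Default: all frames. The ensemble should
    already be superposed; a net frame-to-frame rotation triggers a
    warning, not an error.
    """
    if n_snapshots is not None and stride is not None:
        raise ValueError("give n_snapshots or stride, not both")
    if stride is not None:
        idx = np.arange(0, ensemble.n_frames, stride)
    elif n_snapshots is not None:
        idx = subsample_frames(ensemble.n_frames, n_snapshots)
    else:
        idx = np.arange(ensemble.n_frames)
    if len(idx) < 2:
        raise ValueError("need at least 2 frames after subsampling")
    coords = ensemble.coords[idx]
    mean = coords.mean(axis=0)
    _warn_if_unsuperposed(coords, mean)
    flat = (coords - mean).reshape(len(idx), -1)
    cov = flat.T @ flat / len(idx)
    return CoordinateCovariance(matrix=cov, mean_structure=mean, n_frames_used=len(idx))


def residue_correlation(cov: CoordinateCovariance) -> ResidueCorrelationMap:
    """Reduce the 3N x 3N covariance to the N x N dynamic cross-correlation
    map: c_ij = tr(C_ij) / sqrt(tr(C_ii) tr(C_jj)).

    tr(C_ij) is <dr_i . dr_j>, the scalar covariance of the displacement
    vectors. Residues with zero variance get correlation 0 (warning).
    """
    n = cov.n_residues
    c = cov.matrix
    # trace of each 3x3 block without materialising blocks
    tr = np.zeros((n, n))
    for k in range(3):
        tr += c[k::3, k::3]
    diag = np.diag(tr).copy()
    zero = diag <= 0
    if zero.any():
        logger.warning("%d zero-variance residue(s): correlation set to 0", zero.sum())
        diag[zero] = 1.0
    norm = np.sqrt(np.outer(diag, diag))
    corr = tr / norm
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.clip(corr, -1.0, 1.0, out=corr)
    return ResidueCorrelationMap(matrix=corr)


def essential_modes(cov: CoordinateCovariance) -> EssentialModes:
    """Full eigendecomposition of the coordinate covariance, eigenvalues in
    descending order, mode signs fixed (largest-magnitude component
    positive) for reproducibility."""
    evals, evecs = np.linalg.eigh(cov.matrix)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for k in range(evecs.shape[1]):
        lead = np.argmax(np.abs(evecs[:, k]))
        if evecs[lead, k] < 0:
            evecs[:, k] = -evecs[:, k]
    return EssentialModes(
        eigenvalues=evals, eigenvectors=evecs, mean_structure=cov.mean_structure
    )


def project_frames(
    ensemble: CoordinateEnsemble, modes: EssentialModes, mode_index: int = 0
) -> np.ndarray:
    """Per-frame projection of centered coordinates onto one essential mode.

    For modes computed from this same ensemble (all frames), the population
    variance of the series equals the mode's eigenvalue.
    """
    if not (0 <= mode_index < modes.eigenvectors.shape[1]):
        raise IndexError(f"mode index {mode_index} out of range")
    centered = (ensemble.coords - modes.mean_structure).reshape(ensemble.n_frames, -1)
    return centered @ modes.eigenvectors[:, mode_index]


def flexibility_profile(
    ensemble: CoordinateEnsemble, reference: np.ndarray
) -> FlexibilityProfile:
    """Per-frame Calpha RMSD to ``reference`` and per-residue RMSF about the
    ensemble-mean structure (no re-superposition is performed here)."""
    reference = np.asarray(reference, dtype=float)
    diff = ensemble.coords - reference[None, :, :]
    rmsd = np.sqrt((diff**2).sum(axis=2).mean(axis=1))
    mean = ensemble.coords.mean(axis=0)
    dev = ensemble.coords - mean[None, :, :]
    rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    return FlexibilityProfile(rmsd_per_frame=rmsd, rmsf_per_residue=rmsf)


def segment_flexibility(
    ensemble: CoordinateEnsemble,
    reference: np.ndarray,
    segment_indices: np.ndarray,
    local_superposition: bool = False,
) -> FlexibilityProfile:
    """Flexibility of a residue subset (e.g. an activation loop or helix).

    By default the globally superposed frames are used and the RMSD/RMSF
    are simply restricted to the subset; with ``local_superposition`` each
    frame is first re-superposed on the subset alone, isolating internal
    segment flexibility from segment displacement.
    """
    from .trajectory_io import superpose_ensemble

    idx = np.asarray(segment_indices, dtype=int)
    sub = ensemble.select(idx)
    ref_sub = np.asarray(reference, dtype=float)[idx]
    if local_superposition:
        sub = superpose_ensemble(sub, ref_sub)
    return flexibility_profile(sub, ref_sub)
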