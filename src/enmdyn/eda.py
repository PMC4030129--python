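"""Essential dynamics: superposition, covariance PCA, clustering, DCCM.

The trajectory route to collective motions: (i) remove rigid-body motion by
least-squares fitting every frame to a reference, (ii) build the 3N×3N
coordinate covariance about the mean, (iii) diagonalize it.  Principal
components (PCs) are the trajectory's collective modes; their eigenvalues
are variances in Å².  Conformations are then grouped in the space of the
first PCs and the densest cluster — the most conformations per unit
fluctuation — feeds the cross-correlation analysis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .exceptions import (
    DegenerateSelectionError,
    ParameterError,
    ShapeError,
    UnsuperposedTrajectoryError,
)
from .nma import ModeSet
from .results import (
    BFACTOR_PREFACTOR,
    BFactorProfile,
    DCCM,
    dccm_from_covariance,
)
from .structure import Trajectory

logger = logging.getLogger("enmdyn")


@dataclass
class PCAResult:
    """Covariance PCA of a superposed trajectory.

    ``modes`` holds the PCs as a ModeSet (eigenvalues in Å², descending by
    variance, source "pca"); ``projections`` are centered frames projected
    on every PC; ``frames_used`` indexes the post-burn-in frames of the
    input trajectory.
    """

    mean_coords: np.ndarray       # (N, 3)
    modes: ModeSet
    projections: np.ndarray       # (F_used, 3N)
    frames_used: np.ndarray       # (F_used,) indices into the trajectory

    @property
    def n_frames(self) -> int:
        return self.projections.shape[0]


@dataclass
class ClusterSelection:
    """Densest-cluster pick in PC space.

    ``density_score`` is conformations per unit fluctuation: cluster size
    divided by the RMS fluctuation of its projections (frames·Å⁻¹; infinite
    for a zero-fluctuation cluster).
    """

    cluster_labels: np.ndarray    # per used frame, 1-based cluster ids
    selected_cluster: int
    density_score: float
    frame_indices: np.ndarray     # trajectory frame indices of the selection
    scores: dict

    @property
    def n_selected(self) -> int:
        return len(self.frame_indices)


def superpose(traj: Trajectory, reference: np.ndarray,
              fit_selection=None) -> Trajectory:
    """Least-squares fit every frame onto the reference (Kabsch rotation).

    Translation and proper rotation only (determinant +1; reflections are
    never applied).  ``fit_selection`` restricts the fit to a bead subset;
    the transform is applied to all beads.
    """
    reference = np.asarray(reference, dtype=float)
    if reference.shape != (traj.n_beads, 3):
        raise ShapeError(
            f"reference shape {reference.shape} does not match trajectory "
            f"({traj.n_beads} beads)")
    sel = (np.arange(traj.n_beads) if fit_selection is None
           else np.asarray(fit_selection, dtype=int))
    if len(sel) < 3:
        raise DegenerateSelectionError(
            f"fit selection has {len(sel)} beads; need ≥ 3")
    ref_sel = reference[sel]
    ref_centroid = ref_sel.mean(axis=0)
    ref_centered = ref_sel - ref_centroid
    if np.linalg.matrix_rank(ref_centered, tol=1e-8) < 2:
        raise DegenerateSelectionError("fit selection is collinear")

    fitted = np.empty_like(traj.frames)
    for f, frame in enumerate(traj.frames):
        frm_centroid = frame[sel].mean(axis=0)
        rot, _ = Rotation.align_vectors(ref_centered, frame[sel] - frm_centroid)
        fitted[f] = rot.apply(frame - frm_centroid) + ref_centroid
    return Trajectory(frames=fitted, dt=traj.dt, origin=traj.origin,
                      superposed=True, meta=dict(traj.meta))


def covariance_pca(traj: Trajectory,
                   burn_in_fraction: float = 1.0 / 6.0) -> PCAResult:
    """PCA of the Cα coordinate covariance after discarding burn-in.

    The default burn-in drops the first sixth of the run, mirroring the
    25-of-30-ns convention scaled to arbitrary lengths.  Population
    covariance; eigenvalues clipped at zero.
    """
    if not traj.superposed:
        raise UnsuperposedTrajectoryError(
            "trajectory must go through superpose() before PCA")
    if not 0 <= burn_in_fraction < 1:
        raise ParameterError("burn_in_fraction must be in [0, 1)")
    start = int(np.floor(burn_in_fraction * traj.n_frames))
    frames_used = np.arange(start, traj.n_frames)
    if len(frames_used) < 2:
        raise ParameterError(
            f"{len(frames_used)} frames after burn-in; need ≥ 2")
    x = traj.frames[frames_used].reshape(len(frames_used), -1)
    mean = x.mean(axis=0)
    xc = x - mean
    cov = xc.T @ xc / len(frames_used)
    vals, vecs = np.linalg.eigh(cov)
    vals, vecs = vals[::-1], vecs[:, ::-1]           # descending variance
    if np.any(vals < -1e-10 * max(vals[0], 1.0)):
        raise ParameterError("covariance eigenvalues significantly negative")
    vals = np.clip(vals, 0.0, None)
    # snap numerically-negligible variances (incl. a constant trajectory's
    # round-off) to exactly zero
    tiny = max(vals[0] * 1e-12, 1e-24)
    vals[vals < tiny] = 0.0
    n_zero = int(np.sum(vals == 0.0))
    modes = ModeSet(eigenvalues=vals, eigenvectors=vecs, n_zero=0,
                    source="pca", meta={"n_negligible": n_zero})
    return PCAResult(mean_coords=mean.reshape(-1, 3), modes=modes,
                     projections=xc @ vecs, frames_used=frames_used)


def cluster_select(pca: PCAResult, n_components: int = 3,
                   grid_bins: int = 20) -> ClusterSelection:
    """Pick the cluster with the most conformations per unit fluctuation.

    Frames are histogram-binned in the space of the first ``n_components``
    PCs; clusters are the face-connected sets of occupied bins.  The score
    of a cluster is its frame count over the RMS fluctuation of its
    projections; ties go to the lowest cluster id.
    """
    if pca.n_frames < 10:
        raise ParameterError(
            f"clustering needs ≥ 10 frames, got {pca.n_frames}")
    if pca.projections.shape[1] < n_components:
        raise ParameterError("fewer PCs than n_components")
    p = pca.projections[:, :n_components]

    bin_idx = np.empty_like(p, dtype=int)
    widths = np.zeros(n_components)
    for d in range(n_components):
        lo, hi = p[:, d].min(), p[:, d].max()
        if hi - lo <= 0:
            bin_idx[:, d] = 0
            continue
        widths[d] = (hi - lo) / grid_bins
        edges = np.linspace(lo, hi, grid_bins + 1)
        bin_idx[:, d] = np.clip(np.digitize(p[:, d], edges) - 1,
                                0, grid_bins - 1)
    # a cluster cannot be localized below the grid resolution: clusters with
    # zero projection spread (single occupied point) get half a bin diagonal
    fluct_floor = 0.5 * float(np.sqrt(np.sum(widths ** 2)))

    occupancy = np.zeros((grid_bins,) * n_components, dtype=bool)
    occupancy[tuple(bin_idx.T)] = True
    structure = ndimage.generate_binary_structure(n_components, 1)
    labels_grid, n_clusters = ndimage.label(occupancy, structure=structure)
    labels = labels_grid[tuple(bin_idx.T)]

    best_id, best_score, scores = -1, -1.0, {}
    for cid in range(1, n_clusters + 1):
        members = np.flatnonzero(labels == cid)
        proj = p[members]
        fluct = float(np.sqrt(np.mean(
            np.sum((proj - proj.mean(axis=0)) ** 2, axis=1))))
        if fluct == 0.0:
            fluct = fluct_floor
        score = np.inf if fluct == 0 else len(members) / fluct
        scores[cid] = {"n_frames": int(len(members)), "rms_fluct": fluct,
                       "density": score}
        if score > best_score:
            best_id, best_score = cid, score
    members = np.flatnonzero(labels == best_id)
    return ClusterSelection(cluster_labels=labels, selected_cluster=best_id,
                            density_score=best_score,
                            frame_indices=pca.frames_used[members],
                            scores=scores)


def _subset_frames(traj: Trajectory, frame_subset) -> np.ndarray:
    if frame_subset is None:
        return traj.frames
    if isinstance(frame_subset, ClusterSelection):
        idx = frame_subset.frame_indices
    else:
        idx = np.asarray(frame_subset, dtype=int)
    return traj.frames[idx]


def _raw_covariance(frames: np.ndarray) -> np.ndarray:
    x = frames.reshape(frames.shape[0], -1)
    xc = x - x.mean(axis=0)
    return xc.T @ xc / frames.shape[0]


def eda_dccm(source: Trajectory | PCAResult, mode_list=(1, 2, 3),
             frame_subset=None) -> DCCM:
    """Trajectory cross-correlation map.

    Given a :class:`PCAResult`, the covariance is reconstructed from the
    PCs in ``mode_list`` (default PCs 1–3, matching the combined-mode maps
    of the normal-mode route); ``mode_list=None`` uses all PCs, which is
    identical to the raw-frame covariance.  Given a superposed trajectory,
    the raw covariance of ``frame_subset`` (all frames, an index list, or a
    :class:`ClusterSelection`) is used directly.
    """
    if isinstance(source, PCAResult):
        modes = source.modes
        ks = (list(range(1, modes.n_nonzero + 1)) if mode_list is None
              else list(mode_list))
        v = np.column_stack([modes.mode(k) for k in ks])
        lam = np.array([modes.mode_eigenvalue(k) for k in ks])
        cov = (v * lam) @ v.T
        return dccm_from_covariance(cov, method="eda",
                                    provenance={"mode_list": ks})
    if not source.superposed:
        raise UnsuperposedTrajectoryError(
            "trajectory must be superposed before DCCM")
    frames = _subset_frames(source, frame_subset)
    cov = _raw_covariance(frames)
    return dccm_from_covariance(cov, method="eda",
                                provenance={"n_frames": frames.shape[0]})


def eda_bfactors(traj: Trajectory, frame_subset=None,
                 resids=None, source: str = "eda") -> BFactorProfile:
    """B_i = (8π²/3)·mean-square deviation of bead i from its mean position."""
    if not traj.superposed:
        raise UnsuperposedTrajectoryError(
            "trajectory must be superposed before B-factor extraction")
    frames = _subset_frames(traj, frame_subset)
    mean = frames.mean(axis=0)
    msf = np.mean(np.sum((frames - mean) ** 2, axis=2), axis=0)
    return BFactorProfile(values=BFACTOR_PREFACTOR * msf, source=source,
                          resids=resids)
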