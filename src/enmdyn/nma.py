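"""Normal mode analysis of the ANM Hessian.

Diagonalizing the 3N×3N Hessian of a connected network yields six zero
eigenvalues (rigid translations/rotations) and 3N−6 internal modes.  "Mode
k" throughout means the k-th *internal* mode counted from the softest.
Thermal amplitudes scale as λ⁻¹, so the positional covariance restricted to
a mode subset is

    C = k_B T · Σ_k λ_k⁻¹ v_k v_kᵀ   (Å²),

from which B-factors and cross-correlation maps follow.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .constants import KB_KCAL
from .enm import HessianMatrix
from .exceptions import ParameterError
from .results import BFactorProfile, DCCM, bfactors_from_covariance, \
    dccm_from_covariance

logger = logging.getLogger("enmdyn")

#: Six rigid-body modes for one connected body in 3-D.
N_RIGID_BODY_MODES = 6


@dataclass
class ModeSet:
    """Eigenpairs of an ANM Hessian or a trajectory covariance matrix.

    Eigenvalues are stored with mode 1 first: ascending stiffness for
    ``source="anm"`` (soft internal modes first, after the zero block),
    descending variance for ``source="pca"``.  Eigenvectors are unit
    3N-columns of ``eigenvectors``.
    """

    eigenvalues: np.ndarray       # (n_modes,)
    eigenvectors: np.ndarray      # (3N, n_modes)
    n_zero: int
    source: str                   # "anm" | "pca"
    meta: dict = field(default_factory=dict)

    @property
    def n_beads(self) -> int:
        return self.eigenvectors.shape[0] // 3

    @property
    def n_nonzero(self) -> int:
        return len(self.eigenvalues) - self.n_zero

    def _nonzero_index(self, k: int) -> int:
        if k < 1 or k > self.n_nonzero:
            raise ParameterError(
                f"mode index {k} outside 1..{self.n_nonzero} (zero modes are "
                "not addressable)")
        return self.n_zero + k - 1

    def mode(self, k: int) -> np.ndarray:
        """Unit eigenvector of the k-th nonzero mode (1-based), shape (3N,)."""
        return self.eigenvectors[:, self._nonzero_index(k)]

    def mode_eigenvalue(self, k: int) -> float:
        return float(self.eigenvalues[self._nonzero_index(k)])

    def mode_displacements(self, k: int) -> np.ndarray:
        """The k-th nonzero mode reshaped to per-bead 3-vectors (N, 3)."""
        return self.mode(k).reshape(-1, 3)

    def to_tsv(self, path, n_modes: int | None = None) -> None:
        n = n_modes or self.n_nonzero
        rows = []
        for k in range(1, n + 1):
            rows.append([k, self.mode_eigenvalue(k), *self.mode(k)])
        cols = ["mode", "eigenvalue"] + [
            f"v{i}" for i in range(self.eigenvectors.shape[0])]
        pd.DataFrame(rows, columns=cols).to_csv(
            path, sep="\t", index=False, float_format="%.8g")


def compute_modes(h: HessianMatrix, zero_tol_rel: float = 1e-8) -> ModeSet:
    """Dense symmetric eigendecomposition, ascending eigenvalues.

    Modes with λ < zero_tol_rel·λ_max are flagged as zero modes.  More than
    six zero modes means the network is disconnected; that is propagated as
    a warning and recorded in ``meta``.
    """
    vals, vecs = eigh(h.entries)
    lam_max = vals[-1] if len(vals) else 0.0
    n_zero = int(np.sum(vals < zero_tol_rel * max(lam_max, 0.0)))
    meta = {}
    if n_zero > N_RIGID_BODY_MODES:
        logger.warning("found %d zero modes (> 6): network disconnected",
                       n_zero)
        meta["disconnected"] = True
    return ModeSet(eigenvalues=vals, eigenvectors=vecs, n_zero=n_zero,
                   source="anm", meta=meta)


def mode_covariance(modes: ModeSet, k_list, temperature: float) -> np.ndarray:
    """Thermal positional covariance of the selected nonzero modes, Å².

    C = k_B T Σ_{k∈k_list} λ_k⁻¹ v_k v_kᵀ; positive semidefinite of rank
    |k_list|.  Zero modes are not addressable through ``k_list``.
    """
    if temperature < 0:
        raise ParameterError("temperature must be non-negative")
    k_list = list(k_list)
    if not k_list:
        raise ParameterError("k_list is empty")
    idx = [modes._nonzero_index(k) for k in k_list]
    lam = modes.eigenvalues[idx]
    if np.any(lam <= 0):
        raise ParameterError("selected mode has non-positive eigenvalue")
    v = modes.eigenvectors[:, idx]
    return KB_KCAL * temperature * (v / lam) @ v.T


def all_nonzero_modes(modes: ModeSet) -> list[int]:
    return list(range(1, modes.n_nonzero + 1))


def nma_bfactors(modes: ModeSet, temperature: float = 298.0,
                 k_list=None, resids=None) -> BFactorProfile:
    """Per-bead thermal B-factors from the selected modes (default: all)."""
    k_list = k_list if k_list is not None else all_nonzero_modes(modes)
    cov = mode_covariance(modes, k_list, temperature)
    prof = bfactors_from_covariance(cov, source="nma", resids=resids)
    return prof


def nma_dccm(modes: ModeSet, k_list=(1, 2, 3),
             temperature: float = 298.0) -> DCCM:
    """Cross-correlation map of the selected modes (default: modes 1–3).

    The normalization cancels temperature and any uniform spring rescaling.
    """
    cov = mode_covariance(modes, k_list, temperature)
    return dccm_from_covariance(cov, method="nma",
                                provenance={"k_list": list(k_list)})
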