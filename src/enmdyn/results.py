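"""Shared result containers: displacement fields, DCCMs, B-factor profiles.

These are produced by both the normal-mode route (nma) and the trajectory
route (eda), and consumed by the comparison layer, so they live apart from
either.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ShapeError

logger = logging.getLogger("enmdyn")

# B = (8π²/3) ⟨Δr²⟩ converts a mean-square fluctuation (Å²) to a B-factor.
BFACTOR_PREFACTOR = 8.0 * np.pi ** 2 / 3.0


@dataclass
class DisplacementField:
    """Per-bead 3-vector displacements Δr_i with a provenance tag."""

    values: np.ndarray            # (N, 3)
    source: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ShapeError(
                f"displacement field must be (N, 3), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("displacement field contains non-finite values")

    @property
    def n_beads(self) -> int:
        return self.values.shape[0]


@dataclass
class DCCM:
    """Dynamic cross-correlation map: N×N, values in [−1, 1], unit diagonal.

    Beads with zero fluctuation in the analyzed subspace get zeroed rows
    (0/0 guard); ``guarded`` lists their indices.
    """

    matrix: np.ndarray
    method: str = ""
    provenance: dict = field(default_factory=dict)
    guarded: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.matrix.shape[0]
        if self.matrix.shape != (n, n):
            raise ShapeError(f"DCCM must be square, got {self.matrix.shape}")
        if self.guarded is None:
            self.guarded = np.zeros(0, dtype=int)

    @property
    def n_beads(self) -> int:
        return self.matrix.shape[0]

    def block_mean(self, rows: np.ndarray, cols: np.ndarray) -> float:
        """Mean correlation over a rectangular residue block."""
        return float(np.mean(self.matrix[np.ix_(rows, cols)]))

    def to_csv(self, path, labels=None) -> None:
        n = self.n_beads
        labels = labels if labels is not None else np.arange(1, n + 1)
        df = pd.DataFrame(self.matrix, index=labels, columns=labels)
        df.to_csv(path, float_format="%.6f")


@dataclass
class BFactorProfile:
    """Per-bead B-factors (Å² raw, dimensionless when normalized)."""

    values: np.ndarray
    source: str = ""              # crystal | nma | eda | ceda
    normalization: str = "raw"    # raw | zscore | minmax
    resids: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ShapeError("B-factor profile must be 1-D")
        if self.resids is not None:
            self.resids = np.asarray(self.resids, dtype=int)
            if len(self.resids) != len(self.values):
                raise ShapeError("resids length mismatch")

    @property
    def n_beads(self) -> int:
        return len(self.values)


@dataclass
class OverlapTable:
    """Tidy table of per-mode-pair overlaps, full-protein and per-domain."""

    table: pd.DataFrame           # columns: scope, mode, overlap, note

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6f")

    def value(self, scope: str, mode) -> float:
        row = self.table[(self.table["scope"] == scope)
                         & (self.table["mode"].astype(str) == str(mode))]
        if row.empty:
            raise KeyError(f"no overlap row for scope={scope!r} mode={mode!r}")
        return float(row["overlap"].iloc[0])


def dccm_from_covariance(cov: np.ndarray, method: str = "",
                         provenance: dict | None = None) -> DCCM:
    """Normalize a 3N×3N positional covariance into a DCCM.

    CC_ij = tr(C_ij) / sqrt(tr(C_ii)·tr(C_jj)) — the 3-D vector form of the
    scalar cross-correlation coefficient.  Beads whose own fluctuation
    vanishes get zero correlations and a logged warning.
    """
    three_n = cov.shape[0]
    if cov.shape != (three_n, three_n) or three_n % 3:
        raise ShapeError(f"covariance must be 3N×3N, got {cov.shape}")
    n = three_n // 3
    blocks = cov.reshape(n, 3, n, 3)
    cross = np.trace(blocks, axis1=1, axis2=3)        # (N, N) tr(C_ij)
    msf = np.diag(cross).copy()                       # tr(C_ii)
    guarded = np.flatnonzero(msf <= 0)
    if guarded.size:
        logger.warning("DCCM: %d bead(s) with zero fluctuation; their "
                       "correlations set to 0", guarded.size)
        msf[guarded] = 1.0
    denom = np.sqrt(np.outer(msf, msf))
    cc = cross / denom
    cc[guarded, :] = 0.0
    cc[:, guarded] = 0.0
    np.fill_diagonal(cc, 1.0)
    cc[guarded, guarded] = 0.0
    cc = np.clip(cc, -1.0, 1.0)
    return DCCM(matrix=cc, method=method, provenance=provenance or {},
                guarded=guarded)


def bfactors_from_covariance(cov: np.ndarray, source: str,
                             resids=None) -> BFactorProfile:
    """B_i = (8π²/3)·tr(C_ii) from a 3N×3N positional covariance."""
    n = cov.shape[0] // 3
    msf = np.array([np.trace(cov[3 * i:3 * i + 3, 3 * i:3 * i + 3])
                    for i in range(n)])
    return BFactorProfile(values=BFACTOR_PREFACTOR * msf, source=source,
                          resids=resids)
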