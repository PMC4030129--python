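"""Cross-method comparison: overlaps, B-factor tracks, DCCM pairing.

The central statistic is the normalized absolute inner product of two
per-bead displacement fields,

    O = |Σ_i Δr_i^A · Δr_i^B| / sqrt(Σ_i |Δr_i^A|² · Σ_i |Δr_i^B|²) ∈ [0, 1],

(1 = identical directions of collective motion, 0 = orthogonal), evaluated
mode-against-mode between a normal-mode set and a trajectory PC set, over
the full protein or restricted to a domain.  B-factor profiles from
different sources are compared after z-score normalization; two DCCMs are
paired into one composite matrix (first method above the diagonal, second
below) with per-block summaries.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import (
    ParameterError,
    ShapeError,
    UndefinedOverlapError,
    ZeroVarianceError,
)
from .nma import ModeSet
from .results import BFactorProfile, DCCM, DisplacementField, OverlapTable


def _field_values(f) -> np.ndarray:
    return f.values if isinstance(f, DisplacementField) else \
        np.asarray(f, dtype=float)


def overlap(a, b, selection=None) -> float:
    """Mode overlap between two displacement fields, in [0, 1].

    Accepts :class:`DisplacementField` or bare (N, 3) arrays; ``selection``
    restricts the sum to a bead subset.  Sign- and scale-invariant; raises
    if either field vanishes on the selection.
    """
    va, vb = _field_values(a), _field_values(b)
    if va.shape != vb.shape:
        raise ShapeError(f"field shapes differ: {va.shape} vs {vb.shape}")
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        va, vb = va[sel], vb[sel]
    na2 = float(np.sum(va * va))
    nb2 = float(np.sum(vb * vb))
    if na2 == 0.0 or nb2 == 0.0:
        raise UndefinedOverlapError(
            "overlap undefined: a displacement field is zero on the selection")
    return float(abs(np.sum(va * vb)) / np.sqrt(na2 * nb2))


def mode_overlap_table(set_a: ModeSet, set_b: ModeSet, n_modes: int = 3,
                       domains: dict[str, np.ndarray] | None = None,
                       pairing: str = "index") -> OverlapTable:
    """Index-paired overlaps (mode k vs mode/PC k) plus per-scope averages.

    ``domains`` maps scope names to bead-index arrays; the full protein is
    always included as scope "full".  ``pairing="best"`` instead pairs each
    mode of ``set_a`` with its maximum-overlap partner in the first
    ``n_modes`` of ``set_b`` (diagnostic; never the default).  A domain on
    which both fields vanish yields a NaN overlap with an explanatory note
    rather than silently dropping the row.
    """
    if set_a.n_beads != set_b.n_beads:
        raise ShapeError("mode sets have different bead counts")
    if n_modes < 1 or n_modes > min(set_a.n_nonzero, set_b.n_nonzero):
        raise ParameterError(
            f"n_modes={n_modes} exceeds available nonzero modes")
    if pairing not in ("index", "best"):
        raise ParameterError(f"unknown pairing {pairing!r}")
    scopes = {"full": None}
    if domains:
        scopes.update({name: np.asarray(idx, dtype=int)
                       for name, idx in domains.items()})
    rows = []
    for scope, sel in scopes.items():
        values = []
        for k in range(1, n_modes + 1):
            da = set_a.mode_displacements(k)
            if pairing == "index":
                partners = [k]
            else:
                partners = range(1, n_modes + 1)
            best, best_j, note = np.nan, k, ""
            for j in partners:
                db = set_b.mode_displacements(j)
                try:
                    o = overlap(da, db, selection=sel)
                except UndefinedOverlapError:
                    note = "undefined (zero field on selection)"
                    continue
                if not (best == best) or o > best:   # NaN-safe max
                    best, best_j = o, j
            rows.append({"scope": scope, "mode": str(k),
                         "partner": str(best_j), "overlap": best,
                         "note": note})
            if best == best:
                values.append(best)
        rows.append({"scope": scope, "mode": "average", "partner": "",
                     "overlap": float(np.mean(values)) if values else np.nan,
                     "note": "" if values else "no defined overlaps"})
    return OverlapTable(table=pd.DataFrame(
        rows, columns=["scope", "mode", "partner", "overlap", "note"]))


def normalize_bfactors(p: BFactorProfile,
                       method: str = "zscore") -> BFactorProfile:
    """Normalize a B-factor profile for cross-source comparison.

    z-score (default: mean 0, population SD 1 over defined entries) or
    min-max to [0, 1].  Idempotent when the profile already carries the
    requested normalization; a constant profile cannot be normalized.
    """
    if method not in ("zscore", "minmax"):
        raise ParameterError(f"unknown normalization {method!r}")
    if p.normalization == method:
        return BFactorProfile(values=p.values.copy(), source=p.source,
                              normalization=method, resids=p.resids)
    defined = np.isfinite(p.values)
    v = p.values[defined]
    if v.size == 0:
        raise ZeroVarianceError("profile has no defined entries")
    out = np.full_like(p.values, np.nan)
    if method == "zscore":
        sd = float(np.std(v))
        if sd == 0:
            raise ZeroVarianceError("constant profile: z-score undefined")
        out[defined] = (v - v.mean()) / sd
    else:
        span = float(v.max() - v.min())
        if span == 0:
            raise ZeroVarianceError("constant profile: min-max undefined")
        out[defined] = (v - v.min()) / span
    return BFactorProfile(values=out, source=p.source, normalization=method,
                          resids=p.resids)


def bfactor_delta(bound: BFactorProfile,
                  unbound: BFactorProfile) -> np.ndarray:
    """Elementwise bound − unbound on matching (normalized) profiles."""
    if bound.normalization == "raw" or unbound.normalization == "raw":
        raise ParameterError("normalize both profiles before differencing")
    if bound.resids is not None and unbound.resids is not None:
        if len(bound.resids) != len(unbound.resids) or \
                np.any(bound.resids != unbound.resids):
            missing = sorted(set(bound.resids.tolist())
                             ^ set(unbound.resids.tolist()))
            raise ShapeError(
                f"profiles cover different residues; unmatched resids: "
                f"{missing[:20]}")
    elif bound.n_beads != unbound.n_beads:
        raise ShapeError(
            f"profiles have {bound.n_beads} vs {unbound.n_beads} beads")
    return bound.values - unbound.values


def dccm_pair_report(m1: DCCM, m2: DCCM, regions=None):
    """Composite DCCM (m1 above the diagonal, m2 below) + block summary.

    ``regions`` is a list of (name, row_indices, col_indices) rectangular
    bead blocks; for each, the mean CC and mean |CC| of both methods are
    tabulated — the quantitative handle on which method sees stronger
    coupled motion in that block.
    """
    if m1.n_beads != m2.n_beads:
        raise ShapeError("DCCMs have different sizes")
    n = m1.n_beads
    composite = np.where(np.triu(np.ones((n, n), dtype=bool), 1),
                         m1.matrix, m2.matrix)
    np.fill_diagonal(composite, 1.0)
    comp = DCCM(matrix=composite,
                method=f"{m1.method or 'A'}|{m2.method or 'B'}",
                provenance={"above": m1.method, "below": m2.method})
    rows = []
    for name, ridx, cidx in (regions or []):
        ridx = np.asarray(ridx, dtype=int)
        cidx = np.asarray(cidx, dtype=int)
        for tag, m in ((m1.method or "A", m1), (m2.method or "B", m2)):
            block = m.matrix[np.ix_(ridx, cidx)]
            rows.append({"region": name, "method": tag,
                         "mean_cc": float(block.mean()),
                         "mean_abs_cc": float(np.abs(block).mean())})
    summary = pd.DataFrame(rows,
                           columns=["region", "method", "mean_cc",
                                    "mean_abs_cc"])
    return comp, summary


def save_dccm_heatmap(dccm: DCCM, path, title: str = "") -> None:
    """Render a DCCM to an image file (diverging map, fixed [−1, 1] scale)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4.4))
    im = ax.imshow(dccm.matrix, cmap="RdBu_r", vmin=-1, vmax=1,
                   origin="lower")
    ax.set_xlabel("residue index")
    ax.set_ylabel("residue index")
    ax.set_title(title or dccm.method)
    fig.colorbar(im, ax=ax, label="cross-correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
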