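"""Cα-level structures, trajectories, and domain annotations.

One bead per residue: coordinates, residue mass, experimental B-factor and
chain/residue labels.  PDB reading and multi-model writing go through
biotite; the plain XYZ dialect (count line, comment line, ``element x y z``)
is handled directly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .constants import DEFAULT_RESIDUE_MASS, RESIDUE_MASSES
from .exceptions import (
    DomainError,
    EmptySelectionError,
    ParameterError,
    PDBParseError,
    ShapeError,
    TrajectoryFormatError,
)

logger = logging.getLogger("enmdyn")

#: Sanity band for consecutive Cα-Cα distances (Å); outside it a chain break
#: is assumed and logged unless the beads sit on different chains.
DEFAULT_BOND_BAND = (2.5, 4.5)


@dataclass
class CalphaModel:
    """One bead per residue of a coarse-grained protein model.

    Beads are ordered as in the source file (robust to renumbered PDBs).
    ``resids`` are author residue numbers; ``icodes`` hold insertion codes.
    ``bfactor_exp`` is NaN where the crystallographic B-factor is absent.
    ``domains`` holds an empty string for untagged beads.
    """

    coords: np.ndarray                      # (N, 3) Å
    resids: np.ndarray                      # (N,) int
    chains: np.ndarray                      # (N,) str
    resnames: np.ndarray                    # (N,) str
    icodes: np.ndarray | None = None        # (N,) str
    masses: np.ndarray | None = None        # (N,) amu
    bfactor_exp: np.ndarray | None = None   # (N,) Å²
    domains: np.ndarray | None = None       # (N,) str

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ShapeError(f"coords must be (N, 3), got {self.coords.shape}")
        n = self.coords.shape[0]
        if n < 2:
            raise ParameterError(f"a Cα model needs at least 2 beads, got {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError("coords contain non-finite values")
        self.resids = np.asarray(self.resids, dtype=int)
        self.chains = np.asarray(self.chains, dtype="U4")
        self.resnames = np.asarray(self.resnames, dtype="U5")
        if self.icodes is None:
            self.icodes = np.full(n, "", dtype="U2")
        if self.masses is None:
            self.masses = masses_from_resnames(self.resnames)
        self.masses = np.asarray(self.masses, dtype=float)
        if np.any(self.masses <= 0):
            raise ParameterError("bead masses must be strictly positive")
        if self.bfactor_exp is None:
            self.bfactor_exp = np.full(n, np.nan)
        self.bfactor_exp = np.asarray(self.bfactor_exp, dtype=float)
        if self.domains is None:
            self.domains = np.full(n, "", dtype="U32")
        for name, arr in [("resids", self.resids), ("chains", self.chains),
                          ("resnames", self.resnames), ("icodes", self.icodes),
                          ("masses", self.masses),
                          ("bfactor_exp", self.bfactor_exp),
                          ("domains", self.domains)]:
            if len(arr) != n:
                raise ShapeError(f"{name} has length {len(arr)}, expected {n}")
        self._check_bond_lengths()

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def _check_bond_lengths(self, band=DEFAULT_BOND_BAND):
        d = np.linalg.norm(np.diff(self.coords, axis=0), axis=1)
        same_chain = self.chains[1:] == self.chains[:-1]
        odd = same_chain & ((d < band[0]) | (d > band[1]))
        for i in np.flatnonzero(odd):
            logger.warning(
                "consecutive-bead distance %.2f Å between resid %s and %s "
                "outside sanity band %s; treating as chain break",
                d[i], self.resids[i], self.resids[i + 1], band,
            )

    def copy(self) -> "CalphaModel":
        return CalphaModel(
            coords=self.coords.copy(), resids=self.resids.copy(),
            chains=self.chains.copy(), resnames=self.resnames.copy(),
            icodes=self.icodes.copy(), masses=self.masses.copy(),
            bfactor_exp=self.bfactor_exp.copy(), domains=self.domains.copy(),
        )

    def residue_labels(self) -> np.ndarray:
        """Author residue numbers with insertion codes concatenated."""
        return np.array([f"{r}{i}" for r, i in zip(self.resids, self.icodes)])

    def domain_indices(self) -> dict[str, np.ndarray]:
        """Map each domain name to the bead indices it tags."""
        out: dict[str, np.ndarray] = {}
        for name in dict.fromkeys(self.domains[self.domains != ""]):
            out[str(name)] = np.flatnonzero(self.domains == name)
        return out


@dataclass
class DomainDefinition:
    """A named set of inclusive author-residue-number intervals."""

    name: str
    ranges: list[tuple[int, int]]

    def __post_init__(self):
        if not self.ranges:
            raise DomainError(f"domain {self.name!r} has no ranges")
        for lo, hi in self.ranges:
            if hi < lo:
                raise DomainError(
                    f"domain {self.name!r}: empty interval ({lo}, {hi})")

    def mask(self, resids: np.ndarray) -> np.ndarray:
        m = np.zeros(len(resids), dtype=bool)
        for lo, hi in self.ranges:
            m |= (resids >= lo) & (resids <= hi)
        return m


@dataclass
class Trajectory:
    """Ordered Cα coordinate frames with timestep metadata.

    ``dt`` is the time per *saved* frame in ps.  ``origin`` tags provenance
    (``cgmd``, ``ensemble_sample`` or ``external``); ``superposed`` records
    whether rigid-body motion has been removed, a precondition for PCA.
    """

    frames: np.ndarray                       # (F, N, 3) Å
    dt: float = 1.0
    origin: str = "external"
    superposed: bool = False
    velocities: np.ndarray | None = None     # (F, N, 3) Å/ps, cgmd only
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ShapeError(f"frames must be (F, N, 3), got {self.frames.shape}")
        if self.frames.shape[0] == 0:
            raise TrajectoryFormatError("trajectory has no frames")
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_beads(self) -> int:
        return self.frames.shape[1]


def masses_from_resnames(resnames) -> np.ndarray:
    """Total residue masses from 3-letter codes; unknown types get 110 amu."""
    out = np.empty(len(resnames))
    for k, name in enumerate(resnames):
        key = str(name).upper()
        if key in RESIDUE_MASSES:
            out[k] = RESIDUE_MASSES[key]
        else:
            out[k] = DEFAULT_RESIDUE_MASS
            if key not in ("UNK", ""):
                logger.debug("unknown residue type %r: using %.0f amu",
                             key, DEFAULT_RESIDUE_MASS)
    return out


def read_calpha_pdb(path, chain: str | None = None) -> CalphaModel:
    """Read a PDB file into a one-bead-per-residue model.

    The CA atom of each residue becomes one bead (for alternate locations,
    the alphabetically first altloc wins).  Residues without a CA atom are
    skipped with a logged warning.  HETATM, TER, waters and header records
    are ignored.

    Parameters
    ----------
    path:
        PDB-format text file containing ATOM records.
    chain:
        Optional chain identifier; restricts the model to that chain.
    """
    try:
        pdb = bpdb.PDBFile.read(str(path))
        atoms = pdb.get_structure(model=1, altloc="all",
                                  extra_fields=["b_factor"])
    except Exception as exc:
        raise PDBParseError(f"{path}: not readable as PDB ({exc})") from exc
    atoms = atoms[~atoms.hetero]
    if atoms.array_length() == 0:
        raise PDBParseError(f"{path}: no ATOM records")
    if chain is not None:
        sel = atoms.chain_id == chain
        if not np.any(sel):
            raise EmptySelectionError(
                f"{path}: no ATOM records on chain {chain!r} "
                f"(present: {sorted(set(atoms.chain_id))})")
        atoms = atoms[sel]

    # CA beads only; element check guards against calcium HETATMs that slip
    # through and against hydrogens named CA in odd files.
    is_ca = (atoms.atom_name == "CA") & (atoms.element != "CA")
    ca = atoms[is_ca]
    if ca.array_length() == 0:
        raise PDBParseError(f"{path}: no CA atoms found")

    seen: dict[tuple, int] = {}
    keep: dict[tuple, int] = {}        # residue key -> index into ca
    order: list[tuple] = []
    altloc = ca.get_annotation("altloc_id")
    for idx in range(ca.array_length()):
        res_key = (str(ca.chain_id[idx]), int(ca.res_id[idx]),
                   str(ca.ins_code[idx]))
        full_key = res_key + (str(altloc[idx]),)
        if full_key in seen:
            raise PDBParseError(
                f"{path}: duplicate CA record for chain {res_key[0]!r} "
                f"resid {res_key[1]}{res_key[2]} altloc {altloc[idx]!r}")
        seen[full_key] = idx
        if res_key not in keep:
            keep[res_key] = idx
            order.append(res_key)
        elif str(altloc[idx]) < str(altloc[keep[res_key]]):
            keep[res_key] = idx

    # warn about residues that have atoms but no CA
    all_res = dict.fromkeys(
        (str(c), int(r), str(i))
        for c, r, i in zip(atoms.chain_id, atoms.res_id, atoms.ins_code))
    for res_key in all_res:
        if res_key not in keep:
            logger.warning("residue %s%s (chain %s) has no CA atom; skipped",
                           res_key[1], res_key[2], res_key[0])

    rows = [keep[k] for k in order]
    ca = ca[rows]
    return CalphaModel(
        coords=ca.coord,
        resids=ca.res_id,
        chains=ca.chain_id,
        resnames=ca.res_name,
        icodes=ca.ins_code,
        bfactor_exp=ca.get_annotation("b_factor"),
    )


def _model_to_atom_array(model: CalphaModel, coords: np.ndarray) -> bst.AtomArray:
    n = model.n_beads
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id = model.chains
    arr.res_id = model.resids
    arr.ins_code = model.icodes
    arr.res_name = model.resnames
    arr.atom_name = np.full(n, "CA")
    arr.element = np.full(n, "C")
    arr.hetero = np.zeros(n, dtype=bool)
    b = np.where(np.isfinite(model.bfactor_exp), model.bfactor_exp, 0.0)
    arr.set_annotation("b_factor", b.astype(np.float32))
    return arr


def write_calpha_pdb(model: CalphaModel, path) -> None:
    """Write a single-model Cα PDB file."""
    pdb = bpdb.PDBFile()
    pdb.set_structure(_model_to_atom_array(model, model.coords))
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, model: CalphaModel, path,
                     format: str = "pdb") -> None:
    """Write a trajectory as multi-model PDB or plain XYZ.

    Round-trip safe to the format precision (PDB fixed width: 10⁻³ Å).
    """
    if traj.n_beads != model.n_beads:
        raise ShapeError(
            f"trajectory has {traj.n_beads} beads, model has {model.n_beads}")
    path = Path(path)
    if format == "pdb":
        template = _model_to_atom_array(model, model.coords)
        stack = bst.from_template(template, traj.frames.astype(np.float32))
        pdb = bpdb.PDBFile()
        pdb.set_structure(stack)
        pdb.write(str(path))
    elif format == "xyz":
        with open(path, "w") as fh:
            for f, frame in enumerate(traj.frames):
                fh.write(f"{traj.n_beads}\n")
                fh.write(f"frame {f + 1}\n")
                for xyz in frame:
                    fh.write("C %12.6f %12.6f %12.6f\n" % tuple(xyz))
    else:
        raise ParameterError(f"unknown trajectory format {format!r}")


def read_trajectory(path, format: str = "pdb", dt: float = 1.0) -> Trajectory:
    """Read a multi-model PDB or XYZ trajectory.

    Frames with inconsistent bead counts raise an error naming the offending
    frame index (1-based).
    """
    path = Path(path)
    if format == "pdb":
        pdb = bpdb.PDBFile.read(str(path))
        try:
            stack = pdb.get_structure(altloc="first")
        except Exception as exc:  # biotite raises on ragged models
            raise TrajectoryFormatError(
                f"{path}: inconsistent models ({exc})") from exc
        if isinstance(stack, bst.AtomArray):
            stack = bst.stack([stack])
        ca = stack[..., (stack.atom_name == "CA") & ~stack.hetero]
        if ca.array_length() == 0:
            raise TrajectoryFormatError(f"{path}: no CA atoms in trajectory")
        return Trajectory(frames=ca.coord.astype(float), dt=dt,
                          origin="external")
    if format == "xyz":
        return _read_xyz(path, dt)
    raise ParameterError(f"unknown trajectory format {format!r}")


def _read_xyz(path, dt: float) -> Trajectory:
    frames = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos, frame_no = 0, 0
    while pos < len(lines):
        if lines[pos].strip() == "":
            pos += 1
            continue
        frame_no += 1
        try:
            count = int(lines[pos].split()[0])
        except (ValueError, IndexError):
            raise TrajectoryFormatError(
                f"{path}: bad atom-count line at frame {frame_no}")
        block = lines[pos + 2: pos + 2 + count]
        if len(block) < count:
            raise TrajectoryFormatError(
                f"{path}: truncated frame {frame_no} "
                f"(expected {count} beads, got {len(block)})")
        try:
            coords = np.array(
                [[float(v) for v in ln.split()[1:4]] for ln in block])
        except (ValueError, IndexError):
            raise TrajectoryFormatError(
                f"{path}: malformed coordinates in frame {frame_no}")
        if coords.shape != (count, 3):
            raise TrajectoryFormatError(
                f"{path}: malformed coordinates in frame {frame_no}")
        frames.append(coords)
        pos += 2 + count
    if not frames:
        raise TrajectoryFormatError(f"{path}: no frames")
    counts = {f.shape[0] for f in frames}
    if len(counts) > 1:
        bad = next(i for i, f in enumerate(frames)
                   if f.shape[0] != frames[0].shape[0])
        raise TrajectoryFormatError(
            f"{path}: frame {bad + 1} has {frames[bad].shape[0]} beads, "
            f"expected {frames[0].shape[0]}")
    return Trajectory(frames=np.array(frames), dt=dt, origin="external")


def assign_domains(model: CalphaModel,
                   defs: list[DomainDefinition]) -> CalphaModel:
    """Return a copy of the model with beads tagged by domain name.

    Each bead maps to at most one domain; overlapping definitions are an
    error, as is a definition whose ranges match no residue.
    """
    out = model.copy()
    claimed = np.zeros(model.n_beads, dtype=bool)
    for d in defs:
        m = d.mask(model.resids)
        if not np.any(m):
            raise DomainError(
                f"domain {d.name!r}: ranges {d.ranges} match no residue")
        clash = m & claimed
        if np.any(clash):
            k = int(np.flatnonzero(clash)[0])
            raise DomainError(
                f"domain {d.name!r} overlaps a previous domain at resid "
                f"{model.resids[k]} (bead {k})")
        claimed |= m
        out.domains[m] = d.name
    return out
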