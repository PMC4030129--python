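"""Synthetic Cα structures and thermal ensembles with known ground truth.

The two-domain generator emulates the architecture of multi-domain enzymes
such as the aminoacyl-tRNA synthetases: a compact, contact-dense catalytic
core with a smaller, loosely packed domain inserted into the chain and
tethered by two linkers.  Because the insert makes fewer contacts, any
cutoff-based elastic network built on the result gives it softer, larger
fluctuations and anticorrelated motion against the core — the qualitative
behavior the analysis pipeline is meant to detect, available here without
downloading structures or running all-atom MD.

``sample_anm_ensemble`` draws exact Gaussian thermal frames from a mode
set, so trajectory-analysis code can be tested against a known covariance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB_KCAL
from .exceptions import GenerationError, ParameterError
from .nma import ModeSet
from .structure import CalphaModel, DomainDefinition, Trajectory


@dataclass
class SyntheticSpec:
    """Parameters of the two-domain chain generator.

    Defaults give a 98-bead chain: 60-bead core, 30-bead insert, two 4-bead
    linkers, 3.8 Å virtual bonds, self-avoiding at 2.0 Å.  ``compactness``
    sets the confining-sphere radius as compactness·n^(1/3) Å (default 3.0,
    about 115 Å³ per residue — protein-like packing).
    """

    n_core: int = 60
    n_insert: int = 30
    linker_length: int = 4
    bond_length: float = 3.8
    compactness: float = 3.0
    clash_distance: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_core < 2:
            raise ParameterError("n_core must be ≥ 2")
        if self.n_insert < 0:
            raise ParameterError("n_insert must be ≥ 0")
        if self.n_insert and self.linker_length < 1:
            raise ParameterError("linker_length must be ≥ 1 with an insert")
        if self.bond_length <= self.clash_distance:
            raise ParameterError("bond length must exceed clash distance")


#: Insert confinement is this factor looser than the core, so the inserted
#: domain always packs at lower density (lower contact degree, softer modes).
INSERT_LOOSENESS = 1.35

#: Perpendicular zigzag amplitude of linker beads (Å).  Straight linkers are
#: mechanisms under central-force springs (zero transverse stiffness); a
#: kinked linker keeps the hinge soft but removes the spurious zero modes.
LINKER_ZIGZAG = 0.8


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _grow_walk(rng, placed, n_new, center, radius, start, bond, clash,
               max_tries=200):
    """Self-avoiding bond-length walk confined to a sphere.

    If the walk starts outside the sphere, steps may never increase the
    distance to the center and are biased inward, so a stray tail is pulled
    back into the confinement region.
    """
    coords = list(placed)
    new = []
    pos = start
    for _ in range(n_new):
        for attempt in range(max_tries):
            r_pos = np.linalg.norm(pos - center)
            d = _random_unit(rng)
            if r_pos > radius:
                inward = (center - pos) / r_pos
                d = d + 1.2 * inward
                d = d / np.linalg.norm(d)
            cand = pos + bond * d
            r_cand = np.linalg.norm(cand - center)
            if r_cand > max(radius, r_pos):
                continue
            arr = np.array(coords + new) if (coords or new) else None
            if arr is not None and \
                    np.min(np.linalg.norm(arr - cand, axis=1)) < clash:
                continue
            break
        else:
            raise GenerationError(
                "self-avoiding walk stuck; increase compactness")
        new.append(cand)
        pos = cand
    return new


def _zigzag_linker(start, direction, perp, n_beads, bond, amp, placed, clash):
    """Kinked linker: advance along ``direction`` with alternating ±amp
    perpendicular offsets; every consecutive pair (including the step off
    the unoffset anchor) is exactly ``bond`` apart."""
    step = np.sqrt(bond ** 2 - 4.0 * amp ** 2)
    first = np.sqrt(bond ** 2 - amp ** 2)
    beads = []
    for k in range(1, n_beads + 1):
        along = first + (k - 1) * step
        cand = start + direction * along + ((-1) ** k) * amp * perp
        arr = np.array(placed + beads)
        if np.min(np.linalg.norm(arr - cand, axis=1)) < clash:
            raise GenerationError("linker clash")
        beads.append(cand)
    return beads, first + n_beads * step


def make_two_domain_structure(spec: SyntheticSpec):
    """Generate a core+insert Cα chain and its domain definitions.

    Chain order: first half of the core, linker, insert, linker, second
    half of the core.  Deterministic per seed.  Returns
    ``(CalphaModel, [DomainDefinition...])``; with ``n_insert=0`` a
    single-domain control (core only, no linkers) is produced.

    Retries the whole construction a bounded number of times if the
    self-avoidance constraint wedges.
    """
    last_err = None
    for restart in range(40):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=spec.seed, spawn_key=(restart,)))
        try:
            model, domains = _build_two_domain(spec, rng)
            _validate_two_domain(model, domains, spec)
            return model, domains
        except GenerationError as err:
            last_err = err
    raise GenerationError(
        f"could not generate a valid two-domain chain after 40 restarts; "
        f"try a larger compactness ({last_err})")


def _validate_two_domain(model, domains, spec) -> None:
    """Reject draws that violate the generator's contract.

    The chain must give a connected, well-conditioned elastic network with
    exactly six rigid-body modes at the 8 Å dynamics cutoff, and the insert
    must have strictly lower mean contact degree than the core at both the
    8 Å and 10 Å cutoffs (the packing contrast the architecture encodes).
    """
    from .enm import anm_hessian, build_network
    from .nma import compute_modes

    if spec.n_insert == 0:
        net = build_network(model, r_c=8.0)
        if not net.connected:
            raise GenerationError("core network disconnected at 8 Å")
        return
    from .nma import nma_bfactors, nma_dccm
    from .structure import assign_domains
    tagged = assign_domains(model, domains)
    idx = tagged.domain_indices()
    core, ins = idx["core"], idx["insert"]
    # the two stage parameterizations the analysis pipeline uses
    for r_c, p in ((8.0, 0.0), (10.0, 2.5)):
        net = build_network(model, r_c=r_c, weight_exponent=p)
        if not net.connected:
            raise GenerationError(f"network disconnected at {r_c} Å")
        deg = net.degrees()
        if deg[core].mean() <= deg[ins].mean():
            raise GenerationError(
                f"insert not more loosely packed than core at {r_c} Å")
        modes = compute_modes(anm_hessian(net))
        if modes.n_zero != 6:
            raise GenerationError(f"{modes.n_zero} zero modes at {r_c} Å")
        lam_max = float(modes.eigenvalues[-1])
        if modes.mode_eigenvalue(1) < 1e-6 * lam_max:
            raise GenerationError(
                "quasi-mechanism: softest mode ill-conditioned")
        bf = nma_bfactors(modes).values
        if bf[ins].mean() < 1.5 * bf[core].mean():
            raise GenerationError(
                f"insert not clearly softer than core at {r_c} Å")
        cc = nma_dccm(modes, k_list=(1, 2, 3)).matrix
        if cc[np.ix_(core, ins)].mean() > -0.02:
            raise GenerationError(
                f"core-insert motion not anticorrelated at {r_c} Å")


def _build_two_domain(spec: SyntheticSpec, rng):
    bond, clash = spec.bond_length, spec.clash_distance
    r_core = spec.compactness * spec.n_core ** (1 / 3)
    core_center = np.zeros(3)

    n1 = spec.n_core // 2
    n2 = spec.n_core - n1
    start = rng.uniform(-0.3 * r_core, 0.3 * r_core, size=3)
    half1 = [start] + _grow_walk(rng, [start], n1 - 1, core_center, r_core,
                                 start, bond, clash)

    if spec.n_insert == 0:
        coords = np.array(half1 + _grow_walk(
            rng, half1, n2, core_center, r_core, half1[-1], bond, clash))
        model = _as_model(coords)
        n = len(coords)
        return model, [DomainDefinition("core", [(1, n)])]

    r_ins = max(INSERT_LOOSENESS * spec.compactness
                * spec.n_insert ** (1 / 3), bond)
    amp = min(LINKER_ZIGZAG, 0.4 * bond)
    anchor = half1[-1]
    out_dir = anchor - core_center
    out_dir = out_dir / np.linalg.norm(out_dir) if \
        np.linalg.norm(out_dir) > 1e-9 else np.array([0.0, 0.0, 1.0])
    perp = np.cross(out_dir, _random_unit(rng))
    while np.linalg.norm(perp) < 1e-6:
        perp = np.cross(out_dir, _random_unit(rng))
    perp /= np.linalg.norm(perp)

    placed = list(half1)
    linker1, span = _zigzag_linker(anchor, out_dir, perp,
                                   spec.linker_length, bond, amp,
                                   placed, clash)
    placed += linker1
    ins_center = anchor + out_dir * (span + 0.7 * r_ins)

    ins_start = anchor + out_dir * span \
        + ((-1) ** (spec.linker_length + 1)) * amp * perp
    arr = np.array(placed)
    if np.min(np.linalg.norm(arr - ins_start, axis=1)) < clash:
        raise GenerationError("insert-start clash")
    ins_radius = max(r_ins, np.linalg.norm(ins_start - ins_center) + 0.5)
    insert = [ins_start] + _grow_walk(rng, placed + [ins_start],
                                      spec.n_insert - 1, ins_center,
                                      ins_radius, ins_start, bond, clash)
    placed += insert

    back_dir = core_center - insert[-1]
    back_dir /= np.linalg.norm(back_dir)
    perp2 = np.cross(back_dir, _random_unit(rng))
    while np.linalg.norm(perp2) < 1e-6:
        perp2 = np.cross(back_dir, _random_unit(rng))
    perp2 /= np.linalg.norm(perp2)
    linker2, _ = _zigzag_linker(insert[-1], back_dir, perp2,
                                spec.linker_length, bond, amp,
                                placed, clash)
    placed += linker2

    start2 = linker2[-1]
    half2 = _grow_walk(rng, placed, n2, core_center, r_core,
                       start2, bond, clash)

    coords = np.array(half1 + linker1 + insert + linker2 + half2)
    model = _as_model(coords)
    a = n1
    b = a + spec.linker_length
    c = b + spec.n_insert
    d = c + spec.linker_length
    n = len(coords)
    domains = [
        DomainDefinition("core", [(1, a), (d + 1, n)]),
        DomainDefinition("insert", [(b + 1, c)]),
    ]
    return model, domains


def _as_model(coords: np.ndarray) -> CalphaModel:
    n = len(coords)
    return CalphaModel(
        coords=coords,
        resids=np.arange(1, n + 1),
        chains=np.full(n, "A"),
        resnames=np.full(n, "UNK"),   # sequence not designed: 110 amu beads
    )


def make_helix(n: int, rise: float = 1.5, radius: float = 2.3,
               turn: float = 100.0) -> CalphaModel:
    """Ideal α-helical Cα trace (≈3.8 Å between consecutive beads)."""
    if n < 2:
        raise ParameterError("helix needs at least 2 beads")
    theta = np.deg2rad(turn) * np.arange(n)
    coords = np.column_stack([radius * np.cos(theta),
                              radius * np.sin(theta),
                              rise * np.arange(n)])
    return _as_model(coords)


def sample_anm_ensemble(modes: ModeSet, ref_coords: np.ndarray,
                        temperature: float, n_frames: int,
                        k_list=None, seed: int = 0) -> Trajectory:
    """Draw exact Gaussian thermal frames from selected nonzero modes.

    frame = ref + Σ_k sqrt(k_B T / λ_k) z_k v_k with iid standard-normal
    z_k, so the sample covariance converges to the mode-restricted thermal
    covariance.  Frames carry no rigid-body motion and are therefore marked
    superposed.
    """
    if n_frames < 1:
        raise ParameterError("n_frames must be ≥ 1")
    ref = np.asarray(ref_coords, dtype=float)
    ks = k_list if k_list is not None else list(range(1, modes.n_nonzero + 1))
    ks = list(ks)
    if not ks:
        raise ParameterError("k_list is empty")
    idx = [modes._nonzero_index(k) for k in ks]
    lam = modes.eigenvalues[idx]
    if np.any(lam <= 0):
        raise ParameterError("cannot sample a zero/negative-eigenvalue mode")
    v = modes.eigenvectors[:, idx]                    # (3N, K)
    amp = np.sqrt(KB_KCAL * temperature / lam)        # (K,)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, len(ks)))
    disp = (z * amp) @ v.T                            # (F, 3N)
    frames = ref.reshape(1, -1) + disp
    return Trajectory(frames=frames.reshape(n_frames, -1, 3), dt=1.0,
                      origin="ensemble_sample", superposed=True,
                      meta={"k_list": ks, "temperature": temperature,
                            "seed": seed})
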