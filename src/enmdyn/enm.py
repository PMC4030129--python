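"""Elastic network model: contact map, harmonic potential, forces, ANM Hessian.

The network connects every Cα pair closer than a cutoff ``r_c`` by a spring.
With weight exponent p = 0 the classic uniform model is recovered:

    E = Σ_{i<j, Γ_ij=1} (γ/2) (r_ij − r_ij°)²

With p > 0 each spring constant is scaled by (r_ij°)^−p, the usual
distance-weighted parameterization of anisotropic-network-model servers
(default there: r_c = 10 Å, p = 2.5).  The Hessian of the energy about the
reference structure is the ANM Hessian; its super-elements are

    H_ij = −(γ_ij / r_ij°²) (r_ij° ⊗ r_ij°)   for contacts i ≠ j,

with diagonal blocks fixed by the translational sum rule.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .exceptions import ParameterError, ShapeError, SingularGeometryError
from .structure import CalphaModel

logger = logging.getLogger("enmdyn")


@dataclass
class ElasticNetwork:
    """Reference coordinates plus the contact map and per-spring constants.

    ``edges`` is the unordered contact list (i < j); ``pair_gamma`` the
    effective spring constant of each edge and ``ref_dist`` its rest length.
    """

    ref_coords: np.ndarray        # (N, 3) Å
    gamma: float                  # kcal mol⁻¹ Å⁻²
    r_c: float                    # Å
    weight_exponent: float        # p ≥ 0; 0 = uniform springs
    edges: np.ndarray             # (M, 2) int, i < j
    pair_gamma: np.ndarray        # (M,) kcal mol⁻¹ Å⁻²
    ref_dist: np.ndarray          # (M,) Å
    connected: bool = True

    @property
    def n_beads(self) -> int:
        return self.ref_coords.shape[0]

    @property
    def n_contacts(self) -> int:
        return self.edges.shape[0]

    def contact_matrix(self) -> np.ndarray:
        """Symmetric binary contact map Γ (zero diagonal)."""
        g = np.zeros((self.n_beads, self.n_beads), dtype=bool)
        i, j = self.edges.T
        g[i, j] = g[j, i] = True
        return g

    def degrees(self) -> np.ndarray:
        """Contact count per bead."""
        deg = np.zeros(self.n_beads, dtype=int)
        for col in (0, 1):
            np.add.at(deg, self.edges[:, col], 1)
        return deg

    def to_edge_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("i\tj\tr0\tpair_gamma\n")
            for (i, j), r0, pg in zip(self.edges, self.ref_dist,
                                      self.pair_gamma):
                fh.write(f"{i}\t{j}\t{r0:.6f}\t{pg:.8g}\n")


@dataclass
class HessianMatrix:
    """3N×3N second-derivative matrix of the ENM energy at the reference."""

    entries: np.ndarray           # (3N, 3N) kcal mol⁻¹ Å⁻²
    network: ElasticNetwork

    @property
    def n_beads(self) -> int:
        return self.entries.shape[0] // 3


def build_network(model: CalphaModel | np.ndarray, r_c: float,
                  gamma: float = 1.0,
                  weight_exponent: float = 0.0) -> ElasticNetwork:
    """Detect contacts within ``r_c`` and attach spring constants.

    pair_gamma_ij = gamma · (r_ij°)^−p.  Contacts are strict: 0 < r° < r_c.
    A disconnected contact graph is a warning (the mode spectrum will show
    more than six zero modes), not an error.
    """
    if r_c <= 0:
        raise ParameterError(f"cutoff r_c must be positive, got {r_c}")
    if weight_exponent < 0:
        raise ParameterError(
            f"weight exponent must be non-negative, got {weight_exponent}")
    coords = model.coords if isinstance(model, CalphaModel) else \
        np.asarray(model, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 beads")

    tree = cKDTree(coords)
    pairs = tree.query_pairs(r_c, output_type="ndarray")
    if pairs.size:
        pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))]
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        ok = (d > 0) & (d < r_c)     # query_pairs is r <= r_c; make it strict
        pairs, d = pairs[ok], d[ok]
    else:
        pairs = pairs.reshape(0, 2)
        d = np.zeros(0)
    pair_gamma = gamma * d ** (-weight_exponent) if pairs.size else np.zeros(0)

    adj = csr_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])),
                     shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    connected = n_comp == 1
    if not connected:
        logger.warning("elastic network is disconnected "
                       "(%d components at r_c=%.2f Å)", n_comp, r_c)
    return ElasticNetwork(ref_coords=coords.copy(), gamma=gamma, r_c=r_c,
                          weight_exponent=weight_exponent, edges=pairs,
                          pair_gamma=pair_gamma, ref_dist=d,
                          connected=connected)


def _pair_geometry(net: ElasticNetwork, coords: np.ndarray):
    coords = np.asarray(coords, dtype=float)
    if coords.shape != net.ref_coords.shape:
        raise ShapeError(
            f"coords shape {coords.shape} does not match network "
            f"{net.ref_coords.shape}")
    delta = coords[net.edges[:, 0]] - coords[net.edges[:, 1]]
    dist = np.linalg.norm(delta, axis=1)
    return coords, delta, dist


def enm_energy(net: ElasticNetwork, coords: np.ndarray) -> float:
    """ENM potential energy (kcal/mol); zero at the reference structure."""
    _, _, dist = _pair_geometry(net, coords)
    return float(np.sum(0.5 * net.pair_gamma * (dist - net.ref_dist) ** 2))


def enm_forces(net: ElasticNetwork, coords: np.ndarray) -> np.ndarray:
    """Analytic forces −∇E, kcal mol⁻¹ Å⁻¹, shape (N, 3).

    Net force and net torque vanish (pair forces are central).
    """
    coords, delta, dist = _pair_geometry(net, coords)
    if np.any(dist == 0):
        k = int(np.flatnonzero(dist == 0)[0])
        i, j = net.edges[k]
        raise SingularGeometryError(
            f"bonded beads {i} and {j} are coincident; force undefined")
    # dE/dr_i = pg (d - d0) * delta/d on bead i, opposite on j
    scale = (net.pair_gamma * (dist - net.ref_dist) / dist)[:, None]
    pair_force = -scale * delta
    forces = np.zeros_like(coords)
    np.add.at(forces, net.edges[:, 0], pair_force)
    np.add.at(forces, net.edges[:, 1], -pair_force)
    return forces


def anm_hessian(net: ElasticNetwork) -> HessianMatrix:
    """Assemble the 3N×3N ANM Hessian from the reference geometry."""
    n = net.n_beads
    h = np.zeros((3 * n, 3 * n))
    if np.any(net.ref_dist == 0):
        raise SingularGeometryError("coincident beads in reference geometry")
    delta = net.ref_coords[net.edges[:, 0]] - net.ref_coords[net.edges[:, 1]]
    for (i, j), d0, pg, dvec in zip(net.edges, net.ref_dist,
                                    net.pair_gamma, delta):
        block = -(pg / d0 ** 2) * np.outer(dvec, dvec)
        si, sj = slice(3 * i, 3 * i + 3), slice(3 * j, 3 * j + 3)
        h[si, sj] += block
        h[sj, si] += block
        h[si, si] -= block
        h[sj, sj] -= block
    return HessianMatrix(entries=h, network=net)
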