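"""Anisotropic-network normal modes of a synthetic two-domain protein.

Builds a 98-residue Cα model (rigid core + flexible inserted domain),
constructs the 10 Å distance-weighted elastic network, diagonalizes the
ANM Hessian and prints the soft end of the spectrum, per-domain thermal
B-factors, and the inter-domain cross-correlation.
"""
import numpy as np

from enmdyn import (
    anm_hessian, assign_domains, build_network, compute_modes,
    nma_bfactors, nma_dccm,
)
from enmdyn.synthetic import SyntheticSpec, make_two_domain_structure

model, domains = make_two_domain_structure(SyntheticSpec(seed=1))
model = assign_domains(model, domains)
idx = model.domain_indices()

net = build_network(model, r_c=10.0, gamma=1.0, weight_exponent=2.5)
modes = compute_modes(anm_hessian(net))

print(f"{model.n_beads} beads, {net.n_contacts} contacts, "
      f"{modes.n_zero} zero modes (rigid-body)")
print("softest internal eigenvalues (kcal/mol/A^2):",
      " ".join(f"{modes.mode_eigenvalue(k):.4g}" for k in range(1, 4)))

bf = nma_bfactors(modes, temperature=298.0)
print(f"mean B-factor  core: {bf.values[idx['core']].mean():8.1f} A^2"
      f"   insert: {bf.values[idx['insert']].mean():8.1f} A^2")

cc = nma_dccm(modes, k_list=(1, 2, 3)).matrix
inter = cc[np.ix_(idx["core"], idx["insert"])].mean()
print(f"mean core x insert cross-correlation (modes 1-3): {inter:+.3f}")
print("-> the inserted domain is softer than the core and the two move "
      "against each other (negative correlation): hinge-like dynamics.")
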