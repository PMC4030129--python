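"""Comparing normal modes against trajectory PCA: overlaps and DCCMs.

Samples an exact thermal ensemble of the network's three softest modes,
recovers them with essential-dynamics PCA, and prints the mode-by-mode
overlap table (full protein and per domain) plus the paired
cross-correlation summary.
"""
import numpy as np

from enmdyn import (
    anm_hessian, assign_domains, build_network, compute_modes,
    covariance_pca, dccm_pair_report, eda_dccm, mode_overlap_table,
    nma_dccm,
)
from enmdyn.synthetic import SyntheticSpec, make_two_domain_structure, \
    sample_anm_ensemble

model, domains = make_two_domain_structure(SyntheticSpec(seed=1))
model = assign_domains(model, domains)
idx = model.domain_indices()

net = build_network(model, r_c=8.0, gamma=1.0)
modes = compute_modes(anm_hessian(net))

traj = sample_anm_ensemble(modes, model.coords, temperature=298.0,
                           n_frames=5000, k_list=(1, 2, 3), seed=3)
pca = covariance_pca(traj, burn_in_fraction=0.0)

table = mode_overlap_table(modes, pca.modes, n_modes=3, domains=idx)
print(table.table.to_string(index=False))

m_nma = nma_dccm(modes, k_list=(1, 2, 3))
m_eda = eda_dccm(pca, mode_list=(1, 2, 3))
_, summary = dccm_pair_report(
    m_eda, m_nma, regions=[("core x insert", idx["core"], idx["insert"])])
print()
print(summary.to_string(index=False))
print("\n-> overlaps near 1 mean PCA recovered the generating modes; "
      "both methods agree the domains are anticorrelated.")
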