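"""Essential dynamics of a coarse-grained trajectory (CEDA).

Simulates the two-domain model, removes rigid-body motion, extracts
principal components of the coordinate covariance, picks the densest
conformational cluster in PC1-3 space and prints what the leading PCs
describe.
"""
import numpy as np

from enmdyn import (
    SimulationParams, assign_domains, build_network, cluster_select,
    covariance_pca, eda_bfactors, run_langevin, superpose,
)
from enmdyn.synthetic import SyntheticSpec, make_two_domain_structure

model, domains = make_two_domain_structure(SyntheticSpec(seed=1))
model = assign_domains(model, domains)
idx = model.domain_indices()
net = build_network(model, r_c=8.0, gamma=1.0)

params = SimulationParams(masses=model.masses, n_steps=100_000,
                          save_every=10, seed=7)
traj = run_langevin(net, params)
fitted = superpose(traj, model.coords)

pca = covariance_pca(fitted)                 # drops the first 1/6 as burn-in
var = pca.modes.eigenvalues
print(f"{pca.n_frames} frames analyzed; "
      f"PC1-3 carry {100 * var[:3].sum() / var.sum():.0f}% of the variance")

sel = cluster_select(pca, n_components=3, grid_bins=20)
print(f"cluster {sel.selected_cluster} selected: {sel.n_selected} frames, "
      f"density {sel.density_score:.1f} frames/A")

bf = eda_bfactors(fitted, frame_subset=sel)
print(f"mean B-factor  core: {bf.values[idx['core']].mean():8.1f} A^2"
      f"   insert: {bf.values[idx['insert']].mean():8.1f} A^2")
pc1 = pca.modes.mode_displacements(1)
amp = np.linalg.norm(pc1, axis=1)
print(f"PC1 amplitude insert/core ratio: "
      f"{amp[idx['insert']].mean() / amp[idx['core']].mean():.1f}")
print("-> the dominant collective motion is concentrated on the inserted "
      "domain, as expected for a hinge system.")
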