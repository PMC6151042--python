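"""Generate a synthetic heterogeneous methylation dataset.

Builds a profile model (per-site, per-cell-type mean beta levels with a
controlled fraction of cell-type-informative sites), mixes it with
Dirichlet-drawn cell proportions, adds technical noise, and verifies
that the noise level can be read back off the data by regression.
"""

import bayescce as b
from bayescce.simulator import recover_sigma

profiles = b.make_profile_model(m=1000, k=3, seed=1, separation=0.3)
print(f"profile model: {profiles.m} sites x {profiles.k} cell types, "
      f"{len(profiles.informative_sites)} informative sites")

ds = b.simulate_dataset(profiles, n=200, alpha=b.WHOLE_BLOOD_K3,
                        sigma=0.01, shared_profiles=True, clip=False, seed=2)
print(f"beta matrix: {ds.m} sites x {ds.n} samples; "
      f"true proportions {ds.R_true.shape}")
print(f"mean composition: "
      + ", ".join(f"{n}={v:.3f}" for n, v in ds.R_true.mean().items()))

sigma_hat = recover_sigma(ds.O, ds.R_true)
print(f"technical noise: generated sigma=0.010, recovered {sigma_hat:.4f}")
print("(regressing each site on the true proportions pools the residual "
      "variance; in shared-profile mode this recovers sigma exactly up to "
      "sampling error)")
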