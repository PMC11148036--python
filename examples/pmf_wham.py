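"""Reconstruct a free-energy profile from umbrella-sampling windows.

Samples 15 harmonic windows along the pore coordinate from an analytic
20 kJ/mol cosine barrier, reconstructs the profile with WHAM, attaches
block-bootstrap errors, and reads off the pore-opening cost.
"""

import numpy as np

from lipopore.synth import cosine_landscape, gen_umbrella_dataset
from lipopore.wham import pmf_error_bootstrap, pore_free_energy, wham_solve

barrier = 20.0  # kJ/mol ground truth
G_true = cosine_landscape(barrier)
windows, truth = gen_umbrella_dataset(
    G_true, np.linspace(0.0, 1.0, 15), n_per_window=20_000, seed=1
)
print(f"Sampled 15 windows x 20000 points "
      f"(Metropolis acceptance {truth['acceptance_rates'].mean():.2f})")

profile = wham_solve(windows, n_bins=200, tol=1e-6)
errors = pmf_error_bootstrap(windows, n_boot=25, seed=1)
print(f"WHAM converged in {profile.n_iterations} iterations")

dg = pore_free_energy(profile, xi_flat=0.02, xi_open=0.5)
print(f"Recovered barrier G(0.5) - G(0.02) = {dg:.2f} kJ/mol "
      f"(truth {barrier:.1f})")

ref = G_true(profile.bin_centers)
ref -= ref.min()
mask = (np.isfinite(profile.free_energy)
        & (profile.bin_centers >= 0.1) & (profile.bin_centers <= 0.9))
rmse = np.sqrt(np.mean((profile.free_energy[mask] - ref[mask]) ** 2))
print(f"Profile RMSE vs analytic landscape over xi in [0.1, 0.9]: "
      f"{rmse:.2f} kJ/mol; mean bootstrap error "
      f"{np.nanmean(errors):.2f} kJ/mol")
print("The PMF is the reversible work to open the pore along the "
      "slice-occupancy coordinate xi.")
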