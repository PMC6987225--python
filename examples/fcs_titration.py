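"""Extract a K_D from a simulated FCS titration series.

Simulates noisy autocorrelation decays at seven DNA concentrations
spanning the binding isotherm of a 3 nM-affinity complex, then fits all
decays globally (shared log10 K_D and diffusion times, local molecule
numbers) and combines two replicate titrations by inverse-variance
weighting.
"""

import numpy as np

from tfantenna.fcs_model import FCSModelParams, global_fit_titration
from tfantenna.param_fitting import weighted_mean_kd
from tfantenna.synthetic_data import synthetic_fcs_titration

kd_true = 3e-9
concs = list(np.logspace(-10.5, -7, 7))
base = FCSModelParams()  # tau_prot from D = 122 um^2/s, 0.25 um waist

fits = []
for seed in (1, 2):
    decays = synthetic_fcs_titration(kd_true, concs, noise_sd=0.02, seed=seed)
    fit = global_fit_titration(decays, base)
    fits.append(fit)
    print(f"replicate {seed}: log10 K_D = {fit.log10_kd:.3f} "
          f"+- {fit.interval95:.3f} (95%)  ->  K_D = {fit.kd:.2e} M")

mean, combined = weighted_mean_kd([(f.log10_kd, f.interval95) for f in fits])
print(f"weighted average: log10 K_D = {mean:.3f} +- {combined:.3f}")
print(f"true value:       log10 K_D = {np.log10(kd_true):.3f}")
# The combined interval is narrower than either replicate's, and the
# recovered affinity sits within the stated uncertainty of the truth.
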