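"""Solve the 4-state transcription-antenna kinetic model.

Derives the rate constants from physical inputs (TF concentration, cell
and antenna volumes, per-site affinities, sliding speed), assembles the
generator matrix, and prints the relaxation spectrum, the stationary
populations and the per-gene copy-number partition.
"""

import numpy as np

from tfantenna.antenna_kinetics import (
    STATE_NAMES,
    AntennaPhysical,
    build_rate_matrix,
    copy_number_partition,
    derive_rates,
    detailed_balance_residual,
    solve_kinetics,
)

phys = AntennaPhysical()
rates = derive_rates(phys)
print(f"k1 = {rates.k1:.1e}  k-1 = {rates.k1_rev:.3g}  (entry/escape, 1/s)")
print(f"k2 = {rates.k2:.2e}  k-2 = {rates.k2_rev:.3g}  (degenerate sites)")
print(f"k3 = {rates.k3:.2e}  k-3 = {rates.k3_rev:.3g}  (specific site)")
print(f"slide D_eg->SB = {rates.k_ds:.3f}  SB->D_eg = {rates.k_sd:.1f}  1/s")
print(f"detailed-balance cycle ratio: {detailed_balance_residual(rates):.6f}")

solution = solve_kinetics(build_rate_matrix(rates))
lam = np.sort(solution.relaxation_rates)
print(f"\nrelaxation rates:  {lam[2]:.2e}, {lam[1]:.3g}, {lam[0]:.2e}  1/s")
print(f"SB-finding time (1/lambda_2): {1e3 / lam[1]:.1f} ms")
for name, p in zip(STATE_NAMES, solution.stationary):
    print(f"  p({name:4s}) = {p:.3e}")

in_antenna, elsewhere = copy_number_partition(solution, 30_000, 200)
print(f"\nper regulated gene (30,000 copies / 200 genes):")
print(f"  trapped in the antenna: {in_antenna:.0f} molecules")
print(f"  anywhere else:          {elsewhere:.1f} molecules")
# The antenna traps ~90% of the TF pool; the specific site stays at ~1%
# occupancy yet is found by an antenna-resident molecule within ~11 ms.
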