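"""Recover energy-model parameters from a synthetic K_D titration table.

Generates 30 75-bp constructs with implanted site variants at three
ionic strengths, produces a noisy K_D table from the forward model, fits
the structure-based and PWM energetics globally in log10 K_D, and
compares the two fits with a variance-ratio test.
"""

from tfantenna.binding_model import EnergyModelParams, PWMMatrix
from tfantenna.param_fitting import fit_energy_params, model_compare_ftest
from tfantenna.synthetic_data import (
    implant_sites,
    random_sequence,
    synthetic_titration_table,
)

true_params = EnergyModelParams()
hexamers = ["TAATTA", "TAATTG", "TAATTT", "TATATA", "GAATTG", "CGTGTT"]
seqs = {}
for i in range(30):
    rec = random_sequence(75, 0.57, seed=900 + i, seq_id=f"c{i:02d}")
    rec = implant_sites(rec, [(34, hexamers[i % 6])])
    seqs[rec.id] = rec

records = synthetic_titration_table(
    list(seqs.values()), true_params, noise_sd=0.05, seed=3,
    ionic_strengths=[0.05, 0.15, 0.35] * 10,
)

init = true_params.with_(dg_consensus_core=-2.0, dg_degenerate_at=-1.0,
                         dg_cp=-2.0, dg_elec0=-6.0)
fit_structure = fit_energy_params(records, seqs, "structure", init, seed=0)
print("structure-based fit (truth in parentheses):")
for name, truth in [("dg_consensus_core", -3.53), ("dg_degenerate_at", -1.75),
                    ("dg_cp", -3.91), ("dg_elec0", -8.18)]:
    v, s = fit_structure.params[name], fit_structure.param_sigmas[name]
    print(f"  {name:18s} = {v:7.3f} +- {s:.3f} kJ/mol  ({truth})")

pwm = PWMMatrix.from_consensus("TAATTA")
fit_pwm = fit_energy_params(records, seqs, "pwm", init, pwm=pwm, seed=0)
print(f"\nPWM fit: dg_elec0 = {fit_pwm.params['dg_elec0']:.3f} kJ/mol")

f_stat, p = model_compare_ftest(fit_pwm, fit_structure)
print(f"variance ratio PWM/structure: F = {f_stat:.1f}, p = {p:.2e}")
# The structure-based energetics fit the data far better than the
# single-parameter PWM variant, mirroring the model-selection result.
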