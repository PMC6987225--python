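# Methods

This note records the models implemented in `tfantenna`, their
assumptions, the parameter choices that matter, and what the synthetic
data can and cannot establish.

## Statistical-mechanical binding model

### Partition function

A DNA duplex of *N* bp is treated as a lattice of 2·(*N*−5) potential
6-bp binding sites: every window of the forward strand and every window
of the reverse strand, each read 5′→3′ on its own strand. With the
unbound protein as the reference state (statistical weight 1), the
partition function at total DNA concentration `[DNA]` is

    Q = 1 + [DNA] · w0 · S,    S = Σ_x exp(−ΔG_x / RT),

and derived quantities are `p_x = w_x/Q`, `p_free = 1/Q`,
`p_bound = (Q−1)/Q`, and the global dissociation constant
`K_D = 1/(w0·S)` (the concentration at which Q = 2, i.e. the protein is
half bound). `[DNA]` is the *total* DNA concentration — a ligand-excess
approximation appropriate for FCS-style experiments where DNA is at or
above the protein concentration. Multi-protein occupancy of one molecule
and site-overlap exclusion are not modelled; each site contributes an
independent statistical weight.

`w0` (default 5·10⁻⁴ M⁻¹) is the ratio of the diffusion-limited
association rate constant to the interaction-free dissociation rate
constant. Its value only rescales all ΔG_x; the scale-covariance test
(`K_D ∝ 1/w0`) makes this explicit.

### Structure-based site energetics

For a hexamer site,

    ΔG_x = n_elec · ΔG_elec(I) + n_core · ΔG_cons,core
         + n_degAT · ΔG_deg,AT + [δ16 + (δ15+δ26)/2] · ΔG_cp

- **Electrostatics.** Each site makes `n_elec_central` backbone contacts
  (default 6), one fewer when the site's first base lies within
  `end_margin` = 10 bp (about one helical turn) of either end of its own
  strand; the boundary is inclusive (a site starting exactly at the
  margin counts as an end site). Screening follows a Debye–Hückel form
  `ΔG_elec(I) = ΔG⁰·exp(−√I)` with I in mol/L. The fitted prefactor
  ΔG⁰ = −8.18 kJ/mol is interpreted as the I→0 value; converting a
  buffer recipe to I is the caller's job (`ionic_strength_from_nacl`
  adds a fixed 0.01 M buffer contribution to the NaCl molarity).
  An alternative `elec_contacts="extended"` mode uses 8 central / 7 end
  contacts, matching the site-energy decompositions quoted for worked
  examples in the literature; the 6/5 default follows the fitted formula.
  The two conventions differ by a sequence-independent offset per site
  class, largely absorbed by ΔG⁰ on refitting.
- **Specific contacts.** A base equal to the consensus core tetrad base
  (positions 2–5 of `TAATTA`, i.e. `AATT`) contributes
  ΔG_cons,core = −3.53 kJ/mol; any *other* A or T — including the
  flanking positions 1 and 6 — contributes ΔG_deg,AT = −1.75 kJ/mol
  (a structural preference for the narrow minor groove and higher
  flexibility of A/T-rich DNA); G or C contributes nothing.
- **Cooperativity.** δ15/δ26/δ16 flag a site matching the first five,
  last five, or all six consensus bases. The coefficient
  δ16 + (δ15+δ26)/2 multiplies ΔG_cp = −3.91 kJ/mol, giving 2 for the
  full consensus, ½ for a five-of-six site, 0 otherwise. It represents
  the non-additive entropy loss of locking into the specific complex
  plus the extra hydrogen bonds available once locked.

RT uses R = 8.314 J mol⁻¹ K⁻¹ and T = 297 K (RT ≈ 2.469 kJ/mol), the
midpoint of the 296–298 K experimental range.

### PWM site energetics

`ΔG_x = n_elec·ΔG_elec(I) + Σ_k −RT·ln(p_k^B/0.25)` with no cooperative
term. PWMs are user-supplied (JASPAR-style tab files) or built
synthetically (`PWMMatrix.from_consensus`); a pseudo-count (default
10⁻³) is added and columns renormalized so all entries are positive.
The Engrailed PWM itself is not distributed here.

### Numerical notes

Site enumeration is exact and deliberately simple (a few microseconds
per site); the global fitter instead uses a cached per-site feature
matrix (n_core, n_degAT, coop, n_elec), exploiting that the structure
model is linear in its four free energies. The two paths are verified
identical, and both are checked against a naive per-window brute-force
oracle on random sequences. Sequences shorter than 6 bp are rejected;
exactly 6 bp yields 2 sites. Segment profiles flag a trailing remainder
shorter than the window and skip remainders shorter than 6 bp.

## Global parameter fitting

Fits minimize residuals in log10 K_D (affinities span decades; log
space samples them linearly). The structure variant frees
{ΔG_cons,core, ΔG_deg,AT, ΔG_cp, ΔG⁰}; the PWM variant frees ΔG⁰ only.
The optimizer is scipy's bounded trust-region least squares
(|ΔG| ≤ 50 kJ/mol) with seeded random multi-starts (default 10).
Record uncertainties, when present for every record, enter as
inverse-σ weights; 1σ parameter errors come from the covariance at the
optimum scaled by the reduced chi-square. Model variants are compared
with a variance-ratio test, F = (RSS_A/dof_A)/(RSS_B/dof_B) against
F(dof_A, dof_B); because the variants are not nested this is a
heuristic ranking device, not an exact hypothesis test. Whether the
original analysis weighted records by experimental uncertainty is not
documented; weighting is the default here, with an unweighted fallback.

Replicate K_D estimates are combined by normalized inverse-variance
weighting; the combined uncertainty is `sqrt(1/Σσ_i⁻²)` on the same
scale as the inputs.

## Four-state antenna kinetics

States (C_F, A_F, D_eg, SB) and generator layout are described in the
module docstring; columns are source states and sum to zero. Rates
derive from physical inputs:

- `k1 = 10⁶ M⁻¹s⁻¹ · [TF]` (entry into the antenna volume),
  `k−1 = k1·V_cell/V_antenna` (detailed balance of diffusive exchange;
  1000/0.033 μm³ gives 30.3 s⁻¹);
- `k−2 = k_on·K_D,2 = 100 s⁻¹`, `k−3 = k_on·K_D,3 = 10 s⁻¹` with
  k_on = 10⁹ M⁻¹s⁻¹;
- sliding SB→D_eg at `200 bp/ms ÷ 2500 bp = 80 s⁻¹`; the D_eg→SB rate
  is fixed by exact detailed balance on the A_F–D_eg–SB cycle,
  `k_DS = k_SD·(k3·k−2)/(k−3·k2) = 80/90 ≈ 0.889 s⁻¹`.

**The reconciled rate set.** The published description of this model
prints k₃ = 10⁷ s⁻¹ and k₂ = 900·10⁷ s⁻¹ and labels the 80 s⁻¹ slide as
D_eg→SB. That combination violates detailed balance on the cycle by
more than three orders of magnitude and yields a different spectrum and
stationary state than the ones printed alongside it. The package's
default uses the effective k₃ = 3·10⁴ s⁻¹ with k₂ = 900·k₃ and the
slide direction fixed by detailed balance; this preserves every printed
pairwise ratio (k₂/k₃ = 900, k₂/k−₂ and k₃/k−₃ unchanged, slide ratio
90), closes the cycle exactly, and reproduces all seven printed
spectral outputs (eigenvalue magnitudes 2.7·10⁷, 91, 1.1·10⁻³ s⁻¹;
stationary populations 0.099, 3.3·10⁻⁶, 0.891, 0.0099) at their printed
two-significant-figure precision. The physical origin of the effective
k₃ is not derivable from the stated antenna volume and intrinsic
on-rate; it is kept as a documented constant. The literal printed set
is available behind `reconcile=False` and logs a warning.

The spectral solver sorts eigenvalues by magnitude, normalizes the null
eigenvector as the stationary state, and expands an optional initial
condition in the eigenbasis for kinetic amplitudes. On the default
rates, whose magnitudes span ten decades, double-precision
eigendecomposition carries ~10⁻⁹ relative error and matrix-exponential
propagation conserves probability to ~10⁻⁸ — the tests' tolerances
reflect this. The stochastic cross-check (`gillespie_stationary`,
batch-means standard errors over a seeded jump trajectory) is run on an
antenna-topology matrix with moderate (~1 decade) rate separation: on
the default matrix a 10⁶-jump trajectory essentially never samples C_F
(jump probability A_F→C_F ≈ 10⁻⁶), so no finite-jump time average can
converge for the full distribution. This is a property of the physical
regime, not of the solver.

The copy-number partition multiplies total cellular TF copies by the
stationary antenna fraction p(D_eg)+p(SB) (or its complement) and
divides by the number of regulated genes; with 30,000 copies and 200
genes the default model places ≈135 molecules per gene inside the
antenna and ≈15.0 outside.

## Motif statistics

For A/T content `at`, each consensus base (all are A or T) is matched by
a random base with probability p = at/2 (= 0.285 at the Drosophila-like
57%). Expected counts over the L−5 windows of an L-bp region are
p⁶(L−5) for the consensus, (1−p)·p⁵(L−5) per quintet variant and
(1−p)²·p⁴(L−5) per quartet variant — the (1−p) factors prevent a window
that matches a higher class from also being expected in a lower one.
Observed counting mirrors the same exclusion rule: a quintet/quartet
variant counts only when the remaining in-frame positions *mismatch*
their consensus base. The original description of observed counting does
not state this explicitly; mirroring the expectation formula is this
package's choice, and it is what makes observed/expected ratios
interpretable as enrichment.

Counts use the supplied strand only: the consensus and the central
quartet are palindromic, the two quintet variants (and the flanking
quartet variants) are mutual reverse complements, so summing variants on
one strand equals counting one variant over both strands. Windows
straddling a region boundary are attributed to the region containing
their first base; the regulatory-region count is whole minus CDS, making
the three region rows additive by construction. Expected counts treat
each region fragment independently with L−5 windows (fragments shorter
than 6 bp contribute zero). Ratios for empty regions are reported as NA.
No significance test is attached to the ratios.

## FCS model

G(t) = G_F(t)·G_T(t)·G_D(t): a two-component 3D Gaussian-volume
diffusion term (free protein, protein–DNA complex), a triplet factor
`1 + (T/(1−T))e^(−t/τ_T)` and an unbound-dye factor of the same form.
Two printed formulas in the source description are dimensionally
inconsistent and are implemented in their physically correct form:
the free fraction is `P_prot = 1/(1+[DNA]/K_D)` (not `1/(1+K_D[DNA])`),
and the diffusion time is `τ_D = ω_xy²/(4D)` (not `ω_xy/(4D)`); with
D = 122 μm²/s and ω_xy = 0.25 μm, τ_prot ≈ 1.28·10⁻⁴ s. The diffusion
term's normalization follows the published form exactly — brightness-
squared component weights with a 1/⟨N⟩ prefactor — with the textbook
`Σε_i²N_i/(Σε_iN_i)²` form available behind `normalization="textbook"`.
Binding is two-state: each labeled molecule is free or bound, valid when
the DNA is in excess and dominates the complex's diffusion.

Global titration fits share one log10 K_D (and all fixed shape
parameters) across decays and float one ⟨N⟩ per decay; lags below a
configurable floor (default 10⁻⁶ s) are excluded, emulating the removal
of after-pulsing artifacts. The 95% interval is 2σ from the covariance
at the optimum. The aspect ratio is fixed globally rather than floated
per titration.

## Synthetic data: what it does and does not emulate

Generators produce i.i.d. sequences at a target A/T content, the
G/C-rich construct rule (0.82 G/C else A/T, G/C with probability 1
after any A/T — hence zero A/T dinucleotides and a stationary A/T
fraction of 0.18/1.18 ≈ 0.153), composition-preserving declustering by
rejection of homo-nucleotide runs longer than 2 (the published design
says only "randomly alternating ... to minimize clustering"; the
max-run-2 rejection sampler is this package's concrete, verifiable
choice), site implantation, antenna-like genes (A/T-rich regulatory
regions seeded with clusters of quintet- and quartet-class degenerate
hexamers, A/T-poor CDS at 40%), titration tables from the forward
binding model with multiplicative 10^N(0,σ) noise, and FCS decay series
driven by the binding isotherm. Tandem 300/600-bp construct layouts
(restriction-site ends, linkers, repeated cores) ship as documented
fixtures. The study conditions used throughout the tests — 30
constructs of 75 bp, σ = 0.05 log10 noise, three ionic strengths,
20 seeds for coverage statements; 2% multiplicative FCS noise over
seven concentrations spanning the isotherm — are fixed in the test
suite, and the construct panel (implanted variants from consensus to
highly divergent) stands in for the experimental construct series.

What passing these tests shows: the estimators are unbiased and their
uncertainty estimates calibrated *under the forward model's own noise
process*. What they do not show: robustness to DNA secondary structure
(explicitly unmodelled, and known to matter for G/C-rich constructs),
chromatin context, correlated instrument noise, or model
misspecification of any kind. Real-data K_D values, fitted parameters
from real titrations, genome-scale ChIP fragment histograms and
whole-gene amplification factors require the corresponding external
data and are out of scope here.

## Degenerate inputs and tie-breaks

Sequences with ambiguity codes are rejected at parse time (every window
enters the partition function, so skipping is not an option). GFF3
parsing consumes only gene/mRNA/exon/CDS and selects the transcript
with the longest total CDS. Coordinates are 0-based half-open
internally and 1-based inclusive in reports. Batch K_D propagates
per-record failures as NA rows rather than aborting. The detailed-
balance residual returns ∞ (flagged) when a reverse rate is zero.

## Problem sizes

The test suite and examples run on deliberately small inputs — 75-bp to
7-kb sequences, 30-construct tables, 10⁵–10⁶-step stochastic runs,
20-seed coverage loops — sizes at which every check completes in
seconds while the statistical assertions retain power. All generators
accept larger sizes unchanged.
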