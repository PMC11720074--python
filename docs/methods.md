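# Methods

## Free energy to dissociation constant

Both affinity routes produce one mean binding free energy per variant:
docking scores are averaged over replicates at full precision (the printed
two-decimal averages are never used downstream), and MM-PBSA evidence enters
as a snapshot mean ± SD (sample, n−1 convention by default; configurable).
The mean ΔG converts to a dissociation constant by `Kd = exp(ΔG/rt_eff)`.
Converting the mean — rather than averaging per-replicate Kd values — is the
documented behaviour; it is what reproduces the packaged table.

No temperature is attached to the tabulated conversions, and no physical RT
reproduces every cell at printed precision, so the effective thermal energy
is treated as a calibration constant: a one-parameter least-squares fit of
ΔG = rt_eff·ln Kd over all 18 table rows gives `rt_eff = 0.590335 kcal/mol`,
with every single-row inversion inside [0.59032, 0.59034]. That value (≈297 K)
is the shipped default; `ThermalScale.physical(298.15)` selects true RT.
The implied ~297 K sits slightly below the 300 K of the underlying
simulations; we expose the constant rather than guess the cause.

A variant is flagged *stronger than wild-type* when its Kd is strictly below
wild-type's under the same scoring method. Flags are invariant under any
uniform additive shift of all ΔG values (wild-type included), since the shift
multiplies every Kd by the same factor.

## State-dependent block

The drug-bound (non-conducting) fraction `b` of the Nav conductance pool
obeys one aggregated ODE gated by the instantaneous gating-model occupancies:

    db/dt = D·(kon_o·p_o + kon_i·p_i)·(1−b)
            − (koff_o·p_o + koff_i·p_i + koff_rest·p_rest)·b

with D the cenobamate concentration (µM). Occupancies come from the INa
gates: `p_o = m³·h·j`, `p_i = 1 − h·j` (the non-conducting, non-rested pool —
note this includes the sizeable steady-state inactivation present at the
diastolic potential), `p_rest` the remainder. Unbinding from rested channels
defaults to zero (trapping of the neutral ligand behind the closed inner
gate, guarded-receptor style), which makes block use-dependent in principle;
with the default rates it is in practice pinned at its equilibrium.

Defaults: `kon = 0.01 µM⁻¹ms⁻¹` for both conformations, and koff derived
from the wild-type docking Kd (90.36 µM) so equilibrium behaviour is
anchored to the affinity table; both conformations are assumed to share one
Kd (**flagged assumption** — nothing in the affinity data resolves open vs
inactivated affinity, and a modulated-receptor asymmetry would change the
use-dependence, not the equilibrium). At 17 µM this yields a tonic blocked
fraction of D/(D+Kd) = 0.158 for wild-type — numerically consistent with an
independently measured peak-current IC50 of ~88 µM for this drug on this
channel. Mutants rescale every koff by `Kd_variant/Kd_wildtype` at fixed kon
(exactly reproducing the target Kd), giving 0.31–0.38 at 17 µM for the three
docking-flagged variants.

Because the update is linear in `b` at frozen occupancies, each step uses the
exact exponential relaxation toward the instantaneous fixed point; `b` is
unconditionally confined to [0, 1]. An "equilibrium" mode pins `b` at the
binding isotherm and serves as the fast-equilibrium limit and test oracle;
the kinetic mode converges to it as the rates are scaled up at fixed ratio.

## Myocyte model

The cell model is the published O'Hara–Rudy 2011 human ventricular myocyte
(endocardial parameter set by default; epi/mid selectable), 41 state
variables, with the blocked fraction appended as a 42nd. By default the
conductances carry the CiPA in-silico-pharmacology recalibration
(IKr ×1.013, IKs ×1.870, IK1 ×1.698, INaL ×2.661, ICaL ×1.007), selected
because the strand experiments target the drug-trial configuration of this
model family; `completions=0` restores the original 2011 values. The drug
hook multiplies INa and INaL identically by (1−b); the experimentally
reported difference between peak and late IC50 is not modelled separately.

Validation against the published endocardial behaviour at 1 Hz pacing:
resting potential −88.0 mV, max upstroke velocity 255 V/s, APD90 270 ms,
diastolic [Na⁺]i 7.1 mM — all at their reference values.

## Numerics

Hodgkin–Huxley gates advance by Rush–Larsen exponential updates; membrane
potential and concentrations by forward Euler; `b` by its exact exponential.
Default dt = 0.005 ms. Any internal step whose proposed voltage change
exceeds 0.05 mV is subdivided (up to 256 substeps), which resolves the INa
upstroke independently of the nominal step: halving dt changes a paced AP
trace by < 0.25 mV everywhere. GHK-type driving forces are evaluated with
the voltage nudged off 0 by 10⁻⁶ mV to avoid the removable 0/0. Integration
aborts with a located error if |V| exceeds 200 mV or any state goes
non-finite; NaN inputs are rejected with the offending variable named.
Everything is deterministic — identical configurations produce bit-identical
traces.

Single cells are pre-paced 50 beats at cycle length 1000 ms (configurable)
from the published initial conditions; strand runs start every cell from
that state, drug-free, with binding developing during the simulated beats
(at default rates it reaches its equilibrium within milliseconds).

## Strand and conduction velocity

The strand is a discrete chain (default 50 cells × 100 µm) with one node per
cell — matching the cell-level G_j parameterisation, with no sub-cell
discretisation. Coupling enters as dV_i/dt += k·(V_{i−1} − 2V_i + V_{i+1}),
one-sided at the sealed ends, with k = G_j/1000 ms⁻¹ from the pS/pF unit
identity. The stimulus goes to cell 1 only. The single-cell protocol default
(−80 µA/µF, 0.5 ms) cannot initiate a coupled strand — the gap-junction sink
drains the pulse before INa regenerates, at normal coupling even a 2 ms pulse
fails once 16 % of INa is blocked — so the strand default is −120 µA/µF for
3 ms, chosen for initiation robustness across the G_j × block range (−200
µA/µF overdrives the first cell into the instability guard at low G_j).
Pacing: two beats at cycle length 1000 ms; cv is measured on beat 2.

Activation is the first upward crossing of −20 mV per cell, linearly
interpolated between samples (0.1 ms output stride); the threshold is robust
to the stimulus artefact at cell 1 and to slow upstrokes at low coupling.
cv = (n_cells × cell_length)/(t₅₀ − t₁), the total-string convention (5 mm at
defaults); a beat whose wavefront never activates cell 50 is *not
propagated* and has no cv. Degenerate simultaneous activation raises rather
than returning an infinite velocity.

## Behaviour of the strand under block, and a known limitation

Drug-free, cv rises monotonically with coupling (4.0, 14.8, 30.1 cm/s at
1000, 2000, 6000 pS/pF) and propagation fails below ≈ 500–1000 pS/pF. Near
that margin cv is extremely sensitive to INa: at 2000 pS/pF a 5 % blocked
fraction costs ~0.8 cm/s, 10 % costs ~2 cm/s, and 15.8 % (wild-type at
17 µM) drops the strand into slow, Ca²⁺-assisted crawling conduction
(3.4 cm/s); the mutant block levels (31–38 %) extinguish propagation at both
1000 and 2000 pS/pF. Mechanistically this is the classic source–sink story
of depressed excitability, and it includes the counter-intuitive regime in
which *stronger* coupling kills initiation while weaker coupling preserves
it.

The quantitative consequence is a documented limitation: with block anchored
to the equilibrium dissociation constants, this strand does not reproduce
the reference conduction-velocity table it ships with
(8.0/3.0–3.7 cm/s at 1000 pS/pF and 14.9/11.8–12.4 cm/s at 2000 pS/pF for
wild-type/mutants at 17 µM). Those reference values require a strand that
still conducts at 1000 pS/pF under ~38 % Na⁺-current block, i.e. a
substantially more excitable Na⁺ current than the published model provides —
the reference model's Nav formulation and binding rates come from
experimental fits that are not publicly tabulated. We deliberately do not
rescale GNa or soften the binding kinetics to close the gap, since either
would amount to fitting the very observable under test. The corresponding
end-to-end tests in `tests/test_acceptance.py`
(`test_cv_ordering_and_gap_compression_at_study_conditions`,
`test_cv_values_match_published_within_30_percent`) therefore fail by
design honestly, and the acceptance script reports cv = 0 for
non-propagated conditions. The ordering and monotonicity properties
themselves — cv increasing in G_j, decreasing in binding affinity, wild-type
fastest — are verified in the conducting regime (block ≤ 15.8 % at
2000 pS/pF).

## Synthetic data

The generators emulate the three raw input classes: replicate docking scores
(normal noise around a mean — the real replicate spreads are small and
symmetric; this is a modelling choice, not a claim about the scoring
function), per-snapshot MM-PBSA energies (normal with the tabulated mean/SD,
50 snapshots), and idealised strand traces with sigmoidal upstrokes at exact
constant velocity plus optional end-point-preserving timing jitter. They are
pure functions of (parameters, seed). What they do **not** emulate: docking
score outliers/multimodality (visible in one packaged variant's triplicate),
autocorrelation of snapshot energies along an MD trajectory, and any
electrophysiological structure beyond the upstroke (no repolarisation
heterogeneity). Tests passing on these fixtures therefore validate the
estimators' arithmetic, not the realism of the upstream physics.

## Known limitations

* One-dimensional, homogeneous, endocardial-only strand; no re-entry, no 2D.
* Single binding site, one aggregated blocked pool; no access-pathway
  (fenestration vs gate) modelling, no protonation effects.
* Peak and late Na⁺ current blocked identically.
* The conduction-velocity regression against the shipped reference table
  fails at 17 µM for the reasons above; affinity-side results reproduce the
  reference table to ≤ 0.03 %.
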