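# pdzmc

Monte Carlo simulation and thermodynamic analysis of domain–peptide binding
with a reduced chain model.

Peptide-recognition domains such as PDZ domains bind short, intrinsically
flexible C-terminal peptides in a groove between a β-strand and an α-helix;
the peptide folds as it binds.  `pdzmc` is for studying that coupled
folding-and-binding process at equilibrium and through relaxation
ensembles: it samples a receptor–peptide pair with Metropolis Monte Carlo
(simulated tempering, fixed-temperature runs, and small-step kinetics
ensembles) under an implicit-solvent energy function, and turns the
trajectories into binding curves, two-state fits, specific heat,
free-energy surfaces, and relaxation times.  Its intended users are people
developing or teaching coarse-grained binding simulations who need a fully
reproducible, desk-scale pipeline with exact statistical oracles.

## Model

Each residue is reduced to backbone N, H, Cα, C, O plus one side-chain
site; conformations are parameterized by torsions (φ, ψ, χ) and a peptide
rigid-body frame in a periodic cubic box.  The energy (model units,
k_B = 1) combines directional backbone hydrogen bonding, short-range
hydrophobic attraction between side-chain sites, screened electrostatics
whose strength grows with the buriedness of the charges, a desolvation
penalty for *unsatisfied* backbone NH/CO groups whose solvation probe point
(2.0 Å beyond H along N→H, or beyond O along C→O) is buried by other
protein atoms, soft excluded volume, and harmonic Cα restraints that keep
the receptor near its native structure.

Binding progress is measured by the fraction of native inter-chain contacts
Q, the center-of-mass displacement Δ_CM of the peptide's C-terminal
residues, and the non-optimized peptide RMSD

    RMSD = sqrt( Σ_i |r_i − r_i^nat|² / n )

(no superposition, so it reports both *where* the peptide sits and *how*
it is folded; a frame with RMSD < 6 Å counts as bound).  Observables X(T)
are fitted to the two-state expression

    X(T) = X_U + (X_B − X_U) / (1 + exp[−ΔE (1/T − 1/T_m)])

with baselines X_U, X_B, stability gap ΔE = E_U − E_B and midpoint
temperature T_m; free-energy surfaces are F = −T ln P(E, X) with
single-histogram reweighting between nearby temperatures, and kinetics
ensembles are fitted to a + b·exp(−t/τ).

The package ships deterministic synthetic systems: a toy 24-residue
receptor with a binding groove and 5-residue class I-like (`KASAV`) /
class II-like (`KAVAV`) peptides differing only at P(−2), and an exactly
enumerable mini-system whose Boltzmann distribution is known in closed
form.  See `docs/methods.md` for the full model account.

## Worked example

Sample the class II toy complex at fixed temperature and inspect the
binding observables:

```python
import numpy as np
from pdzmc import (EnergyParams, ToyComplexSpec, make_toy_complex,
                   run_fixed_T, fit_two_state, p_bound_curve)

system = make_toy_complex(ToyComplexSpec(pattern="classII"))
params = EnergyParams()
traj = run_fixed_T(system, params, T=0.8, n_steps=200_000, seed=1)

eq = traj.df.iloc[len(traj.df) // 5:]          # discard equilibration
print(f"P_bound  = {(eq.rmsd < 6).mean():.2f}")
print(f"<Q>      = {eq.Q.mean():.2f}")
print(f"<E_hb_inter> = {eq.E_hb_inter.mean():.2f}")
print(f"min E    = {traj.min_energy:.2f}")
```

Typical output (seed 1):

```
P_bound  = 1.00
<Q>      = 0.38
<E_hb_inter> = -3.02
min E    = -31.26
```

At T = 0.8 — just below this system's midpoint — the peptide stays in the
pocket throughout (`P_bound` = 1) while still exchanging native contacts
with the groove (⟨Q⟩ ≈ 0.4 at this temperature; it grows toward 1 as T
drops) and making favorable inter-chain hydrogen bonds; `min E` is the
lowest total energy visited, whose snapshot `traj.min_coords` holds the
best bound structure of the run.

The same pipeline is scriptable from the shell:

```
pdzmc gen-toy --pattern classII --seed 7 --out toy/
pdzmc sample-fixed --config toy/run.yaml --out runs/
pdzmc analyze-thermo runs/fixed_*.tsv --out analysis/
```

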