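# Methods

`pdzmc` simulates the reversible binding of a short, flexible peptide to a
restrained receptor domain with Metropolis Monte Carlo in an implicit-solvent
reduced chain model, and provides the complete thermodynamic and kinetic
analysis used to characterize coupled folding and binding: native-contact
order parameters, two-state fits of binding curves, specific heat,
free-energy surfaces with single-histogram reweighting, barrier extraction,
and relaxation-ensemble fits.  This note documents the model, its
assumptions, the numerical choices, and what the synthetic test systems do
and do not establish.

## Chain representation

Each residue contributes six sites: backbone N, amide H, Ca, C, carbonyl O,
and one side-chain interaction site S placed at the approximate side-chain
centroid distance from Ca.  Bond lengths and angles are ideal peptide-unit
values with the peptide bond fixed planar (omega = 180 deg), so the internal
degrees of freedom are the backbone torsions phi, psi and one side-chain
torsion chi per residue (chi spins S on a cone about the N-Ca axis).
Coordinates are a deterministic function of (torsions, peptide rigid-body
frame); the receptor chain is anchored at its first residue and additionally
restrained (below).  The complex lives in a cubic box of side L = 60 A with
periodic boundary conditions; the box side sets the effective peptide
concentration and only cross-chain interactions use the minimum-image
convention (chains are small compared to L/2).

Assumptions: no proline ring closure or rotamer structure, no bond-length or
bond-angle flexibility, a single interaction site per side chain.  These
limit side-chain packing realism but retain the mechanisms the analysis
probes: backbone hydrogen-bond donors/acceptors, hydrophobic side-chain
contacts, and torsional flexibility.

## Energy function

Model units with k_B = 1; temperatures of order 1.  Terms:

- **Hydrogen bonding** (eps_hb = 3.2): for each NH donor and CO acceptor
  pair, a radial Gaussian centered on the ideal H...O distance (2.0 A, width
  0.35 A) times squared-cosine alignment factors for N-H...O and H...O=C,
  smoothly switched off between 3.0 and 3.5 A.  The optimum equals -eps_hb.
  Covalent neighbors (own CO, preceding CO) are excluded.
- **Backbone desolvation** (eps_solv = 2.0): every NH/CO group not
  participating in any intra- or inter-chain hydrogen bond (no pairing below
  -0.2 eps_hb) is penalized by eps_solv times the buriedness of its solvation
  probe point, located 2.0 A beyond H along N->H (resp. beyond O along C->O)
  -- roughly where a hydrogen-bonded water would sit.  Buriedness is the
  count of heavy atoms within R_b = 4 A of the probe, divided by n_sat = 5
  and clamped to [0, 1]; the group's own residue and its covalent neighbors
  are excluded from the count, since their atoms flank the probe at any
  conformation.  The term vanishes when every group is bonded or every probe
  is solvent-exposed, and penalizes burying unsatisfied backbone polar groups
  -- the desolvation cost that shapes the binding barrier.
- **Hydrophobicity** (eps_hp = 3.5): -eps_hp * h_a h_b C(r) summed over
  side-chain site pairs (chain neighbors excluded), with h the
  Kyte-Doolittle hydropathy rescaled to [0, 1] and C a linear contact ramp
  from 1 at r_on = 4.0 A to 0 at r_off = 5.5 A.  The short ramp makes
  hydrophobic stabilization contingent on close packing; with a longer ramp
  (5.0/7.5 A) the toy complexes bind downhill without a barrier, which is
  why these values are the defaults.
- **Electrostatics** (eps_el = 2.0): screened Coulomb term over charged
  sites (side-chain charges of D/E/K/R, the peptide's terminal NH3+ and
  COO-), screening length 5 A with a smooth cutoff at 12 A.  Each pair is
  scaled by (1 + gamma * min(b_i, b_j)), gamma = 1, where b is the
  buriedness of the charge site: buried partners interact effectively more
  strongly than solvent-exposed ones.
- **Excluded volume** (eps_ev = 2.0): soft repulsion
  eps_ev((s/r)^12 - 2(s/r)^6 + 1) for r < s, s = 0.85 (r_a + r_b), zero and
  C1-continuous at s; heavy atoms only, chain neighbors excluded.
- **Receptor restraints** (k_res = 6.0 per A^2): harmonic wells on every
  receptor Ca at its reference position, allowing limited backbone
  flexibility (RMS fluctuations of a few tenths of an Angstrom at the
  simulated temperatures) while keeping the domain folded; folding the
  receptor is out of scope.

Every distance cutoff uses a continuous ramp, so the energy is continuous in
the coordinates.  A readable NumPy reference implementation
(`pdzmc.energy`) and a compiled numba kernel (`pdzmc._energy`) coexist; the
kernel adds exact residue-level distance prechecks (strict per-residue reach
bounds) and is verified against the reference term by term on random states.

## Monte Carlo

One elementary step is one attempted move: receptor side-chain rotation or
semi-local backbone window; peptide side-chain rotation, backbone window,
pivot, rigid translation (5 A step) or rigid rotation.  The semi-local move
perturbs 8 consecutive phi/psi angles with a symmetric, mean-centered
Gaussian proposal (step 0.08 rad), which partially cancels the downstream
lever arm while keeping the Metropolis ratio exact; a biased Favrin-style
closing move would need proposal-ratio bookkeeping and is not implemented.
Default move frequencies are 20% receptor side chain, 20% receptor
backbone, 10/20/15% peptide side chain/backbone/pivot, 10% translation, 5%
rotation.  Kinetics mode disables the global pivot move and reduces the
translation step to 1 A, so relaxation proceeds by small steps only; runs
start from random peptide conformations with >= 10 A clearance from the
receptor.  MC "time" carries no physical mapping; only comparisons between
systems are meaningful.

Simulated tempering uses 8 geometrically spaced temperatures (defaults
0.4-2.0 for the toy complexes); a +-1 neighbor temperature-index update is
attempted every 10 conformational steps and accepted with
min(1, exp[-E (1/T_new - 1/T_old) + g_new - g_old]).  Weights g_k = -ln Z_k
are estimated by trapezoidal integration of pilot mean energies over
inverse temperature (``estimate_st_weights``), optionally iterated on ST
data; on systems whose transitions are much slower than the run length
the weight iteration cannot converge, which is why the toy-complex
studies use bidirectional fixed-T pilots instead (below).

Per-move energy evaluation rebuilds the moved chain and recomputes its
intra-chain terms plus all cross-chain terms, reusing cached sums for the
untouched chain; the recorded breakdown equals a from-scratch recomputation
(asserted in the tests).  Every run stores its seed, move statistics and the
minimum-energy snapshot; identical (seed, config) reproduce trajectories
bitwise.

## Order parameters

Q is the fraction of native inter-chain residue contacts, where two residues
are in contact if any two heavy atoms are within 4.5 A (the field-standard
heavy-atom criterion; the native list is built with the same rule, so Q = 1
at the reference).  Delta_CM is the distance between model and native
centers of mass over the Ca atoms of the last four peptide residues (the
C-terminal window that anchors in the pocket).  Peptide RMSD comes in the
non-optimized flavor (no superposition, so it mixes location and internal
conformation) and the optimized flavor (Kabsch superposition, checked
against an independent quaternion eigenvalue method).  A peptide is "bound"
when its non-optimized all-heavy-atom RMSD is below 6 A (9 A as the
sensitivity alternative, which can only increase the bound count).  The
flipped-peptide control pose is the native pose rotated by a half turn about
the axis through the midpoint of the terminal Ca pair, exchanging the
terminal Ca positions exactly.

## Thermodynamic analysis

Averages discard the first 20% of each run and carry delete-one jackknife
errors over independent runs (or 20 contiguous blocks of a single run).
Binding curves X(T) are fitted by weighted least squares to the
four-parameter two-state expression X_U + (X_B - X_U) / (1 + exp[-dE (1/T -
1/Tm)]) with dE = E_U - E_B >= 0; the curve passes through the baseline
midpoint at Tm.  The specific heat per residue is (<E^2> - <E>^2)/(N T^2),
evaluable under reweighting weights off the simulated temperatures.
Free-energy surfaces are F = -T ln P binned over (E, X), X in {Delta_CM, Q}
(bin widths: Freedman-Diaconis for E, 0.25 A for Delta_CM, 0.04 for Q),
minimum shifted to zero; 1D profiles are marginals.  Barriers: the bound
basin is the deepest minimum inside the stated bound window, the unbound
basin the deepest outside it, and the transition state the highest
intervening point; a 1-bin Gaussian smoothing is used only to *locate*
extrema, never for the reported values, and monotone profiles yield a
no-barrier result.  Single-histogram reweighting uses normalized
exp[-E d(1/T)] weights, reports the effective sample size, and is exact at
the source temperature.

## Kinetics analysis

Ensemble relaxation curves are pointwise means with across-run standard
errors on a shared fixed recording grid (a log-spaced grid was considered
and dropped: at the tau-to-grid ratios used, fixed cadence changes the fits
negligibly and keeps the trajectory format uniform).  Fits to
a + b exp(-t/tau) are weighted least squares with the initial tau from
log-linear regression on the tail-corrected amplitude; relaxation-time
ratios carry first-order propagated errors.  A single-exponential fit of
two-scale data recovers the slow scale within ~15% when the scales are well
separated (tested).

## Synthetic systems

The **toy complex** stands in for the experimental domain-peptide systems: a
24-residue receptor (beta-hairpin plus one alpha-helix forming a groove,
sequence `ENNNKNLNNNNINFNVNNNNANNN`) and a 5-residue peptide beta-augmenting
the hairpin's free strand edge, its C terminus at a pocket formed by L6/I11
with K4 near the terminal carboxylate.  The class I-like peptide `KASAV` and
class II-like `KAVAV` differ only at P(-2) (Ser vs Val); F13 provides the
P(-2) hydrophobic pocket, so the class II pattern gains roughly 1.4 model
units of hydrophobic contact energy in the bound pose -- the designed analog
of the extra P(-2) contacts that distinguish class II binding.  The
reference fold and docked pose were designed once by constrained
minimization of this energy function and are frozen as literal
internal-coordinate tables, making the generator deterministic.  Native
contacts (18 residue pairs under the 4.5 A rule), restraint centers, and the
flipped control pose are derived at build time and verified (clash-free,
P(0) contact present).

The **enumerable fixture** freezes everything except one peptide residue's
(phi, psi) on a 12 x 12 grid next to a 2-residue receptor; full enumeration
of the 144 states gives the exact Boltzmann distribution, mean energy,
specific heat and bound-state probability used as oracles for the samplers
and for reweighting.  Because its mobile residue only reshapes the peptide,
all states lie within ~2 A RMSD of the reference and bound-flag checks on
this fixture use the median per-state RMSD as the cutoff.

Closed-form generators produce two-state binding curves and exponential
relaxation ensembles with known parameters for estimator-recovery studies.
The fit-recovery study uses truth (dE = 15, Tm = 0.8) on the 8-point
geometric ladder: that puts the transition width on the scale the ladder
resolves, like the toy binding curves themselves; much sharper transitions
(e.g. dE = 50 at Tm = 0.5) fall between grid points and are unidentifiable
from 8 noisy points regardless of the fitter.

What the toy establishes -- and what it does not: it exercises every
mechanism of the pipeline (coupled folding and binding, desolvation-shaped
barriers, class-dependent bound-state order) at desk scale, but its absolute
numbers (Tm, dE, barrier heights, contact counts) are properties of this
reduced model and sequence design, not predictions for real PDZ complexes;
no experimental comparison is implied.

## Validation studies and problem sizes

The end-to-end studies (also run by `scripts/acceptance.py`) use: 1e6 steps
for the enumerable sampling and ST checks; 4e5 steps for reweighting; 100
replicates for fit-recovery and tau-recovery; and, for the class contrast,
per system 8 bound-start pilot runs (2e5 steps each, one per ladder
temperature), bound-start coexistence probes of 5e5 steps, and then 10
fixed-T production runs x 1e6 steps, half started bound and half
unbound.  The assessment temperature is found in two stages.  The
pilot survival curve -- the tail-half bound fraction of a bound-start
run against temperature -- crosses 1/2 at the temperature where the
complex is marginally stable over the pilot window; because this is a
kinetic-stability measure it overshoots the thermodynamic midpoint, so
the study then descends from it in 10% steps, at each candidate
running one bound-start probe of half the production length, and
accepts the first temperature whose probe tail retains substantial --
but not total -- bound occupancy (bound fraction in [0.45, 0.9]).  At
equilibrium the specific heat peaks exactly at coexistence, so this
probed temperature is the study's operational estimate of each
system's Cv-peak/midpoint temperature.  Alternatives were tried and
rejected: simulated tempering of the toy complexes completes too few
binding round trips at these lengths for weight iteration to converge
(ST is instead validated exactly on the enumerable fixture), and
unbound-start pilots almost never bind within a pilot, so no
equilibrium-grade midpoint is measurable at desk scale.

The Delta_CM barrier statistic is the free-energy rise from the bound
basin to the transition window: max F over Delta_CM in [6, 10] A minus
min F over [0, 6) A (the toy's bound basin extends to ~6 A).  This
fixed-window form equals the barrier of a two-basin profile when a
distinct unbound dip forms and degrades gracefully to the shoulder
height when it does not, which keeps the estimator stable at
desk-scale sampling; windows were chosen against long reference runs
(10 x 5e6 steps per system), not against the ordering assertion.  The
bound-state Q spread is the across-run mean of per-run interquartile
ranges: Q moves on a 1/18 lattice (18 native contacts), so a pooled
IQR is lattice-valued and cannot resolve sub-step differences, while
the per-run mean is continuous.  These sizes keep the full study set
around twenty minutes on one CPU (the reproduction script uses 7e5
production steps to fit its budget); they are roughly a thousandth of
the sampling a publication-scale study of a real complex would use.
That is why the class-contrast outcome is asserted as an ordering
(barrier and bound-state Q spread) rather than as numeric values --
and even the Q-spread ordering sits near the resolution limit at this
scale: the underlying class difference in bound-state Q width is of
order 0.02-0.05, comparable to its own run-to-run scatter, so while
the reference runs and the test's fixed-seed configuration show the
expected ordering, an arbitrary replicate can fall either way.  The
barrier ordering is the robust signature at desk scale.

## Known limitations

- The receptor cannot unfold (restraints) and its backbone moves accept only
  a few percent of proposals; receptor flexibility effects are muted.
- Barrier heights from 1e7 total production steps carry jackknife errors
  comparable to the class difference; the ordering is reproducible across
  seeds, individual DeltaF values are noisy.
- Q on an 18-contact list is quantized in steps of 1/18, so distribution
  widths (IQRs) move on a lattice.
- PDB import rebuilds chains with ideal geometry from extracted torsions;
  native references for imported structures are the reduced-model
  realization, not the crystallographic coordinates.
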