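# Methods

This note records the model, the numerical choices and the open design
decisions behind `cldmd`, and what the synthetic benchmark does and does
not demonstrate.

## Coarse-grained model

The chain is a Cα trace: one bead of unit mass per residue.  All
interactions are piecewise-constant ("step") pair potentials, the
representation in which event-driven discrete molecular dynamics is
exact.  Units are Å, kcal/mol and k_B = 1, so temperature carries units
of kcal/(mol·k_B) and velocities Å per DMD time unit.

| term | form | parameters (default) |
|---|---|---|
| virtual bond (i, i+1) | infinite square well | 3.8 (1 ± δ) Å, δ = 0.02 |
| pseudo-angle (i, i+2) | flat bottom, finite walls | 4.5–7.3 Å, 4.0 kcal/mol outside, hard core 3.0 Å |
| hydrophobic–hydrophobic | two-step well | −1.0 then −0.4 kcal/mol at 4.0–6.5–8.0 Å |
| opposite charges | one-step well | −0.6 kcal/mol to 12 Å |
| like charges | one-step shoulder | +0.6 kcal/mol to 12 Å |
| all other pairs | hard sphere | core 4.0 Å |
| crosslink constraint | flat bottom, single outer step | 0 in [4.0, r_max(reagent)] Å, +2.0 kcal/mol beyond |

Residue classes: hydrophobic AVLIMFWC, positive KRH, negative DE, polar
GSTNQYP.  Implicit solvation is absorbed into the hydrophobic step
depths; there is no separate solvation term.  The pseudo-angle wall is
finite (not an infinite well) so that slightly strained geometries are
penalized rather than forbidden — a fully extended trace would otherwise
be an inadmissible start state.

Reagent maxima (Cα–Cα): ABAS 17 Å, EDC 10 Å, SDA 15 Å, TATA 14 Å,
CBDPS 25 Å.  Satisfaction is strict (`<`).  EDC is chemically
zero-length but its satisfaction scale is stated on Cα atoms, which adds
two side-chain lengths; 10 Å is the operative width.  The finite
2 kcal/mol penalty per constraint is deliberate: with conflicting
restraints the simulation should satisfy an optimal subset, not stall
against an infeasible one.  All constraints enter every replica; no
per-conformer assignment is attempted.

## Event-driven propagation

Between events every bead moves ballistically.  An event is one pair
reaching a shell boundary of its (merged) step potential; the crossing
resolves by conservation laws along the line of centers — transmission
with radial speed √(v_r² − 2ΔU/μ) when the radial kinetic energy exceeds
the step, elastic reflection otherwise.  Kinetic plus potential energy
is conserved exactly between thermostat actions and pair momentum is
conserved per collision; the test suite audits both (drift < 1e−8
relative per 10³ events) along with the absence of hard-core tunneling.

Scheduling uses a per-pair array of next-crossing times: a prediction
stays valid until either bead's velocity changes, so each event costs an
O(n_pairs) argmin scan plus O(n) re-predictions.  For chains up to a few
hundred beads this flat layout (compiled with numba) outperforms a heap
with lazy invalidation and has no stale-event states by construction.
Simultaneous events process in first-pair-index order, making replays
bitwise deterministic.  Two robustness details matter in practice:
the current radial shell of every pair is *tracked* across events and
carried across engine calls (a pair resting numerically on a boundary
must not be reclassified by a fresh distance computation), and sampled
frames are advanced 1e−9 time units off the collision surface so that
from-scratch energy recomputation of a stored frame agrees with the
incremental bookkeeping.

The thermostat is Andersen-style: at Poisson times (rate 0.1 per bead
per time unit by default) a random bead's velocity is redrawn from the
Maxwell–Boltzmann distribution.  The time-weighted mean kinetic energy
per bead converges to (3/2)T within 2%; note that *event-count*
averages are biased upward because collisions cluster in fast
configurations — averages over frames must weight by inter-frame time.

One "DMD time step" is counted as one event (ghost collisions
included).  Production runs use the reference protocol's 6×10⁶ steps
divided by a `scale_factor` (default 100), with the first third
discarded as equilibration.

## Replica exchange and WHAM

24 replicas (default) occupy an arithmetic temperature ladder on
[0.375, 0.605].  Each replica starts from its own seeded self-avoiding
random coil — the natural "completely unfolded" state of a disordered
chain — which also decorrelates the replicas' folding attempts.  Every
`exchange_every` events (default 10³, the attempt period being
protocol-unspecified) adjacent rungs attempt Metropolis swaps in
alternating even/odd order; accepted swaps exchange temperatures and
rescale velocities by √(T_new/T_old), equivalent to configuration
exchange.  The WHAM iteration runs in log space with the density of
states anchored at the lowest occupied energy bin; histogram bins are
Freedman–Diaconis on the pooled energies unless overridden.  Cv(T)
follows from the fluctuation formula under the reweighted ensemble.

## Ensemble analysis

Selection keeps the lowest 10% of production-frame energies (stable
ties).  The clustering cutoff is the modal bin center of the
Freedman–Diaconis histogram of upper-triangle pairwise Kabsch RMSDs
(ties resolve to the smallest center; two structures use their RMSD
directly).  Daura clustering then repeatedly promotes the structure with
the most neighbours within the cutoff (ties to the lowest frame index).
Populations are fractions of the selected set; clusters below 2% are
reported but not further analyzed (RMSF is undefined for singletons).
All leading clusters are reported as the predicted ensemble — no
single-model selection; `min_population` (default 0.05) marks the
"major" ones.  Contacts are inclusive (≤ 8.0 Å) with the trivial
|i−j| ≤ 2 band excluded.

The overfit probe relaxes the top centroid with all constraint wells
removed at T = 0.45 for the scaled equivalent of 2×10⁶ steps (first
500k-equivalent discarded) and reports the Rg trace and the expansion
ratio mean(Rg)/Rg(start).

## Validation observables

All ensemble scores are population-weighted means in [0, 1].  Burial is
a neighbour-count proxy (residues |i−j| > 2 within 10 Å; buried above
the upper-quartile count — quantile-based so the rule is chain-length
robust).  Surface-modification agreement compares the >1.5 heavy/light
protection rule against majority burial.  Secondary structure is
assigned from Cα geometry alone: helix requires (i, i+3) ∈ 4.8–5.6 Å
and (i, i+4) ∈ 5.8–6.6 Å sustained over four residues; strand requires
two consecutive cross-strand pairings ≤ 5.5 Å at |i−j| > 4 in parallel
or antiparallel register.  The HDX proxy equates amide protection with
H/E occupancy and ignores tertiary solvent shielding — a declared
simplification, flagged in reports; experimental secondary-structure
fractions (e.g. from CD) are surfaced for comparison, never computed.

## Synthetic benchmark

`cldmd.synthetic` plants a ground truth and emulates its data:

* **Fold.**  A geometric motif (two ideal helices with a searched turn;
  a three-lobed "claw"; or a compact random globule) built with exact
  3.8 Å bonds, the (i, i+2) window and ≥ 4 Å self-avoidance.  The trace
  is then *annealed into the force field's own basin* by a small
  unconstrained replica-exchange quench (6 rungs on 0.25–0.45, 3×10⁴
  events each; lowest-energy frame kept) and re-projected onto exact
  chain geometry by SHAKE-style iteration.  A planted native must be a
  representable low-energy state of the model class, or recovering it
  from emulated data is ill-posed.
* **Sequence.**  Minimally frustrated by construction: the most-buried
  35% of positions get hydrophobic residues; exposed positions that
  contact each other get complementary charges (greedy two-colouring of
  the surface contact graph); the rest are polar.
* **Crosslinks.**  Drawn from chemically compatible pairs (amine:
  lysine/N-terminus; carboxyl: D/E/C-terminus; photo: any) whose native
  distance is inside the reagent span, with probability decaying
  exponentially (3 Å scale) in that distance — a reagent bridges
  residues that actually encounter each other, so near-contact pairs
  dominate observed tables.  A uniform draw is available as an option.
  False positives replace a rounded fraction of records and violate
  their threshold by ≥ 5 Å, keeping recovery metrics clear of boundary
  noise.
* **SM / HDX tables.**  Ratio 2.0 for buried residues versus 1.0
  exposed (log-normal noise optional); deuteration 0.1 in assigned H/E
  versus 0.95 in coil.

Default study size is 40 residues with 12 constraints (10% false
positive rate), sized so the full paired folding experiment runs in
minutes on one CPU.

**What the benchmark shows — and does not.**  With these defaults the
constrained runs recover the planted topology actively: top-cluster
centroids satisfy 92–100% of the driving constraints while unconstrained
controls reach only ~60–75% population-weighted satisfaction, a margin
observed in every seed examined, and the recovered model's radius of
gyration is essentially stable (expansion ratio ~1.0–1.1) when the
constraint wells are removed.  The centroid's fraction of native
contacts, however, averages ≈ 0.5 with seed-to-seed scatter of ± 0.06:
at desk scale (6×10⁴ events per replica) the constrained ensemble
remains broad, its dominant cluster's centroid is a thermal snapshot
from a wide basin, and roughly half the native's 8 Å contact map is
reproduced in any single representative.  Runs started *from* the native
hold Q ≈ 0.6, so the limit is folding kinetics within the scaled event
budget, not the thermodynamics of the constrained model.  None of this
says anything about real proteins with all-atom force fields — the
synthetic data contain no peptide-level detection effects, no
digestion or spectral noise, and the planted force-field-consistent
native is a best case for recoverability.

## Known limitations

* The coarse force field has no hydrogen bonding and no secondary-
  structure propensity; helices and strands appear in the synthetic
  natives by geometric design, not spontaneously in folding runs.
* Constraint wells exert no force outside their outer step; approach to
  an unsatisfied restraint is purely diffusive (satisfied restraints act
  as ratchets).
* Event-count time scaling makes desk-scale runs short in physical
  time; quantitative kinetics should not be read off these
  trajectories.
* WHAM here is one-dimensional in energy; no multistate/MBAR estimator
  is provided.
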