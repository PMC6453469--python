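# cldmd — crosslink-guided discrete molecular dynamics

`cldmd` folds a protein chain under experimentally derived distance
restraints and characterizes the resulting conformational ensemble.  It
is aimed at structural-proteomics workflows in which short-range
chemical crosslinking (XL-MS) yields a table of residue pairs known to
lie within a reagent-specific Cα–Cα distance, and the question is what
compact conformations — for a disordered protein, what *ensemble* of
conformations — are consistent with those proximities and with
orthogonal observables (surface modification, hydrogen/deuterium
exchange, long-spacer crosslinks).

The default modelling target is the 140-residue α-synuclein chain,
shipped as a packaged constant together with synthetic stand-in tables
for the crosslink, surface-modification and HDX supplements.

## The method

**Model.** One bead per residue at the Cα position.  Every interaction
is a *step potential*: piecewise constant in the pair distance.  Virtual
bonds are infinite square wells at 3.8 (1 ± 0.02) Å; a pseudo-angle well
keeps d(i, i+2) in 4.5–7.3 Å; nonbonded pairs interact through a
residue-class table (hydrophobic two-step well −1.0/−0.4 kcal/mol to
8 Å, ±0.6 kcal/mol single steps to 12 Å for charge pairs, universal
4 Å hard core).

**Constraints.** Each observed crosslink (ABAS, EDC, SDA, TATA) becomes
a flat-bottom well: zero energy below the reagent's maximum Cα–Cα span
(17, 10, 15, 14 Å respectively), a finite +2 kcal/mol penalty beyond it.
Finite penalties let mutually conflicting restraints — expected when one
table reports several interconverting conformers — resolve by partial
satisfaction instead of deadlock.  Long-spacer CBDPS records (25 Å) are
held out for validation only.

**Dynamics.** Because potentials are piecewise constant, the equations
of motion solve exactly: beads fly ballistically between *events*, at
which one pair exchanges momentum across a potential step (transmission
or reflection from energy and momentum conservation).  Energy is
conserved to machine precision between thermostat interventions; an
Andersen-style ghost-collision thermostat makes long runs canonical at
temperature T (units: Å, kcal/mol, k_B = 1).

**Sampling.** 24 temperature replicas spread uniformly over
0.375–0.605 kcal/(mol·k_B) run in parallel from independent random-coil
starts and periodically attempt Metropolis temperature swaps.  Energy
histograms pooled across rungs feed a WHAM estimate of the density of
states and the heat-capacity curve Cv(T), the convergence diagnostic.

**Analysis.** After discarding the first third as equilibration, the
lowest 10% of frames by potential energy are clustered on pairwise Cα
RMSD (Kabsch superposition) with the greedy neighbour-counting
(Daura/GROMOS) algorithm, at a cutoff set to the peak of the pairwise
RMSD distribution.  Each cluster is reported with its population,
centroid, per-residue RMSF, contact-frequency map (contacts: Cα pairs
within 8 Å, |i−j| ≥ 3) and radius of gyration.  An unconstrained
relaxation of the top centroid at T = 0.45 probes overfitting: a model
held together only by the restraint wells balloons once they are
removed.

**Validation.** Ensemble scores are population-weighted: fraction of
held-out CBDPS crosslinks within 25 Å; agreement between
surface-modification protection labels (heavy/light ratio > 1.5 ⇒
buried) and a neighbour-count burial proxy; and an HDX protection
estimate equating protected amides with residues in assigned
helix/strand geometry.

## Worked example

Generate a synthetic study — a planted 40-residue fold plus the
experiment tables it would produce — then fold from the tables alone and
compare against the hidden truth:

```
$ cldmd synth --n-res 40 --n-constraints 12 --seed 1 --out study
$ cldmd fold --fasta study/sequence.fasta --crosslinks study/crosslinks.csv \
             --seed 1 --out fold_out
$ cldmd analyze --ensemble fold_out/production.pdb \
                --frames fold_out/frames.csv --out analysis
480/4800 frames selected, cutoff 6.73 Å, populations [0.863, 0.129, 0.008]
```

The analysis keeps the lowest-energy tenth of 4800 production frames,
places the clustering cutoff at the 6.7 Å peak of their pairwise-RMSD
distribution, and finds one dominant conformational family (86.3% of
selected frames) plus minor ones.  Scoring the centroids:

```
$ cldmd validate --centroids analysis/centroids.pdb \
                 --clusters analysis/clusters.csv \
                 --crosslinks study/crosslinks.csv \
                 --sm study/sm.csv --hdx study/hdx.csv --out validation.json
"constraint_satisfaction": {"weighted": 0.917, ...}
"long_distance": {"weighted_fraction": 1.0, "n_records": 3}
"surface_modification": {"agreement": 1.0}
"hdx": {"expected_protected_count": 15.45, "measured_protected_count": 15, ...}
```

Every centroid satisfies 11 of the 12 driving constraints — the twelfth
is the study's planted false positive — along with all three held-out
long-distance crosslinks; the ensemble's burial pattern matches the
surface-modification labels exactly and its expected protected-amide
count (15.45) sits next to the table's measured 15.

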