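# Methods

## The sampling problem

The huntingtin N-terminal peptide Htt(1-19), MATLEKLMKAFESLKSFQQ, is
intrinsically disordered in water but has a latent amphipathic-helix
propensity that is modulated by post-translational modifications:
phosphorylation of Thr3 raises helicity, additional phosphorylation of
Ser13/Ser16 lowers it, and acetylation of the Lys6 epsilon-amine abolishes
the Thr3 effect.  Sampling such an ensemble is hard because helical and
collapsed-coil states are separated by slow transitions.  The solvent-
scaling replica-exchange strategy implemented here (SWISH, "sampling water
interfaces through scaled Hamiltonians") attacks this by running several
replicas whose water/apolar-atom dispersion attraction is multiplied by a
coefficient lambda — rungs with lambda > 1 favor solvated, extended states
and rungs with lambda < 1 favor hydrophobically collapsed ones — and
periodically swapping neighboring rungs, so conformations diffuse across
solvation conditions while the unscaled rung (lambda = 1) accumulates
physically meaningful statistics.

This package implements the full protocol — ladder construction, Metropolis
propagation, the exchange criterion, demultiplexing, diagnostics — together
with the trajectory observables (DSSP-style helicity split into alpha and
3-10 classes, geometric hydrogen bonds, salt bridges, radius of gyration,
Ramachandran histograms, Aurora-Rose N-capping motifs) at desk scale, on a
coarse-grained peptide model that stands in for the explicit-solvent
all-atom force field.  It makes no attempt to reproduce all-atom helicity
percentages; its acceptance checks are exactness checks (the exchange
criterion, the hydrogen-bond rules, motif matching), statistical-mechanics
checks against enumerable oracles, and direction-only mechanistic checks.

## The coarse-grained model

Each residue carries backbone sites N, H, CA, C, O at ideal internal
geometry (N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A, C=O 1.231 A, N-H 1.0 A,
sp2 angles, omega fixed trans) plus one side-chain bead SC on the canonical
C-beta direction at a per-residue centroid distance.  Only (phi, psi) are
degrees of freedom; the Cartesian build is a deterministic NeRF chain, so
configurations are fully specified by their dihedral lists and all energies
are rigid-body invariant by construction.

The energy splits exactly as U(lambda) = U0 + lambda * W.

U0 contains:

* **Torsion**: two Gaussian wells per interior residue, a helical basin at
  (-57, -47) (depth 2.5 kcal/mol, width 20 deg) and an extended basin at
  (-135, 135) (depth 1.6 kcal/mol, width 25 deg).  Residues 1 and L carry
  no torsion energy (their phi / psi are not fully defined by flanking
  atoms); psi_L still places the terminal carbonyl oxygen.
* **Bead Lennard-Jones** between CA/C/SC beads of residues at least two
  apart (Lorentz-Berthelot combination; hydrophobic SC epsilon 0.30,
  polar SC 0.12 kcal/mol).  Backbone N and O additionally carry a weak
  LJ site (epsilon 0.05, sigma 2.8 A) purely as excluded volume: without
  it the sampler can push an amide hydrogen inside 0.5 A of a carbonyl,
  which is unphysical and rejected by the Kabsch-Sander evaluator.
* **Debye-Hueckel electrostatics** between formally charged groups
  (charged side-chain beads, the N-terminal amine on N1 and the
  C-terminal carboxylate on C_L) with dielectric 78.5 and screening
  length 9.6 A, the Debye length of 100 mM salt at 300 K.  The distance
  is floored at a saturation radius of 6.0 A ("flat-bottom" interaction).
  This is deliberate: the formal charge of a side chain sits at the end
  of a flexible arm that a single centroid bead cannot represent.  With
  bare 1/r interactions a salt bridge scores far better at the ~3.5 A
  contacts reachable only in collapsed coil than at the 5.5-6.5 A
  centroid separations of helical geometry, and the model then predicts
  phosphorylation to *disorder* the N-terminus — the opposite of its
  established effect.  Flooring the distance at roughly the combined arm
  reach makes every contact within reach equally rewarding, which is the
  physically sensible bead-resolution statement.
* PTM effects enter as data, not extra terms: phosphorylation sets the
  Ser/Thr side-chain charge to -2 (configurable to -1) and extends the
  bead by 1.2 A; side-chain acetylation zeroes the Lys charge and extends
  the bead by 1.0 A; N-terminal acetylation zeroes the terminal amine.

W is the lambda-coupled solvent-dispersion analogue: every apolar bead
(CA and C of all residues, SC of hydrophobic-class residues — mirroring
"all carbons plus sulfur-bearing side chains" at bead resolution)
contributes its solvent exposure max(0, n_max - n_neighbors), with a
6.5 A neighbor cutoff over the CA/C/SC bead set and n_max = 10, times the
coefficient s = -0.08 kcal/mol.  s is negative because water/apolar
dispersion is attractive; lambda > 1 therefore rewards exposure, which is
the sign convention the sampling strategy requires.

### Calibration

The torsion depths, LJ epsilons and s were set once, by short scans, to
put the unmodified peptide at lambda = 1 and 300 K in the regime the model
is meant to emulate: mostly coil with transient helical stretches (overall
helicity of a few percent, drifting down as lambda grows), with exchange
acceptance well above one half on the 0.05-spaced ladder.  With those
defaults the model reproduces, as directions rather than numbers, the
qualitative PTM ordering: pThr3 raises Ala2-Leu7 helicity relative to the
unmodified peptide; adding acLys6 removes the increase; acLys6 alone
raises helicity.  No quantitative agreement with all-atom or experimental
helicities is claimed, and none should be inferred from passing tests.

## Sampling

One Monte Carlo sweep is a Metropolis pass over all 2L dihedrals in
residue order; each move perturbs a single angle uniformly within
+/- 25 deg (symmetric proposal, no Hastings factor) and accepts with
min(1, exp(-dU(lambda)/kT)).  Replica exchange attempts, every
``swap_interval`` sweeps (default 10 — the sweep-count analogue of the
5 ps swap period of the molecular-dynamics protocol), run over adjacent
rung pairs of alternating parity.  Because U is exactly linear in lambda,
the same-temperature exchange exponent reduces to

    delta = (lambda_m - lambda_n) (W_n - W_m) / kT,

computed from cached W values and verified in the tests against the full
four-energy expression to 1e-10 relative.  Each replica owns an RNG stream
spawned from the master seed and keyed to its permanent identity, so swaps
never touch random-number state and runs are bit-reproducible from (seed,
configuration).  Frames are recorded per rung; the demultiplexer replays
accepted swaps from the exchange log to recover walker-continuous paths
and is exactly invertible.

Reported statistics use the lambda = 1.0 rung only, discarding the first
10% of sweeps by default (configurable; the relaxation from the arbitrary
starting conformation is fast but visible).

## Observables

* **Secondary structure**: Kabsch-Sander hydrogen-bond energy
  E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol, bond iff
  E < -0.5.  Two consecutive i -> i+4 turns make an alpha run (H), two
  consecutive i -> i+3 turns a 3-10 run (G, alpha priority on overlap);
  isolated turns are T, the rest C.  Beta classes and the pi helix are
  intentionally not assigned — the observable of record is the fraction of
  residue-frames labeled H or G.  On ideal alpha, 3-10, extended and mixed
  structures the bond decisions agree with mdtraj's independent
  Kabsch-Sander implementation on 100% of pairs.  Amide hydrogens missing
  from external trajectories are placed 1.0 A from N_i along C_{i-1} -
  O_{i-1}; residue 1 never donates.
* **Geometric hydrogen bonds**: heavy-heavy distance <= 3.5 A (inclusive)
  and heavy-H-heavy angle > 120 deg (exclusive).  Backbone CO(i) -> NH(i+k)
  frequencies are tabulated for offsets k = 1..4; group frequencies use
  any-pair union semantics (a frame counts if any atom pair in the group
  product qualifies).  Side-chain donors get an implicit hydrogen 1.0 A
  outward along CA -> SC; acetylated lysines and phosphorylated Ser/Thr do
  not donate.
* **Salt bridges**: opposite-sign charged groups within 4.0 A
  (conventional heavy-atom cutoff, configurable).
* **Radius of gyration**: mass-weighted RMS distance from the weighted
  centroid (bead masses from residue composition, +80 Da per phosphate,
  +42 Da per acetyl); an unweighted variant is available.
* **N-capping motifs**: Aurora-Rose patterns Ia (h-xpxhx), Ib (h-xpxph),
  IIa (hp-xpxhx) over h = {A,V,L,I,M,F,W,Y,C} + {K,R} (the Lys/Arg alkyl
  stems are hydrophobic) and p = {S,T,N,Q,D,E,H} + {K,R}; x is
  indifferent and '-' the helix boundary, with pre-boundary characters
  applying to the residues immediately preceding the N-cap.  This is the
  unique alignment consistent with all three reference assignments on the
  unmodified sequence (Ib at Ala2, IIa at Leu4, Ia at Phe11).
  Phosphorylated S/T remain polar; acetylated Lys keeps its alkyl
  h-membership.  Class membership is a pure function of residue type and
  PTM state, never of position.

## Oracles and what passing means

The enumerable toy system (a tiny peptide restricted to a discrete
per-residue dihedral alphabet, <= 256 microstates, with exact (U0, W)
tables computed from the same energy model) allows the per-rung sampled
distributions of a full replica-exchange run to be compared against exact
Boltzmann sums — the operational meaning of "the exchange criterion
preserves replica statistics".  The lambda = 1 stream of a 6-rung run is
additionally required to agree, within three standard errors, with plain
Metropolis sampling at lambda = 1.  The plain-MC reference is deliberately
an ensemble of independent chains started from dispersed conformations
(half extended, half ideal helix) whose error bar is the between-chain
standard error: a single chain at lambda = 1 is strongly metastable at
desk scale — helical episodes persist for thousands of sweeps, so one
12000-sweep chain can sit at 24% helicity while another sits at 6% — and
within-chain block averaging would understate its uncertainty badly.
(That metastability is, of course, the problem the replica-exchange
ladder exists to solve.)  The SWISH stream itself mixes across rungs and
uses within-stream block averaging.

The synthetic generator and the coarse-grained model emulate chain
connectivity, torsional helix propensity, excluded volume, screened
electrostatics of formal charges and a burial-based solvation term.  They
do not emulate explicit water, backbone amide dipoles (no helix
macrodipole), side-chain rotamers, or all-atom dispersion, so passing
tests validate the sampling machinery and the analysis stack, not
quantitative helicity of the real peptide.

## Numerical choices and edge cases

* k_B T at 300 K = 0.5961 kcal/mol (k_B = 0.0019872041 kcal/mol/K);
  energies kcal/mol, distances A, angles degrees; 1-based residue
  numbering everywhere.
* Bead overlaps below 1.2 A report U = +inf (the move is rejected); the
  Kabsch-Sander evaluator rejects geometries with inter-atom distances
  below 0.5 A as malformed.
* Ladder bounds must be commensurate with the step (no silent
  truncation); a ladder without the 1.0 rung runs but flags that no
  reporting ensemble exists.
* Ideal-structure dihedrals: alpha (-57, -47); 3-10 (-49, -26) (standard
  textbook values); extended (-135, 135).
* Multi-model PDB is the only trajectory format (round-trip precision
  1e-3 A, fixed-width records); the SC bead is written as CB.
* Problem sizes used by the test suite and the acceptance script (1e5
  sweeps for the enumerable-system check, 3000-6000 sweeps for the
  19-mer runs, 10 blocks for error bars) were chosen as the smallest runs
  whose pass/fail behavior was stable across seeds during development.

## Known limitations

* Single-bead side chains cannot form orientation-specific hydrogen
  bonds; side-chain H-bond statistics are centroid-geometry proxies.
* The flat-bottom electrostatics trade short-range energetic detail for
  the correct contact topology; absolute salt-bridge energies are not
  meaningful.
* The torsion potential has no residue-specific helix propensities
  beyond the hydrophobic/polar LJ split; glycine/proline special-casing
  is absent (neither occurs in the reference sequence).
* Exchange acceptance on the default ladder is high (~0.95) because the
  coarse-grained W fluctuates much less than an explicit-solvent
  dispersion energy would; the ladder spacing is kept at the protocol
  values rather than re-optimized.
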