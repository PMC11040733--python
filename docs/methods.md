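# Methods

## The model

`asmgo` builds structure-based ("Go-type") coarse-grained force fields for
multiprotein complexes. Each amino acid becomes one pseudobead of unit mass
at its Calpha position; all beads share the same size and differ only in
their interactions, which are derived from a known native structure of the
assembled complex. The potential is

    V = sum_bonds    k_b (r - b_ij)^2
      + sum_angles   k_a (theta - a_ijk)^2
      + sum_dihedrals k_1 [1 - cos(phi - d_ijkl)] + k_3 [1 - cos 3(phi - d_ijkl)]
      + sum_{native intra pairs} eps_intra [ (s_ij/r)^12 - 2 (s_ij/r)^6 ]
      + sum_{native inter pairs} eps_inter [ (s_ij/r)^12 - 2 (s_ij/r)^6 ]
      + sum_{all other pairs}    eps (sigma_R / r)^12

with every equilibrium value (b, a, d, s) measured on the native
conformation, so the native structure is by construction the global energy
minimum (the folding-funnel assumption). Native pairs are residue pairs in
atomic contact in the native structure; everything else repels. The two
dihedral multiplicities share the native equilibrium angle; since mirrored
structures have dihedrals of opposite sign, this term excludes refolding
into the mirror image. Electrostatics are implicit: they shaped the native
conformation that defines the interactions.

The distinguishing features over a plain single-chain Go model:

1. **Intra/inter splitting.** Contacts within a chain and between chains
   carry separate global strength multipliers (`epsilon_intra`,
   `epsilon_inter`), decoupling folding stability from binding strength and
   enabling coupled folding-and-binding studies.
2. **Chain merging (permutation invariance).** Chains with exactly identical
   sequences become one molecule type; intermolecular native pairs are
   expressed between *atom types* (one type per residue position of a
   merged molecule), so any two copies can bind through any native
   interface — identical subunits are exchangeable, as they are physically.
3. **Multiple native conformations.** Several models in the input structure
   define several minima. Angle and dihedral terms of a multi-conformer
   molecule become dense tables holding the pointwise *minimum* over the
   per-conformer potentials; native pairs are pooled over conformers (the
   short contact range keeps the basins nearly independent); bond lengths
   are taken from the first conformer.
4. **Interaction groups.** The intermolecular contacts between one pair of
   chains form one interface ("interaction group"); symmetry-equivalent
   interfaces (identical residue-pair sets in merged coordinates) share a
   group *type* whose contact strength can be scaled by a per-type factor
   (e.g. weakening ring-ring stacking relative to in-ring contacts).

## Units

Energies are multiples of a generic unit eps, mapped to 1 kJ/mol in exported
files. Temperatures are quoted in the reduced unit kappa with
kT = 0.0083145 · T eps (kappa is numerically the Kelvin-shaped unit a
simulation engine sees at eps = 1 kJ/mol); times in the reduced unit tau.
Because all force constants are type-uniform, results are qualitative:
reduced temperatures and times do not convert meaningfully to physical
units. Internally all distances are Angstrom and angles radians; exported
files use nm and degrees.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `k_bond` | 100 eps/A^2 | harmonic bond constant, V = k (r-b)^2 |
| `k_angle` | 20 eps/rad^2 | harmonic angle constant |
| `k_dihedral_1`, `k_dihedral_3` | 1.0, 0.5 eps | dihedral multiplicity 1 / 3 prefactors |
| `epsilon_intra`, `epsilon_inter` | 1.0, 1.0 | global native-contact depths |
| `repulsive_radius` | 4.0 A | bead repulsion radius; sigma_R = 4.0/2^(1/6) |
| `contact_scale` | 1.0 | contact when d <= scale · (r_vdw_a + r_vdw_b) |
| `exclusion_window` | 4 | min sequence separation of intra native pairs |
| `rmsd_cutoff` | 1.5 A | conformer-merging RMSD cutoff (Kabsch superposition) |
| `angle_dihedral_cutoff` | 170 deg | suppress dihedrals with near-straight flanking angles |
| table grids | 1000 (angle), 1440 (dihedral) | multi-minimum table resolution |

The bonded force constants follow the classic Calpha Go-model lineage
(bond >> angle >> dihedral stiffness) in the V = k·x^2 convention; on export
they are doubled for the simulator's ½kx² convention. The contact criterion
is an atom-level van-der-Waals cutoff: two residues are native partners when
any interatomic distance is within `contact_scale` times the sum of the
Bondi-style van-der-Waals radii (H = 1.10 A; hydrogens participate when
present — inputs should be protonated, otherwise raise `contact_scale`).
The `exclusion_window` of 4 reflects that residues i..i+3 are already
governed by the bond/angle/dihedral terms.

## Numerical choices

* **Dihedral convention**: IUPAC right-handed sign, range (-180, 180] deg.
* **Dihedral suppression**: a dihedral whose flanking bond angle exceeds
  `angle_dihedral_cutoff` is dropped entirely (not softened) and recorded;
  near-straight angles make the dihedral direction numerically unstable.
* **Multi-minimum tables**: grid energies are the exact pointwise minimum
  over conformer branches; the derivative column comes from the
  lower-energy branch, so it is discontinuous exactly at branch crossings
  (where the force is small); evaluation interpolates energy and derivative
  with a cubic Hermite polynomial, keeping force and energy mutually
  consistent.
* **Merging determinism**: averages over member chains sort values before
  summation, so merged topologies are bit-identical under any permutation
  of identical chains in the input; group-type ids are assigned from
  canonically sorted pair-set signatures for the same reason.
* **Same-type override leakage**: a type-level intermolecular pair between
  two positions of the same molecule type would also act inside one copy;
  the exporter adds an intramolecular exclusion plus a repulsion-only pairs
  entry there, restoring default behavior (the in-memory evaluator mirrors
  this).
* **Alternate locations** resolve to the highest-occupancy conformer (tie:
  first in file); non-amino-acid HETATM records are dropped with a log
  line; nonstandard amino acids are an error (substitute them upstream).
* **Random placement** rejects candidate positions with any interchain bead
  distance below 4 A (minimum image) and is deterministic given a seed.

## The internal dynamics engine

The package carries a small BAOAB-splitting Langevin integrator (uniform
mass 1, default dt 0.002 tau, friction 1/tau) over the exact analytic
forces. It exists to make generated force fields testable end to end —
folding, binding and assembly smoke tests on desk-scale fixtures — without
an external simulation engine; production assembly simulations are meant to
run in GROMACS on the exported files. With friction 0 the scheme reduces to
velocity Verlet, which the energy-conservation test uses. The r^-12
repulsion is truncated at 3 sigma_R and energy-shifted (force error at the
cutoff ~1e-5 eps/A). Non-bonded candidate pairs come from a precomputed
pair list below 400 beads and a periodic k-d tree above.

## Synthetic fixtures: what they emulate and what they do not

All tests run on generated structures: idealized alpha-helical chains with
a small all-atom-like backbone (N, CA, C, O, CB and two hydrogens per
residue), helix-turn-helix "hairpin" chains with intramolecular contacts,
exactly Cn-symmetric rings with engineered adjacent-chain interfaces,
stacked double rings (two interface classes), two-conformer chains, and
schematic binding trajectories with a known binding frame. They reproduce
the *geometric* features the pipeline depends on — atom-level packing at
interfaces, exact symmetry, identical sequences, multiple models — at sizes
(tens of residues, 3-10 chains) where oracles (brute-force contact scans,
exhaustive permutation searches, finite-difference gradients) are exact and
fast. They do not reproduce real protein packing density, side-chain
diversity, or realistic contact-order distributions; passing tests verify
the machinery (detection, merging, export, bookkeeping, analysis), not
biophysical accuracy on real complexes. Desk-scale dynamics checks (toy
dimer binding in ~200 tau, hairpin unfolding at T = 200 kappa) use small
systems and short runs sized for a single CPU; they demonstrate
qualitative model behavior, not converged statistics.

## Trajectory analysis

Before analysis, periodic trajectories are unwrapped chain-wise (make each
chain whole along its bonds, then keep each chain's centroid continuous
between frames by minimum-image shifts). Two chains count as *bound* in a
frame when the centered moving-window (default 11 frames) mean of their
centroid distance is below a distance threshold and its standard deviation
is below 1.5 A — stable proximity rather than a fly-by. The bound relation
defines a graph per frame; connected components of two or more chains are
subassemblies and the multiset of their sizes labels the assembly state
("3+2" = trimer + dimer, "0" = fully disassembled). For n chains the
possible labels are the partitions with parts >= 2 of every m <= n (7
states for a pentamer). Transition statistics count state *changes* at a
configurable lag and normalize per source state (outgoing probabilities sum
to 100%); transitions that cannot be a single binding/unbinding event are
flagged. Structural accuracy uses a chain-permutation-invariant RMSD:
exhaustive over the permutations of identical chains up to 6 copies, and a
Hungarian assignment on chain centroids with iterated Kabsch refinement
above (verified against the exhaustive search at 5 copies; potentially
suboptimal for pathological geometries at larger copy numbers). The
fraction of native contacts Q counts native pairs within 1.2 · r0 (a
standard tolerance).

The binding smoke test is a *re-docking* protocol: the toy dimer's second
chain is displaced 6 A along the interface normal with a random tilt of up
to 8 degrees, then simulated for 160 tau at T = 30 kappa in a periodic
box. This probes descent of the binding funnel and stability of the bound
state; diffusive first-encounter binding from fully random placements needs
two to three orders of magnitude more simulation time and belongs in the
exported-GROMACS workflow, not in a desk-scale check.

The binding thresholds (window 11, std 1.5 A, distance threshold of order
1.2 × the native interface centroid distance) are configurable package
choices; they are validated on trajectories with known ground truth.

## Design choices where the design was open

* Identical sequence means *exact* string equality; chains with missing
  residues never merge with complete ones (a gapped chain is a different
  molecule as far as a position-indexed topology is concerned).
* Interfaces of a heteromer are symmetrized (A-to-B and B-to-A are one
  group type).
* Duplicate native pairs arising from multiple conformers or members
  average their r0 values.
* Group-type equality is exact pair-set identity by default; an optional
  Jaccard tolerance (>= 0.9 recommended) merges near-identical interfaces
  from slightly asymmetric crystal contacts.
* Interface strength factors come from the config file (non-interactive,
  reproducible runs).

## Limitations

* Residue size, mass, orientation and chirality beyond the dihedral sign
  are ignored (uniform beads).
* No shadow/cutoff contact-map variants; no per-residue contact energies.
* Kinetics are qualitative; no hydrodynamic coupling.
* Nucleic acids, carbohydrates and other non-protein components are not
  supported and must be removed from inputs.
* The internal integrator is for validation, not production performance.

A sample GROMACS run-parameter file for the exported force field (Langevin
dynamics, tabulated bonded interactions) is in `docs/sample_langevin.mdp`.
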