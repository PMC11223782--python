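# Methods

## Scope and model

`pie` treats a protein–protein or protein–ligand interface as a pair of
atom sets and a cavity between them. The pipeline is deterministic end
to end: given the same inputs and configuration it produces identical
artifacts, which the test suite verifies by hashing a full rerun.

### Inclusion and quality filters

A heterodimer (HD) complex is kept when, after removing waters and
heteroatoms, exactly two polymer chains remain, their entity accessions
differ, and each has more than three residues (residues are counted
when they are polymeric and have at least one resolved heavy atom). A
protein–ligand (PL) complex is kept when its ligand — a non-polymer,
non-water residue — has at least `min_heavy` (default 8) heavy atoms
made exclusively of drug-like elements (default H, C, N, O, S, P, F,
Cl, Br, I). Both defaults are configuration-exposed; they follow common
druglikeness practice rather than any single authoritative value.

Experimental quality is filtered per method, all thresholds inclusive:
NMR structures pass with no numeric check; X-ray requires resolution
≤ 3.5 Å and R-free − R-factor ≤ 0.07; cryo-EM requires resolution
≤ 3.0 Å and a reported FSC value ≤ 0.143 (read literally as a threshold
on the reported number). Any missing required metric fails closed.
Structures with alternative-location atoms inside the interaction patch
are excluded; altlocs elsewhere are harmless. Inputs are assumed
complete (no side-chain rebuilding or protonation is performed); a
warning is logged when a polymer residue misses expected backbone heavy
atoms.

### Interaction patch

The patch between target and partner is the set of atoms of each side
within 6.0 Å (inclusive) of any atom of the other side, straight
Euclidean distance over all atoms, hydrogens included when present (a
heavy-only switch exists). The k-d-tree implementation is contractually
identical to the brute-force all-pairs computation, which the tests
check on random scenes.

### Negative-image cavity detection

A cubic lattice (spacing 1.5 Å) is built over the bounding box of the
partner-side patch atoms plus a 4.0 Å margin, with the origin snapped
down to spacing multiples so the lattice is a pure function of the
input. Lattice points within 2.5 Å of a host heavy atom are occupied;
free points are scored for buriedness by casting 120 fixed
quasi-uniform rays (Fibonacci sphere) of length 8.0 Å against host
heavy atoms modelled as 1.7 Å spheres. Points with at least 55 blocked
rays (≈ 46% occlusion) survive, are clustered by 26-connectivity, and
clusters of fewer than 10 probes are dropped. Each probe takes the
pharmacophore type complementary to its nearest typed host atom within
4.0 Å (donor atom → acceptor probe, carboxylate O → positive-donor
probe, aromatic-ring C → aromatic probe, other C/S → hydrophobic, no
typed atom in range → dummy), with ties broken by distance then atom
serial. The residue/atom typing table ships with the package
(`pie._atom_types`); histidine is treated as a neutral donor/acceptor
pair rather than charged.

All lattice parameters are configuration-exposed. The grid is
axis-aligned, so probe placement is translation-equivariant but *not*
rotation-equivariant; downstream shape descriptors are rotation
invariant functions of the probe cloud, which is what pocket comparison
uses.

### Retention and classification

A detected pocket is retained when at least 4 probes lie within 1.0 Å
of a partner atom (partner protein for HD, ligand for PL) — cavities
nothing binds into are discarded. To classify a PL pocket, the monomer
is mapped into the heterodimer frame by a least-squares rigid
superposition (Kabsch, via scipy's rotation solver) on CA atoms of the
shared chain paired by author residue number (insertion codes must
match; fewer than 3 pairs is an error). With k the number of
heterodimer-pocket probes having a ligand heavy atom within 1.0 Å: the
pocket is orthosteric iff k ≥ 4, else allosteric (PLA); an orthosteric
pocket is competitive (PLOC) when any ligand heavy atom comes within
the overlap cutoff (default 1.0 Å) of a superposed epitope atom, else
non-competitive (PLONC). The k ≥ 4 orthosteric rule reuses the
retention arithmetic symmetrically; the 1.0 Å overlap cutoff is a
design choice exposed in configuration, since "proximity to the
partner" admits several readings.

### Descriptors (109 = 89 + 10 + 10)

*Base (89):* pocket volume (probe count × spacing³, Å³); one overall
count for each of 8 categories (7 probe types plus total-polar =
donor + acceptor + both ionizable); and those 8 counts split over 10
right-closed deciles of normalized buriedness (blocked rays / 120).
1 + 8 + 8×10 = 89. The internal structure of this block is this
package's reconstruction of a volume + pharmacophore-by-buriedness
scheme; only the total is externally fixed.

*Amalgamated (10):* fractions of total probes per typed category and
dummy, the polar fraction, exposure (fraction of probes in the lowest
three buriedness deciles) and mean normalized buriedness — all in
[0, 1].

*Geometric (10):* from the gyration tensor eigenvalues λ1 ≤ λ2 ≤ λ3 and
unit-mass principal inertia moments I1 ≤ I2 ≤ I3 of the probe cloud:
Rg = √(λ1+λ2+λ3); asphericity = ((λ3−λ2)² + (λ2−λ1)² + (λ1−λ3)²) /
(2(λ1+λ2+λ3)²); spherocity = 3λ1/Σλ; eccentricity = √(1 − I1/I3);
inertial shape factor I2/(I1·I3); PMI1–3; NPR1 = I1/I3, NPR2 = I2/I3.
Degenerate conventions: a single probe has Rg 0, asphericity 0,
spherocity 1, eccentricity 0, NPR1 = NPR2 = 1, shape factor 0; a
collinear cloud (I1 = 0) has eccentricity 1 and shape factor 0. Rg,
NPR1 and NPR2 agree with RDKit's 3D descriptor implementations on
equal-mass point clouds (cross-checked in the tests); the asphericity
normalization here maps to [0, 1] (0 = sphere-like, 1 = rod).

### Similarity and pocketome

Descriptor columns are pruned (kept iff non-zero in strictly more than
95% of rows — "exactly 95 of 100" is dropped), standardized column-wise
with the population standard deviation (constant columns are dropped
with a warning), and compared by Euclidean distance. σ is the
population standard deviation of the n(n−1)/2 unordered pair distances;
PSI_ij = exp(−d_ij²/2σ²) with the diagonal defined as 1. σ = 0 (all
pockets identical) is an error, not a silent division. Population
moments were chosen over sample moments for self-consistency between
scaling and σ; a `ddof` switch flips both. Pruning operates on the
pooled pocket sample by default.

The pocketome is the exact minimum spanning tree of the complete pocket
graph weighted by distance (Kruskal over edges sorted by (weight,
min id, max id), so ties are resolved deterministically). Because the
Gaussian kernel is strictly decreasing, the same edge set maximizes
total PSI; PSI is attached to edges as an attribute. No approximate
LSH-based tree or 2D layout is computed — the exported GraphML/JSON/TSV
can be laid out by any graph viewer. Node annotations (volume,
exposure, hydrophobicity, aromaticity, asphericity, class, family tag)
use raw, pre-standardization descriptor values; family tags come from a
user-supplied metadata table, never from the network.

### Hot spots

ΔΔG tables (kcal/mol) are consumed, not computed. A residue is a
critical hot spot at ΔΔG ≥ 1.5 and a warm hot spot in [0.5, 1.5); the
upper bound belongs to the critical class because 1.5 is claimed by
"1.5 or more", and the warm lower bound is taken inclusive. Negative
(stabilizing) values are unlabelled.

## Synthetic data

The fixtures module emulates the canonical peptide-in-groove interface:
chain A is a half-pipe of 126 alanine-like residues (cross-section
radius 4 Å, wall azimuths covering all but a 100° top opening, 9 rings
along the axis), and the partner is either a 9-residue peptide on the
channel axis (HD) or a 12-heavy-atom C/N/O ligand (PL). By construction
the complex passes selection, the patch is non-empty, cavity detection
finds one channel pocket that passes retention, and the PL ligand
occupies the same groove as the HD peptide (hence classifies PLOC). A
flat-sheet fixture provides the negative control: contact without
concavity, hence no pocket at default buriedness. Atom placement is
deterministic; an optional seed-controlled jitter (default 0)
diversifies geometry. Synthetic accessions (FIXA/FIXB) keep everything
network-free.

What the fixtures do *not* emulate: real side-chain chemistry and
rotamers, crystallographic packing, structural noise, divergent
constructs requiring sequence alignment, or dataset-scale pocket
diversity. Passing tests therefore demonstrate the correctness of the
rules and numerics, not recovery of any production-scale dataset
statistics, which would require a full structure-database snapshot.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately small problems: one
groove complex has ~670 atoms and yields a ~45-probe pocket; end-to-end
runs use 2 HD + 2 PL complexes; similarity checks use 10×82 matrices;
the MST oracle enumerates all spanning trees up to n = 6. Threshold
sweeps use grids fine enough (0.001–0.05 in the respective unit) to pin
each rule constant exactly.

Tolerances: MOL2 coordinates round-trip to 1e-3 Å (4-decimal format);
rotation invariance of shape descriptors is asserted at 1e-6; kernel
values against the brute-force oracle at 1e-12. Rotation matrices are
validated to det = +1 within 1e-6. Buriedness uses exact ray-sphere
intersection tests (a point inside a blocking sphere counts as fully
buried); the ray direction table is a fixed Fibonacci sphere, so probe
scores carry no randomness.

## Known limitations

- Probe placement depends on grid orientation (axis-aligned lattice);
  only the descriptor layer is rotation-invariant.
- Chain pairing for superposition is by author residue number; no
  sequence alignment fallback for renumbered or divergent constructs.
- The lattice parameters (spacing, clash distance, ray count, the
  55/120 buriedness threshold, 10-probe minimum) are package defaults
  chosen to make the negative-image concept concrete; they are not
  calibrated against any licensed cavity-detection tool's output.
- The 10 amalgamated descriptor formulas are this package's registry;
  other reasonable definitions of "exposure" or "polarity" exist.
- FSC filtering is a literal threshold on a reported number; if the
  metadata reports the FSC-criterion *resolution* instead, the cryo-EM
  resolution filter is the operative check.
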