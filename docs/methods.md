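# Methods

`ionbridge` analyses how cations mediate the nano-scale clustering of
charged lipids — above all the polyphosphoinositides (PPIs: PI, PI(4,5)P2,
PI(3,5)P2) — in asymmetric bilayers. It implements the full chain from
ion–lipid contact detection to cluster statistics, hydration profiling,
bond networks, leaflet tessellation, association scores and lateral
diffusion, and ships a synthetic-trajectory generator whose planted ground
truth validates every stage. This note records the models, the defaults
and why, the numerical choices, and what the synthetic tests do and do not
establish about real simulation data.

## Data model and conventions

Lengths are Angstrom, times ps, charges in units of e; indices are
0-based. Boxes are orthorhombic only — triclinic input is rejected —
and coordinates are stored wrapped into `[0, L)` per axis. Atom naming
follows the CHARMM36 convention (4-phosphate oxygens OP42/OP43/OP44,
5-phosphate OP52/OP53/OP54, diester prefix OP1), so atom-level analyses
run unchanged on synthetic pseudo-atom systems and on real all-atom input.

Leaflets are assigned once, from the first frame, by the sign of each
lipid's headgroup reference atom (the phosphate P, or the hydroxyl O3 for
cholesterol) relative to the median headgroup height, and frozen
thereafter: equilibrated bilayers of this kind do not flip lipids on
analysis timescales, and freezing makes every downstream grouping
deterministic. Assignment fails loudly if a leaflet would be empty.
Which atom anchors the assignment is a genuinely open choice; the species
table makes it configurable per species.

## N-bridges and cluster graphs

A cation is *bound* to a lipid when the minimum distance over all atom
pairs lies within the cation's first-solvation-shell radius d_s — close
enough to exclude water. Defaults: 3.0 A for Na+ and K+, 2.3 A for Mg2+,
2.6 A for Ca2+, the first minima of the respective ion–water RDFs. An
ion bound to N distinct lipids is an N-bridge; stacked per-frame counts
keyed by (ion species, N, whether a PPI is involved) form the charging
curve. The default lipid scope is the inner (charged) leaflet only.

Bridges of order >= 2 are reduced to lipid–lipid edges — an order-3
bridge contributes all three pairwise edges (clique), since one shared
desolvated ion bonds each pair simultaneously; a star reduction is
available as a toggle and yields identical connected components.
1-bridges contribute no edges, so singleton "clusters" are not reported:
a cluster is by construction a set of >= 2 lipids joined through shared
ions. Components come from the standard graph library; tests verify them
against a hand-rolled union-find.

## Hydration profile

The conditional hydration profile asks: when a cation sits at minimum
distance r from a lipid, how many waters remain in its first shell?  For
every (cation, lipid, frame) pair the distance d_{c,l} is binned half-open
at resolution eps = 0.05 A, and the number of water oxygens within d_s of
that cation is recorded, giving per-bin ion counts, the integer
water-count distribution, and its mean (the per-bin average corresponds to
normalising by the ion count). The printed source formula for this
quantity is typographically garbled (sum/product markup); the
implementation follows the accompanying prose, which is unambiguous.
Waters are identified by their oxygen position only, because shell
definitions are oxygen-distance based. The minimum over *all* lipid
atoms is the default (per the distance definition "any two atoms"); a
headgroup-only toggle exists.

First-shell radii are extracted from RDFs as the first local minimum
after the first maximum of a 3-bin moving-average-smoothed g(r); a
candidate first peak must reach 20% of the global maximum, so baseline
noise below the contact distance cannot pose as a shell. Monotone
profiles raise "no first shell" rather than returning a guess.

## Hydrogen bonds and salt bridges

Hydrogen bonds use the geometric criterion: donor–acceptor distance
<= 3.4 A (inclusive) and donor–hydrogen–acceptor angle > 160 degrees
(strict), with the angle measured at the hydrogen — the standard
convention for a near-linear criterion. Donor–hydrogen pairing comes
from the species table; a donor without its bonded hydrogen is a
topology error, not a silent skip.

A salt bridge is a lipid–cation–lipid contact with one anionic heavy atom
from each of two distinct lipids within 3.4 A of the cation. The
eligible atoms are the deprotonated phosphate/carboxylate oxygens per
species; our PI(4,5)P2 is protonated at OP52, which is therefore excluded
and shows up as an empty row/column in the per-atom heat maps.  Only the
distance criterion is required (no simultaneous desolvation test), as the
definition states. The salt-bridge cutoff (3.4 A) is deliberately
distinct from the solvation-shell cutoffs used for N-bridges; a
consistency test confirms that when the shell radius is relaxed to 3.4 A,
every salt-bridging cation classifies as a bridge of order >= 2.

Heat maps are normalised per lipid; for within-species pairs each record
lands in one canonical cell (row atom first in axis order), making the map
independent of detector record orientation and exactly conservative:
total x n_lipids = record count.

## Periodic tessellation and leaflet areas

Lipid centers of mass (mass-weighted, molecules made whole by min-image
reconstruction before averaging) are projected to the xy-plane and
triangulated on the torus: the point set is tiled over the 3x3 periodic
images, qhull triangulates the tiling, and each simplex is canonically
deduplicated by translating it so its lowest-id vertex sits in the
central cell. Cocircular degeneracies (regular lattices) are broken by a
deterministic 1e-6 A jitter derived from the point index, so output is
reproducible and areas are unaffected beyond tolerance. The resulting
mesh satisfies the torus Euler relation V − E + F = 0, every point has
>= 3 neighbours, and the Voronoi dual partitions the box cross-section
exactly (tested to 1e-6 relative).

The 3D (rugged) leaflet area restores each center's COM z over the
projected mesh and sums 3D triangle areas; it is always >= the projected
area, equal for a flat leaflet, and converges to the analytic surface
integral for a sinusoidally corrugated sheet as point density grows.
Whether to lift the mesh by COM z or by a fitted surface was open; COM z
was chosen as the direct reading of "mesh between lipid centres of mass".

## Association scores

Lipid adjacency = sharing a Delaunay edge; triplets = mesh triangles.
The score of a species combination is observed count / expected count,
where the expectation averages seeded random label permutations on the
*fixed observed mesh* (default n = 1000). Permuting labels rather than
re-sampling geometry isolates compositional preference from mesh geometry
and is exactly reproducible; a closed-form label-frequency approximation
is provided for cross-checks (they agree within 2% on lattices), and a
re-sampled-geometry baseline would be a straightforward extension.
Classes with zero expectation are reported as undefined (NaN), never
infinite. Under the null, scores sit at 1.0 within the permutation band.

## Lateral diffusion

Molecule COM tracks are unwrapped by minimum-image increment
accumulation (an increment reaching half a box edge raises
"undersampled"), optionally drift-corrected by subtracting each leaflet's
per-frame COM displacement, and the xy MSD is averaged over all
overlapping time origins per molecule. D is the least-squares MSD slope
divided by 4 (2D Einstein relation), fit per molecule over lags 10–40% of
the trajectory by default — short lags are noise-dominated, long lags
statistics-starved — then averaged per species with the SD over molecules
reported as the spread. Finite periodic boxes bias lateral diffusion
low; the result carries a metadata note and no hydrodynamic correction.

## Synthetic data: what it emulates, what it does not

The generator builds the reference asymmetric composition — outer leaflet
75% POPC / 25% cholesterol, inner 50% DOPE / 25% cholesterol / 15% DOPS /
10% PPI, 400 molecules per leaflet on a regular 1 nm grid — with species
assigned by seeded shuffle, neutralising cations plus 150 mM salt
scattered in the solvent slab (>= 3 A from lipids), and the PPI net
charge configurable at −3/−4/−5 e (default −4). Mole fractions become
integer counts by the largest-remainder method with ties broken by name
order, so counts are exact and deterministic. Per-species reference
areas (POPC 64.7, DOPE 63.0, DOPS 65.3, cholesterol 40.0, PI 68.0, PIP2
70.0 A^2 — literature-style values, configurable) verify that the
leaflet nominal-area mismatch of this composition stays below 5%.

Lipids are coarse pseudo-atom sets (headgroup phosphorus and oxygens,
H-bond hydrogens, a glycerol bead, a tail bead) carrying real CHARMM36
atom names. Motion is rigid 2D Brownian translation with per-axis step
variance 2·D·dt plus optional leaflet drift. Planted structure comes
with a ledger: bridge plants place a cation at the smallest enclosing
ball of one anionic oxygen per listed lipid for exactly the requested
lifetime (parked far in the solvent otherwise) and *validate* each frame
that the classifier-visible bound set equals the plan — geometric
infeasibility is an error, never a silent approximation. Because grid
lipids at 1 nm spacing cannot host multi-lipid bridges within 2.3–3.0 A
shells, the dedicated bridge fixture arranges each planted bridge's
lipids as a tight rosette (one oxygen per lipid facing a shared site) on
well-separated sites. Hydration plants put exactly n water oxygens on a
Fibonacci-lattice shell around each ion, trying a deterministic sweep of
shell rotations to avoid steric clashes before failing. Hydrogen-bond
plants build a minimal two-molecule system at an exact distance/angle
geometry (closed-form placement).

What passing these tests shows: the detectors, graphs, tessellations and
estimators compute exactly what they claim on input whose truth is known.
What they do not show: anything about force-field fidelity, sampling
convergence, or the specific cluster sizes, occupancies and condensation
effects reported for real 500 ns all-atom trajectories — those require
the original simulations, which are not public. The generator has no
energetics, no acyl-chain detail, no correlated motions, and water only
where analyses need it (a bulk-density option exists for RDF
normalisation tests).

## Problem sizes used in the shipped tests

The test suite and the calibration script run at deliberately compact
sizes chosen to exercise every code path with exact oracles: bilayers of
36–400 molecules per leaflet, 50-bridge fixtures, tessellations of up to
~400 points, diffusion recovery at 400 molecules x 500 frames (recovered
within 10%, typically ~3%), and association nulls with 100 label draws x
1000 permutations. All are the package's own defaults for validation
runs and complete in seconds to a few minutes on one CPU.

## Known limitations

- Orthorhombic boxes only; no triclinic support.
- No bridge formation/breakage kinetics, no bond-lifetime
  autocorrelations, no area-compressibility modulus, no curvature fields.
- The permutation baseline conditions on the observed mesh; if lipid
  *positions* themselves respond strongly to composition, a
  re-sampled-geometry null would differ.
- Salt placement models a slab of implicit solvent; ionic strength is
  interpreted as the salt concentration added beyond neutralisation.
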