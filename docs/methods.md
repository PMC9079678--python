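# Methods

This note documents the models, conventions and numerical choices
behind `dynet`, and what its validation on synthetic data does and does
not establish.

## Node set and representative positions

One node per amino acid and per ligand.  Waters, ions and lipids are
excluded by residue name; hydrogens stay in the coordinate arrays (the
hydrogen-bond criterion needs them) but are never heavy atoms.  A
residue's representative position is its Cα; a ligand's is the center
of geometry of its heavy atoms, recomputed per frame.  Ligand node
position is a convention choice — nothing in the correlation definition
dictates it — and the heavy-atom center keeps one 3-vector per node
without privileging any ligand atom.

The sink ("effector region") is a configuration-level node selection,
not a structural annotation: any set of node labels can serve as the
sink, and a pathway's SPL to a region is the minimum over its members.

## Fluctuation correlation

`C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩)` with `Δr_i(t) = r_i(t) − ⟨r_i⟩`,
time averages over the analysis window.  The dot product pools the
three Cartesian components, so the effective sample count per pair is
3 × frames.  Zero-variance nodes would divide by zero; their
off-diagonal correlations are set to 0 with a warning and the diagonal
stays 1.

**Superposition.** Rigid-body fitting exists to remove global
diffusion/tumbling before measuring internal fluctuations.  The fit is
least-squares on representative positions (applied to all atoms), with
an iterated fit-to-mean reference so superposing an already-superposed
trajectory is a no-op.  For file-based input the pipeline superposes by
default.  For generator input it does not (`superpose="auto"`): the
generator produces frames in a fixed laboratory frame with no net
motion, and frame-wise fitting would *introduce* spurious correlations
by subtracting the per-frame spatial mean — a frame-wise average over
nodes — from displacements whose statistics are defined per node over
time.  The flag can be forced either way.

## Edges, lengths, and the covalent exclusion

An edge requires heavy-atom contact (minimum interatomic distance below
4.5 Å, strict) in at least 75 % of frames (inclusive ≥, so exact-boundary
fixtures behave deterministically), between nodes that are not
covalently bonded.  In a polypeptide the only inter-node covalent links
are backbone peptide bonds, so the exclusion is implemented as
chain-sequence neighbours; ligands are assumed non-covalently bound.
Edge strength is |C_ij| ∈ (0, 1]; edges with C_ij exactly 0 have no
defined length and are dropped with a warning.

**Path length transform.** Dijkstra needs additive positive lengths;
ℓ_ij = −log |C_ij| is the standard choice for correlation networks: it
maps strength 1 to length 0, is additive over serial steps
(multiplicative over correlations), and produces SPL magnitudes of a
few units for chains of moderately correlated contacts.  Any other
monotone decreasing transform would preserve single-path orderings but
not path sums; the logarithm is the one under which "total pathway
correlation" factorizes.

**Occupancy computation.** The exact criterion scans all heavy-atom
pairs per frame; a bounding-sphere prefilter (per-node centroid
trajectories plus maximal atom radius) skips pairs that can never reach
the cutoff, which keeps the scan tractable at tens of thousands of
frames.

## Replicates and the consensus network

Independent trajectories are never concatenated.  Each replicate gets
its own correlation matrix, occupancy matrix and network; pathway SPLs
are averaged over replicates (mean ± sd, n−1 weighting, sd = 0 for a
single replicate).  For community analysis and summaries a consensus
network keeps edges present in a strict majority of replicates, with
weights (and occupancies) averaged over the replicates that have the
edge and lengths recomputed from the averaged weight.  Occupancy
gating is per replicate, then voted — not pooled across replicates —
so one drifting replicate cannot manufacture or veto an edge on its
own.

## Communities

Girvan–Newman: repeatedly delete the edge with the highest betweenness,
computed on the ℓ = −log|C| lengths; over the resulting dendrogram
(including the initial connected-components partition) keep the
partition with maximal Newman modularity on the |C| weights.
Betweenness ties are broken by the lexicographically smallest node
pair, which makes the output reproducible.  Components are never
merged, and a graph with no edges partitions into singletons with
modularity 0.  "Isolated clusters" are connected components with no
edge to the component containing the largest community — cut off from
the main information flow.  Note the classic GN cost (betweenness
recomputed per deletion, O(V·E) each) is acceptable for networks of
hundreds of nodes but is the slowest stage of the pipeline.

Summary betweenness values (node and edge maxima) use networkx's
standard normalizations — 2/((n−1)(n−2)) and 2/(n(n−1)) respectively —
computed on weighted (length) shortest paths by default, with an
unweighted flag exposed.

## Pathways and transfer efficiency

Shortest paths are Dijkstra on edge lengths, to the nearest member of
the sink set.  Among exactly tied optima the lexicographically smallest
node-id sequence is returned; ties are resolved on the shortest-path
DAG with a relative tolerance of 1e-9 to absorb float round-off.  An
unreachable sink returns a flagged unreachable result, not an
exception.

Weakening a ligand deletes all edges incident to it and re-runs the
analyses; the node set is unchanged.  Because edge deletion can only
lengthen or disconnect paths, every SPL is non-decreasing under
weakening (this is asserted as a property, not assumed).

Efficiency of information transfer compares systems that share a sink
definition: `100 × Σ SPL_ref / Σ SPL_sys`, summed over the regulation
pathways of each system.  The reference scores exactly 100 %.  On the
curated M2 table this formula reproduces the published F396A value
(7.80/13.21 = 59.05 %) exactly; for Y403A it yields 56.32 % against a
published 56.41 %, consistent with the published number having been
computed from unrounded SPL intermediates.  The published single-ligand
efficiencies (42.55 % and 27.07 %) cannot be reproduced from any
combination of the tabulated SPLs under this (or any sum-ratio)
formula — those systems have one pathway each and 4.40/7.80 = 56.4 %,
6.60/7.80 = 84.6 % — so the package implements the formula validated on
the mutants and surfaces the discrepancy here rather than guessing an
undocumented variant.

Mutant systems are separate pipeline runs on their own trajectories,
not graph surgery on the wild type.

## Interaction fingerprints

Populations are fractions of frames satisfying a criterion, aggregated
per node pair (a frame counts if any qualifying atom combination
satisfies it).  Side-chain mass centers exclude backbone N/CA/C/O/OXT;
glycine falls back to Cα; ligands use all heavy atoms.  The charged set
is Asp⁻/Glu⁻/Arg⁺/Lys⁺ plus His⁺ by default (protonation-state
agnostic; His is configurable).  Hydrogen-bond donors/acceptors come
from an atom-name table; when the input has no hydrogens an ideal
hydrogen is placed 1.0 Å along the donor valence (away from the
centroid of the donor's bonded heavy neighbours) and the records are
flagged approximate.  The D–H–A angle is evaluated at the hydrogen.
The "strong interaction" report threshold is a pure population filter
(default 0.4) applied to frames pooled across replicates.

## Stability metrics

RMSD fits each frame to the reference before measuring (a no-fit mode
exists for closed-form checks).  RMSF is measured after one global
superposition to the window mean, not per-frame-pair fits.  PCA
eigen-decomposes the 3N×3N covariance of representative coordinates;
variance fractions are eigenvalue shares (clipped at 0 for round-off),
so they sum to 1 and RMSF_i² equals the trace of node i's 3×3 block.
Both analyses run at the representative-atom level to match the
residue-level networks; all-atom PCA is out of scope.

## The synthetic generator

The generator is a statistical stand-in for MD, not a force field: no
solvent, no membrane, no physical energetics.  It emulates exactly the
features the pipeline consumes — a contact geometry and a planted
displacement-correlation structure — and nothing else.

**Correlation model.** A latent factor model: one global factor
(loading √ρ_inter), one factor per block (√(ρ_intra−ρ_inter)), one
factor per cross-block pathway edge (√(ρ_path−ρ_inter)), plus
independent residuals scaled so every node has unit variance.  The
implied correlation matrix is exactly ρ_intra within blocks, ρ_inter
across, ρ_path on cross-block pathway edges, and is positive
semi-definite by construction whenever the loadings are feasible
(infeasible parameter combinations are rejected at validation; a
non-PSD explicitly-supplied matrix would be eigenvalue-clipped with a
warning).  Feasibility bounds ρ_path ≤ (1 − ρ_intra + 2ρ_inter)/2 for a
node carrying two pathway edges — hence the default ρ_path = 0.12 under
the 0.8/0.05 block levels, chosen once as the strongest feasible
cross-block coupling with a safety margin.  Displacements are isotropic
(the same correlation structure on x, y, z independently) with per-axis
amplitude 0.3 Å; each node's three beads translate rigidly with it.

**Geometry.** Each block occupies its own chain: a ring of beads (ring
chord 3.8 Å) plus entry/exit relay beads anchored 4.0 Å outside the
135°/45° ring faces; blocks are strung along x with the exit relay of
one block in direct contact (3.8 Å) with the entry relay of the next.
The planted pathway runs ligand → ring short arc → exit relay → next
entry relay → … → sink, so consecutive pathway nodes are always in
contact.  One weak decoy bridge per adjacent block pair — closed
through satellite beads aimed at each other, correlated only at the
background level — gives the shortest-path search a genuine wrong
alternative (a decoy crossing costs −log 0.05 ≈ 3.0 per bridge versus
−log 0.12 ≈ 2.1 for a pathway crossing, so the planted chain is the
unique optimum by a margin).  Ring positions hold the chain sequence in
a strided order, so geometrically adjacent ring beads are never
peptide-bonded and ring edges survive the covalent exclusion; blocks on
separate chains keep cross-block pathway steps non-covalent.  Every
built geometry is verified numerically: planted contacts ≤ 4.1 Å,
all other node pairs ≥ 4.9 Å, no two atoms within 1.5 Å.  With
amplitude 0.3 Å these margins put planted-contact occupancies near 1
and non-contact occupancies near 0, far from the 0.75 gate on both
sides.

**Determinism.** All replicate streams spawn from the single spec seed
(`numpy.random.SeedSequence`); equal specs give bit-identical
trajectories.

**Reference study conditions.** 40 nodes in 4 equal blocks,
ρ_intra = 0.8, ρ_inter = 0.05, ρ_path = 0.12, 25 000 frames × 5
replicates, amplitude 0.3 Å.  At these sizes the sampling error of a
correlation entry is ≈ (1−ρ²)/√(3T) ≤ 0.004, so the observed maximal
deviation from the planted matrix (≈ 0.012 across all pairs and
replicates) is consistent with pure sampling noise and sits well inside
the 0.03 recovery tolerance asserted in the acceptance suite.

**What passing on synthetic data shows — and does not.** Recovery of
the planted blocks, contacts and pathway establishes that the pipeline
measures what it claims on data whose generative process matches its
assumptions (stationary Gaussian fluctuations, rigid nodes, fixed
contact topology).  Real trajectories violate all three — anharmonic
and non-stationary dynamics, side-chain rearrangements, contacts that
form and break — so success here validates the *software*, not the
biological conclusions one might draw from any particular receptor
system.

## Problem sizes

The shipped validation runs at the reference study conditions above
(the full-scale recovery takes about a minute on one CPU); unit tests
use the same structure at 1 500 frames × 3 replicates.  The oracle
comparisons use 200 random graphs of ≤ 8 nodes (exhaustive simple-path
enumeration) and 50 block-network fixtures for the perturbation
monotonicity sweep; betweenness is cross-checked against an independent
scipy shortest-path implementation on graphs of ≤ 20 nodes.

## Known limitations

* Girvan–Newman is quadratic-ish in edges per deletion; networks beyond
  a few thousand edges need a faster community method (out of scope).
* The linear (Pearson-type) correlation misses anti-phase and
  non-linear coupling; no mutual-information generalization is
  provided.
* Ideal-hydrogen placement for donors is geometric, not chemical; with
  explicit hydrogens in the input it is bypassed.
* PDB round trips quantize coordinates to 3 decimals (±0.0005 Å);
  networks built from written-then-reread fixtures can in principle
  differ at exact-threshold boundaries, which the generator's margins
  are wide enough to absorb.
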