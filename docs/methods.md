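# Methods

## Scope and data model

`allodyn` analyses multi-replica coordinate ensembles of one protein in
several ligand states. Everything internal is in ångström; trajectory
formats that store nm (XTC/TRR) are converted on read, and a
`unit_hint="nm"` flag covers nonstandard PDB files written in nm. All
output axes carry author (PDB) residue numbers, never array offsets, so
profiles and matrices read directly against the structure. Frames are
used exactly as provided — any stride is the producer's choice and is
only recorded as metadata; persistence fractions and time averages are
therefore defined over the frames given.

## Superposition and essential-dynamics filtering

Each replica is rigid-body superposed (Kabsch least squares) on the Cα
atoms of its own first frame — the starting conformation — with the
option of supplying any other reference. PCA is done on the Cartesian
Cα coordinates about their time mean with population (1/T)
normalisation, so the eigenvalue sum equals the total variance exactly.
Filtering reconstructs each frame from the first *k* components
(default 10, applied per run, not to concatenated runs); *k* = 3N is
the identity. Degenerate eigenvalue ties are resolved by a sign
convention (largest-magnitude component positive) so outputs are
bit-reproducible.

The distance-fluctuation matrix is computed on the filtered ensemble by
default (a flag switches to raw aligned coordinates). Because internal
distances are superposition-invariant, any ensemble of rigid-body
images of one structure gives A ≡ 0; this null is enforced in the
tests.

## Distance fluctuations and rigidity maps

A_ij is the variance of the scalar Cα–Cα distance over frames (Å²). A
mean-absolute-deviation variant (units Å) is available behind
`mode="mean_abs"` for robustness checks but is not the default, since
the 0.3/0.4/2 Å² thresholds used throughout are variances. Replica
averaging is element-wise; the rigidity map is 1 where A < 0.3 Å²
(diagonal 1 by convention) and thresholding is strictly monotone.

Semi-rigid block structure is summarised by average-linkage
agglomerative clustering on A as a dissimilarity, cut at a requested
number of groups (default 4, after the four nucleotide-binding-domain
subdomains of Hsp70; the method itself is a free choice — the source
analyses eyeball the block character of the map, and average linkage
was picked for determinism and interpretability). Intra- and
inter-group mean fluctuations are reported so the block character is
quantified, not just asserted.

## Geometric strain and mobility

The strain of residue i in frame t is the weighted mean of squared
deviations of its inter-residue distances from their time averages.
The neighbour switch is logistic, f(d) = 1/(1 + exp((d − d0)/w)) with
d0 = 7 Å and w = 0.5 Å: the cutoff distance is stated in the method's
description, the functional form and steepness are not, so both are
exposed as parameters. Weights are evaluated on the *time-mean*
distances, fixing each residue's neighbour set over a run (using
instantaneous distances would make the neighbourhood itself
fluctuate). The weighted-*mean* normalisation makes per-residue values
comparable to the 0.4/2 Å² flexibility bands regardless of packing
density; the raw weighted sum is available behind a flag and differs
only by the per-residue weight total.

Mobility is the per-run time average, summarised across replicas by
mean and standard error of the mean; with a single run the SE is
reported as NaN ("undefined"). State differences Δ = m_a − m_b carry
the propagated error √(SE_a² + SE_b²), and residues with |Δ| ≤ k·error
(k = 1 by default, i.e. "within statistical error") are zeroed in the
reported histogram; surviving peaks are ranked by |Δ|. Flexibility
classes use strict inequalities: < 0.4 Å² rigid, > 2 Å² flexible,
boundaries intermediate.

## Hydrogen-bond networks

A bond is present in a frame when donor–acceptor ≤ 3.5 Å and the
H–donor–acceptor angle ≤ 30° (both configurable); topologies without
hydrogens (Cα-level synthetic fixtures) use the distance criterion
alone. Donor/acceptor flags derive from atom and residue names; bonds
within a residue or between immediate sequence neighbours are excluded
as trivially guaranteed. Persistence is pooled over a state's
replicas — total present frames over total frames — which is the
stricter of the two readings of "30% of the whole simulation time over
three trajectories"; per-replica fractions are reported on every edge
for comparison with per-run tables. Residue-level edges take the
maximum over atom-level bonds.

Propagation is breadth-first from the ligand: level k+1 collects
residues bonded at ≥ 30% persistence to any level-k residue and not
yet included; growth over a finite residue set guarantees termination,
and raising the threshold can only shrink the node set (both are
property-tested). After growth, every qualifying edge among included
nodes is reported, and the graph records whether and at what depth the
target segment (e.g. the interdomain linker) was reached.

## GROMOS clustering and RMSD maps

Snapshot-to-snapshot RMSD uses per-pair Kabsch superposition on the
fit selection (identical to the RMSD selection unless overridden).
Clustering is the classic neighbour-count scheme: the unassigned frame
with the most neighbours within the cutoff seeds a cluster and removes
them; ties on the neighbour count go to the earliest frame index (the
original method leaves this open; the choice is recorded in output
metadata and makes partitions bit-reproducible). Default cutoffs are
5 Å for whole-domain clustering and 2 Å for the binding-site variant
restricted to the Cα atoms of a residue-range list such as
`2-15;160-225;360-390`. Cross-maps accept trajectories of different
lengths.

## Synthetic ensembles

The generator stands in for MD with exact, seedable Gaussian sampling
whose covariance is known in closed form — precisely the property the
validation needs. The toy protein is a chain of helical blocks
(consecutive Cα spacing 3.8 Å) joined by hinge residues, with the
chain direction turning at each hinge; construction fails if
non-adjacent residues come closer than 3.5 Å.

Two covariance models are provided:

* **`enm`** (default): the pseudo-inverse of an anisotropic-network
  Hessian. Intra-block pairs get the stiff spring at all ranges (a
  fully triangulated, genuinely quasi-rigid domain); cross-block and
  hinge contacts within 8 Å get the soft spring; all remaining pairs
  get a weak background spring. The background term is required: with
  a one-residue hinge a pure contact network leaves an exact torsional
  zero mode and the Gaussian is undefined. Defaults (block 5.0, hinge
  0.02, background 0.02 kT/Å², temperature 1) put hinge mobility far
  above block mobility and were fixed once for the study design.
  Six rigid-body modes are removed; a seventh near-zero mode is
  reported as a disconnected structure.
* **`rigid_blocks`**: independent isotropic translation per block plus
  per-atom jitter (hinge residues take the mean of their neighbour
  blocks). This model exists because a pairwise-spring network cannot
  place all inter-block pair-distance variances at one level — its
  softest modes are rotation-like, so near-pivot pairs fluctuate an
  order of magnitude less than distal ones, and no spring choice puts
  every intra-block pair below 0.3 Å² and every inter-block pair above
  it. The rigid-blocks covariance realises the planted levels exactly:
  jitter 0.025 Å² per coordinate gives intra-block distance variance
  2s² = 0.05 Å², relative translation variance 0.95 Å² gives
  inter-block variance 1.0 Å², cleanly straddling the 0.3 Å²
  threshold. It is still an exact multivariate Gaussian with an
  analytic covariance, sampled with the same seeding scheme.

State dependence enters as per-block and per-hinge stiffness
multipliers (variances divide by the multiplier), emulating
ligand-induced rigidification across an apo/ATP/ADP-like design of
states × replicas, each with a child seed derived from one base seed;
regeneration is bit-identical.

Planted donor–acceptor chains are geometric, not energetic: each bond
is an independent per-frame Bernoulli draw at its occupancy, and the
bond geometry is realised on a detached rail lattice well outside the
structure (donor slots 8 Å apart; an ON acceptor 2.9 Å from its
partner slot; OFF and bystander acceptors parked 10 Å above). This
makes planted contacts the only contacts the detection geometry can
see — on-structure placements were found to produce incidental ≥ 30%
contacts near the hinge that corrupt exact chain recovery. The rail
positions carry no signal beyond bond presence; the construction is
synthetic by design and labelled as such.

What the generator does **not** emulate: anharmonicity, solvent
friction and kinetics, sequence-specific packing, side-chain
chemistry, or correlated bond networks. Passing tests therefore
demonstrate that each statistic measures what it claims on data with
known structure — not that real MD data will show any particular
biology.

## Numerical and validation choices

* Population-normalised covariances throughout; oracles in the tests
  use the same convention.
* Brute-force re-implementations (double/triple loops, set-based
  clustering, Euler-grid superposition) act as independent oracles at
  10 residues × 20–50 frames, agreeing to 1e-9.
* Sampling consistency is checked as the RMS relative deviation of
  empirical per-coordinate variances from the model covariance
  diagonal at 5000 frames (the per-coordinate noise floor is
  √(2/n) ≈ 2%, so a maximum-over-coordinates check would reject a
  correct sampler).
* Validation problem sizes (41-residue toys, 120–500 frames, 50 seeds
  for recovery rates) were chosen as the smallest designs at which the
  planted effects are statistically unambiguous.
* Single-replica mobility has no SE; the significance filter then
  treats the error as zero and warns, retaining every difference.
* Isolated residues (total neighbour weight < 1e-12) get strain 0 with
  a warning rather than a 0/0.

## Known limitations

* PDB text carries three decimals, so PDB round-trips are exact only
  to 1e-3 Å; the tab-delimited matrix/profile formats round-trip to
  1e-6.
* The H-bond acceptor rules are name-based and deliberately simple
  (any O; common unprotonated ring nitrogens); exotic chemistry needs
  explicit flags.
* `pairwise_rmsd` is O(frames²) with a Python pair loop — fine for the
  intended hundreds of frames per state, not for tens of thousands.
* Network propagation computes all-against-all donor/acceptor
  distances per frame; very large systems would need a spatial
  prefilter.
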