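# Methods

## Scope and model overview

`gnome` couples two models:

1. **Conformation inference.** A diploid genome is represented as chains
   of spherical beads, one bead per topologically associated domain
   (TAD). A Markov-chain Monte Carlo polymer solver arranges the chains
   inside a spherical or ellipsoidal nucleus so that Hi-C-derived
   contact constraints are satisfied, beads stay encapsulated,
   lamina-associated (LAD) beads sit near the periphery, and beads do
   not overlap.
2. **Radiation damage.** Energy depositions — from the photon model or
   from an LET-parameterised straight-track surrogate — are converted
   into backbone strand breaks inside beads, and breaks are clustered
   into double- and single-strand-break (DSB/SSB) damage sites whose
   spatial statistics can then be compared across conformations.

All internal lengths are micrometres; genomic intervals are 0-based
half-open base-pair coordinates; homologous chromosome copies carry an
`_A`/`_B` label suffix.

## Bead model and inputs

Input genomes are Chrom3D-dialect gtrack files (tab-separated: seqid,
start, end, id, optional radius, periphery flag, `;`-joined contact
edges; `:weight` suffixes on edges are read and ignored). Edges are
symmetrized and validated on load. When the radius column is absent,
bead radii follow from the occupancy condition

    sum_i (4/3) pi r_i^3 = occupancy * V_nucleus,   r_i^3 proportional to bp_i,

with occupancy 0.15 by default. The synthetic generator emulates a
normal diploid human genome: 6 Gbp over 23 chromosome pairs with sizes
in human proportions, TAD beads drawn uniformly from 1–3 Mbp, contact
edges mostly intra-chromosomal with geometrically distributed genomic
offsets (mean edge count per bead = `contact_density`, default 1), and a
periphery (LAD) flag per bead with probability 0.3 — roughly the
genome fraction covered by LADs in mammalian cells. Homolog copies get
independent edges.

## Solver

The objective is a sum of hinge losses, each zero exactly when its
constraint is satisfied (the functional forms are this package's
choice; only the boundary term's zero-inside behaviour is externally
prescribed):

- contact: `max(0, d_ab - (r_a + r_b))` per constrained pair;
- boundary (active under `--ConstrainNucleus`): euclidean distance
  outside the nucleus, 0 inside. For ellipsoids the scaled-radial
  approximation `|p| (1 - 1/t)` with `t` the normalised radius is used
  (the true point-ellipsoid distance has no closed form; the
  approximation is exact for spheres and on the axes);
- LAD: `max(0, 0.8 - t) * (abc)^(1/3)` for periphery-flagged beads —
  flagged beads are pushed out of the inner 80 %-radius shell;
- overlap: `max(0, (r_i + r_j) - d_ij)` over all bead pairs.

Weights default to 1 and are configurable. Five move types are drawn
uniformly by default: crankshaft (rotation of an interior segment about
the axis through two fixed pivot beads, angle uniform on [0, 2pi)), arm
rotation (rigid rotation of one arm about a pivot bead), arm wiggle
(regrowth of an arm as a touching-bead random walk kept inside the
nucleus), whole-chromosome translation (components uniform on [-1, 1]
um — the symmetric version of a 1 um bound, so the proposal is
reversible) and whole-chromosome rotation (axis uniform on the sphere).
Acceptance is greedy (strict improvement), Metropolis
(`exp(-delta/T)`), or simulated annealing with geometric cooling per
accepted move. Iterations are counted as *accepted* moves (default
budget 2,000,000), with an attempt cap of 50x the budget to guarantee
termination. Cost updates use an incremental per-move delta (O(k n) in
the k moved beads), accelerated with a numba kernel when available and
verified in the tests against full re-evaluation.

The default annealing cooling factor 0.999995 gives ~e^-10 of the
initial temperature over the 2-million-acceptance budget; scaled-down
runs in the test suite use the same e^-10 rule (e.g. 0.9998 for a
50,000-acceptance budget).

## Geometry statistics

Clustering metrics count, for every object (bead centre or DSB
centroid), the objects within a cluster radius (inclusive,
centre-to-centre). Pairs on homologous copies of one chromosome are
excluded from both the inter- and intra-chromosomal counts and reported
separately, so total = inter + intra + homolog is auditable. The
3D Ripley statistic is

    K(CR) = V_nuc / n^2 * sum_i sum_{j != i} I[D(i,j) <= CR] / V_s(i),

with `V_s(i)` the fraction of the CR-sphere around point i inside the
nucleus (analytic sphere–sphere lens volume for spherical nuclei,
seeded Monte Carlo for ellipsoids). The normalised statistic
`K / ((4/3) pi CR^3) - 1` has expectation -1/n (≈ 0) under complete
spatial randomness; reference values are means over geometry ensembles.
Radial positioning scores a bead central when its centre lies inside
the axis-scaled copy of the nucleus holding half the volume (scale
2^(-1/3)), with bp-weighted 10 Mbp bins; chord adjacency reports
chromosome pairs with interchromosomal beads strictly closer than
500 nm in at least a threshold fraction (default 40 %) of an ensemble;
the proximity score is the mean centre-to-centre distance of
contact-constrained bead pairs (per-bead mean, then averaged over
constrained beads), ignoring boundary and LAD terms.

## Damage model

Deposits inside beads become strand breaks after two independent
draws: a Bernoulli(0.141) sensitive-fraction draw (the backbone
fraction of bead volume, implemented i.i.d. per deposit — statistically
equivalent at bead level to a fixed sensitive sub-volume and
geometry-free) and a linear energy ramp, 0 below 5 eV to 1 above
37.5 eV. Breaks get a uniform strand (1 or 2) and a uniform bp position
within the bead's interval, and keep the deposit's 3D position.

Breaks on one chromosome are linked transitively when separated by at
most 10 bp genomically **or** 3.2 nm spatially — the two statements of
the same criterion at 0.32 nm/bp; both are applied because bp positions
within Mbp-scale beads carry no sub-bead spatial information, while
deposit positions do. A linked cluster containing both strands is one
DSB with complexity = backbone count; every other break is one SSB.
Duplicate breaks at identical (chromosome, strand, bp) are merged
(keeping the spatially smallest position, making the output independent
of input order). Photon exposures bypass track structure entirely:
N ~ Poisson(25 x dose) DSB sites are placed on chromosomes with
probability proportional to bp, beads within chromosomes proportional
to bp, uniformly inside the bead sphere; photon sites are emitted with
complexity 2 and never re-clustered, so photon yields are independent
of nucleus shape by construction.

Damage sites are written in a minimal Standard DNA Damage (SDD)
dialect: `key, value;` header lines ending with `***EndOfHeader***;`,
then one record per site with five `;`-delimited groups —
classification; centroid x,y,z (um); chromosome id; bp position
(smallest bp of the site's breaks); backbone count.

## Track surrogate

Ion exposures use a parameterised amorphous-track generator, not a
transport code: its contract is an LET-correct energy budget and
spatially concentrated deposition. Each primary is a straight chord
(entry uniform over the projected disc; parallel beam by default,
isotropic optional). The track count for a dose is
`round(dose * mass / (LET * <chord> * 1.602e-16 J/keV))` with
`<chord> = 4V/S` and the nucleus taken as liquid water at 1.0 g/cm^3.
Deposits arrive in nm-scale ionization clusters: cluster centres are
uniform along the chord with Gaussian lateral jitter (sigma 5 nm),
cluster multiplicity is 1 + Poisson with mean 1 + 0.05 * LET (the
nanodosimetric shift of ionization cluster size with stopping power —
the mechanism by which higher LET concentrates damage), within-cluster
spread is 1.5 nm, and deposit energies are exponential with mean 60 eV
(a typical ionization-scale energy). The expected energy per track is
LET x chord regardless of clustering, and the realised dose of a
planned exposure reproduces the requested dose to within a few percent
(tested). Absolute ion yields are indicative only; the surrogate is
built to reproduce *trends*: DSB/Gy rising and SSB/Gy falling with LET,
growing DSB complexity, and damage localisation (higher
intra-chromosomal DSB clustering, lower inter/intra ratio) at high LET.

## Ensemble comparison

Per-geometry metric distributions are compared between groups with the
two-sided two-sample Kolmogorov–Smirnov test (asymptotic p-values,
appropriate at the 200-geometries-per-group design) at every
(LET, cluster-radius) grid cell; Benjamini–Hochberg adjustment spans
all cells of one comparison pair. Cells carry the mean difference and a
significance class: red p > 0.05, purple 0.01 < p <= 0.05, yellow
0.001 < p <= 0.01, green p <= 0.001.

## Problem sizes used in the tests

The full-scale study design (200 geometries per group, 2 million
accepted moves per solve, 50 exposures per geometry) is the package's
default configuration; the test suite exercises the same code paths at
reduced sizes chosen to keep each suite to minutes on one CPU:

- solver properties: a 206-bead diploid fixture (8 chromosomes,
  400 Mbp), 50,000 accepted annealed moves from a pseudo-random start;
- LET trends: the default 6 Gbp genome in a 5 um sphere, 10 log-spaced
  LET values in 5–100 keV/um, 20 exposures of 20 Gy each, yields
  normalised by each exposure's realised dose (20 Gy per exposure makes
  the break-budget noise small against the SSB-absorption signal);
- CSR Ripley-K: 20 pseudo-random geometries of 5,000 beads each
  (ensemble means, matching how the reference curve is defined);
- null calibration of the KS test: 1,000 replicate pairs of n = 200.

## What the synthetic data does and does not show

The synthetic genome reproduces the bookkeeping of real gtrack inputs
(sizes, diploidy, TAD segmentation, contact sparsity, LAD fractions)
but its contact edges are random rather than derived from measured
contact maps, so solved synthetic geometries exhibit generic polymer
territory structure, not cell-type-specific organisation. Passing tests
therefore demonstrate that the machinery — optimisation, damage
conversion, statistics — behaves correctly and reproduces the model's
printed parameters and trends, not that any particular biological
contact map is recovered. The track surrogate likewise stands in for
transport-code physics: it preserves dose/LET bookkeeping and damage
concentration, but not particle-specific deposit spectra, so absolute
ion damage yields are out of numeric scope.

## Numerical choices and degenerate inputs

- Initial conformations are touching-bead random walks with <= 1000
  placement retries per bead and 100 chain restarts before a placement
  error; overlap with non-adjacent beads is tolerated at initialisation
  and penalised by the solver.
- The incremental solver delta and the full objective agree to ~1e-9
  per move (tested); the final cost is always re-evaluated from
  scratch.
- Cluster membership is inclusive (<= radius); chord proximity is
  strict (< 500 nm).
- Ratio metrics (inter/intra, proximity score with no constraints,
  backbones per DSB with no DSBs) return flagged-undefined values, not
  exceptions.
- Degenerate moves (crankshaft on < 3 beads, arms of length 0) are
  resampled; coincident crankshaft pivots fall back to a random axis.
- `edge_correction_vs` raises for centres outside the nucleus; centres
  on the boundary are valid (lens fraction 1/2 - (3/16) CR/R).
- KS p-values are capped at 1; BH adjustment is the standard step-up
  with cumulative-minimum monotonicity.

## Known limitations

- The ellipsoid boundary cost uses the scaled-radial distance
  approximation; it underestimates the true distance off-axis.
- The LAD shell term uses a fixed 80 % shell fraction rather than a
  measured lamina contact probability.
- Break clustering treats the genomic and spatial windows as one
  criterion; models with sub-bead DNA geometry would resolve the two.
- The photon model places whole DSBs directly and therefore carries no
  SSB yield or complexity distribution for photons.
- The track surrogate's lateral and cluster parameters are effective
  constants, not particle- or energy-specific physics.
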