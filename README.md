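# gnome

**Hi-C-constrained 3D genome conformations coupled to radiation-induced
DNA damage simulation.**

Chromosomal intermingling — how much the territories of different
chromosomes overlap in the nucleus — is a key driver of radiation-induced
mis-repair and chromosome aberration. `gnome` is a Python library and
command-line tool for researchers in radiation biophysics and genome
organisation who want to quantify that link *in silico*: it infers
ensembles of 3D genome conformations from Hi-C-derived contact
constraints, irradiates them with photons or LET-parameterised ion
tracks, and measures where the resulting DNA damage falls.

## The model

**Conformation inference.** The genome is a set of chromosome chains of
spherical beads, one bead per topologically associated domain (TAD),
read from Chrom3D-dialect gtrack files (or synthesized). Bead radii
satisfy Σ (4/3)πr³ = 0.15 · V_nucleus with r³ ∝ bp. A Markov-chain
Monte Carlo polymer solver minimises a sum of hinge objectives —
contact gaps max(0, d − (r_a + r_b)), distance outside the nuclear
boundary (the `--ConstrainNucleus` flag), lamina-association of flagged
beads, bead overlap — via five move types (crankshaft, arm rotation,
arm wiggle, chromosome translation ≤ 1 µm, chromosome rotation) under
greedy, Metropolis–Hastings (exp(−ΔC/T)) or simulated-annealing
acceptance, counting iterations as accepted moves (default budget
2 × 10⁶).

**Damage simulation.** Energy deposits inside beads become backbone
strand breaks after a 14.1 % sensitive-fraction draw and a linear
energy ramp (p = 0 at 5 eV to 1 at 37.5 eV). Breaks on one chromosome
within 10 bp / 3.2 nm cluster into damage sites: a cluster spanning
both strands is a double-strand break (DSB) with complexity equal to
its backbone count, anything else is a single-strand break (SSB).
Photon exposures draw DSBs directly, Poisson with mean 25 DSB/Gy,
placed ∝ bp. Ion exposures use a straight-track surrogate whose
contract is an LET-correct energy budget (n tracks =
dose·mass / (LET·⟨4V/S⟩·1.602×10⁻¹⁶ J/keV)) with nm-scale ionization
clustering. Damage is written in a minimal Standard DNA Damage (SDD)
dialect.

**Statistics.** Inter-/intra-chromosomal clustering (homolog pairs
excluded from both), the edge-corrected 3D Ripley statistic
K(CR) = V_nuc Σᵢ Σ_{j≠i} I[D(i,j) ≤ CR]/V_s / n² with the analytic
lens-volume correction, radial positioning against the half-volume
shell, 500 nm chord adjacency across ensembles, the contact proximity
score, and two-sided Kolmogorov–Smirnov comparisons with
Benjamini–Hochberg correction over LET × cluster-radius grids.

## Worked example

Synthesize a small genome, solve a conformation, irradiate it, and
analyse the geometry:

```bash
gnome synth --total-bp 200000000 --tad-bp-min 1000000 --tad-bp-max 3000000 \
      --seed 1 --out demo.gtrack
# -> wrote 94 beads to demo.gtrack

gnome solve --gtrack demo.gtrack --radius-um 5 --iterations 20000 \
      --scheme anneal --seed 1 --ConstrainNucleus --out demo
# -> accepted 20000/27577 moves; cost 178.8621 -> 86.0520

gnome irradiate --coords demo.coords.tsv --mode photon --dose-gy 1 --seed 2 --out photon.sdd
# -> DSB/Gy=21.00 SSB/Gy=0.00
# -> wrote 21 damage sites to photon.sdd

gnome irradiate --coords demo.coords.tsv --mode tracks --let 30 --dose-gy 1 --seed 3 --out ion.sdd
# -> DSB/Gy=11.00 SSB/Gy=505.00
# -> wrote 516 damage sites to ion.sdd

gnome analyze --coords demo.coords.tsv --radii-nm 500 --out report.tsv
```

Reading the numbers: the solver reduced the total objective from 178.9
to 86.1 µm of summed hinge violations over 20,000 accepted moves. The
1 Gy photon exposure drew 21 DSBs — one Poisson(25) sample; photons
produce no SSBs in this model because whole DSBs are placed directly.
The 30 keV/µm ion exposure converted its track deposits into 505 SSBs
and 11 DSBs per Gy — sparser LET gives fewer, less complex DSBs. The
analysis report contains one tidy row per metric: e.g. a proximity
score of 2.23 µm (mean distance between contact-constrained bead
pairs; lower is better optimised) and a normalised Ripley-K of −0.77 at
500 nm for this 94-bead chain geometry (negative: beads are more
dispersed than a random point cloud at that radius, as chains with
excluded volume must be).

`gnome solve` also writes a Chimera marker file (`demo.cmm`) for 3D
rendering and a cost trace TSV; `gnome run --config cfg.yaml --out dir`
drives the whole pipeline (ensembles of geometries × exposures, with a
manifest of seeds and output hashes); `gnome compare` builds the
KS + BH significance grid between two metric ensembles.

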