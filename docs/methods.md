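# Methods

This note records the model as implemented, the parameter choices and
their rationale, the numerical conventions, and the known limitations.

## 1. Genome and genetic code

A genome is a vector of `L = 18,000` bases over the alphabet {0,1,2,3},
read in a fixed, non-overlapping triplet frame starting at base 0 (no
frame shifts).  Codon `(a,b,c)` indexes the 64-entry code table at
`16a + 4b + c`.

Role categories: `START`, `STOP`, `PART`, `FEATURE`, `MAGNITUDE`.  Genes
are maximal runs from a `START` codon to the next `STOP` codon;
`START` codons inside an open gene are ordinary (ignored) codons, and a
trailing `START` with no `STOP` forms no gene.  Within a gene, only the
**first** `PART` codon is expressed; later `PART` codons are inert
surplus, and all `FEATURE`/`MAGNITUDE` codons in the gene regulate the
expressed part.  A gene with no `PART` codon is regulatory-only and
contributes nothing by itself.

Fixed codon assignments in the default table:

| codon | role |
|---|---|
| (0,0,0), (0,0,1) | PART: segment |
| (1,0,0) | PART: sensor |
| (2,0,0) | PART: joint |
| (3,0,0) | FEATURE: motorize joint |
| (1,1,0) / (1,2,0) | FEATURE: sphere sensor, x / z axis |
| (1,3,0) | FEATURE: wire may connect any endpoint classes |
| (1,0,1..3) | FEATURE: sensor output channel 1/2/3 |

Choices made where the assignment was otherwise open: neuron `(0,1,0)`,
wire `(0,2,0)`, `START = (3,3,3)`, `STOP = (3,3,2)`; 12 `MAGNITUDE`
codons in three attribute families of four levels each — `(0,3,c)` size,
`(2,3,c)` mounts, `(3,2,c)` connectors, level `c+1`; the remaining
codons are `FEATURE` with kind `generic` (inert), giving 44 `FEATURE`
codons in total (the table requires more than half the code to be
`FEATURE`).  The table is shipped as JSON
(`src/ecesim/data/default_code_table.json`) and validated on load;
alternative codes can be supplied as JSON files.

## 2. Stochastic operators

Both mutation (rate μ, germline, heritable) and transcription error
(rate τ, per development, non-heritable) use the same per-base operator:
each base is hit independently with the given probability and, if hit,
replaced by one of the three *other* bases uniformly.  The expected
number of changes per genome is exactly `rate × L` (90 at μ = 0.005,
L = 18,000); a hit never silently restores the original base.

Transcription applies τ to gene bodies only; a `START` or `STOP`
arising from an error truncates nothing retroactively but can change a
codon's role, including producing a null (non-expressing) transcript.

## 3. Development

**Early development.** Each transcript yields a part with default
attributes (`DevelopmentConfig`): segment radius 1.0 with 2 joint
mounts and 2 accessory mounts; neurons with 2 connectors; sensors with
1 output; wires of class `direct` (sensor→joint only) unless the
any-class feature fires.  `MAGNITUDE` size codons add
`radius_increment = 0.25` per level; mount and connector magnitudes add
their level.  A regulator whose kind does not match the part kind is
inert.

**Late development, mechanical.** Assembly is elongation with
branching: the active segment chain extends segment by segment; a joint
is placed at the first open joint mount, scanning segments in
connection order, and consumes one joint mount on **both** the parent
and the child segment (a joint occupies a mount on each body it
connects — this symmetric choice is what bounds branching by the mount
budget).  Assembly stops when segments, joints, or open mounts are
exhausted; segments with zero joint mounts cannot be attached and are
skipped.  The result is always a tree, hence the invariant
`joints = segments − 1` for any non-empty body, verified over 10³
random genomes in the acceptance run.

**Late development, sensorimotor.** Neurons are mounted before sensors
on accessory mounts (`neurons_before_sensors = True`), then wires are
laid by trying endpoint classes in the order sensor→joint,
sensor→neuron, neuron→neuron, neuron→joint, subject to budgets: each
sensor offers one output, each motorized joint accepts one input, each
neuron spends from its connector budget.  `direct`-class wires may only
form sensor→joint links.

**Viability.** ≥ 2 segments, ≥ 1 joint, ≥ 1 sensor, and a sensor must
reach a motorized joint through the wire graph (breadth-first search;
neuron–neuron wires are traversed in both directions).  Non-viable
bodies score zero fitness.

## 4. Behavior backends

Fitness is absolute displacement over `time_steps = 501` trial steps.

The default **surrogate** backend computes
`(steps/501) · (1.0·min(driven_joints, 8) + 0.25·min(segments, 12) + jitter)`
where `driven_joints` counts motorized joints reached by a sensor
circuit and `jitter` is a deterministic hash of the body plan scaled by
0.05.  It preserves the properties analyses rely on — referential
transparency, strict monotonicity in circuits and segments below
saturation, and distinct scores for distinct body plans — but does not
emulate dynamics: no gait, balance, interference between limbs, or
diminishing returns other than the hard saturations.  Results obtained
with it characterize the evolutionary machinery, not locomotion per se.

The **physics** backend drives the same interface through `pybullet`
(optional extra); it imports lazily and raises a clear `RuntimeError`
when the dependency is absent, so the core package has no physics
requirement.

## 5. Evolution and experimental design

Populations are non-overlapping: all parents die each generation.
Selection is truncation to the top half by fitness, with stable-index
tie-breaking (`argsort` on negated fitness, stable kind) so equal
fitness favors the lower index deterministically.  Offspring counts
follow rank bands 4/3/2/1; at the canonical population size 60 the
bands are ranks 1–3, 4–9, 10–18, 19–30.  For other even sizes,
`ReproductionSchedule.for_size(n)` solves the integer program
`a+b+c+d = n/2`, `3a+2b+c = n/2` minimizing L1 deviation from band
fractions (0.05, 0.10, 0.15, 0.20)·n; it recovers (3, 6, 9, 12) at
n = 60.  Generation 0 consists of the developed founders (τ applied, no
mutation).

The full factorial design: μ, τ ∈ {0, 0.0005, …, 0.0050} (11 levels
each, 121 conditions), 9 independent founder populations per condition
(1,089 cells), population size 60, 100 generations — 6,534,000 possible
individuals.  Sweeps are resumable: each cell writes one CSV and a
manifest records completion and the seed spawn key.

**Seeding.** All randomness derives from one `numpy` `SeedSequence`:
the sweep spawns one child per cell, and each cell's run spawns one
child per generation, so any cell or generation is reproducible in
isolation and results are byte-identical across re-runs and resume.

## 6. Population metrics

- **Complexity**: mechanical = segment count; sensorimotor = sensors +
  neurons + wires; total = their sum.
- **Genetic variance**: sum of pairwise Hamming distances over the
  population, computed per locus from base counts
  (`L·C(n,2) − Σ_b C(count_b, 2)` summed over loci), O(4L) rather than
  O(n²L).  For uniform-random genomes its expectation is
  `0.75·L·C(n,2)`; the acceptance run measures the ratio (1.00005 at
  seed 1).
- **Phenotypic variance**: median absolute deviation, unscaled by
  default; multiply by `MAD_NORMAL_CONSISTENCY = 1.4826` for the
  normal-consistent estimator.
- **Selection gradients**: per group (founder, μ, τ, generation), OLS
  fit of `fitness = A + B₁·mechanical + B₂·sensorimotor` via
  `numpy.linalg.lstsq`; a record is flagged not-ok when n < 3 or the
  design matrix is rank-deficient (e.g. a complexity measure constant
  within the group), and flagged records carry NaN coefficients rather
  than misleading values.
- **Landscape paths**: per-group, per-generation means of fitness and
  the three complexity measures, for plotting trajectories on the
  (complexity, fitness) plane.

## 7. Problem sizes used in validation

The shipped validation exercises use reduced sizes so the whole cycle
runs in minutes on one core: structural checks use 10³ random genomes
of L = 1,800; the evolution profile is 2 founders × μ, τ ∈
{0, 0.0025, 0.0050} × 30 individuals × 25 generations on the surrogate
backend (14,040 individuals).  The full 1,089-cell design runs through
the same code path via `ece run` and is sized for a multi-hour batch.

## 8. Known limitations

- The surrogate control law is a stand-in: it rewards circuits and body
  size monotonically and cannot exhibit locomotor trade-offs (e.g. a
  body plan that is large but uncoordinated).  Conclusions about *which*
  morphologies win should be re-checked under the physics backend.
- At the scaled profile's size (6 populations per μ level), final-generation
  genetic variance is noisy: it increases with μ in expectation and at
  most seeds, but individual seeds can invert adjacent levels.  The
  full design's 99 populations per level average this out.
- Magnitude semantics are coarse (four discrete levels per attribute
  family); segment radius currently has no behavioral consequence under
  the surrogate backend.
- Wiring is greedy in a fixed endpoint-class order, not optimal; a
  different order would yield different (still deterministic) circuits.
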