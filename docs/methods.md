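# Methods

## Problem and model

G-protein-coupled receptors share a conserved architecture: seven
transmembrane (TM) helices packed into a ring-like bundle, joined by three
intracellular and three extracellular loops.  Homology models of a GPCR
inherit their TM bundle from templates of limited sequence identity, and
the bundle's packing — helix positions, tilts and azimuthal phases — is
usually the accuracy bottleneck for everything downstream (loop building,
docking).  `gpcrbundle` refines the 7-TM bundle of a length-matched target
by treating each helix as a rigid body and searching over rigid-body
placements under a coarse membrane-aware energy, optionally recombining
well-modelled helices from several templates.

The refinement protocol per pipeline has three greedy stages applied to
each assigned helix in turn:

1. **translate** — a rigid shift with each lab-frame component drawn
   uniformly from ±5 Å,
2. **spin** — a rotation about the helix's own axis, drawn uniformly from
   ±180°,
3. **tilt** — the angle between the helix axis and the membrane normal is
   re-set to a target drawn from N(30°, 5°²) (an absolute re-tilt, not an
   increment).

A proposal is accepted only if the full-pose energy strictly decreases
(ties are rejected, guarded by a 1e-9 tolerance so that analytically
energy-neutral moves cannot be accepted on floating-point round-off).
After the three stages one randomly chosen loop is re-closed.  Stage
cycle counts default to 10 each and are configurable; the canonical
choice scales linearly with chain length.

The multi-template framework runs eight such pipelines per iteration.
Pipeline 1 owns TM1 plus the N-terminal tail, pipeline 8 owns TM7 plus
the C terminus, and pipelines 2–7 own the adjacent pairs
{TM(k−1), TMk} plus the loop between them.  Each pipeline draws its
starting pose uniformly from the elite pool (from the templates on the
first iteration), refines its region, and then the **crossing step**
grafts other pipelines' best-so-far versions of each owned helix into the
recipient's best pose; a graft is kept only on strict energy decrease,
loops are never grafted, and broken junctions are re-closed.  Improved
poses (strictly better than their starting energy) enter a bounded,
energy-sorted **elite pool** (default capacity 4 × number of templates)
that seeds the next iteration.  The pool's best energy is therefore
non-increasing in the iteration count.

### Concurrency model

Pipelines are logically independent.  This implementation executes them
sequentially within an iteration — a deterministic barrier schedule in
which crossing reads an immutable snapshot of best-so-far poses taken at
the iteration boundary.  That is exactly the consistency contract an
asynchronous thread pool would have to honour, and it makes every run
bitwise reproducible from the master seed; per-pipeline random streams
are spawned from a `numpy` `SeedSequence`.

## Energy

The score of a pose is

    E_m = surrogate_membrane + weight · E′(S)

**Packing term E′.**  Each helix axis (principal component of its CA
coordinates, sign-fixed N→C) is intersected with the membrane midplane;
the seven intersection points p1..p7 and their centroid O form a closed
fan of seven triangles following TM sequence order with wraparound
TM7→TM1.  With S the summed triangle area,

    E′ = ((S − S_min)/S_min)²  if S < S_min
       = 0                     if S_min ≤ S ≤ S_max
       = ((S − S_max)/S_max)²  if S > S_max.

Small S means a tight bundle, large S a loose one; the band
[S_min, S_max] is calibrated as the min/max of S over a reference set of
bundles (`calibrate_area_bounds`).  The shipped default band comes from
the synthetic ideal-bundle family at ring radii 12.5% below and above the
default 12 Å.  The printed form of the third branch condition in the
source description of this term contains an obvious sign typo; the
implementation uses S > S_max, the only reading that makes the function
well-defined.  E′ is continuous at both bounds, non-negative, strictly
monotone outside the band, and invariant under any rotation of the bundle
about the membrane normal and any in-plane translation (areas are
centroid-relative).  Default weight 100: E′ is a squared *relative* area
deviation, so a ~10% band violation (E′ ≈ 0.01) then costs about as much
as one mild steric violation — comparable leverage on the greedy search.

**Surrogate membrane score.**  A full membrane potential (environment,
residue pair and depth-dependent terms over side chains) is outside this
package's scope; in its place a backbone-only surrogate supplies the same
qualitative forces.  Four terms, all with configurable weights:

* *Sterics* — helices are spherocylinders: pairs of fitted axis segments
  approaching below `d_clash_cyl` = 9 Å are penalised quadratically.  A
  CA–CA soft-sphere alternative (`clash_model="ca"`, 4 Å, pairs ≥ 4 apart
  in sequence, optionally restricted to TM residues) is provided.
* *Depth* — axis-projected TM residue positions beyond the membrane slab
  half-thickness (19.2 Å) are penalised quadratically.
* *Packing wells* — first- and second-neighbour helix-centroid
  separations around the seven-ring are held in contact wells
  (10.4 ± 0.5 Å and 18.8 ± 0.5 Å): the conserved near-regular packing
  geometry of the 7-TM ring, and the stand-in for the attractive terms
  of a real membrane potential.  Without them a repulsion-only score
  lets the ring drift apart, buckle or pucker.
* *Interface anchoring* — the two axis-projected ends of each helix are
  pulled to |z| = 18.7 Å (the membrane interfaces, emulating
  aromatic-belt anchoring; weight 8).  This is what makes over-tilted or
  vertically slipped helices expensive.

**Spin invariance, by design.**  A backbone-only score has no physical
basis for ranking the azimuthal phase of a helix — that information lives
in the side chains.  Any term that couples to spin only through geometric
noise turns the ±180° spin stage into an accepted-noise channel that
randomises helix phases while the energy decreases.  Every surrogate term
is therefore built spin-invariant (axis segments, axis-projected depths,
centroids), so spin proposals tie and are rejected; the stage becomes
active only when a score that can rank phase is plugged in.

**Defaults are co-designed with the synthetic family.**  The numeric
defaults above (contact distances 10.4/18.8 Å, anchor 18.7 Å, slab
19.2 Å) are the measured geometry of the default synthetic bundle —
ring radius 12 Å, 25-residue ideal helices whose actual rise is 1.56
Å/residue — so that family's ideal bundle scores exactly zero and the
energy's global-minimum neighbourhood is known by construction.  For
other bundle geometries `default_membrane_params(spec)` rescales them, or
they can be calibrated from reference structures.

## Loop closure

Rigid-body helix moves break the chain at helix–loop junctions; the
junction gap is |d(C_i, N_{i+1}) − 1.33 Å|.  Internal loops are re-closed
by cyclic coordinate descent (CCD) on the loop's φ/ψ dihedrals: the loop
is first rigidly re-attached at its N-side junction (a translation along
the existing C–N bond direction), then a ghost copy of the downstream
anchor's N/CA/C — attached to the loop end with ideal peptide geometry
(C–N 1.33 Å, CA–C–N 116.2°, C–N–CA 121.7°) and the anchor's own internal
triangle — is driven onto the real anchor atoms, one pivot rotation at a
time, each pivot taking the analytically optimal angle.  ω is never
touched, so peptide-unit geometry is exactly preserved and no atom
outside the loop moves.  Iteration control keeps the best-gap snapshot
across outer cycles, so the retained gap is non-increasing even though
the working state may traverse worse configurations.  If CCD stalls, the
loop is re-grown from the N anchor with jittered extended dihedrals and
closed again (a deterministic restart schedule — the geometric analogue
of fragment-resampling loop protocols).  Terminal tails have a free end
and are re-attached rigidly (exact closure).  Closure tolerance defaults
to 0.08 Å, the conventional CCD criterion; kinematic closure is left as
an interface slot.

Closure can genuinely fail: after large combined perturbations of both
flanking helices the junction separation can exceed what a 6-residue
loop can span.  Non-convergence is reported (`converged=False` with the
final gap), never raised.

## Synthetic data

`make_ideal_bundle` builds seven ideal α-helices (φ = −57°, ψ = −47°,
ideal bond geometry via internal-coordinate chain growth) on a ring of
radius 12 Å, antiparallel (axes alternating ±z), CA centroids in the
z = 0 midplane, connected by 6-residue loops grown extended and closed by
CCD to a construction gap below 0.05 Å.  `perturb_bundle` applies
independent uniform rigid perturbations per helix (translation, spin,
tilt) with recorded ground-truth transforms, then re-closes all loops;
`make_complementary_templates` perturbs the helices outside a given
subset heavily (default 6 Å translations, ±60° spin, ±15° tilt) and the
subset lightly (0.3 Å, 5°, 2°), so each template is individually wrong
somewhere and the set is jointly correct everywhere — the regime in which
helix crossing should pay off.

What the family does *not* emulate: real side chains (so no spin-phase
signal, see above), sequence-dependent helix irregularity (kinks,
bulges — helices here are ideal and rigid), realistic loop conformations
(closure is geometric, not energetic), and the irregular, non-planar ring
of a real receptor.  Passing the synthetic-recovery tests therefore shows
that the search machinery descends a known landscape to its known
minimum basin; it does not certify accuracy on real receptors, where the
landscape comes from the plugged-in energy.

## Problem sizes and expected behaviour

The shipped test suite runs the full protocol at these sizes: synthetic
recovery uses the default 211-residue bundle, 20 seeds, one pipeline pass
over all seven helices (60/5/15 stage cycles); crossing efficacy uses two
complementary templates, 8 pipelines, 3 iterations, 10 master seeds.
Under those conditions median TM RMSD to the generating bundle improves
from ≈2.9 Å to ≈2.0–2.7 Å (a floor is set by the spin component of the
perturbation, which is unrecoverable by a spin-blind score, and by
partially recovered tilts), and the multi-template run with crossing
beats the better single-template run in a clear majority of master seeds
while the advantage disappears with crossing disabled.

## Design choices where the protocol was open

* Helix axis estimator: principal component of CAs, sign-fixed N→C.  For
  a finite helix this deviates from the true axis by a degree or two (the
  z–phase covariance of a spiral); all package geometry uses the same
  estimator consistently.
* Tilt is *set* to the sampled angle rather than incremented; the
  sampler's wording supports the absolute reading.
* Tilt σ defaults to 5°; the protocol's description is internally
  inconsistent (σ = 5 in the call signature vs a variance of 6 in prose)
  and the call signature wins; configurable.
* Translations are lab-frame axis-aligned; any such translation
  decomposes into components along and perpendicular to the helix axis.
  A helix-frame mode is not provided.
* Stage order is fixed (translate → spin → tilt → loops).  Helix axes and
  the membrane frame are re-fitted as helices move (`refresh_axes=True`);
  a frozen-axes mode reproduces the compute-once-up-front variant.
* Pipelines refine ≤ 2 helices when driven by the 8-pipeline framework,
  but `PipelineConfig` accepts any contiguous helix set — the
  single-pipeline protocol itself iterates over all seven helices, and
  the recovery tests exercise it that way.
* Crossing donors are tried in pipeline-index order; the first strictly
  improving graft wins per helix.  A donor donates any helix of its best
  full pose (ownership governs refinement, not donation).  Grafts are
  scored before junction re-closure — under the cylinder steric model
  loop coordinates do not enter the energy, so closure cannot change the
  verdict — and the accepted pose is re-closed and re-scored.
* Elite-pool admission is improved-only (a pipeline's best enters only if
  strictly better than its starting energy), keeping the pool elitist.
* Consensus TM-boundary detection from topology-prediction servers is an
  explicit extension point: boundaries are an input here.

## Known limitations

* The surrogate score is backbone-only and cannot rank spin phase; spin
  recovery is impossible by construction, which bounds achievable TM RMSD
  on spun starting structures.
* E′ constrains only the *total* fan area, so compensating distortions
  (one helix out, a neighbour in) are invisible to it; the contact wells,
  not E′, hold the ring shape.
* Greedy acceptance finds the nearest basin; there is no annealing or
  basin-hopping, in keeping with the strictly greedy protocol.
* Templates must be length-matched to the target; alignment is upstream.
  mmCIF, side chains and insertion codes are unsupported.
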