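# Methods

This note records the models, conventions and numerical choices behind
`dimerlens`, in the order the pipeline applies them.

## Distance observable and regime model

All geometry is computed in nm under an orthorhombic periodic box with
the component-wise minimum-image convention; triclinic cells are
rejected at parse time because the component-wise reduction would be
wrong for them. The dimerization observable is the minimum distance
between the *transmembrane* beads (helix labels I–VII) of the two
receptors; loop beads are excluded because a long intracellular loop
can approach the partner receptor without any helix–helix association
and would otherwise dominate the minimum.

Segmentation is a two-threshold hysteresis. A dimer interval opens at
the first of `min_dimer_frames` (default 5) consecutive frames below
`dimer_cutoff` (0.5 nm) and closes at the first frame above
`dissociation_threshold` (1.5 nm). The gap between the two thresholds
is deliberate: distances in (0.5, 1.5] are ambiguous between a bound
pair breathing and two monomers passing, and hysteresis assigns them to
the current regime instead of flickering. Closed intervals shorter than
`min_transient_duration` (100 ns) are treated as grazing approaches and
folded back into the monomer regime; the dwell minimum separates
pre-dimerization close contacts from genuine short-lived dimers. Both
values are configuration, not physics: nothing in the distance series
itself fixes them, and they are recorded in every output's metadata
side-car.

## Rotational angles

θ₁ is the signed four-point dihedral over the backbone beads
48–164–167 of receptor 1 and 167 of receptor 2; θ₂ swaps the roles.
The convention is right-handed about the 164→167 axis with range
(−180°, 180°]: the canonical staircase (0,0,0), (1,0,0), (1,1,0),
(1,1,1) evaluates to +90°, and rotating the partner's anchor about the
hinge by δ changes θ by exactly δ. All three bond vectors are reduced
by minimum image so receptors split across the boundary are handled;
collinear anchors yield NaN and the frame is reported missing rather
than guessed. Whether to fold the sign is left to the consumer — the
signed value is emitted.

Orientation densities are 2-D histograms over dimer-regime frames with
`angle_bin_width` (10°) bins, normalized to unit sum. When compositions
contribute unequal numbers of simulations, groups can be subsampled to
the smallest count with a seeded generator so pooled densities are
comparable. Conformer regions (A, B, C, A′) are axis-aligned rectangles
shipped as editable configuration; the defaults are a calibration on
synthetic data with A centred on the symmetric homodimer at (0, 0),
A′ the ring around it, B the site-2 quadrant and C the two mixed
quadrants. Containment is half-open so touching rectangles cannot
double-assign; overlapping interiors are a configuration error.

## Contact maps

Residue–residue contact is any-bead-to-any-bead distance below
`contact_cutoff` (0.5 nm). The stable map weights each long-lived
event's per-pair interface-frame fraction by event duration divided by
trajectory length and normalizes the pooled matrix to its maximum; the
transient map weights by association period (ns) and also normalizes to
the maximum, which makes equal-duration events score proportionally to
their instance counts (three I–I transients versus one IV–V gives
exactly 3:1). These normalizations are declared, not derived: the raw
accumulators are written next to every normalized map so alternative
conventions can be applied afterwards. Maps are computed ordered
(receptor 1 × receptor 2) and also emitted symmetrized (element-wise
max with the transpose). Contacts involving loop residues go to a side
table, never into the 7×7 matrices. Normalization is per composition;
pooling across compositions is the caller's choice.

## Lipid occupancy

Maximum occupancy of a lipid species at a residue is the longest run of
consecutive regime frames in which *one* molecule of that species has
any bead within `lipid_contact_cutoff` of any bead of the residue,
divided by the regime length in frames. The default cutoff is 0.6 nm —
deliberately looser than the 0.5 nm protein–protein contact, since
residence definitions for lipids vary between studies — and is
configurable and recorded in metadata. A single frame out of cutoff
breaks a run (gap tolerance zero), and runs never bridge separate
regime intervals: a contact that survives a dissociation is two
residences, not one. Profiles are computed per receptor; averaging over
the two receptors (for monomer-regime profiles) and normalizing to the
profile maximum are explicit, separate steps.

## Bilayer thickness

The thickness map is built in the body frame of one receptor: each
frame is translated so the receptor's TM centroid sits at the origin
and rotated so the centroid→helix-I axis is +x, so angular sectors of
the map correspond to fixed helices. The centroid is computed from
minimum-image displacements relative to a reference bead — a plain mean
of wrapped coordinates is wrong whenever the receptor straddles a
boundary. Phosphates are assigned to leaflets by the sign of z against
the per-frame phosphate median; per planar cell (`grid_bin`, 0.2 nm)
the thickness is mean upper-leaflet z minus mean lower-leaflet z over
all samples. Normalization divides by the far-field thickness measured
from phosphates at least `farfield_min_distance` (3 nm) from every
receptor bead in their frame. Phosphates within that distance of the
*other* receptor are excluded from the subject's map entirely:
otherwise the neighbour's deformation field is mis-attributed to the
subject's surroundings. Cells with no samples in either leaflet are
reported missing (NA), never interpolated.

## Interface occupancy score

Per receptor, each helix takes the maximum dimer-regime residue
occupancy over its residues, normalized by that receptor's highest
helix value. Each helix's interface probability is the fraction of
stable-dimer frames in which it participates in at least one interface
contact on that receptor's side — a genuine probability in [0, 1],
which is what a 70 % threshold requires (a max-normalized contact-map
marginal is not, which is why the estimator is defined this way). The
matrix entry (h_occ, h_int) is the product of the two; entries are
zeroed unless occupancy ≥ 0.7 *and* probability ≥ 0.7, with both
filters applied to the factors after normalization. Per-receptor
matrices are emitted alongside their average. A per-stable-event JSON
(orientation, conformer label, per-event interface probabilities) is
written so conformer-resolved scores can be assembled when a trajectory
contains several distinct stable conformations.

## Synthetic generator

The generator is kinematic placement plus random walk, not dynamics:
ground-truth control is the point, and no thermostat, force field or
energetics is modelled. Consequences to keep in mind when reading
passing tests: planted dimers form by instantaneous placement rather
than diffusion-limited encounter, lipids have no excluded volume, the
bilayer has no thermal roughness, and receptor poses are rigid during
events. Recovery tests therefore demonstrate the *correctness of the
estimators* (geometry, bookkeeping, normalization), not their
robustness to thermal noise in real MARTINI data.

Receptors are rigid assemblies: seven vertical helix rods (four
backbone beads at z = ±0.15, ±0.45 nm) on a 1.4 nm ring with seeded
placement jitter, one outward sidechain bead and two tangential
sidechain beads per helix (the tangential beads give each helix a
contact face wide enough that off-facing planted orientations of
roughly ±20° can still touch), plus two intracellular-loop beads inside
the ring. Residues follow the P08908 transmembrane ranges, putting
residue 48 on helix I and 164/167 on helix IV; the 164–167 axis is
vertical by construction, which reduces the planted-angle problem to
planar azimuths.

Planted poses are solved in closed form. Fixing receptor 1's rotation
as gauge, requested (θ₁, θ₂) determine the azimuth of the 167→167′ leg
and receptor 2's rotation outright; the one remaining unknown, the
slide distance along that azimuth, is bisected until the planted helix
faces sit at 0.45 nm. The solver then verifies that the planted pair is
the *only* pair within the contact cutoff (margin 0.03 nm) and that the
realized angles match the request to 1e-6°; failures raise a generation
error rather than silently shifting the ground truth. When no angles
are requested, the helices are placed facing each other and the
realized angles are recorded as truth.

The default box is 14×14×9 nm. The planar size is a geometric
requirement, not taste: the 167–167′ leg of an in-contact pair can
reach ~6.3 nm, and the minimum-image reduction is only faithful while
that stays below half the box length.

Free diffusion uses per-frame Gaussian steps (receptor D = 0.04,
lipid D = 0.045 nm²/ns at dt = 1 ns) with a centre-separation floor
that keeps the bead-bead minimum distance above the monomer threshold;
planted grazing approaches override it with one-to-two-frame excursions
to 0.65–0.85 nm, below the monomer threshold but above the dimer
cutoff, so segmentation hysteresis is genuinely exercised. Transient
intervals end with an immediate placement at 1.62 nm — beyond the
dissociation threshold — so planted interval bounds are frame-exact.

Lipids are vertical bead stacks (POPC: phosphate, glycerol, tail;
cholesterol: two beads) permanently assigned to a leaflet. Phosphate z
follows the planted thickness field: inside a helix's angular sector
(half-width 180/7°) the leaflet offset (2.0 nm) is scaled by the
planted multiplier, constant out to 2.0 nm from the receptor centre,
decaying linearly to flat at 2.8 nm — fully inside the 3 nm far-field
distance. Overlapping fields from the two receptors combine by the
largest absolute deviation from 1, so identical planted multipliers do
not stack when the receptors pass each other. Hot-spot lipids are
pinned 0.25 nm from their residue (in the leaflet nearest it) for a
contiguous run of round(target × regime length) frames inside the
longest interval of their regime, and held at least 1.2 nm away
otherwise, making the planted occupancy exact to one frame; targets
whose run cannot fit inside a single interval are rejected at
generation time.

The four packaged scenarios (0, 9, 30, 50 mole % cholesterol; 1600–2000
frames at 1 ns spacing, 64 POPC, cholesterol by mole fraction) were
sized to run the full pipeline in seconds each while covering every
recovery target: grazing approaches, transient and stable dimers with
planted interfaces and angles (including a 3:1 transient instance
ratio and an off-facing stable orientation at (30°, −45°)), monomer-
and dimer-regime hot-spots, a flat bilayer and a +10 % helix-I
thickness sector.

## Numerical conventions and degenerate inputs

- GRO coordinates are written at the format's 3-decimal precision;
  planted distances keep ≥ 0.02 nm margins to every threshold so
  rounding cannot flip a classification.
- Histogram normalizations are exact sums (no density scaling); an
  empty dimer regime yields an all-zero density with a warning rather
  than NaNs.
- Contact maps with zero events warn and return all-zero matrices;
  occupancy with zero lipids of the requested kind warns and returns
  zeros.
- Thickness normalization refuses to proceed when either leaflet has no
  far-field samples or the far-field thickness is non-positive.
- Ties in contact-map argmax are resolved by helix order (I before
  VII), relevant only for exactly symmetric synthetic inputs.

## Known limitations

- The per-composition equal-weight subsampling for orientation
  densities drops whole simulations; with few simulations per group the
  seeded choice visibly affects the density.
- The thickness map assumes the receptor axis is normal to the bilayer
  (no tilt correction) and a single receptor per map; crowded systems
  would need the neighbour exclusion radius revisited.
- Occupancy gap tolerance is fixed at zero frames; trajectories stored
  at coarse intervals will fragment residences that a finer stride
  would join.
- XTC reading requires MDAnalysis and converts its ps/Å units; the GRO
  path is the canonical, dependency-free route.
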