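# Methods

## The model system

Major facilitator superfamily (MFS) transporters, including the bacterial
proton-coupled oligopeptide transporters (POT family: PepT_So, PepT_St), carry
substrates by alternating access: a central binding cavity between two
six-helix bundles is exposed to only one side of the membrane at a time.
Access is controlled by two transient constrictions — the periplasmic gate,
formed by the tips of helices H1 & H2 packing against H7 & H8, and the
cytoplasmic gate, formed by H4 & H5 against H10 & H11. The fold decomposes
into four inverted-topology three-helix repeat units (A = H1–H3, B = H4–H6,
C = H7–H9, D = H10–H12); the third helix of each unit (H3/H6/H9/H12) is a
comparatively static scaffold. Bacterial POT transporters additionally carry
two accessory helices (HA/HB) between the halves that belong to no repeat
unit.

`mfsgate` implements the computational analyses that characterize this gating
cycle and makes every stage testable on synthetic structures with known ground
truth.

## Pore profiling

The pore profile is the largest spherical probe that fits in the protein as a
function of the membrane-normal coordinate z:

    radius(z) = max over in-plane centers c  [ min over atoms i ( |c − x_i| − vdw_i ) ]

Atoms carry Bondi-type element radii (C 1.70, N 1.55, O 1.52, S 1.80 Å, …);
hydrogens are ignored by default because crystal structures rarely resolve
them. Radii are capped at `r_max` (default 5 Å) to mark bulk solvent, and may
be ≤ 0 where a slab is fully blocked.

Two deterministic search modes are provided, both exactly checkable by a dense
grid search:

- **axis** (default): at every z, maximize over a disk of radius
  `track_radius` (default 3.5 Å) around the channel seed — the pore axis of an
  oriented structure. The per-z searches are independent, so the profile is
  deterministic, rotation-invariant about z, and never wanders into surface
  pockets or bulk. A stochastic-walk channel tracer in the tradition of
  pore-profiling programs was deliberately not used: a path-dependent search is
  not reproducible by an independent grid oracle, and its branch choices at
  the channel mouths depend on floating-point noise. The trade-off is that
  curved (non-axial) channels are out of scope.
- **box**: per-z maximization over a square box (half-width 6 Å); used for
  analytic benchmark geometries.

The maximization itself is a coarse grid (0.25 Å) followed by Nelder–Mead
refinement from the two best well-separated starts, clamped to the admissible
region; refinement can never fall below its own coarse grid. Equivalence with
an exhaustive 0.05 Å grid is enforced to 0.1 Å by tests on bundles and on
hollow cylinders whose on-axis radius is analytic (wall radius − atom vdw).

Gate regions are located from the profile itself: the cavity center z₀ is the
radius maximum within the central 50% of the profiled span; the cytoplasmic
region runs from the bottom of the span to z₀ − 2 Å and the periplasmic region
from z₀ + 2 Å to the top. Each gate is summarized by the mean radius over a
4 Å window centered on the region's minimum (ties resolved toward the cavity).

## Gate identification and state classification

Candidate gates are all combinations of one contiguous helix pair per half:
nine on the periplasmic side ((H1&H2, H3&H4, H5&H6) × (H7&H8, H9&H10,
H11&H12)) and four on the cytoplasmic side ((H2&H3, H4&H5) × (H8&H9,
H10&H11)). A helix tip is its first or last ten Cα on the relevant side —
resolved by sequence using the topology rule (N terminus cytoplasmic, helices
alternate). Shorter helices use all residues, with a warning. The tip-pair
metric is the *minimum* Cα–Cα distance over the cross-half union of the two
tips, matching the single scalar per combination that the analysis requires.
The gate-defining combination is the one whose metric correlates best
(Pearson r; Spearman available) with the probe radius of the same gate across
a structure set.

States follow the two-distance rule at a 9 Å threshold: both distances below
9 Å is occluded; periplasmic ≥ 9 Å with cytoplasmic < 9 Å is outward open; the
mirror case is inward open. Both ≥ 9 Å — a regime without crystallographic
precedent — is labeled channel-like. The boundary convention is ≥ for open.

A quadrant classification on probe radii is also provided. Its 1.15 Å default
threshold is the color-break convention used to display probe surfaces of real
MFS structures, not a physical constant; `calibrate_radius_threshold` maps the
9 Å tip-distance rule onto a radius threshold by linear regression over a
calibration sweep, which is the appropriate choice for structure sets (such as
the synthetic bundles below) whose radius scale differs from real,
side-chain-packed proteins.

Ensemble mobility (RMSF per Cα, aggregated per helix, per repeat unit and per
half) is computed after superposing all models on the ensemble mean over the
scaffold helices H3/H6/H9/H12 — chosen as the reference because they are the
least mobile helix of each repeat unit; the reference selection is an argument.

## Repeat-swap modelling

Because A and B (and C and D) are related by a twofold pseudo-symmetry axis in
the membrane plane, threading the sequence of unit A onto the structure of
unit B — and vice versa, simultaneously for C and D — yields a template of the
same protein in the opposite conformational state. The alignment is seeded by
superposing partner units with index-wise helix correspondence (H1↔H4, H2↔H5,
H3↔H6; H7↔H10, H8↔H11, H9↔H12; N-to-C, truncated to the shorter helix),
re-pairing residues by nearest Cα within 5 Å, and reducing the votes to one
contiguous sequence offset per helix so helix blocks contain no internal gaps
(the automatic stand-in for manual alignment curation; a plain-text alignment
file can override it). A seed superposition RMSD above 12 Å aborts with advice
to supply a manual alignment. Backbone coordinates (N, Cα, C, O, plus Cβ) are
then transferred; the B-factor column flags placed residues. Accessory helices
(HA/HB/LH) never enter alignments or templates. Homology-model refinement of
the raw template is out of scope.

The sequence-based tip rule makes state inversion of the raw template exact:
the threaded H1 occupies H4's (inverted) position, so H1's sequence-defined
periplasmic tip sits where the old cytoplasmic gate was — the template's two
gate distances are the input's two distances exchanged.

## Salt bridges

A bridge is scored between basic side-chain nitrogens (Lys NZ; Arg
NE/NH1/NH2) and acidic carboxylate oxygens (Asp OD1/OD2; Glu OE1/OE2) when the
minimum N–O distance is ≤ 4.0 Å — the common crystallographic convention,
exposed as a flag. Pairs up to 2 Å beyond the cutoff are reported as near
misses for diagnostics. Histidine is excluded by default (protonation unknown
in crystal structures). Propensities are per-state fractions of frames in
which each bridge is formed, conditioned on the same frames' state labels;
bridges never formed anywhere are excluded. Named residue-pair presets for the
bacterial oligopeptide transporters ship for reporting runs on those
structures.

## DEER prediction

For a pair of labeled sites, a rotamer cloud is mapped onto each residue's
backbone frame (built from N/Cα/C with the z axis along the idealized Cβ
direction), rotamers whose pseudo-atoms (mid-linker point and spin center,
effective radius 2.0 Å) come within `vdw_i + vdw_j − clash_tol` (tolerance
0.5 Å) of any protein heavy atom outside the site residue are removed, weights
are renormalized, and the weighted histogram of all inter-site spin-center
distances gives p(r) (bin width 0.5 Å). Protein conformation and rotamer state
are treated as independent beyond the clash filter. The shipped library is a
synthetic MTSL-like cloud: 20 uniformly weighted spin centers on three rings
5.5/7.0/8.5 Å from the Cα within ~40° of the Cβ axis, respecting the label's
~9 Å maximum linker reach; externally derived libraries in the same plain-text
format can be substituted, since published rotamer libraries are not
redistributable here. Distribution comparison reports the overlap coefficient
Σ min(p, q) after mass-conserving rebinning, the peak offset, and a
within-bounds flag (≥ 95% of predicted mass inside the experimental support by
default).

## The synthetic-bundle generator

The generator emulates the MFS fold at fixture fidelity so that every stage
has a computable ground truth:

- Twelve ideal α-helices (24 residues, 1.5 Å rise, 100°/turn, Cα radius
  2.3 Å) with N/Cα/C/O backbone atoms at canonical cylindrical offsets and a
  Cβ bead per residue. The Cβ bead carries an enlarged effective radius
  (2.25 Å) standing in for the whole side chain — bare poly-alanine traces are
  far more porous than real proteins and their closed gates would not occlude
  the probe.
- The C-terminal half is the 180°-about-z copy of the N-terminal half (the
  pseudo-twofold); helix direction alternates with the N terminus cytoplasmic.
- Gate apertures are set by rigid scissor rotations about a hinge at the
  membrane midplane: all four periplasmic-gate helices move; on the
  cytoplasmic side only H4/H10 (the helices adjacent to the pore axis) move,
  with H5/H11 as static wall supports — a concession to sterics, since tilting
  H5/H11 would sweep them through the periplasmic helices' cytoplasmic flares.
  The scissor angle is solved numerically (bisection on the measured tip
  metric) so the generated aperture matches the request to well within 0.5 Å;
  infeasible requests raise a geometry error, and no two helix axes may come
  within 2 × helix radius.
- Per-state aperture ranges: open gates are drawn from [10.5, 16] Å and closed
  gates from [4.5, 8] Å, straddling the 9 Å criterion with a margin.
- Static helices (H3/H5/H6/H9/H11/H12) receive seeded in-plane anchor jitter
  (SD 0.3 Å, clipped at 0.45 Å so the steric floor is unreachable). This
  emulates the structural heterogeneity of a set of distinct transporter
  structures; without it, every non-gate helix would sit at identical
  coordinates across a sweep and spurious tip-distance correlations would
  appear. Same seed and parameters give bit-identical output.
- Optional proline-like kinks (rigid rotation of the post-hinge segment,
  bending radially outward), charged-residue placements with side-chain
  charge-center pseudo-atoms, and per-frame salt-bridge schedules realized by
  placing those atoms at 3.0 Å (formed) or 7.0 Å (broken) N–O separation.
- Ensembles draw per-frame apertures from the per-state ranges and add
  isotropic Gaussian coordinate jitter.

What the generator does **not** emulate: physical side-chain packing, loops,
force-field energetics, realistic B-factors, or sequence conservation.
Consequently the absolute probe-radius scale of closed gates sits ~1.5 Å above
real side-chain-sealed gates (hence the calibrated radius threshold above),
and passing tests demonstrate the correctness of the geometric machinery and
the self-consistency of the analysis chain — not agreement with any particular
experimental structure.

## Problem sizes and numerical choices

Tests and the acceptance script use: 20 bundles for probe-oracle equivalence
(0.5 Å z-step; the grid oracle uses Lipschitz pruning, which leaves the exact
0.05 Å grid maximum unchanged), a 50-bundle sweep for gate-pair recovery, 30
noiseless and 200 jittered frames for state recovery, and 10 bundles for
repeat-swap state inversion. The jittered-recovery run draws closed apertures
from [4.5, 7.5] Å so that every aperture is at least 1.5 Å from the 9 Å
threshold, the stated condition for the ≥95% recovery guarantee. Nelder–Mead
uses a fixed initial simplex (xatol 1e-4), making all outputs bit-reproducible
for a given seed. Degenerate inputs (empty schedules, regions narrower than a
grid step, sites whose rotamers all clash, helices with too few residues for
an axis fit) raise typed errors rather than returning silently wrong numbers.

## Known limitations

- The pore search assumes a straight, z-aligned channel (appropriate after
  `orient_membrane_normal`); curved pores are unsupported.
- Raw repeat-swapped templates are backbone-only and unrefined; they encode
  the opposite state's geometry but are not stereochemically valid models.
- The salt-bridge criterion is distance-only (no angular terms, no pKa).
- Kink angles from least-squares axis fits are smoothed over one helical turn;
  segments shorter than ~6 residues remain noisy (±2°).
- The DEER library is a geometric stand-in; predicted p(r) is comparable
  between structures, not calibrated against any published rotamer set.
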