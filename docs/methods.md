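# Methods

This note documents the models and conventions implemented in
`mdinteract`, the choices made where several defensible conventions exist,
and what the synthetic-data generators do and do not emulate.

## Scope and assumptions

All analyses operate on multi-model PDB trajectories sharing one topology:
atoms carry element, residue identity and Cartesian coordinates in Å;
residue numbering is taken verbatim from the file. The package assumes
whole, unwrapped coordinates (solvent-stripped complexes, synthetic
fixtures); there is no periodic-boundary / minimum-image handling
anywhere, because for a compact protein–ligand complex such logic would be
dead code. Waters and ions (HOH, ZN, CA, CL) are ordinary residues.
Element symbols come from PDB columns 77–78 when present, otherwise from
the atom name (digits stripped, leading alphabetic token, with a fixed
lookup disambiguating Zn/Cl/Br/... from C/N; `CA`/`NA` read as
calcium/sodium only inside the matching monatomic-ion residue).

## Superposition and RMSD

Rigid superposition is the SVD (Kabsch) solution with the determinant sign
forced positive, so reflections are never returned. Degenerate inputs
(1–2 points, collinear sets) still yield the minimal RMSD; the rotation is
then one deterministic representative fixed by the SVD convention.
Mass-weighting is deliberately not offered — every published quantity the
package mirrors is an unweighted heavy-atom RMSD.

## Ion coordination

The radial profile stores the **mean pair count per bin per frame**, not a
bulk-density-normalised g(r): a binding site buried in a protein interior
has no well-defined bulk density, and only the running number integral is
used quantitatively. Defaults: bin width 0.05 Å, r_max 10 Å.

Distance convention everywhere: an atom is *inside* a cutoff when its
distance is strictly less than the cutoff, with ties at machine precision
(1e-9 Å) counting as inside — fixed so that integer counting tests are
exact. `integral_at(r)` floors `r` to the greatest bin edge ≤ r (the
histogram carries no sub-bin information); it therefore agrees exactly
with direct counting whenever no pair distance falls between that edge and
`r`, and in particular at every bin edge.

First-minimum detection runs on the density after an optional 3-bin
moving-average pass (default on) to suppress single-bin shot-noise minima;
the returned value is always a raw bin centre. The minimum is the
lowest-density bin strictly between the first peak and the next rise; a
plateau of equal minima resolves to the smallest radius, and a profile
that never rises again after its first peak raises a detection error
rather than inventing a minimum. No automatic procedure is asserted to be
*the* procedure behind any published minimum — the analysis cutoff is
always reportable and overridable in config.

Denticity classifies each frame by how many of a carboxylate's two oxygen
atoms lie within the cutoff (2 bidentate, 1 monodentate, 0 unbound);
element filtering of RDF partners is part of the selection, never
hard-coded, so the same machinery serves Zn–O/N shells and Zn–water
oxygen solvent-access counts.

## Hydrogen bonds

A triple is bonded in a frame iff the hydrogen–acceptor distance is below
the distance threshold (default 3.0 Å) **and** the deviation from
linearity is below the angular threshold (default 35°). Two readings of a
"donor-acceptor-hydrogen angle" are defensible, so both are implemented
behind `angle_vertex`: at the **donor** (default) the deviation is the
angle between donor→hydrogen and donor→acceptor; at the **acceptor** it is
the angle between acceptor→donor and acceptor→hydrogen. Both are 0° for a
perfectly linear bond. The distance criterion is hydrogen-to-acceptor — a
literal hydrogen-to-donor distance is a covalent bond of ~1 Å and cannot
discriminate anything (the hydrogen's covalent attachment to the donor,
< 1.2 Å in the first frame, is instead validated as a precondition).

Mean contact distances average over **all** frames, bonded or not. This is
the only convention consistent with reporting a 4.4 Å mean distance next
to a 4.8% occupancy for the same contact: a bonded-frames-only mean could
never exceed the 3.0 Å gate. When the acceptor is a set (a carboxylate's
two oxygens), the closest member per frame is used.

## Stacking

Ring planes are least-squares best-fit planes (smallest principal
component of the centred ring coordinates); rings whose RMS plane residual
is ≥ 0.3 Å are rejected as non-planar. With centroid distance d and the
inter-normal angle θ folded to [0°, 90°], a pair is parallel-displaced if
d ≤ 6.5 Å and θ ≤ 30°, T-shaped if d ≤ 6.5 Å and θ ≥ 60°, otherwise
unclassified. These gates are conventional values from the aromatic-
stacking literature, not derived from any particular dataset, and are
config values.

## Per-residue RMSD heatmaps

The loaded trajectory is compared frame-by-frame against one reference
frame of an apo ("empty") system, matching atoms across systems by
(residue number, atom name); unmatched residues are reported as skipped,
never silently dropped. Each frame receives **one global fit** (default:
the Cα atoms shared by both systems) and per-residue heavy-atom RMSDs are
measured without per-residue refitting — a per-residue refit would erase
exactly the collective lid-opening displacements the heatmap exists to
expose. The correction subtracts, per residue, the time-mean of the apo
system's RMSD against its own reference frame, then clamps at zero (the
heatmap lives on a non-negative colour scale). By construction the
self-comparison of a static system is identically zero.

The ligand RMSD series uses the same policy: fit on the protein, apply the
transform to the ligand, measure with no second fit — a ligand-refit
variant would render dissociation invisible. Sidechain RMSD summaries use
heavy atoms excluding the backbone names N/CA/C/O/OXT; residues without
sidechain heavy atoms (glycine) are skipped with a report.

One known and quantifiable artefact of the global-fit policy: atoms that
genuinely move pull the fit slightly, leaking a small apparent
displacement (of order `drift × n_moving/n_fit`) onto static residues.
The recovery tests operate at generator conditions (6 drifting residues in
a 60-residue chain) where the planted signal dominates this leakage by a
comfortable margin.

## SASA

Shrake–Rupley with a deterministic Fibonacci point lattice (seedless and
reproducible; default 960 points, probe 1.4 Å, Bondi radii). A target
atom's area is the inaccessible-free fraction of test points on its
probe-inflated sphere times `4π(r_atom + r_probe)²`; occlusion is tested
against all target and context atoms. A test point lying exactly on
another inflated sphere — the coincident-atom corner case — belongs to the
lowest-index atom among those whose surface it lies on, so duplicated
atoms can never double-count area. The lattice can optionally be
co-rotated with the coordinates (`orientation=`), making total SASA
exactly rotation-invariant instead of invariant only to the ~0.1% lattice
discretisation.

Summary statistics use the sample SD (n−1) and a normal-quantile
confidence half-width `z(level)·sd/√n`. This convention exactly reproduces
both printed half-width/SD/n combinations the package's tests pin
(0.7 Å² from SD 12.0 and 1.4 Å² from SD 22.7 at n = 1000, 95%), which is
what identifies it among the plausible alternatives (t-quantile, SEM
without z). The probe radius and radii set are documented assumptions, not
claims about any specific published workflow.

## QM/MM boundary utilities

Link atoms cap Cα–Cβ bonds cut by a QM/MM partition, placed at
`L = Cα + ρ(Cβ − Cα)`. The parameter table covers six residue types
(δ- and ε-protonated histidine, Glu, Asp, and the ligand's two link bonds)
at triple-zeta and double-zeta basis-set levels; the rows are consumed as
published constants, their derivation being a separate methodology. The
harmonic correction uses the force-field convention `E = k_L (r − r₀)²`
without the ½ factor, consistent with k in kcal/mol/Å²; the ½-convention
is available as a switch since the defining publication does not write the
formula. The restoring force is the exact magnitude of dE/dr, verified
against central finite differences for every table row.

Electrostatic-embedding export scales **all** MM charges by one global
factor (default 0.666) — a deliberate simplification of distance-dependent
Gaussian-blurred schemes — and excludes QM-selection atoms from the point
charge set. Scaling is linear and order-independent; the exported file is
neutral whitespace-delimited `x y z q`. Per-step QM charge recomputation
(Mulliken) is out of scope; raw charges are caller-provided force-field
values.

## Synthetic-data generators

Every generator is a pure function of its arguments including the seed
(byte-identical reruns) and returns a ground-truth record sufficient to
predict each downstream output:

- **Zn site** — ion at the origin, n O/N partners at bond length 2.0 Å
  (near the ~2.03 Å most-likely distance of a protein zinc site) with
  isotropic Gaussian noise (default SD 0.05 Å), waters at 6–9 Å. The
  noise SD is refused above (cutoff − bond length)/4, which guarantees
  the base shell cannot cross the 2.83 Å analysis cutoff, making the
  coordination number exact by construction; per-frame counts are
  additionally recorded from the generated coordinates. An optional
  partner crosses the cutoff in exactly ⌊fraction·n⌋ frames.
- **H-bond triple** — bonded frames at H···A ≈ 2.0 Å / 5° deviation,
  unbonded at ≈ 4.1 Å / 60°, comfortably on either side of both gates.
  Deterministic mode bonds exactly ⌊occupancy·n⌋ frames so recovery tests
  are exact, not statistical; Bernoulli mode draws frames independently
  for calibration against the binomial interval.
- **Fluctuating chain** — pseudo-residues (CA/CB/CG) on a helical
  backbone; a straight chain would be collinear and degenerate the global
  superposition. Quiet residues fluctuate with SD 0.1 Å, loud ones with
  0.2 Å; the loaded twin additionally displaces the loud block 1.0 Å
  radially off the helix axis (a lid-opening-like motion). Defaults
  (60 residues, 6 drifting) keep the drift signal well above the
  global-fit leakage discussed above. The recorded expected corrected
  column mean, `sqrt(drift² + 6σ²) − sqrt(6σ²)`, treats frame and
  reference noise as adding in quadrature over three atoms and three
  axes and is approximate (it ignores the fit).
- **Stacked rings** — ideal 1.39 Å-edge hexagons in the requested
  arrangement (parallel planes offset 1.5 Å laterally / 3.5 Å vertically,
  or perpendicular planes 5.0 Å apart) with optional jitter.

What passing recovery tests show is that the analysis operators measure
what they claim on data whose answer is known by construction. The
generators emulate none of the physics of a real trajectory — no
force-field dynamics, no frame-to-frame correlation, no water structure,
no anisotropic fluctuations — so they validate the *measurement*, not any
claim about real simulations.

## Pipeline determinism and problem sizes

The pipeline validates every configured selection against the trajectory
before any stage runs (fail-fast, no partial outputs) and writes reports
with sorted keys and fixed precision; identical config and inputs yield
byte-identical outputs, and each run logs the tool version, config hash,
seed and input digests. The test and verification workloads use
deliberately compact problem sizes — 100–200-frame fixtures, 50-seed
Bernoulli calibration at n = 1000, 60-residue chains, 960–10,000-point
SASA lattices — chosen as the smallest sizes at which each statistical
check is decisive.

## Known limitations

- The PDB reader ignores alternate locations and insertion codes and does
  not read mmCIF or binary trajectory formats.
- H-bond triples are configured explicitly; there is no automatic
  donor/acceptor perception from topology, and no energy-based H-bond
  scoring.
- SASA offers no Lee–Richards slicing and no per-residue relative
  accessibility normalisation.
- The corrected heatmap inherits the global-fit leakage artefact above;
  for systems where most of the structure moves, a domain-restricted fit
  selection should be supplied in config.
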