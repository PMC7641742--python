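# Methods

`qdhfold` implements a desk-scale restraint-driven structure-determination
pipeline for quadruplex–duplex hybrid (QDH) DNA, together with the two CD
analyses that usually accompany such work: two-component population
decomposition of a mixture spectrum and baseline-referenced melting-
temperature extraction.  The two QDH folds of the human *PIM1* promoter
region are built in as declarative topologies; everything else (restraint
generation, distance-geometry embedding, restrained simulated annealing,
ensemble statistics) operates on any valid topology.

## Topologies

A `QDHTopology` declares, per fold: the construct sequence, per-residue
glycosidic states (syn/anti), an ordered list of tetrads (G-tetrads with
cyclic Hoogsteen donor→acceptor member order, or G·C·G·C tetrads given as
two Watson–Crick pairs), Watson–Crick pairs, loops and groove labels.
Groove labels are annotations only; no groove-width geometry is computed.
Residue numbering is 1-based on the construct (G1…G27 style).  The two
built-in models:

* **Form 1** (`GCGGGAGGGCGCGCCAGCGGGGTCGGG`): (3+1) core of three
  G-tetrads G3·G25·G22·G7, G4·G8·G21·G26, G5·G9·G20·G27
  (hydrogen-bond directionality anticlockwise/clockwise/clockwise), stem
  pairs G19·C10, G11·C18, G17·C12 capped by the hairpin loop
  G13–C14–C15–A16, propeller loop A6, lateral loop T23–C24, syn set
  {G1, G3, G7, G20, G21, G25}.
* **Form 2** (`GGGAGGGCGCGCCAGCGGGGTCGGGC`): chair-type core of two
  G-tetrads G2·G7·G18·G25 and G3·G24·G19·G6 plus a slipped G·C·G·C
  tetrad G1·C26·G17·C8 whose halves double as junction Watson–Crick
  pairs; stem pairs G9·C16 and G15·C10; lateral loops A4–G5 and
  G20–T21–C22–G23; hairpin loop G11–C12–C13–A14; syn set
  {G2, G6, G18, G24}.  No hydrogen-bond directionality is recorded for
  the Form 2 tetrads (none is established for this fold), so the
  direction fields default to "unspecified".

The imino census predicts 1D imino-proton peak counts: one per G-tetrad
guanine (Hoogsteen-protected, 10.8–12 ppm region) and one per
Watson–Crick G·C pair (12.7–14 ppm region).  G·C·G·C-tetrad guanines are
hydrogen-bonded to their cytosines, so they are counted in the
Watson–Crick tally: Form 1 gives (12, 3), Form 2 gives (8, 4).

## Restraints

Four classes, with the force constants listed under the annealing
schedule:

* **NOE distances** (flat-bottom windows, Å): non-exchangeable
  strong/medium/weak = 2.7 ± 0.8, 3.8 ± 0.9, 5.5 ± 1.7; exchangeable =
  4.0 ± 1.0, 4.8 ± 1.4, 5.5 ± 1.7.  Distances involving thymine methyl
  protons are redirected to the methyl carbon C7 with both bounds
  loosened by 0.5 Å.
* **Hydrogen bonds**: per Hoogsteen G→G edge, H21–N7 = 2.0 ± 0.2,
  N2–N7 = 2.9 ± 0.3, H1–O6 = 2.0 ± 0.2, N1–O6 = 2.9 ± 0.3 (4 restraints ×
  4 edges per G-tetrad); per Watson–Crick G·C pair, H21–O2, H1–N3, O6–H41
  at 2.0 ± 0.2 and N2–O2, N1–N3, O6–N4 at 2.9 ± 0.3 (6 per pair).
  G·C·G·C members are restrained through their Watson–Crick pairs, so the
  built-in folds yield 66 (Form 1: 3·16 + 3·6) and 56 (Form 2: 2·16 + 4·6).
* **χ dihedrals** (O4′–C1′–N9–C4 for purines, O4′–C1′–N1–C2 for
  pyrimidines): centre 60° for syn, 240° for anti; halfwidth 70° by
  default, 40° when tightened (global flag or per-residue override — the
  position-dependent tight/loose choice is left to the user because no
  general mapping exists).  Which residues are restrained is a modelling
  rule of this package: every G/C that belongs to a tetrad or a
  Watson–Crick pair, plus any residue explicitly marked syn (this covers
  Form 1's syn 5′-terminal G1).  This rule gives 19 restraints for Form 1
  and 16 for Form 2.  Loop residues carry no dihedral or planarity
  restraints.
* **Planarity**: one unit per G-tetrad, per G·C·G·C tetrad, and per
  Watson–Crick pair not already inside a G·C·G·C tetrad (6 units for
  Form 1, 5 for Form 2); members contribute their ring heavy atoms.

The bookkeeping summary partitions NOE restraints intra-/inter-residue and
by solvent (exchangeable-proton peaks are observed in H₂O, the rest in
D₂O).

## Molecular model

Ideal nucleotide geometry (atoms, bonds, reference coordinates for
DA/DC/DG/DT) is taken from the chemical component dictionary bundled with
biotite; ideal bond lengths, angles and improper torsions are derived from
those reference coordinates, so the template is internally consistent by
construction.  Every residue carries a 5′-phosphate (OP3 and its proton
are dropped); the O3′ hydroxyl proton is kept only on the 3′-terminal
residue.  The inter-residue linkage uses O3′–P = 1.607 Å with flanking
angles C3′–O3′–P = 119.7° and O3′–P–O5′ = 104.0°; the remaining
junction-spanning angles and the phosphate impropers are intentionally
unrestrained.  One naming normalisation is applied: amino protons are
relabelled where necessary so that Hx1 (H21/H41/H61) is the proton *cis*
to the flanking Watson–Crick-edge ring nitrogen — the proton that actually
hydrogen-bonds in G·C pairs and G-tetrads.  Without this the canonical
hydrogen-bond distance set is geometrically unsatisfiable.

The energy model (kcal/mol, Å, amu) is the standard NMR-annealing
reduced force field: harmonic bonds (k = 60 kcal·mol⁻¹·Å⁻²), angles
(k = 15 kcal·mol⁻¹·rad⁻²) and impropers (k = 10 kcal·mol⁻¹·rad⁻²) around
the template ideals; a purely repulsive soft-sphere nonbonded term
(quadratic below 0.85 × the sum of van der Waals radii,
k = 10 kcal·mol⁻¹·Å⁻², pairs separated by ≤ 3 bonds excluded); no
electrostatics and no explicit ions or solvent.  Restraints enter as
flat-bottom quadratics (distances), square-well quadratics on the minimal
angular difference beyond the halfwidth (χ), and squared distances of
member ring atoms from each unit's best-fit plane (planarity).  All
gradients are analytic and are verified against central finite
differences in the test suite.

## Structure calculation

1. **Chain construction.** A deterministic extended all-atom chain is
   built residue by residue (rigid template copies; extended junction
   torsions), satisfying every template ideal exactly.
2. **Distance bounds.** Covalent 1-2/1-3 distances are fixed; restraint
   pairs get their windows; all other pairs default to [sum of vdW radii,
   999 Å].  Upper bounds are triangle-smoothed by an all-pairs
   shortest-path pass (Floyd–Warshall).
3. **Embedding.** A random distance matrix is drawn between the bounds —
   one global fraction per structure plus small per-pair jitter
   (sd 0.1), which keeps the sample close to a consistent metric — and
   embedded via the classical metric-matrix method (best three
   eigenvalues).  Handedness is unresolved at this point; signed improper
   torsions at the chiral sugar carbons are compared with the template
   and the model is mirrored if the majority is inverted.
4. **Regularisation.** L-BFGS minimisation under the full force field
   with softened repulsion (5%) and the *final* distance constants
   (16/8), to turn the raw embedding into a chemically sensible starting
   structure already pulled into the restraint windows — at desk scale
   the shortened annealing cannot recover from a weakly regularised
   start.  The covalent constants are deliberately soft relative to the
   restraint constants: the flat-bottom equilibrium of a locally strained
   conformation sits at violation ≈ (covalent force)/(2·k_distance), and
   stiff covalent terms hold small violations open that soft ones do not.
5. **Simulated annealing.** Velocity-Verlet dynamics with a Langevin
   (BAOAB) thermostat by default (friction 10 ps⁻¹; periodic velocity
   rescaling is available as an option — the stochastic thermostat
   samples barrier crossings better in short desk-scale runs) through
   the stage sequence: heat 300→1000 K over 14 ps at distance force constant
   2 kcal·mol⁻¹·Å⁻², equilibrate 6 ps, ramp distance constants to 16
   (non-exchangeable) / 8 (exchangeable) over 20 ps, equilibrate 50 ps at
   1000 K, cool to 300 K over 42 ps, equilibrate 18 ps; coordinates are
   saved every 0.5 ps over the final 10 ps and averaged.  χ (50
   kcal·mol⁻¹·rad⁻²) and planarity (1 kcal·mol⁻¹·Å⁻²) constants are held
   throughout.  The soft-sphere term runs at 5% strength while hot and
   ramps to full during cooling, the standard device for letting the
   chain rearrange at high temperature.  `scale_factor` multiplies every
   stage duration uniformly for desk-scale runs.  The timestep default is
   1 fs (2 fs is stable but integrates the stiff X–H bond terms
   noticeably worse at 1000 K).
6. **Final minimisation.** The averaged coordinates are re-minimised
   until the energy-gradient criterion 0.1 kcal/mol is met or an
   iteration cap is reached (cap exhaustion is a reported warning, not an
   error).

`run_pipeline` repeats embed→anneal→minimise for `n_structures`
independent runs (per-run seeds spawned from the master seed), ranks by
total energy, and flags the `n_select` lowest.  Failed runs are excluded
and logged; only total failure raises.  Identical seeds give bit-identical
ensembles: the force-field state is reset at each stage so a run is a pure
function of (conformer, schedule, seed).

## Ensemble statistics

Violations count distance restraints whose distance exceeds
upper + 0.2 Å or falls below lower − 0.2 Å, with *strict* inequality at
the threshold (the convention is not standardised; strict was chosen).
Geometry deviations are RMS over bonds (Å), angles and impropers (deg)
against the template ideals.  Pairwise RMSD is computed over all
unordered pairs of flagged conformers after optimal proper-rotation
(Kabsch) superposition; the named selections are "G-tetrad core" (heavy
atoms of G-tetrad member residues; the G·C·G·C tetrad is excluded) and
"all heavy atoms".  Mean ± sd uses the population (n-divisor) standard
deviation.  Pairwise statistics are computed pair-by-pair, not against a
mean structure.

## CD analyses

Two-component decomposition solves min ‖m − w·c₁ − (1−w)·c₂‖ with
w ∈ [0, 1] in closed form (w = ⟨m − c₂, c₁ − c₂⟩/‖c₁ − c₂‖², clipped),
after linear-interpolation resampling onto the common support of the
three spectra.  The simplex constraint guarantees interpretable
percentages.  Identical component spectra are rejected as degenerate.

Melting analysis fits linear folded/unfolded baselines by least squares
over user-chosen low/high temperature windows (≥ 3 points each,
non-overlapping), forms the folded fraction
θ(T) = (y − y_u)/(y_f − y_u) clipped to [0, 1], and reports Tm as the
first downward 0.5-crossing located by linear interpolation between grid
points.  θ never crossing 0.5 (incomplete transition) is an error.  The
procedure is invariant to affine rescaling of the ellipticity axis.

## Synthetic data

The generators provide ground truth for every stage; all are seeded,
deterministic functions of their arguments.

* **Idealized QDH coordinates.** Tetrad layers are stacked planar units
  (rise 3.4 Å, twist 30° between tetrad layers): the in-plane placement
  of a fourfold-symmetric G-tetrad guanine is solved by least squares so
  the four Hoogsteen distances are met (to ~0.04 Å), and likewise the
  Watson–Crick pair for its six distances.  Layers are ordered so
  sequence-adjacent members stack in columns (brute-force over layer
  permutations, G·C·G·C on the stem side); stem pairs stack coaxially
  below; loops and tails are placed by geometric interpolation with an
  outward bulge.  Full residues are rigid template copies fitted onto the
  placed bases, with χ rotated to 60° (syn) or 240° (anti).  The raw
  assembly already satisfies every hydrogen-bond window; a three-stage
  regularisation (backbone-only relaxation with base atoms frozen, a
  full relaxation under the fold's own hydrogen-bond/χ/planarity
  restraints, and a final high-constant hydrogen-bond polish so every
  window is satisfied strictly rather than within a tolerance) produces
  a physically consistent reference.  The result is
  a *synthetic* idealisation — approximate, not an energy-minimised
  experimental model; deposited coordinates can be read in as an
  alternative reference but are never required.
* **NOE peak lists.** Every proton pair within 6 Å (thymine methyls
  represented by C7) is emitted; true distances are jittered
  (sd 0.1 Å default) and quantised to strong/medium/weak at boundaries
  (3.0, 4.5) Å — (4.5, 5.5) Å for exchangeable pairs, whose windows start
  higher — and a seeded false-negative fraction is dropped.  Geminal
  pairs and pairs below the per-type minimum distance (2.0 / 3.0 Å) are
  excluded: those distances are fixed by covalent geometry or belong to
  the hydrogen-bond restraints, and their inclusion would make the
  jitter-free round trip (peak → window contains the true distance)
  unsatisfiable.
* **CD spectra.** Parametric Gaussian-band components qualitatively
  matching the two folds' signatures (hybrid-type: +265 nm with a 290 nm
  shoulder, −245 nm; antiparallel: +290 nm, −255 nm); mixtures are
  w·c₁ + (1−w)·c₂ plus seeded Gaussian noise scaled to the spectrum
  maximum.
* **Melting curves.** Two-state van't Hoff θ(T) with ΔS = ΔH/Tm
  (θ(Tm) = ½ exactly) mixed between sloping linear baselines, plus seeded
  noise.  Default ΔH = 80 kcal/mol: sharp enough that the 15–25 °C and
  85–95 °C baseline windows are effectively pure folded/unfolded for Tm
  in the 60s, which is what the ±0.2 °C recovery contract needs on a 1 °C
  grid — at ΔH = 50 the unfolded baseline window is visibly contaminated
  (θ(85 °C) ≈ 0.015) and the recovered Tm biases by ~0.3 °C.

What the generators do *not* emulate: real NOESY intensities (no
relaxation theory), spin diffusion, peak overlap or assignment errors;
real CD band shapes or instrument baselines; oligomer/aggregation
equilibria in melting.  Passing the recovery tests therefore shows the
pipeline inverts its own generative model at realistic noise levels, not
that it reproduces the experimental analysis of real spectra.

## Problem sizes and numerical choices

The recovery tests run the pipeline on the Form 1 reference with
n_structures = 10, n_select = 5 and scale_factor = 0.1 (15 ps of total
dynamics per structure at 1 fs), which keeps a full recovery run within
minutes on one CPU while exercising every stage at the full restraint
count (~2 400 NOE + 66 hydrogen-bond restraints, 868 atoms).  The
selection-contract test uses a toy 6-mer at a much smaller scale factor,
where only energy ranking matters.  Degenerate inputs are rejected with
diagnostics (non-embeddable bounds, identical CD components, incomplete
melting transitions, windows with fewer than three points); dynamics
blow-ups raise an error naming the stage.  Ties in energy ranking are
resolved by stable sort order (run index).

## Known limitations

* The reduced force field has no electrostatics, ions or stacking terms;
  absolute energies are meaningless outside ranking, and loop regions are
  restrained only by NOEs.
* At scale_factor = 0.1 the annealing is far shorter than the full
  protocol and its equilibrium typically leaves on the order of one
  residual flat-bottom violation (0.2–0.4 Å excess) per structure at a
  locally misfolded sugar or backbone segment — a different restraint in
  different runs.  Recovery runs therefore reliably reach sub-1.5 Å
  tetrad-core RMSD, and individual runs reach zero violations, but the
  violation count across an ensemble does not vanish at this scale; the
  full-length schedule (scale_factor = 1) is the remedy when minutes per
  structure are acceptable.  An ensemble is computed and only the
  lowest-energy subset reported for exactly this reason.
* The idealized reference is a geometric construction; its loop
  conformations are arbitrary within the restraint windows.
* The G·C·G·C tetrad of the Form 2 reference relaxes slightly non-planar
  (planarity cost ≈ 3.7 kcal/mol at k = 1); its hydrogen bonds stay
  within 0.1 Å of their windows, well inside the ±0.4 Å construction
  margin.
* PDB I/O covers single-chain ATOM/MODEL records only (no mmCIF, no
  multi-chain).
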