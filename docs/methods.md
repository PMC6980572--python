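# Methods

This note records the models, conventions and numerical choices behind
porescope, in the order the pipeline runs them.

## Coordinate and unit conventions

Coordinates are Å, times ns, energies kcal/mol, charges e, fields Volt/Å
throughout. Residue numbering is 1-based within each chain; a pentamer's
global numbering is sequential across chains (global =
(chain−1)·chain_length + local), which with five 136-residue chains puts
the pore-lining lysine ring at 106/242/378/514/650. Two fixed physical
constants connect the unit system: the Coulomb constant
332.0636 kcal·Å/(mol·e²) and 1 e·V/Å = 23.0605 kcal/(mol·Å).

## Synthetic data: what it emulates and what it does not

The generators produce the ground-truth fixtures every analysis is tested
against.

* **Ideal pentamer.** Residue *i* of chain 1 is centred at
  (R(i)·cos φᵢ, R(i)·sin φᵢ, i·spacing); chains 2–5 are exact 72°
  rotations. Atom offsets inside a pseudo-residue sum to the zero vector,
  so residue centroids (heavy-only or all-atom) sit exactly on the
  construction ring and the channel-radius analysis must recover R(i) to
  machine precision. Default axial spacing is 1.5 Å/residue (an α-helical
  rise); pseudo-residues carry 1 site or a 4-atom mainchain (N/CA/C/O),
  optionally with two hydrogens.
* **Thermal noise** is i.i.d. isotropic Gaussian per atom per frame,
  uncorrelated in time, with frame 0 unperturbed. Real trajectories have
  correlated, anisotropic fluctuations; passing these tests therefore
  validates the estimators' algebra and invariances, not their behaviour
  under autocorrelation (the SE spread, in particular, assumes
  independent frames — see Limitations).
* **Crossing traces** are piecewise-linear alternations between
  ±amplitude plateaus (n+1 plateaus give exactly n side switches) plus
  Gaussian jitter; with amplitude (default 12 Å) above the hysteresis
  band (5 Å) and jitter (0.3 Å) below it, the detector count is exact by
  construction. The study-scale fixture packs 15 crossings into 50 ns.
* **Lipid slab** sites are uniform in a box of the configured thickness
  (default 18 Å) — enough for center-of-mass bookkeeping, with no packing
  or chemistry.
* **Toy force fields** supply per-atom charge/LJ/GB parameters at
  plausible magnitudes (|q| ≤ 0.4 e, Rmin/2 = 1.7 Å, ε = 0.12 kcal/mol,
  GB radii 1.5–2 Å, screening 0.8); receptor residues are individually
  charge-neutral. They enable exact oracle tests of the energy code, not
  chemical realism.

All generators are seed-deterministic.

## Channel radius

r(position) is, per frame, the mean over the five equivalent residues of
the distance between each residue's geometric center and the ring center
(the mean of the five centers); r averages the per-frame values and the
spread is the standard error over frames (sd/√n, 0 for a single frame;
no block averaging). Residue centers use heavy atoms by default —
hydrogens are often absent from deposited structures — with explicit
`all` and `CA` policies. Frames are weighted equally. r is invariant
under rigid transforms and equals the construction radius exactly on
ideal pentamers. Δr subtracts two profiles elementwise and combines
spreads in quadrature; scenario labels (I–VII in the channel study:
apo, two ligand-bound states, two field-opened complexes, two
ligand-maintained open states) are free-text strings.

## Superposition and RMSD

Kabsch superposition via SVD with the determinant correction, so a proper
rotation is always returned (a mirror image keeps a nonzero residual);
fewer than three or collinear fit atoms raise a degenerate-fit error.
LS-Fit mode with fit = measure reports the minimal RMSD of that set; with
distinct selections, and always in No-Fit mode, the fit-set transform is
applied once and the measure set's RMSD taken with no refit ("fit once,
measure once"). LS-Fit on a set is therefore a lower bound for any
No-Fit measurement of the same set, a property the suite checks on every
fixture.

"Secondary structures" are supplied as a selection (residue ranges per
chain), not computed by assignment: the analyses treat them as a fixed
atom set, and importing a DSSP-like assigner would add a dependency
without changing any downstream quantity.

**Symmetry-corrected RMSD** minimizes over element-preserving bond-graph
automorphisms (networkx isomorphism search, exhaustive up to a 10⁴
budget), optionally refitting per permutation. This repairs the
inflation seen when topologically equivalent atoms — the two oxygens of
a nitro group after a ~180° bond rotation — are matched by index.

**Equilibrium onset** is the earliest time from which every sliding
window (default 10 ns) stays within a band (default 1.0 Å, max−min).
The window/band defaults are a declared convention: published curves are
typically judged by eye, so the parameters are explicit and overridable
rather than reconstructed.

**Cluster segmentation** places change-points where the median over the
following dwell window differs from the preceding one by at least the
jump threshold (default 1.5 Å), picked greedily by shift size; because
the windowed-median shift plateaus around a clean step, each boundary is
snapped to the largest single-sample jump inside the detection window.
Representatives are per-segment RMSD medoids, earliest frame on ties.

**Open-state persistence** ends at the first sample from which the RMSD
stays above the threshold (default 3.0 Å) to the end of the series —
sustained exceedance, not first touch, so single-frame spikes that
recover do not terminate the state. A series that never sustains an
exceedance returns its full span flagged as censored.

## Passage detection

The ring axis is the best-fit plane normal of the five residue centers
(SVD), sign-fixed toward the first frame's +z so the offset sign is
stable under channel tilt. Events are defined on the signed axial
offset, not the unsigned plotted distance (which cannot distinguish
sides): the detector arms when the offset leaves the ±5 Å hysteresis
band and fires when the armed side switches; jitter inside the band
never counts, and crossing times are interpolated linearly at zero
offset. The numeric criterion (hysteresis on the signed offset) is this
package's convention — the underlying study counts passages off a
distance plot without stating one. A run is "successful" if it contains
at least one event; run summaries report per-run counts and the binomial
success fraction, covering both the per-run and the events-within-a-run
reading of published counts.

## Permeation surrogate

Overdamped 1-D Euler–Maruyama dynamics along the channel axis:
dz = (F/γ)dt + √(2k_BT dt/γ)ξ, F = qEC − dU/dz with a Gaussian barrier
U at the ring plane. Lateral confinement is folded into the effective
barrier; the only observable consumed downstream is the axial trace.
Defaults: γ = 15 kcal·ps/(mol·Å²) (the Stokes–Einstein friction of a
DHS-sized solute in water at 298 K), T = 298 K, barrier 3 kcal/mol ×
3 Å, channel half-length 20 Å, dt = 0.02 ps. A step whose worst-case
drift exceeds the barrier width raises a stability error. The mouths
reflect the permeant until it has crossed the ring plane; afterwards
reaching a mouth is a completed exit and the permeant re-inserts at the
opposite mouth. The re-insertion teleport re-arms the hysteresis
detector on the far side, so a run with k driven traversals reports
~2k−1 detector events with alternating directions; the simulator also
reports its own completed-exit count. Two analytic limits anchor the
integrator: zero field with a symmetric potential gives zero mean net
displacement (checked over 64 pinned seeds), and the barrier-free drift
velocity is qEC/γ. Field titration runs independently seeded batteries
per EEF value and pools duplicate field entries. The surrogate
reproduces the protocol's logic — field on the permeant only, titration,
event counting — not any all-atom event count.

## MM-GB(SA)

Energies are evaluated on snapshots as given (no minimization), all
pairs, no cutoffs — fixtures are small and determinism is worth more
than speed. LJ uses Rmin/2 radii with Lorentz–Berthelot combining.

**Generalized Born.** Effective radii by Hawkins–Cramer–Truhlar pairwise
descreening (no radius offset; screening factor default 0.8 when a table
omits it; a heavily descreened inverse radius is clamped at 10⁻⁶ Å⁻¹;
the rare fully-engulfed-atom correction term is not implemented — toy
tables do not reach that regime). Polar energy
−(k/2)(1/ε_in − 1/ε_out)Σᵢⱼ qᵢqⱼ/f_GB including self terms, so an
isolated ion reduces exactly to the Born equation and ε_out = ε_in gives
zero. The Poisson–Boltzmann solve the original protocol uses for binding
energies is deliberately replaced by this GB backend everywhere; the
membrane-dielectric comparison logic (ε_lip ∈ {1, 2, 4} as the external
dielectric with the membrane on, ligand alone always at ε = 80 with the
membrane off) is preserved, and the per-snapshot membrane center offset
mctrdz (protein center z minus lipid center z, 18 Å slab) is recorded.

**SASA** by Shrake–Rupley with a deterministic golden-spiral point set
(default 960 points, 240 in the fast test configuration; an isolated
sphere is exact to ~0.5% at the default). Because the point set is fixed
in the lab frame, the surface term is rotation invariant only to
quadrature tolerance; the MM and GB terms are exactly invariant.
Nonpolar energy is the affine map 0.0054·SAS + 0.92 (kcal/mol, Å²). The
intercept makes the nonpolar term non-additive across species, so the
non-interacting limit ΔG → 0 holds exactly only with the intercept
zeroed; with the default it tends to −0.92 kcal/mol.

**Binding and decomposition.** Single-trajectory approximation
throughout. Per-residue interaction = Coulomb + LJ cross terms with the
ligand + the residue's share of the GB cross term (complex Born radii) +
optionally slope·(residue SAS in complex − residue SAS in free
receptor), the residue's share of surface burial (included by default,
excludable by flag since published decompositions are ambiguous about
the nonpolar share). The residue terms sum to the corresponding totals
exactly — conservation is checked to 1e-9 against brute-force pair sums.
Hotspots are residues at or below −1.0 kcal/mol (configurable). The
entropy term is not computed; every report carries
`entropy_included = False` rather than silently mimicking it.

**Pose ranking** follows the dominance logic: the best pose must have the
smallest complex free energy at every lipid dielectric — a low binding
difference at one ε does not select a pose when the complex energy is
poor — falling back to the grid mean with an explicit warning when no
pose dominates. Snapshot thinning uses floor((i+0.5)·N/n), which maps a
1350-snapshot set to 135 frames at constant spacing 10.

## Pipeline

A single YAML file declares scenarios (trajectory paths or synthetic
generators), analyses and parameters; validation happens before any
computation, stages run in dependency order, and the manifest echoes the
package version, seeds, all parameters and SHA-256 input digests, making
every output reproducible bit-for-bit from config + seed. The demo runs
every stage in a few seconds (quick mode under 10 s); problem sizes —
25-frame trajectories, 45–136-residue chains, 2 ns surrogate runs, toy
complexes of ~200 atoms — were chosen so the full suite exercises every
code path at interactive speed while leaving the statistics (SE spreads,
titration monotonicity) resolvable.

## Known limitations

* SE spreads assume independent frames; block averaging for correlated
  trajectories is a noted extension.
* The GB backend approximates, not reproduces, PB numerics; only the
  comparison logic across dielectrics is claimed.
* The implicit membrane does not modulate f_GB per atom depth; it enters
  through ε_out and mctrdz bookkeeping only.
* The permeation surrogate is 1-D and memoryless; it cannot exhibit
  lateral escape, permeant flexibility, or channel gating feedback.
* PDB support is the fixed-column v3.3 subset described in the README;
  mmCIF and compressed trajectory formats are out of scope.
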