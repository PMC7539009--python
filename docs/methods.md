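# Methods

`znseal` re-implements, at desk scale, a hybrid NMR/template structure
determination workflow for a complex between a rigid, crystallographically
known domain and a short Zn²⁺-clasped peptide, together with the
quantitative companion analyses such a study uses: chemical-shift
perturbation mapping, buried-surface computation, and single-site binding
thermodynamics.  This note records the models, the parameters that matter,
the numerical choices, and what the synthetic-data validation does and does
not establish.

## The structural model

The complex is represented in Cartesian coordinates with explicit hydrogens.
The domain (chain A) is not solved from scratch: its conformation is held
near a fixed template by tiered harmonic "NCS" restraints, while the peptide
(chain B) and the interfacial side of the domain evolve freely under
experimental-style restraints.

### Distance restraints

NOE cross-peak intensities are taken proportional to r⁻⁶.  The intensity
scale k (intensity = k·r⁻⁶) is calibrated per spectrum on reference peaks
whose distance is fixed by regular secondary structure; the shipped
reference distances are

| reference | distance (Å) |
|---|---|
| sequential Hα(i)–HN(i+1), antiparallel β-sheet | 2.2 |
| sequential HN(i)–HN(i+1), α-helix | 2.8 |
| Hα(i)–HN(i+3), α-helix | 3.4 |

The estimator over multiple reference peaks is the **median** (robust to
overlap artefacts; the estimator is this package's choice).  Transfer of
the scale to filtered spectra uses the median intensity ratio of peaks
observable free of overlap in both spectra.

Each peak's implied distance d = (k/I)^(1/6) selects one of four categories
with upper bounds 2.3, 2.9, 3.5 and 5.0 Å; **all lower bounds are zero**.
A tie at a bin boundary goes to the tighter bin.  Peaks implying d > 5 Å
(the NOE detection limit) are assigned to the weak category rather than
discarded — an observed peak always carries distance information — with a
flag to discard instead.

Ambiguity is handled by r⁻⁶ summation over all cross pairs of the two
(wildcard-expandable) proton groups: d_eff = (Σ r⁻⁶)^(−1/6), which is
always ≤ the minimum pairwise distance.  No stereoassignment protocol is
applied; prochiral groups stay as wildcard groups.

The restraint potential is a square well with force constant
50 kcal mol⁻¹ Å⁻²: zero inside [0, upper], harmonic outside.  During early
annealing a *soft* form is used whose violation branch turns linear beyond
Δ = slope/(2k); the asymptote slope is ramped geometrically (default
1 → 20 kcal mol⁻¹ Å⁻¹) across the ramp cycles, then the potential is
switched to the hard square well before cooling.  The endpoint slopes are
configuration values: only the existence of the tilt schedule, not its
endpoints, is prescribed by standard practice.

### Template (NCS) restraints

The template similarity term is a direct harmonic restraint of selected
atoms to stored template coordinates — mathematically equivalent to the
classical construction of duplicating the molecule, shifting the copy far
away, fixing it, and defining NCS terms between the copies.  Tiers:

| tier | force constant (kcal mol⁻¹ Å⁻²) | scope |
|---|---|---|
| strong | 100.0 | backbone of the rigid core |
| medium | 2.0 | backbone elsewhere; sidechains away from the interface |
| weak | 0.1 | interface sidechains |

`restraints.vps29_tier_table()` ships the residue lists for the 181-residue
domain of the original system; the toy generator derives an analogous table
from its own detected interface.  NCS terms are inactive during the final
tail-addition stage.

### Dihedral restraints

χ¹ restraints (J-coupling-derived in the laboratory setting; measured from
ground truth in the synthetic setting) are flat-bottomed harmonic wells with
half-width 20° and force constant 50 kcal mol⁻¹ rad⁻².

## Force field

A deliberately simplified annealing field, matching common structure-
calculation practice in which the restraints carry the information:

* bonds, angles and impropers: harmonic terms whose ideal values are read
  off an ideal-geometry reference build of each residue type (alphabet:
  Gly, Ala, Ser, Cys, Leu, Met/seleno-Met), k = 500 / 100 / 50;
* a peptide-bond ω torsion well (k = 25), trans by default, cis where
  configured;
* nonbonded: **purely repulsive** quartic, E = s·(r₀² − r²)² for r < r₀
  with r₀ = 0.8·(R_i + R_j) and the scale s ramped 0.01 → 4 during
  annealing; 1-2 and 1-3 pairs excluded; no electrostatics, no attractive
  van der Waals term;
* Zn sites: the Zn is created at the geometric centroid of the four
  cysteinyl sulfurs, then held by Zn–S bonds (target 2.30 Å, k = 200) and
  S–Zn–S angles (109.5°, k = 30).  The 2.30 Å / 109.5° targets are standard
  thiolate-Zn geometry, chosen here because only "bond and angle terms"
  are prescribed by the source protocol;
* no Ramachandran database potential of mean force: that term is internal
  to the original software and not reproducible from its description.  The
  ω well plus impropers keep the backbone geometrically sane; this is a
  documented deviation.

Energies in kcal mol⁻¹, lengths in Å.  All atoms carry a uniform 100 amu
mass, the standard trick that removes fast hydrogen vibrations so the
annealing timestep can be large; dynamics uses BAOAB Langevin integration
(dt = 0.015 AKMA units ≈ 0.73 fs·(m/1 amu)^½-scaled, friction 0.5 per time
unit).  Friction and timestep are not prescribed by the source protocol;
they were chosen once for stability at 1000 K and never revisited.

"Powell minimization" is treated as a contract — a bounded-iteration,
monotonically non-increasing energy minimization — and satisfied with
L-BFGS; the best-seen conformation is returned, so the energy never
increases across a minimization call.

## The staged protocol

Per start: (1) the peptide is rebuilt with randomized φ/ψ, random
orientation, and its centre placed at a Gaussian-distributed distance
(mean 150 Å, sd 15 Å — the sd is unstated in the source and is a flagged
default) from the template centre; (2) stage 1: minimization, 1000 K
Langevin dynamics, van-der-Waals/asymptote ramp cycles, square-well switch,
cooling to 300 K, final minimization; (3) Zn placement at the sulfur
centroid and registration of its bonded terms; (4) stage 2: re-anneal with
a torsion-restraint ramp and 250-step cooling cycles; (5) optionally,
flexible tails are added from fully randomized positions inside a 200 Å
cube with the core rigidly fixed, five independent repeats, lowest E(total)
kept.  Of the completed runs the n_accept lowest-E(total) models form the
ensemble (default 50 starts → 25 accepted).  Runs that diverge to
non-finite energy are logged and excluded; the batch fails only if fewer
than n_accept complete.

The shipped default schedules carry the published step counts (500/5000/
1000/500 for stage 1; 500, 1000+2000 ramps, 250-cycle cooling, 1000 for
stage 2; the 500 K tail stage).  **Desk scaling**: `desk_scale_protocols`
multiplies dynamics step counts by 0.05 but keeps full final-minimization
budgets (800/1500 iterations), because acceptance statistics are read off
minimized structures.  One further desk-scale adaptation: stage 1 includes
a deterministic **rigid-body approach** step that minimizes the distance-
restraint energy over rigid motions of the peptide.  At full step counts
the high-temperature dynamics performs this slow diffusive approach from
150 Å itself; at 5 % step counts it cannot, so the approach is collapsed
into an equivalent 6-DOF Powell optimization.  It changes where the peptide
is when conformational annealing begins, not the annealing itself.

Determinism: a master seed fully determines every start conformation,
thermostat stream and repeat seed, hence the entire ensemble, on one
platform.

## Ensemble analysis

* Superposition: closed-form Kabsch (SVD) least squares; det(R) = +1
  enforced.  Verified in tests against an independent quaternion-method
  oracle.
* Pairwise rmsd superposes **each pair independently** on the evaluated
  selection (the source table does not state pairwise vs common-frame;
  independent-pair matches the "average pairwise" reading).  Backbone
  scope is N, Cα, C′; heavy scope is all non-hydrogens.
* rmsd-to-mean iterates: superpose all models on the current mean, average,
  repeat until the mean moves < 10⁻⁶ Å rmsd.  The mean-to-mean value is
  always ≤ the mean pairwise value.
* SASA: Shrake–Rupley with a 960-point Fibonacci sphere per atom, probe
  1.4 Å, radii C 1.70 / N 1.55 / O 1.52 / S 1.80 / Se 1.90 / Zn 1.39 /
  H 1.10; hydrogens excluded by default (toggleable).  Buried surface is
  the two-sided total SASA(A) + SASA(B) − SASA(AB).  Areas are exact only
  to sampling density: rigid-motion invariance and the two-sphere closed
  form hold to ~1–2 %.

## Shift perturbation and binding analyses

CSP: two combined-shift variants are implemented —
`figure` CSP = √(Δδ(¹H)² + 0.2·Δδ(¹⁵N)²) and
`methods` Δδ = √(Δδ(¹H)² + (Δδ(¹⁵N)/5)²) — because the source reports both
and they disagree (0.2 vs 0.04 weighting of the squared ¹⁵N term).  The
figure variant is the default: it is the one tied to the published maximum
perturbation value (0.662 ppm).  Colour classification maps [0, max/2]
linearly onto a ramp and saturates above half-max.  Prolines/unassigned
residues are emitted as missing, never zero.

Binding: equilibrium fits use unweighted least squares of
R = R_max·C/(K_D + C) with K_D initialized at the geometric mean of the
concentration range plus a small multistart grid (no weighting scheme is
stated in the source; unweighted OLS is this package's choice).  Kinetics
fit the closed-form 1:1 association/dissociation solutions globally in
log-parameters with R_max fixed from the equilibrium analysis.  Van't Hoff:
OLS of ln K_D (K_D in mol L⁻¹) on 1/T, slope = ΔH/R, intercept = −ΔS/R,
R = 8.314 J K⁻¹ mol⁻¹, temperatures converted K = °C + 273.15.  The linear
form assumes ΔH, ΔS constant over the fitted range (277–298 K).

## Synthetic data: what it emulates, what it does not

The toy system is a generated 60-residue helix-hairpin mini-domain plus a
12-residue peptide carrying the CxxxCxCxxC four-cysteine motif, folded so
the sulfurs clasp a Zn²⁺ at near-tetrahedral geometry and docked against
one helix face; the final ground truth is relaxed into a genuine force-field
minimum (residual ≈ 10 kcal mol⁻¹) so that restraint-consistent annealing
can in principle reach it.  Simulated peaks cover intra-peptide pairs,
intermolecular pairs, and template-side pairs restricted to the detected
contact residues (mimicking interface-limited template data); intensities
are k·d_eff⁻⁶ with a hard 5 Å detection limit and optional multiplicative
log-normal noise (positivity-preserving).  Binding responses and shift
tables follow the models above exactly, with the stated laboratory
conditions as defaults (40 → 0.3 µM analyte, 4–25 °C, ΔH° = −20 kJ mol⁻¹,
ΔS° = +36 J K⁻¹ mol⁻¹, largest CSP 0.662 ppm).

A green recovery test therefore establishes: calibration inverts the
generator; classification reproduces the generating bins; the annealing
engine converts a consistent restraint network plus template restraints
into the generating pose (accepted-model peptide backbone rmsd < 1.5 Å at
desk scale) with correctly constructed Zn geometry; and acceptance keeps
exactly the lowest-energy half.  It does **not** establish performance on
real spectra (peak overlap, mis-assignment, spin diffusion are not
simulated), nor chemical-shift realism, nor force-field accuracy beyond
restraint satisfaction.

## Known limitations

* The restraint network (upper bounds only, zero lower bounds) leaves real
  slack: desk-scale accepted models show maximum violations up to ~0.6 Å,
  comparable to the ~0.65 Å maximum the original full-scale calculation
  reports, and pose recovery is ~1 Å rather than exact.
* Absolute energies are not comparable to the original software's values
  (different nonbonded form, no database potential); only orderings and
  decompositions are meaningful.
* The PDB writer emits the classic fixed-column dialect only (no mmCIF);
  B-factors/occupancies are not modelled.
* The amino-acid alphabet covers the residue types the generators use;
  reading arbitrary PDB files works for all residue types, but bonded-term
  construction (annealing) requires the supported alphabet.
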