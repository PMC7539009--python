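# znseal

Hybrid NMR/template structure determination for complexes between a rigid,
crystallographically known domain and a short zinc-clasped peptide — the
"Zn-fingernail" situation, where a ~10-residue CxxxCxCxxC motif folds four
cysteine sulfurs around a single Zn²⁺ and presents a binding epitope to a
partner protein.  The package is aimed at structural-NMR practitioners who
want a transparent, testable implementation of this workflow and of the
quantitative analyses that accompany it.

## What it does

**Structure calculation** (`znseal.restraints`, `znseal.anneal`):

* NOE intensity calibration against secondary-structure reference
  distances, classification into the four standard categories
  (upper bounds 2.3 / 2.9 / 3.5 / 5.0 Å, all lower bounds zero), and
  ambiguous group restraints with r⁻⁶ summation,
  d_eff = (Σ_pairs r⁻⁶)^(−1/6);
* tiered harmonic template ("NCS") restraints (100 / 2.0 / 0.1
  kcal mol⁻¹ Å⁻²) that keep the known domain near its crystallographic
  conformation while interface sidechains stay soft;
* a staged restrained simulated-annealing protocol: randomized peptide
  starts ~150 Å from the template, soft square-well NOE potential with a
  tilted asymptote ramped during 1000 K dynamics, square-well switch and
  cooling (stage 1); Zn²⁺ placement at the centroid of the four cysteinyl
  sulfurs with bond/angle terms (stage 2); optional tail addition from
  randomized positions with the core rigidly fixed; acceptance of the
  lowest-E(total) models (50 starts → 25 accepted at full scale).

**Ensemble analysis** (`znseal.metrics`): Kabsch superposition, average
pairwise and to-mean rmsd statistics, restraint-violation tables, and
Shrake–Rupley solvent-accessible / buried surface areas.

**Companion analyses**: amide chemical-shift perturbation mapping with the
half-max colour ramp (`znseal.csp`), and single-site binding analysis —
equilibrium isotherm fits, 1:1 kinetics, and linear van't Hoff
thermodynamics, ln K_D = ΔH/(R·T) − ΔS/R (`znseal.thermo`).

**Synthetic data with known ground truth** (`znseal.synth`): a toy
60-residue domain + 12-residue Zn-fingernail complex, r⁻⁶ NOE peak
simulation with a 5 Å detection limit, localized shift perturbations, and
van't Hoff-consistent binding series — so the entire pipeline is testable
without downloads.

## Worked example

`examples/structure_recovery.py` simulates NOE peaks from the toy complex,
calibrates and classifies them, runs the annealing protocol at desk scale
(6 starts, accept 3) and scores the accepted models against the generating
coordinates:

```
restraints: 999 ambiguous distance restraints
accepted models: 3
  E(total) =    190.0 kcal/mol   peptide pose rmsd to truth = 0.70 Å   max violation = 0.44 Å
  E(total) =    607.4 kcal/mol   peptide pose rmsd to truth = 1.27 Å   max violation = 0.58 Å
  E(total) =    740.9 kcal/mol   peptide pose rmsd to truth = 1.23 Å   max violation = 0.66 Å
mean restraint violation: 0.0079 Å
```

Pose rmsds around 1 Å mean the peptide's Zn-clasped fold and its docking
site were recovered purely from the simulated restraint network; acceptance
kept exactly the lowest-energy half of the completed runs.

`examples/binding_thermo.py` fits simulated temperature-series binding data
and recovers the generating thermodynamics:

```
  4.0 °C: fitted K_D =  2.34 µM (true  2.24 µM), R_max = 100.6
 12.0 °C: fitted K_D =  2.78 µM (true  2.86 µM), R_max = 98.3
 25.0 °C: fitted K_D =  3.94 µM (true  4.13 µM), R_max = 97.5
van't Hoff: ΔH = -19.1 kJ/mol (exothermic: slope < 0), ΔS = 39.4 J/K/mol, R² = 0.958
predicted K_D at 12 °C: 2.82 µM
```

The negative slope (ΔH < 0) marks the interaction exothermic; the predicted
cold-temperature K_D lands in the low-micromolar range.  The other examples
(`noe_calibration.py`, `csp_mapping.py`, `ensemble_analysis.py`) each run
in seconds and print what their numbers mean.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's headline quantities from scratch at the given
seed: the van't Hoff K_D prediction at 12 °C, equilibrium/kinetic/van't
Hoff fits on freshly simulated binding data, the CSP-maximum recovery, a
full 10-start/accept-5 annealing recovery run with pose and violation
statistics, refinement-table ensemble statistics, and the toy complex's
buried interface area, then writes the results JSON to `--out`.  Runtime is
about five minutes on one CPU.

## Design notes

See `docs/methods.md` for the force-field simplifications, the desk-scale
protocol adaptations, the numerical choices and the limits of what the
synthetic validation establishes.
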