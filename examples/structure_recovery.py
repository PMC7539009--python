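"""Ground-truth recovery with the staged annealing protocol (desk scale).

Builds a toy complex (60-residue rigid domain + 12-residue Zn-clasped
peptide), simulates NOE peaks from it, calibrates and classifies them into
ambiguous distance restraints, then runs the staged simulated-annealing
protocol from randomized distant starts and scores the accepted models
against the generating coordinates.  Takes a few minutes.
"""

import numpy as np

from znseal.validation import toy_recovery

result = toy_recovery(n_starts=6, n_accept=3, master_seed=1)

print(f"restraints: {result.n_restraints} ambiguous distance restraints")
print(f"accepted models: {len(result.ensemble)}")
for rmsd, viol, e in zip(result.pose_rmsds, result.max_violations,
                         result.ensemble.energies):
    print(f"  E(total) = {e.e_total:8.1f} kcal/mol   "
          f"peptide pose rmsd to truth = {rmsd:.2f} Å   "
          f"max violation = {viol:.2f} Å")
print(f"mean restraint violation: {result.mean_violation:.4f} Å")
print(f"all completed-run energies: "
      f"{np.round(result.ensemble.completed_energies, 1)}")
# Acceptance keeps exactly the lowest-energy half; pose rmsds under ~1.5 Å
# mean the peptide's Zn-clasped fold and its docking site were both
# recovered purely from the simulated restraint network.
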