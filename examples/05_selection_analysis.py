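"""Counting-based selection analysis (NG86 sites, SLAC-style tests).

Strips signal peptides, subsamples one paralog per species in triplicate,
and estimates per-site substitution patterns and a global dN/dS (omega)
for families simulated under purifying (omega = 0.3) and diversifying
(omega = 2.0) regimes.
"""

import numpy as np

from scripkit import global_omega
from scripkit.selection import SelectionConfig, run_selection, strip_signal_peptides
from scripkit.simulate import SynthConfig, generate_family, simulate_codon_alignment

# Regime recovery on star-tree simulations with known truth:
for omega_true in (0.3, 2.0):
    estimates = []
    for s in range(5):
        aln, tree = simulate_codon_alignment(12, 150, omega_true, 40, seed=100 + s)
        estimates.append(global_omega(tree, aln))
    print(f"true omega {omega_true}: median estimate "
          f"{np.median(estimates):.3f} over 5 simulations")
# The counting estimator lands close to truth on both sides of neutrality.

# Replicated pipeline on a synthetic family (4 paralogs per species):
cfg = SynthConfig(seed=7, n_subfamilies=1, members_per_subfamily=16,
                  omega_per_subfamily=[0.5],
                  species_pool=[("Acropora millepora", "Acroporidae",
                                 "scleractinia_complex"),
                                ("Orbicella faveolata", "Merulinidae",
                                 "scleractinia_robust"),
                                ("Actinia tenebrosa", "Actiniidae",
                                 "actiniaria"),
                                ("Metridium senile", "Metridiidae",
                                 "actiniaria")])
family = generate_family(cfg)
mature = strip_signal_peptides(family.records)
results, summary = run_selection(mature, SelectionConfig(n_replicates=3, seed=1))
print()
print(summary.to_string(index=False))
# One row per paralog-subsampling replicate (one sequence per species),
# plus the arithmetic-mean global omega across replicates; n_negative
# counts sites significant for purifying selection at alpha = 0.05.
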