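"""Estimate dN/dS for one simulated ortholog pair with all three methods.

Simulates 500 codons at omega = 0.5, kappa = 3, synonymous depth ~0.3, then
compares NG86 counting, the YN00-style approximate method and ML model
averaging on the same alignment.
"""

import numpy as np

from orthoscan.dnds import ml_pairwise, ng86, yn00
from orthoscan.simulate import simulate_pair_alignment

rng = np.random.default_rng(42)
aln = simulate_pair_alignment(omega=0.5, kappa=3.0, t_total=0.87, n_codons=500, rng=rng)
print(f"simulated pair: {aln.ungapped_codon_columns} codon columns, "
      f"true omega = 0.5, true kappa = 3.0\n")

header = f"{'method':8} {'dN':>7} {'dS':>7} {'dN/dS':>7} {'kappa':>6} {'Fisher P':>10}"
print(header)
for est in (ng86(aln), yn00(aln), ml_pairwise(aln)):
    kappa = f"{est.kappa:.2f}" if est.kappa else "-"
    print(f"{est.method:8} {est.dN:7.4f} {est.dS:7.4f} {est.omega:7.3f} "
          f"{kappa:>6} {est.p_value:10.2e}")

# NG86 ignores the transition/transversion bias, so at kappa = 3 it miscounts
# synonymous sites slightly; YN and ML correct for kappa and should land
# closer to the truth. A small Fisher P means the substitution pattern departs
# detectably from neutrality (omega = 1).
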