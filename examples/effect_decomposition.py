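"""Decompose genotype-combination values into direct, indirect and
genome-genome epistatic effects, with variance shares and heritability.

Uses a single-time worked example: four combo means of species A's
abundance, partitioned by the quarter-contrast formulas.
"""

import numpy as np

from cocom import ComboValues, decompose_effects, variance_components

# combo order AB, Ab, aB, ab; one time point
species_a_values = np.array([[4.0], [2.0], [2.0], [0.0]])
species_b_values = np.array([[1.0], [-1.0], [-1.0], [1.0]])

eff = decompose_effects(ComboValues(species_a=species_a_values,
                                    species_b=species_b_values))
print("species A phenotype: mean = %.2f, direct a_A^A = %.2f, "
      "indirect a_B^A = %.2f, epistasis I^A = %.2f"
      % (eff.mu_a[0], eff.direct_a[0], eff.indirect_b_on_a[0], eff.epi_a[0]))
print("species B phenotype: mean = %.2f, direct a_B^B = %.2f, "
      "indirect a_A^B = %.2f, epistasis I^B = %.2f"
      % (eff.mu_b[0], eff.direct_b[0], eff.indirect_a_on_b[0], eff.epi_b[0]))
# Species A carries equal direct and indirect effects and no epistasis;
# species B's pattern (1, -1, -1, 1) is pure genome-genome epistasis.

vc = variance_components(eff, species="a", pheno_var=8.0)
print("species A variance shares: direct %.2f, indirect %.2f, epistatic %.2f; "
      "h2 = %.3f" % (vc.prop_direct[0], vc.prop_indirect[0],
                     vc.prop_epistatic[0], vc.h2[0]))
# Under equal combo frequencies the three contrasts are orthogonal, so the
# shares are the squared effects over their sum (here 0.5 / 0.5 / 0).
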