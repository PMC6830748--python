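"""Pedigree machinery: relationship matrix, inbreeding, immigrant ancestry.

Builds a tiny five-member pedigree containing a full-sib mating and prints
the numerator relationship matrix A, the inbreeding coefficients it
implies, and immigrant-ancestry proportions when one founder is labelled
an immigrant. The inbred calf has F = 0.25 (its parents are full sibs) and
a diagonal entry of 1.25 in A.
"""

import numpy as np
import pandas as pd

from wildqg import (additive_relationship_matrix, genetic_group_proportions,
                    inbreeding_coefficients, validate_pedigree)

ped = validate_pedigree(pd.DataFrame({
    "id":   ["sire", "dam", "son", "daughter", "calf"],
    "sire": ["", "", "sire", "sire", "son"],
    "dam":  ["", "", "dam", "dam", "daughter"],
    "sex":  ["M", "F", "M", "F", "F"],
    "cohort": [0, 0, 1, 1, 2],
}))

A = additive_relationship_matrix(ped)
print("relationship matrix A (rows/cols:", ", ".join(ped.ids), ")")
print(np.round(A, 3))
print("\ninbreeding coefficients:",
      {i: float(f) for i, f in zip(ped.ids, inbreeding_coefficients(ped))})
q = genetic_group_proportions(ped, {"sire": 1.0})
print("immigrant ancestry q (sire labelled immigrant):",
      {i: float(v) for i, v in zip(ped.ids, q)})
print("\nThe calf's diagonal entry 1 + F = 1.25 reflects the full-sib mating;"
      "\nits q = 0.5 because half of its genome descends from the immigrant sire.")
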