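"""Pedigree relationships and prospective inbreeding.

Builds a tiny pedigree by hand, computes the additive (numerator)
relationship matrix with the tabular method, and asks what the inbreeding
coefficient of a few candidate matings' progeny would be — the quantity the
mate-allocation rule drives to zero.
"""

import pandas as pd

from pedeval.pedigree import (
    inbreeding,
    make_pedigree,
    prospective_inbreeding,
    relationship_matrix,
)

frame = pd.DataFrame({
    "id":   [1, 2, 3, 4, 5, 6, 7],
    "sire": [0, 0, 0, 1, 1, 3, 0],
    "dam":  [0, 0, 0, 2, 2, 2, 0],
})
ped = make_pedigree(frame)
A = relationship_matrix(ped)
F = inbreeding(ped, A)

print("additive relationship matrix (diagonal = 1 + F):")
print(pd.DataFrame(A, index=ped.original_id, columns=ped.original_id).round(3))
print()
for s, d in [(4, 5), (4, 6), (4, 7)]:
    f = prospective_inbreeding(ped, s, d, A)
    print(f"progeny of {s} x {d}: F = {f:.3f}"
          + ("  (full sibs: excluded by the F=0 rule)" if f >= 0.25 else
             "  (half sibs via dam 2)" if f > 0 else "  (unrelated: acceptable)"))
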