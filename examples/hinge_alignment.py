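"""Flexible alignment across a 90-degree hinge motion.

Two conformers of the same two-domain protein: identical residues, but the
second domain is swung by 90 degrees about a linker pivot.  Superposition-
based methods see two very different shapes; the contact-area matrices are
nearly unchanged, so the contact-based aligner recovers the full
residue-level correspondence.
"""

import numpy as np

import cabalign as cb
from cabalign.types import Alignment

A, B = cb.make_hinge_pair(n_per_domain=14, linker_length=6,
                          hinge_angle=90.0, seed=0)
cmA = cb.contact_area_matrix(A)
cmB = cb.contact_area_matrix(B)

drift = np.abs(cmA.a - cmB.a).sum() / 2 / cmA.total_area
print(f"contact-matrix change under the hinge: {100 * drift:.1f}% of T")

result = cb.cab_align(A, B, cmA=cmA, cmB=cmB)
identical = sum(1 for a, b in result.alignment.as_tuples() if a == b)
print(f"aligned {result.L}/{len(A)} residues, "
      f"{identical} on the identity diagonal")
print(f"S = {result.S:.1f}, NormS = {result.normS:.2f}")

self_s = cb.alignment_score_S(Alignment.identity(len(A)), cmA, cmA)
print(f"S / self-alignment S = {result.S / self_s:.3f}")
# A ratio near 1 is the method's central property: the hinge motion moved
# half the protein but barely moved the similarity score.
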