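"""Alignment-quality metrics on small hand-checkable inputs.

Shows the four evaluation tools: agreement/reliability against a reference,
confidence-stratified accuracy AQ(x), triplet consistency, and ROC/PRC of a
similarity score as a homolog classifier.
"""

import numpy as np

import cabalign as cb
from cabalign.types import Alignment

# agreement / reliability: 2 of 3 reference pairs recovered
ref = cb.ReferenceAlignment(Alignment([(0, 0), (1, 1), (2, 2)]),
                            confidence=np.array([9, 9, 3]))
test = Alignment([(0, 0), (2, 2), (3, 4)])
res = cb.agreement_reliability(test, ref)
print(f"Nc={res.n_correct} agreement={res.agreement:.3f} "
      f"reliability={res.reliability:.3f}")

# AQ(x): restricted to reference positions with confidence >= x
for x in (0, 5):
    print(f"AQ({x}) = {cb.aq(test, ref, x):.3f}")
# AQ(5) looks only at the two confidence-9 positions; the test alignment
# recovers one of them plus the low-confidence one, hence the difference.

# triplet consistency: one broken A->B->C->A cycle
tri = cb.triplet_consistency(
    Alignment.identity(5), Alignment.identity(5),
    Alignment([(0, 1), (2, 2), (3, 3), (4, 4)]), 5, 5, 5)
print(f"Nconsist={tri.n_consist} AL={tri.al} "
      f"Cov={tri.cov:.2f} Rate={tri.rate:.2f}")

# ROC / PRC of a score column
roc = cb.roc_prc([0.9, 0.7, 0.5, 0.4, 0.2, 0.1], [1, 1, 0, 1, 0, 0])
print(f"AUC={roc.auc:.3f} AUPRC={roc.auprc:.3f}")
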