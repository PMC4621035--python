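"""Score a real structure pair against a curated reference alignment.

Requires two locally supplied inputs (not bundled; both are freely
downloadable):

* PDB entries 2c2f and 1j30 (chain A of each), e.g. from
  https://files.rcsb.org/download/2c2f.pdb
* the curated SISYPHUS reference alignment for this pair, exported as a
  two-row gapped FASTA (optionally with a ``>confidence`` digit row).

Run:
    python examples/sisyphus_worked_example.py 2c2f.pdb 1j30.pdb ref.fasta

On this pair the contact-area alignment agrees almost perfectly with the
curated reference (agreement close to 0.99).
"""

import sys

import cabalign as cb
from cabalign.reports import read_reference_fasta

if len(sys.argv) != 4:
    sys.exit(__doc__)

pdb_a, pdb_b, ref_path = sys.argv[1:]
A = cb.read_pdb_chain(pdb_a, "A")
B = cb.read_pdb_chain(pdb_b, "A")
print(f"{pdb_a}:A {len(A)} residues, {pdb_b}:A {len(B)} residues")

result = cb.cab_align(A, B)
print(f"L={result.L} S={result.S:.1f} NormS={result.normS:.2f}")

ref = read_reference_fasta(ref_path)
res = cb.agreement_reliability(result.alignment, ref)
print(f"agreement={res.agreement:.3f} reliability={res.reliability:.3f}")
if ref.confidence is not None:
    for x, v in cb.aq_profile(result.alignment, ref).items():
        print(f"AQ({x}) = {'NA' if v is None else f'{v:.3f}'}")
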