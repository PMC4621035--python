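"""Text formats: alignment reports, gapped FASTA, reference alignments.

The reference-alignment format is a two-record gapped FASTA; an optional
third record named ``confidence`` carries one digit (0-9) per column,
read at the columns where both sequences have a residue (gap columns may
hold any filler character).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .alignment import ScoredAlignment
from .evaluation import ReferenceAlignment
from .structure import ChainStructure
from .types import Alignment


def gapped_rows(seq_a: str, seq_b: str, aln: Alignment) -> tuple[str, str]:
    """Render an alignment as two gapped rows covering both full sequences.

    Unaligned stretches are emitted with the A-residues first, then the
    B-residues, each opposite gaps.
    """
    ra: list[str] = []
    rb: list[str] = []
    pa = pb = 0
    for iA, iB in [*aln.as_tuples(), (len(seq_a), len(seq_b))]:
        while pa < iA:
            ra.append(seq_a[pa]); rb.append("-"); pa += 1
        while pb < iB:
            ra.append("-"); rb.append(seq_b[pb]); pb += 1
        if iA < len(seq_a):
            ra.append(seq_a[iA]); rb.append(seq_b[iB])
            pa, pb = iA + 1, iB + 1
    return "".join(ra), "".join(rb)


def alignment_fasta(A: ChainStructure, B: ChainStructure,
                    aln: Alignment, id_a: str = "A", id_b: str = "B") -> str:
    ra, rb = gapped_rows(A.sequence(), B.sequence(), aln)
    return f">{id_a}\n{ra}\n>{id_b}\n{rb}\n"


def _read_fasta(path) -> list[tuple[str, str]]:
    records: list[tuple[str, list[str]]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            records.append((line[1:].split()[0], []))
        else:
            if not records:
                raise ValueError(f"{path}: sequence data before first header")
            records[-1][1].append(line)
    return [(name, "".join(chunks)) for name, chunks in records]


def read_reference_fasta(path) -> ReferenceAlignment:
    """Parse a two-row gapped FASTA (plus optional confidence row)."""
    records = _read_fasta(path)
    if len(records) < 2:
        raise ValueError(f"{path}: need two aligned sequences")
    (_, row_a), (_, row_b) = records[0], records[1]
    if len(row_a) != len(row_b):
        raise ValueError(f"{path}: aligned rows differ in length")
    conf_row = None
    for name, row in records[2:]:
        if name.lower().startswith("conf"):
            if len(row) != len(row_a):
                raise ValueError(f"{path}: confidence row length mismatch")
            conf_row = row
    pairs = []
    confidence = []
    ia = ib = 0
    for col, (ca, cb) in enumerate(zip(row_a, row_b)):
        a_res = ca not in "-."
        b_res = cb not in "-."
        if a_res and b_res:
            pairs.append((ia, ib))
            if conf_row is not None:
                ch = conf_row[col]
                if not ch.isdigit():
                    raise ValueError(
                        f"{path}: column {col}: confidence {ch!r} is not 0-9")
                confidence.append(int(ch))
        ia += a_res
        ib += b_res
    aln = Alignment(pairs) if pairs else Alignment.empty()
    conf = np.array(confidence) if conf_row is not None else None
    return ReferenceAlignment(pairs=aln, confidence=conf)


def alignment_report(A: ChainStructure, B: ChainStructure,
                     scored: ScoredAlignment, params=None) -> str:
    """TSV report of aligned pairs with author residue IDs and a summary
    header (L, S, NormS, parameters; S sums over ordered pairs)."""
    lines = [
        f"# L={scored.L} S={scored.S:.3f} NormS={scored.normS:.4f}",
        "# scoring=contact-area, ordered pairs of aligned positions",
    ]
    if params is not None:
        lines.append(
            f"# gamma={params.gamma} gap_open={params.gap_open_iter} "
            f"gap_extend={params.gap_extend_iter} "
            f"windows={','.join(map(str, params.windows))} pow={params.pow}")
    lines.append("iA\tauthA\tresA\tiB\tauthB\tresB")
    for iA, iB in scored.alignment.as_tuples():
        resA = A.residues[iA]
        resB = B.residues[iB]
        lines.append(f"{iA}\t{resA.author_id}\t{resA.residue_name}"
                     f"\t{iB}\t{resB.author_id}\t{resB.residue_name}")
    return "\n".join(lines) + "\n"


def seeds_tsv(seeds: list[Alignment]) -> str:
    """Debug dump: one seed per line as semicolon-joined iA,iB pairs."""
    lines = ["seed\tL\tpairs"]
    for k, aln in enumerate(seeds):
        body = ";".join(f"{a},{b}" for a, b in aln.as_tuples())
        lines.append(f"{k}\t{len(aln)}\t{body}")
    return "\n".join(lines) + "\n"
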