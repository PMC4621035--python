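"""Contact-area similarity scoring and its optimisation by iterative DP.

The similarity S of an alignment is a sum over ordered pairs of aligned
positions of a symmetrised, overprediction-tolerant contact-area term
(a modified CAD-score).  Because the score depends only on the two chains'
internal contact-area matrices — never on superposed coordinates — the final
optimisation is superposition-free and indifferent to hinge motions and
domain rearrangements.

Optimisation: from each seed, a preliminary similarity field M is built
(what each candidate pair (kA, kB) would contribute given the non-conflicting
aligned pairs), smoothed along the diagonal into M', and Smith-Waterman DP
is run on M'; repeat until S converges, shrinking the smoothing window.
The best alignment over the whole trajectory (seed included) is kept.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from ._dp import sw_affine_kernel
from .config import CabParams, SeedParams, SurfaceParams
from .seeds import seed_set
from .structure import ChainStructure
from .surface import ContactAreaMatrix, contact_area_matrix
from .types import Alignment

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ScoredAlignment:
    alignment: Alignment
    S: float
    normS: float = 0.0

    @property
    def L(self) -> int:
        return len(self.alignment)


def pair_weight(i: tuple[int, int], j: tuple[int, int],
                gamma: float = 0.5) -> float:
    """Sequence-separation weight of two aligned pairs.

    0 for separations <= 1 in either chain (suppresses trivially-adjacent
    contacts, including i == j), 1 for separations >= 5 in both chains,
    ``gamma`` otherwise.
    """
    dA = abs(i[0] - j[0])
    dB = abs(i[1] - j[1])
    if dA <= 1 or dB <= 1:
        return 0.0
    if dA >= 5 and dB >= 5:
        return 1.0
    return gamma


def _weights(dA: np.ndarray, dB: np.ndarray, gamma: float) -> np.ndarray:
    dA = np.abs(dA)
    dB = np.abs(dB)
    return np.where((dA <= 1) | (dB <= 1), 0.0,
                    np.where((dA >= 5) & (dB >= 5), 1.0, gamma))


def theta(i: tuple[int, int], j: tuple[int, int],
          cmA: ContactAreaMatrix, cmB: ContactAreaMatrix,
          gamma: float = 0.5) -> float:
    """Per-pair contact-area similarity term.

    With aA = a^A[iA, jA] and aB = a^B[iB, jB]:
    ``w * (max(0, aA - |aA-aB|) + max(0, aB - |aA-aB|))``.
    Equal areas score 2a; a contact entirely missing in one chain scores 0;
    a strongly over-predicted contact still earns the smaller area's worth —
    overprediction is penalised less than omission.  Symmetric in (A, B).
    """
    aA = cmA.a[i[0], j[0]]
    aB = cmB.a[i[1], j[1]]
    d = abs(aA - aB)
    return pair_weight(i, j, gamma) * (max(0.0, aA - d) + max(0.0, aB - d))


def alignment_score_S(aln: Alignment, cmA: ContactAreaMatrix,
                      cmB: ContactAreaMatrix, gamma: float = 0.5) -> float:
    """Raw similarity S: theta summed over all ordered pairs of aligned
    positions (the i == j terms carry weight 0)."""
    if len(aln) == 0:
        return 0.0
    ia = aln.pairs[:, 0]
    ib = aln.pairs[:, 1]
    aA = cmA.a[np.ix_(ia, ia)]
    aB = cmB.a[np.ix_(ib, ib)]
    d = np.abs(aA - aB)
    t = np.maximum(0.0, aA - d) + np.maximum(0.0, aB - d)
    w = _weights(ia[:, None] - ia[None, :], ib[:, None] - ib[None, :], gamma)
    return float((w * t).sum())


def build_M(aln: Alignment, cmA: ContactAreaMatrix, cmB: ContactAreaMatrix,
            gamma: float = 0.5) -> np.ndarray:
    """Preliminary similarity field M over all residue pairs (kA, kB).

    M(k) sums theta(i, k) over the given aligned pairs i that do not
    conflict with k, i.e. those strictly on one side of k in both chains
    ((kA - iA)(kB - iB) > 0); crossing or tied pairs contribute nothing.
    """
    nA, nB = cmA.n, cmB.n
    M = np.zeros((nA, nB))
    kA = np.arange(nA)
    kB = np.arange(nB)
    for iA, iB in aln.pairs:
        aA = cmA.a[iA][:, None]          # (nA, 1)
        aB = cmB.a[iB][None, :]          # (1, nB)
        d = np.abs(aA - aB)
        t = np.maximum(0.0, aA - d) + np.maximum(0.0, aB - d)
        w = _weights(kA[:, None] - iA, kB[None, :] - iB, gamma)
        mask = (kA[:, None] - iA) * (kB[None, :] - iB) > 0
        M += np.where(mask, w * t, 0.0)
    return M


def smooth_M(M: np.ndarray, nw: int) -> np.ndarray:
    """Diagonal sliding-window average of M with half-width ``nw``.

    M'(k) averages M over diagonal offsets -nw..+nw, skipping out-of-range
    cells but always dividing by the full window size 2*nw + 1, so edge
    cells are down-weighted.
    """
    if nw < 0:
        raise ValueError("window half-width must be >= 0")
    out = np.zeros_like(M)
    nA, nB = M.shape
    for d in range(-nw, nw + 1):
        if d >= 0:
            out[:nA - d, :nB - d] += M[d:, d:]
        else:
            out[-d:, -d:] += M[:d, :d]
    return out / (2 * nw + 1)


def iterate_dp(seed: Alignment, cmA: ContactAreaMatrix,
               cmB: ContactAreaMatrix,
               params: CabParams | None = None) -> ScoredAlignment:
    """Optimise one seed by windowed iterative DP; best-of-trajectory.

    For each window half-width in ``params.windows``: rebuild M from the
    current alignment, smooth to M', run Smith-Waterman with the iterative
    gap penalties, and adopt the new alignment — until an alignment repeats,
    S stops changing, or the per-window iteration cap is reached.  The true
    S of every intermediate (and of the seed itself) is recorded and the
    argmax returned, so the result never scores below the seed.
    """
    params = params or CabParams()
    gamma = params.gamma
    best = ScoredAlignment(seed, alignment_score_S(seed, cmA, cmB, gamma))
    current = seed
    s_current = best.S
    for nw in params.windows:
        seen = {current.key()}
        for _ in range(params.max_iter_per_window):
            M = build_M(current, cmA, cmB, gamma)
            Mp = smooth_M(M, nw)
            _, pairs = sw_affine_kernel(np.ascontiguousarray(Mp),
                                        params.gap_open_iter,
                                        params.gap_extend_iter)
            new = Alignment(pairs)
            s_new = alignment_score_S(new, cmA, cmB, gamma)
            if s_new > best.S:
                best = ScoredAlignment(new, s_new)
            if new.key() in seen or abs(s_new - s_current) < params.s_tol:
                current, s_current = new, s_new
                break
            seen.add(new.key())
            current, s_current = new, s_new
    return best


def dedupe(seeds: list[Alignment]) -> list[Alignment]:
    """Drop exact-duplicate pair lists, keeping first occurrences in order."""
    seen: set[bytes] = set()
    out: list[Alignment] = []
    for aln in seeds:
        k = aln.key()
        if k not in seen:
            seen.add(k)
            out.append(aln)
    return out


def norm_s(S: float, T_A: float, T_B: float, pow: float = 0.7) -> float:
    """Size-normalised similarity: S / T_A^pow + S / T_B^pow.

    T_A and T_B are the chains' total inter-residue contact areas; the
    exponent trades off absolute similarity against its rate relative to
    each chain's contact budget, for cross-pair comparison.
    """
    if T_A <= 0 or T_B <= 0:
        raise ValueError("total contact areas must be positive "
                         "(degenerate structure?)")
    return S / T_A ** pow + S / T_B ** pow


def cab_align(A: ChainStructure, B: ChainStructure,
              params: CabParams | None = None,
              surface_params: SurfaceParams | None = None,
              seed_params: SeedParams | None = None,
              cmA: ContactAreaMatrix | None = None,
              cmB: ContactAreaMatrix | None = None) -> ScoredAlignment:
    """Full contact-area alignment of two chains.

    Generates the seed set, de-duplicates it, optimises every seed by
    iterative DP, and returns the alignment with the globally highest S,
    with the normalised score filled in.  Deterministic for fixed inputs.
    Contact matrices may be passed in to reuse a precalculation.
    """
    params = params or CabParams()
    if len(A) < 7 or len(B) < 7:
        raise ValueError("both chains need at least 7 residues")
    if cmA is None:
        cmA = contact_area_matrix(A, surface_params)
    if cmB is None:
        cmB = contact_area_matrix(B, surface_params)
    seeds = dedupe(seed_set(A, B, seed_params))
    logger.info("optimising %d unique seeds (of 580)", len(seeds))
    best: ScoredAlignment | None = None
    for seed in seeds:
        cand = iterate_dp(seed, cmA, cmB, params)
        if best is None or cand.S > best.S:
            best = cand
    assert best is not None
    best.normS = norm_s(best.S, cmA.total_area, cmB.total_area, params.pow)
    return best
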