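"""Seed alignments from local and global backbone similarity.

The contact-area objective is optimised by iterative DP, which needs good
starting points.  Two families of seeds are generated:

* *local*: Smith-Waterman over a unit-vector RMS (URMS) heptapeptide
  similarity matrix, swept over a grid of 58 affine gap-penalty pairs with
  four suboptimal alignments each — 290 alignments;
* *global*: each local seed refined by the TM-score superpose-and-realign
  heuristic — another 290.

The counts are structural constants of the procedure (290 and 580),
independent of the input pair.
"""

from __future__ import annotations

import logging

import numpy as np

from ._dp import nw_semiglobal_kernel, sw_affine_kernel
from .config import SeedParams
from .structure import ChainStructure
from .types import Alignment, GapPenalty

logger = logging.getLogger(__name__)

WINDOW = 7          # heptapeptide
_NVEC = WINDOW - 1  # unit vectors per window


def _unit_vectors(ca: np.ndarray) -> np.ndarray:
    """Successive CA->CA unit vectors; NaN rows propagate."""
    d = np.diff(ca, axis=0)
    norm = np.linalg.norm(d, axis=1, keepdims=True)
    return d / norm


def _optimal_trace(C: np.ndarray) -> np.ndarray:
    """max_R trace(R @ C) over rotations, batched over leading axes."""
    U, s, Vt = np.linalg.svd(C)
    det = np.linalg.det(U @ Vt)
    return s[..., 0] + s[..., 1] + np.sign(det) * s[..., 2]


def urms(hepta_a: np.ndarray, hepta_b: np.ndarray) -> float:
    """Unit-vector RMS distance between two heptapeptide CA windows.

    The six successive CA->CA unit vectors of each window are optimally
    rotated onto each other; the residual root-mean-square is returned.
    Rotation- and translation-invariant, symmetric, in [0, 2].
    """
    hepta_a = np.asarray(hepta_a, dtype=float)
    hepta_b = np.asarray(hepta_b, dtype=float)
    if hepta_a.shape != (WINDOW, 3) or hepta_b.shape != (WINDOW, 3):
        raise ValueError(f"each window must contain exactly {WINDOW} CA coordinates")
    ua = _unit_vectors(hepta_a)
    ub = _unit_vectors(hepta_b)
    tr = _optimal_trace(ua.T @ ub)
    msd = max(0.0, (2.0 * _NVEC - 2.0 * tr) / _NVEC)
    return float(np.sqrt(msd))


def urms_score_matrix(A: ChainStructure, B: ChainStructure,
                      params: SeedParams | None = None) -> np.ndarray:
    """Local-similarity score matrix over all heptapeptide window pairs.

    Entry (l, m) scores the windows *starting* at l and m:
    ``10 * (ref - URMS_lm) / ref`` when URMS_lm is below the random
    expectation ``ref``, else 0.  Rows/columns whose window runs off a
    terminus, or whose window lacks a CA, are 0.
    """
    params = params or SeedParams()
    nA, nB = len(A), len(B)
    if nA < WINDOW or nB < WINDOW:
        raise ValueError(f"both chains need at least {WINDOW} residues "
                         f"(got {nA} and {nB})")
    uA = _unit_vectors(A.ca_coords())
    uB = _unit_vectors(B.ca_coords())
    nwA, nwB = nA - _NVEC, nB - _NVEC
    # windows of 6 consecutive unit vectors
    WA = np.stack([uA[l:l + _NVEC] for l in range(nwA)])
    WB = np.stack([uB[m:m + _NVEC] for m in range(nwB)])
    validA = np.all(np.isfinite(WA), axis=(1, 2))
    validB = np.all(np.isfinite(WB), axis=(1, 2))
    WA = np.nan_to_num(WA)
    WB = np.nan_to_num(WB)

    C = np.einsum("lkx,mky->lmxy", WA, WB)
    tr = _optimal_trace(C)
    msd = np.clip((2.0 * _NVEC - 2.0 * tr) / _NVEC, 0.0, None)
    u = np.sqrt(msd)

    ref = params.urms_ref
    score = np.where(u < ref, 10.0 * (ref - u) / ref, 0.0)
    score[~validA, :] = 0.0
    score[:, ~validB] = 0.0
    out = np.zeros((nA, nB))
    out[:nwA, :nwB] = score
    return out


def sw_affine(scores: np.ndarray, gap: GapPenalty) -> Alignment:
    """Optimal local alignment of a score matrix under affine gap costs.

    Traceback ties break deterministically: diagonal, then vertical, then
    horizontal.  Returns the empty alignment when the best local score is 0.
    """
    scores = np.ascontiguousarray(scores, dtype=np.float64)
    if not np.all(np.isfinite(scores)):
        raise ValueError("score matrix must be finite")
    _, pairs = sw_affine_kernel(scores, float(gap.open), float(gap.extend))
    return Alignment(pairs)


def suboptimal_alignments(scores: np.ndarray, gap: GapPenalty,
                          count: int = 4, damping: float = 0.9) -> list[Alignment]:
    """Suboptimal local alignments by iterative score damping.

    After each DP run the matrix cells at the just-aligned positions are
    multiplied by ``damping`` (cumulatively across rounds), and DP is re-run;
    exactly ``count`` alignments are returned even if some repeat.
    """
    work = np.array(scores, dtype=np.float64)
    previous = sw_affine(work, gap)
    out: list[Alignment] = []
    for _ in range(count):
        for iA, iB in previous.pairs:
            work[iA, iB] *= damping
        previous = sw_affine(work, gap)
        out.append(previous)
    return out


def gap_penalty_grid(params: SeedParams | None = None) -> list[GapPenalty]:
    """The 58 affine-penalty combinations with open >= extend."""
    params = params or SeedParams()
    return [GapPenalty(a, b) for a in params.gap_opens
            for b in params.gap_extends if a >= b]


def local_seed_set(A: ChainStructure, B: ChainStructure,
                   params: SeedParams | None = None) -> list[Alignment]:
    """The 290 local seeds: (1 optimal + 4 suboptimal) x 58 penalty pairs."""
    params = params or SeedParams()
    scores = urms_score_matrix(A, B, params)
    seeds: list[Alignment] = []
    for gap in gap_penalty_grid(params):
        seeds.append(sw_affine(scores, gap))
        seeds.extend(suboptimal_alignments(scores, gap, params.n_suboptimal,
                                           params.subopt_damping))
    return seeds


# ---------------------------------------------------------------------------
# TM-score refinement of seeds

def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping P onto Q.

    Raises ``np.linalg.LinAlgError`` for degenerate (collinear or coincident)
    point sets, where the rotation is not determined.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    Pc, Qc = P.mean(axis=0), Q.mean(axis=0)
    C = (P - Pc).T @ (Q - Qc)
    U, s, Vt = np.linalg.svd(C)
    if s[1] <= 1e-8 * max(s[0], 1.0):
        raise np.linalg.LinAlgError("degenerate point set: rotation undetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Qc - R @ Pc
    return R, t


def tm_d0(l_min: int) -> float:
    """Length-dependent TM-score distance scale, floored at 0.5 Å."""
    return max(0.5, 1.24 * np.cbrt(max(l_min - 15, 0)) - 1.8)


def tm_refine(A: ChainStructure, B: ChainStructure, seed: Alignment,
              params: SeedParams | None = None) -> Alignment:
    """Re-align a seed by the TM-score superpose-and-realign heuristic.

    Repeats {superpose A onto B on the current pairs' CA atoms; rebuild the
    TM-score similarity matrix; global DP with free end gaps and gap
    penalties (0.6, 0)} until an alignment repeats or the round cap is hit.
    Seeds with fewer than 3 pairs are returned unchanged.
    """
    params = params or SeedParams()
    if len(seed) < 3:
        return seed
    caA = A.ca_coords()
    caB = B.ca_coords()
    okA = np.all(np.isfinite(caA), axis=1)
    okB = np.all(np.isfinite(caB), axis=1)
    d0sq = tm_d0(min(len(A), len(B))) ** 2

    current = seed
    seen = {current.key()}
    for _ in range(params.tm_max_rounds):
        mask = okA[current.pairs[:, 0]] & okB[current.pairs[:, 1]]
        pairs = current.pairs[mask]
        if len(pairs) < 3:
            return current
        try:
            R, t = kabsch(caA[pairs[:, 0]], caB[pairs[:, 1]])
        except np.linalg.LinAlgError:
            logger.warning("degenerate superposition; seed returned unchanged")
            return seed
        moved = np.nan_to_num(caA, nan=1e6) @ R.T + t
        d2 = ((moved[:, None, :] - np.nan_to_num(caB, nan=-1e6)[None, :, :]) ** 2
              ).sum(axis=2)
        sim = 1.0 / (1.0 + d2 / d0sq)
        sim[~okA, :] = 0.0
        sim[:, ~okB] = 0.0
        _, new_pairs = nw_semiglobal_kernel(
            np.ascontiguousarray(sim), params.tm_gap_open, params.tm_gap_extend)
        new = Alignment(new_pairs)
        if new.key() in seen:
            return new
        seen.add(new.key())
        current = new
    return current


def seed_set(A: ChainStructure, B: ChainStructure,
             params: SeedParams | None = None) -> list[Alignment]:
    """All 580 seeds: the 290 local seeds plus their 290 TM refinements."""
    params = params or SeedParams()
    local = local_seed_set(A, B, params)
    refined = [tm_refine(A, B, s, params) for s in local]
    return local + refined
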