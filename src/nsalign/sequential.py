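"""Sequential (SQ) alignment: five initial alignments, then iterations of
TM-optimal superposition and Needleman-Wunsch re-alignment until the pair
set repeats.

The NW step is a global dynamic program over the residue-level TM-score
matrix with a linear gap penalty of -0.6; ties during traceback prefer the
diagonal, then the vertical (gap in B), then the horizontal move, which
makes the whole mode deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .core import Alignment, CoordinateChain, ScoreReport, Transform
from .geometry import kabsch
from .scoring import (
    d0_for_chain,
    optimal_tm_superposition,
    residue_tm_matrix,
    score_report,
    tm_score,
)
from .secondary import SSEAnnotation, assign_secondary_structure

GAP_PENALTY = -0.6
MAX_ITER = 30


@dataclass
class AlignConfig:
    """Tunable knobs shared by the alignment modes."""

    gap_penalty: float = GAP_PENALTY
    max_iter: int = MAX_ITER
    k_neighbors: int = 5
    ns_distance_filter: float = 8.0  # A; drop farther NS pairs before reporting
    greedy_floor: float = 0.0
    refine_superposition: bool = True
    fns_iteration_matrix: str = "point"  # "point" (Eq.6 form) or "fragment"
    fragment_stride: Optional[int] = None  # None -> max(1, L // 10)


@njit(cache=False)
def _nw_fill(scores, gap):  # pragma: no cover - exercised via nw_align
    n, m = scores.shape
    f = np.zeros((n + 1, m + 1))
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    for i in range(1, n + 1):
        ptr[i, 0] = 1
    for j in range(1, m + 1):
        ptr[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = f[i - 1, j - 1] + scores[i - 1, j - 1]
            up = f[i - 1, j] + (gap if j < m else 0.0)
            left = f[i, j - 1] + (gap if i < n else 0.0)
            if diag >= up and diag >= left:
                f[i, j] = diag
                ptr[i, j] = 0
            elif up >= left:
                f[i, j] = up
                ptr[i, j] = 1
            else:
                f[i, j] = left
                ptr[i, j] = 2
    return f, ptr


def nw_align(scores: np.ndarray, gap_penalty: float = GAP_PENALTY) -> Tuple[Alignment, float]:
    """Needleman-Wunsch global alignment of a similarity matrix.

    The linear gap penalty applies to internal gaps only; gaps at either
    terminus are free (zero-initialized first row/column, free moves along
    the last row/column), the convention structure alignment needs so that a
    length mismatch or a circularly permuted half-chain is not punished for
    its overhangs.  Returns the alignment and the total DP score (matched
    entries plus penalized gaps).
    """
    s = np.ascontiguousarray(np.asarray(scores, dtype=float))
    if s.ndim != 2 or s.size == 0:
        raise ValueError("score matrix must be non-empty and 2-D")
    if not np.isfinite(s).all():
        raise ValueError("score matrix must be finite")
    if gap_penalty > 0:
        raise ValueError("gap penalty must be <= 0")
    f, ptr = _nw_fill(s, float(gap_penalty))
    i, j = s.shape
    pairs = []
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return Alignment(pairs=pairs, is_sequential=True), float(f[s.shape[0], s.shape[1]])


def _gapless_candidates(L_a: int, L_b: int, min_overlap: int = 4):
    lo = min(min_overlap, L_a, L_b)
    for offset in range(-(L_a - lo), L_b - lo + 1):
        i0 = max(0, -offset)
        j0 = max(0, offset)
        n = min(L_a - i0, L_b - j0)
        yield [(i0 + k, j0 + k) for k in range(n)]


def _eval_pairs_tm(chain_a, chain_b, pairs, d0, L_norm) -> float:
    """TM of a candidate pair set after a Kabsch fit plus one outlier-trimmed
    refit, so a few far pairs cannot tilt the fit away from a good core."""
    ia = np.array([p[0] for p in pairs])
    jb = np.array([p[1] for p in pairs])
    pa, pb = chain_a.points[ia], chain_b.points[jb]
    t = kabsch(pa, pb)
    d = np.linalg.norm(t.apply(pa) - pb, axis=1)
    tm = tm_score(d, L_norm, d0)
    sel = d < max(d0, 4.5)
    if 3 <= sel.sum() < len(d):
        t2 = kabsch(pa[sel], pb[sel])
        d2 = np.linalg.norm(t2.apply(pa) - pb, axis=1)
        tm = max(tm, tm_score(d2, L_norm, d0))
    return tm


def _best_gapless(chain_a, chain_b, d0, L_norm) -> Alignment:
    best, best_tm = None, -1.0
    for pairs in _gapless_candidates(chain_a.L, chain_b.L):
        if len(pairs) < 3:
            continue
        tm = _eval_pairs_tm(chain_a, chain_b, pairs, d0, L_norm)
        if tm > best_tm:
            best_tm, best = tm, pairs
    if best is None:  # chains too short for any 3-pair overlap
        n = min(chain_a.L, chain_b.L)
        best = [(k, k) for k in range(n)]
    return Alignment(pairs=best, is_sequential=True)


def _ss_match_matrix(ss_a: SSEAnnotation, ss_b: SSEAnnotation) -> np.ndarray:
    a = np.array([ord(c) for c in ss_a.states])
    b = np.array([ord(c) for c in ss_b.states])
    return (a[:, None] == b[None, :]).astype(float)


def _fragment_seed(
    chain_a, chain_b, frag_len: int, stride: int, d0, L_norm, gap_penalty
) -> Optional[Alignment]:
    """Best fragment-pair Kabsch fit, converted to a full NW alignment.

    Candidate fits are ranked by the TM of the gapless extension of the
    fragment diagonal, which is cheap; only the winner pays for a full score
    matrix and NW pass.
    """
    frag_len = max(3, min(frag_len, chain_a.L, chain_b.L))
    best, best_tm = None, -1.0
    for ia in range(0, chain_a.L - frag_len + 1, stride):
        wa = chain_a.points[ia : ia + frag_len]
        for jb in range(0, chain_b.L - frag_len + 1, stride):
            wb = chain_b.points[jb : jb + frag_len]
            t = kabsch(wa, wb)
            offset = jb - ia
            i0, j0 = max(0, -offset), max(0, offset)
            n = min(chain_a.L - i0, chain_b.L - j0)
            d = np.linalg.norm(
                t.apply(chain_a.points[i0 : i0 + n]) - chain_b.points[j0 : j0 + n],
                axis=1,
            )
            tm = tm_score(d, L_norm, d0)
            if tm > best_tm:
                best_tm, best = tm, t
    if best is None:
        return None
    matrix = residue_tm_matrix(best.apply(chain_a.points), chain_b.points, d0)
    alignment, _ = nw_align(matrix, gap_penalty)
    return alignment


def initial_alignments(
    chain_a: CoordinateChain,
    chain_b: CoordinateChain,
    ss_a: Optional[SSEAnnotation] = None,
    ss_b: Optional[SSEAnnotation] = None,
    config: Optional[AlignConfig] = None,
) -> List[Alignment]:
    """The five SQ seeds: gapless sliding, secondary-structure matching,
    their half-half combination, large-fragment superposition (L/2 and L/3),
    and small-fragment superposition (length 4)."""
    config = config or AlignConfig()
    L_norm = min(chain_a.L, chain_b.L)
    d0 = d0_for_chain(chain_a if chain_a.L <= chain_b.L else chain_b)
    if min(chain_a.L, chain_b.L) < 4:
        return [_best_gapless(chain_a, chain_b, d0, L_norm)]
    if ss_a is None:
        ss_a = assign_secondary_structure(chain_a)
    if ss_b is None:
        ss_b = assign_secondary_structure(chain_b)
    seeds: List[Alignment] = []

    gapless = _best_gapless(chain_a, chain_b, d0, L_norm)
    seeds.append(gapless)

    ss_matrix = _ss_match_matrix(ss_a, ss_b)
    seeds.append(nw_align(ss_matrix, config.gap_penalty)[0])

    # half-half: SS matching combined with the distance score implied by the
    # best gapless superposition
    ia, jb = gapless.arrays()
    t = kabsch(chain_a.points[ia], chain_b.points[jb])
    dist_matrix = residue_tm_matrix(t.apply(chain_a.points), chain_b.points, d0)
    seeds.append(nw_align(0.5 * ss_matrix + 0.5 * dist_matrix, config.gap_penalty)[0])

    L = min(chain_a.L, chain_b.L)
    stride = config.fragment_stride or max(1, L // 10)
    for frag_len in (L // 2, L // 3):
        seed = _fragment_seed(
            chain_a, chain_b, frag_len, stride, d0, L_norm, config.gap_penalty
        )
        if seed is not None and seed.l_ali >= 3:
            seeds.append(seed)
    small = _fragment_seed(
        chain_a, chain_b, 4, max(2, stride), d0, L_norm, config.gap_penalty
    )
    if small is not None and small.l_ali >= 3:
        seeds.append(small)
    return seeds


def _iterate_from_seed(
    chain_a,
    chain_b,
    seed: Alignment,
    d0: float,
    L_norm: int,
    config: AlignConfig,
    realign,
) -> Tuple[Alignment, Transform, float]:
    """Superposition <-> re-alignment loop; returns the best state ever seen.

    ``realign(matrix, current)`` produces the next alignment from the
    residue-level score matrix; convergence is exact repetition of a pair
    set, capped at ``config.max_iter`` iterations.
    """
    current = seed
    best: Tuple[Alignment, Transform, float] = (None, None, -1.0)
    seen = set()
    for _ in range(config.max_iter):
        if current.l_ali < 3:
            break
        t, tm = optimal_tm_superposition(
            chain_a, chain_b, current, d0, L_norm, refine=config.refine_superposition
        )
        if tm > best[2]:
            best = (current, t, tm)
        key = current.pair_set()
        if key in seen:
            break
        seen.add(key)
        matrix = residue_tm_matrix(t.apply(chain_a.points), chain_b.points, d0)
        current = realign(matrix, current)
    return best


def align_sq(
    chain_a: CoordinateChain,
    chain_b: CoordinateChain,
    config: Optional[AlignConfig] = None,
) -> Tuple[Alignment, Transform, ScoreReport]:
    """Sequential alignment maximizing the TM-score normalized by the
    shorter chain; both normalizations are reported."""
    config = config or AlignConfig()
    if chain_a.L < 3 or chain_b.L < 3:
        raise ValueError("chains must have at least 3 alignable units")
    L_norm = min(chain_a.L, chain_b.L)
    d0 = d0_for_chain(chain_a if chain_a.L <= chain_b.L else chain_b)

    def realign(matrix, _current):
        return nw_align(matrix, config.gap_penalty)[0]

    best: Tuple[Alignment, Transform, float] = (None, None, -1.0)
    for seed in initial_alignments(chain_a, chain_b, config=config):
        state = _iterate_from_seed(chain_a, chain_b, seed, d0, L_norm, config, realign)
        if state[2] > best[2]:
            best = state
    alignment, transform, _ = best
    if alignment is None:
        raise ValueError("no seed produced a superposable alignment")
    report = score_report(chain_a, chain_b, alignment, transform)
    return alignment, transform, report
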