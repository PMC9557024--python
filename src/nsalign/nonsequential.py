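"""Non-sequential alignment: fully non-sequential (fNS) alignment via
K-nearest-neighborhood fragment scoring plus Enhanced Greedy Search (EGS),
and semi-non-sequential (sNS) alignment via SQ seeding plus a swap stage
constrained to keep every secondary-structure element's partners sequential.

EGS treats the two chains as point clouds: a greedy pass repeatedly fixes
the best remaining similarity-matrix entry, and a local-search pass then
exchanges partners between assigned pairs (plus reassignments to unassigned
rows/columns, and 3-cycle rotations once pair exchanges stall) while the
total similarity keeps increasing.  The search is deterministic: ties break
toward the lowest index and no randomness is used anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import (
    Alignment,
    CoordinateChain,
    ScoreReport,
    Transform,
    is_sequential_pairs,
)
from .scoring import (
    d0_for_chain,
    optimal_tm_superposition,
    residue_tm_matrix,
    score_report,
)
from .secondary import assign_secondary_structure
from .sequential import AlignConfig, _iterate_from_seed, align_sq, nw_align

_GAIN_TOL = 1e-12


@dataclass
class NeighborFragment:
    """The K residues closest in space to a center residue (center first)."""

    center: int
    members: List[int]
    coords: np.ndarray


@dataclass
class Assignment:
    """Order-free one-to-one pairing produced by EGS."""

    pairs: List[Tuple[int, int]]
    total_score: float


def _neighbor_orders(points: np.ndarray, K: int) -> np.ndarray:
    """(L, K) member indices per center, sorted by distance, center first;
    ties go to the lower index (stable sort)."""
    L = len(points)
    if L < K:
        raise ValueError("chain too short for fNS seeding")
    # rounding keeps geometric ties (symmetric neighbours) exact so the
    # stable sort can break them toward the lower index
    dist = np.round(squareform(pdist(points)), 6)
    np.fill_diagonal(dist, -1.0)  # force the center to rank first
    return np.argsort(dist, axis=1, kind="stable")[:, :K]


def neighbor_fragment(chain: CoordinateChain, i: int, K: int = 5) -> NeighborFragment:
    """The K spatially closest residues to residue i, including i itself."""
    members = _neighbor_orders(chain.points, K)[i].tolist()
    return NeighborFragment(center=i, members=members, coords=chain.points[members])


def fns_initial_scores(
    chain_a: CoordinateChain,
    chain_b: CoordinateChain,
    K: int = 5,
    d0: Optional[float] = None,
) -> np.ndarray:
    """Fragment-based similarity matrix seeding the fNS search.

    Entry (i, j) superposes the K-neighborhood of residue i in A onto the
    K-neighborhood of j in B (rank-to-rank correspondence, Kabsch fit) and
    scores 1 / (1 + (d/d0)^2) on the distance d between the two rank-K
    members after the fit.  The fits are batched: one SVD per (i, j) pair
    over stacked 3x3 covariance matrices.
    """
    if d0 is None:
        d0 = d0_for_chain(chain_a if chain_a.L <= chain_b.L else chain_b)
    ma = _neighbor_orders(chain_a.points, K)
    mb = _neighbor_orders(chain_b.points, K)
    fa = chain_a.points[ma]  # (LA, K, 3)
    fb = chain_b.points[mb]
    ca = fa.mean(axis=1)
    cb = fb.mean(axis=1)
    fac = fa - ca[:, None, :]
    fbc = fb - cb[:, None, :]
    h = np.einsum("ikx,jky->ijxy", fac, fbc)
    u, _, vt = np.linalg.svd(h)
    v = vt.transpose(0, 1, 3, 2)
    ut = u.transpose(0, 1, 3, 2)
    sign = np.sign(np.linalg.det(v @ ut))
    corr = np.broadcast_to(np.eye(3), v.shape).copy()
    corr[..., 2, 2] = sign
    rot = v @ corr @ ut  # rot[i, j] maps A-fragment frame onto B's
    a_last = fac[:, K - 1, :]  # rank-K member, centered
    b_last = fbc[:, K - 1, :]
    moved = np.einsum("ijxy,iy->ijx", rot, a_last)
    d = np.linalg.norm(moved - b_last[None, :, :], axis=2)
    return 1.0 / (1.0 + (d / d0) ** 2)


def _greedy_assign(scores: np.ndarray, floor: float) -> List[Tuple[int, int]]:
    s = scores.astype(float).copy()
    pairs = []
    for _ in range(min(s.shape)):
        flat = int(np.argmax(s))  # first max: lowest i, then lowest j
        i, j = divmod(flat, s.shape[1])
        if s[i, j] <= floor:
            break
        pairs.append((i, j))
        s[i, :] = -np.inf
        s[:, j] = -np.inf
    return pairs


def swap_refine(
    scores: np.ndarray,
    pairs: Sequence[Tuple[int, int]],
    allowed: Optional[Callable] = None,
    use_triples: bool = True,
    floor: float = 0.0,
) -> List[Tuple[int, int]]:
    """Improve a one-to-one assignment by best-improvement local search.

    The matrix is zero-padded to a square so that reassignments to
    unassigned rows/columns become ordinary exchanges with zero-scoring
    dummy partners.  Pair exchanges run first; 3-cycle rotations are scanned
    only once no exchange improves (they are what closes the gap to the
    exhaustive optimum on tiny matrices).  ``allowed(old_pair_1, old_pair_2,
    current_pairs)`` may veto exchanges (used by the sNS element
    constraint); vetoed moves are skipped in gain order.
    """
    n, m = scores.shape
    N = max(n, m)
    s = np.zeros((N, N))
    s[:n, :m] = scores
    perm = np.full(N, -1, dtype=int)
    for i, j in pairs:
        perm[i] = j
    free = sorted(set(range(N)) - {j for _, j in pairs})
    for a in range(N):
        if perm[a] < 0:
            perm[a] = free.pop(0)

    def real_pairs():
        return [
            (a, int(perm[a]))
            for a in range(n)
            if perm[a] < m and s[a, perm[a]] > floor
        ]

    def old_pair(a):
        i = a if a < n else None
        j = int(perm[a]) if perm[a] < m else None
        return (i, j)

    rows = np.arange(N)
    max_moves = 10 * N + 100
    for _ in range(max_moves):
        p = s[rows[:, None], perm[None, :]]  # p[a, b] = s[a, perm[b]]
        diag = s[rows, perm]
        g2 = p + p.T - diag[:, None] - diag[None, :]
        np.fill_diagonal(g2, -np.inf)
        moved = False
        if allowed is None:
            a, b = np.unravel_index(int(np.argmax(g2)), g2.shape)
            if g2[a, b] > _GAIN_TOL:
                perm[a], perm[b] = perm[b], perm[a]
                moved = True
        else:
            order = np.argsort(g2, axis=None)[::-1]
            current = real_pairs()
            for flat in order:
                a, b = np.unravel_index(int(flat), g2.shape)
                if g2[a, b] <= _GAIN_TOL:
                    break
                if allowed(old_pair(a), old_pair(b), current):
                    perm[a], perm[b] = perm[b], perm[a]
                    moved = True
                    break
        if not moved and use_triples and allowed is None:
            best_gain, best = _GAIN_TOL, None
            chunk = 64
            for a0 in range(0, N, chunk):
                asl = slice(a0, min(a0 + chunk, N))
                g3 = (
                    p[asl][:, :, None]
                    + p[None, :, :]
                    + p[:, asl].T[:, None, :]
                    - diag[asl][:, None, None]
                    - diag[None, :, None]
                    - diag[None, None, :]
                )
                flat = int(np.argmax(g3))
                a, b, c = np.unravel_index(flat, g3.shape)
                if g3[a, b, c] > best_gain:
                    best_gain = float(g3[a, b, c])
                    best = (a0 + a, b, c)
            if best is not None:
                a, b, c = best
                perm[a], perm[b], perm[c] = perm[b], perm[c], perm[a]
                moved = True
        if not moved:
            break
    return real_pairs()


def egs_assign(
    scores: np.ndarray,
    floor: float = 0.0,
    use_triples: bool = True,
) -> Assignment:
    """Enhanced Greedy Search: greedy maximum-entry assignment followed by
    swap refinement.  Entries must be finite; entries <= ``floor`` are never
    assigned."""
    s = np.asarray(scores, dtype=float)
    if s.ndim != 2 or s.size == 0:
        raise ValueError("score matrix must be non-empty and 2-D")
    if not np.isfinite(s).all():
        raise ValueError("score matrix must be finite")
    pairs = _greedy_assign(s, floor)
    pairs = swap_refine(s, pairs, use_triples=use_triples, floor=floor)
    total = float(sum(s[i, j] for i, j in pairs))
    return Assignment(pairs=sorted(pairs), total_score=total)


def _elements_monotonic(mapping, inverse, elements_a, elements_b) -> bool:
    for start, end in elements_a:
        last = -1
        for i in range(start, end):
            j = mapping.get(i)
            if j is None:
                continue
            if j <= last:
                return False
            last = j
    for start, end in elements_b:
        last = -1
        for j in range(start, end):
            i = inverse.get(j)
            if i is None:
                continue
            if i <= last:
                return False
            last = i
    return True


def sse_swap_allowed(
    current_pairs: Sequence[Tuple[int, int]],
    swap: Tuple[Tuple[Optional[int], Optional[int]], Tuple[Optional[int], Optional[int]]],
    elements_a: Sequence[Tuple[int, int]],
    elements_b: Sequence[Tuple[int, int]],
) -> bool:
    """True iff the proposed partner exchange keeps every secondary-structure
    element's aligned partners strictly monotonic in sequence order.

    ``swap`` holds the two current pairs whose partners would be exchanged;
    ``None`` in a slot marks an unassigned row/column (a reassignment).
    """
    (i1, j1), (i2, j2) = swap
    mapping = dict(current_pairs)
    for i, j in ((i1, j1), (i2, j2)):
        if i is not None and mapping.get(i) == j:
            del mapping[i]
    if i1 is not None and j2 is not None:
        mapping[i1] = j2
    if i2 is not None and j1 is not None:
        mapping[i2] = j1
    inverse = {j: i for i, j in mapping.items()}
    return _elements_monotonic(mapping, inverse, elements_a, elements_b)


def _finalize_ns(
    chain_a, chain_b, state, d0, L_norm, config
) -> Tuple[Alignment, Transform, ScoreReport]:
    """Distance-filter an NS result and rebuild scores on the kept pairs."""
    alignment, transform, _ = state
    if alignment is None:
        raise ValueError("non-sequential search produced no alignment")
    ia, jb = alignment.arrays()
    d = np.linalg.norm(
        transform.apply(chain_a.points[ia]) - chain_b.points[jb], axis=1
    )
    keep = d < config.ns_distance_filter
    if 3 <= keep.sum() < len(d):
        pairs = list(zip(ia[keep].tolist(), jb[keep].tolist()))
        filtered = Alignment(pairs=pairs, is_sequential=False)
        t_f, _ = optimal_tm_superposition(
            chain_a, chain_b, filtered, d0, L_norm, refine=config.refine_superposition
        )
        # keep the filtered result only when re-fitting on the near pairs does
        # not lose TM-score; otherwise the far pairs' small contributions stand
        if _short_tm(chain_a, chain_b, filtered, t_f) >= _short_tm(
            chain_a, chain_b, alignment, transform
        ):
            alignment, transform = filtered, t_f
    final = Alignment(
        pairs=alignment.pairs, is_sequential=is_sequential_pairs(alignment.pairs)
    )
    report = score_report(chain_a, chain_b, final, transform)
    return final, transform, report


def _short_tm(chain_a, chain_b, alignment, transform) -> float:
    rep = score_report(chain_a, chain_b, alignment, transform)
    return rep.tm_norm_a if chain_a.L <= chain_b.L else rep.tm_norm_b


def align_fns(
    chain_a: CoordinateChain,
    chain_b: CoordinateChain,
    config: Optional[AlignConfig] = None,
) -> Tuple[Alignment, Transform, ScoreReport]:
    """Fully non-sequential alignment.

    Seeds from EGS on the K-neighborhood fragment matrix, then iterates
    TM-optimal superposition and EGS re-assignment on the point-distance
    score matrix until the pair set repeats; the best-TM state ever visited
    wins.  Pairs farther than the configured distance filter are dropped
    before reporting.
    """
    config = config or AlignConfig()
    K = config.k_neighbors
    if chain_a.L < K or chain_b.L < K:
        raise ValueError("chain too short for fNS seeding")
    L_norm = min(chain_a.L, chain_b.L)
    d0 = d0_for_chain(chain_a if chain_a.L <= chain_b.L else chain_b)
    matrix0 = fns_initial_scores(chain_a, chain_b, K=K, d0=d0)
    seed_pairs = egs_assign(matrix0, floor=config.greedy_floor).pairs
    seed = Alignment(pairs=seed_pairs, is_sequential=False)

    def realign(matrix, _current):
        m = matrix0 if config.fns_iteration_matrix == "fragment" else matrix
        pairs = egs_assign(m, floor=config.greedy_floor).pairs
        return Alignment(pairs=pairs, is_sequential=False)

    state = _iterate_from_seed(chain_a, chain_b, seed, d0, L_norm, config, realign)
    return _finalize_ns(chain_a, chain_b, state, d0, L_norm, config)


def align_sns(
    chain_a: CoordinateChain,
    chain_b: CoordinateChain,
    config: Optional[AlignConfig] = None,
) -> Tuple[Alignment, Transform, ScoreReport]:
    """Semi-non-sequential alignment.

    Starts from the SQ result, then iterates superposition -> NW alignment
    -> EGS swap stage, where an exchange is vetoed if it would make any
    secondary-structure element's partners non-sequential.  Because the SQ
    seed is the first state evaluated, the returned TM-score never falls
    below the SQ one.
    """
    config = config or AlignConfig()
    seed, _, _ = align_sq(chain_a, chain_b, config)
    L_norm = min(chain_a.L, chain_b.L)
    d0 = d0_for_chain(chain_a if chain_a.L <= chain_b.L else chain_b)
    elements_a = assign_secondary_structure(chain_a).elements
    elements_b = assign_secondary_structure(chain_b).elements

    def gate(pair1, pair2, current):
        return sse_swap_allowed(current, (pair1, pair2), elements_a, elements_b)

    # NW pairs scoring below the similarity at the NS distance filter are
    # treated as unassigned before the swap stage: free-end-gap NW matches
    # every residue rather than pay internal gaps, and those junk matches
    # would otherwise pin both partners and veto every element-crossing swap
    swap_floor = 1.0 / (1.0 + (config.ns_distance_filter / d0) ** 2)

    def realign(matrix, _current):
        nw, _ = nw_align(matrix, config.gap_penalty)
        near = [(i, j) for i, j in nw.pairs if matrix[i, j] > swap_floor]
        pairs = swap_refine(
            matrix, near, allowed=gate, use_triples=False, floor=swap_floor
        )
        return Alignment(pairs=pairs, is_sequential=False)

    state = _iterate_from_seed(
        chain_a,
        chain_b,
        Alignment(pairs=seed.pairs, is_sequential=False),
        d0,
        L_norm,
        config,
        realign,
    )
    return _finalize_ns(chain_a, chain_b, state, d0, L_norm, config)
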