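"""Score functions: d0 scales, TM-score, score matrices, structure overlap,
and the fragment-enumeration search for the TM-optimal superposition.

The TM-score of an alignment with per-pair distances ``d_i`` is

    TM = (1 / L_norm) * sum_i 1 / (1 + (d_i / d0)^2)

where ``L_norm`` is the length of the normalizing chain and ``d0`` a
length-dependent distance scale that makes the score independent of molecule
size.  Scores of 1 mean identical structures; TM >= 0.5 (proteins) or
TM >= 0.45 (RNA) marks a pair sharing the same topology.
"""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .core import (
    PROTEIN,
    Alignment,
    CoordinateChain,
    ScoreReport,
    Transform,
    is_sequential_pairs,
)
from .geometry import kabsch

SO_CUTOFF = 3.5  # Angstrom, strict inequality
TM_SIGNIFICANT_PROTEIN = 0.5
TM_SIGNIFICANT_NUCLEIC = 0.45


def d0_protein(L: int) -> float:
    """Length-dependent TM-score distance scale for proteins (Angstrom)."""
    if L < 1:
        raise ValueError("length must be >= 1")
    if L > 21:
        return 1.24 * (L - 15.0) ** (1.0 / 3.0) - 1.8
    return 0.5


def d0_nucleic(L: int) -> float:
    """Length-dependent TM-score distance scale for nucleic acids (Angstrom)."""
    if L < 1:
        raise ValueError("length must be >= 1")
    if L >= 30:
        return 0.6 * np.sqrt(L - 0.5) - 2.5
    if L >= 24:
        return 0.7
    if L >= 20:
        return 0.6
    if L >= 16:
        return 0.5
    if L >= 12:
        return 0.4
    return 0.3


def d0_for_chain(chain: CoordinateChain) -> float:
    """d0 for normalizing by this chain (alignment units as the length)."""
    if chain.molecule_type == PROTEIN:
        return d0_protein(chain.L)
    return d0_nucleic(chain.L)


def tm_score(distances, L_norm: int, d0: float) -> float:
    """TM-score of the aligned-pair distances under normalizing length L_norm."""
    d = np.asarray(distances, dtype=float)
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    if L_norm < len(d):
        raise ValueError("L_norm smaller than the number of aligned pairs")
    if L_norm < 1:
        raise ValueError("L_norm must be >= 1")
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / L_norm)


def residue_tm_matrix(points_a_transformed, points_b, d0: float) -> np.ndarray:
    """Residue-level TM-score matrix: entry (i, j) = 1 / (1 + (dist/d0)^2)."""
    if d0 <= 0:
        raise ValueError("d0 must be positive")
    dist = cdist(np.asarray(points_a_transformed, float), np.asarray(points_b, float))
    return 1.0 / (1.0 + (dist / d0) ** 2)


def structure_overlap(distances, L_A: int, L_B: int) -> float:
    """Structure overlap: percent of pairs closer than 3.5 A, over min(L_A, L_B)."""
    if L_A < 1 or L_B < 1:
        raise ValueError("chain lengths must be >= 1")
    d = np.asarray(distances, dtype=float)
    return float(100.0 * np.count_nonzero(d < SO_CUTOFF) / min(L_A, L_B))


def _window_lengths(n: int) -> list:
    """Halving fragment-length schedule n, ceil(n/2), ..., down to 4."""
    if n < 4:
        return [n]
    lens = []
    l = n
    while l > 4:
        lens.append(l)
        l = -(-l // 2)
    lens.append(4)
    return lens


def _pair_distances(pa: np.ndarray, pb: np.ndarray, t: Transform) -> np.ndarray:
    return np.linalg.norm(t.apply(pa) - pb, axis=1)


def optimal_tm_superposition(
    chain_a: CoordinateChain,
    chain_b: CoordinateChain,
    alignment: Alignment,
    d0: float,
    L_norm: int,
    refine: bool = True,
) -> Tuple[Transform, float]:
    """Search for the rigid superposition maximizing the alignment's TM-score.

    Exact TM-optimal superposition is intractable, so the search enumerates
    every contiguous window of the aligned-pair list (ordered by chain-A
    index) at lengths L_ali, ceil(L_ali/2), ceil(L_ali/4), ..., 4, Kabsch-fits
    each window, and scores the full alignment under each candidate.  An
    optional greedy refinement then re-fits on the pairs within a distance
    cutoff of the best candidate until the selected subset repeats, keeping
    the best TM ever seen.
    """
    ia, jb = alignment.arrays()
    n = len(ia)
    if n < 3:
        raise ValueError("need at least 3 aligned pairs for superposition")
    pa = chain_a.points[ia]
    pb = chain_b.points[jb]

    best_t: Optional[Transform] = None
    best_tm = -1.0
    for wlen in _window_lengths(n):
        for start in range(0, n - wlen + 1):
            t = kabsch(pa[start : start + wlen], pb[start : start + wlen])
            tm = tm_score(_pair_distances(pa, pb, t), L_norm, d0)
            if tm > best_tm:
                best_tm, best_t = tm, t

    if refine and best_t is not None:
        cutoff = max(d0, 4.5)
        t = best_t
        seen = set()
        for _ in range(30):
            d = _pair_distances(pa, pb, t)
            sel = d < cutoff
            if sel.sum() < 3:
                cutoff *= 1.5
                continue
            key = sel.tobytes()
            if key in seen:
                break
            seen.add(key)
            t = kabsch(pa[sel], pb[sel])
            tm = tm_score(_pair_distances(pa, pb, t), L_norm, d0)
            if tm > best_tm:
                best_tm, best_t = tm, t
    return best_t, best_tm


def sequence_identity(chain_a: CoordinateChain, chain_b: CoordinateChain, pairs) -> float:
    """Fraction of aligned pairs whose unit residue names are identical."""
    if not pairs:
        return 0.0
    same = sum(1 for i, j in pairs if chain_a.unit_names[i] == chain_b.unit_names[j])
    return same / len(pairs)


def score_report(
    chain_a: CoordinateChain,
    chain_b: CoordinateChain,
    alignment: Alignment,
    transform: Transform,
) -> ScoreReport:
    """Assemble the full score summary for an alignment under a transform.

    Each TM normalization uses the d0 of its own normalizing chain, per the
    convention that a pairwise alignment carries two TM-scores.
    """
    ia, jb = alignment.arrays()
    pa, pb = chain_a.points[ia], chain_b.points[jb]
    d = _pair_distances(pa, pb, transform)
    d0a, d0b = d0_for_chain(chain_a), d0_for_chain(chain_b)
    tm_a = tm_score(d, chain_a.L, d0a)
    tm_b = tm_score(d, chain_b.L, d0b)
    rms = float(np.sqrt(np.mean(d**2))) if len(d) else 0.0
    return ScoreReport(
        tm_norm_a=tm_a,
        tm_norm_b=tm_b,
        tm_avg=0.5 * (tm_a + tm_b),
        rmsd=rms,
        l_ali=len(d),
        so_percent=structure_overlap(d, chain_a.L, chain_b.L),
        seq_identity=sequence_identity(chain_a, chain_b, list(zip(ia, jb))),
        is_sequential=is_sequential_pairs(list(zip(ia, jb))),
        l_a=chain_a.L,
        l_b=chain_b.L,
        d0_a=d0a,
        d0_b=d0b,
    )
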