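"""Secondary-structure assignment from representative-atom geometry.

Proteins get one of four states (helix H, strand E, turn T, coil C) from the
six pairwise C-alpha distances within the 5-residue window centred on each
residue.  Nucleic acids get a three-state base-pairing annotation (unpaired,
paired with a downstream base '(', paired with an upstream base ')') from
C3'-C3' geometry plus Watson-Crick/wobble complementarity.  Both feed the
initial alignments and the per-element monotonicity constraint of the
semi-non-sequential mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import PROTEIN, CoordinateChain

HELIX, STRAND, TURN, COIL = "H", "E", "T", "C"
UNPAIRED, PAIR_DOWN, PAIR_UP = ".", "(", ")"

# reference distances (A) and half-widths for the 4-state assignment
_HELIX_REF = {"d15": 6.37, "d14": 5.18, "d25": 5.18, "d13": 5.45, "d24": 5.45, "d35": 5.45}
_HELIX_TOL = 2.1
_STRAND_REF = {"d15": 13.0, "d14": 10.4, "d25": 10.4, "d13": 6.1, "d24": 6.1, "d35": 6.1}
_STRAND_TOL = 1.42
_TURN_D15 = 8.0

PAIR_DIST_MIN, PAIR_DIST_MAX = 12.5, 15.0
PAIR_DIST_MID = 0.5 * (PAIR_DIST_MIN + PAIR_DIST_MAX)
ALLOWED_PAIRS = {("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"), ("A", "U"), ("U", "A")}

MIN_PROTEIN_ELEMENT = 3  # residues per reported helix/strand element
MIN_NUCLEIC_ELEMENT = 2  # consecutive paired nucleotides per element


@dataclass
class SSEAnnotation:
    """Per-unit secondary-structure states plus the element runs used by sNS.

    ``elements`` lists half-open ``(start, end)`` runs of helix/strand
    (protein) or consecutive paired (nucleic) states.
    """

    states: List[str]
    elements: List[Tuple[int, int]]

    def to_string(self) -> str:
        return "".join(self.states)


def ca_distance_profile(points: np.ndarray, i: int) -> dict:
    """The six C-alpha distances among residues i-2 ... i+2."""
    p = points

    def d(a, b):
        return float(np.linalg.norm(p[a] - p[b]))

    return {
        "d13": d(i - 2, i),
        "d14": d(i - 2, i + 1),
        "d15": d(i - 2, i + 2),
        "d24": d(i - 1, i + 1),
        "d25": d(i - 1, i + 2),
        "d35": d(i, i + 2),
    }


def classify_profile(prof: dict) -> str:
    """4-state call for one interior residue from its distance profile."""
    if max(abs(prof[k] - v) for k, v in _HELIX_REF.items()) < _HELIX_TOL:
        return HELIX
    if max(abs(prof[k] - v) for k, v in _STRAND_REF.items()) < _STRAND_TOL:
        return STRAND
    if prof["d15"] < _TURN_D15:
        return TURN
    return COIL


def _runs(states: List[str], targets, min_len: int) -> List[Tuple[int, int]]:
    elements = []
    start = None
    prev = None
    for idx, s in enumerate(states + ["\0"]):
        if s in targets and s == prev:
            continue
        if start is not None and idx - start >= min_len:
            elements.append((start, idx))
        start = idx if s in targets else None
        prev = s
    return elements


def assign_protein_ss(chain: CoordinateChain) -> SSEAnnotation:
    """Assign helix/strand/turn/coil per residue from C-alpha distances.

    Helix is tested before strand, so helix wins any (rare) overlap of the
    two criteria.  The two residues at each terminus lack a full window and
    are assigned coil.
    """
    if chain.molecule_type != PROTEIN:
        raise ValueError("protein secondary structure requires a protein chain")
    L = chain.L
    states = [COIL] * L
    for i in range(2, L - 2):
        states[i] = classify_profile(ca_distance_profile(chain.points, i))
    elements = _runs(states, {HELIX}, MIN_PROTEIN_ELEMENT) + _runs(
        states, {STRAND}, MIN_PROTEIN_ELEMENT
    )
    elements.sort()
    return SSEAnnotation(states=states, elements=elements)


def _complementary(a: str, b: str) -> bool:
    a = "U" if a in ("T", "DT", "DU") else a.lstrip("D")
    b = "U" if b in ("T", "DT", "DU") else b.lstrip("D")
    return (a, b) in ALLOWED_PAIRS


def assign_rna_basepairs(chain: CoordinateChain) -> SSEAnnotation:
    """Assign base-pairing states from C3' geometry and residue identity.

    A candidate pair (i, j) needs (a) a C3'-C3' distance within
    [12.5, 15.0] A, (b) G:C, G:U or A:U complementarity (T read as U), and
    (c) a stacked neighbour: (i-1, j+1) or (i+1, j-1) must also satisfy
    (a)+(b), which excludes singleton pairs.  Each nucleotide keeps at most
    one partner; conflicts go to the pair whose distance is closest to the
    13.75 A window midpoint, then to the lowest index.
    """
    if chain.molecule_type == PROTEIN:
        raise ValueError("base pairing requires a nucleic-acid chain")
    L = chain.L
    names = chain.unit_names
    dist = squareform(pdist(chain.points))
    cand = np.zeros((L, L), dtype=bool)
    for i in range(L):
        for j in range(i + 1, L):
            if PAIR_DIST_MIN <= dist[i, j] <= PAIR_DIST_MAX and _complementary(names[i], names[j]):
                cand[i, j] = True

    def ok(i, j):
        return 0 <= i < L and 0 <= j < L and i < j and cand[i, j]

    survivors = [
        (i, j)
        for i in range(L)
        for j in range(i + 1, L)
        if cand[i, j] and (ok(i - 1, j + 1) or ok(i + 1, j - 1))
    ]
    survivors.sort(key=lambda p: (abs(dist[p[0], p[1]] - PAIR_DIST_MID), p[0], p[1]))
    partner = {}
    for i, j in survivors:
        if i not in partner and j not in partner:
            partner[i] = j
            partner[j] = i
    states = [UNPAIRED] * L
    for i, j in partner.items():
        states[i] = PAIR_DOWN if j > i else PAIR_UP
    elements = _runs(
        [s if s == UNPAIRED else "P" for s in states], {"P"}, MIN_NUCLEIC_ELEMENT
    )
    return SSEAnnotation(states=states, elements=elements)


def assign_secondary_structure(chain: CoordinateChain) -> SSEAnnotation:
    if chain.molecule_type == PROTEIN:
        return assign_protein_ss(chain)
    return assign_rna_basepairs(chain)
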