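"""Synthetic ground-truth structures for testing and benchmarking.

Chains are assembled from parametric elements — ideal alpha-helices
(1.5 A rise, 2.3 A radius, 100 deg/residue), extended zigzag strands
(3.3 A axial advance, alternating 1 A lateral offset), random-walk coil at
3.8 A steps, and an idealized antiparallel nucleic-acid duplex whose
cross-strand C3'-C3' distances sit inside the 12.5-15.0 A pairing window.
Every generator is a pure function of its spec and seed, and every derived
fixture (rigid copy, circular permutant, fragment swap) carries the exact
ground-truth correspondence, so recovery can be scored exactly.

The duplex is a geometric stand-in for A-form RNA, not a physically
accurate model: it reproduces the distance/complementarity rules the
pairing assignment tests, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.transform import Rotation

from .core import PROTEIN, RNA, CoordinateChain, Residue, Transform

AMINO_NAMES = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
_COMPLEMENT = {"G": "C", "C": "G", "A": "U", "U": "A"}

HELIX_RISE, HELIX_RADIUS, HELIX_TWIST_DEG = 1.5, 2.3, 100.0
STRAND_ADVANCE, STRAND_OFFSET = 3.3, 1.0
STEP = 3.8  # junction / coil step, the C-alpha virtual bond length


@dataclass
class FixtureSpec:
    """Recipe for one synthetic chain: ordered (kind, length) elements plus
    coordinate noise and a seed that fully determines the output."""

    layout: List[Tuple[str, int]]
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for kind, length in self.layout:
            if kind not in ("helix", "strand", "coil", "na_duplex"):
                raise ValueError(f"unknown element kind {kind!r}")
            if length < 1:
                raise ValueError("element lengths must be >= 1")


def helix_points(n: int) -> np.ndarray:
    k = np.arange(n)
    theta = np.deg2rad(HELIX_TWIST_DEG) * k
    return np.column_stack(
        [HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), HELIX_RISE * k]
    )


def strand_points(n: int) -> np.ndarray:
    k = np.arange(n)
    return np.column_stack(
        [STRAND_OFFSET * (-1.0) ** k, np.zeros(n), STRAND_ADVANCE * k]
    )


def coil_points(n: int, rng: np.random.Generator) -> np.ndarray:
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    pts = np.cumsum(STEP * steps, axis=0)
    return pts - pts[0]


def duplex_geometry(n: int) -> Tuple[np.ndarray, int]:
    """2n C3' positions for an antiparallel duplex: residue i pairs with
    2n-1-i at exactly 13.75 A; within-strand spacing 5.5 A."""
    step, sep = 5.5, 13.75
    strand1 = np.column_stack([step * np.arange(n), np.zeros(n), np.zeros(n)])
    x2 = step * (2 * n - 1 - np.arange(n, 2 * n))
    strand2 = np.column_stack([x2, np.full(n, sep), np.zeros(n)])
    return np.vstack([strand1, strand2]), 2 * n


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(random_state=np.random.RandomState(rng.integers(2**31 - 1))).as_matrix()


def make_chain(spec: FixtureSpec, name: str = "fixture") -> Tuple[CoordinateChain, List[str]]:
    """Build the chain and its ground-truth per-residue states.

    Protein states are H/E/C by element kind; a duplex chain gets '('/')'
    for the two strands.  Protein and nucleic elements cannot be mixed.
    """
    kinds = {k for k, _ in spec.layout}
    if "na_duplex" in kinds and kinds != {"na_duplex"}:
        raise ValueError("na_duplex cannot be mixed with protein elements")
    rng = np.random.default_rng(spec.seed)

    if kinds == {"na_duplex"}:
        pieces, states = [], []
        offset = np.zeros(3)
        for _, length in spec.layout:
            pts, total = duplex_geometry(length)
            pieces.append(pts + offset)
            offset = offset + np.array([0.0, 40.0, 0.0])
            states += ["("] * length + [")"] * length
        points = np.vstack(pieces)
        seq: List[str] = []
        for _, length in spec.layout:
            half = [str(x) for x in rng.choice(list("GACU"), size=length)]
            seq += half + [_COMPLEMENT[x] for x in reversed(half)]
        points = points + rng.normal(0.0, spec.noise_sigma, points.shape)
        residues = [
            Residue(index=i, name=seq[i], author_id=str(i + 1), coords={"C3'": points[i]})
            for i in range(len(points))
        ]
        chain = CoordinateChain(
            molecule_type=RNA,
            residues=residues,
            points=points,
            unit_labels=[f"{i + 1}:{seq[i]}:C3'" for i in range(len(points))],
            unit_names=seq,
            unit_residue=list(range(len(points))),
            name=name,
        )
        return chain, states

    pieces, states = [], []
    end = None
    for kind, length in spec.layout:
        if kind == "helix":
            local, state = helix_points(length), "H"
        elif kind == "strand":
            local, state = strand_points(length), "E"
        else:
            local, state = coil_points(length, rng), "C"
        rot = _random_rotation(rng)
        local = local @ rot.T
        if end is None:
            start = np.zeros(3)
        else:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            start = end + STEP * direction
        local = local - local[0] + start
        pieces.append(local)
        end = local[-1]
        states += [state] * length
    points = np.vstack(pieces)
    points = points + rng.normal(0.0, spec.noise_sigma, points.shape)
    seq = [str(x) for x in rng.choice(AMINO_NAMES, size=len(points))]
    residues = [
        Residue(index=i, name=seq[i], author_id=str(i + 1), coords={"CA": points[i]})
        for i in range(len(points))
    ]
    chain = CoordinateChain(
        molecule_type=PROTEIN,
        residues=residues,
        points=points,
        unit_labels=[f"{i + 1}:{seq[i]}:CA" for i in range(len(points))],
        unit_names=seq,
        unit_residue=list(range(len(points))),
        name=name,
    )
    return chain, states


def _reorder(chain: CoordinateChain, order: Sequence[int], name: str) -> CoordinateChain:
    if len(chain.points) != len(chain.residues):
        raise ValueError("reordering requires one point per residue")
    order = list(order)
    residues = []
    for new_idx, old in enumerate(order):
        src = chain.residues[old]
        residues.append(
            Residue(index=new_idx, name=src.name, author_id=src.author_id, coords=dict(src.coords))
        )
    return CoordinateChain(
        molecule_type=chain.molecule_type,
        residues=residues,
        points=chain.points[order],
        unit_labels=[chain.unit_labels[o] for o in order],
        unit_names=[chain.unit_names[o] for o in order],
        unit_residue=list(range(len(order))),
        name=name,
    )


def circular_permute(chain: CoordinateChain, cut: int) -> Tuple[CoordinateChain, Dict[int, int]]:
    """Rotate the residue order by ``cut`` (coordinates untouched).

    Returns the permuted chain and the old-index -> new-index map; the new
    chain starts at old residue ``cut``.
    """
    L = chain.L
    if not 0 < cut < L:
        raise ValueError("cut must satisfy 0 < cut < L")
    order = list(range(cut, L)) + list(range(cut))
    mapping = {old: (old - cut) % L for old in range(L)}
    return _reorder(chain, order, f"{chain.name}|cp{cut}"), mapping


def swap_fragments(
    chain: CoordinateChain,
    range1: Tuple[int, int],
    range2: Tuple[int, int],
) -> Tuple[CoordinateChain, Dict[int, int]]:
    """Exchange the sequence order of two disjoint half-open residue ranges
    (coordinates untouched); returns the chain and old -> new index map."""
    (s1, e1), (s2, e2) = sorted([tuple(range1), tuple(range2)])
    L = chain.L
    if not (0 <= s1 < e1 <= s2 < e2 <= L):
        raise ValueError("ranges must be disjoint, ordered and in bounds")
    order = (
        list(range(0, s1))
        + list(range(s2, e2))
        + list(range(e1, s2))
        + list(range(s1, e1))
        + list(range(e2, L))
    )
    mapping = {old: new for new, old in enumerate(order)}
    return _reorder(chain, order, f"{chain.name}|swap"), mapping


def rigid_copy(
    chain: CoordinateChain,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> Tuple[CoordinateChain, Transform]:
    """Random proper rotation + translation of the chain, plus i.i.d.
    Gaussian coordinate noise; returns the copy and the transform used."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    rot = _random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, 3)
    t = Transform(rot, trans)
    points = t.apply(chain.points) + rng.normal(0.0, noise_sigma, chain.points.shape)
    residues = []
    for idx, (src, pos) in enumerate(zip(chain.residues, points)):
        coords = dict(src.coords)
        rep = next(iter(coords))
        coords = {rep: pos}
        residues.append(Residue(index=idx, name=src.name, author_id=src.author_id, coords=coords))
    copy = CoordinateChain(
        molecule_type=chain.molecule_type,
        residues=residues,
        points=points,
        unit_labels=list(chain.unit_labels),
        unit_names=list(chain.unit_names),
        unit_residue=list(chain.unit_residue),
        name=f"{chain.name}|copy{seed}",
    )
    return copy, t


def helix_bundle(
    n_helices: int = 4,
    helix_len: int = 13,
    linker_len: int = 3,
    spacing: float = 9.0,
    seed: int = 0,
    noise_sigma: float = 0.0,
) -> Tuple[CoordinateChain, List[Tuple[int, int]]]:
    """An up-down helix bundle: parallel axes on a line, alternating
    direction, short straight linkers.  Returns the chain and the half-open
    residue range of each helix, for building permuted-order variants whose
    true correspondence stays monotonic within every helix.
    """
    rng = np.random.default_rng(seed)
    pieces: List[np.ndarray] = []
    ranges: List[Tuple[int, int]] = []
    pos = 0
    for k in range(n_helices):
        h = helix_points(helix_len)
        if k % 2 == 1:
            h = h[::-1] @ np.diag([1.0, -1.0, -1.0])  # run back down
        h = h + np.array([k * spacing, 0.0, 0.0]) - np.array([0.0, 0.0, h[0, 2]])
        if pieces:
            prev_end = pieces[-1][-1]
            gaps = np.linspace(prev_end, h[0], linker_len + 2)[1:-1]
            pieces.append(gaps)
            pos += linker_len
        ranges.append((pos, pos + helix_len))
        pieces.append(h)
        pos += helix_len
    points = np.vstack(pieces)
    points = points + rng.normal(0.0, noise_sigma, points.shape)
    seq = [str(x) for x in rng.choice(AMINO_NAMES, size=len(points))]
    residues = [
        Residue(index=i, name=seq[i], author_id=str(i + 1), coords={"CA": points[i]})
        for i in range(len(points))
    ]
    chain = CoordinateChain(
        molecule_type=PROTEIN,
        residues=residues,
        points=points,
        unit_labels=[f"{i + 1}:{seq[i]}:CA" for i in range(len(points))],
        unit_names=seq,
        unit_residue=list(range(len(points))),
        name=f"bundle_{n_helices}x{helix_len}",
    )
    return chain, ranges


def two_helix_chain(
    n: int = 60, seed: int = 0, noise_sigma: float = 0.0
) -> CoordinateChain:
    """The canonical 60-residue two-helix test chain (two equal helices
    joined by a short coil linker)."""
    per = (n - 4) // 2
    spec = FixtureSpec(
        layout=[("helix", per), ("coil", n - 2 * per), ("helix", per)],
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return make_chain(spec, name=f"two_helix_{n}")[0]
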