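"""Core data containers shared across the alignment pipeline.

A structure comparison runs on three kinds of objects: a
:class:`CoordinateChain` (the ordered representative-atom point cloud of one
molecule), an :class:`Alignment` (a one-to-one residue correspondence between
two chains), and a :class:`Transform` (the proper rigid-body motion placing
one chain in the frame of the other).  A finished comparison is summarised in
a :class:`ScoreReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

PROTEIN = "protein"
RNA = "rna"
DNA = "dna"

MOLECULE_TYPES = (PROTEIN, RNA, DNA)


@dataclass
class Residue:
    """One polymer residue with its atom coordinates.

    ``index`` is the 0-based ordinal position in the chain (contiguous, file
    order); ``author_id`` keeps the original residue number plus insertion
    code as text, for output only.  ``coords`` maps atom names to (3,) arrays
    in Angstrom.
    """

    index: int
    name: str
    author_id: str
    coords: dict = field(default_factory=dict)

    def atom(self, name: str) -> Optional[np.ndarray]:
        return self.coords.get(name)


@dataclass
class Transform:
    """Proper rigid-body motion ``y = R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @classmethod
    def identity(cls) -> "Transform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "Transform") -> "Transform":
        """Return the transform applying ``other`` first, then ``self``."""
        return Transform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "Transform":
        rt = self.rotation.T
        return Transform(rt, -rt @ self.translation)

    def is_proper(self, tol: float = 1e-8) -> bool:
        r = self.rotation
        return (
            np.allclose(r.T @ r, np.eye(3), atol=tol)
            and abs(np.linalg.det(r) - 1.0) <= tol
        )


@dataclass
class CoordinateChain:
    """Ordered representative-atom coordinates for one molecule.

    ``points`` holds one 3D position per alignment unit (usually one per
    residue; two per nucleotide under the "PC4'" convention).  ``unit_labels``
    map each point back to its source residue and atom, ``unit_names`` carry
    the residue name of each unit (for sequence identity), and
    ``unit_residue`` the 0-based source residue index.
    """

    molecule_type: str
    residues: list
    points: np.ndarray
    unit_labels: list
    unit_names: list
    unit_residue: list
    name: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.molecule_type not in MOLECULE_TYPES:
            raise ValueError(f"unknown molecule type {self.molecule_type!r}")
        if len(self.points) < 1:
            raise ValueError("chain has no alignable points")
        if not (len(self.points) == len(self.unit_labels) == len(self.unit_names)):
            raise ValueError("points and unit labels disagree in length")
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite coordinates in chain")

    @property
    def L(self) -> int:
        return len(self.points)

    @property
    def is_nucleic(self) -> bool:
        return self.molecule_type in (RNA, DNA)


def check_one_to_one(pairs: Sequence) -> None:
    ia = [p[0] for p in pairs]
    jb = [p[1] for p in pairs]
    if len(set(ia)) != len(ia) or len(set(jb)) != len(jb):
        raise ValueError("alignment is not one-to-one")


def is_sequential_pairs(pairs: Sequence) -> bool:
    """True iff pairs sorted by the first index are strictly increasing in the second."""
    ordered = sorted(pairs)
    return all(b[1] > a[1] for a, b in zip(ordered, ordered[1:]))


@dataclass
class Alignment:
    """One-to-one residue correspondence between chain A and chain B.

    ``pairs`` is a list of ``(i, j)`` unit indices.  ``d`` optionally carries
    the per-pair distances (Angstrom) under a stated transform, in the order
    of ``pairs`` sorted by ``i``.
    """

    pairs: list
    is_sequential: bool = True
    d: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pairs = [(int(i), int(j)) for i, j in self.pairs]
        check_one_to_one(self.pairs)
        if self.is_sequential and not is_sequential_pairs(self.pairs):
            raise ValueError("pairs violate the sequentiality invariant")

    @property
    def l_ali(self) -> int:
        return len(self.pairs)

    def pair_set(self) -> frozenset:
        return frozenset(self.pairs)

    def sorted_pairs(self) -> list:
        return sorted(self.pairs)

    def arrays(self):
        """Return (i_indices, j_indices) sorted by i, as int arrays."""
        ordered = self.sorted_pairs()
        if not ordered:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.asarray(ordered, dtype=int)
        return arr[:, 0], arr[:, 1]


@dataclass
class ScoreReport:
    """Summary scores for a finished pairwise alignment.

    ``tm_norm_a`` / ``tm_norm_b`` are the TM-scores normalized by the length
    of chain A / chain B (each with its own d0); ``so_percent`` is the
    structure overlap, the percentage of aligned units within 3.5 A of their
    partners relative to the shorter chain.
    """

    tm_norm_a: float
    tm_norm_b: float
    tm_avg: float
    rmsd: float
    l_ali: int
    so_percent: float
    seq_identity: float
    is_sequential: bool
    l_a: int = 0
    l_b: int = 0
    d0_a: float = 0.0
    d0_b: float = 0.0
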