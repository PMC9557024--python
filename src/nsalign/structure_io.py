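"""Read PDB/mmCIF structures into coordinate chains and write superposed models.

Parsing goes through gemmi.  Alternate locations are resolved to the
highest-occupancy conformer (ties: first in file), waters are dropped, and
modified residues are kept under their author names.  Internally residues are
renumbered 0-based in file order; the author numbering survives only as text
labels for output.
"""

from __future__ import annotations

import logging
from typing import List, Optional, Tuple

import gemmi
import numpy as np

from .core import DNA, PROTEIN, RNA, CoordinateChain, Residue, Transform

logger = logging.getLogger(__name__)

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL", "UNK",
}
RNA_RESIDUES = {"A", "U", "G", "C", "I", "N"}
DNA_RESIDUES = {"DA", "DT", "DG", "DC", "DI", "DU", "DN"}
WATERS = {"HOH", "DOD", "WAT"}


class ParseError(ValueError):
    """Raised when a structure file cannot be parsed or a chain is missing."""


def _read_structure(path: str) -> gemmi.Structure:
    try:
        st = gemmi.read_structure(str(path))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError variants
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: file contains no models")
    return st


def _pick_altloc(res: gemmi.Residue) -> dict:
    """Atom-name -> coordinate map with altlocs resolved by occupancy."""
    best: dict = {}
    occ: dict = {}
    for atom in res:
        pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
        name = atom.name
        if name not in best or atom.occ > occ[name] + 1e-9:
            # ties keep the first-in-file conformer
            if name in best and atom.occ <= occ[name] + 1e-9:
                continue
            best[name] = pos
            occ[name] = atom.occ
    return best


def parse_structure(
    path: str,
    chain_id: Optional[str] = None,
    model_index: int = 0,
) -> List[Tuple[str, List[Residue]]]:
    """Parse a PDB/mmCIF file into per-chain residue lists.

    Only the requested model (default: first) is read.  Waters are excluded;
    HETATM residues that are part of the polymer (e.g. MSE) are retained.
    """
    st = _read_structure(path)
    if model_index >= len(st):
        raise ParseError(
            f"{path}: model {model_index} not present ({len(st)} model(s))"
        )
    model = st[model_index]
    chains = []
    for ch in model:
        residues: List[Residue] = []
        for res in ch:
            if res.name in WATERS:
                continue
            coords = _pick_altloc(res)
            if not coords:
                continue
            author = f"{res.seqid.num}{(res.seqid.icode or '').strip()}"
            residues.append(
                Residue(index=len(residues), name=res.name.strip(), author_id=author, coords=coords)
            )
        if residues:
            chains.append((ch.name, residues))
    if chain_id is not None:
        selected = [c for c in chains if c[0] == chain_id]
        if not selected:
            avail = ", ".join(c[0] for c in chains) or "(none)"
            raise ParseError(f"{path}: chain {chain_id!r} not found; available: {avail}")
        return selected
    if not chains:
        raise ParseError(f"{path}: no residues with coordinates found")
    return chains


def detect_molecule_type(residues: List[Residue]) -> str:
    """Classify a residue list as protein, rna or dna by majority vote.

    DNA vs RNA is decided by DT/T residue names or, failing that, by the
    absence of O2' atoms (deoxyribose lacks the 2'-hydroxyl).
    """
    if not residues:
        raise ValueError("empty residue list")
    n_prot = sum(1 for r in residues if r.name in AMINO_ACIDS)
    n_rna = sum(1 for r in residues if r.name in RNA_RESIDUES)
    n_dna = sum(1 for r in residues if r.name in DNA_RESIDUES or r.name == "T")
    n = len(residues)
    if n_prot > n / 2:
        if n_rna + n_dna > 0:
            raise ValueError("mixed amino-acid/nucleotide chain is not supported")
        return PROTEIN
    if n_rna + n_dna > n / 2:
        if n_prot > 0:
            raise ValueError("mixed amino-acid/nucleotide chain is not supported")
        if n_dna > 0:
            return DNA
        has_o2p = any("O2'" in r.coords or "O2*" in r.coords for r in residues)
        return RNA if has_o2p or not _any_sugar(residues) else DNA
    raise ValueError("unknown polymer type: majority of residues unrecognized")


def _any_sugar(residues: List[Residue]) -> bool:
    return any("C4'" in r.coords or "C4*" in r.coords for r in residues)


def _get_atom(res: Residue, names: Tuple[str, ...]) -> Optional[np.ndarray]:
    for nm in names:
        if nm in res.coords:
            return res.coords[nm]
    return None


CA_NAMES = ("CA",)
C3_NAMES = ("C3'", "C3*")
C4_NAMES = ("C4'", "C4*")
P_NAMES = ("P",)


def select_representative_atoms(
    residues: List[Residue],
    molecule_type: str,
    atom_spec: Optional[str] = None,
    name: str = "",
) -> CoordinateChain:
    """Reduce residues to the representative-atom point list used for alignment.

    Default convention: one point per residue — C-alpha for amino acids, C3'
    for nucleotides.  With ``atom_spec="PC4'"`` each nucleotide contributes
    two points, P then C4' in backbone order (a 5'-terminal nucleotide
    lacking P contributes only C4'); this matches the two-atom nucleotide
    representation used for cross-molecule protein/nucleic-acid alignment,
    chosen because adjacent P-C4' distances sit near the 3.8 A C-alpha
    spacing.  Residues missing every requested atom are dropped with a
    warning.
    """
    if not residues:
        raise ValueError("empty residue list")
    spec = (atom_spec or "").replace("*", "'").upper().replace('"', "")
    two_atom = spec in ("PC4'", "PC4")
    points, labels, names, src = [], [], [], []
    kept_residues = []
    for res in residues:
        added = False
        if molecule_type == PROTEIN:
            pos = _get_atom(res, CA_NAMES)
            if pos is not None:
                points.append(pos)
                labels.append(f"{res.author_id}:{res.name}:CA")
                names.append(res.name)
                src.append(res.index)
                added = True
        elif two_atom:
            p = _get_atom(res, P_NAMES)
            c4 = _get_atom(res, C4_NAMES)
            for atom_name, pos in (("P", p), ("C4'", c4)):
                if pos is not None:
                    points.append(pos)
                    labels.append(f"{res.author_id}:{res.name}:{atom_name}")
                    names.append(res.name)
                    src.append(res.index)
                    added = True
        else:
            pos = _get_atom(res, C3_NAMES)
            if pos is not None:
                points.append(pos)
                labels.append(f"{res.author_id}:{res.name}:C3'")
                names.append(res.name)
                src.append(res.index)
                added = True
        if added:
            kept_residues.append(res)
        else:
            logger.warning("residue %s %s lacks representative atoms; dropped", res.name, res.author_id)
    if not points:
        raise ValueError("no alignable atoms after representative-atom selection")
    return CoordinateChain(
        molecule_type=molecule_type,
        residues=kept_residues,
        points=np.asarray(points),
        unit_labels=labels,
        unit_names=names,
        unit_residue=src,
        name=name,
    )


def load_chain(
    path: str,
    chain_id: Optional[str] = None,
    model_index: int = 0,
    molecule_type: Optional[str] = None,
    atom_spec: Optional[str] = None,
) -> CoordinateChain:
    """Convenience: parse a file and build the coordinate chain in one step.

    With no ``chain_id`` the first chain in the file is used.
    """
    chains = parse_structure(path, chain_id=chain_id, model_index=model_index)
    cid, residues = chains[0]
    mtype = molecule_type or detect_molecule_type(residues)
    return select_representative_atoms(
        residues, mtype, atom_spec=atom_spec, name=f"{path}:{cid}"
    )


def _add_chain(model: gemmi.Model, cid: str, residues: List[Residue], t) -> None:
    chain = gemmi.Chain(cid)
    for k, res in enumerate(residues):
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(k + 1, " ")
        for atom_name, pos in res.coords.items():
            at = gemmi.Atom()
            at.name = atom_name
            xyz = pos if t is None else t.apply(pos.reshape(1, 3))[0]
            at.pos = gemmi.Position(*map(float, xyz))
            at.occ = 1.0
            at.element = gemmi.Element(_guess_element(atom_name))
            gres.add_atom(at)
        chain.add_residue(gres)
    model.add_chain(chain)


def _write_pdb(st: gemmi.Structure, path: str) -> None:
    st.setup_entities()
    st.write_pdb(str(path))


def write_superposed(
    residues_a: List[Residue],
    transform: Transform,
    residues_b: List[Residue],
    path: str,
    chain_ids: Tuple[str, str] = ("A", "B"),
) -> None:
    """Write chain A transformed into B's frame plus chain B as a 2-chain PDB."""
    st = gemmi.Structure()
    st.name = "superposed"
    model = gemmi.Model("1")
    _add_chain(model, chain_ids[0], residues_a, transform)
    _add_chain(model, chain_ids[1], residues_b, None)
    st.add_model(model)
    _write_pdb(st, path)


def write_chain_pdb(residues: List[Residue], path: str, chain_id: str = "A") -> None:
    """Write a single residue list as a one-chain PDB file."""
    st = gemmi.Structure()
    st.name = "chain"
    model = gemmi.Model("1")
    _add_chain(model, chain_id, residues, None)
    st.add_model(model)
    _write_pdb(st, path)


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip("0123456789'*\"")
    if stripped[:2] in ("CL", "BR", "FE", "MG", "ZN", "SE"):
        return stripped[:2]
    return stripped[:1] or "C"
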