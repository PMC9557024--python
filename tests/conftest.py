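import numpy as np
import pytest

from nsalign import fixtures as fx


def atom_line(serial, name, resname, chain, resseq, x, y, z, occ=1.0, altloc=" ",
              element=None, icode=" "):
    """One fixed-column PDB ATOM record."""
    element = element or name.strip("0123456789'*")[:1]
    aname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {aname}{altloc}{resname:>3s} {chain}{resseq:4d}{icode}"
        f"   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}          {element:>2s}"
    )


def protein_pdb_text(n=5, chain="A", resname="ALA", start=1, offset=0.0):
    lines = []
    for i in range(n):
        lines.append(
            atom_line(i + 1, "CA", resname, chain, start + i, 3.8 * i + offset, 0.0, 0.0)
        )
    lines.append("TER")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def two_helix():
    """Canonical 60-residue two-helix chain.

    Carries 0.05 A coordinate noise: a perfectly ideal helix is congruent
    with itself shifted by one residue, so the true register of a permuted
    copy would be unidentifiable from geometry alone.
    """
    return fx.two_helix_chain(60, seed=1, noise_sigma=0.05)


@pytest.fixture(scope="session")
def line_chain():
    """Straight C-alpha trace at 3.8 A spacing (coil by construction)."""
    from nsalign.core import CoordinateChain, Residue

    n = 12
    pts = np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)])
    residues = [
        Residue(index=i, name="GLY", author_id=str(i + 1), coords={"CA": pts[i]})
        for i in range(n)
    ]
    return CoordinateChain(
        molecule_type="protein",
        residues=residues,
        points=pts,
        unit_labels=[f"{i + 1}:GLY:CA" for i in range(n)],
        unit_names=["GLY"] * n,
        unit_residue=list(range(n)),
        name="line",
    )
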