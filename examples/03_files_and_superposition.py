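"""Round-trip through structure files: write fixtures as PDB, align them,
and write the superposed model.

The same run is available from the shell as
    nsalign align a.pdb b.pdb --mode sq -o superposed.pdb
"""

import tempfile
from pathlib import Path

from nsalign import align_sq, load_chain
from nsalign.fixtures import rigid_copy, two_helix_chain
from nsalign.structure_io import write_chain_pdb, write_superposed

workdir = Path(tempfile.mkdtemp(prefix="nsalign_example_"))
chain = two_helix_chain(60, seed=2, noise_sigma=0.05)
moved, true_transform = rigid_copy(chain, seed=5, noise_sigma=0.2)

path_a = workdir / "a.pdb"
path_b = workdir / "b.pdb"
write_chain_pdb(chain.residues, path_a)
write_chain_pdb(moved.residues, path_b)

a = load_chain(path_a)
b = load_chain(path_b)
alignment, transform, report = align_sq(a, b)

out = workdir / "superposed.pdb"
write_superposed(a.residues, transform, b.residues, out)

print(f"wrote {path_a.name}, {path_b.name} and {out.name} under {workdir}")
print(
    f"TM-score {report.tm_norm_a:.4f} (normalized by L={report.l_a}, "
    f"d0={report.d0_a:.2f} A), RMSD {report.rmsd:.2f} A over "
    f"{report.l_ali} aligned residues"
)
print(
    "\nThe superposed file holds chain A rotated into B's frame plus chain B\n"
    "unchanged, ready for a molecular viewer.  TM-score near 1 with a\n"
    "sub-Angstrom RMSD confirms the rigid copy was recovered."
)
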