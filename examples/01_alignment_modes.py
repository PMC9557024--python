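"""Compare the three alignment modes on a circularly permuted chain.

Builds a 60-residue two-helix chain, cuts it at residue 30 and swaps the
halves (coordinates untouched), then aligns the original against the
permutant in sequential (SQ), semi-non-sequential (sNS) and fully
non-sequential (fNS) mode.
"""

from nsalign import align_fns, align_sns, align_sq
from nsalign.fixtures import circular_permute, two_helix_chain

chain = two_helix_chain(60, seed=1, noise_sigma=0.05)
permuted, truth = circular_permute(chain, 30)

print(f"chain length {chain.L}; permuted copy cut at residue 30\n")
for name, fn in (("SQ", align_sq), ("sNS", align_sns), ("fNS", align_fns)):
    alignment, transform, report = fn(chain, permuted)
    recovered = len(set(alignment.pairs) & set(truth.items())) / chain.L
    print(
        f"{name:>3s}: TM-score {report.tm_norm_a:.4f}  L_ali {report.l_ali:2d}  "
        f"RMSD {report.rmsd:5.2f} A  true pairs recovered {100 * recovered:5.1f}%"
    )

print(
    "\nSequential alignment can only match one unbroken half (TM ~ 0.5);\n"
    "the non-sequential modes rejoin both halves and recover the full\n"
    "correspondence (TM ~ 1), which is what makes circular permutations\n"
    "visible to structure comparison."
)
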