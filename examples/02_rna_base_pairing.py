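"""Assign base-pairing states to a synthetic RNA duplex.

The generator places two antiparallel strands with complementary sequence
and cross-strand C3'-C3' distances inside the 12.5-15.0 A pairing window.
The assignment applies three rules per candidate pair: the distance window,
the G:C / G:U / A:U whitelist, and singleton exclusion (a pair with no
stacked neighbouring pair is dropped).
"""

from nsalign.fixtures import FixtureSpec, make_chain
from nsalign.secondary import assign_rna_basepairs

chain, expected = make_chain(FixtureSpec([("na_duplex", 12)], seed=4))
annotation = assign_rna_basepairs(chain)

print("sequence :", "".join(chain.unit_names))
print("assigned :", annotation.to_string())
print("expected :", "".join(expected))
print("elements :", annotation.elements)
print(
    "\n'(' pairs with a downstream base, ')' with an upstream base, '.' is\n"
    "unpaired.  Every nucleotide of the duplex pairs with its antiparallel\n"
    "partner; an isolated contact without a stacked neighbouring pair would\n"
    "have been rejected by the singleton rule."
)
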