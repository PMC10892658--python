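"""Cysteine-framework descriptors: parse, derive, match.

Builds the descriptor table of the published query set, derives a
framework from a concrete peptide, and checks two homologs against each
other at a one-residue gap tolerance.
"""

from scripkit import derive_framework, match_framework, parse_framework
from scripkit.framework import framework_consensus
from scripkit.reference_data import QUERY_FRAMEWORKS

frameworks = {name: parse_framework(desc) for name, _, _, _, desc in QUERY_FRAMEWORKS}

print(f"{len(frameworks)} published query frameworks, all with "
      f"{frameworks['Amil_SCRiP2'].n_cys} cysteines")

consensus, gap_table = framework_consensus(list(frameworks.values()))
print("modal consensus:", consensus.format())
# The consensus descriptor summarises the family: eight cysteines whose
# spacings vary by a few residues, ending in three adjacent cysteines.

a = frameworks["Amil_SCRiP2"]
b = frameworks["Ofav_SCRiP2"]
print("Amil_SCRiP2:", a.format())
print("Ofav_SCRiP2:", b.format())
print("match at tolerance 0:", match_framework(a, b, 0))
print("match at tolerance 1:", match_framework(a, b, 1))
# At tolerance 1 the two species' homologs share the same framework up to
# one residue of spacing drift per gap.

peptide = "KNCTDAAGQCVAENNPCPAGLVCINGKCHCTNE"
fw = derive_framework(peptide)
print("derived from peptide:", fw.format(), "| tail triplet:", fw.tail_triplet)
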