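"""Masking, identity matrices, and an NJ tree with bootstrap supports.

Masks weakly informative codon columns, computes nucleotide and protein
identity under the union-denominator convention, and builds a
neighbor-joining tree whose internal nodes carry bootstrap percentages
from resampled codon columns.
"""

from scripkit import group_identity, identity_matrix, mask_columns
from scripkit.phylo import BootstrapConfig, bootstrap_supports
from scripkit.simulate import SynthConfig, generate_family

family = generate_family(SynthConfig(seed=11, n_subfamilies=3, members_per_subfamily=6))
aln = mask_columns(family.alignment, 0.10)
print(f"{len(aln.ids)} sequences, {aln.n_codon_columns} codon columns, "
      f"{len(aln.column_mask)} kept at the 10% informative threshold")

ident_nt = identity_matrix(aln, "nucleotide")
ident_aa = identity_matrix(aln, "protein")
groups: dict[str, list[str]] = {}
for rid, sf in family.truth.items():
    groups.setdefault(sf, []).append(rid)
for sf, members in sorted(groups.items()):
    ni = group_identity(ident_nt, members)
    pi = group_identity(ident_aa, members)
    print(f"  {sf}: within ni = {ni:.1f}%  pi = {pi:.1f}%")
# Within-subfamily nucleotide identity sits near the generator's 75%
# target; protein identity is higher because most fixed changes under
# purifying regimes are synonymous.

tree = bootstrap_supports(aln, BootstrapConfig(n_replicates=200, seed=1))
supports = sorted(
    n.support.bootstrap_pct for n in tree.preorder() if n.support is not None
)
print(f"bootstrap supports: min {supports[0]:.0f}, max {supports[-1]:.0f} "
      f"({len(supports)} internal nodes)")
print(tree.to_newick()[:120] + "...")
# Planted subfamily clades reach 100% support; arbitrary resolutions of
# the star-like deep structure stay weakly supported.
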