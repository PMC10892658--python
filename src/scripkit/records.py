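"""Core sequence records and the standard genetic code.

A :class:`SeqRecord` bundles a candidate toxin coding sequence with its
translation and the biology metadata (species, hexacorallian family,
lineage, data source, life stage, tissue) that the downstream
classification and reporting layers consume.  Coordinates are 1-based and
inclusive throughout, matching how protein residues are cited in the toxin
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio.Data import CodonTable

__all__ = [
    "SeqRecord",
    "translate",
    "LINEAGES",
    "SOURCES",
    "COMPLETENESS",
    "LIFE_STAGES",
    "STOP_CODONS",
    "SENSE_CODONS",
    "CODON_TO_AA",
]

LINEAGES = frozenset(
    {"scleractinia_complex", "scleractinia_robust", "actiniaria", "octocorallia", "other"}
)
SOURCES = frozenset({"genome", "transcriptome", "query"})
COMPLETENESS = frozenset({"complete", "partial"})
LIFE_STAGES = frozenset({"egg", "gastrula", "larva", "adult", "unknown"})

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

_DNA = set("ACGT")


def translate(nt: str) -> str:
    """Translate a CDS under the standard genetic code.

    A terminal stop codon is stripped; an internal stop is an error.  Codons
    containing ambiguity characters (anything outside ACGT) translate to
    ``'X'``; ``'X'`` never counts as a match in identity computations.

    Parameters
    ----------
    nt:
        Nucleotide coding sequence, length divisible by 3.

    Raises
    ------
    ValueError
        If the length is not a multiple of 3 or an internal stop codon is
        present (the error names the 1-based codon index).
    """
    nt = nt.upper()
    if len(nt) % 3:
        raise ValueError(f"CDS length {len(nt)} is not divisible by 3")
    n_codons = len(nt) // 3
    out = []
    for i in range(n_codons):
        codon = nt[3 * i : 3 * i + 3]
        if codon in STOP_CODONS:
            if i == n_codons - 1:
                break
            raise ValueError(f"internal stop codon at codon {i + 1}")
        if set(codon) <= _DNA:
            out.append(CODON_TO_AA[codon])
        else:
            out.append("X")
    return "".join(out)


@dataclass
class SeqRecord:
    """One candidate or query toxin sequence with provenance metadata."""

    id: str
    aa: str = ""
    nt: str = ""
    species: str = ""
    taxon_family: str = ""
    lineage: str = "other"
    source: str = "query"
    completeness: str = "complete"
    life_stage: Optional[str] = None
    tissue: Optional[str] = None
    signal_peptide_end: Optional[int] = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.completeness not in COMPLETENESS:
            raise ValueError(f"unknown completeness {self.completeness!r}")
        if self.life_stage is not None and self.life_stage not in LIFE_STAGES:
            raise ValueError(f"unknown life_stage {self.life_stage!r}")
        self.aa = self.aa.upper()
        self.nt = self.nt.upper()
        if self.nt and not self.aa:
            self.aa = translate(self.nt)
        if self.nt and self.completeness == "complete":
            if translate(self.nt) != self.aa:
                raise ValueError(f"{self.id}: translation of nt does not match aa")
        if self.signal_peptide_end is not None:
            if not (1 <= self.signal_peptide_end < len(self.aa)):
                raise ValueError(
                    f"{self.id}: signal_peptide_end {self.signal_peptide_end} "
                    f"outside [1, {len(self.aa) - 1}]"
                )

    @property
    def mature_aa(self) -> str:
        """Mature-peptide region (residues after the signal peptide)."""
        if self.signal_peptide_end is None:
            return self.aa
        return self.aa[self.signal_peptide_end :]

    def with_(self, **kwargs) -> "SeqRecord":
        return replace(self, **kwargs)


def check_unique_ids(records: Iterable[SeqRecord]) -> None:
    seen: set[str] = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate record id {r.id!r}")
        seen.add(r.id)
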