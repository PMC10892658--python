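"""FASTA and tabular readers/writers.

Thin wrappers around Bio.SeqIO and pandas that enforce the pipeline's
contracts: unique ids, alphabet validation with positional error messages,
uppercase normalisation, deterministic row order on round-trip.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .records import SeqRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_predictions",
    "write_table",
]

_ALPHABETS = {
    # IUPAC nucleotide codes plus gap; 'U' deliberately excluded (CDS input).
    "nt": set("ACGTRYSWKMBDHVN-"),
    # 20 residues + ambiguity X + gap.
    "aa": set("ACDEFGHIKLMNPQRSTVWYX-*"),
}

METADATA_COLUMNS = [
    "id", "species", "taxon_family", "lineage", "source",
    "completeness", "life_stage", "tissue",
]


def read_fasta(path, alphabet: str = "aa") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, SEQUENCE), ...]`` preserving order.

    The id is the first whitespace-delimited token of the header; sequences
    are uppercased and validated against the requested alphabet.
    """
    if alphabet not in _ALPHABETS:
        raise ValueError(f"alphabet must be 'nt' or 'aa', got {alphabet!r}")
    allowed = _ALPHABETS[alphabet]
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        sid = rec.id
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for id {sid!r}")
        if sid in seen:
            raise ValueError(f"duplicate id {sid!r}")
        seen.add(sid)
        for pos, ch in enumerate(seq, start=1):
            if ch not in allowed:
                raise ValueError(
                    f"illegal {alphabet} character {ch!r} at position {pos} in {sid!r}"
                )
        out.append((sid, seq))
    return out


def write_fasta(path, pairs: Iterable[tuple[str, str]], width: int = 0) -> None:
    """Write ``(id, seq)`` pairs as FASTA; ``width=0`` means unwrapped."""
    with open(path, "w") as fh:
        for sid, seq in pairs:
            fh.write(f">{sid}\n")
            if width and width > 0:
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
            else:
                fh.write(seq + "\n")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"metadata TSV missing columns: {missing}")
    if df["id"].duplicated().any():
        dups = sorted(df.loc[df["id"].duplicated(), "id"])
        raise ValueError(f"duplicate ids in metadata: {dups}")
    return df


def write_metadata(records: Sequence[SeqRecord], path) -> None:
    rows = [
        {
            "id": r.id,
            "species": r.species,
            "taxon_family": r.taxon_family,
            "lineage": r.lineage,
            "source": r.source,
            "completeness": r.completeness,
            "life_stage": r.life_stage or "",
            "tissue": r.tissue or "",
        }
        for r in records
    ]
    write_table(pd.DataFrame(rows, columns=METADATA_COLUMNS), path)


def read_predictions(path) -> pd.DataFrame:
    """Read an external secretion-prediction TSV.

    Expected columns: ``id``, ``sp_prob`` (fraction), ``cleavage_end``
    (1-based last signal-peptide residue), ``tm_count``.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["id", "sp_prob", "cleavage_end", "tm_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"predictions TSV missing columns: {missing}")
    return df
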