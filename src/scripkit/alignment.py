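"""Codon alignments, column masking and identity matrices.

The pipeline treats a codon multiple sequence alignment (gaps only as full
``---`` codons) as the shared coordinate system for nucleotide identity
(ni), protein identity (pi), distance matrices for tree building, and the
informative-column masks applied before phylogenetics (10% threshold) and
selection analysis (50% threshold).

Identity convention: positions where *both* rows are gaps are excluded
from the denominator; positions where exactly one row is a gap count as
mismatches ("union" denominator).  An "overlap" denominator (both rows
non-gap) is available because published identity values may follow either
convention.  Ambiguous nucleotides, and the 'X' residues they translate
to, never match anything.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .records import translate, STOP_CODONS

__all__ = [
    "CodonAlignment",
    "IdentityMatrix",
    "mask_columns",
    "pairwise_identity",
    "identity_matrix",
    "group_identity",
    "between_identity",
    "p_distance_matrix",
]

_DNA = set("ACGT")
GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """Aligned nucleotide rows in codon coordinates.

    ``column_mask`` lists the kept codon-column indices (0-based
    internally; the sidecar TSV is written 1-based).
    """

    ids: list[str]
    rows: list[str]
    column_mask: Optional[list[int]] = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        self.rows = [r.upper() for r in self.rows]
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")
        (length,) = lengths or {0}
        if length % 3:
            raise ValueError("alignment length not divisible by 3")
        for sid, row in zip(self.ids, self.rows):
            for c in range(length // 3):
                codon = row[3 * c : 3 * c + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"{sid}: partial gap codon {codon!r} at codon column {c + 1}"
                    )
        if self.column_mask is None:
            self.column_mask = list(range(length // 3))

    @property
    def n_codon_columns(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon(self, row_index: int, col: int) -> str:
        return self.rows[row_index][3 * col : 3 * col + 3]

    def row_index(self, sid: str) -> int:
        try:
            return self.ids.index(sid)
        except ValueError:
            raise KeyError(f"id {sid!r} not in alignment") from None

    def masked_row(self, row_index: int, columns: Optional[Sequence[int]] = None) -> str:
        cols = self.column_mask if columns is None else columns
        row = self.rows[row_index]
        return "".join(row[3 * c : 3 * c + 3] for c in cols)

    def subset(self, keep_ids: Sequence[str]) -> "CodonAlignment":
        idx = [self.row_index(s) for s in keep_ids]
        return CodonAlignment(
            [self.ids[i] for i in idx],
            [self.rows[i] for i in idx],
            list(self.column_mask),
        )

    def write_mask_tsv(self, path) -> None:
        pd.DataFrame({"codon_column": [c + 1 for c in self.column_mask]}).to_csv(
            path, sep="\t", index=False
        )


def _informative(codon: str) -> bool:
    # Informative = unambiguous AND non-gap.
    return set(codon) <= _DNA


def mask_columns(alignment: CodonAlignment, min_informative_frac: float) -> CodonAlignment:
    """Drop codon columns whose informative fraction is < the threshold.

    A codon is informative for a row iff it has no gap and no ambiguity
    character.  A column at exactly the threshold is kept (the rule is
    "less than").
    """
    if not (0 < min_informative_frac <= 1):
        raise ValueError("min_informative_frac must be in (0, 1]")
    n = len(alignment.rows)
    kept = []
    for c in alignment.column_mask:
        frac = sum(_informative(alignment.codon(i, c)) for i in range(n)) / n
        if frac >= min_informative_frac:
            kept.append(c)
    return CodonAlignment(list(alignment.ids), list(alignment.rows), kept)


def _pair_identity_nt(a_codons: list[str], b_codons: list[str], denominator: str) -> float:
    matches = 0
    total = 0
    for ca, cb in zip(a_codons, b_codons):
        if ca == GAP_CODON and cb == GAP_CODON:
            continue
        for x, y in zip(ca, cb):
            both = x != "-" and y != "-"
            if denominator == "overlap" and not both:
                continue
            total += 1
            if x == y and x in _DNA:
                matches += 1
    return 100.0 * matches / total if total else 0.0


def _pair_identity_aa(a_codons: list[str], b_codons: list[str], denominator: str) -> float:
    matches = 0
    total = 0
    for ca, cb in zip(a_codons, b_codons):
        a_gap, b_gap = ca == GAP_CODON, cb == GAP_CODON
        if a_gap and b_gap:
            continue
        if a_gap or b_gap:
            if denominator == "union":
                total += 1
            continue
        ra = translate(ca) if ca not in STOP_CODONS else "*"
        rb = translate(cb) if cb not in STOP_CODONS else "*"
        ra = ra or "*"
        rb = rb or "*"
        total += 1
        if ra == rb and ra not in ("X", "*"):
            matches += 1
    return 100.0 * matches / total if total else 0.0


def pairwise_identity(
    alignment: CodonAlignment,
    id_a: str,
    id_b: str,
    level: str = "nucleotide",
    columns: Optional[Sequence[int]] = None,
    denominator: str = "union",
) -> float:
    """Percent identity between two rows over the masked columns."""
    if level not in ("nucleotide", "protein"):
        raise ValueError("level must be 'nucleotide' or 'protein'")
    if denominator not in ("union", "overlap"):
        raise ValueError("denominator must be 'union' or 'overlap'")
    ia, ib = alignment.row_index(id_a), alignment.row_index(id_b)
    cols = alignment.column_mask if columns is None else list(columns)
    a_codons = [alignment.codon(ia, c) for c in cols]
    b_codons = [alignment.codon(ib, c) for c in cols]
    if level == "nucleotide":
        return _pair_identity_nt(a_codons, b_codons, denominator)
    return _pair_identity_aa(a_codons, b_codons, denominator)


@dataclass
class IdentityMatrix:
    """Symmetric pairwise percent-identity matrix."""

    ids: list[str]
    values: np.ndarray
    level: str = "nucleotide"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("identity matrix must be symmetric")
        if (self.values < -1e-9).any() or (self.values > 100 + 1e-9).any():
            raise ValueError("identities must lie in [0, 100]")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def identity_matrix(
    alignment: CodonAlignment,
    level: str = "nucleotide",
    columns: Optional[Sequence[int]] = None,
    denominator: str = "union",
) -> IdentityMatrix:
    n = len(alignment.ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            v = pairwise_identity(
                alignment, alignment.ids[i], alignment.ids[j], level,
                columns=columns, denominator=denominator,
            )
            vals[i, j] = vals[j, i] = v
    return IdentityMatrix(list(alignment.ids), vals, level)


def group_identity(matrix: IdentityMatrix, members: Sequence[str]) -> Optional[float]:
    """Mean pairwise identity over unordered within-group pairs.

    Undefined (None) for singleton groups.
    """
    members = list(members)
    if not members:
        raise ValueError("empty group")
    if len(members) < 2:
        return None
    vals = [
        matrix.get(members[i], members[j])
        for i in range(len(members))
        for j in range(i + 1, len(members))
    ]
    return float(np.mean(vals))


def between_identity(
    matrix: IdentityMatrix, group_a: Sequence[str], group_b: Sequence[str]
) -> float:
    """Mean identity over all cross pairs of two disjoint groups."""
    if not group_a or not group_b:
        raise ValueError("empty group")
    vals = [matrix.get(a, b) for a in group_a for b in group_b]
    return float(np.mean(vals))


def p_distance_matrix(
    alignment: CodonAlignment,
    level: str = "nucleotide",
    columns: Optional[Sequence[int]] = None,
) -> tuple[list[str], np.ndarray]:
    """(100 - identity)/100 as a distance matrix; feeds neighbor joining.

    p-distances need not satisfy the triangle inequality.
    """
    m = identity_matrix(alignment, level, columns=columns)
    d = (100.0 - m.values) / 100.0
    np.fill_diagonal(d, 0.0)
    return list(m.ids), d
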