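"""Cysteine-framework descriptors.

Small cysteine-rich toxin peptides are conventionally described by the
spacing pattern of their cysteines, written ``C(6)C(6)CP(5)C(6)C(6)CCC(2)``:
``C(n)`` means *n* residues between this cysteine and the next, adjacent
cysteines are written back-to-back (``CC``), ``CP(k)`` marks a proline
immediately after the cysteine (the proline counts inside the gap, so the
gap is k+1), and a trailing ``(n)`` is the number of residues after the
last cysteine (the C-terminal tail).  The coral/sea-anemone SCRiP family
canonically shows eight cysteines with the last three mutually adjacent.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "CysFramework",
    "parse_framework",
    "derive_framework",
    "match_framework",
    "framework_consensus",
]


@dataclass(frozen=True)
class CysFramework:
    """Ordered cysteine-spacing descriptor.

    ``gaps[i]`` is the number of residues strictly between cysteine *i* and
    cysteine *i+1*; ``proline_first[i]`` is true when the residue
    immediately after cysteine *i* is proline; ``tail`` counts residues
    after the last cysteine.
    """

    n_cys: int
    gaps: tuple[int, ...]
    proline_first: tuple[bool, ...] = ()
    tail: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "gaps", tuple(self.gaps))
        pf = tuple(self.proline_first) or (False,) * (self.n_cys - 1)
        object.__setattr__(self, "proline_first", pf)
        if self.n_cys < 2:
            raise ValueError("a framework needs at least 2 cysteines")
        if len(self.gaps) != self.n_cys - 1:
            raise ValueError("gaps must have length n_cys - 1")
        if len(pf) != self.n_cys - 1:
            raise ValueError("proline_first must have length n_cys - 1")
        if any(g < 0 for g in self.gaps) or self.tail < 0:
            raise ValueError("gaps and tail must be non-negative")
        for g, p in zip(self.gaps, pf):
            if p and g < 1:
                raise ValueError("a proline-led gap must be >= 1")

    @property
    def length(self) -> int:
        """Residue span from the first cysteine to the end of the tail."""
        return self.n_cys + sum(self.gaps) + self.tail

    @property
    def tail_triplet(self) -> bool:
        """True when the last three cysteines are mutually adjacent."""
        return self.n_cys >= 3 and self.gaps[-1] == 0 and self.gaps[-2] == 0

    def format(self) -> str:
        parts: list[str] = []
        for i in range(self.n_cys - 1):
            g = self.gaps[i]
            if self.proline_first[i]:
                parts.append("CP" + (f"({g - 1})" if g - 1 > 0 else ""))
            else:
                parts.append("C" + (f"({g})" if g > 0 else ""))
        parts.append("C" + (f"({self.tail})" if self.tail > 0 else ""))
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


_TOKEN = re.compile(r"C(P?)(?:\((\d+)\))?")


def _normalize(s: str) -> str:
    # Table typography varies: underscores and stray spaces are cosmetic.
    return s.replace("_", "").replace(" ", "")


def parse_framework(s: str) -> CysFramework:
    """Parse a descriptor string such as ``"C(6)C(6)CP(5)C(6)C(6)CCC(2)"``.

    Raises ``ValueError`` with the character offset on a malformed token.
    """
    text = _normalize(s)
    pos = 0
    cys: list[tuple[bool, int | None]] = []  # (proline, explicit number)
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            raise ValueError(f"malformed framework token at offset {pos} in {s!r}")
        proline = m.group(1) == "P"
        num = int(m.group(2)) if m.group(2) is not None else None
        cys.append((proline, num))
        pos = m.end()
    if len(cys) < 2:
        raise ValueError(f"descriptor {s!r} contains fewer than 2 cysteines")

    n_cys = len(cys)
    gaps: list[int] = []
    proline_first: list[bool] = []
    for proline, num in cys[:-1]:
        if proline:
            gaps.append((num or 0) + 1)  # proline sits inside the gap
        else:
            gaps.append(num or 0)
        proline_first.append(proline)
    last_proline, tail = cys[-1]
    if last_proline:
        raise ValueError(f"trailing CP token has no following cysteine in {s!r}")
    return CysFramework(n_cys, tuple(gaps), tuple(proline_first), tail or 0)


def derive_framework(aa: str) -> CysFramework:
    """Derive the framework of a protein sequence from its cysteine positions.

    Uses the first eight cysteines when more than eight exist (the record
    should be flagged by the caller); fewer than two cysteines is an error.
    """
    aa = aa.upper()
    positions = [i for i, ch in enumerate(aa) if ch == "C"]
    if len(positions) < 2:
        raise ValueError("no framework: fewer than 2 cysteines")
    if len(positions) > 8:
        positions = positions[:8]
    gaps = [positions[i + 1] - positions[i] - 1 for i in range(len(positions) - 1)]
    proline_first = [
        positions[i] + 1 < len(aa) and aa[positions[i] + 1] == "P" and gaps[i] >= 1
        for i in range(len(positions) - 1)
    ]
    # Tail measured from the last counted cysteine; when extra cysteines
    # were truncated they fall inside the tail.
    tail = len(aa) - positions[-1] - 1
    return CysFramework(len(positions), tuple(gaps), tuple(proline_first), tail)


def match_framework(
    candidate: CysFramework,
    reference: CysFramework,
    gap_tolerance: int = 0,
    require_tail_triplet: bool = False,
) -> bool:
    """Positionwise framework comparison with a per-gap tolerance."""
    if gap_tolerance < 0:
        raise ValueError("gap_tolerance must be >= 0")
    if candidate.n_cys != reference.n_cys:
        return False
    if any(
        abs(c - r) > gap_tolerance for c, r in zip(candidate.gaps, reference.gaps)
    ):
        return False
    if require_tail_triplet and not candidate.tail_triplet:
        return False
    return True


def framework_consensus(
    frameworks: Sequence[CysFramework],
) -> tuple[CysFramework, list[dict]]:
    """Modal consensus framework plus a per-gap min/max/modal table.

    All inputs must share ``n_cys``.  Modal ties break toward the smaller
    gap; the same rule applies to the tail.
    """
    if not frameworks:
        raise ValueError("no frameworks given")
    n_cys = frameworks[0].n_cys
    if any(f.n_cys != n_cys for f in frameworks):
        raise ValueError("mixed cysteine counts; consensus undefined")

    def modal(values: list[int]) -> int:
        counts = Counter(values)
        best = max(counts.values())
        return min(v for v, c in counts.items() if c == best)

    gap_table: list[dict] = []
    gaps: list[int] = []
    prolines: list[bool] = []
    for i in range(n_cys - 1):
        vals = [f.gaps[i] for f in frameworks]
        gaps.append(modal(vals))
        prolines.append(
            sum(f.proline_first[i] for f in frameworks) * 2 > len(frameworks)
        )
        gap_table.append({"gap": i + 1, "min": min(vals), "max": max(vals),
                          "modal": gaps[-1]})
    tails = [f.tail for f in frameworks]
    consensus = CysFramework(n_cys, tuple(gaps), tuple(prolines), modal(tails))
    gap_table.append({"gap": "tail", "min": min(tails), "max": max(tails),
                      "modal": consensus.tail})
    return consensus, gap_table
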