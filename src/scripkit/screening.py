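"""Candidate-validation cascade for putative secreted toxin peptides.

Four ordered stages, each idempotent and fully logged:

1. ``length``   — preprotein length inside [min_len_aa, max_len_aa]
                  (defaults 60-100 aa, inclusive).
2. ``collapse`` — exact protein-duplicate removal (100% identity only).
3. ``secretion``— signal-peptide probability strictly > threshold
                  (default 0.65) and at most ``max_tm_domains``
                  transmembrane domains (default 1, the signal peptide
                  itself).  Predictions come from an external TSV when
                  available; otherwise from the transparent hydropathy
                  heuristic below, which is a stand-in and makes no claim
                  to replicate neural predictors.
4. ``homology`` — best global-alignment identity against a reference
                  toxin set must be >= 40% unless the id is on the
                  declared outgroup whitelist (distant relatives used for
                  rooting are retained at 30-40% identity).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .records import SeqRecord

__all__ = [
    "ScreenConfig",
    "ScreenReport",
    "length_filter",
    "collapse_identical",
    "heuristic_signal_peptide",
    "heuristic_tm_count",
    "heuristic_predictions",
    "secretion_filter",
    "global_identity",
    "homology_filter",
    "run_screen",
]

STAGES = ("length", "collapse", "secretion", "homology")

# Hydropathy heuristic constants: an 8-residue window over the first 30
# residues; the logistic is centred so that a window mean Kyte-Doolittle
# hydropathy of ~2.1 crosses the 0.65 probability threshold (hydrophobic
# signal-peptide cores typically average 2.5-4.5).
_WINDOW = 8
_N_REGION = 30
_LOGISTIC_K = 2.0
_LOGISTIC_C = 1.8


@dataclass
class ScreenConfig:
    min_len_aa: int = 60
    max_len_aa: int = 100
    sp_prob_threshold: float = 0.65
    max_tm_domains: int = 1
    min_identity_pct: float = 40.0
    evalue_ceiling: float = 1e-5
    outgroup_whitelist: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 < self.min_len_aa <= self.max_len_aa):
            raise ValueError("need 0 < min_len_aa <= max_len_aa")
        if not (0 <= self.sp_prob_threshold <= 1):
            raise ValueError("sp_prob_threshold must be a fraction")
        if not (0 <= self.min_identity_pct <= 100):
            raise ValueError("min_identity_pct must be a percentage")
        if self.max_tm_domains < 0:
            raise ValueError("max_tm_domains must be >= 0")
        self.outgroup_whitelist = frozenset(self.outgroup_whitelist)


@dataclass
class ScreenReport:
    """Per-record audit of the cascade.

    A record rejected at stage *k* has no recorded outcome for any later
    stage.
    """

    entries: dict[str, dict] = field(default_factory=dict)

    def start(self, rid: str) -> None:
        self.entries[rid] = {
            "stage_passed": {},
            "rejection_stage": None,
            "duplicate_of": None,
            "best_reference_hit": None,
            "identity_pct": None,
            "outgroup": False,
        }

    def record(self, rid: str, stage: str, passed: bool) -> None:
        e = self.entries[rid]
        e["stage_passed"][stage] = passed
        if not passed and e["rejection_stage"] is None:
            e["rejection_stage"] = stage

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rid, e in self.entries.items():
            row = {"id": rid, "rejection_stage": e["rejection_stage"] or "",
                   "duplicate_of": e["duplicate_of"] or "",
                   "best_reference_hit": e["best_reference_hit"] or "",
                   "identity_pct": e["identity_pct"],
                   "outgroup": e["outgroup"]}
            for st in STAGES:
                row[f"passed_{st}"] = e["stage_passed"].get(st)
            rows.append(row)
        return pd.DataFrame(rows)


def length_filter(
    records: Sequence[SeqRecord], config: ScreenConfig
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Keep records whose protein length is within the inclusive bounds."""
    kept, rejected = [], []
    for r in records:
        (kept if config.min_len_aa <= len(r.aa) <= config.max_len_aa else rejected).append(r)
    return kept, rejected


def collapse_identical(
    records: Sequence[SeqRecord],
) -> tuple[list[SeqRecord], dict[str, list[str]]]:
    """Collapse exact protein duplicates (the 100%-identity clustering).

    The representative of each identical group is the lexicographically
    smallest id; ``duplicate_map`` maps representative -> other members.
    Idempotent.
    """
    groups: dict[str, list[SeqRecord]] = {}
    order: list[str] = []
    for r in records:
        if r.aa not in groups:
            groups[r.aa] = []
            order.append(r.aa)
        groups[r.aa].append(r)
    representatives: list[SeqRecord] = []
    duplicate_map: dict[str, list[str]] = {}
    for aa in order:
        members = sorted(groups[aa], key=lambda r: r.id)
        rep = members[0]
        representatives.append(rep)
        if len(members) > 1:
            duplicate_map[rep.id] = [m.id for m in members[1:]]
    return representatives, duplicate_map


def _window_means(aa: str) -> list[float]:
    region = aa[:_N_REGION]
    scores = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in region]
    return [
        sum(scores[i : i + _WINDOW]) / _WINDOW
        for i in range(0, len(region) - _WINDOW + 1)
    ]


def heuristic_signal_peptide(aa: str) -> tuple[float, Optional[int]]:
    """Sliding-window hydropathy score for an N-terminal signal peptide.

    Returns ``(probability-like score in [0, 1], predicted 1-based
    cleavage index)``.  The score is a fixed logistic of the maximal
    8-residue mean Kyte-Doolittle hydropathy within the first 30 residues;
    the cleavage index is the end of the best window plus two residues.
    Deterministic; sequences shorter than 20 residues score 0.
    """
    aa = aa.upper()
    if len(aa) < 20:
        return 0.0, None
    means = _window_means(aa)
    best = max(range(len(means)), key=lambda i: (means[i], -i))
    score = 1.0 / (1.0 + math.exp(-_LOGISTIC_K * (means[best] - _LOGISTIC_C)))
    cleavage = min(best + _WINDOW + 2, len(aa) - 1)  # 1-based end of window + 2
    return score, cleavage


def heuristic_tm_count(aa: str) -> int:
    """Count candidate transmembrane segments by hydropathy.

    A TM segment is a cluster of 15-residue windows with mean
    Kyte-Doolittle hydropathy >= 2.0; clusters separated by more than one
    window length are counted separately.  The hydrophobic signal-peptide
    core itself counts as one segment.
    """
    w = 15
    aa = aa.upper()
    scores = [KYTE_DOOLITTLE.get(ch, 0.0) for ch in aa]
    marked = [
        i
        for i in range(0, len(aa) - w + 1)
        if sum(scores[i : i + w]) / w >= 2.0
    ]
    count = 0
    prev = None
    for i in marked:
        if prev is None or i - prev > w:
            count += 1
        prev = i
    return count


def heuristic_predictions(records: Sequence[SeqRecord]) -> pd.DataFrame:
    """Secretion-feature table from the built-in heuristics (TSV-shaped)."""
    rows = []
    for r in records:
        sp, cleave = heuristic_signal_peptide(r.aa)
        rows.append(
            {"id": r.id, "sp_prob": sp, "cleavage_end": cleave,
             "tm_count": heuristic_tm_count(r.aa)}
        )
    return pd.DataFrame(rows, columns=["id", "sp_prob", "cleavage_end", "tm_count"])


def secretion_filter(
    records: Sequence[SeqRecord],
    predictions: Mapping[str, Mapping] | pd.DataFrame,
    config: ScreenConfig,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Keep records with sp_prob strictly above threshold and tm_count
    within bounds; annotates ``signal_peptide_end`` on kept records."""
    if isinstance(predictions, pd.DataFrame):
        predictions = {
            row["id"]: row for _, row in predictions.iterrows()
        }
    missing = [r.id for r in records if r.id not in predictions]
    if missing:
        raise ValueError(f"missing secretion predictions for: {sorted(missing)}")
    kept, rejected = [], []
    for r in records:
        p = predictions[r.id]
        ok = float(p["sp_prob"]) > config.sp_prob_threshold and int(
            p["tm_count"]
        ) <= config.max_tm_domains
        if ok:
            end = p.get("cleavage_end") if hasattr(p, "get") else p["cleavage_end"]
            end = int(end) if end is not None and not pd.isna(end) else None
            if end is not None and 1 <= end < len(r.aa):
                r = r.with_(signal_peptide_end=end)
            kept.append(r)
        else:
            rejected.append(r)
    return kept, rejected


_aligner: Optional[Align.PairwiseAligner] = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -1.0
        _aligner = a
    return _aligner


def global_identity(a: str, b: str) -> float:
    """Needleman-Wunsch percent identity (BLOSUM62, gap open 10/extend 1).

    Identity = matches / alignment columns x 100, counting gap columns in
    the denominator; 'X' matches nothing.  Symmetric.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = _get_aligner().align(a.upper(), b.upper())[0]
    sa, sb = str(aln[0]), str(aln[1])
    matches = sum(
        1 for x, y in zip(sa, sb) if x == y and x not in ("-", "X")
    )
    return 100.0 * matches / len(sa)


def homology_filter(
    records: Sequence[SeqRecord],
    reference_set: Sequence[tuple[str, str]],
    config: ScreenConfig,
) -> tuple[list[SeqRecord], list[SeqRecord], pd.DataFrame]:
    """Best-hit identity against the reference toxin set.

    ``reference_set`` is ``[(ref_id, aa), ...]``.  Kept iff best identity
    >= min_identity_pct, or the record id is whitelisted as outgroup.
    """
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    kept, rejected, rows = [], [], []
    for r in records:
        best_id, best_pct = None, -1.0
        for ref_id, ref_aa in reference_set:
            pct = global_identity(r.aa, ref_aa)
            if pct > best_pct:
                best_id, best_pct = ref_id, pct
        is_outgroup = r.id in config.outgroup_whitelist
        ok = best_pct >= config.min_identity_pct or is_outgroup
        rows.append(
            {"id": r.id, "best_ref": best_id, "identity_pct": round(best_pct, 2),
             "outgroup": is_outgroup, "kept": ok}
        )
        (kept if ok else rejected).append(r)
    return kept, rejected, pd.DataFrame(rows)


def run_screen(
    records: Sequence[SeqRecord],
    reference_set: Sequence[tuple[str, str]],
    predictions: Optional[pd.DataFrame] = None,
    config: Optional[ScreenConfig] = None,
) -> tuple[list[SeqRecord], ScreenReport]:
    """Run the full cascade: length -> collapse -> secretion -> homology."""
    config = config or ScreenConfig()
    if not reference_set:
        raise ValueError("reference set must be non-empty")
    report = ScreenReport()
    for r in records:
        report.start(r.id)

    kept, rejected = length_filter(records, config)
    for r in kept:
        report.record(r.id, "length", True)
    for r in rejected:
        report.record(r.id, "length", False)

    reps, duplicate_map = collapse_identical(kept)
    rep_ids = {r.id for r in reps}
    for r in kept:
        report.record(r.id, "collapse", r.id in rep_ids)
    for rep, members in duplicate_map.items():
        for m in members:
            report.entries[m]["duplicate_of"] = rep

    preds = predictions if predictions is not None else heuristic_predictions(reps)
    kept2, rejected2 = secretion_filter(reps, preds, config)
    for r in kept2:
        report.record(r.id, "secretion", True)
    for r in rejected2:
        report.record(r.id, "secretion", False)

    kept3, rejected3, hits = homology_filter(kept2, reference_set, config)
    for r in kept3:
        report.record(r.id, "homology", True)
    for r in rejected3:
        report.record(r.id, "homology", False)
    for _, row in hits.iterrows():
        e = report.entries[row["id"]]
        e["best_reference_hit"] = row["best_ref"]
        e["identity_pct"] = row["identity_pct"]
        e["outgroup"] = bool(row["outgroup"])

    return kept3, report
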