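"""Summary arithmetic and run manifests.

Reproduces the bookkeeping layer of a gene-family survey: counts and
percentages by completeness/source/lineage/species/life stage/tissue, and
per-subfamily replicate omega summaries with their arithmetic means.
Percentages are rounded half-even to 2 decimals; published tables
occasionally truncate instead, so comparisons downstream should allow
+/- 0.01.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .records import SeqRecord

__all__ = ["summarize_dataset", "summarize_selection", "percentage", "RunManifest"]


def percentage(count: int, total: int, decimals: int = 2) -> float:
    """Half-even rounded percentage; 0 when the total is empty."""
    if total == 0:
        return 0.0
    # float() of np.round keeps half-even semantics (numpy rounds half to even)
    return float(np.round(100.0 * count / total, decimals))


_CATEGORIES = ("completeness", "source", "lineage", "species", "life_stage", "tissue")


def summarize_dataset(records: Sequence[SeqRecord]) -> pd.DataFrame:
    """Counts and percentages per metadata category.

    One row per (category, value); percentages within a category sum to
    100 up to rounding.  Empty input gives an empty table.
    """
    rows: list[dict] = []
    total = len(records)
    for cat in _CATEGORIES:
        counts: dict[str, int] = {}
        for r in records:
            val = getattr(r, cat) or ""
            counts[val] = counts.get(val, 0) + 1
        for val in sorted(counts):
            rows.append(
                {
                    "category": cat,
                    "value": val,
                    "count": counts[val],
                    "pct": percentage(counts[val], total),
                }
            )
    return pd.DataFrame(rows, columns=["category", "value", "count", "pct"])


def summarize_selection(
    replicate_omegas: Mapping[str, Sequence[float]], decimals: int = 3
) -> pd.DataFrame:
    """Per-group replicate omega values and their arithmetic mean.

    ``replicate_omegas`` maps a group name (e.g. a subfamily) to its
    replicate global-omega values; the mean is rounded to ``decimals``
    decimals (published values use 2-3 significant decimals).
    """
    rows = []
    for group in replicate_omegas:
        vals = [v for v in replicate_omegas[group] if v is not None]
        if not vals:
            raise ValueError(f"group {group!r} has no replicate omega values")
        rows.append(
            {
                "group": group,
                "n_replicates": len(vals),
                "omegas": ";".join(f"{v:g}" for v in vals),
                "mean_omega": float(np.round(float(np.mean(vals)), decimals)),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n_replicates", "omegas", "mean_omega"])


@dataclass
class RunManifest:
    """Provenance of one pipeline run; re-running with the same manifest
    reproduces the outputs."""

    tool_version: str
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.config, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def add_input(self, name: str, path) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        self.input_checksums[name] = h.hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "tool_version": self.tool_version,
                "seed": self.seed,
                "config": self.config,
                "config_hash": self.config_hash,
                "input_checksums": self.input_checksums,
                "stage_counts": self.stage_counts,
            },
            indent=2,
            sort_keys=True,
        )

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json() + "\n")
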