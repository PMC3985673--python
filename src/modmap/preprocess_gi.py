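"""Classification of genetic interactions from paired screens.

Quantitative genetic-interaction screens report an S-score per gene
pair in untreated cells and in cells perturbed by a DNA-damaging agent,
plus a p-value for differential interaction between the two conditions.
Two categories feed the map builder:

* *DNA damage-specific positive*: no positive interaction untreated
  (S < 0), clearly positive under treatment (S > 0.5), and significant
  differential interaction (p < 0.01);
* *stable positive*: strongly positive in both conditions
  (S > 1.5 untreated and treated).

All thresholds are strict; boundary values fall to ``other``.  The two
categories are mutually exclusive (S cannot be both < 0 and > 1.5).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .graph_core import DomainError

logger = logging.getLogger("modmap")

DAMAGE_SPECIFIC_POSITIVE = "damage_specific_positive"
STABLE_POSITIVE = "stable_positive"
OTHER = "other"


@dataclass(frozen=True)
class GIRecord:
    gene_a: str
    gene_b: str
    s_untreated: float
    s_treated: float
    p_diff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise DomainError("a genetic interaction needs two distinct genes")
        if self.p_diff is not None and not (0.0 <= self.p_diff <= 1.0):
            raise DomainError(f"p_diff out of [0, 1]: {self.p_diff}")


def classify_differential_gi(rec: GIRecord) -> str:
    """Assign one of the three categories; order of genes is irrelevant."""
    if rec.s_untreated > 1.5 and rec.s_treated > 1.5:
        return STABLE_POSITIVE
    if rec.s_untreated < 0 and rec.s_treated > 0.5:
        if rec.p_diff is None:
            logger.warning(
                "pair (%s, %s) passes the S-score filters but lacks a "
                "differential p-value; classified as other",
                rec.gene_a, rec.gene_b,
            )
            return OTHER
        if rec.p_diff < 0.01:
            return DAMAGE_SPECIFIC_POSITIVE
    return OTHER


def read_gi_table(path: str | Path) -> list[GIRecord]:
    """Read a 5-column TSV (gene_a, gene_b, s_untreated, s_treated, p_diff).

    ``p_diff`` may be "NA".  A header row is detected by non-numeric
    score columns.  Identical gene pairs keep their last row.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 4:
        raise DomainError("expected >= 4 tab-separated columns")
    first = df.iloc[0]
    try:
        float(first[2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    records: dict[frozenset, GIRecord] = {}
    for _, row in df.iterrows():
        p_raw = row[4] if len(row) > 4 else None
        p = None
        if p_raw is not None and str(p_raw).strip().upper() not in ("", "NA", "NAN"):
            p = float(p_raw)
        rec = GIRecord(str(row[0]), str(row[1]), float(row[2]), float(row[3]), p)
        records[frozenset((rec.gene_a, rec.gene_b))] = rec
    return list(records.values())


def classify_table(records: Iterable[GIRecord]) -> dict[str, list[GIRecord]]:
    out: dict[str, list[GIRecord]] = {
        DAMAGE_SPECIFIC_POSITIVE: [],
        STABLE_POSITIVE: [],
        OTHER: [],
    }
    for rec in records:
        out[classify_differential_gi(rec)].append(rec)
    return out


def write_edge_lists(classified: dict[str, list[GIRecord]], out_dir: str | Path) -> None:
    """Write one two-column edge list per non-empty category, usable as G."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for kind in (DAMAGE_SPECIFIC_POSITIVE, STABLE_POSITIVE):
        rows = sorted(
            (min(r.gene_a, r.gene_b), max(r.gene_a, r.gene_b))
            for r in classified.get(kind, [])
        )
        with (out_dir / f"{kind}.tsv").open("w") as fh:
            fh.write("node_a\tnode_b\n")
            for a, b in rows:
                fh.write(f"{a}\t{b}\n")
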