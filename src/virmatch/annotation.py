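"""Protein-domain hit filtering and auxiliary-metabolic-gene curation.

Consumes the per-domain tabular output of HMMER's hmmscan (domtblout),
applies the bit-score/E-value reporting thresholds (>= 30 bits, E <= 1e-3),
and sorts the surviving hits into curated categories.  The category rules are
case-insensitive substring patterns over the domain's target name and
description, shipped as an editable TSV seeded with the classes most relevant
to contaminated-aquifer viromes — copper and other metal resistance,
beta-lactamase / multidrug-efflux / aminoglycoside antibiotic resistance,
toxin-antitoxin systems, phage hallmark genes and generic metabolism — with
anything unmatched falling through to ``not_categorized``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

CATEGORIES = (
    "metal_resistance",
    "antibiotic_resistance",
    "toxin_antitoxin",
    "phage_hallmark",
    "metabolism",
    "not_categorized",
)

MIN_BIT_SCORE = 30.0
MAX_E_VALUE = 1e-3


@dataclass
class DomainHit:
    virus_id: str
    protein_id: str
    target_name: str
    target_accession: str
    description: str
    bit_score: float
    e_value: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("E-value must be non-negative")


@dataclass
class CurationRule:
    category: str
    patterns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not self.patterns and self.category != "not_categorized":
            raise ValueError("rules need at least one pattern")


def default_virus_of(protein_id: str) -> str:
    """Contig id from an ORF id of the form <contig>_<n>."""
    return protein_id.rsplit("_", 1)[0] if "_" in protein_id else protein_id


def read_domain_hits(path: str | Path, virus_of=default_virus_of) -> list[DomainHit]:
    """Parse a whitespace-delimited domtblout file ('#' lines are comments).

    One hit per domain line; the full-sequence E-value and score (columns 7
    and 8) are used.  Malformed lines are logged and skipped.
    """
    hits: list[DomainHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split(None, 22)
            if len(fields) < 14:
                logger.warning("%s:%d: truncated line skipped", path, lineno)
                continue
            try:
                e_value = float(fields[6])
                bit_score = float(fields[7])
            except ValueError:
                logger.warning("%s:%d: malformed line skipped", path, lineno)
                continue
            hits.append(
                DomainHit(
                    virus_id=virus_of(fields[3]),
                    protein_id=fields[3],
                    target_name=fields[0],
                    target_accession=fields[1],
                    description=fields[22].strip() if len(fields) > 22 else "",
                    bit_score=bit_score,
                    e_value=e_value,
                )
            )
    return hits


def filter_hits(
    hits: Iterable[DomainHit],
    min_bit: float = MIN_BIT_SCORE,
    max_e: float = MAX_E_VALUE,
) -> list[DomainHit]:
    """Keep hits with bit score >= *min_bit* and E-value <= *max_e*."""
    return [h for h in hits if h.bit_score >= min_bit and h.e_value <= max_e]


def load_rules(path: str | Path | None = None) -> list[CurationRule]:
    """Load the curation rule table (category, pattern, priority).

    Rules are ordered by ascending priority, then file order; resistance
    classes ship with lower priority numbers than generic classes so they win
    on overlapping patterns.  Without *path* the packaged defaults are used.
    """
    if path is None:
        source = resources.files("virmatch").joinpath("data/curation_rules.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    rows.sort(key=lambda r: int(r["priority"]))
    ordered: list[CurationRule] = []
    for row in rows:
        if ordered and ordered[-1].category == row["category"]:
            ordered[-1].patterns.append(row["pattern"])
        else:
            ordered.append(CurationRule(row["category"], [row["pattern"]]))
    return ordered


def categorize(
    hits: Sequence[DomainHit],
    rules: Sequence[CurationRule] | None = None,
) -> pd.DataFrame:
    """Assign each hit the first matching rule's category.

    Matching is a case-insensitive substring test against the hit's target
    name or description; unmatched hits become ``not_categorized``.  Returns
    a tidy frame (one row per hit) with its category.
    """
    if rules is None:
        rules = load_rules()
    records = []
    for h in hits:
        haystack = f"{h.target_name} {h.description}".lower()
        category = "not_categorized"
        for rule in rules:
            if any(p.lower() in haystack for p in rule.patterns):
                category = rule.category
                break
        records.append(
            {
                "virus_id": h.virus_id,
                "protein_id": h.protein_id,
                "target_name": h.target_name,
                "target_accession": h.target_accession,
                "description": h.description,
                "bit_score": h.bit_score,
                "e_value": h.e_value,
                "category": category,
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["virus_id", "protein_id", "target_name", "target_accession",
                 "description", "bit_score", "e_value", "category"],
    )


def category_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-virus count matrix (viruses x categories)."""
    if table.empty:
        return pd.DataFrame(columns=list(CATEGORIES))
    counts = (
        table.groupby(["virus_id", "category"]).size().unstack(fill_value=0)
    )
    return counts.reindex(columns=list(CATEGORIES), fill_value=0)
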