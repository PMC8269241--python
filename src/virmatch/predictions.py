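"""Shared host-prediction record and its TSV dialect.

All four methods (4mer, blast, blast99, crispr) emit the same record so the
consensus stage can merge them.  No-calls are explicit rows with a status
column, distinguishing "method ran, no prediction" from "method not run".
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

METHODS = ("4mer", "blast", "blast99", "crispr")

#: confidence ordering used for the consensus best-rank call
METHOD_PRIORITY = {"crispr": 0, "blast99": 1, "blast": 2, "4mer": 3}


@dataclass
class HostPrediction:
    virus_id: str
    method: str
    taxon_name: str | None
    taxon_rank: str | None
    score: float | None = None
    evidence: list[str] = field(default_factory=list)
    n_candidates: int = 0
    unresolved: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown prediction method {self.method!r}")

    @property
    def is_call(self) -> bool:
        return self.taxon_name is not None

    @classmethod
    def no_call(cls, virus_id: str, method: str) -> "HostPrediction":
        return cls(virus_id=virus_id, method=method, taxon_name=None, taxon_rank=None)


PREDICTION_COLUMNS = (
    "virus_id",
    "method",
    "status",
    "assigned_taxon",
    "assigned_rank",
    "score",
    "n_candidates",
    "evidence",
)


def write_predictions(preds: Iterable[HostPrediction], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(PREDICTION_COLUMNS)
        for p in preds:
            writer.writerow(
                [
                    p.virus_id,
                    p.method,
                    "call" if p.is_call else "no_call",
                    p.taxon_name or "",
                    p.taxon_rank or "",
                    "" if p.score is None else f"{p.score:.6g}",
                    p.n_candidates,
                    ";".join(p.evidence),
                ]
            )


def read_predictions(path: str | Path) -> list[HostPrediction]:
    out: list[HostPrediction] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            is_call = row["status"] == "call"
            out.append(
                HostPrediction(
                    virus_id=row["virus_id"],
                    method=row["method"],
                    taxon_name=row["assigned_taxon"] if is_call else None,
                    taxon_rank=row["assigned_rank"] if is_call else None,
                    score=float(row["score"]) if row["score"] else None,
                    evidence=row["evidence"].split(";") if row["evidence"] else [],
                    n_candidates=int(row["n_candidates"]),
                )
            )
    return out
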