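"""End-to-end orchestration, consensus merging and cluster consistency.

Per-method predictions are merged into one row per virus.  Agreement is
judged at genus rank: the calling methods agree when all of their calls sit
on one lineage chain at genus rank or shallower (a strain-level call and a
genus-level call to the same genus agree; calls in different families
disagree).  The best-rank call is the deepest-rank prediction, ties resolved
by the methods' accuracy ordering crispr > blast99 > blast > 4mer.

Within-cluster consistency takes a virus -> cluster map (clusters stand in
for virus genera grouped by shared gene content) and reports, per cluster,
the LCA of the members' best-rank host calls and the rank it lands on.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import circularity as circ
from . import community as comm
from . import crispr as cr
from . import kmer as km
from . import similarity as sim
from .predictions import (
    METHOD_PRIORITY,
    METHODS,
    HostPrediction,
    write_predictions,
)
from .taxonomy import RANKS, TaxonNode, TaxonomyTree, lca_nodes

logger = logging.getLogger(__name__)

_RANK_DEPTH = {r: i for i, r in enumerate(RANKS)}
_GENUS_DEPTH = _RANK_DEPTH["genus"]


class PipelineError(RuntimeError):
    pass


@dataclass
class ConsensusRow:
    virus_id: str
    assignments: dict[str, TaxonNode]  # method -> resolved node (calls only)
    genus_agreement: str = field(init=False)  # agree | disagree | single-method
    best_method: str = field(init=False)
    best_taxon: TaxonNode = field(init=False)

    def __post_init__(self) -> None:
        if not self.assignments:
            raise PipelineError(f"{self.virus_id}: consensus row without any call")
        self.genus_agreement = self._agreement()
        self.best_method, self.best_taxon = self._best_rank_call()

    def _agreement(self) -> str:
        if len(self.assignments) == 1:
            return "single-method"
        lifted = []
        for node in self.assignments.values():
            if node.depth > _GENUS_DEPTH:
                node = node.ancestor_at("genus") or node
            lifted.append(node)
        deepest = max(lifted, key=lambda n: n.depth)
        ok = all(n.is_ancestor_of(deepest) for n in lifted)
        return "agree" if ok else "disagree"

    def _best_rank_call(self) -> tuple[str, TaxonNode]:
        method = min(
            self.assignments,
            key=lambda m: (-self.assignments[m].depth, METHOD_PRIORITY[m]),
        )
        return method, self.assignments[method]


def consensus(
    predictions: Sequence[HostPrediction], tree: TaxonomyTree
) -> list[ConsensusRow]:
    """One row per virus with at least one call, agreement judged at genus.

    Strain-rank methods (blast99, crispr) may legitimately emit several
    strains for one virus; those collapse to the strains' LCA.  Two rows for
    one (virus, method) naming different taxa at the same rank are treated as
    a conflicting duplicate and rejected for the single-call methods.
    """
    by_virus_method: dict[str, dict[str, list[HostPrediction]]] = {}
    for p in predictions:
        if not p.is_call:
            continue
        by_virus_method.setdefault(p.virus_id, {}).setdefault(p.method, []).append(p)

    rows = []
    for vid in sorted(by_virus_method):
        assignments: dict[str, TaxonNode] = {}
        for method, preds in by_virus_method[vid].items():
            nodes = [tree.node(p.taxon_name, p.taxon_rank) for p in preds]
            if len(nodes) > 1 and method in ("4mer", "blast"):
                raise PipelineError(
                    f"conflicting duplicate predictions for ({vid}, {method})"
                )
            assignments[method] = nodes[0] if len(nodes) == 1 else lca_nodes(nodes)
        rows.append(ConsensusRow(virus_id=vid, assignments=assignments))
    return rows


CONSENSUS_COLUMNS = (
    "virus_id", "4mer", "blast", "blast99", "crispr",
    "genus_agreement", "best_method", "best_taxon", "best_rank",
)


def write_consensus(rows: Sequence[ConsensusRow], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CONSENSUS_COLUMNS)
        for r in rows:
            cells = []
            for m in METHODS:
                node = r.assignments.get(m)
                cells.append(f"{node.name}({node.rank})" if node else "no_call")
            w.writerow([r.virus_id, *cells, r.genus_agreement,
                        r.best_method, r.best_taxon.name, r.best_taxon.rank])


@dataclass
class ClusterConsistency:
    cluster_id: str
    member_viruses: list[str]
    predicted_members: list[str]
    cluster_lca: TaxonNode | None
    consistent_at_rank: str | None

    @property
    def n_predicted(self) -> int:
        return len(self.predicted_members)


def cluster_consistency(
    rows: Sequence[ConsensusRow],
    cluster_map: Mapping[str, str],
) -> list[ClusterConsistency]:
    """Per-cluster LCA of the members' best-rank host calls.

    Mapped viruses missing from the consensus count as no-prediction members
    (logged); a cluster with a single predicted member is trivially
    consistent at that member's rank (flagged by n_predicted = 1).
    """
    by_virus = {r.virus_id: r for r in rows}
    clusters: dict[str, list[str]] = {}
    for vid, cid in cluster_map.items():
        clusters.setdefault(cid, []).append(vid)
    out = []
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        predicted = [v for v in members if v in by_virus]
        for v in members:
            if v not in by_virus:
                logger.info("cluster %s: member %s has no prediction", cid, v)
        if predicted:
            node = lca_nodes([by_virus[v].best_taxon for v in predicted])
            rank = node.rank
        else:
            node, rank = None, None
        out.append(
            ClusterConsistency(
                cluster_id=cid,
                member_viruses=members,
                predicted_members=predicted,
                cluster_lca=node,
                consistent_at_rank=rank,
            )
        )
    return out


CLUSTER_COLUMNS = ("cluster_id", "n_members", "n_predicted",
                   "cluster_lca", "consistent_at_rank")


def write_cluster_consistency(
    results: Sequence[ClusterConsistency], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLUSTER_COLUMNS)
        for c in results:
            w.writerow([
                c.cluster_id, len(c.member_viruses), c.n_predicted,
                c.cluster_lca.name if c.cluster_lca else "",
                c.consistent_at_rank or "",
            ])


# ---------------------------------------------------------------------------
# full run

ALL_STAGES = ("simulate", "circularity", "predict-kmer", "predict-similarity",
              "predict-crispr", "annotate", "consensus", "cluster-consistency")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunResult:
    out_dir: Path
    community: comm.Community
    circularity_calls: list[circ.CircularityCall]
    predictions: list[HostPrediction]
    consensus_rows: list[ConsensusRow]
    clusters: list[ClusterConsistency]
    regions: dict[str, list[sim.SimilarityRegion]]
    arrays: list[cr.CrisprArray]
    matches: list[cr.SpacerMatch]


def run_all(
    out_dir: str | Path,
    seed: int,
    config: comm.CommunityConfig | None = None,
    stages: Sequence[str] | None = None,
    domtblout: str | Path | None = None,
    threads: int = 1,
) -> RunResult:
    """Simulate the default community and run every stage over it.

    Outputs are deterministic for a fixed (config, seed): rerunning writes
    byte-identical TSVs, and *threads* never affects any output (the contract
    holds trivially — every stage is sequential).  A manifest records the
    package version, parameters and input checksums.
    """
    stages = list(stages or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages: {sorted(unknown)}")
    if domtblout is not None and not Path(domtblout).exists():
        raise PipelineError(f"domain hits file not found: {domtblout}")

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    com = comm.generate_community(seed, config)
    input_paths = {}
    if "simulate" in stages:
        input_paths = comm.write_community(com, out / "inputs")

    calls: list[circ.CircularityCall] = []
    if "circularity" in stages:
        for vid, info in com.viruses.items():
            pairs = [(p.r1, p.r2) for p in com.reads[vid]]
            calls.append(circ.classify_circular(vid, info.contig, pairs))
        circ.write_calls(calls, out / "circularity.tsv")

    predictions: list[HostPrediction] = []
    virus_contigs = com.virus_contigs()
    host_contigs = com.host_contigs()

    if "predict-kmer" in stages:
        host_profiles = km.profile_database(host_contigs)
        kmer_preds = []
        for vid, contig in virus_contigs.items():
            vp = km.canonical_profile(contig, owner_id=vid)
            pred = km.predict_host_kmer(vid, vp, host_profiles, com.tree)
            if len(contig) < 4_000:
                pred.evidence.append("low_confidence:short_contig")
            kmer_preds.append(pred)
        write_predictions(kmer_preds, out / "predictions_4mer.tsv")
        predictions.extend(kmer_preds)

    regions: dict[str, list[sim.SimilarityRegion]] = {}
    if "predict-similarity" in stages:
        regions = sim.scan_community(virus_contigs, host_contigs)
        blast_preds, blast99_preds = [], []
        for vid, contig in virus_contigs.items():
            blast_preds.append(
                sim.predict_host_blast(vid, len(contig), regions[vid], com.tree)
            )
            strain_calls = sim.predict_host_blast99(vid, len(contig), regions[vid])
            if strain_calls:
                blast99_preds.extend(strain_calls)
            else:
                blast99_preds.append(HostPrediction.no_call(vid, "blast99"))
        write_predictions(blast_preds, out / "predictions_blast.tsv")
        write_predictions(blast99_preds, out / "predictions_blast99.tsv")
        predictions.extend(blast_preds)
        predictions.extend(blast99_preds)

    arrays: list[cr.CrisprArray] = []
    matches: list[cr.SpacerMatch] = []
    if "predict-crispr" in stages:
        for strain, contigs in host_contigs.items():
            arrays.extend(cr.detect_crispr_arrays(strain, contigs))
        matches = cr.match_spacers(arrays, virus_contigs)
        crispr_preds = cr.predict_host_crispr(matches, host_contigs)
        called = {p.virus_id for p in crispr_preds}
        for vid in virus_contigs:
            if vid not in called:
                crispr_preds.append(HostPrediction.no_call(vid, "crispr"))
        cr.write_arrays(arrays, out / "crispr_arrays.tsv")
        cr.write_matches(matches, out / "crispr_matches.tsv")
        write_predictions(crispr_preds, out / "predictions_crispr.tsv")
        predictions.extend(crispr_preds)

    if "annotate" in stages and domtblout is not None:
        from . import annotation as ann

        hits = ann.filter_hits(ann.read_domain_hits(domtblout))
        table = ann.categorize(hits)
        table.to_csv(out / "annotation_categories.tsv", sep="\t", index=False)
        ann.category_counts(table).to_csv(out / "annotation_counts.tsv", sep="\t")

    rows: list[ConsensusRow] = []
    if "consensus" in stages:
        rows = consensus(predictions, com.tree)
        write_consensus(rows, out / "consensus.tsv")

    clusters: list[ClusterConsistency] = []
    if "cluster-consistency" in stages:
        clusters = cluster_consistency(rows, com.cluster_map)
        write_cluster_consistency(clusters, out / "cluster_consistency.tsv")

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": seed,
        "threads": threads,
        "stages": stages,
        "config": {k: v for k, v in vars(com.config).items()},
        "input_checksums": {
            name: _sha256(p)
            for name, p in sorted(input_paths.items())
            if isinstance(p, Path) and p.is_file()
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n"
    )
    return RunResult(
        out_dir=out,
        community=com,
        circularity_calls=calls,
        predictions=predictions,
        consensus_rows=rows,
        clusters=clusters,
        regions=regions,
        arrays=arrays,
        matches=matches,
    )
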