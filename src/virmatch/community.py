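"""Default synthetic community: taxa, viruses and planted signals.

This is the standing test-bed for the pipeline: ten host strains across four
genera (two Proteobacteria genera, one Actinobacteria, one Firmicutes) and
eighteen viruses covering every planted relationship class the prediction
methods are supposed to detect:

* six composition-linked viruses (genus Markov model shared with the host),
* three uniform-background viruses (should produce no-calls everywhere),
* two full prophages (strain-level containment; one planted in two strains),
* three partial prophages of 6 kb at 0.75 / 0.85 / 0.95 identity,
* two below-threshold controls (4.5 kb at 0.95, and 6 kb at 0.65) that must
  never produce a shared-region call,
* two CRISPR-targeted viruses whose spacers sit in host arrays at 0, 1 and 2
  mismatches (the 2-mismatch spacer is a planted negative).

Sizes are deliberately modest (60-kb hosts, 10-30-kb viruses) so an
end-to-end run takes seconds while keeping 4-mer sampling noise comfortably
below the 0.001 assignment threshold.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from . import synthetic as syn
from .taxonomy import LINEAGE_COLUMNS, TaxonomyTree

# strain -> (phylum, class, order, family, genus, species)
DEFAULT_TAXA: dict[str, tuple[str, ...]] = {
    "Pseudomonas_P1": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
                       "Pseudomonadaceae", "Pseudomonas", "Pseudomonas fluorescens"),
    "Pseudomonas_P2": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
                       "Pseudomonadaceae", "Pseudomonas", "Pseudomonas putida"),
    "Pseudomonas_P3": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonadales",
                       "Pseudomonadaceae", "Pseudomonas", "Pseudomonas stutzeri"),
    "Acidovorax_A1": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales",
                      "Comamonadaceae", "Acidovorax", "Acidovorax delafieldii"),
    "Acidovorax_A2": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales",
                      "Comamonadaceae", "Acidovorax", "Acidovorax temperans"),
    "Acidovorax_A3": ("Proteobacteria", "Betaproteobacteria", "Burkholderiales",
                      "Comamonadaceae", "Acidovorax", "Acidovorax facilis"),
    "Streptomyces_S1": ("Actinobacteria", "Actinomycetia", "Streptomycetales",
                        "Streptomycetaceae", "Streptomyces", "Streptomyces coelicolor"),
    "Streptomyces_S2": ("Actinobacteria", "Actinomycetia", "Streptomycetales",
                        "Streptomycetaceae", "Streptomyces", "Streptomyces griseus"),
    "Bacillus_B1": ("Firmicutes", "Bacilli", "Bacillales",
                    "Bacillaceae", "Bacillus", "Bacillus subtilis"),
    "Bacillus_B2": ("Firmicutes", "Bacilli", "Bacillales",
                    "Bacillaceae", "Bacillus", "Bacillus cereus"),
}

GENUS_OF = {strain: lineage[4] for strain, lineage in DEFAULT_TAXA.items()}


@dataclass
class CommunityConfig:
    """Generator knobs; the defaults are the standing study conditions."""

    host_length: int = 60_000
    strain_mutation_rate: float = 0.005
    n_contigs: int = 1
    divergence: float = 1.0  # genus Dirichlet concentration
    linked_virus_length: int = 30_000
    prophage_virus_length: int = 10_000
    region_virus_length: int = 20_000
    partial_region_len: int = 6_000
    partial_identities: tuple[float, ...] = (0.75, 0.85, 0.95)
    n_read_pairs: int = 1_000
    read_len: int = 100
    insert_mean: int = 500
    insert_sd: float = 50.0
    terminal_repeat: int = 45


@dataclass
class VirusInfo:
    virus_id: str
    genome: str  # the circular (or linear) genome itself
    contig: str  # assembled representation (terminal repeat if circular)
    circular: bool
    source_genus: str | None  # genus model it was emitted from, None = background


@dataclass
class Community:
    config: CommunityConfig
    seed: int
    tree: TaxonomyTree
    lineage_rows: list[dict[str, str]]
    hosts: dict[str, syn.HostGenome]
    viruses: dict[str, VirusInfo]
    truth: list[syn.TruthRecord]
    arrays: list[syn.PlantedArray]
    reads: dict[str, list[syn.ReadPair]]
    cluster_map: dict[str, str] = field(default_factory=dict)

    def host_contigs(self) -> dict[str, list[str]]:
        return {s: g.contigs for s, g in self.hosts.items()}

    def virus_contigs(self) -> dict[str, str]:
        return {v: info.contig for v, info in self.viruses.items()}


DEFAULT_CLUSTERS = {
    "VC_pseudo": ("v_comp_pseudo_a", "v_comp_pseudo_b", "v_full_pseudo", "v_part_95"),
    "VC_acido": ("v_comp_acido_a", "v_comp_acido_b", "v_full_acido"),
    "VC_strep": ("v_comp_strep_a", "v_part_75"),
    "VC_bac": ("v_comp_bac_a", "v_part_85"),
    "VC_crispr": ("v_cr_a", "v_cr_b"),
    "VC_bg": ("v_bg_a", "v_bg_b", "v_bg_c", "v_ctrl_short", "v_ctrl_lowid"),
}


def _strain_seed(seed: int, label: str) -> int:
    return int(syn.child_rng(seed, f"seed:{label}").integers(0, 2**31))


def generate_community(seed: int, config: CommunityConfig | None = None) -> Community:
    """Build the default community deterministically from one global seed."""
    cfg = config or CommunityConfig()

    # taxonomy
    tree = TaxonomyTree()
    lineage_rows = []
    for strain, lineage in DEFAULT_TAXA.items():
        pairs = list(zip(LINEAGE_COLUMNS, lineage))
        tree.add_strain(strain, pairs)
        lineage_rows.append({"strain_id": strain, **dict(pairs)})

    # genus composition models
    genera = sorted(set(GENUS_OF.values()))
    models = {
        g: syn.build_genus_model(g, seed=_strain_seed(seed, f"model:{g}"),
                                 divergence=cfg.divergence)
        for g in genera
    }

    # host genomes: independent emissions per strain, plus strain-level SNPs
    hosts = {
        strain: syn.generate_host_genome(
            models[GENUS_OF[strain]],
            length=cfg.host_length,
            seed=_strain_seed(seed, f"host:{strain}"),
            strain_id=strain,
            strain_mutation_rate=cfg.strain_mutation_rate,
            n_contigs=cfg.n_contigs,
        )
        for strain in DEFAULT_TAXA
    }

    truth: list[syn.TruthRecord] = []
    viruses: dict[str, VirusInfo] = {}

    def add_virus(vid: str, length: int, genus: str | None, circular: bool = True) -> str:
        genome = syn.generate_virus(
            length,
            seed=_strain_seed(seed, f"virus:{vid}"),
            virus_id=vid,
            source_model=models[genus] if genus else None,
        )
        contig = syn.circularized_contig(genome, cfg.terminal_repeat) if circular else genome
        viruses[vid] = VirusInfo(vid, genome, contig, circular, genus)
        return genome

    # composition-linked viruses (signal: 4-mer only)
    comp_plan = [
        ("v_comp_pseudo_a", "Pseudomonas", "Pseudomonas_P1"),
        ("v_comp_pseudo_b", "Pseudomonas", "Pseudomonas_P2"),
        ("v_comp_acido_a", "Acidovorax", "Acidovorax_A1"),
        ("v_comp_acido_b", "Acidovorax", "Acidovorax_A2"),
        ("v_comp_strep_a", "Streptomyces", "Streptomyces_S1"),
        ("v_comp_bac_a", "Bacillus", "Bacillus_B1"),
    ]
    for vid, genus, rep_strain in comp_plan:
        add_virus(vid, cfg.linked_virus_length, genus)
        truth.append(syn.TruthRecord(vid, rep_strain, "composition_only"))

    # background viruses (no planted signal at all)
    for vid in ("v_bg_a", "v_bg_b", "v_bg_c"):
        add_virus(vid, cfg.linked_virus_length, None)

    # full prophages (signal: whole-virus containment)
    g = add_virus("v_full_pseudo", cfg.prophage_virus_length, "Pseudomonas")
    hosts["Pseudomonas_P1"], rec = syn.plant_prophage(
        hosts["Pseudomonas_P1"], "v_full_pseudo", g, "full",
        seed=_strain_seed(seed, "plant:v_full_pseudo"))
    truth.append(rec)
    g = add_virus("v_full_acido", cfg.prophage_virus_length, "Acidovorax")
    for strain in ("Acidovorax_A1", "Acidovorax_A2"):
        hosts[strain], rec = syn.plant_prophage(
            hosts[strain], "v_full_acido", g, "full",
            seed=_strain_seed(seed, f"plant:v_full_acido:{strain}"))
        truth.append(rec)

    # partial prophages at graded identities
    partial_plan = list(zip(
        ("v_part_75", "v_part_85", "v_part_95"),
        ("Streptomyces", "Bacillus", "Pseudomonas"),
        ("Streptomyces_S1", "Bacillus_B1", "Pseudomonas_P2"),
        cfg.partial_identities,
    ))
    for vid, genus, strain, ident in partial_plan:
        g = add_virus(vid, cfg.region_virus_length, genus)
        hosts[strain], rec = syn.plant_prophage(
            hosts[strain], vid, g, "partial",
            seed=_strain_seed(seed, f"plant:{vid}"),
            region_len=cfg.partial_region_len, target_identity=ident)
        truth.append(rec)

    # below-threshold controls (must never yield shared-region calls)
    g = add_virus("v_ctrl_short", cfg.region_virus_length, None, circular=False)
    hosts["Acidovorax_A3"], rec = syn.plant_prophage(
        hosts["Acidovorax_A3"], "v_ctrl_short", g, "partial",
        seed=_strain_seed(seed, "plant:v_ctrl_short"),
        region_len=4_500, target_identity=0.95, as_control=True)
    truth.append(rec)
    g = add_virus("v_ctrl_lowid", cfg.region_virus_length, None, circular=False)
    hosts["Streptomyces_S2"], rec = syn.plant_prophage(
        hosts["Streptomyces_S2"], "v_ctrl_lowid", g, "partial",
        seed=_strain_seed(seed, "plant:v_ctrl_lowid"),
        region_len=cfg.partial_region_len, target_identity=0.65, as_control=True)
    truth.append(rec)

    # CRISPR-targeted viruses; arrays carry 0-, 1- and 2-mismatch spacers
    add_virus("v_cr_a", cfg.region_virus_length, None)
    add_virus("v_cr_b", cfg.region_virus_length, None)
    vpool = {vid: info.genome for vid, info in viruses.items()}
    arrays: list[syn.PlantedArray] = []

    repeat_rng = syn.child_rng(seed, "crispr-repeats")
    repeat_a = syn.emit_uniform(28, repeat_rng)
    repeat_b = syn.emit_uniform(30, repeat_rng)
    hosts["Pseudomonas_P3"], arr, recs = syn.plant_crispr_array(
        hosts["Pseudomonas_P3"], repeat_a,
        [syn.SpacerSpec("v_cr_a", 32, 0),
         syn.SpacerSpec("v_cr_a", 34, 2),
         syn.SpacerSpec(None, 30)],
        vpool, seed=_strain_seed(seed, "array:P3"))
    arrays.append(arr)
    truth.extend(recs)
    hosts["Bacillus_B2"], arr, recs = syn.plant_crispr_array(
        hosts["Bacillus_B2"], repeat_b,
        [syn.SpacerSpec("v_cr_b", 33, 1),
         syn.SpacerSpec(None, 36)],
        vpool, seed=_strain_seed(seed, "array:B2"))
    arrays.append(arr)
    truth.extend(recs)

    # read pairs per virus, drawn from the circular (or linear) genome
    reads = {
        vid: syn.simulate_read_pairs(
            info.genome,
            topology="circular" if info.circular else "linear",
            n_pairs=cfg.n_read_pairs,
            seed=_strain_seed(seed, f"reads:{vid}"),
            read_len=cfg.read_len,
            insert_mean=cfg.insert_mean,
            insert_sd=cfg.insert_sd,
            id_prefix=vid,
        )
        for vid, info in viruses.items()
    }

    cluster_map = {
        vid: cid for cid, vids in DEFAULT_CLUSTERS.items() for vid in vids
    }
    return Community(
        config=cfg, seed=seed, tree=tree, lineage_rows=lineage_rows,
        hosts=hosts, viruses=viruses, truth=truth, arrays=arrays,
        reads=reads, cluster_map=cluster_map,
    )


def kmer_recovery_experiment(
    seed: int,
    n_viruses: int = 100,
    config: CommunityConfig | None = None,
) -> dict[str, float]:
    """Composition-method recovery rates over freshly seeded viruses.

    Generates the default host collection, then *n_viruses* new viruses —
    alternating host-linked (cycling through the genera) and uniform
    background — and runs the 4-mer prediction on each.  Reports the fraction
    of host-linked viruses whose call resolves to the true genus and the
    fraction of background viruses left as no-calls.
    """
    from . import kmer as km

    cfg = config or CommunityConfig()
    com = generate_community(seed, cfg)
    host_profiles = km.profile_database(com.host_contigs())
    genera = sorted(set(GENUS_OF.values()))

    linked_total = linked_genus_ok = bg_total = bg_nocall = 0
    for i in range(n_viruses):
        vid = f"vx_{i:03d}"
        linked = i % 2 == 0
        genus = genera[(i // 2) % len(genera)] if linked else None
        model = (
            syn.build_genus_model(
                genus, seed=_strain_seed(seed, f"model:{genus}"),
                divergence=cfg.divergence)
            if linked else None
        )
        seq = syn.generate_virus(
            cfg.linked_virus_length, seed=_strain_seed(seed, f"xvirus:{vid}"),
            virus_id=vid, source_model=model)
        pred = km.predict_host_kmer(
            vid, km.canonical_profile(seq, owner_id=vid), host_profiles, com.tree
        )
        if linked:
            linked_total += 1
            if pred.is_call:
                node = com.tree.node(pred.taxon_name, pred.taxon_rank)
                at_genus = node.ancestor_at("genus")
                if at_genus is not None and at_genus.name == genus:
                    linked_genus_ok += 1
        else:
            bg_total += 1
            if not pred.is_call:
                bg_nocall += 1
    return {
        "n_linked": linked_total,
        "n_background": bg_total,
        "linked_genus_recovery": linked_genus_ok / linked_total,
        "background_no_call": bg_nocall / bg_total,
    }


def write_community(com: Community, out_dir: str | Path) -> dict[str, Path]:
    """Serialise a community to FASTA/FASTQ/TSV under *out_dir*."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    host_seqs = {
        f"{strain}_c{i}": contig
        for strain, genome in com.hosts.items()
        for i, contig in enumerate(genome.contigs)
    }
    paths["hosts"] = out / "hosts.fasta"
    syn.write_fasta(host_seqs, paths["hosts"])

    paths["viruses"] = out / "viruses.fasta"
    syn.write_fasta(com.virus_contigs(), paths["viruses"])

    paths["lineage"] = out / "lineage.tsv"
    from .taxonomy import write_taxonomy

    write_taxonomy(com.lineage_rows, paths["lineage"])

    paths["truth"] = out / "truth.tsv"
    syn.write_truth(com.truth, paths["truth"])

    paths["arrays"] = out / "arrays_truth.tsv"
    with open(paths["arrays"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["host_strain", "contig_index", "start", "end", "repeat", "spacers"])
        for a in com.arrays:
            w.writerow([a.host_strain, a.contig_index, a.start, a.end,
                        a.repeat, ";".join(a.spacers)])

    paths["clusters"] = out / "cluster_map.tsv"
    with open(paths["clusters"], "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["virus_id", "cluster_id"])
        for vid, cid in com.cluster_map.items():
            w.writerow([vid, cid])

    reads_dir = out / "reads"
    reads_dir.mkdir(exist_ok=True)
    for vid, pairs in com.reads.items():
        syn.write_fastq_pairs(pairs, reads_dir / vid)
    paths["reads_dir"] = reads_dir
    return paths
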