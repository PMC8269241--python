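"""Synthetic phage-host community generator with ground truth.

Builds everything the downstream stages consume — host genomes, viral
contigs, planted prophages, CRISPR arrays, paired reads — together with truth
tables recording every planted virus-host relationship, so the whole pipeline
is testable without any external download.

The generative model is an order-3 Markov chain per genus: each genus gets a
transition table (3-mer context -> base distribution) drawn from a Dirichlet,
and both the genus's host strains and its host-linked viruses are emitted
from that shared table.  This directly controls the tetranucleotide signal
the composition method consumes: same-genus sequences converge to the same
4-mer profile while different genera (or the uniform background) stay apart.

Prophage integration is emulated by inserting a (possibly substitution-
mutated) copy of a virus, or a window of it, into a host contig; CRISPR
history by inserting a repeat-spacer array whose spacers are windows of the
viral pool carrying an exact number of mismatches.  Reads are drawn from
circular or linear templates so junction-spanning pairs exist exactly when
the template is circular.

All generation is a pure function of (config, seed).  One global seed expands
to per-component child seeds via ``SeedSequence([seed, crc32(label)])`` where
*label* names the component (documented splitting rule; regeneration of one
component never perturbs another).
"""

from __future__ import annotations

import csv
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ORDER = 3
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

RELATIONS = (
    "composition_only",
    "full_prophage",
    "partial_prophage",
    "crispr_spacer",
    "control_region",  # deliberately out-of-threshold negative controls
)


class GeneratorError(ValueError):
    pass


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Per-component generator derived from the global seed (splitting rule)."""
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))
    )


# ---------------------------------------------------------------------------
# composition models and sequence emission


@dataclass
class CompositionModel:
    """Order-3 Markov emission model defining a genus's nucleotide signature."""

    genus_id: str
    transition_probs: np.ndarray  # (64, 4), rows sum to 1
    order: int = ORDER

    def __post_init__(self) -> None:
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        if self.transition_probs.shape != (4**self.order, 4):
            raise GeneratorError("transition table must be (64, 4)")
        if (self.transition_probs < 0).any() or np.any(
            np.abs(self.transition_probs.sum(axis=1) - 1.0) > 1e-9
        ):
            raise GeneratorError("each context's probabilities must sum to 1")
        self._cum = np.cumsum(self.transition_probs, axis=1)

    @property
    def cumprobs(self) -> np.ndarray:
        return self._cum


def build_genus_model(
    genus_id: str, seed: int, divergence: float = 1.0
) -> CompositionModel:
    """Draw a genus composition model.

    *divergence* is the Dirichlet concentration per context: lower values give
    more distinctive genus compositions, and in the limit of large
    concentration every context approaches uniform(0.25).  The default of 1.0
    was calibrated so that two independently drawn genera differ by a 4-mer
    MAE well above the 0.001 assignment threshold.
    """
    if divergence <= 0:
        raise GeneratorError("divergence must be positive")
    rng = child_rng(seed, f"genus-model:{genus_id}")
    probs = rng.dirichlet(np.full(4, divergence), size=4**ORDER)
    return CompositionModel(genus_id=genus_id, transition_probs=probs)


def emit_sequence(model: CompositionModel, length: int, rng: np.random.Generator) -> str:
    """Emit *length* bases from the Markov model (first ORDER bases uniform)."""
    if length < 4 * (ORDER + 1):
        raise GeneratorError(f"length {length} too short for order-{ORDER} emission")
    cum = [tuple(row) for row in model.cumprobs]
    us = rng.random(length)
    out = bytearray(length)
    bases = b"ACGT"
    ctx = 0
    for i in range(ORDER):
        b = min(int(us[i] * 4), 3)
        out[i] = bases[b]
        ctx = ((ctx << 2) | b) & 63
    for i in range(ORDER, length):
        u = us[i]
        row = cum[ctx]
        if u < row[0]:
            b = 0
        elif u < row[1]:
            b = 1
        elif u < row[2]:
            b = 2
        else:
            b = 3
        out[i] = bases[b]
        ctx = ((ctx << 2) | b) & 63
    return out.decode("ascii")


def emit_uniform(length: int, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=length)
    return "".join(_BASES[c] for c in codes)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-site substitutions at the given rate (never identity)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hit.size:
        code = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            code[ord(b)] = i
        old = code[arr[hit]]
        new = (old + rng.integers(1, 4, size=hit.size)) % 4
        lut = np.frombuffer(b"ACGT", dtype=np.uint8)
        arr[hit] = lut[new]
    return arr.tobytes().decode("ascii")


def mutate_exact(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly *n_subs* distinct positions (Hamming distance n_subs)."""
    if n_subs == 0:
        return seq
    if n_subs > len(seq):
        raise GeneratorError("more substitutions than positions")
    arr = list(seq)
    pos = rng.choice(len(seq), size=n_subs, replace=False)
    for p in pos:
        choices = [b for b in _BASES if b != arr[p]]
        arr[p] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# hosts and viruses


@dataclass
class HostGenome:
    strain_id: str
    contigs: list[str]
    parent: str  # pre-mutation emission, for mutation-rate checks

    @property
    def length(self) -> int:
        return sum(len(c) for c in self.contigs)


def generate_host_genome(
    model: CompositionModel,
    length: int,
    seed: int,
    strain_id: str = "strain",
    strain_mutation_rate: float = 0.0,
    n_contigs: int = 1,
) -> HostGenome:
    """Emit a (possibly multi-contig) host genome from a genus model.

    The same (model, seed) always yields the same parent emission; strain-
    level point mutations are then applied at *strain_mutation_rate*, so two
    strains generated from the same model and seed with rate 0 are identical.
    """
    if length < 4 * (ORDER + 1):
        raise GeneratorError(f"genome length {length} too short")
    if n_contigs < 1 or n_contigs > length:
        raise GeneratorError("invalid contig count")
    rng = child_rng(seed, f"host:{model.genus_id}")
    parent = emit_sequence(model, length, rng)
    mut_rng = child_rng(seed, f"host-mut:{strain_id}")
    genome = mutate(parent, strain_mutation_rate, mut_rng)
    bounds = np.linspace(0, length, n_contigs + 1).astype(int)
    contigs = [genome[bounds[i] : bounds[i + 1]] for i in range(n_contigs)]
    return HostGenome(strain_id=strain_id, contigs=contigs, parent=parent)


VIRUS_LENGTH_RANGE = (4_000, 300_000)


def generate_virus(
    length: int,
    seed: int,
    virus_id: str = "virus",
    source_model: CompositionModel | None = None,
) -> str:
    """Emit one viral contig, either host-linked (genus model) or background.

    Host-linked viruses share the genus Markov table, emulating the tendency
    of phage genomes to mirror their host's composition; background viruses
    are uniform i.i.d. sequence.
    """
    lo, hi = VIRUS_LENGTH_RANGE
    if not lo <= length <= hi:
        raise GeneratorError(f"virus length {length} outside [{lo}, {hi}]")
    rng = child_rng(seed, f"virus:{virus_id}")
    if source_model is None:
        return emit_uniform(length, rng)
    return emit_sequence(source_model, length, rng)


# ---------------------------------------------------------------------------
# truth records


@dataclass
class TruthRecord:
    """One planted virus-host relationship."""

    virus_id: str
    true_host_strain: str
    relation: str
    host_contig: int = 0
    host_start: int = -1  # 0-based insertion point in the mutated contig
    region_len: int = 0
    virus_start: int = -1  # source window start on the virus
    target_identity: float = 1.0
    spacer_mismatches: int = -1  # only for crispr_spacer rows
    spacer_seq: str = ""

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise GeneratorError(f"unknown relation {self.relation!r}")
        if self.relation == "partial_prophage":
            if self.region_len < 4_900:
                raise GeneratorError("partial prophage regions must be >= 4.9 kb")
            if not 0.70 <= self.target_identity <= 1.0:
                raise GeneratorError("partial prophage identity must be in [0.70, 1]")
        if self.relation == "crispr_spacer" and self.spacer_mismatches not in (0, 1, 2):
            raise GeneratorError("spacer mismatches must be 0, 1 or 2")


TRUTH_COLUMNS = (
    "virus_id",
    "true_host_strain",
    "relation",
    "host_contig",
    "host_start",
    "region_len",
    "virus_start",
    "target_identity",
    "spacer_mismatches",
    "spacer_seq",
)


def write_truth(records: Iterable[TruthRecord], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.virus_id,
                    r.true_host_strain,
                    r.relation,
                    r.host_contig,
                    r.host_start,
                    r.region_len,
                    r.virus_start,
                    f"{r.target_identity:.4f}",
                    r.spacer_mismatches,
                    r.spacer_seq,
                ]
            )


def read_truth(path: str | Path) -> list[TruthRecord]:
    out: list[TruthRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                TruthRecord(
                    virus_id=row["virus_id"],
                    true_host_strain=row["true_host_strain"],
                    relation=row["relation"],
                    host_contig=int(row["host_contig"]),
                    host_start=int(row["host_start"]),
                    region_len=int(row["region_len"]),
                    virus_start=int(row["virus_start"]),
                    target_identity=float(row["target_identity"]),
                    spacer_mismatches=int(row["spacer_mismatches"]),
                    spacer_seq=row["spacer_seq"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# prophage and CRISPR planting

EDGE_EXCLUSION = 1_000  # planted loci stay this far from contig ends


def _insertion_point(contig_len: int, rng: np.random.Generator) -> int:
    lo, hi = EDGE_EXCLUSION, contig_len - EDGE_EXCLUSION
    if hi <= lo:
        raise GeneratorError("contig too short for an interior insertion")
    return int(rng.integers(lo, hi))


def plant_prophage(
    host: HostGenome,
    virus_id: str,
    virus_seq: str,
    mode: str,
    seed: int,
    region_len: int | None = None,
    target_identity: float = 1.0,
    as_control: bool = False,
) -> tuple[HostGenome, TruthRecord]:
    """Insert a full or partial prophage copy into a host contig.

    ``full`` mode inserts an exact copy of the whole virus (strain-level
    containment signal); ``partial`` inserts a window of *region_len* bases
    mutated to exactly the requested Hamming identity (shared-region signal).
    *as_control* relaxes the >=4.9 kb / >=0.70 constraints and records the
    relation as ``control_region`` — used to plant below-threshold negatives.
    """
    rng = child_rng(seed, f"prophage:{virus_id}:{host.strain_id}")
    if mode == "full":
        region_len = len(virus_seq)
        v_start = 0
        insert = virus_seq
        relation = "full_prophage"
        target_identity = 1.0
    elif mode == "partial":
        if region_len is None:
            raise GeneratorError("partial mode requires region_len")
        if region_len > len(virus_seq):
            raise GeneratorError("region longer than the virus")
        if not as_control:
            if region_len < 4_900:
                raise GeneratorError("partial prophage regions must be >= 4.9 kb")
            if not 0.70 <= target_identity <= 1.0:
                raise GeneratorError("target identity must be in [0.70, 1]")
        v_start = int(rng.integers(0, len(virus_seq) - region_len + 1))
        window = virus_seq[v_start : v_start + region_len]
        n_subs = round((1.0 - target_identity) * region_len)
        insert = mutate_exact(window, n_subs, rng)
        relation = "control_region" if as_control else "partial_prophage"
    else:
        raise GeneratorError(f"unknown prophage mode {mode!r}")

    ci = max(range(len(host.contigs)), key=lambda i: len(host.contigs[i]))
    contig = host.contigs[ci]
    pos = _insertion_point(len(contig), rng)
    new_contigs = list(host.contigs)
    new_contigs[ci] = contig[:pos] + insert + contig[pos:]
    record = TruthRecord(
        virus_id=virus_id,
        true_host_strain=host.strain_id,
        relation=relation,
        host_contig=ci,
        host_start=pos,
        region_len=region_len,
        virus_start=v_start,
        target_identity=target_identity,
    )
    return replace(host, contigs=new_contigs), record


@dataclass
class PlantedArray:
    """Ground truth for one inserted repeat-spacer locus."""

    host_strain: str
    contig_index: int
    start: int
    end: int
    repeat: str
    spacers: list[str]


@dataclass
class SpacerSpec:
    """Recipe for one spacer: copy a viral window with n mismatches, or random."""

    source_virus: str | None  # None = random spacer
    length: int
    mismatches: int = 0


REPEAT_LEN_RANGE = (19, 38)
SPACER_LEN_RANGE = (19, 48)


def plant_crispr_array(
    host: HostGenome,
    repeat_seq: str,
    spacer_specs: Sequence[SpacerSpec],
    viruses: dict[str, str],
    seed: int,
) -> tuple[HostGenome, PlantedArray, list[TruthRecord]]:
    """Insert a repeat-spacer-...-repeat array whose spacers sample the viral pool.

    n spacers give n+1 repeat copies.  Virus-derived spacers differ from their
    source window by exactly the requested number of substitutions.
    """
    if not REPEAT_LEN_RANGE[0] <= len(repeat_seq) <= REPEAT_LEN_RANGE[1]:
        raise GeneratorError("repeat length must be in [19, 38]")
    if len(spacer_specs) < 2:
        raise GeneratorError("need >= 2 spacers (>= 3 repeats)")
    rng = child_rng(seed, f"crispr:{host.strain_id}")
    spacers: list[str] = []
    records: list[TruthRecord] = []
    for spec in spacer_specs:
        if not SPACER_LEN_RANGE[0] <= spec.length <= SPACER_LEN_RANGE[1]:
            raise GeneratorError("spacer length must be in [19, 48]")
        if spec.source_virus is None:
            spacers.append(emit_uniform(spec.length, rng))
            continue
        vseq = viruses[spec.source_virus]
        v_start = int(rng.integers(0, len(vseq) - spec.length + 1))
        window = vseq[v_start : v_start + spec.length]
        spacer = mutate_exact(window, spec.mismatches, rng)
        spacers.append(spacer)
        records.append(
            TruthRecord(
                virus_id=spec.source_virus,
                true_host_strain=host.strain_id,
                relation="crispr_spacer",
                region_len=spec.length,
                virus_start=v_start,
                spacer_mismatches=spec.mismatches,
                spacer_seq=spacer,
            )
        )
    parts = [repeat_seq]
    for sp in spacers:
        parts.append(sp)
        parts.append(repeat_seq)
    array_seq = "".join(parts)

    ci = max(range(len(host.contigs)), key=lambda i: len(host.contigs[i]))
    contig = host.contigs[ci]
    # The planted repeat must be maximal, otherwise the locus is ill-defined:
    # if every base flanking the repeat copies coincided, the true repeat
    # would by definition be one column wider than the one we inserted.
    # Spacer flanks are fixed, so resample the insertion point until the
    # host-side bases break any unanimity.
    for _ in range(100):
        pos = _insertion_point(len(contig), rng)
        lefts = {contig[pos - 1], *(s[-1] for s in spacers)}
        rights = {*(s[0] for s in spacers), contig[pos]}
        if len(lefts) > 1 and len(rights) > 1:
            break
    else:  # pragma: no cover - needs pathological spacer/host composition
        raise GeneratorError("could not place a maximal repeat array")
    new_contigs = list(host.contigs)
    new_contigs[ci] = contig[:pos] + array_seq + contig[pos:]
    planted = PlantedArray(
        host_strain=host.strain_id,
        contig_index=ci,
        start=pos,
        end=pos + len(array_seq),
        repeat=repeat_seq,
        spacers=spacers,
    )
    for r in records:
        r.host_contig = ci
        r.host_start = pos
    return replace(host, contigs=new_contigs), planted, records


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class ReadPair:
    pair_id: str
    r1: str
    r2: str
    frag_start: int
    insert: int
    wraps: bool  # fragment crosses the circular origin
    clean_straddle: bool  # wraps, and neither read itself crosses the origin


def simulate_read_pairs(
    template: str,
    topology: str,
    n_pairs: int,
    seed: int,
    read_len: int = 100,
    insert_mean: int = 300,
    insert_sd: float = 30.0,
    error_rate: float = 0.0,
    id_prefix: str = "pair",
) -> list[ReadPair]:
    """Draw error-free (by default) FR read pairs from a circular or linear template.

    Insert sizes follow a normal truncated below at *read_len* and above at
    the template length.  For circular topology the fragment start is uniform
    over the whole template so fragments may wrap the origin; pairs whose
    fragment wraps while both reads stay intact in linear coordinates are
    flagged ``clean_straddle`` — these are the pairs a junction-spanning
    counter can recover.
    """
    L = len(template)
    if topology not in ("circular", "linear"):
        raise GeneratorError(f"unknown topology {topology!r}")
    if insert_mean >= L:
        raise GeneratorError("insert_mean must be below the template length")
    if read_len > insert_mean:
        raise GeneratorError("read_len must not exceed insert_mean")
    rng = child_rng(seed, f"reads:{id_prefix}:{topology}")
    doubled = template + template
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        insert = int(np.clip(round(rng.normal(insert_mean, insert_sd)), read_len, L))
        if topology == "circular":
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, L - insert + 1))
        frag = doubled[start : start + insert]
        r1 = frag[:read_len]
        r2 = revcomp(frag[-read_len:])
        if error_rate > 0:
            r1 = mutate(r1, error_rate, rng)
            r2 = mutate(r2, error_rate, rng)
        wraps = start + insert > L
        clean = wraps and (start + read_len <= L) and (start + insert - read_len >= L)
        pairs.append(
            ReadPair(
                pair_id=f"{id_prefix}_{i}",
                r1=r1,
                r2=r2,
                frag_start=start,
                insert=insert,
                wraps=wraps,
                clean_straddle=clean,
            )
        )
    return pairs


def circularized_contig(genome: str, terminal_repeat: int = 45) -> str:
    """Linearise a circular genome the way assemblers emit it: with the first
    *terminal_repeat* bases duplicated at the end (a direct terminal repeat)."""
    if terminal_repeat >= len(genome):
        raise GeneratorError("terminal repeat longer than the genome")
    return genome + genome[:terminal_repeat]


# ---------------------------------------------------------------------------
# file output (FASTA / FASTQ)


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pairs(pairs: Sequence[ReadPair], prefix: str | Path) -> tuple[Path, Path]:
    """Write mates to <prefix>_R1.fastq / <prefix>_R2.fastq (Phred-33 'I')."""
    p1, p2 = Path(f"{prefix}_R1.fastq"), Path(f"{prefix}_R2.fastq")
    for path, mate in ((p1, "r1"), (p2, "r2")):
        recs = []
        for pair in pairs:
            seq = getattr(pair, mate)
            rec = SeqRecord(Seq(seq), id=f"{pair.pair_id}/{mate[-1]}", description="")
            rec.letter_annotations["phred_quality"] = [40] * len(seq)
            recs.append(rec)
        SeqIO.write(recs, str(path), "fastq")
        if not recs:  # SeqIO.write leaves a zero-byte file; keep it valid/empty
            path.write_text("")
    return p1, p2


def read_fastq_pairs(prefix: str | Path) -> list[tuple[str, str, str]]:
    """Read mate files back as (pair_id, r1, r2) triples."""
    p1, p2 = Path(f"{prefix}_R1.fastq"), Path(f"{prefix}_R2.fastq")
    r1s = list(SeqIO.parse(str(p1), "fastq"))
    r2s = list(SeqIO.parse(str(p2), "fastq"))
    out = []
    for a, b in zip(r1s, r2s, strict=True):
        out.append((a.id.rsplit("/", 1)[0], str(a.seq), str(b.seq)))
    return out
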