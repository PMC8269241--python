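"""Canonical tetranucleotide profiles and composition-based host prediction.

Phages tend to carry a nucleotide composition close to that of their host, so
the mean absolute error (d) between canonical 4-mer frequency vectors of a
viral contig and a candidate host genome is a host-range signal.  A host
qualifies when d < 0.001; among qualifying hosts the five lowest-distance
strains are collapsed to their lowest common ancestor.

There are 136 canonical 4-mers: of the 256 raw 4-mers, 16 are their own
reverse complement and the remaining 240 pair up, (256 - 16) / 2 + 16 = 136.
Counting is strand-symmetric: every ACGT window contributes one count under
the lexicographic minimum of itself and its reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .predictions import HostPrediction
from .taxonomy import TaxonomyTree

K = 4
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"


def _revcomp_kmer(kmer: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(kmer))


def _build_tables() -> tuple[list[str], np.ndarray]:
    """All 136 canonical 4-mers (lexicographic) and a 256->136 index map."""
    canon: dict[str, None] = {}
    for code in range(4**K):
        kmer = "".join(_BASES[(code >> (2 * (K - 1 - i))) & 3] for i in range(K))
        canon[min(kmer, _revcomp_kmer(kmer))] = None
    kmers = sorted(canon)
    index = {kmer: i for i, kmer in enumerate(kmers)}
    code_to_canon = np.empty(4**K, dtype=np.int64)
    for code in range(4**K):
        kmer = "".join(_BASES[(code >> (2 * (K - 1 - i))) & 3] for i in range(K))
        code_to_canon[code] = index[min(kmer, _revcomp_kmer(kmer))]
    return kmers, code_to_canon


CANONICAL_KMERS, _CODE_TO_CANON = _build_tables()
N_CANONICAL = len(CANONICAL_KMERS)  # 136

_CHAR_CODE = np.full(256, -1, dtype=np.int64)
for _b, _c in _BASE_CODE.items():
    _CHAR_CODE[ord(_b)] = _c
    _CHAR_CODE[ord(_b.lower())] = _c


class ProfileError(ValueError):
    pass


def encode(seq: str) -> np.ndarray:
    """Sequence -> int8 codes (A0 C1 G2 T3, anything else -1)."""
    return _CHAR_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class KmerProfile:
    """Canonical 4-mer counts and frequencies for one sequence set.

    Multi-contig inputs are pooled at the count level before normalisation
    (length weighting), never by averaging per-contig frequencies.
    """

    owner_id: str
    counts: np.ndarray
    freqs: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_CANONICAL,):
            raise ProfileError(f"expected {N_CANONICAL} canonical counts")
        total = int(self.counts.sum())
        if total == 0:
            raise ProfileError(f"{self.owner_id}: no informative windows")
        self.freqs = self.counts / total


def _window_counts(seq: str) -> np.ndarray:
    codes = encode(seq)
    counts = np.zeros(N_CANONICAL, dtype=np.int64)
    if codes.size < K:
        return counts
    valid = codes >= 0
    # window is countable only if all 4 positions are ACGT
    ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    if not ok.any():
        return counts
    raw = (
        codes[:-3].clip(0) * 64
        + codes[1:-2].clip(0) * 16
        + codes[2:-1].clip(0) * 4
        + codes[3:].clip(0)
    )
    np.add.at(counts, _CODE_TO_CANON[raw[ok]], 1)
    return counts


def canonical_profile(sequences: str | Iterable[str], owner_id: str = "") -> KmerProfile:
    """Canonical tetranucleotide profile of one sequence or a pool of contigs.

    Windows containing non-ACGT characters are skipped; counting never crosses
    a contig boundary.  Raises :class:`ProfileError` when no window is
    countable.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    counts = np.zeros(N_CANONICAL, dtype=np.int64)
    for seq in sequences:
        counts += _window_counts(seq)
    return KmerProfile(owner_id=owner_id, counts=counts)


def mae_distance(p: KmerProfile, q: KmerProfile) -> float:
    """Mean absolute error d between two canonical 4-mer frequency vectors.

    d = (1/136) * sum_i |p_i - q_i|; symmetric, zero iff identical, and
    bounded by 2/136 (total-variation bound for two distributions).
    """
    for prof in (p, q):
        if abs(float(prof.freqs.sum()) - 1.0) > 1e-9:
            raise ProfileError(f"{prof.owner_id}: profile not normalised")
    return float(np.abs(p.freqs - q.freqs).mean())


def predict_host_kmer(
    virus_id: str,
    virus_profile: KmerProfile,
    host_profiles: Mapping[str, KmerProfile],
    tree: TaxonomyTree,
    d_max: float = 0.001,
    top_n: int = 5,
) -> HostPrediction:
    """Composition-based host call for one viral contig.

    Hosts with d strictly below *d_max* qualify; the *top_n* lowest-distance
    qualifying strains (ties at the boundary included) are collapsed by LCA.
    Returns a no-call prediction when no host qualifies.
    """
    if not host_profiles:
        raise ProfileError("empty host profile database")
    dists = sorted(
        (
            (mae_distance(virus_profile, prof), strain)
            for strain, prof in host_profiles.items()
        ),
        key=lambda t: (t[0], t[1]),
    )
    candidates = [(d, s) for d, s in dists if d < d_max]
    if not candidates:
        return HostPrediction.no_call(virus_id, "4mer")
    cutoff = candidates[min(top_n, len(candidates)) - 1][0]
    top = [(d, s) for d, s in candidates if d <= cutoff]  # include boundary ties
    node = tree.lca([s for _, s in top])
    return HostPrediction(
        virus_id=virus_id,
        method="4mer",
        taxon_name=node.name,
        taxon_rank=node.rank,
        score=top[0][0],
        evidence=[f"{s}:{d:.6g}" for d, s in top],
        n_candidates=len(candidates),
        unresolved=node is tree.root,
    )


def profile_database(
    genomes: Mapping[str, Sequence[str] | str]
) -> dict[str, KmerProfile]:
    """Profiles for a strain -> contigs mapping, pooled per strain."""
    return {
        strain: canonical_profile(contigs, owner_id=strain)
        for strain, contigs in genomes.items()
    }
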