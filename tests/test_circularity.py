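"""Circular-scaffold criteria: terminal repeats, spanning pairs, verdicts."""

import pysam

from virmatch import circularity as circ
from virmatch import synthetic as syn
from virmatch.synthetic import revcomp


def _random_seq(seed, n):
    return syn.emit_uniform(n, syn.child_rng(seed, "circ-test"))


def _naive_terminal_repeat(contig, min_len=35, max_scan=1_000):
    best = 0
    for k in range(min_len, min(max_scan, len(contig) // 2) + 1):
        if contig[:k] == contig[-k:]:
            best = k
    return best


# -- terminal repeats -------------------------------------------------------


def test_constructed_terminal_repeat_found_exactly():
    x = _random_seq(1, 40)
    y = _random_seq(2, 3_000)
    assert circ.find_terminal_repeat(x + y + x) == 40


def test_repeat_of_34_is_below_threshold():
    x = _random_seq(3, 34)
    y = _random_seq(4, 3_000)
    contig = x + y + x
    assert _naive_terminal_repeat(contig, min_len=1) == 34
    assert circ.find_terminal_repeat(contig) == 0


def test_random_contigs_have_no_terminal_repeat():
    # chance of a >=35 bp repeat in 3 kb is ~ 3000^2 * 4^-35, i.e. never
    for seed in range(100):
        contig = _random_seq(100 + seed, 3_000)
        assert circ.find_terminal_repeat(contig) == _naive_terminal_repeat(contig) == 0


def test_inverted_repeat_does_not_count():
    x = _random_seq(5, 40)
    y = _random_seq(6, 3_000)
    assert circ.find_terminal_repeat(x + y + revcomp(x)) == 0


# -- spanning pairs ---------------------------------------------------------


def _junction_pair(contig, right_start, left_start, read_len=50):
    """A pair oriented as a junction-spanning fragment would map."""
    r1 = contig[right_start : right_start + read_len]  # + strand, right end
    r2 = revcomp(contig[left_start : left_start + read_len])  # - strand, left
    return (r1, r2)


def test_spanning_pair_window_boundary():
    contig = _random_seq(7, 4_000)
    L = len(contig)
    inside = _junction_pair(contig, L - 500, 10)  # starts 500 bp from end
    outside = _junction_pair(contig, L - 501, 10)  # starts 501 bp from end
    assert circ.count_spanning_pairs(contig, [inside]) == 1
    assert circ.count_spanning_pairs(contig, [outside]) == 0
    # left mate must also sit wholly inside the window
    left_out = _junction_pair(contig, L - 100, 451)  # left mate ends at 501
    assert circ.count_spanning_pairs(contig, [left_out]) == 0


def test_wrong_orientation_not_counted():
    contig = _random_seq(8, 4_000)
    L = len(contig)
    r1 = contig[10:60]  # + strand at the left end: points away from junction
    r2 = revcomp(contig[L - 60 : L - 10])
    assert circ.count_spanning_pairs(contig, [(r1, r2)]) == 0


def test_ambiguous_reads_excluded():
    core = _random_seq(9, 4_000)
    dup = core[50:100]
    contig = core + dup  # the mate sequence occurs twice
    pair = (_random_seq(10, 50), revcomp(contig[50:100]))
    assert circ.count_spanning_pairs(contig, [pair]) == 0


def test_simulated_circular_counts_match_generator_truth():
    for seed in (11, 12, 13):
        genome = _random_seq(seed, 8_000)
        pairs = syn.simulate_read_pairs(genome, "circular", 400, seed=seed,
                                        read_len=100, insert_mean=400)
        expected = sum(p.clean_straddle for p in pairs)
        observed = circ.count_spanning_pairs(genome, [(p.r1, p.r2) for p in pairs])
        assert observed == expected


# -- classification ---------------------------------------------------------


def _circular_fixture(seed, genome_len=3_000, repeat=40, n_pairs=400):
    genome = _random_seq(seed, genome_len)
    contig = syn.circularized_contig(genome, repeat)
    reads = syn.simulate_read_pairs(genome, "circular", n_pairs, seed=seed,
                                    read_len=100, insert_mean=400)
    return contig, [(p.r1, p.r2) for p in reads]


def test_constructed_circular_contig_is_circular():
    contig, pairs = _circular_fixture(20)
    call = circ.classify_circular("c", contig, pairs)
    assert call.verdict == "circular"
    assert call.terminal_repeat_len == 40
    assert call.spanning_pairs >= 2
    assert call.failed_criteria == []


def test_length_boundary_flips_verdict():
    genome = _random_seq(21, 1_999 - 40)
    contig = syn.circularized_contig(genome, 40)
    assert len(contig) == 1_999
    reads = syn.simulate_read_pairs(genome, "circular", 500, seed=21,
                                    read_len=100, insert_mean=400)
    pairs = [(p.r1, p.r2) for p in reads]
    call = circ.classify_circular("c", contig, pairs)
    assert call.verdict == "not_circular"
    assert "length" in call.failed_criteria
    # two bases longer clears the >2 kb rule with everything else equal
    genome2 = _random_seq(21, 2_001 - 40)
    contig2 = syn.circularized_contig(genome2, 40)
    reads2 = syn.simulate_read_pairs(genome2, "circular", 500, seed=21,
                                     read_len=100, insert_mean=400)
    call2 = circ.classify_circular("c", contig2, [(p.r1, p.r2) for p in reads2])
    assert call2.verdict == "circular"


def test_single_spanning_pair_is_not_enough():
    contig, pairs = _circular_fixture(22)
    spanning = [
        p for p in pairs if circ.count_spanning_pairs(contig, [p]) == 1
    ]
    rest = [p for p in pairs if p not in spanning]
    call = circ.classify_circular("c", contig, rest + spanning[:1])
    assert call.spanning_pairs == 1
    assert call.verdict == "not_circular"
    assert call.failed_criteria == ["spanning_pairs"]


def test_monotonicity_in_spanning_pairs():
    contig, pairs = _circular_fixture(23)
    call = circ.classify_circular("c", contig, pairs)
    assert call.verdict == "circular"
    more = pairs + pairs[:50]
    call2 = circ.classify_circular("c", contig, more)
    assert call2.spanning_pairs >= call.spanning_pairs
    assert call2.verdict == "circular"


def test_rotation_invariance_of_classification():
    genome = _random_seq(24, 6_000)
    for rotation in (0, 1_500, 4_321):
        rotated = genome[rotation:] + genome[:rotation]
        contig = syn.circularized_contig(rotated, 45)
        reads = syn.simulate_read_pairs(rotated, "circular", 500, seed=24,
                                        read_len=100, insert_mean=400)
        call = circ.classify_circular("c", contig, [(p.r1, p.r2) for p in reads])
        assert call.verdict == "circular"


def test_sam_evidence_matches_exact_matching(tmp_path):
    genome = _random_seq(25, 6_000)
    reads = syn.simulate_read_pairs(genome, "circular", 300, seed=25,
                                    read_len=100, insert_mean=400)
    expected = circ.count_spanning_pairs(genome, [(p.r1, p.r2) for p in reads])
    # write the same placements as a SAM file
    path = tmp_path / "aln.sam"
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": len(genome)}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for p in reads:
            for mate_idx, seq in ((1, p.r1), (2, p.r2)):
                for strand, s in (("+", seq), ("-", revcomp(seq))):
                    pos = genome.find(s)
                    if pos == -1 or genome.find(s, pos + 1) != -1:
                        continue
                    a = pysam.AlignedSegment()
                    a.query_name = p.pair_id
                    a.query_sequence = s
                    a.reference_id = 0
                    a.reference_start = pos
                    a.cigarstring = f"{len(s)}M"
                    a.flag = 16 if strand == "-" else 0
                    sam.write(a)
                    break
    assert circ.spanning_pairs_from_sam(path, "c", len(genome)) == expected
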