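"""Shared-region detection, genus-level calls and whole-virus containment."""

import numpy as np
import pytest

from virmatch import synthetic as syn
from virmatch.similarity import (
    ScoringScheme,
    find_similar_regions,
    predict_host_blast,
    predict_host_blast99,
    read_blast_tab,
    scan_community,
)
from virmatch.synthetic import revcomp


def _rand(seed, n):
    return syn.emit_uniform(n, syn.child_rng(seed, "sim-test"))


def _plant(host, insert, pos):
    return host[:pos] + insert + host[pos:]


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


# -- region detection -------------------------------------------------------


def test_exact_copy_yields_one_full_identity_region():
    virus = _rand(1, 20_000)
    host = _plant(_rand(2, 30_000), virus[5_000:11_000], 12_000)
    regions = find_similar_regions("v", virus, "h", [host])
    assert len(regions) == 1
    r = regions[0]
    assert r.identity == 1.0
    assert r.length_bp >= 6_000
    assert r.strand == "+"
    # coordinates point at the planted copy
    assert host[r.h_start : r.h_end] == virus[r.v_start : r.v_end]


def test_mutated_region_identity_estimated_within_tolerance():
    virus = _rand(3, 20_000)
    window = virus[2_000:8_000]
    rng = syn.child_rng(3, "mut")
    mutated = syn.mutate_exact(window, round(0.20 * len(window)), rng)
    assert _hamming(window, mutated) == round(0.20 * len(window))
    host = _plant(_rand(4, 30_000), mutated, 10_000)
    regions = find_similar_regions("v", virus, "h", [host])
    big = [r for r in regions if r.length_bp >= 4_900]
    assert len(big) == 1
    assert 0.77 <= big[0].identity <= 0.83


def test_minus_strand_region_detected_and_remapped():
    virus = _rand(5, 20_000)
    host = _plant(_rand(6, 30_000), revcomp(virus[5_000:11_000]), 9_000)
    regions = find_similar_regions("v", virus, "h", [host])
    big = [r for r in regions if r.length_bp >= 5_000]
    assert len(big) == 1
    r = big[0]
    assert r.strand == "-"
    assert revcomp(host[r.h_start : r.h_end]) == virus[r.v_start : r.v_end]


def test_strand_symmetry_under_host_reverse_complement():
    virus = _rand(7, 15_000)
    host = _plant(_rand(8, 25_000), virus[1_000:7_000], 8_000)
    fwd = find_similar_regions("v", virus, "h", [host])
    rev = find_similar_regions("v", virus, "h", [revcomp(host)])
    L = len(host)
    fwd_set = {(r.v_start, r.v_end, r.h_start, r.h_end, r.strand) for r in fwd}
    remapped = {
        (r.v_start, r.v_end, L - r.h_end, L - r.h_start,
         "+" if r.strand == "-" else "-")
        for r in rev
    }
    assert fwd_set == remapped


def test_independent_random_sequences_share_no_qualifying_region():
    for seed in range(20):
        a = _rand(100 + seed, 100_000)
        b = _rand(200 + seed, 100_000)
        regions = find_similar_regions("v", a, "h", [b])
        assert not any(
            r.length_bp >= 4_900 and r.identity >= 0.70 for r in regions
        )


def test_bit_score_and_e_value_formulas():
    scheme = ScoringScheme()
    # 25 exact matches: raw 50 -> bit = (0.625*50 - ln 0.41)/ln 2
    bit = scheme.bit_score(50)
    assert bit == pytest.approx((0.625 * 50 - np.log(0.41)) / np.log(2))
    assert scheme.e_value(50, 1_000, 1_000_000) == pytest.approx(
        1e9 * 2 ** (-bit)
    )
    assert scheme.e_value(40_000, 1_000, 1_000_000) == 0.0  # underflow guard


# -- genus-level prediction -------------------------------------------------


@pytest.fixture(scope="module")
def planted_scan():
    """One virus, three hosts: a 6-kb 0.95 region in P1, nothing elsewhere."""
    virus = _rand(9, 20_000)
    window = virus[3_000:9_000]
    rng = syn.child_rng(9, "mut")
    region = syn.mutate_exact(window, round(0.05 * 6_000), rng)
    hosts = {
        "P1": [_plant(_rand(10, 30_000), region, 15_000)],
        "P2": [_rand(11, 30_000)],
        "A1": [_rand(12, 30_000)],
    }
    return virus, scan_community({"v": virus}, hosts)["v"]


def test_blast_prediction_singleton_lca_is_strain(planted_scan, small_tree):
    virus, regions = planted_scan
    pred = predict_host_blast("v", len(virus), regions, small_tree)
    assert pred.is_call and pred.method == "blast"
    assert (pred.taxon_name, pred.taxon_rank) == ("P1", "strain")


def test_blast_length_boundary(planted_scan, small_tree):
    virus, _ = planted_scan
    window = virus[3_000 : 3_000 + 4_500]
    host = _plant(_rand(13, 30_000), window, 10_000)
    regions = find_similar_regions("v", virus, "P1", [host])
    assert any(r.length_bp >= 4_500 and r.identity == 1.0 for r in regions)
    pred = predict_host_blast("v", len(virus), regions, small_tree)
    assert not pred.is_call  # 4.5 kb < 4.9 kb


def test_blast_identity_boundary(small_tree):
    virus = _rand(14, 20_000)
    window = virus[2_000:8_000]
    rng = syn.child_rng(14, "mut")
    region = syn.mutate_exact(window, round(0.35 * 6_000), rng)  # 65% identity
    host = _plant(_rand(15, 30_000), region, 10_000)
    regions = find_similar_regions("v", virus, "P1", [host])
    pred = predict_host_blast("v", len(virus), regions, small_tree)
    assert not pred.is_call


def test_blast_top5_collapses_same_genus(small_tree):
    virus = _rand(16, 20_000)
    window = virus[2_000:8_000]
    hosts = {
        "P1": [_plant(_rand(17, 30_000), window, 9_000)],
        "P2": [_plant(_rand(18, 30_000), window, 9_000)],
    }
    regions = scan_community({"v": virus}, hosts)["v"]
    pred = predict_host_blast("v", len(virus), regions, small_tree)
    assert (pred.taxon_name, pred.taxon_rank) == ("Pseudomonas", "genus")


# -- whole-virus containment (blast99) --------------------------------------


def test_full_prophage_in_three_strains_gives_three_predictions():
    virus = _rand(19, 10_000)
    hosts = {
        s: [_plant(_rand(20 + i, 30_000), virus, 12_000)]
        for i, s in enumerate(("P1", "P2", "A1"))
    }
    regions = scan_community({"v": virus}, hosts)["v"]
    preds = predict_host_blast99("v", len(virus), regions)
    assert sorted(p.taxon_name for p in preds) == ["A1", "P1", "P2"]
    assert all(p.taxon_rank == "strain" for p in preds)


def test_partial_coverage_is_excluded():
    virus = _rand(21, 10_000)
    host = _plant(_rand(22, 30_000), virus[:9_800], 12_000)  # 98% coverage
    regions = find_similar_regions("v", virus, "P1", [host])
    assert predict_host_blast99("v", len(virus), regions) == []


def test_two_percent_divergence_is_excluded():
    virus = _rand(23, 10_000)
    rng = syn.child_rng(23, "mut")
    copy = syn.mutate_exact(virus, round(0.02 * len(virus)), rng)
    host = _plant(_rand(24, 30_000), copy, 12_000)
    regions = find_similar_regions("v", virus, "P1", [host])
    assert predict_host_blast99("v", len(virus), regions) == []


def test_blast99_hosts_subset_of_blast_qualifying(community1, pipeline_result):
    blast99 = {
        (p.virus_id, p.taxon_name)
        for p in pipeline_result.predictions
        if p.method == "blast99" and p.is_call
    }
    qualifying = {
        (r.virus_id, r.host_strain)
        for rs in pipeline_result.regions.values()
        for r in rs
        if r.length_bp >= 4_900 and r.identity >= 0.70
    }
    assert blast99 <= qualifying


# -- tabular alignment input ------------------------------------------------


def test_read_blast_tab_coordinates_and_strand(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text(
        "v1\tP1\t95.50\t6000\t270\t0\t101\t6100\t20001\t26000\t1e-50\t5000\n"
        "v1\tP2\t99.00\t5000\t50\t0\t1\t5000\t30000\t25001\t0.0\t4500\n"
    )
    regions = read_blast_tab(path)
    a, b = regions
    assert (a.v_start, a.v_end) == (100, 6_100)
    assert (a.h_start, a.h_end, a.strand) == (20_000, 26_000, "+")
    assert a.identity == pytest.approx(0.955)
    assert (b.h_start, b.h_end, b.strand) == (25_000, 30_000, "-")
    assert b.e_value == 0.0
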