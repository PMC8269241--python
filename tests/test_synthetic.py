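"""Generator determinism, planted-signal fidelity and read simulation."""

import numpy as np
import pytest

from virmatch import synthetic as syn
from virmatch.kmer import canonical_profile, mae_distance


def _hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


# -- composition models -----------------------------------------------------


def test_genus_model_deterministic_for_seed():
    m1 = syn.build_genus_model("g", seed=5)
    m2 = syn.build_genus_model("g", seed=5)
    assert np.array_equal(m1.transition_probs, m2.transition_probs)
    m3 = syn.build_genus_model("g", seed=6)
    assert not np.array_equal(m1.transition_probs, m3.transition_probs)


def test_huge_concentration_approaches_uniform():
    m = syn.build_genus_model("g", seed=1, divergence=1e7)
    assert np.allclose(m.transition_probs, 0.25, atol=1e-3)


def test_nonpositive_concentration_rejected():
    with pytest.raises(syn.GeneratorError):
        syn.build_genus_model("g", seed=1, divergence=0.0)


def test_default_concentration_separates_genera():
    """Two independently drawn genera differ by >0.001 4-mer MAE (>=95/100)."""
    ok = 0
    for trial in range(100):
        a = syn.build_genus_model("a", seed=trial)
        b = syn.build_genus_model("b", seed=trial)
        rng_a = syn.child_rng(trial, "sep-a")
        rng_b = syn.child_rng(trial, "sep-b")
        pa = canonical_profile(syn.emit_sequence(a, 100_000, rng_a))
        pb = canonical_profile(syn.emit_sequence(b, 100_000, rng_b))
        if mae_distance(pa, pb) > 0.001:
            ok += 1
    assert ok >= 95


# -- host genomes -----------------------------------------------------------


def test_zero_mutation_rate_gives_identical_strains():
    m = syn.build_genus_model("g", seed=3)
    g1 = syn.generate_host_genome(m, 50_000, seed=9, strain_id="s1")
    g2 = syn.generate_host_genome(m, 50_000, seed=9, strain_id="s2")
    assert g1.contigs == g2.contigs


def test_multi_contig_lengths_conserved():
    m = syn.build_genus_model("g", seed=3)
    g = syn.generate_host_genome(m, 90_000, seed=1, n_contigs=3)
    assert len(g.contigs) == 3
    assert sum(len(c) for c in g.contigs) == 90_000


def test_mutation_rate_matches_binomial_expectation():
    m = syn.build_genus_model("g", seed=3)
    g = syn.generate_host_genome(
        m, 100_000, seed=4, strain_mutation_rate=0.01
    )
    frac = _hamming("".join(g.contigs), g.parent) / 100_000
    assert 0.008 <= frac <= 0.012


def test_too_short_genome_rejected():
    m = syn.build_genus_model("g", seed=3)
    with pytest.raises(syn.GeneratorError):
        syn.generate_host_genome(m, 10, seed=1)


# -- viruses ----------------------------------------------------------------


def test_virus_length_bounds():
    with pytest.raises(syn.GeneratorError):
        syn.generate_virus(3_999, seed=1)
    with pytest.raises(syn.GeneratorError):
        syn.generate_virus(300_001, seed=1)
    # the largest observed contig size is accepted
    assert len(syn.generate_virus(296_356, seed=1)) == 296_356


def test_host_linked_virus_close_and_background_far():
    """Linked viruses fall under, background viruses over, the d threshold."""
    for trial in range(5):
        m = syn.build_genus_model("g", seed=trial)
        host = syn.generate_host_genome(m, 100_000, seed=trial)
        hp = canonical_profile(host.contigs)
        linked = canonical_profile(
            syn.generate_virus(50_000, seed=trial, virus_id="lk", source_model=m)
        )
        background = canonical_profile(
            syn.generate_virus(50_000, seed=trial, virus_id="bg")
        )
        assert mae_distance(linked, hp) < 0.001
        assert mae_distance(background, hp) >= 0.001


# -- prophage planting ------------------------------------------------------


@pytest.fixture(scope="module")
def host_and_virus():
    m = syn.build_genus_model("g", seed=11)
    host = syn.generate_host_genome(m, 60_000, seed=11, strain_id="H")
    virus = syn.generate_virus(20_000, seed=11, virus_id="V", source_model=m)
    return host, virus


def test_full_prophage_conserves_lengths(host_and_virus):
    host, virus = host_and_virus
    mutated, rec = syn.plant_prophage(host, "V", virus, "full", seed=2)
    assert mutated.length == host.length + len(virus)
    assert rec.relation == "full_prophage"
    # exact copy present -> whole-virus containment trivially satisfied
    assert virus in mutated.contigs[rec.host_contig]


def test_partial_prophage_has_exact_target_identity(host_and_virus):
    host, virus = host_and_virus
    mutated, rec = syn.plant_prophage(
        host, "V", virus, "partial", seed=3, region_len=6_000,
        target_identity=0.80,
    )
    planted = mutated.contigs[rec.host_contig][rec.host_start : rec.host_start + 6_000]
    source = virus[rec.virus_start : rec.virus_start + 6_000]
    identity = 1 - _hamming(planted, source) / 6_000
    assert 0.78 <= identity <= 0.82


def test_partial_prophage_validates_geometry(host_and_virus):
    host, virus = host_and_virus
    with pytest.raises(syn.GeneratorError):
        syn.plant_prophage(host, "V", virus, "partial", seed=1,
                           region_len=4_000)
    with pytest.raises(syn.GeneratorError):
        syn.plant_prophage(host, "V", virus, "partial", seed=1,
                           region_len=6_000, target_identity=0.5)
    with pytest.raises(syn.GeneratorError):
        syn.plant_prophage(host, "V", virus, "partial", seed=1,
                           region_len=len(virus) + 1)


# -- CRISPR planting --------------------------------------------------------


def test_crispr_array_fencepost_and_mismatches(host_and_virus):
    host, virus = host_and_virus
    repeat = "ACGTACGTACGTACGTACGTACGTACGT"  # 28 bp
    mutated, arr, recs = syn.plant_crispr_array(
        host, repeat,
        [syn.SpacerSpec("V", 32, 0), syn.SpacerSpec("V", 30, 1),
         syn.SpacerSpec("V", 25, 2)],
        {"V": virus}, seed=4,
    )
    assert len(arr.spacers) == 3  # 4 repeats -> 3 spacers
    locus = mutated.contigs[arr.contig_index][arr.start : arr.end]
    expect = repeat + "".join(s + repeat for s in arr.spacers)
    assert locus == expect
    for rec, spacer in zip(recs, arr.spacers):
        window = virus[rec.virus_start : rec.virus_start + rec.region_len]
        assert _hamming(spacer, window) == rec.spacer_mismatches


def test_crispr_geometry_violations(host_and_virus):
    host, virus = host_and_virus
    with pytest.raises(syn.GeneratorError):
        syn.plant_crispr_array(host, "A" * 18, [syn.SpacerSpec(None, 30)] * 2,
                               {}, seed=1)
    with pytest.raises(syn.GeneratorError):
        syn.plant_crispr_array(host, "A" * 28, [syn.SpacerSpec(None, 18)] * 2,
                               {}, seed=1)
    with pytest.raises(syn.GeneratorError):
        syn.plant_crispr_array(host, "A" * 28, [syn.SpacerSpec(None, 30)],
                               {}, seed=1)


# -- read simulation --------------------------------------------------------


def test_linear_template_never_straddles():
    template = syn.emit_uniform(5_000, syn.child_rng(1, "t"))
    pairs = syn.simulate_read_pairs(template, "linear", 200, seed=1,
                                    read_len=100, insert_mean=300)
    assert pairs and not any(p.wraps for p in pairs)


def test_circular_straddle_rate_within_binomial_bounds():
    template = syn.emit_uniform(5_000, syn.child_rng(2, "t"))
    n, L, insert = 200, 5_000, 300
    pairs = syn.simulate_read_pairs(template, "circular", n, seed=2,
                                    read_len=100, insert_mean=insert)
    observed = sum(p.wraps for p in pairs)
    p = insert / L
    sigma = (n * p * (1 - p)) ** 0.5
    assert abs(observed - n * p) <= 3 * sigma


def test_zero_pairs_yields_valid_empty_fastq(tmp_path):
    template = syn.emit_uniform(5_000, syn.child_rng(3, "t"))
    pairs = syn.simulate_read_pairs(template, "circular", 0, seed=3)
    p1, p2 = syn.write_fastq_pairs(pairs, tmp_path / "empty")
    assert p1.exists() and p2.exists()
    assert syn.read_fastq_pairs(tmp_path / "empty") == []


def test_read_length_and_insert_preconditions():
    template = syn.emit_uniform(5_000, syn.child_rng(4, "t"))
    with pytest.raises(syn.GeneratorError):
        syn.simulate_read_pairs(template, "circular", 10, seed=1,
                                read_len=400, insert_mean=300)
    with pytest.raises(syn.GeneratorError):
        syn.simulate_read_pairs(template, "circular", 10, seed=1,
                                insert_mean=6_000)


def test_fastq_round_trip(tmp_path):
    template = syn.emit_uniform(5_000, syn.child_rng(5, "t"))
    pairs = syn.simulate_read_pairs(template, "circular", 25, seed=5,
                                    id_prefix="rt")
    syn.write_fastq_pairs(pairs, tmp_path / "rt")
    back = syn.read_fastq_pairs(tmp_path / "rt")
    assert [(p.pair_id, p.r1, p.r2) for p in pairs] == back


# -- truth tables and community invariants ----------------------------------


def test_truth_round_trip(tmp_path, community1):
    path = tmp_path / "truth.tsv"
    syn.write_truth(community1.truth, path)
    assert syn.read_truth(path) == community1.truth


def test_empty_truth_is_header_only(tmp_path):
    path = tmp_path / "truth.tsv"
    syn.write_truth([], path)
    assert path.read_text().strip() == "\t".join(syn.TRUTH_COLUMNS)
    assert syn.read_truth(path) == []


def test_generation_is_pure_function_of_seed(community1):
    from virmatch import community as comm

    again = comm.generate_community(1)
    assert again.virus_contigs() == community1.virus_contigs()
    assert again.host_contigs() == community1.host_contigs()
    other = comm.generate_community(2)
    assert other.virus_contigs() != community1.virus_contigs()


def test_planted_coordinates_index_into_emitted_sequences(community1):
    for rec in community1.truth:
        if rec.relation == "composition_only":
            continue
        if rec.relation == "crispr_spacer":
            virus = community1.viruses[rec.virus_id].genome
            assert 0 <= rec.virus_start <= len(virus) - rec.region_len
            continue
        contig = community1.hosts[rec.true_host_strain].contigs[rec.host_contig]
        assert 0 <= rec.host_start <= len(contig) - rec.region_len
        virus = community1.viruses[rec.virus_id].genome
        assert 0 <= rec.virus_start <= len(virus) - rec.region_len
    for arr in community1.arrays:
        contig = community1.hosts[arr.host_strain].contigs[arr.contig_index]
        assert 0 <= arr.start < arr.end <= len(contig)
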