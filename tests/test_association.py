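"""Read merging, exact-match extraction, and barcode-map filters."""

import itertools
import random

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from synstarr.designs import (
    acgt_flank_design,
    assemble_construct,
    enumerate_variants,
    reverse_complement,
)
from synstarr.association import (
    build_barcode_map,
    extract_pair,
    merge_pairs,
)

Q = "I"


def as_read(seq, qual=None):
    return (seq, qual if qual is not None else Q * len(seq))


def test_merge_identical_reads_full_overlap():
    frag = "ACGTGCTAGCTAGGCATCGATTTACGGTCA"  # 30 nt
    merged = merge_pairs(as_read(frag), as_read(reverse_complement(frag)))
    assert merged == frag


def test_merge_fragment_geometry():
    rng = random.Random(42)
    frag = "".join(rng.choice("ACGT") for _ in range(100))
    r1 = frag[:60]
    r2 = reverse_complement(frag[40:])
    merged = merge_pairs(as_read(r1), as_read(r2))
    assert merged == frag
    assert len(merged) == 100  # overlap of 20 consumed once


def test_merge_rejects_overlap_above_mismatch_threshold():
    rng = random.Random(7)
    frag = "".join(rng.choice("ACGT") for _ in range(40))
    r1 = frag[:30]
    tail = list(frag[10:])
    # 3 mismatches inside the 20-nt overlap: 15% > 8%
    for pos in (2, 9, 16):
        tail[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[tail[pos]]
    r2 = reverse_complement("".join(tail))
    merged = merge_pairs(as_read(r1), as_read(r2))
    if merged is not None:  # a shorter chance overlap may still qualify
        assert len(merged) != 40


def test_merge_consensus_prefers_higher_quality_base():
    frag = "ACGTACGTACGTACGTACGT"
    r2 = list(frag)
    r2[10] = "A" if frag[10] != "A" else "C"
    # read 2 claims higher quality at the disagreeing position
    q1 = Q * 20
    q2 = "J" * 20
    merged = merge_pairs((frag, q1),
                         (reverse_complement("".join(r2)), q2[::-1]))
    assert merged is not None
    assert merged[10] == r2[10]


def test_merge_requires_minimum_overlap():
    assert merge_pairs(as_read("ACGTA"), as_read("TTTTT"),
                       min_overlap=6) is None


def test_extract_rejects_anchor_window_and_barcode_errors(flank_design):
    v = enumerate_variants(flank_design)[100]
    construct = assemble_construct(v, "CAGAACGCGCTA", flank_design)
    assert extract_pair(construct, flank_design)[0] == (v.key, "CAGAACGCGCTA")

    # substitution inside the upstream fixed anchor
    broken = "G" + construct[1:] if construct[0] != "G" else "T" + construct[1:]
    assert extract_pair(broken, flank_design) == (None, "anchor")

    # substitution at a fixed window position (core position 23 in context)
    pos = 23
    base = "A" if construct[pos] != "A" else "G"
    assert extract_pair(construct[:pos] + base + construct[pos + 1:],
                        flank_design) == (None, "window")

    # T at a V-position of the barcode slot (barcode offset 132 + 6)
    pos = 132 + 6
    assert extract_pair(construct[:pos] + "T" + construct[pos + 1:],
                        flank_design) == (None, "barcode")


def brute_force_map(pair_counts, min_pair_reads, min_barcodes):
    """Independent reimplementation of the association filters."""
    surviving = {pair: n for pair, n in pair_counts.items()
                 if n >= min_pair_reads}
    barcode_variants = {}
    for (key, bc) in surviving:
        barcode_variants.setdefault(bc, set()).add(key)
    result = {}
    for (key, bc), n in surviving.items():
        if len(barcode_variants[bc]) == 1:
            result[bc] = (key, n)
    kept_variants = {}
    for bc, (key, n) in result.items():
        kept_variants.setdefault(key, []).append(bc)
    kept_variants = {k: v for k, v in kept_variants.items()
                     if len(v) >= min_barcodes}
    return {bc: kv for bc, kv in result.items()
            if kv[0] in kept_variants}


def stream_from(pair_counts):
    for (key, bc), n in pair_counts.items():
        yield from itertools.repeat((key, bc), n)


def test_pair_read_count_filter_boundary():
    table = {("v1", "b1"): 12, ("v1", "b2"): 9}
    m = build_barcode_map(stream_from(table), min_pair_reads=10,
                          min_barcodes=1)
    assert m.barcode_to_key == {"b1": "v1"}
    m10 = build_barcode_map(stream_from({("v1", "b1"): 10}),
                            min_pair_reads=10, min_barcodes=1)
    assert m10.barcode_to_key == {"b1": "v1"}  # boundary inclusive


def test_variant_barcode_count_filter():
    table = {("v1", f"b{i}"): 20 for i in range(4)}
    m = build_barcode_map(stream_from(table), min_barcodes=5)
    assert m.variants == []
    table[("v1", "b4")] = 20
    m = build_barcode_map(stream_from(table), min_barcodes=5)
    assert m.variants == ["v1"]


def test_colliding_barcode_dropped_entirely():
    table = {("v1", "b3"): 50, ("v2", "b3"): 40}
    m = build_barcode_map(stream_from(table), min_barcodes=1)
    assert "b3" not in m.barcode_to_key
    assert m.report["barcode_collisions_removed"] == 1


def test_empty_stream_gives_empty_map_and_zeroed_report():
    m = build_barcode_map(iter([]))
    assert len(m.entries) == 0
    assert m.report["barcodes_detected"] == 0
    assert m.report["variants_associated"] == 0


def random_pair_table(rng, n_pairs):
    variants = [f"v{i}" for i in range(rng.integers(1, 12))]
    barcodes = [f"b{i}" for i in range(rng.integers(1, 30))]
    table = {}
    for _ in range(n_pairs):
        pair = (str(rng.choice(variants)), str(rng.choice(barcodes)))
        table[pair] = int(rng.integers(1, 30))
    return table


@pytest.mark.parametrize("seed", range(100))
def test_map_matches_brute_force_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    table = random_pair_table(rng, int(rng.integers(1, 200)))
    min_reads = int(rng.integers(1, 15))
    min_bcs = int(rng.integers(1, 5))
    m = build_barcode_map(stream_from(table), min_pair_reads=min_reads,
                          min_barcodes=min_bcs)
    got = {bc: (key, n) for bc, key, n in
           m.entries[["barcode", "key", "n_reads"]].itertuples(index=False)}
    assert got == brute_force_map(table, min_reads, min_bcs)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(1, 4))
def test_raising_min_barcodes_never_adds_entries(seed, bump_bcs):
    rng = np.random.default_rng(seed)
    table = random_pair_table(rng, 80)
    base = build_barcode_map(stream_from(table), min_pair_reads=5,
                             min_barcodes=2)
    strict = build_barcode_map(stream_from(table), min_pair_reads=5,
                               min_barcodes=2 + bump_bcs)
    assert set(strict.barcode_to_key.items()) <= set(base.barcode_to_key.items())
    assert set(strict.variants) <= set(base.variants)


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2**31 - 1), st.integers(1, 6))
def test_raising_min_pair_reads_monotone_without_collisions(seed, bump_reads):
    # the read filter precedes collision removal, so on tables where no
    # barcode is shared between variants raising it can only remove entries
    rng = np.random.default_rng(seed)
    table = random_pair_table(rng, 80)
    seen = {}
    table = {(key, bc): n for (key, bc), n in table.items()
             if seen.setdefault(bc, key) == key}
    base = build_barcode_map(stream_from(table), min_pair_reads=5,
                             min_barcodes=2)
    strict = build_barcode_map(stream_from(table),
                               min_pair_reads=5 + bump_reads,
                               min_barcodes=2)
    assert set(strict.barcode_to_key.items()) <= set(base.barcode_to_key.items())
    assert set(strict.variants) <= set(base.variants)


def test_sequencing_errors_yield_subset_of_truth_without_false_pairs(tmp_path):
    # at 1% per-base error, exact-match extraction plus the read-count
    # filter keep only true pairs; recovered pairs are a subset of truth
    from synstarr.simulate import (SimulationConfig, draw_ground_truth,
                                   emit_fastq, simulate_counts)
    from synstarr.association import associate_fastq

    design = acgt_flank_design()
    cfg = SimulationConfig(seed=31, n_variants=30, n_barcodes_fixed=5,
                           dna_depth=15_000, rna_depth=0,
                           base_error_rate=0.01, collision_rate=0.0)
    truth = draw_ground_truth(design, cfg)
    counts = simulate_counts(truth, cfg)
    paths = emit_fastq(truth, counts, design, cfg, tmp_path)
    bc_map = associate_fastq(paths["assoc_r1"], paths["assoc_r2"], design,
                             min_barcodes=1)
    recovered = set(zip(bc_map.entries["barcode"], bc_map.entries["key"]))
    expected = set(zip(truth.pairs["barcode"], truth.pairs["key"]))
    assert recovered  # errors reduce yield but do not empty the map
    assert recovered <= expected  # 100% precision
    assert bc_map.report.get("reject_anchor", 0) > 0
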