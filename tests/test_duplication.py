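"""duplication: fragment rule, merging, identity, labels, allelic content."""

from __future__ import annotations

import pytest

from ploidyscope.core_io import Assembly, GeneModel, SegmentRecord
from ploidyscope.duplication import (
    DuplicatedRegionPair,
    Region,
    allelic_content,
    assign_copy_labels,
    detect_duplicated_fragments,
    duplication_summary,
    merge_adjacent_pairs,
    natural_key,
    region_nt_identity,
    regions_to_segments,
    segdup_homolog_pairs,
    whole_genome_identity,
)
from ploidyscope.homology import HomologyHit


def _gene(gid, scaf, start, length=300, cds="ATG" + "AAA" * 99):
    return GeneModel(gene_id=gid, scaffold_id=scaf, start=start,
                     end=start + length, strand="+", cds=cds, protein="M")


def _hit(q, t, e=1e-30, qcov=95.0, tcov=95.0):
    return HomologyHit(query_id=q, target_id=t, bitscore=100, evalue=e,
                       pct_identity=90.0, query_coverage=qcov, target_coverage=tcov)


# ---------------------------------------------------------------------------
# segdup_homolog_pairs thresholds
# ---------------------------------------------------------------------------

def test_segdup_pair_thresholds():
    hits = [
        _hit("a", "b", e=1e-19),           # e-value too weak
        _hit("c", "d", e=1e-20),           # boundary: retained (<=)
        _hit("e", "f", qcov=85, tcov=79),  # target coverage too low
        _hit("g", "h", qcov=80, tcov=95),  # coverage is strict >80
    ]
    assert segdup_homolog_pairs(hits) == {("c", "d")}


# ---------------------------------------------------------------------------
# detect_duplicated_fragments
# ---------------------------------------------------------------------------

def _two_scaffold_instance():
    genes = [_gene(f"g{i}", "s1", i * 1000) for i in range(1, 5)]
    genes += [_gene(f"h{i}", "s2", i * 1000) for i in range(1, 5)]
    return genes


def test_fragment_hand_example():
    genes = _two_scaffold_instance()
    pairs = {("g1", "h1"), ("g2", "h2"), ("g4", "h4")}
    (frag,) = detect_duplicated_fragments(genes, pairs)
    assert frag.homolog_fraction_a == pytest.approx(0.75)
    assert frag.homolog_fraction_b == pytest.approx(0.75)
    assert (frag.n_genes_a, frag.n_genes_b) == (4, 4)
    assert frag.region_a == Region("s1", 1000, 4300)
    assert frag.region_b == Region("s2", 1000, 4300)
    assert set(frag.anchor_pairs) == pairs


def test_fragment_no_pairs():
    assert detect_duplicated_fragments(_two_scaffold_instance(), set()) == []


def test_fragment_min_genes():
    genes = [_gene("g1", "s1", 0), _gene("g2", "s1", 1000),
             _gene("h1", "s2", 0), _gene("h2", "s2", 1000)]
    assert detect_duplicated_fragments(genes, {("g1", "h1"), ("g2", "h2")}) == []


def test_fragment_reversed_block_detected():
    genes = [_gene(f"g{i}", "s1", i * 1000) for i in range(3)]
    genes += [_gene(f"h{i}", "s2", (2 - i) * 1000) for i in range(3)]
    pairs = {(f"g{i}", f"h{i}") for i in range(3)}
    (frag,) = detect_duplicated_fragments(genes, pairs)
    assert frag.homolog_fraction_a == 1.0


def test_fragment_gap_breaks_chain():
    """Anchors separated by more than max_anchor_gap_genes do not chain."""
    genes = [_gene(f"g{i}", "s1", i * 1000) for i in range(10)]
    genes += [_gene(f"h{i}", "s2", i * 1000) for i in range(10)]
    pairs = {("g0", "h0"), ("g9", "h9")}
    assert detect_duplicated_fragments(genes, pairs) == []
    frags = detect_duplicated_fragments(genes, pairs, min_genes=2,
                                        max_anchor_gap_genes=8)
    assert len(frags) == 0  # 2/10 homolog fraction still below 0.5


def test_fragment_low_fraction_rejected():
    genes = [_gene(f"g{i}", "s1", i * 1000) for i in range(8)]
    genes += [_gene(f"h{i}", "s2", i * 1000) for i in range(8)]
    pairs = {("g0", "h0"), ("g3", "h3"), ("g7", "h7")}
    # full window 8 genes, 3 homologs -> 0.375 < 0.5; no valid sub-window of >=3
    frags = detect_duplicated_fragments(genes, pairs)
    for f in frags:
        assert f.homolog_fraction_a >= 0.5 and f.homolog_fraction_b >= 0.5


# ---------------------------------------------------------------------------
# merge_adjacent_pairs
# ---------------------------------------------------------------------------

def _pair(a0, a1, b0, b1, ident, scaf_a="s1", scaf_b="s2"):
    return DuplicatedRegionPair(
        region_a=Region(scaf_a, a0, a1), region_b=Region(scaf_b, b0, b1),
        anchor_pairs=[("x", "y")], n_genes_a=3, n_genes_b=3,
        homolog_fraction_a=1.0, homolog_fraction_b=1.0, nt_identity=ident)


def test_merge_weighted_identity():
    p1 = _pair(0, 10_000, 0, 10_000, 90.0)
    p2 = _pair(13_000, 23_000, 13_000, 23_000, 94.0)
    (merged,) = merge_adjacent_pairs([p1, p2])
    assert merged.nt_identity == pytest.approx(92.0)
    assert merged.region_a == Region("s1", 0, 23_000)
    assert merged.region_b == Region("s2", 0, 23_000)


def test_merge_gap_boundary():
    p1 = _pair(0, 10_000, 0, 10_000, 90.0)
    p2 = _pair(16_000, 26_000, 16_000, 26_000, 94.0)  # 6 kb gap
    assert len(merge_adjacent_pairs([p1, p2])) == 2
    p3 = _pair(14_999, 24_999, 16_000, 26_000, 94.0)  # 4999 / 6000 bp gaps
    assert len(merge_adjacent_pairs([p1, p3])) == 2  # both sides must be < 5 kb


def test_merge_idempotent():
    pairs = [_pair(0, 10_000, 0, 10_000, 90.0),
             _pair(13_000, 23_000, 13_000, 23_000, 94.0),
             _pair(40_000, 50_000, 40_000, 50_000, 88.0)]
    once = merge_adjacent_pairs(pairs)
    twice = merge_adjacent_pairs(once)
    assert [(p.region_a, p.region_b, p.nt_identity) for p in once] == \
        [(p.region_a, p.region_b, p.nt_identity) for p in twice]


def test_merge_different_scaffold_pairs_untouched():
    p1 = _pair(0, 10_000, 0, 10_000, 90.0)
    p2 = _pair(11_000, 21_000, 11_000, 21_000, 94.0, scaf_b="s3")
    assert len(merge_adjacent_pairs([p1, p2])) == 2


# ---------------------------------------------------------------------------
# region_nt_identity
# ---------------------------------------------------------------------------

def test_region_identity_identical():
    genes = {"a": _gene("a", "s1", 0, cds="ACGT" * 250),
             "b": _gene("b", "s2", 0, cds="ACGT" * 250)}
    pair = _pair(0, 1000, 0, 1000, float("nan"))
    pair.anchor_pairs = [("a", "b")]
    assert region_nt_identity(pair, genes) == 100.0


def test_region_identity_weighted_hand_example():
    genes = {
        "a1": _gene("a1", "s1", 0, cds="A" * 1000),
        "b1": _gene("b1", "s2", 0, cds="A" * 1000),
        "a2": _gene("a2", "s1", 2000, cds="A" * 3000),
        "b2": _gene("b2", "s2", 2000, cds="A" * 2700 + "C" * 300),
    }
    pair = _pair(0, 5000, 0, 5000, float("nan"))
    pair.anchor_pairs = [("a1", "b1"), ("a2", "b2")]
    assert region_nt_identity(pair, genes) == pytest.approx(92.5)


def test_region_identity_requires_anchors():
    pair = _pair(0, 1000, 0, 1000, float("nan"))
    pair.anchor_pairs = []
    with pytest.raises(ValueError):
        region_nt_identity(pair, {})


# ---------------------------------------------------------------------------
# duplication_summary
# ---------------------------------------------------------------------------

def test_summary_hand_example():
    asm = Assembly([("s1", "A" * 10_000)])
    pairs = [
        _pair(0, 3000, 3000, 6000, 96.0, scaf_a="s1", scaf_b="s1"),
        _pair(0, 3000, 5000, 8000, 90.0, scaf_a="s1", scaf_b="s1"),
    ]
    genes = [_gene("in1", "s1", 100), _gene("out1", "s1", 9000)]
    summary = duplication_summary(pairs, genes, asm)
    assert summary.duplicated_fraction_of_assembly == pytest.approx(0.8)
    assert summary.content_fractions["gt95"] == pytest.approx(0.5)
    assert summary.genes_in_duplicated_regions == 1
    assert summary.genes_in_single_copy_regions == 1
    assert summary.unpaired_length == 2000
    assert summary.mean_nt_identity == pytest.approx(93.0)


def test_summary_empty():
    asm = Assembly([("s1", "A" * 1000)])
    genes = [_gene("g", "s1", 0)]
    summary = duplication_summary([], genes, asm)
    assert summary.duplicated_fraction_of_assembly == 0.0
    assert summary.genes_in_single_copy_regions == 1
    assert summary.unpaired_length == 1000


def test_summary_length_conservation(small_allo_run):
    sim, result = small_allo_run
    s = result.summary
    total = sim.assembly.total_length
    assert 0 <= s.duplicated_fraction_of_assembly <= 1
    assert s.unpaired_length + round(s.duplicated_fraction_of_assembly * total) == total
    assert s.genes_in_duplicated_regions + s.genes_in_single_copy_regions == len(sim.genes)


# ---------------------------------------------------------------------------
# copy labels
# ---------------------------------------------------------------------------

def test_natural_key_ordering():
    assert natural_key("scaffold_2") < natural_key("scaffold_10")
    assert sorted(["scaffold_10", "scaffold_2"], key=natural_key) == \
        ["scaffold_2", "scaffold_10"]


def test_copy_labels_natural_order():
    genes = [_gene("a", "scaffold_4", 0), _gene("b", "scaffold_14", 0)]
    pair = _pair(0, 300, 0, 300, 95.0, scaf_a="scaffold_14", scaf_b="scaffold_4")
    pair.anchor_pairs = [("b", "a")]
    labeled = {g.gene_id: g.copy_label for g in assign_copy_labels([pair], genes)}
    assert labeled == {"a": "copy1", "b": "copy2"}


def test_copy_labels_simple_pair_and_unpaired():
    genes = [_gene("a", "scaffold_1", 0), _gene("b", "scaffold_2", 0),
             _gene("c", "scaffold_3", 0)]
    pair = _pair(0, 300, 0, 300, 95.0, scaf_a="scaffold_1", scaf_b="scaffold_2")
    pair.anchor_pairs = [("a", "b")]
    labeled = {g.gene_id: g.copy_label for g in assign_copy_labels([pair], genes)}
    assert labeled == {"a": "copy1", "b": "copy2", "c": "unpaired"}


def test_copy_labels_triplicate():
    genes = [_gene("a", "scaffold_1", 0), _gene("b", "scaffold_2", 0),
             _gene("c", "scaffold_3", 0)]
    p1 = _pair(0, 300, 0, 300, 95.0, scaf_a="scaffold_1", scaf_b="scaffold_2")
    p1.anchor_pairs = [("a", "b")]
    p2 = _pair(0, 300, 0, 300, 95.0, scaf_a="scaffold_1", scaf_b="scaffold_3")
    p2.anchor_pairs = [("a", "c")]
    labeled = {g.gene_id: g.copy_label for g in assign_copy_labels([p1, p2], genes)}
    assert labeled["a"] == "triplicate"


def test_copy_labels_partition(small_allo_run):
    _, result = small_allo_run
    labels = {g.copy_label for g in result.labeled_genes}
    assert labels <= {"copy1", "copy2", "triplicate", "unpaired"}
    assert len(result.labeled_genes) == len({g.gene_id for g in result.labeled_genes})


def test_copy_labels_input_permutation_stable():
    genes = [_gene("a", "scaffold_1", 0), _gene("b", "scaffold_2", 0)]
    pair = _pair(0, 300, 0, 300, 95.0, scaf_a="scaffold_1", scaf_b="scaffold_2")
    pair.anchor_pairs = [("a", "b")]
    fwd = [(g.gene_id, g.copy_label) for g in assign_copy_labels([pair], genes)]
    rev = [(g.gene_id, g.copy_label) for g in assign_copy_labels([pair], genes[::-1])]
    assert fwd == rev


# ---------------------------------------------------------------------------
# allelic content
# ---------------------------------------------------------------------------

def test_allelic_hand_example():
    asm = Assembly([("big", "A" * 100_000), ("small", "A" * 10_000)])
    segs = [SegmentRecord("small", "big", 0, 6000, 0, 6000, 97.0)]
    genes = [_gene("m1", "small", 100), _gene("m2", "small", 5000),
             _gene("m3", "small", 8000), _gene("m4", "big", 0)]
    report = allelic_content(segs, asm, genes)
    assert report.allelic_model_ids == ["m1", "m2"]
    assert report.scaffold_coverage["small"] == pytest.approx(0.6)
    assert report.allelic_fraction == pytest.approx(2 / 4)


def test_allelic_identity_threshold():
    asm = Assembly([("big", "A" * 100_000), ("small", "A" * 10_000)])
    segs = [SegmentRecord("small", "big", 0, 6000, 0, 6000, 95.0)]  # not > 95
    genes = [_gene("m1", "small", 100)]
    report = allelic_content(segs, asm, genes)
    assert report.allelic_model_ids == []


def test_allelic_requires_larger_partner():
    asm = Assembly([("s1", "A" * 10_000), ("s2", "A" * 10_000)])
    segs = [SegmentRecord("s1", "s2", 0, 6000, 0, 6000, 99.0)]
    report = allelic_content(segs, asm, [_gene("m1", "s1", 100)])
    assert report.allelic_model_ids == []  # equal sizes: no smaller scaffold


# ---------------------------------------------------------------------------
# whole-genome identity
# ---------------------------------------------------------------------------

def test_whole_genome_identity_dedupes_and_weights():
    segs = [
        SegmentRecord("sA", "sB", 0, 3000, 0, 3000, 90.0),
        SegmentRecord("sA", "sC", 0, 3000, 0, 3000, 95.0),  # same ref interval
        SegmentRecord("sB", "sC", 0, 2000, 0, 2000, 80.0),
    ]
    ident = whole_genome_identity(segs)
    assert ident == pytest.approx((3000 * 95 + 2000 * 80) / 5000)


def test_whole_genome_identity_min_len_and_error():
    segs = [SegmentRecord("sA", "sB", 0, 1000, 0, 1000, 90.0)]
    with pytest.raises(ValueError, match="segment"):
        whole_genome_identity(segs)
    assert whole_genome_identity(segs, min_len=500) == pytest.approx(90.0)


def test_regions_to_segments_roundtrip_fields():
    p = _pair(10, 4010, 20, 4020, 92.5)
    (seg,) = regions_to_segments([p])
    assert (seg.ref_scaffold, seg.ref_start, seg.ref_end) == ("s1", 10, 4010)
    assert (seg.qry_scaffold, seg.qry_start, seg.qry_end) == ("s2", 20, 4020)
    assert seg.pct_identity == 92.5
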