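"""Divergent-pair mining, expression filtering, promoter/core extraction."""

import numpy as np
import pytest

from harbormine.errors import EmptyPromoterError
from harbormine.expression import counts_from_arrays
from harbormine.genome_model import GenomeSequence, reverse_complement
from harbormine.promoters import (
    PromoterConfig,
    classify_adjacent_pairs,
    extract_bidirectional_promoter,
    extract_core_promoters,
    filter_pairs_by_expression,
    find_divergent_pairs,
)

from conftest import make_annotation, random_annotation, random_seq
from oracles import brute_force_adjacent_pairs


def test_divergent_pair_coordinates():
    ann = make_annotation(
        [("chr1", 100, 500, "g1", "-"), ("chr1", 800, 1200, "g2", "+")]
    )
    (p,) = find_divergent_pairs(ann)
    assert (p.promoter_start0, p.promoter_end0, p.length_bp) == (500, 799, 299)
    assert p.pair_id == "g1|g2"


@pytest.mark.parametrize(
    "s1,s2", [("+", "+"), ("-", "-"), ("+", "-")]
)
def test_non_divergent_orientations_yield_no_pair(s1, s2):
    ann = make_annotation(
        [("chr1", 100, 500, "g1", s1), ("chr1", 800, 1200, "g2", s2)]
    )
    assert find_divergent_pairs(ann) == []


def test_intervening_third_gene_blocks_the_outer_pair():
    """g1(-) ... mid(+) ... g2(+): adjacency is (g1,mid) and (mid,g2); the
    outer g1/g2 combination is never paired."""
    ann = make_annotation(
        [
            ("chr1", 100, 500, "g1", "-"),
            ("chr1", 600, 700, "mid", "+"),
            ("chr1", 800, 1200, "g2", "+"),
        ]
    )
    ids = [p.pair_id for p in find_divergent_pairs(ann)]
    assert ids == ["g1|mid"]
    assert "g1|g2" not in ids


def test_adjacent_pair_classes_partition_and_match_oracle():
    rng = np.random.default_rng(1618)
    for _ in range(100):
        ann = random_annotation(rng, max_genes=40, max_chrom_len=60_000)
        classes = classify_adjacent_pairs(ann)
        got = sorted(
            (l.gene_id, r.gene_id, cls)
            for cls, pairs in classes.items()
            for l, r in pairs
        )
        assert got == sorted(brute_force_adjacent_pairs(ann))
        # the three classes partition all adjacent pairs
        all_ids = [(l.gene_id, r.gene_id) for pairs in classes.values() for l, r in pairs]
        assert len(all_ids) == len(set(all_ids))
        divergent_ids = {(p.left_gene.gene_id, p.right_gene.gene_id)
                         for p in find_divergent_pairs(ann)}
        assert divergent_ids == {(l.gene_id, r.gene_id) for l, r in classes["divergent"]}


def _pair_fixture():
    return make_annotation(
        [("chr1", 100, 500, "gA", "-"), ("chr1", 800, 1200, "gB", "+")]
    )


def _counts_with_ranks(pair_high_in_libs, n_libs=6, n_genes=40):
    """gA/gB get top counts in the given libraries, background otherwise."""
    gids = ["gA", "gB"] + [f"bg{i:02d}" for i in range(n_genes - 2)]
    rng = np.random.default_rng(4)
    counts = rng.integers(100, 1000, size=(n_genes, n_libs))
    for li in range(n_libs):
        if li in pair_high_in_libs:
            counts[0, li] = 10_000
            counts[1, li] = 9_000
        else:
            counts[0, li] = 1
            counts[1, li] = 2
    return counts_from_arrays(gids, [f"L{j}" for j in range(n_libs)], counts)


def test_filter_keeps_dominant_pair_in_all_libraries():
    ann = _pair_fixture()
    pairs = find_divergent_pairs(ann)
    m = _counts_with_ranks(set(range(6)))
    cfg = PromoterConfig(expr_quantile=0.10, min_libraries=6)
    assert filter_pairs_by_expression(pairs, m, cfg) == pairs


def test_filter_drops_pair_high_in_one_of_six_libraries():
    ann = _pair_fixture()
    pairs = find_divergent_pairs(ann)
    m = _counts_with_ranks({0})
    cfg = PromoterConfig(expr_quantile=0.10, min_libraries=4)
    assert filter_pairs_by_expression(pairs, m, cfg) == []


def test_filter_vacuous_with_full_quantile_single_library():
    ann = _pair_fixture()
    pairs = find_divergent_pairs(ann)
    m = _counts_with_ranks(set())
    cfg = PromoterConfig(expr_quantile=1.0, min_libraries=1)
    assert filter_pairs_by_expression(pairs, m, cfg) == pairs


def test_filter_monotone_in_quantile_and_antimonotone_in_min_libraries(default_dataset):
    ds = default_dataset
    pairs = find_divergent_pairs(ds.annotation)
    prev = set()
    for q in (0.02, 0.05, 0.1, 0.5, 1.0):
        kept = {
            p.pair_id
            for p in filter_pairs_by_expression(
                pairs, ds.counts, PromoterConfig(expr_quantile=q, min_libraries=4)
            )
        }
        assert prev <= kept
        prev = kept
    prev = None
    for m_req in (1, 2, 4, 6):
        kept = {
            p.pair_id
            for p in filter_pairs_by_expression(
                pairs, ds.counts, PromoterConfig(expr_quantile=0.1, min_libraries=m_req)
            )
        }
        if prev is not None:
            assert kept <= prev
        prev = kept


def test_extract_bidirectional_promoter_is_exact_substring():
    rng = np.random.default_rng(21)
    s = random_seq(rng, 2000)
    seq = GenomeSequence({"chr1": s})
    ann = make_annotation(
        [("chr1", 100, 500, "g1", "-"), ("chr1", 800, 1200, "g2", "+")],
        {"chr1": 2000},
    )
    (p,) = find_divergent_pairs(ann)
    name, prom = extract_bidirectional_promoter(p, seq)
    assert name == "g1|g2"
    assert prom == s[500:799]  # 1-based bases 501..799
    # the left gene sees the reverse complement of the same interval
    assert reverse_complement(prom) == reverse_complement(s[500:799])


def test_abutting_divergent_genes_raise_empty_promoter():
    seq = GenomeSequence({"chr1": "A" * 1000})
    ann = make_annotation(
        [("chr1", 1, 500, "g1", "-"), ("chr1", 501, 900, "g2", "+")],
        {"chr1": 1000},
    )
    (p,) = find_divergent_pairs(ann)
    assert p.length_bp == 0
    with pytest.raises(EmptyPromoterError):
        extract_bidirectional_promoter(p, seq)


def test_core_promoters_match_string_slice_oracle():
    """Gene ranks known by construction; windows checked by direct slicing."""
    rng = np.random.default_rng(8)
    s = random_seq(rng, 40_000)
    seq = GenomeSequence({"chr1": s})
    genes, counts, gids = [], [], []
    pos = 1000
    for i in range(12):
        strand = "+" if i % 2 == 0 else "-"
        gid = f"g{i:02d}"
        genes.append(("chr1", pos + 1, pos + 1000, gid, strand))
        gids.append(gid)
        counts.append([10_000 - 500 * i])  # strictly decreasing: rank = index
        pos += 3000
    ann = make_annotation(genes, {"chr1": 40_000})
    m = counts_from_arrays(gids, ["L"], counts, gene_length_bp={g: 1000 for g in gids})
    cfg = PromoterConfig(core_len=200, top_n=8)
    out = extract_core_promoters(ann, seq, m, cfg, library="L")
    assert [g for g, _ in out] == gids[:8]
    for gid, window in out:
        g = ann.by_id(gid)
        if g.strand == "+":
            assert window == s[g.start0 - 200 : g.start0]
        else:
            assert window == reverse_complement(s[g.end0 : g.end0 + 200])
        assert len(window) == 200


def test_core_promoters_skip_out_of_bounds_and_take_next_ranked():
    rng = np.random.default_rng(13)
    s = random_seq(rng, 10_000)
    seq = GenomeSequence({"chr1": s})
    ann = make_annotation(
        [
            ("chr1", 5, 900, "top", "+"),        # no room for 200 bp upstream
            ("chr1", 2001, 3000, "second", "+"),
            ("chr1", 5001, 6000, "third", "+"),
        ],
        {"chr1": 10_000},
    )
    m = counts_from_arrays(
        ["top", "second", "third"], ["L"], [[900], [500], [100]],
        gene_length_bp={"top": 896, "second": 1000, "third": 1000},
    )
    out = extract_core_promoters(
        ann, seq, m, PromoterConfig(core_len=200, top_n=2), library="L"
    )
    assert [g for g, _ in out] == ["second", "third"]


def test_core_promoters_partial_output_when_no_room():
    seq = GenomeSequence({"chr1": "A" * 1000})
    ann = make_annotation([("chr1", 5, 900, "only", "+")], {"chr1": 1000})
    m = counts_from_arrays(["only"], ["L"], [[5]], gene_length_bp={"only": 896})
    out = extract_core_promoters(
        ann, seq, m, PromoterConfig(core_len=200, top_n=1), library="L"
    )
    assert out == []
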