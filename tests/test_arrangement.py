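"""Synteny blocks, Type I-IV classification, puf typing, core gene set."""

import pytest

from pgckit.arrangement import (
    classify_arrangement,
    core_gene_intersection,
    find_block,
    type_puf_operon,
)
from pgckit.catalog import default_catalog
from pgckit.delineation import PGCRegion, delineate_pgc
from pgckit.errors import InputError
from pgckit.genomeio import GeneFeature, reflect_replicon
from pgckit.simulate import SimulationSpec, generate_genome


def _region(symbols_strands, rid="r1", gene_len=800, gap=100):
    catalog = default_catalog()
    feats, pos = [], 1000
    for sym, strand in symbols_strands:
        d = catalog.canonicalize(sym)
        feats.append(
            GeneFeature(label=sym, symbol=getattr(d, "symbol", None), category=d.category,
                        start=pos, end=pos + gene_len, strand=strand, replicon_id=rid)
        )
        pos += gene_len + gap
    return PGCRegion(replicon_id=rid, start=feats[0].start, end=feats[-1].end, genes=tuple(feats))


B1_GENES = ["bchF", "bchN", "bchB", "bchH", "bchL", "bchM", "lhaA", "puhA", "puhB", "puhC"]


def test_find_block_tolerates_interspersed_hypotheticals():
    genes = B1_GENES[:3] + ["hyp"] + B1_GENES[3:]
    block = find_block(_region([(g, "+") for g in genes]), "B1")
    assert block is not None
    assert block.completeness == 1.0 and block.strand == "+"
    assert [g.symbol for g in block.matched_genes] == B1_GENES


def test_find_block_mirror_orientation():
    block = find_block(_region([(g, "-") for g in reversed(B1_GENES)]), "B1")
    assert block is not None and block.strand == "-"
    assert block.completeness == 1.0


def test_find_block_below_completeness_floor_is_none():
    assert find_block(_region([("bchF", "+"), ("puhC", "+")]), "B1", max_missing=2) is None


def test_find_block_tolerates_bounded_missing_genes():
    genes = [g for g in B1_GENES if g not in ("bchH", "puhB")]
    block = find_block(_region([(g, "+") for g in genes]), "B1", max_missing=2)
    assert block is not None and block.completeness == pytest.approx(0.8)


@pytest.mark.parametrize(
    "layout, expected",
    [
        # B1 '+' then B2 '+' downstream
        ([(g, "+") for g in B1_GENES] + [(g, "+") for g in ["crtF", "bchC", "bchX", "bchY", "bchZ"]], "I"),
        # B1 '+' then B2 '-' downstream
        ([(g, "+") for g in B1_GENES] + [(g, "-") for g in ["bchZ", "bchY", "bchX", "bchC", "crtF"]], "II"),
        # B2 '+' upstream of B1 '+'
        ([(g, "+") for g in ["crtF", "bchC", "bchX", "bchY", "bchZ"]] + [(g, "+") for g in B1_GENES], "III"),
        # B1 '-' leftmost, B2 '+' rightmost
        ([(g, "-") for g in reversed(B1_GENES)] + [(g, "+") for g in ["crtF", "bchC", "bchX", "bchY", "bchZ"]], "IV"),
    ],
)
def test_classify_arrangement_types(layout, expected):
    call = classify_arrangement(_region(layout))
    assert call.type_label == expected
    assert call.normalized == (expected == "IV")


def test_classify_missing_block_is_unclassified_with_diagnostic():
    call = classify_arrangement(_region([(g, "+") for g in B1_GENES]))
    assert call.type_label == "unclassified"
    assert "B2" in call.diagnostic


@pytest.mark.parametrize("arr", ["I", "II", "III", "IV"])
def test_classification_invariant_under_reflection(arr):
    rep, truth = generate_genome(
        SimulationSpec(strain_id=f"refl{arr}", arrangement_type=arr,
                       clade_template="rhodobacter" if arr == "IV" else "roseobacter",
                       puf_type="pufQBALMX" if arr == "IV" else "pufQBALMC",
                       genome_length_bp=300_000, seed=17)
    )
    (fwd,) = delineate_pgc(rep).regions
    (rev,) = delineate_pgc(reflect_replicon(rep)).regions
    assert classify_arrangement(fwd).type_label == truth.arrangement_type
    assert classify_arrangement(rev).type_label == truth.arrangement_type


@pytest.mark.parametrize(
    "symbols_strands, label",
    [
        ([(f"puf{s}", "+") for s in "QBALMC"], "pufQBALMC"),
        ([(f"puf{s}", "+") for s in "QBALM"], "pufQBALM"),
        ([(f"puf{s}", "+") for s in "BALM"], "pufBALM"),
        ([(f"puf{s}", "+") for s in "LMCBA"], "pufLMCBA"),
        # same operon on the minus strand, genome order reversed
        ([(f"puf{s}", "-") for s in "ABCML"], "pufLMCBA"),
        ([(f"puf{s}", "+") for s in "QBALMX"], "novel"),
    ],
)
def test_puf_operon_typing(symbols_strands, label):
    t = type_puf_operon(_region(symbols_strands))
    assert t.label == label


def test_puf_operon_allows_single_intervening_gene():
    layout = [("pufQ", "+"), ("pufB", "+"), ("hyp", "+"), ("pufA", "+"),
              ("pufL", "+"), ("pufM", "+"), ("pufC", "+")]
    assert type_puf_operon(_region(layout)).label == "pufQBALMC"


def test_no_puf_genes_is_an_error_distinct_from_novel():
    with pytest.raises(InputError):
        type_puf_operon(_region([("bchF", "+"), ("bchN", "+")]))


def test_core_intersection_identity_and_monotonicity():
    s = {"bchF", "pufM", "crtC"}
    assert core_gene_intersection([s, set(s)]) == sorted(s)
    sets = [s, {"bchF", "pufM"}, {"bchF"}]
    sizes = [len(core_gene_intersection(sets[: k + 1])) for k in range(1, len(sets))]
    assert sizes == sorted(sizes, reverse=True)
    with pytest.raises(InputError):
        core_gene_intersection([s])


def test_core_unchanged_by_extra_set_lacking_non_core_gene(aap_profiles):
    sets = [p.pgc_symbols for p in aap_profiles.values()]
    core = core_gene_intersection(sets)
    assert "pufC" not in core  # Sphingomonadales and SKA53 lack pufC
    eleventh = set(core) | {"bchE"}  # no pufC either
    assert core_gene_intersection(sets + [eleventh]) == core
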