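"""Replicon I/O: coordinate conventions, GC, region extraction, reflection."""

from io import StringIO

import pytest
from hypothesis import given, settings, strategies as st

import pgckit
from pgckit.errors import FormatError, RangeError, UndefinedGCError
from pgckit.genomeio import (
    AnnotatedReplicon,
    GeneFeature,
    extract_region,
    gc_fraction,
    read_gene_table,
    read_genbank,
    reflect_replicon,
    write_gene_table,
    write_genbank,
)
from pgckit.simulate import SimulationSpec, generate_genome


def _feat(label, start, end, strand="+", symbol=None, category="other", rid="r1"):
    return GeneFeature(label=label, symbol=symbol, category=category,
                       start=start, end=end, strand=strand, replicon_id=rid)


@pytest.fixture(scope="module")
def synthetic():
    rep, truth = generate_genome(
        SimulationSpec(strain_id="synt1", genome_length_bp=250_000,
                       emit_sequence=True, seed=11)
    )
    return rep, truth


# -- gene table -------------------------------------------------------------

def test_gene_table_converts_one_based_inclusive_to_internal():
    text = "replicon_id\tgene\tstart\tend\tstrand\nJL354x\tpufL\t1000\t1860\t+\n"
    (rep,) = read_gene_table(text)
    f = rep.features[0]
    assert (f.start, f.end, f.symbol, f.category) == (999, 1860, "pufL", "puf")


def test_gene_table_gc_percent_column_supplies_gc():
    text = (
        "replicon_id\tgene\tstart\tend\tstrand\treplicon_length\tgc_percent\n"
        "s1\tbchF\t100\t900\t+\t50000\t65\n"
    )
    (rep,) = read_gene_table(text)
    assert rep.length_bp == 50_000
    assert rep.gc == pytest.approx(0.65)


def test_gene_table_empty_after_header_is_empty_list():
    assert read_gene_table("replicon_id\tgene\tstart\tend\tstrand\n") == []


def test_gene_table_missing_column_and_bad_row():
    with pytest.raises(FormatError, match="strand"):
        read_gene_table("replicon_id\tgene\tstart\tend\nr\tg\t1\t2\n")
    with pytest.raises(FormatError, match="end"):
        read_gene_table("replicon_id\tgene\tstart\tend\tstrand\nr\tg\t500\t100\t+\n")


# -- GenBank ----------------------------------------------------------------

def test_genbank_complement_coordinates_and_ids(synthetic):
    rep = AnnotatedReplicon(
        id="recA1", length_bp=1000,
        features=[_feat("pufM", 100, 400, "-", "pufM", "puf", "recA1")],
        sequence="ACGT" * 250,
    )
    buf = StringIO()
    write_genbank([rep, synthetic[0]], buf)
    out = read_genbank(buf.getvalue())
    assert [r.id for r in out] == ["recA1", "synt1"]
    f = out[0].features[0]
    assert (f.start, f.end, f.strand, f.symbol) == (100, 400, "-", "pufM")
    assert "complement(101..400)" in buf.getvalue()


def test_genbank_roundtrip_preserves_synthetic_features(synthetic):
    rep, _ = synthetic
    buf = StringIO()
    write_genbank([rep], buf)
    (back,) = read_genbank(buf.getvalue())
    assert back == rep


def test_gene_table_roundtrip(synthetic):
    rep, _ = synthetic
    buf = StringIO()
    write_gene_table([rep], buf)
    (back,) = read_gene_table(buf.getvalue())
    assert back.features == rep.features
    assert back.length_bp == rep.length_bp


def test_truncated_genbank_raises_format_error():
    with pytest.raises(FormatError):
        read_genbank("LOCUS       broken        100 bp DNA linear\nFEATURES\n")


# -- GC ---------------------------------------------------------------------

@pytest.mark.parametrize("seq, gc", [("ATGC", 0.5), ("GGCC", 1.0), ("ATGCN", 0.5)])
def test_gc_fraction_examples(seq, gc):
    assert gc_fraction(seq) == pytest.approx(gc)


def test_gc_fraction_undefined_inputs():
    with pytest.raises(UndefinedGCError):
        gc_fraction("")
    with pytest.raises(UndefinedGCError):
        gc_fraction("NNNN")


@settings(deadline=None, max_examples=60)
@given(st.text(alphabet="ACGTNacgtn", min_size=1).filter(lambda s: set(s.upper()) != {"N"}))
def test_gc_fraction_matches_per_character_count(seq):
    s = seq.upper()
    denom = sum(s.count(b) for b in "ACGT")
    expected = (s.count("G") + s.count("C")) / denom
    assert gc_fraction(seq) == pytest.approx(expected)


# -- region extraction ------------------------------------------------------

def test_extract_region_identity_and_boundary_rule(synthetic):
    rep, _ = synthetic
    whole = extract_region(rep, 0, rep.length_bp)
    assert whole == rep
    # a feature straddling the cut is excluded
    f = rep.features[5]
    cut = extract_region(rep, f.start + 1, rep.length_bp)
    assert all(g.label != f.label or g.start != 0 for g in cut.features)
    assert len(cut.features) < len(rep.features)
    with pytest.raises(RangeError):
        extract_region(rep, -1, 10)


def test_extract_region_gc_matches_direct_count(synthetic):
    rep, truth = synthetic
    sub = extract_region(rep, truth.pgc_start, truth.pgc_end)
    piece = rep.sequence[truth.pgc_start:truth.pgc_end]
    assert sub.gc == pytest.approx((piece.count("G") + piece.count("C")) / len(piece))


# -- reflection -------------------------------------------------------------

def test_reflection_is_involution_and_preserves_content(synthetic):
    rep, _ = synthetic
    refl = reflect_replicon(rep)
    assert reflect_replicon(refl) == rep
    assert refl.gc == pytest.approx(rep.gc)
    before = sorted((f.symbol or f.label, f.length, f.category) for f in rep.features)
    after = sorted((f.symbol or f.label, f.length, f.category) for f in refl.features)
    assert before == after


def test_reflection_arithmetic():
    rep = AnnotatedReplicon(
        id="r", length_bp=1000,
        features=[_feat("pufM", 100, 400, "+", "pufM", "puf", "r")],
    )
    f = reflect_replicon(rep).features[0]
    assert (f.start, f.end, f.strand) == (600, 900, "-")
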