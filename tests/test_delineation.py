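"""Cluster delineation, summary statistics and clade summaries."""

import pytest

from pgckit.delineation import (
    delineate_pgc,
    pgc_statistics,
    summarize_collection,
    tag_photosynthesis_genes,
    category_counts,
    StatRow,
)
from pgckit.errors import InputError
from pgckit.genomeio import AnnotatedReplicon, GeneFeature, reflect_replicon
from pgckit.rounding import round_half_up
from pgckit.simulate import SimulationSpec, generate_genome


def _replicon(genes, length=1_000_000, rid="r1"):
    """genes: (label, start) tuples; 900 bp each, untagged symbols."""
    feats = [
        GeneFeature(label=lbl, symbol=None, category="other",
                    start=s, end=s + 900, strand="+", replicon_id=rid)
        for lbl, s in genes
    ]
    return AnnotatedReplicon(id=rid, length_bp=length, features=feats)


def test_tagging_assigns_categories_and_counts():
    rep = tag_photosynthesis_genes(
        _replicon([("bchF", 1000), ("gyrA", 3000), ("crtA", 5000)])
    )
    cats = {f.label: f.category for f in rep.features}
    assert cats == {"bchF": "bch", "gyrA": "other", "crtA": "crt"}
    assert category_counts(rep) == {"bch": 1, "other": 1, "crt": 1}


def test_all_decoy_replicon_yields_no_regions():
    rep = tag_photosynthesis_genes(_replicon([("gyrA", 1000), ("recA", 3000)]))
    res = delineate_pgc(rep)
    assert res.regions == () and res.outside_genes == ()


@pytest.fixture(scope="module")
def planted():
    rep, truth = generate_genome(
        SimulationSpec(strain_id="p1", clade_template="sphingomonadales",
                       puf_type="pufBALM", genome_length_bp=500_000, seed=3)
    )
    return rep, truth


def test_planted_interval_recovered_exactly(planted):
    rep, truth = planted
    res = delineate_pgc(rep)
    assert len(res.regions) == 1
    region = res.regions[0]
    assert (region.start, region.end) == (truth.pgc_start, truth.pgc_end)
    # first and last members are photosynthesis genes
    assert region.genes[0].is_photosynthetic and region.genes[-1].is_photosynthetic


def test_isolated_crt_genes_reported_outside(planted):
    rep, truth = planted
    res = delineate_pgc(rep)
    outside = {f.symbol for f in res.outside_genes}
    expected = {s for s, v in truth.crt_statuses.items() if v == "outside"}
    assert expected and outside == expected


def test_photo_gene_partition_property(planted):
    rep, _ = planted
    res = delineate_pgc(rep)
    photo = [f for f in rep.features if f.is_photosynthetic]
    in_regions = [f for r in res.regions for f in r.photo_genes]
    assert len(in_regions) == len(set(map(id, in_regions)))  # no double counting
    assert sorted(map(id, in_regions + list(res.outside_genes))) == sorted(map(id, photo))


def test_delineation_invariant_under_reflection(planted):
    rep, _ = planted
    res = delineate_pgc(rep)
    res_r = delineate_pgc(reflect_replicon(rep))
    assert len(res_r.regions) == len(res.regions) == 1
    a, b = res.regions[0], res_r.regions[0]
    assert (b.start, b.end) == (rep.length_bp - a.end, rep.length_bp - a.start)


@pytest.mark.parametrize(
    "genome_kb, pgc_kb, ratio",
    [(4417.8, 48.1, 1.09), (3063.7, 41.2, 1.34), (3576.1, 43.6, 1.22), (4762.6, 45.1, 0.95)],
)
def test_statistics_ratio_reproduces_printed_values(genome_kb, pgc_kb, ratio):
    assert round_half_up(pgc_kb / genome_kb * 100, 2) == ratio


def test_pgc_statistics_from_region(planted):
    rep, truth = planted
    (region,) = delineate_pgc(rep).regions
    row = pgc_statistics(region, rep, strain_id="p1")
    assert row.genome_kb == pytest.approx(rep.length_bp / 1000)
    assert row.pgc_kb == pytest.approx((truth.pgc_end - truth.pgc_start) / 1000)
    expected = round_half_up(
        float(round_half_up(row.pgc_kb, 1)) / float(round_half_up(row.genome_kb, 1)) * 100, 2
    )
    assert row.ratio_percent == expected
    # annotation-only spec: genome GC came through as metadata, region GC unknown
    assert row.genome_gc_percent == pytest.approx(60.0)
    assert row.pgc_gc_percent is None
    assert row.as_table_row()["pgc_gc"] is None


def test_degenerate_ratio_whole_genome_cluster(planted):
    rep, _ = planted
    (region,) = delineate_pgc(rep).regions
    tiny = AnnotatedReplicon(id="t", length_bp=region.end, features=list(region.genes))
    row = pgc_statistics(region, tiny, genome_kb=region.size_kb)
    assert row.ratio_percent == 100.00


def _rows(values):
    return [
        StatRow(strain_id=f"s{i}", genome_kb=4000.0, pgc_kb=v,
                genome_gc_percent=None, pgc_gc_percent=None, ratio_percent=0.0)
        for i, v in enumerate(values)
    ]


def test_summarize_collection_clade_means():
    rows = _rows([38.7, 38.9, 44.7, 43.6])
    clades = {"s0": "A", "s1": "A", "s2": "B", "s3": "B"}
    summary = summarize_collection(rows, clades)
    assert summary["clades"]["A"]["mean_pgc_kb"] == pytest.approx(38.8)
    assert summary["clades"]["A"]["mean_pgc_kb_rounded"] == 39
    assert summary["clades"]["B"]["n"] == 2
    assert summary["genome_kb_min"] == summary["genome_kb_max"] == 4000.0


def test_summarize_single_row_clade_and_empty_error():
    summary = summarize_collection(_rows([41.2]), {"s0": "solo"})
    assert summary["clades"]["solo"]["mean_pgc_kb"] == pytest.approx(41.2)
    with pytest.raises(InputError):
        summarize_collection([], {})
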