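"""Shipped annotation fixtures for the twelve reference strains.

The ten AAP strains analysed in the comparative study (six Roseobacter
clade, two Sphingomonadales, two NOR5/OM60) plus the two anaerobic
*Rhodobacter* outgroups are encoded as gene-table TSV files under
``data/fixtures/``, one replicon each.  The files are synthetic
reconstructions of each strain's published PGC architecture — gene
content, block order/orientation, *puf* operon structure, carotenoid gene
localization — not the deposited annotations; genome lengths and cluster
spans are pinned to the published kilobase values so the summary-table
statistics recompute exactly, and published GC percentages travel as
metadata (the fixtures carry no nucleotide sequence).

``build_fixture_replicon`` regenerates any fixture deterministically from
the architecture tables below; a test asserts the shipped files match.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from io import StringIO

import numpy as np
import yaml

from .genomeio import AnnotatedReplicon, GeneFeature, read_gene_table, write_gene_table
from .catalog import default_catalog
from .simulate import arm_a_genes, arm_b_genes, assemble_cluster, layout_features

PGC_START = 1_000_000
_OUTSIDE_CRT_START = 2_000_000
_OUTSIDE_CRT_SPACING = 25_000
_DECOY_POSITIONS = (150_000, 400_000, 650_000, 2_700_000, 2_900_000)
_DECOY_LABELS = ("gyrA", "recA", "dnaK", "rpoB", "ftsZ")


@dataclass(frozen=True)
class StrainArchitecture:
    strain_id: str
    organism: str
    clade: str            # Table-1 style grouping
    matrix_clade: str     # carotenoid-matrix column
    genome_kb: float
    pgc_kb: float
    genome_gc: int
    pgc_gc: int
    arrangement_type: str
    puf: str
    crt_inside: tuple[str, ...]   # crt run of arm A, in operon order ("hyp" = hypothetical)
    crt_outside: tuple[str, ...] = ()
    regulators: tuple[str, ...] = ("ppsR", "ppaA")
    hem: str | None = "hemA"
    hem_outside: bool = False     # L. vestfoldensis-style gene spread outside the PGC
    dxps: bool = True
    bluf: bool = False
    bchEJ: bool = False
    between_arms: tuple[str, ...] = ()
    outgroup: bool = False


_ROSEO_CRT = ("crtA", "crtI", "crtB", "crtK", "hyp", "crtC", "crtD", "crtE")

ARCHITECTURES: tuple[StrainArchitecture, ...] = (
    StrainArchitecture(
        "OCh114", "Roseobacter denitrificans OCh 114", "Rhodobacterales", "Roseobacter clade",
        4331.2, 44.6, 58, 60, "I", "pufQBALMC", _ROSEO_CRT,
    ),
    StrainArchitecture(
        "Och149", "Roseobacter litoralis Och 149", "Rhodobacterales", "Roseobacter clade",
        4678.9, 48.3, 57, 59, "I", "pufQBALMC", _ROSEO_CRT,
        between_arms=("rpaA", "rpaB"),  # centromere-like anchor genes on the PGC plasmid
    ),
    StrainArchitecture(
        "Roseovarius217", "Roseovarius sp. 217", "Rhodobacterales", "Roseobacter clade",
        4762.6, 45.1, 60, 64, "II", "pufQBALMC",
        ("crtA", "crtI", "crtB", "crtC", "crtD", "crtE"),
    ),
    StrainArchitecture(
        "DFL12", "Dinoroseobacter shibae DFL 12", "Rhodobacterales", "Roseobacter clade",
        4417.8, 48.1, 65, 67, "III", "pufQBALMC",
        ("crtA", "hyp", "crtI", "crtB", "crtK", "crtC", "crtD", "crtE"),  # crtA split from crtIBK
    ),
    StrainArchitecture(
        "CCS1", "Jannaschia sp. CCS1", "Rhodobacterales", "Roseobacter clade",
        4404.0, 45.8, 62, 62, "III", "pufQBALMC",
        ("crtC", "crtD", "crtE", "crtA", "crtI", "crtB"),  # recombined crt run
    ),
    StrainArchitecture(
        "SKA53", "Loktanella vestfoldensis SKA53", "Rhodobacterales", "Roseobacter clade",
        3063.7, 41.2, 59, 60, "III", "pufQBALM",
        ("crtA", "crtI", "crtB", "crtC", "crtD", "crtE"),
        hem_outside=True,
    ),
    StrainArchitecture(
        "NAP1", "Erythrobacter sp. NAP1", "Sphingomonadales", "Erythrobacter NAP1",
        3265.3, 38.9, 61, 62, "III", "pufBALM",
        ("crtC", "crtD"), crt_outside=("crtI", "crtB", "crtE", "crtY", "crtZ"),
        dxps=False,
    ),
    StrainArchitecture(
        "JL354", "Citromicrobium sp. JL354", "Sphingomonadales", "Citromicrobium JL354",
        3273.3, 38.7, 65, 67, "III", "pufBALM",
        ("crtC",), crt_outside=("crtI", "crtB", "crtE", "crtY", "crtZ", "crtW"),
        dxps=False,
    ),
    StrainArchitecture(
        "KT71", "Congregibacter litoralis KT71", "NOR5/OM60", "NOR5",
        4328.1, 44.7, 58, 59, "II", "pufLMCBA",
        ("crtI", "crtB", "crtC", "crtE"), crt_outside=("crtD",),
        regulators=("crtJ",), hem="hemN", dxps=False, bluf=True, bchEJ=True,
    ),
    StrainArchitecture(
        "HTCC2080", "Gammaproteobacterium HTCC2080", "NOR5/OM60", "NOR5",
        3576.1, 43.6, 51, 53, "II", "pufLMCBA",
        ("crtI", "crtB", "crtC", "crtE"), crt_outside=("crtD",),
        regulators=("crtJ",), hem="hemN", dxps=False, bluf=True,
    ),
    StrainArchitecture(
        "Rsphaeroides", "Rhodobacter sphaeroides 2.4.1", "Rhodobacter", "Rhodobacter",
        4602.0, 45.0, 69, 69, "IV", "pufQBALMX", _ROSEO_CRT,
        dxps=False, bchEJ=True, outgroup=True,
    ),
    StrainArchitecture(
        "Rcapsulatus", "Rhodobacter capsulatus SB 1003", "Rhodobacter", "Rhodobacter",
        3871.9, 46.0, 66, 66, "IV", "pufQBALMX", _ROSEO_CRT,
        regulators=("ppsR", "ppaA", "crtJ"), dxps=False, bchEJ=True, outgroup=True,
    ),
)

STRAIN_IDS = tuple(a.strain_id for a in ARCHITECTURES)
AAP_STRAIN_IDS = tuple(a.strain_id for a in ARCHITECTURES if not a.outgroup)
OUTGROUP_IDS = tuple(a.strain_id for a in ARCHITECTURES if a.outgroup)


def architecture(strain_id: str) -> StrainArchitecture:
    for a in ARCHITECTURES:
        if a.strain_id == strain_id:
            return a
    raise KeyError(strain_id)


def build_fixture_replicon(strain_id: str) -> AnnotatedReplicon:
    """Deterministically rebuild a fixture replicon from its architecture."""
    arch = architecture(strain_id)
    index = STRAIN_IDS.index(strain_id)
    catalog = default_catalog()
    rng = np.random.default_rng(1000 + index)

    puf_genes = catalog.expand_gene_string(arch.puf)
    arm_a = arm_a_genes(arch.crt_inside, puf_genes, bchEJ=arch.bchEJ, dxps=arch.dxps)
    arm_b = arm_b_genes(arch.regulators, arch.hem, bluf=arch.bluf)
    if arch.hem_outside:
        arm_b = [g for g in arm_b if g != arch.hem]
    layout = assemble_cluster(arm_a, arm_b, arch.arrangement_type, between=arch.between_arms)

    features = layout_features(
        layout, PGC_START, strain_id, rng,
        gene_length=(700, 1100), target_span=int(round(arch.pgc_kb * 1000)),
    )

    genome_length = int(round(arch.genome_kb * 1000))
    extras: list[GeneFeature] = []
    outside = list(arch.crt_outside) + ([arch.hem] if arch.hem_outside else [])
    for i, sym in enumerate(outside):
        d = catalog.canonicalize(sym)
        start = _OUTSIDE_CRT_START + i * _OUTSIDE_CRT_SPACING
        extras.append(
            GeneFeature(
                label=sym, symbol=getattr(d, "symbol", None), category=d.category,
                start=start, end=start + 900,
                strand="+" if i % 2 == 0 else "-", replicon_id=strain_id,
            )
        )
    for pos, label in zip(_DECOY_POSITIONS, _DECOY_LABELS):
        extras.append(
            GeneFeature(
                label=label, symbol=None, category="other",
                start=pos, end=pos + 900, strand="+", replicon_id=strain_id,
            )
        )
    return AnnotatedReplicon(
        id=strain_id,
        length_bp=genome_length,
        features=features + extras,
        supplied_gc=arch.genome_gc / 100.0,
    )


def fixture_table_text(strain_id: str) -> str:
    """Gene-table TSV text of a rebuilt fixture."""
    buf = StringIO()
    write_gene_table([build_fixture_replicon(strain_id)], buf)
    return buf.getvalue()


def write_fixture_files(directory) -> None:
    """(Re)write all fixture TSVs plus the strain metadata YAML."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sid in STRAIN_IDS:
        (directory / f"{sid}.tsv").write_text(fixture_table_text(sid))
    meta = {
        a.strain_id: {
            "organism": a.organism,
            "clade": a.clade,
            "matrix_clade": a.matrix_clade,
            "genome_gc_percent": a.genome_gc,
            "pgc_gc_percent": a.pgc_gc,
            "outgroup": a.outgroup,
        }
        for a in ARCHITECTURES
    }
    (directory / "strains.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))


def load_strain(strain_id: str) -> AnnotatedReplicon:
    """Load one shipped fixture replicon."""
    text = resources.files("pgckit.data.fixtures").joinpath(f"{strain_id}.tsv").read_text()
    (replicon,) = read_gene_table(text)
    return replicon


def strain_metadata() -> dict:
    """Published per-strain metadata (organism, clade, GC percentages)."""
    text = resources.files("pgckit.data.fixtures").joinpath("strains.yaml").read_text()
    return yaml.safe_load(text)


def load_all(include_outgroups: bool = False) -> dict[str, AnnotatedReplicon]:
    ids = STRAIN_IDS if include_outgroups else AAP_STRAIN_IDS
    return {sid: load_strain(sid) for sid in ids}
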