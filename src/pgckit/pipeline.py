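"""End-to-end per-strain profiling and cohort comparison.

``profile_strain`` runs the full chain on one strain's replicons —
delineate the PGC, compute summary statistics, classify the arrangement,
type the *puf* operon, build the carotenoid localization profile and infer
the pathway — and ``compare_cohort`` aggregates profiles into the
cross-strain report (core gene set, arrangement/puf/pathway tallies).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .arrangement import (
    ArrangementCall,
    PufOperonType,
    classify_arrangement,
    core_gene_intersection,
    type_puf_operon,
)
from .carotenoids import CrtProfile, PathwayCall, crt_status_matrix, infer_pathway
from .delineation import (
    DEFAULT_MAX_GAP_KB,
    DEFAULT_MAX_INTERVENING,
    DEFAULT_MIN_PHOTO_GENES,
    PGCRegion,
    StatRow,
    delineate_pgc,
    pgc_statistics,
)
from .errors import InputError
from .genomeio import AnnotatedReplicon


@dataclass(frozen=True)
class DelineationParams:
    max_gap_kb: float = DEFAULT_MAX_GAP_KB
    max_intervening: int = DEFAULT_MAX_INTERVENING
    min_photo_genes: int = DEFAULT_MIN_PHOTO_GENES


@dataclass
class StrainProfile:
    strain_id: str
    regions: tuple[PGCRegion, ...]
    main_region: PGCRegion | None
    stats: StatRow | None
    arrangement: ArrangementCall | None
    puf: PufOperonType | None
    crt: CrtProfile
    pathway: PathwayCall
    outside_photo_genes: tuple = ()

    @property
    def pgc_symbols(self) -> set[str]:
        """Canonical symbols inside accepted clusters (union over regions)."""
        out: set[str] = set()
        for r in self.regions:
            out |= r.symbols
        return out

    def to_dict(self) -> dict:
        return {
            "strain_id": self.strain_id,
            "n_regions": len(self.regions),
            "pgc": None
            if self.main_region is None
            else {
                "replicon_id": self.main_region.replicon_id,
                "start": self.main_region.start,
                "end": self.main_region.end,
                "size_kb": self.main_region.size_kb,
                "n_photo_genes": self.main_region.n_photo_genes,
            },
            "stats": None if self.stats is None else self.stats.as_table_row(),
            "arrangement_type": None if self.arrangement is None else self.arrangement.type_label,
            "puf_type": None if self.puf is None else self.puf.label,
            "crt_statuses": dict(self.crt.statuses),
            "pathway": {
                "pathway": self.pathway.pathway,
                "subtype": self.pathway.subtype,
                "tentative": self.pathway.tentative,
                "completeness": self.pathway.completeness,
                "missing": list(self.pathway.missing),
            },
            "pgc_symbols": sorted(self.pgc_symbols),
            "outside_photo_genes": sorted({g.symbol or g.label for g in self.outside_photo_genes}),
        }


def profile_strain(
    replicons: Sequence[AnnotatedReplicon],
    strain_id: str | None = None,
    params: DelineationParams = DelineationParams(),
    genome_kb: float | None = None,
    genome_gc_percent: float | None = None,
    pgc_gc_percent: float | None = None,
) -> StrainProfile:
    """Run the full analysis on one strain (all of its replicons).

    GC overrides feed annotation-only inputs where published values travel
    as metadata rather than sequence.
    """
    if not replicons:
        raise InputError("profile_strain requires at least one replicon")
    strain_id = strain_id or replicons[0].id
    regions: list[PGCRegion] = []
    outside = []
    for rep in replicons:
        res = delineate_pgc(
            rep,
            max_gap_kb=params.max_gap_kb,
            max_intervening=params.max_intervening,
            min_photo_genes=params.min_photo_genes,
        )
        regions.extend(res.regions)
        outside.extend(res.outside_genes)

    main = max(regions, key=lambda r: r.n_photo_genes, default=None)
    stats = arrangement = puf = None
    if main is not None:
        host = next(r for r in replicons if r.id == main.replicon_id)
        if genome_kb is None:
            genome_kb = sum(r.length_bp for r in replicons) / 1000.0
        if genome_gc_percent is None and host.gc is not None:
            genome_gc_percent = host.gc * 100
        stats = pgc_statistics(
            main, host, strain_id=strain_id, genome_kb=genome_kb,
            genome_gc_percent=genome_gc_percent, pgc_gc_percent=pgc_gc_percent,
        )
        arrangement = classify_arrangement(main)
        try:
            puf = type_puf_operon(main)
        except InputError:
            puf = None
    crt = crt_status_matrix(replicons, regions, strain_id=strain_id)
    pathway = infer_pathway(crt)
    return StrainProfile(
        strain_id=strain_id,
        regions=tuple(regions),
        main_region=main,
        stats=stats,
        arrangement=arrangement,
        puf=puf,
        crt=crt,
        pathway=pathway,
        outside_photo_genes=tuple(outside),
    )


def compare_cohort(profiles: Sequence[StrainProfile]) -> dict:
    """Cohort report: core gene set plus arrangement/puf/pathway tallies."""
    if len(profiles) < 2:
        raise InputError("compare_cohort requires at least two strain profiles")
    core = core_gene_intersection([p.pgc_symbols for p in profiles])

    def tally(values):
        out: dict[str, int] = {}
        for v in values:
            key = v if v is not None else "none"
            out[key] = out.get(key, 0) + 1
        return dict(sorted(out.items()))

    return {
        "n_strains": len(profiles),
        "core_genes": core,
        "core_size": len(core),
        "arrangement_tally": tally(
            p.arrangement.type_label if p.arrangement else None for p in profiles
        ),
        "puf_tally": tally(p.puf.label if p.puf else None for p in profiles),
        "pathway_tally": tally(p.pathway.pathway for p in profiles),
    }
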