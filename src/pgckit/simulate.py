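"""Seeded generation of annotated genomes with planted PGC architectures.

Every genome carries exactly one planted photosynthesis gene cluster built
from two arms — arm B holds the conserved *bchFNBHLM-lhaA-puhABC* block
(B1) together with *bchIDO/bchOP*, *bchG*, the clade's regulators and the
*puh* tail; arm A holds the *crt* run, the *crtF-bchCXYZ* block (B2) and
the *puf* operon — composed in the order and orientation that realizes the
requested arrangement type:

* I   — arm B ``+`` then arm A ``+``
* II  — arm B ``+`` then arm A reversed on ``-``
* III — arm A ``+`` then arm B ``+``
* IV  — arm B reversed on ``-`` then arm A ``+``

Clade templates encode the qualitative architecture differences between
the three AAP lineages (regulator complement, *hemA* vs *hemN*, the
displaced *ascF* next to a BLUF sensor in NOR5/OM60, *dxps* downstream of
*puf* in the Roseobacter clade, reduced *crt* sets with genes relocated
outside the cluster in Sphingomonadales), plus a Rhodobacter-like template
for the anaerobic Type-IV outgroups.  Decoy genes come from a fixed
housekeeping vocabulary that never collides with the catalog.

Gene lengths are drawn uniformly on 600–1500 bp and intergenic spacers on
20–200 bp; both are stand-ins for real distributions and configurable at
the layout level.  All randomness flows from the spec's seed, so equal
specs produce byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

from .catalog import default_catalog
from .carotenoids import CRT_SYMBOLS, CrtProfile, infer_pathway
from .errors import SpecValidationError, TruthSchemaError
from .genomeio import AnnotatedReplicon, GeneFeature

CLADE_TEMPLATES = ("roseobacter", "sphingomonadales", "nor5", "rhodobacter", "custom")

_TEMPLATES: dict[str, dict] = {
    "roseobacter": dict(
        puf="pufQBALMC",
        allowed_puf={"pufQBALMC", "pufQBALM"},
        crt_inside=("crtA", "crtI", "crtB", "crtK", "crtC", "crtD", "crtE"),
        crt_outside=(),
        regulators=("ppsR", "ppaA"),
        hem="hemA",
        dxps=True,
        bluf=False,
        bchEJ=False,
        pathway=("spheroidenone", None),
    ),
    "sphingomonadales": dict(
        puf="pufBALM",
        allowed_puf={"pufBALM"},
        crt_inside=("crtC", "crtD"),
        crt_outside=("crtI", "crtB", "crtE", "crtY", "crtZ"),
        regulators=("ppsR", "ppaA"),
        hem="hemA",
        dxps=False,
        bluf=False,
        bchEJ=False,
        pathway=("zeaxanthin", None),
    ),
    "nor5": dict(
        puf="pufLMCBA",
        allowed_puf={"pufLMCBA"},
        crt_inside=("crtI", "crtB", "crtC", "crtE"),
        crt_outside=("crtD",),
        regulators=("crtJ",),
        hem="hemN",
        dxps=False,
        bluf=True,
        bchEJ=True,
        pathway=("spirilloxanthin", None),  # subtype resolved from crtD placement
    ),
    "rhodobacter": dict(
        puf="pufQBALMX",
        allowed_puf={"pufQBALMX", "pufQBALMC"},
        crt_inside=("crtA", "crtI", "crtB", "crtK", "crtC", "crtD", "crtE"),
        crt_outside=(),
        regulators=("ppsR", "ppaA", "crtJ"),
        hem="hemA",
        dxps=False,
        bluf=False,
        bchEJ=True,
        pathway=("spheroidenone", None),
    ),
}

#: decoy vocabulary for background/intra-cluster non-photosynthesis genes.
DECOY_GENES = (
    "gyrA", "gyrB", "recA", "dnaA", "dnaK", "rpoB", "rpoC", "ftsZ",
    "secA", "rpsA", "rplB", "infB", "tufA", "groL", "uvrA", "polA",
)

MIN_GENOME_LENGTH = 200_000
RELOCATION_DISTANCE = 100_000  # minimum bp between cluster and relocated genes


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic genome with a planted cluster."""

    strain_id: str
    arrangement_type: str = "III"
    clade_template: str = "roseobacter"
    puf_type: str | None = None  # defaults to the template's operon
    crt_relocation: frozenset[str] | None = None  # crt genes placed outside; template default if None
    crt_absent: frozenset[str] = frozenset()
    gc_target: float = 0.60
    genome_length_bp: int = 1_000_000
    n_decoy_genes_inside: int = 3
    seed: int = 0
    emit_sequence: bool = False
    template_overrides: tuple = ()  # (key, value) pairs for clade_template="custom"

    def resolved_template(self) -> dict:
        if self.clade_template == "custom":
            cfg = dict(_TEMPLATES["roseobacter"])
            cfg.update(dict(self.template_overrides))
            return cfg
        return dict(_TEMPLATES[self.clade_template])

    def validate(self) -> None:
        if self.arrangement_type not in ("I", "II", "III", "IV"):
            raise SpecValidationError(f"unknown arrangement type {self.arrangement_type!r}")
        if self.clade_template not in CLADE_TEMPLATES:
            raise SpecValidationError(f"unknown clade template {self.clade_template!r}")
        if not (0.2 < self.gc_target < 0.8):
            raise SpecValidationError(f"gc_target {self.gc_target} outside (0.2, 0.8)")
        if self.genome_length_bp < MIN_GENOME_LENGTH:
            raise SpecValidationError(f"genome_length_bp must be >= {MIN_GENOME_LENGTH}")
        cfg = self.resolved_template()
        puf = self.puf_type or cfg["puf"]
        if self.clade_template != "custom" and puf not in cfg["allowed_puf"]:
            raise SpecValidationError(
                f"puf operon {puf!r} is inconsistent with the {self.clade_template!r} "
                f"template (allowed: {sorted(cfg['allowed_puf'])})"
            )
        relocated = set(self.crt_relocation) if self.crt_relocation is not None else set(cfg["crt_outside"])
        if "crtF" in relocated:
            raise SpecValidationError("crtF belongs to the conserved crtF-bchCXYZ block and cannot be relocated")
        bad = {s for s in relocated | set(self.crt_absent) if s not in CRT_SYMBOLS}
        if bad:
            raise SpecValidationError(f"not crt genes: {sorted(bad)}")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth sufficient to score every pipeline output."""

    strain_id: str
    seed: int
    arrangement_type: str
    puf_label: str
    pgc_start: int
    pgc_end: int
    b1_strand: str
    b2_strand: str
    cluster_gene_order: tuple[str, ...]
    crt_statuses: dict[str, str]
    pathway: str
    pathway_subtype: str | None
    gc_target: float | None


TRUTH_FIELDS = tuple(TruthRecord.__dataclass_fields__)


def write_truth(truth: TruthRecord) -> str:
    """Serialize a truth record to its JSON document form."""
    doc = asdict(truth)
    doc["cluster_gene_order"] = list(doc["cluster_gene_order"])
    return json.dumps(doc, indent=2, sort_keys=True)


def read_truth(text: str) -> TruthRecord:
    """Parse and schema-validate a truth JSON document."""
    doc = json.loads(text)
    missing = [f for f in TRUTH_FIELDS if f not in doc]
    extra = [k for k in doc if k not in TRUTH_FIELDS]
    if missing or extra:
        raise TruthSchemaError(f"truth document: missing={missing} unexpected={extra}")
    if doc["arrangement_type"] not in ("I", "II", "III", "IV"):
        raise TruthSchemaError(f"invalid arrangement_type {doc['arrangement_type']!r}")
    if set(doc["crt_statuses"]) != set(CRT_SYMBOLS):
        raise TruthSchemaError("crt_statuses must cover every crt symbol")
    doc["cluster_gene_order"] = tuple(doc["cluster_gene_order"])
    return TruthRecord(**doc)


# ---------------------------------------------------------------------------
# layout machinery (shared with the shipped strain fixtures)


def arm_a_genes(
    crt_inside: Sequence[str],
    puf_genes: Sequence[str],
    *,
    bchEJ: bool = False,
    dxps: bool = False,
) -> list[str]:
    """Arm A: crt run, the crtF-bchCXYZ block and the puf operon."""
    genes: list[str] = []
    if bchEJ:
        genes += ["bchE", "bchJ"]
    genes += [g for g in crt_inside if g != "crtF"]
    genes += ["crtF", "bchC", "bchX", "bchY", "bchZ"]
    genes += list(puf_genes)
    if dxps:
        genes.append("dxps")
    return genes


def arm_b_genes(
    regulators: Sequence[str],
    hem: str,
    *,
    bluf: bool = False,
    tail_hyp: bool = True,
) -> list[str]:
    """Arm B: bchIDO/bchOP run, regulators, the B1 block and the puh tail.

    The regulator slot sits between *bchOP* and *bchFNBHLM*.  In the NOR5
    style (``bluf=True``) the cluster opens with a BLUF sensor and the
    displaced *ascF*, and the puh tail is just *puhE* + *hemN*; otherwise
    the conserved *puhABC-hyp-ascF-puhE* tail is laid down, followed by
    *hemA*.
    """
    genes: list[str] = []
    if bluf:
        genes += ["bluf", "ascF"]
    genes += ["bchI", "bchD", "bchO", "bchP", "bchG"]
    genes += list(regulators)
    genes += ["bchF", "bchN", "bchB", "bchH", "bchL", "bchM", "lhaA", "puhA", "puhB", "puhC"]
    if bluf:
        genes += ["puhE", hem]
    else:
        if tail_hyp:
            genes.append("hyp")
        genes += ["ascF", "puhE", hem]
    return genes


def assemble_cluster(
    arm_a: Sequence[str],
    arm_b: Sequence[str],
    arrangement_type: str,
    between: Sequence[str] = (),
) -> list[tuple[str, str]]:
    """Order and orient the two arms to realize an arrangement type.

    Returns (label, strand) pairs in genome order; ``between`` genes land
    at the arm junction.
    """
    fwd = lambda genes: [(g, "+") for g in genes]
    rev = lambda genes: [(g, "-") for g in reversed(genes)]
    mid = fwd(between)
    if arrangement_type == "I":
        return fwd(arm_b) + mid + fwd(arm_a)
    if arrangement_type == "II":
        return fwd(arm_b) + mid + rev(arm_a)
    if arrangement_type == "III":
        return fwd(arm_a) + mid + fwd(arm_b)
    if arrangement_type == "IV":
        return rev(arm_b) + mid + fwd(arm_a)
    raise SpecValidationError(f"unknown arrangement type {arrangement_type!r}")


def layout_features(
    layout: Sequence[tuple[str, str]],
    start: int,
    replicon_id: str,
    rng: np.random.Generator,
    *,
    gene_length=(600, 1500),
    spacer=(20, 200),
    target_span: int | None = None,
) -> list[GeneFeature]:
    """Place (label, strand) pairs on the genome from ``start`` onward.

    Gene lengths and intergenic spacers are drawn uniformly from the given
    ranges.  When ``target_span`` is set, spacers are instead computed so
    the first-gene-start to last-gene-end distance equals it exactly
    (shipped fixtures pin cluster sizes to published values this way).
    """
    catalog = default_catalog()
    n = len(layout)
    lengths = [int(rng.integers(gene_length[0], gene_length[1] + 1)) for _ in range(n)]
    if target_span is None:
        gaps = [int(rng.integers(spacer[0], spacer[1] + 1)) for _ in range(n - 1)]
    else:
        slack = target_span - sum(lengths)
        if n == 1:
            lengths = [target_span]
            gaps = []
        else:
            base, rem = divmod(slack, n - 1)
            if base < 1:
                raise SpecValidationError(
                    f"target span {target_span} too small for {n} genes"
                )
            gaps = [base + (1 if i < rem else 0) for i in range(n - 1)]
    features = []
    pos = start
    for i, (label, strand) in enumerate(layout):
        end = pos + lengths[i]
        d = catalog.canonicalize(label)
        features.append(
            GeneFeature(
                label=label,
                symbol=getattr(d, "symbol", None),
                category=d.category,
                start=pos,
                end=end,
                strand=strand,
                replicon_id=replicon_id,
            )
        )
        pos = end + (gaps[i] if i < n - 1 else 0)
    return features


def synthesize_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random nucleotide string with the given expected GC fraction."""
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("GCAT"), size=length, p=p))


# ---------------------------------------------------------------------------
# generation


def generate_genome(spec: SimulationSpec) -> tuple[AnnotatedReplicon, TruthRecord]:
    """Generate one annotated replicon with a planted PGC and its truth."""
    spec.validate()
    cfg = spec.resolved_template()
    rng = np.random.default_rng(spec.seed)
    catalog = default_catalog()
    L = spec.genome_length_bp

    puf_label = spec.puf_type or cfg["puf"]
    puf_genes = catalog.expand_gene_string(puf_label)

    complement = set(cfg["crt_inside"]) | set(cfg["crt_outside"])
    relocated = set(spec.crt_relocation) if spec.crt_relocation is not None else set(cfg["crt_outside"])
    complement |= relocated
    complement -= set(spec.crt_absent)
    relocated = (relocated - set(spec.crt_absent)) & complement
    crt_inside = [g for g in cfg["crt_inside"] if g in complement and g not in relocated]
    crt_outside = sorted(relocated)

    arm_a = arm_a_genes(crt_inside, puf_genes, bchEJ=cfg["bchEJ"], dxps=cfg["dxps"])
    arm_b = arm_b_genes(cfg["regulators"], cfg["hem"], bluf=cfg["bluf"])
    layout = assemble_cluster(arm_a, arm_b, spec.arrangement_type)

    # interior decoys: one per inter-gene slot at most, so block detection
    # (which tolerates a bounded number of insertions per gap) is unaffected
    n_decoy = min(spec.n_decoy_genes_inside, len(layout) - 1)
    if n_decoy:
        slots = sorted(rng.choice(np.arange(1, len(layout)), size=n_decoy, replace=False), reverse=True)
        for i, slot in enumerate(slots):
            strand = layout[slot - 1][1]
            layout.insert(int(slot), (f"hyp{i + 1}", strand))

    cluster_start = int(rng.integers(int(0.04 * L), int(0.10 * L)))
    features = layout_features(layout, cluster_start, spec.strain_id, rng)
    pgc_start, pgc_end = features[0].start, features[-1].end

    # relocated crt genes near the far end of the replicon
    outside_feats = []
    for i, sym in enumerate(crt_outside):
        gene_start = L - (i + 1) * 3_000
        d = catalog.lookup(sym)
        outside_feats.append(
            GeneFeature(
                label=sym, symbol=sym, category=d.category,
                start=gene_start, end=gene_start + 900,
                strand="+" if rng.integers(2) else "-",
                replicon_id=spec.strain_id,
            )
        )
    if outside_feats and min(f.start for f in outside_feats) - pgc_end < RELOCATION_DISTANCE:
        raise SpecValidationError(
            "genome too short to keep relocated crt genes "
            f">= {RELOCATION_DISTANCE} bp from the cluster"
        )

    # background housekeeping decoys away from the cluster and relocated genes
    background = []
    occupied = [(pgc_start - 5_000, pgc_end + 5_000)] + [
        (f.start - 2_000, f.end + 2_000) for f in outside_feats
    ]
    pos = 10_000
    vi = 0
    while pos + 1_000 < L:
        if not any(lo <= pos <= hi for lo, hi in occupied):
            background.append(
                GeneFeature(
                    label=DECOY_GENES[vi % len(DECOY_GENES)],
                    symbol=None, category="other",
                    start=pos, end=pos + 900,
                    strand="+" if rng.integers(2) else "-",
                    replicon_id=spec.strain_id,
                )
            )
            vi += 1
        pos += int(rng.integers(20_000, 40_001))

    sequence = synthesize_sequence(L, spec.gc_target, rng) if spec.emit_sequence else None
    replicon = AnnotatedReplicon(
        id=spec.strain_id,
        length_bp=L,
        features=features + outside_feats + background,
        sequence=sequence,
        supplied_gc=None if spec.emit_sequence else spec.gc_target,
    )

    statuses = {}
    for sym in CRT_SYMBOLS:
        if sym in {f.symbol for f in features}:
            statuses[sym] = "in_pgc"
        elif sym in crt_outside:
            statuses[sym] = "outside"
        else:
            statuses[sym] = "absent"

    pathway, subtype = _planted_pathway(spec, cfg, statuses)
    b1_strand = {"I": "+", "II": "+", "III": "+", "IV": "-"}[spec.arrangement_type]
    b2_strand = {"I": "+", "II": "-", "III": "+", "IV": "+"}[spec.arrangement_type]
    truth = TruthRecord(
        strain_id=spec.strain_id,
        seed=spec.seed,
        arrangement_type=spec.arrangement_type,
        puf_label=puf_label if puf_label in ("pufQBALMC", "pufQBALM", "pufBALM", "pufLMCBA") else "novel",
        pgc_start=pgc_start,
        pgc_end=pgc_end,
        b1_strand=b1_strand,
        b2_strand=b2_strand,
        cluster_gene_order=tuple(label for label, _ in layout),
        crt_statuses=statuses,
        pathway=pathway,
        pathway_subtype=subtype,
        gc_target=spec.gc_target,
    )
    return replicon, truth


def _planted_pathway(spec, cfg, statuses) -> tuple[str, str | None]:
    """The pathway the planted crt complement encodes, per clade template."""
    if spec.clade_template == "custom":
        call = infer_pathway(CrtProfile(strain_id=spec.strain_id, statuses=statuses))
        return call.pathway, call.subtype
    pathway, subtype = cfg["pathway"]
    if pathway == "spirilloxanthin":
        subtype = "typical" if statuses.get("crtD") == "in_pgc" else "unusual"
    if pathway == "zeaxanthin":
        subtype = "ketolase_extension" if statuses.get("crtW", "absent") != "absent" else None
    return pathway, subtype


def generate_cohort(specs: Iterable[SimulationSpec]) -> list[tuple[AnnotatedReplicon, TruthRecord]]:
    """Generate independent genomes for a list of specs."""
    specs = list(specs)
    if not specs:
        raise SpecValidationError("empty cohort")
    ids = [s.strain_id for s in specs]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise SpecValidationError(f"duplicate strain_id(s): {sorted(dupes)}")
    return [generate_genome(s) for s in specs]


def reference_cohort_specs(base_seed: int = 0, genome_length_bp: int = 1_000_000) -> list[SimulationSpec]:
    """Canned cohort emulating the twelve reference architectures: the ten
    AAP strains (arrangement types I×2, II×3, III×5) plus the two
    Rhodobacter Type-IV outgroups."""
    plan = [
        ("sim_OCh114", "I", "roseobacter", "pufQBALMC", None, ()),
        ("sim_Och149", "I", "roseobacter", "pufQBALMC", None, ()),
        ("sim_Roseovarius217", "II", "roseobacter", "pufQBALMC", None, ("crtK",)),
        ("sim_KT71", "II", "nor5", "pufLMCBA", None, ()),
        ("sim_HTCC2080", "II", "nor5", "pufLMCBA", None, ()),
        ("sim_DFL12", "III", "roseobacter", "pufQBALMC", None, ()),
        ("sim_CCS1", "III", "roseobacter", "pufQBALMC", None, ("crtK",)),
        ("sim_SKA53", "III", "roseobacter", "pufQBALM", None, ("crtK",)),
        ("sim_NAP1", "III", "sphingomonadales", "pufBALM", None, ()),
        ("sim_JL354", "III", "sphingomonadales", "pufBALM",
         frozenset({"crtI", "crtB", "crtE", "crtY", "crtZ", "crtW"}), ("crtD",)),
        ("sim_Rsphaeroides", "IV", "rhodobacter", "pufQBALMX", None, ("crtJ",)),
        ("sim_Rcapsulatus", "IV", "rhodobacter", "pufQBALMX", None, ()),
    ]
    return [
        SimulationSpec(
            strain_id=sid,
            arrangement_type=arr,
            clade_template=clade,
            puf_type=puf,
            crt_relocation=reloc,
            crt_absent=frozenset(absent),
            genome_length_bp=genome_length_bp,
            seed=base_seed + i,
        )
        for i, (sid, arr, clade, puf, reloc, absent) in enumerate(plan)
    ]
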