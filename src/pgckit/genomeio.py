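"""Annotated-replicon containers and GenBank / gene-table I/O.

Internally every interval is 0-based half-open and sorted by start; both
file dialects (GenBank flat files via Biopython, and the gene-table TSV
used for shipped strain fixtures) are 1-based inclusive on disk and are
converted on read/write.  Replicons may carry their nucleotide sequence
(GC is then computed) or only a supplied GC fraction (annotation-only
mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from io import StringIO
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import gc_fraction as _bio_gc_fraction

from .catalog import GeneCatalog, UnknownGene, default_catalog
from .errors import FormatError, RangeError, UndefinedGCError

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["replicon_id", "gene", "start", "end", "strand"]
OPTIONAL_COLUMNS = ["replicon_length", "gc_percent"]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a replicon (0-based, half-open)."""

    label: str
    symbol: str | None  # canonical symbol, or None for unknown genes
    category: str
    start: int
    end: int
    strand: str
    replicon_id: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise RangeError(f"{self.label}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise RangeError(f"{self.label}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    @property
    def is_photosynthetic(self) -> bool:
        return self.category != "other"


@dataclass
class AnnotatedReplicon:
    """An annotated contig/chromosome/plasmid."""

    id: str
    length_bp: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: str | None = None
    supplied_gc: float | None = None  # used when no sequence is carried

    def __post_init__(self):
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.label))
        for f in self.features:
            if f.end > self.length_bp:
                raise RangeError(
                    f"feature {f.label} [{f.start},{f.end}) exceeds replicon "
                    f"length {self.length_bp}"
                )
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise FormatError(
                f"replicon {self.id}: sequence length {len(self.sequence)} != "
                f"declared length {self.length_bp}"
            )

    @property
    def gc(self) -> float | None:
        """GC fraction: computed from sequence when present, else supplied."""
        if self.sequence is not None:
            return gc_fraction(self.sequence)
        return self.supplied_gc

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotatedReplicon):
            return NotImplemented
        return (
            self.id == other.id
            and self.length_bp == other.length_bp
            and self.features == other.features
            and self.sequence == other.sequence
        )


# ---------------------------------------------------------------------------
# GC


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / (#A + #C + #G + #T); Ns are excluded from the denominator."""
    if not sequence:
        raise UndefinedGCError("GC fraction of an empty sequence is undefined")
    if set(sequence.upper()) <= {"N"}:
        raise UndefinedGCError("GC fraction of an all-N sequence is undefined")
    return _bio_gc_fraction(sequence, ambiguous="remove")


# ---------------------------------------------------------------------------
# reading


def _resolve(label: str, catalog: GeneCatalog) -> tuple[str | None, str]:
    d = catalog.canonicalize(label)
    if isinstance(d, UnknownGene):
        return None, "other"
    return d.symbol, d.category


def read_genbank(source: str | TextIO, catalog: GeneCatalog | None = None) -> list[AnnotatedReplicon]:
    """Read GenBank flat-file records into annotated replicons.

    Gene labels are canonicalized against the catalog; ``gene`` features
    are preferred, with ``CDS`` features adding any loci not already seen.
    Features without a usable location or label are skipped with a logged
    warning, never silently.
    """
    catalog = catalog or default_catalog()
    handle = StringIO(source) if isinstance(source, str) else source
    replicons = []
    try:
        records = list(SeqIO.parse(handle, "genbank"))
    except ValueError as exc:
        raise FormatError(f"malformed GenBank input: {exc}") from exc
    for rec in records:
        features = []
        seen: set[tuple[int, int, str, str]] = set()
        for ftype in ("gene", "CDS"):
            for feat in rec.features:
                if feat.type != ftype:
                    continue
                parsed = _parse_genbank_feature(rec.id, feat, catalog)
                if parsed is None:
                    continue
                key = (parsed.start, parsed.end, parsed.strand, parsed.label)
                if key in seen:
                    continue
                seen.add(key)
                features.append(parsed)
        try:
            seq = str(rec.seq)
        except Exception:  # undefined sequence
            seq = None
        replicons.append(
            AnnotatedReplicon(
                id=rec.id, length_bp=len(rec), features=features, sequence=seq or None
            )
        )
    return replicons


def _parse_genbank_feature(rec_id, feat, catalog) -> GeneFeature | None:
    quals = feat.qualifiers
    label = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or [None])[0]
    if label is None:
        logger.warning("%s: skipping %s feature at %s with no label", rec_id, feat.type, feat.location)
        return None
    if feat.location is None or feat.location.strand not in (1, -1):
        logger.warning("%s: skipping feature %s with unusable location", rec_id, label)
        return None
    if len(feat.location.parts) != 1:
        logger.warning("%s: skipping compound-location feature %s", rec_id, label)
        return None
    # keyword match on product description helps BLUF-domain sensors
    resolved = catalog.canonicalize(label)
    if isinstance(resolved, UnknownGene):
        product = (quals.get("product") or [""])[0]
        if product:
            resolved = catalog.canonicalize(f"{label} {product}") if "bluf" in product.lower() else resolved
    symbol = None if isinstance(resolved, UnknownGene) else resolved.symbol
    category = "other" if isinstance(resolved, UnknownGene) else resolved.category
    return GeneFeature(
        label=label,
        symbol=symbol,
        category=category,
        start=int(feat.location.start),
        end=int(feat.location.end),
        strand="+" if feat.location.strand == 1 else "-",
        replicon_id=rec_id,
    )


def read_gene_table(source: str | TextIO, catalog: GeneCatalog | None = None) -> list[AnnotatedReplicon]:
    """Read the gene-table TSV dialect (1-based inclusive coordinates).

    Required columns: replicon_id, gene, start, end, strand; optional:
    replicon_length, gc_percent.  One replicon per distinct replicon_id,
    in order of first appearance.
    """
    catalog = catalog or default_catalog()
    handle = StringIO(source) if isinstance(source, str) else source
    df = pd.read_csv(handle, sep="\t", dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"gene table missing required column(s): {', '.join(missing)}")
    replicons = []
    for rid, group in df.groupby("replicon_id", sort=False):
        features = []
        for idx, row in group.iterrows():
            try:
                start1, end1 = int(row["start"]), int(row["end"])
            except ValueError as exc:
                raise FormatError(f"row {idx + 2}: non-integer coordinates") from exc
            if end1 < start1:
                raise FormatError(f"row {idx + 2}: end {end1} < start {start1}")
            symbol, category = _resolve(str(row["gene"]), catalog)
            features.append(
                GeneFeature(
                    label=str(row["gene"]),
                    symbol=symbol,
                    category=category,
                    start=start1 - 1,
                    end=end1,
                    strand=str(row["strand"]),
                    replicon_id=str(rid),
                )
            )
        length = max((f.end for f in features), default=0)
        gc = None
        if "replicon_length" in group.columns:
            vals = group["replicon_length"].dropna()
            if len(vals):
                length = int(float(vals.iloc[0]))
        if "gc_percent" in group.columns:
            vals = group["gc_percent"].dropna()
            if len(vals):
                gc = float(vals.iloc[0]) / 100.0
        replicons.append(
            AnnotatedReplicon(id=str(rid), length_bp=length, features=features, supplied_gc=gc)
        )
    return replicons


# ---------------------------------------------------------------------------
# writing


def write_gene_table(replicons: Iterable[AnnotatedReplicon], handle: TextIO) -> None:
    """Write replicons in the gene-table TSV dialect (deterministic order)."""
    cols = TABLE_COLUMNS + OPTIONAL_COLUMNS
    handle.write("\t".join(cols) + "\n")
    for r in replicons:
        gc = "" if r.gc is None else f"{r.gc * 100:.4f}".rstrip("0").rstrip(".")
        for f in r.features:
            row = [r.id, f.label, str(f.start + 1), str(f.end), f.strand, str(r.length_bp), gc]
            handle.write("\t".join(row) + "\n")


def write_genbank(replicons: Iterable[AnnotatedReplicon], handle: TextIO, *, date: str = "20-SEP-2011") -> None:
    """Write replicons as GenBank flat files (requires sequences).

    The record date is fixed so output is byte-identical across runs.
    """
    records = []
    for r in replicons:
        if r.sequence is None:
            raise FormatError(
                f"replicon {r.id}: GenBank output requires a sequence "
                "(use the gene-table format for annotation-only replicons)"
            )
        rec = SeqRecord(Seq(r.sequence), id=r.id, name=r.id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "linear"
        rec.annotations["date"] = date
        for f in r.features:
            rec.features.append(
                SeqFeature(
                    SimpleLocation(f.start, f.end, strand=1 if f.strand == "+" else -1),
                    type="gene",
                    qualifiers={"gene": [f.label]},
                )
            )
        records.append(rec)
    SeqIO.write(records, handle, "genbank")


# ---------------------------------------------------------------------------
# region arithmetic


def extract_region(replicon: AnnotatedReplicon, start: int, end: int) -> AnnotatedReplicon:
    """Sub-replicon over [start, end); keeps only wholly contained features."""
    if not (0 <= start < end <= replicon.length_bp):
        raise RangeError(
            f"region [{start}, {end}) out of bounds for replicon of length {replicon.length_bp}"
        )
    features = [
        replace(f, start=f.start - start, end=f.end - start)
        for f in replicon.features
        if f.start >= start and f.end <= end
    ]
    seq = replicon.sequence[start:end] if replicon.sequence is not None else None
    return AnnotatedReplicon(
        id=replicon.id,
        length_bp=end - start,
        features=features,
        sequence=seq,
        supplied_gc=replicon.supplied_gc,
    )


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reflect_replicon(replicon: AnnotatedReplicon) -> AnnotatedReplicon:
    """Mirror a replicon end-to-end: x → length − x, strands flipped,
    sequence reverse-complemented.  An involution."""
    L = replicon.length_bp
    features = [
        replace(f, start=L - f.end, end=L - f.start, strand="+" if f.strand == "-" else "-")
        for f in replicon.features
    ]
    seq = replicon.sequence[::-1].translate(_COMPLEMENT) if replicon.sequence is not None else None
    return AnnotatedReplicon(
        id=replicon.id,
        length_bp=L,
        features=features,
        sequence=seq,
        supplied_gc=replicon.supplied_gc,
    )
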