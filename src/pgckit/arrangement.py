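"""Synteny-block detection, Type I–IV arrangement classification, *puf*
operon typing and the cross-strain core gene set.

Two conserved blocks anchor every intact PGC: B1 = *bchFNBHLM-lhaA-puhABC*
(~12–15 kb) and B2 = *crtF-bchCXYZ* (~10 kb, with the *puf* operon
attached).  Their relative order and orientation define four arrangement
types.  "Forward"/"reverse" in cluster drawings refers to the direction
genes are drawn, not an absolute genome strand — genome deposition strand
is arbitrary — so classification first normalizes by reflection until B1
reads '+', then keys on B2's strand and its position relative to B1:

=====  =========  ============
type   B2 strand  B2 position
=====  =========  ============
I      ``+``      downstream
II     ``-``      downstream
III    ``+``      upstream
IV     ``-``      upstream
=====  =========  ============

which makes the call invariant under whole-replicon reflection.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InputError
from .delineation import PGCRegion
from .genomeio import GeneFeature

#: ordered gene templates of the conserved regions.
BLOCK_TEMPLATES: dict[str, tuple[str, ...]] = {
    "B1": ("bchF", "bchN", "bchB", "bchH", "bchL", "bchM", "lhaA", "puhA", "puhB", "puhC"),
    "B2": ("crtF", "bchC", "bchX", "bchY", "bchZ"),
    "bchIDO": ("bchI", "bchD", "bchO"),
    "bchOP": ("bchO", "bchP"),
    "puh_tail": ("puhA", "puhB", "puhC", "ascF", "puhE"),
}

DEFAULT_MAX_INSERTIONS = 3
DEFAULT_MAX_MISSING = 2

#: the four recognized puf operon structures (suffix-letter order along the
#: coding strand).
PUF_OPERON_TYPES = ("pufQBALMC", "pufQBALM", "pufBALM", "pufLMCBA")

ARRANGEMENT_TYPES = ("I", "II", "III", "IV")

#: consensus strand must be shared by at least this fraction of matched genes.
STRAND_CONSENSUS_FLOOR = 0.8


@dataclass(frozen=True)
class SyntenyBlock:
    """An ordered template match on a consistent strand within a cluster."""

    template_name: str
    matched_genes: tuple[GeneFeature, ...]  # in genome order
    strand: str
    span: tuple[int, int]
    completeness: float

    @property
    def midpoint(self) -> float:
        return (self.span[0] + self.span[1]) / 2


@dataclass(frozen=True)
class ArrangementCall:
    type_label: str  # I, II, III, IV or "unclassified"
    b1: SyntenyBlock | None
    b2: SyntenyBlock | None
    normalized: bool = False  # whether reflection was applied before typing
    diagnostic: str = ""


@dataclass(frozen=True)
class PufOperonType:
    label: str  # one of PUF_OPERON_TYPES or "novel"
    genes_found: tuple[str, ...]  # symbols along the coding strand
    strand: str


# ---------------------------------------------------------------------------
# block detection


def find_block(
    pgc: PGCRegion,
    template: str | tuple[str, ...],
    max_insertions: int = DEFAULT_MAX_INSERTIONS,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> SyntenyBlock | None:
    """Locate the best ordered match of a block template in a cluster.

    Scans both orientations: genes must appear in template order along the
    consensus strand, with at most ``max_insertions`` non-matched genes
    between consecutive matches and at most ``max_missing`` template genes
    absent.  Returns ``None`` when no chain reaches the completeness floor
    ``1 - max_missing / len(template)``.
    """
    name = template if isinstance(template, str) else "custom"
    symbols = BLOCK_TEMPLATES[template] if isinstance(template, str) else tuple(template)
    floor = 1.0 - max_missing / len(symbols)

    best: SyntenyBlock | None = None
    for orientation in ("+", "-"):
        order = symbols if orientation == "+" else tuple(reversed(symbols))
        chain = _best_chain(pgc.genes, order, max_insertions)
        if not chain:
            continue
        completeness = len(chain) / len(symbols)
        if completeness < floor:
            continue
        strand = _consensus_strand(chain)
        if strand is None or strand != orientation:
            continue
        block = SyntenyBlock(
            template_name=name,
            matched_genes=tuple(chain),
            strand=strand,
            span=(chain[0].start, chain[-1].end),
            completeness=completeness,
        )
        if best is None or block.completeness > best.completeness:
            best = block
    return best


def _best_chain(
    genes: tuple[GeneFeature, ...], order: tuple[str, ...], max_insertions: int
) -> list[GeneFeature]:
    """Longest chain of genes matching ``order`` as a subsequence, with at
    most ``max_insertions`` genes between consecutive chain members."""
    n, k = len(genes), len(order)
    # best[j][t]: length of best chain ending with gene j matched to order[t]
    best = [[0] * k for _ in range(n)]
    back: dict[tuple[int, int], tuple[int, int]] = {}
    for j in range(n):
        for t in range(k):
            if genes[j].symbol != order[t]:
                continue
            best[j][t] = 1
            lo = max(0, j - max_insertions - 1)
            for jp in range(lo, j):
                for tp in range(t):
                    if best[jp][tp] and best[jp][tp] + 1 > best[j][t]:
                        best[j][t] = best[jp][tp] + 1
                        back[(j, t)] = (jp, tp)
    top, pos = 0, None
    for j in range(n):
        for t in range(k):
            if best[j][t] > top:
                top, pos = best[j][t], (j, t)
    chain: list[GeneFeature] = []
    while pos is not None:
        chain.append(genes[pos[0]])
        pos = back.get(pos)
    chain.reverse()
    return chain


def _consensus_strand(genes) -> str | None:
    plus = sum(1 for g in genes if g.strand == "+")
    frac = plus / len(genes)
    if frac >= STRAND_CONSENSUS_FLOOR:
        return "+"
    if 1 - frac >= STRAND_CONSENSUS_FLOOR:
        return "-"
    return None


# ---------------------------------------------------------------------------
# arrangement classification


def classify_arrangement(
    pgc: PGCRegion,
    max_insertions: int = DEFAULT_MAX_INSERTIONS,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> ArrangementCall:
    """Classify a cluster into arrangement Type I–IV.

    Finds B1 and B2; if B1 reads '-', the cluster is (virtually) reflected
    so B1 reads '+'; the type then follows from B2's normalized strand and
    position relative to B1's midpoint.  Missing blocks or interleaved
    block spans yield ``unclassified`` with a diagnostic.
    """
    b1 = find_block(pgc, "B1", max_insertions, max_missing)
    b2 = find_block(pgc, "B2", max_insertions, max_missing)
    if b1 is None or b2 is None:
        missing = [n for n, b in (("B1", b1), ("B2", b2)) if b is None]
        return ArrangementCall("unclassified", b1, b2, diagnostic=f"block(s) not found: {','.join(missing)}")
    if _spans_overlap(b1.span, b2.span):
        return ArrangementCall("unclassified", b1, b2, diagnostic="B1 and B2 spans overlap")

    normalized = b1.strand == "-"
    # reflection flips both the relative position and every strand
    b2_strand = b2.strand if not normalized else ("-" if b2.strand == "+" else "+")
    downstream = (b2.midpoint > b1.midpoint) != normalized
    label = {
        ("+", True): "I",
        ("-", True): "II",
        ("+", False): "III",
        ("-", False): "IV",
    }[(b2_strand, downstream)]
    return ArrangementCall(label, b1, b2, normalized=normalized)


def _spans_overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


# ---------------------------------------------------------------------------
# puf operon typing


def type_puf_operon(pgc: PGCRegion, max_gap_genes: int = 1) -> PufOperonType:
    """Read the *puf* operon along its coding strand and match the order
    against the four recognized structures.

    Contiguous puf-category genes (allowing up to ``max_gap_genes``
    non-puf genes between consecutive members) form the operon; the
    longest run wins.  Mixed strands within the run, or an order and
    membership not matching any recognized structure exactly, yield
    ``novel`` with the observed order.
    """
    runs: list[list[tuple[int, GeneFeature]]] = []
    for i, g in enumerate(pgc.genes):
        if g.category != "puf":
            continue
        if runs and i - runs[-1][-1][0] - 1 <= max_gap_genes:
            runs[-1].append((i, g))
        else:
            runs.append([(i, g)])
    if not runs:
        raise InputError(f"cluster at {pgc.replicon_id}:{pgc.start} contains no puf genes")
    run = [g for _, g in max(runs, key=len)]

    strands = {g.strand for g in run}
    if len(strands) > 1:
        return PufOperonType("novel", tuple(g.symbol for g in run), strand="+")
    strand = run[0].strand
    ordered = run if strand == "+" else list(reversed(run))
    symbols = tuple(g.symbol for g in ordered)
    observed = "puf" + "".join(s[3:] for s in symbols)
    label = observed if observed in PUF_OPERON_TYPES else "novel"
    return PufOperonType(label, symbols, strand=strand)


# ---------------------------------------------------------------------------
# core gene set


def core_gene_intersection(gene_sets: list[set[str]]) -> list[str]:
    """Exact intersection of per-strain PGC gene complements, sorted.

    Only genes inside the delineated clusters count (photosynthesis genes
    scattered elsewhere on the chromosome are excluded by construction of
    the input sets).
    """
    if len(gene_sets) < 2:
        raise InputError("core_gene_intersection requires at least two gene sets")
    core = set(gene_sets[0])
    for s in gene_sets[1:]:
        core &= set(s)
    return sorted(core)
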