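"""Carotenoid gene localization and biosynthetic-pathway inference.

Per strain, every *crt* gene is classed ``in_pgc`` (inside a delineated
cluster), ``outside`` (elsewhere in the genome) or ``absent``; the
per-clade localization matrix and a rule engine over those statuses then
assign one of three biosynthetic routes:

* **spheroidenone** — the Roseobacter-clade route; requires *crtA* plus
  *crtI/B/C/D/F* (the necessary set; *crtE* is expected but its absence is
  surfaced as a warning rather than a rule failure).
* **zeaxanthin** — the Sphingomonadales route via lycopene cyclase
  (*crtY*) and β-carotene hydroxylase (*crtZ*), typically encoded outside
  the PGC; a *crtW* ketolase flags a possible keto-carotenoid extension.
* **spirilloxanthin** — the NOR5/OM60 route (*crtI/B/C/E/F*, no
  *crtA/Y/Z*); when *crtD* lies outside the PGC the shorter "unusual"
  variant is inferred, a tentative call.

*crtK* participates in no known pathway and never influences a call;
*crtJ* is a transcriptional regulator and is likewise never required.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .delineation import PGCRegion
from .genomeio import AnnotatedReplicon

#: all crt symbols tracked in a profile.
CRT_SYMBOLS = (
    "crtA", "crtI", "crtB", "crtC", "crtD", "crtE",
    "crtF", "crtJ", "crtY", "crtZ", "crtW", "crtK",
)

#: display order of the localization matrix; crtK is excluded because it
#: participates in no known carotenoid pathway.
MATRIX_ROWS = ("crtA", "crtI", "crtB", "crtC", "crtD", "crtE", "crtF", "crtJ", "crtY", "crtZ", "crtW")

IN_PGC, OUTSIDE, ABSENT = "in_pgc", "outside", "absent"

SPHEROIDENONE_REQUIRED = ("crtA", "crtI", "crtB", "crtC", "crtD", "crtF")
ZEAXANTHIN_REQUIRED = ("crtY", "crtZ")
SPIRILLOXANTHIN_REQUIRED = ("crtI", "crtB", "crtC", "crtE", "crtF")


@dataclass(frozen=True)
class CrtProfile:
    """Localization status of every crt gene in one strain."""

    strain_id: str
    statuses: dict[str, str]

    def __post_init__(self):
        missing = [s for s in CRT_SYMBOLS if s not in self.statuses]
        extra = [s for s in self.statuses if s not in CRT_SYMBOLS]
        if missing or extra:
            raise ValueError(f"profile must cover exactly {CRT_SYMBOLS}; missing={missing} extra={extra}")

    def present(self, symbol: str) -> bool:
        return self.statuses[symbol] != ABSENT

    def status(self, symbol: str) -> str:
        return self.statuses[symbol]


@dataclass(frozen=True)
class PathwayCall:
    pathway: str  # spheroidenone | zeaxanthin | spirilloxanthin | undetermined
    subtype: str | None  # typical/unusual for spirilloxanthin; ketolase_extension flag
    required_present: tuple[str, ...]
    missing: tuple[str, ...]
    completeness: float
    tentative: bool = False
    warnings: tuple[str, ...] = field(default_factory=tuple)


def crt_status_matrix(
    replicons: Sequence[AnnotatedReplicon],
    pgc_regions: Sequence[PGCRegion],
    strain_id: str = "",
) -> CrtProfile:
    """Classify every crt gene of a strain as in_pgc / outside / absent.

    ``replicons`` are all replicons of the strain (chromosome plus any
    plasmids); ``pgc_regions`` the accepted clusters across them.
    """
    in_pgc = {g.symbol for r in pgc_regions for g in r.genes if g.symbol}
    anywhere = {f.symbol for rep in replicons for f in rep.features if f.symbol}
    statuses = {}
    for sym in CRT_SYMBOLS:
        if sym in in_pgc:
            statuses[sym] = IN_PGC
        elif sym in anywhere:
            statuses[sym] = OUTSIDE
        else:
            statuses[sym] = ABSENT
    return CrtProfile(strain_id=strain_id or (replicons[0].id if replicons else ""), statuses=statuses)


def infer_pathway(profile: CrtProfile) -> PathwayCall:
    """Apply the pathway rules, in order of precedence; exactly one fires.

    Presence anywhere in the genome satisfies a rule; only the
    typical/unusual spirilloxanthin discriminator keys on *crtD*'s
    localization, and that subtype is flagged tentative.
    """
    # R1: spheroidenone
    if all(profile.present(s) for s in SPHEROIDENONE_REQUIRED):
        warnings = ()
        if not profile.present("crtE"):
            warnings = ("crtE absent: GGPP synthase expected alongside the spheroidenone set",)
        return PathwayCall(
            pathway="spheroidenone",
            subtype=None,
            required_present=SPHEROIDENONE_REQUIRED,
            missing=(),
            completeness=1.0,
            warnings=warnings,
        )
    # R2: zeaxanthin branch
    if all(profile.present(s) for s in ZEAXANTHIN_REQUIRED):
        subtype = "ketolase_extension" if profile.present("crtW") else None
        return PathwayCall(
            pathway="zeaxanthin",
            subtype=subtype,
            required_present=ZEAXANTHIN_REQUIRED,
            missing=(),
            completeness=1.0,
        )
    # R3: spirilloxanthin
    if all(profile.present(s) for s in SPIRILLOXANTHIN_REQUIRED) and not any(
        profile.present(s) for s in ("crtA", "crtY", "crtZ")
    ):
        typical = profile.status("crtD") == IN_PGC
        return PathwayCall(
            pathway="spirilloxanthin",
            subtype="typical" if typical else "unusual",
            required_present=SPIRILLOXANTHIN_REQUIRED,
            missing=(),
            completeness=1.0,
            tentative=not typical,
        )
    # R4: undetermined
    considered = sorted(set(SPHEROIDENONE_REQUIRED + ZEAXANTHIN_REQUIRED + SPIRILLOXANTHIN_REQUIRED) | {"crtE"})
    missing = tuple(s for s in considered if not profile.present(s))
    present = tuple(s for s in considered if profile.present(s))
    return PathwayCall(
        pathway="undetermined",
        subtype=None,
        required_present=present,
        missing=missing,
        completeness=0.0,
    )


# ---------------------------------------------------------------------------
# clade matrix rendering

_STATUS_GLYPH = {IN_PGC: "•", OUTSIDE: "○", ABSENT: ""}
_STATUS_RANK = {IN_PGC: 0, OUTSIDE: 1, ABSENT: 2}


def clade_matrix(
    profiles: Iterable[CrtProfile],
    clade_assignment: dict[str, str],
    column_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Aggregate per-strain profiles into a per-clade localization matrix.

    Rows are crt genes (crtK excluded), columns clades.  When members of a
    clade disagree, the most localized status wins (in_pgc > outside >
    absent) — a gene found in the PGC of any member is reported for the
    clade.
    """
    by_clade: dict[str, list[CrtProfile]] = {}
    for p in profiles:
        clade = clade_assignment.get(p.strain_id, p.strain_id)
        by_clade.setdefault(clade, []).append(p)
    columns = list(column_order) if column_order else sorted(by_clade)
    data = {}
    for clade in columns:
        members = by_clade.get(clade, [])
        col = {}
        for sym in MATRIX_ROWS:
            statuses = [m.status(sym) for m in members] or [ABSENT]
            col[sym] = min(statuses, key=_STATUS_RANK.__getitem__)
        data[clade] = col
    return pd.DataFrame(data, index=list(MATRIX_ROWS))


def render_matrix_text(matrix: pd.DataFrame) -> str:
    """Text rendering with the conventional glyphs (• in PGC, ○ outside)."""
    glyphs = matrix.map(lambda s: _STATUS_GLYPH.get(s, s))
    return glyphs.to_string()
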