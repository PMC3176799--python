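"""Deterministic linear gene-map SVGs (one arrow per gene).

Arrow direction encodes strand; fill colour encodes catalog category,
following the conventional cluster-figure palette (bch green, puf red,
puh pink, crt orange, regulators dark red, lhaA yellow, precursors blue,
unknown grey).
"""

from __future__ import annotations

from xml.sax.saxutils import escape

from .arrangement import ArrangementCall
from .delineation import PGCRegion

CATEGORY_COLORS = {
    "bch": "#2e8b57",
    "puf": "#d7301f",
    "puh": "#f4a6c8",
    "crt": "#f97b00",
    "regulatory": "#8b1a1a",
    "assembly": "#f5d327",
    "precursor": "#3a6ea5",
    "other": "#c8c8c8",
}

_H = 120          # canvas height
_TRACK_Y = 60     # arrow baseline
_ARROW_H = 22
_HEAD_FRAC = 0.35


def render_gene_map(
    pgc: PGCRegion,
    arrangement: ArrangementCall | None = None,
    width: int = 1200,
) -> str:
    """Render a cluster as an SVG document string."""
    span = pgc.end - pgc.start
    scale = (width - 40) / span

    def x(coord: int) -> float:
        return 20 + (coord - pgc.start) * scale

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{_H}" '
        f'viewBox="0 0 {width} {_H}">',
        f'<line x1="20" y1="{_TRACK_Y}" x2="{width - 20}" y2="{_TRACK_Y}" '
        'stroke="#555" stroke-width="1"/>',
    ]
    title = f"{pgc.replicon_id}:{pgc.start + 1}-{pgc.end} ({pgc.size_kb:.1f} kb)"
    if arrangement is not None:
        title += f" type {arrangement.type_label}"
    parts.append(f'<text x="20" y="18" font-size="12" font-family="sans-serif">{escape(title)}</text>')
    for g in pgc.genes:
        parts.append(_arrow(x(g.start), x(g.end), g.strand, CATEGORY_COLORS.get(g.category, "#c8c8c8"), g.label))
    parts.append("</svg>")
    return "\n".join(parts) + "\n"


def _arrow(x0: float, x1: float, strand: str, color: str, label: str) -> str:
    y, h = _TRACK_Y, _ARROW_H / 2
    w = x1 - x0
    head = min(w * _HEAD_FRAC, 8.0)
    if strand == "+":
        pts = [(x0, y - h), (x1 - head, y - h), (x1, y), (x1 - head, y + h), (x0, y + h)]
    else:
        pts = [(x1, y - h), (x0 + head, y - h), (x0, y), (x0 + head, y + h), (x1, y + h)]
    points = " ".join(f"{px:.2f},{py:.2f}" for px, py in pts)
    return (
        f'<polygon class="gene" points="{points}" fill="{color}" stroke="#333" '
        f'stroke-width="0.5"><title>{escape(label)}</title></polygon>'
    )
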