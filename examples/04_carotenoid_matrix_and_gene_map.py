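"""Render the carotenoid localization matrix and an SVG gene map.

The matrix mirrors the conventional published layout: rows are crt genes,
columns are clades, • marks a gene inside the PGC and ○ a gene elsewhere
in the genome.  The SVG draws the D. shibae cluster with one arrow per
gene (direction = strand, colour = gene family).
"""

from pathlib import Path

import pgckit
from pgckit import fixtures
from pgckit.carotenoids import clade_matrix, render_matrix_text

meta = fixtures.strain_metadata()
profiles = {
    sid: pgckit.profile_strain([rep], strain_id=sid)
    for sid, rep in fixtures.load_all(include_outgroups=True).items()
}

matrix = clade_matrix(
    [p.crt for p in profiles.values()],
    {sid: meta[sid]["matrix_clade"] for sid in profiles},
    column_order=("Roseobacter clade", "Rhodobacter", "Erythrobacter NAP1",
                  "Citromicrobium JL354", "NOR5"),
)
print(render_matrix_text(matrix))

prof = profiles["DFL12"]
svg = pgckit.render_gene_map(prof.main_region, prof.arrangement)
out = Path("dfl12_cluster.svg")
out.write_text(svg)
print(f"\nwrote {out} ({svg.count('<polygon')} gene arrows, "
      f"type {prof.arrangement.type_label} cluster)")
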