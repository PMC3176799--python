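"""Profile the twelve shipped reference strains and print the summary table.

Each strain's replicon is delineated into its photosynthesis gene cluster
(PGC); the table shows genome and cluster size (kb), GC percentages, the
cluster's share of the genome, the arrangement type (from the order and
orientation of the conserved bchFNBHLM-lhaA-puhABC and crtF-bchCXYZ
blocks), the puf operon structure and the inferred carotenoid pathway.
"""

import pgckit
from pgckit import fixtures

meta = fixtures.strain_metadata()
print(f"{'strain':16s} {'genome_kb':>9s} {'pgc_kb':>7s} {'gc':>3s} {'pgc_gc':>6s} "
      f"{'ratio%':>6s} {'type':>4s} {'puf':10s} pathway")
for sid, replicon in fixtures.load_all(include_outgroups=True).items():
    m = meta[sid]
    prof = pgckit.profile_strain(
        [replicon], strain_id=sid,
        genome_gc_percent=m["genome_gc_percent"], pgc_gc_percent=m["pgc_gc_percent"],
    )
    row = prof.stats.as_table_row()
    subtype = f" ({prof.pathway.subtype})" if prof.pathway.subtype else ""
    print(f"{sid:16s} {row['genome_kb']:9.1f} {row['pgc_kb']:7.1f} {row['genome_gc']:3d} "
          f"{row['pgc_gc']:6d} {row['ratio_percent']:6.2f} {prof.arrangement.type_label:>4s} "
          f"{prof.puf.label:10s} {prof.pathway.pathway}{subtype}")
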