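"""Cross-strain comparison: the core gene set and cohort tallies.

Intersecting the cluster gene complements of the ten AAP strains yields
the genes every PGC carries — dominated by bacteriochlorophyll-synthesis
(bch) genes, plus the reaction-centre/LH1 structural genes, assembly
factors and just two carotenoid genes.  The tallies count arrangement
types, puf operon structures and carotenoid pathways across the cohort.
"""

import pgckit
from pgckit import fixtures

profiles = [
    pgckit.profile_strain([rep], strain_id=sid)
    for sid, rep in fixtures.load_all(include_outgroups=False).items()
]
report = pgckit.compare_cohort(profiles)

print(f"core gene set across {report['n_strains']} strains: {report['core_size']} genes")
print("  " + " ".join(report["core_genes"]))
print("arrangement types:", report["arrangement_tally"])
print("puf operon types: ", report["puf_tally"])
print("pathways:         ", report["pathway_tally"])
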