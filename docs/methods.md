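# Methods

## Scope and model

pgckit analyses the **photosynthesis gene cluster (PGC)** of aerobic
anoxygenic phototrophic (AAP) bacteria: a contiguous genomic region of
roughly 39–48 kb that concentrates the genes for bacteriochlorophyll *a*
biosynthesis (*bch*), the reaction centre and LH1 antenna (*puf*, *puh*),
carotenoid biosynthesis (*crt*), the LH1 assembly factor *lhaA* and a
small set of regulators (*ppsR*, *ppaA*, *crtJ*, BLUF-domain sensors).
The pipeline is annotation-driven: genes are identified by their
annotation labels against a synonym-aware catalog, never by sequence
similarity.  That keeps every step deterministic and auditable, at the
cost of inheriting whatever the annotation got wrong — a mislabeled gene
is an unknown gene to pgckit.

The pipeline stages are:

1. **Delineation.**  Photosynthesis-tagged genes (any catalog category
   except `other`) are chained greedily: consecutive tagged genes join one
   chain when separated by at most `max_gap_kb` kilobases **and** at most
   `max_intervening` untagged genes.  Chains with at least
   `min_photo_genes` tagged members become PGC regions spanning
   first-gene start to last-gene end; everything inside the span
   (hypothetical proteins included) is a member.  Tagged genes in no
   accepted region are reported as *outside* — these are real biology
   (isolated *crtY/crtZ* and similar) and feed the carotenoid matrix.
2. **Arrangement typing.**  Two conserved blocks anchor intact clusters:
   B1 = *bchFNBHLM-lhaA-puhABC* and B2 = *crtF-bchCXYZ* (with the *puf*
   operon attached to B2).  Each block is located by a small dynamic
   program that finds the longest in-order chain of template genes on a
   consistent strand, tolerating `max_insertions` interlopers between
   consecutive matches and `max_missing` absent template genes.  Because
   the deposition strand of a genome is arbitrary, the cluster is
   (virtually) reflected until B1 reads `+`; the arrangement type then
   follows from B2's normalized strand and position: downstream `+` → I,
   downstream `-` → II, upstream `+` → III, upstream `-` → IV.  This
   makes classification provably invariant under whole-replicon
   reflection, which the tests exercise directly.
3. ***puf* typing.**  Contiguous puf-category genes (at most one
   intervening gene) are read along their coding strand and matched
   *exactly* against the four recognized structures (pufQBALMC, pufQBALM,
   pufBALM, pufLMCBA); anything else — including the *pufX*-carrying
   Rhodobacter operon — is reported as `novel` with its observed order.
4. **Core gene set.**  Exact set intersection of per-strain cluster
   complements, over canonical catalog symbols only; hypothetical or
   unrecognized genes never enter the sets, so two strains sharing the
   label "hyp" do not fabricate a core gene.
5. **Carotenoid analysis.**  Every *crt* gene is classed `in_pgc` /
   `outside` / `absent` per strain; a three-rule precedence engine then
   assigns the pathway: spheroidenone (*crtA* + *crtIBCDF* present
   anywhere), else zeaxanthin (*crtY* + *crtZ*; *crtW* flags a ketolase
   extension), else spirilloxanthin (*crtIBCEF* present, *crtA/Y/Z*
   absent; *crtD* outside the cluster selects the shorter "unusual"
   variant, flagged tentative).  *crtE* is expected alongside the
   spheroidenone set but its absence only warns: the necessary-gene set
   for that route is *crtAIBCDF*.  *crtK* and *crtJ* never influence a
   call.

## Parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `max_gap_kb` | 5 | kb | larger than any intra-cluster intergenic gap observed in the reference architectures, far smaller than the distance to scattered *crt* genes |
| `max_intervening` | 8 | genes | tolerates hypothetical-gene runs and the plasmid-anchor (*RPA*) pair inside clusters |
| `min_photo_genes` | 20 | genes | intact clusters carry ~35–45 tagged genes; isolated *crt* pairs stay far below |
| `max_insertions` | 3 | genes | per inter-match gap during block detection |
| `max_missing` | 2 | genes | completeness floor 1 − 2/10 for B1, 1 − 2/5 for B2 |

The field has no operational definition of PGC boundaries; these
defaults are this package's choice, made so that each reference
architecture yields exactly one region while relocated *crt* genes stay
outside, and all are exposed on the CLI and API.

Rounding follows printed-table convention: half-up, sizes to one decimal
kilobase, GC to integer percent, cluster/genome ratios to two decimals.
Stored values keep full precision; `pgckit.rounding.round_half_up` is the
single chokepoint.

## Reference fixtures

The twelve shipped fixtures (ten AAP strains, two anaerobic *Rhodobacter*
outgroups) are synthetic reconstructions of each strain's published
cluster architecture, not the deposited annotations: gene content, block
order/orientation, *puf* structure and *crt* localization follow the
published descriptions, while individual gene lengths are drawn from a
per-strain seeded generator and intergenic spacers are solved so the
cluster span and replicon length equal the published kilobase values
exactly.  Published GC percentages travel as metadata because the
fixtures carry no nucleotide sequence.  One deliberate reconciliation:
the published localization table leaves *crtC*/*crtF* blank for
*Citromicrobium* JL354, which contradicts the same study's repeated
statement that those two genes (and the *crtF-bchCXYZ* block) occur in
**all** ten clusters and belong to the 27-gene core; the fixtures follow
the core-set statement and place both genes inside the JL354 cluster, and
the expected matrix used in tests carries those two cells accordingly.
Each strain is a single replicon even where the organism keeps its PGC on
a plasmid; multi-replicon strains are supported by the API (regions are
delineated per replicon) and covered by a synthetic test instead.

The outgroup genome/cluster sizes are plausible values for the two
*Rhodobacter* genomes; no statistic computed from them is asserted
anywhere — they exist to realize arrangement Type IV and the *crtJ*/
*pufX*-bearing architecture.

## Synthetic data

The simulator emulates an annotated bacterial replicon containing one
planted cluster: arm B (B1 + *bchIDO/bchOP* + regulators + *puh* tail)
and arm A (*crt* run + B2 + *puf*) are composed per arrangement type;
clade templates encode the lineage differences (regulator complement,
*hemA* vs *hemN*, NOR5's BLUF + displaced *ascF*, Roseobacter's *dxps*
downstream of *puf*, Sphingomonadales' reduced and partly relocated *crt*
set).  Gene lengths are uniform on 600–1500 bp and spacers on 20–200 bp —
a configurable stand-in, not an empirical intergenic model.  Interior
decoy genes are inserted at most one per inter-gene slot so planted
decoys can never exceed the per-gap insertion tolerance of block
detection.  Relocated *crt* genes are kept ≥ 100 kb from the cluster;
background genes come from a fixed housekeeping vocabulary disjoint from
the catalog.  Sequence emission is optional: with it, bases are drawn
i.i.d. at the target GC (so a 1 Mb sequence lands within ±0.01 of target
with overwhelming probability); without it, the target GC travels as
metadata and region GC is reported as unknown rather than guessed.

What passing the synthetic suite does **not** show: robustness to
mis-annotation, frame-shifted or split genes, compound GenBank locations
(skipped with a warning), degraded clusters below the completeness floor,
or realistic intergenic structure.  The generator plants exactly one
cluster per replicon; multi-cluster replicons are handled by the
delineator but only exercised synthetically.

Default problem sizes — 100 genomes of 300 kb (annotation-only) for the
recovery sweep and a single 1 Mb sequence-emitting genome for GC
calibration — keep the whole suite in a few seconds while the binomial
concentration at 1 Mb makes the ±0.01 GC check essentially exact.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open; both file dialects are
  1-based inclusive on disk.  Reflection maps x → L − x and is an exact
  involution on integers.
* Block position comparisons use span midpoints; interleaved or
  overlapping B1/B2 spans yield `unclassified` with a diagnostic rather
  than a guess.
* Strand consensus requires ≥ 80 % agreement among matched block genes.
* GC excludes N from the denominator; empty or all-N input is an error,
  not 0.
* Missing GC metadata produces `None` statistics fields, not a failure.
* Equal-length tie in puf-run selection takes the first run in genome
  order; mixed strands within a run yield `novel`.

## Known limitations

* Annotation-label identification only; no HMM/alignment fallback.
* The typical/unusual spirilloxanthin discriminator encodes only the
  *crtD*-localization criterion; the full step lists of the two variants
  are not modelled, hence the `tentative` flag.
* Terminal products beyond zeaxanthin (nostoxanthin, erythroxanthin
  sulfate) are annotations keyed to clade, not inferred — no genes are
  assigned to those hydroxylation steps.
* GFF3/EMBL input, LH2 cluster detection and any phylogenetic tree
  construction are out of scope.
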