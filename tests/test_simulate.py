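"""Synthetic-genome generator: determinism, validation, planted truth."""

from io import StringIO

import pytest

import pgckit
from pgckit.errors import SpecValidationError, TruthSchemaError
from pgckit.simulate import (
    SimulationSpec,
    generate_cohort,
    generate_genome,
    read_truth,
    reference_cohort_specs,
    write_truth,
)


def test_same_seed_gives_byte_identical_genbank():
    spec = SimulationSpec(strain_id="det", arrangement_type="II", clade_template="nor5",
                          genome_length_bp=250_000, emit_sequence=True, seed=7)
    outputs = []
    for _ in range(2):
        rep, _ = generate_genome(spec)
        buf = StringIO()
        pgckit.write_genbank([rep], buf)
        outputs.append(buf.getvalue())
    assert outputs[0] == outputs[1]


def test_different_seeds_differ():
    a, _ = generate_genome(SimulationSpec(strain_id="s", seed=1, genome_length_bp=250_000))
    b, _ = generate_genome(SimulationSpec(strain_id="s", seed=2, genome_length_bp=250_000))
    assert a.features != b.features


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(puf_type="pufQBALMC", clade_template="sphingomonadales"),  # lacks pufQ/pufC
        dict(gc_target=0.9),
        dict(genome_length_bp=50_000),
        dict(crt_relocation=frozenset({"crtF"})),  # conserved-block member
        dict(arrangement_type="V"),
        dict(crt_relocation=frozenset({"bchF"})),  # not a crt gene
    ],
)
def test_inconsistent_specs_rejected(kwargs):
    with pytest.raises(SpecValidationError):
        SimulationSpec(strain_id="bad", **kwargs).validate()


def test_gc_of_generated_sequence_hits_target():
    rep, _ = generate_genome(
        SimulationSpec(strain_id="gc", gc_target=0.60, genome_length_bp=1_000_000,
                       emit_sequence=True, seed=5)
    )
    assert abs(rep.gc - 0.60) < 0.01
    direct = (rep.sequence.count("G") + rep.sequence.count("C")) / len(rep.sequence)
    assert rep.gc == pytest.approx(direct)


def test_truth_json_roundtrip_and_schema():
    _, truth = generate_genome(SimulationSpec(strain_id="t", arrangement_type="IV",
                                              clade_template="rhodobacter", seed=9,
                                              genome_length_bp=250_000))
    assert truth.arrangement_type == "IV"
    doc = write_truth(truth)
    assert read_truth(doc) == truth
    import json
    broken = json.loads(doc)
    del broken["pgc_start"]
    with pytest.raises(TruthSchemaError):
        read_truth(json.dumps(broken))


def test_cohort_duplicate_ids_rejected():
    spec = SimulationSpec(strain_id="dup", genome_length_bp=250_000)
    with pytest.raises(SpecValidationError):
        generate_cohort([spec, spec])
    with pytest.raises(SpecValidationError):
        generate_cohort([])


def test_reference_cohort_realizes_published_type_multiset():
    specs = reference_cohort_specs(base_seed=3, genome_length_bp=300_000)
    assert len(specs) == 12
    types = sorted(s.arrangement_type for s in specs)
    assert types.count("I") == 2 and types.count("II") == 3
    assert types.count("III") == 5 and types.count("IV") == 2
    # the generated truths agree with the specs
    for rep, truth in generate_cohort(specs):
        assert truth.arrangement_type == next(
            s.arrangement_type for s in specs if s.strain_id == truth.strain_id
        )


def test_interior_decoys_do_not_change_the_arrangement_call():
    base = dict(strain_id="d", arrangement_type="I", clade_template="roseobacter",
                genome_length_bp=300_000, seed=21)
    for n_decoys in (0, 3, 8):
        rep, truth = generate_genome(SimulationSpec(n_decoy_genes_inside=n_decoys, **base))
        prof = pgckit.profile_strain([rep])
        assert prof.arrangement.type_label == truth.arrangement_type == "I"
        assert (prof.main_region.start, prof.main_region.end) == (truth.pgc_start, truth.pgc_end)


def test_full_pipeline_recovers_every_truth_field():
    for rep, truth in pgckit.generate_cohort(reference_cohort_specs(11, genome_length_bp=300_000)):
        prof = pgckit.profile_strain([rep])
        assert (prof.main_region.start, prof.main_region.end) == (truth.pgc_start, truth.pgc_end)
        assert prof.arrangement.type_label == truth.arrangement_type
        assert prof.puf.label == truth.puf_label
        assert dict(prof.crt.statuses) == truth.crt_statuses
        assert (prof.pathway.pathway, prof.pathway.subtype) == (truth.pathway, truth.pathway_subtype)
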