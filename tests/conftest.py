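import pytest

import pgckit
from pgckit import fixtures


@pytest.fixture(scope="session")
def catalog():
    return pgckit.default_catalog()


@pytest.fixture(scope="session")
def strain_metadata():
    return fixtures.strain_metadata()


@pytest.fixture(scope="session")
def strain_replicons():
    """All twelve shipped reference replicons, keyed by strain id."""
    return fixtures.load_all(include_outgroups=True)


@pytest.fixture(scope="session")
def strain_profiles(strain_replicons, strain_metadata):
    """Full pipeline output for every reference strain."""
    profiles = {}
    for sid, replicon in strain_replicons.items():
        meta = strain_metadata[sid]
        profiles[sid] = pgckit.profile_strain(
            [replicon],
            strain_id=sid,
            genome_gc_percent=meta["genome_gc_percent"],
            pgc_gc_percent=meta["pgc_gc_percent"],
        )
    return profiles


@pytest.fixture(scope="session")
def aap_profiles(strain_profiles):
    """Profiles of the ten AAP strains (outgroups excluded)."""
    return {sid: strain_profiles[sid] for sid in fixtures.AAP_STRAIN_IDS}
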