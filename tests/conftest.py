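import datetime as dt

import pytest

from barcodegap.markers import MarkerRegion
from barcodegap.records import (
    AccessionRecord,
    DistributionClass,
    GrowthForm,
    Source,
    SpeciesRecord,
    ThreatClass,
)
from barcodegap.simulate import SyntheticConfig, generate_bundle


def mk_species(binomial, family="Testaceae", order="Testales",
               threat="NONE", dist="non_endemic", growth="tree",
               naturalized=False):
    return SpeciesRecord(
        binomial=binomial,
        genus=binomial.split()[0],
        family=family,
        order=order,
        growth_form=GrowthForm(growth),
        naturalized=naturalized,
        threat_class=ThreatClass(threat),
        distribution_class=DistributionClass(dist),
    )


_counter = {"n": 0}


def mk_accession(species, marker=MarkerRegion.RBCL, date="2010-06-15",
                 source="genbank", raw=None):
    _counter["n"] += 1
    return AccessionRecord(
        accession_id=f"T{_counter['n']:06d}",
        raw_taxon=raw if raw is not None else species,
        species=species,
        marker=marker,
        submission_date=dt.date.fromisoformat(date),
        source=Source(source),
    )


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: same structure, ~5x smaller."""
    return SyntheticConfig(
        seed=42, n_species=400, n_genera=100, n_families=30, n_orders=10,
        n_accessions=2400, n_surveys=25, individuals_per_survey=800,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_inputs(small_bundle, tmp_path_factory):
    """Loaded checklist + resolved accessions + surveys from the small bundle."""
    from barcodegap.io import load_accessions, load_checklist, load_surveys
    from barcodegap.simulate import write_bundle

    d = tmp_path_factory.mktemp("bundle")
    paths = write_bundle(small_bundle, d)
    checklist = load_checklist(paths["checklist"])
    accessions, report = load_accessions(paths["accessions"], checklist)
    surveys = load_surveys(paths["surveys"], checklist)
    return {"checklist": checklist, "accessions": accessions,
            "surveys": surveys, "report": report, "paths": paths}
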