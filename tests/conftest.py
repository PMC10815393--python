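import pytest
from hypothesis import HealthCheck, settings

from cftrfreq.catalog import (
    load_packaged_fixture,
    read_cohort_table,
    read_spectrum_table,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cohorts():
    """The packaged Russian cohort AF matrix, keyed by cohort id."""
    return {c.cohort_id: c for c in read_cohort_table(load_packaged_fixture("cohort_af_russia.tsv"))}


@pytest.fixture(scope="session")
def district_spectra():
    """Registry spectra: national aggregate + 8 federal districts."""
    return read_spectrum_table(load_packaged_fixture("cf_patient_spectra_districts.tsv"))


@pytest.fixture(scope="session")
def biocollection_spectra():
    """Local biocollection spectra: St. Petersburg and Yugra."""
    return read_spectrum_table(load_packaged_fixture("cf_patient_spectra_biocollections.tsv"))


@pytest.fixture(scope="session")
def spectra_by_region(district_spectra, biocollection_spectra):
    return {s.region_id: s for s in [*district_spectra, *biocollection_spectra]}
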