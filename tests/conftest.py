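import pytest

from famvarnet.family_filter import (
    affected_carrier_counts,
    apply_frequency_filter,
    carrier_matrix,
    split_by_consequence,
)
from famvarnet.prioritization import prioritize, rank_by_revel
from famvarnet.synthetic_data import load_family_study


@pytest.fixture(scope="session")
def bundle():
    return load_family_study()


@pytest.fixture(scope="session")
def filtered(bundle):
    return apply_frequency_filter(bundle.records, bundle.panel, bundle.pedigree)


@pytest.fixture(scope="session")
def split(filtered):
    return split_by_consequence(filtered)


@pytest.fixture(scope="session")
def missense(split):
    return split["missense"]


@pytest.fixture(scope="session")
def filtered_matrix(bundle, filtered):
    return carrier_matrix(filtered, bundle.pedigree)


@pytest.fixture(scope="session")
def full_matrix(bundle):
    return carrier_matrix(bundle.records, bundle.pedigree)


@pytest.fixture(scope="session")
def ranked_decisions(bundle, missense, filtered_matrix):
    counts = affected_carrier_counts(filtered_matrix, bundle.pedigree)
    return rank_by_revel(bundle.prediction_matrix, missense, counts)


@pytest.fixture(scope="session")
def final_decisions(bundle, ranked_decisions):
    return prioritize(ranked_decisions, regulatory=bundle.annotations)


@pytest.fixture()
def fixture_dir(tmp_path):
    from famvarnet.synthetic_data import write_family_study

    return write_family_study(tmp_path / "fx")
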