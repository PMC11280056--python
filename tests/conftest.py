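import pytest

from dietmodel import (
    load_ddg,
    load_default_mapping,
    load_phd,
    load_registry,
)
from dietmodel.food_grouping import assign_catalog, load_criteria, load_nova_rules
from dietmodel.report_cli import load_published_profile
from dietmodel.synthetic_data import (
    generate_composition_table,
    generate_consumption_survey,
)


@pytest.fixture(scope="session")
def phd():
    return load_phd()


@pytest.fixture(scope="session")
def ddg():
    return load_ddg()


@pytest.fixture(scope="session")
def mapping():
    return load_default_mapping()


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture(scope="session")
def nova_rules():
    return load_nova_rules()


@pytest.fixture(scope="session")
def criteria():
    return load_criteria()


@pytest.fixture(scope="session")
def phd_nl():
    """Published daily totals of the PHD operationalized with Dutch foods."""
    return load_published_profile("phd_nl")


@pytest.fixture(scope="session")
def ddg_nl():
    """Published daily totals of the Dutch-guidelines diet."""
    return load_published_profile("ddg_nl")


@pytest.fixture(scope="session")
def synth_bundle(nova_rules, criteria):
    """Default-noise synthetic catalog + survey + assignments (seed 11)."""
    foods, truth = generate_composition_table(n_foods=120, seed=11)
    records = generate_consumption_survey(
        n_participants=150, seed=11, foods=foods, truth=truth
    )
    assignments = assign_catalog(foods, nova_rules, criteria)
    return foods, truth, records, assignments


@pytest.fixture(scope="session")
def synth_bundle_cv0(nova_rules, criteria):
    """Noise-free synthetic bundle: densities at targets, deterministic intakes."""
    foods, truth = generate_composition_table(
        n_foods=60, seed=3, cv=0.0, excluded_fraction=0.0
    )
    records = generate_consumption_survey(
        n_participants=25, seed=3, foods=foods, truth=truth, grams_cv=0.0
    )
    assignments = assign_catalog(foods, nova_rules, criteria)
    return foods, truth, records, assignments
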