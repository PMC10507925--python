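import pandas as pd
import pytest

from wgspanel.synth import (
    GeneratorParams,
    gen_cohort_fixture,
    gen_small_variants,
    gen_sv_bundle,
    make_panel,
)


@pytest.fixture(scope="session")
def params():
    return GeneratorParams(seed=7, n_small_variants=400, n_sv_per_caller=80)


@pytest.fixture(scope="session")
def small_table(params):
    return gen_small_variants(params)


@pytest.fixture(scope="session")
def panel(params):
    return make_panel(params)


@pytest.fixture(scope="session")
def sv_bundle(params):
    return gen_sv_bundle(params)


@pytest.fixture(scope="session")
def cohort():
    cases, variants = gen_cohort_fixture()
    return cases, variants


def small_variant_row(**overrides):
    """A minimal valid small-variant record for unit tests."""
    row = {
        "variant_id": "X1",
        "chrom": "pc1",
        "pos": 100,
        "ref": "A",
        "alt": "T",
        "variant_class": "snv",
        "consequence": "missense",
        "gene": "APC",
        "clinvar_status": "none",
        "vaf": 0.5,
        "cohort_af": 0.0,
        "inhouse_af": 0.0,
    }
    for pop in ("afr", "amr", "asj", "eas", "fin", "nfe", "sas"):
        row[f"gnex_{pop}"] = 0.0
        row[f"gnge_{pop}"] = 0.0
    row.update(overrides)
    return pd.Series(row)
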