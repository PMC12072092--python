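import numpy as np
import pytest

from serosim import (
    GenotypeRecord,
    ModelParameters,
    VmaxSet,
    default_expression,
    default_variant_defs,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def defs():
    return default_variant_defs()


@pytest.fixture(scope="session")
def expr():
    return default_expression()


def make_record(
    sample_id="S1",
    sex="female",
    group="unaffected",
    rs11178998=("A", "A"),
    rs4290270=("T", "T"),
    rs7305115=("G", "G"),
    httlpr=("L", "L"),
    uvntr=("4R", "4R"),
):
    if sex == "male" and len(uvntr) == 2:
        uvntr = uvntr[:1]
    return GenotypeRecord(
        sample_id=sample_id,
        sex=sex,
        group=group,
        genotype={
            "rs11178998": rs11178998,
            "rs4290270": rs4290270,
            "rs7305115": rs7305115,
            "5-HTTLPR": httlpr,
            "uVNTR": uvntr,
        },
    )


@pytest.fixture
def reference_record():
    """All-reference genotype: C = 2 for every gene."""
    return make_record()


@pytest.fixture(scope="session")
def reference_vmaxes(expr):
    """Literal Vmax products of the all-reference genotype (C = 2, scale 1)."""
    return VmaxSet(
        tph2=expr["TPH2"].e_nx_uM * 2 * expr["TPH2"].kcat_per_h,
        sert=expr["SLC6A4"].e_nx_uM * 2 * expr["SLC6A4"].kcat_per_h,
        maoa=expr["MAOA"].e_nx_uM * 2 * expr["MAOA"].kcat_per_h,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


def random_states(rng, n, scale=100.0):
    """Non-negative random states spanning several orders of magnitude."""
    mags = rng.uniform(-3, np.log10(scale), size=(n, 8))
    return 10.0**mags * (rng.random((n, 8)) > 0.1)
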