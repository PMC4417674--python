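import pytest

from editaudit import (
    CallParams,
    EmbryoScenario,
    GuideSpec,
    generate_donor,
    generate_locus_pair,
)


@pytest.fixture(scope="session")
def locus():
    return generate_locus_pair(length=400, n_discriminating=4, seed=7)


@pytest.fixture(scope="session")
def donor(locus):
    return generate_donor(locus, n_signatures=6, arm_length=63, seed=1)


@pytest.fixture(scope="session")
def params():
    return CallParams()


@pytest.fixture()
def scenario():
    return EmbryoScenario(
        embryo_id="e01",
        mixture={"WT": 0.4, "NHEJ_INDEL": 0.3, "HDR_OLIGO": 0.1,
                 "HDR_PARALOG": 0.1, "HDR_PARTIAL": 0.1},
        n_reads=50,
        seed=3,
    )
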