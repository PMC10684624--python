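import pytest
from hypothesis import HealthCheck, settings

import silylms as s

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def tbdms():
    return s.get_reagent("TBDMS")


@pytest.fixture(scope="session")
def tms():
    return s.get_reagent("TMS")


@pytest.fixture(scope="session")
def quercetin():
    return s.parse_formula("C15H10O7")


@pytest.fixture(scope="session")
def ted13():
    return s.parse_formula("C14H10O6")


@pytest.fixture(scope="session")
def ztf_parent():
    """The re-proposed neutral formula of the unknown flavonoid ZTF 1016."""
    return s.parse_formula("C15H22O11")


@pytest.fixture(scope="session")
def ztf_table_rows():
    """The vendor-reported candidate ion formulas for ZTF 1016.

    Five [M+H]+ candidates per observed ion: underivatized
    (m/z 379.1179), once-derivatized (493.2097), four-times-derivatized
    (835.4821).
    """
    return [
        (0, ["C22H19O6", "C29H15O", "C11H23O14", "C15H23O11", "C18H19O9"]),
        (1, ["C28H33O6Si", "C35H29OSi", "C17H37O14Si", "C21H37O11Si", "C32H33O3Si"]),
        (4, ["C50H75O3Si4", "C43H79O8Si4", "C36H83O13Si4", "C39H79O11Si4", "C54H75Si4"]),
    ]


@pytest.fixture(scope="session")
def ztf_table_mzs():
    return {0: 379.1179, 1: 493.2097, 4: 835.4821}
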