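from __future__ import annotations

import pytest

from peririsk.fixtures import make_meningitis_fixture


@pytest.fixture(scope="session")
def meningitis():
    """The worked cochlear-implantation infection example: specification
    plus the positive/negative/boundary/missing records."""
    return make_meningitis_fixture()


@pytest.fixture(scope="session")
def meningitis_spec(meningitis):
    return meningitis[0]


@pytest.fixture(scope="session")
def meningitis_records(meningitis):
    return {r.subject_id: r for r in meningitis[1]}
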