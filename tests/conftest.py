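import pytest

from labharmony.examples import core_tables, demo_knowledge_base, demo_tables
from labharmony.knowledge import UnitConcept


@pytest.fixture(scope="session")
def kb():
    """Referentially complete demo knowledge base (strictly validated)."""
    return demo_knowledge_base()


@pytest.fixture(scope="session")
def core_frames():
    return core_tables()


@pytest.fixture(scope="session")
def demo_frames():
    return demo_tables()


@pytest.fixture(scope="session")
def units():
    """Units keyed by a short label."""
    return {
        "preferred_platelet": UnitConcept("1287856009", "×10(3)/mcL"),
        "synonym_platelet": UnitConcept("277288007", "10*9/L"),
        "cells_per_uL": UnitConcept("258878000", "cells/µL"),
        "fL": UnitConcept("258775009", "fL"),
        "g_dL": UnitConcept("258795003", "g/dL"),
        "mg_dL": UnitConcept("258797006", "mg/dL"),
        "g_L": UnitConcept("258794004", "g/L"),
        "mmol_L": UnitConcept("258813002", "mmol/L"),
        "mEq_L": UnitConcept("258865000", "mEq/L"),
        "percent": UnitConcept("118582008", "Percentage"),
        "unmapped": UnitConcept("424242424", "furlongs/fortnight"),
    }
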