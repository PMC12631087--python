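import random

import pytest

from pseudokit import Engine
from pseudokit.store import Database


@pytest.fixture
def engine() -> Engine:
    """Fresh in-memory engine with a seeded generator for reproducible draws."""
    return Engine(Database(":memory:"), rng=random.Random(12345))


@pytest.fixture
def visits_tree(engine):
    """The study/visits domain tree exercising attribute inheritance.

    study
      telephone visits   (algorithm overwritten: random_string)
        visit 1          (inherits algorithm; end date overwritten)
          visit 1 data   (start and end both overwritten)
        visit 2          (algorithm overwritten: consecutive counter, 8 digits;
                          start date overwritten, propagated)
          PROMs          (inherits everything from visit 2)
    """
    from datetime import datetime, timezone

    eng = engine
    eng.create_domain("study")
    eng.create_domain("telephone visits", parent="study")
    eng.update_domain("telephone visits", {"algorithm": "random_string"})
    eng.create_domain("visit 1", parent="telephone visits")
    eng.create_domain("visit 2", parent="telephone visits")
    eng.update_domain(
        "visit 2",
        {"algorithm": "consecutive", "alphabet": "digits",
         "check_digit": False, "length": 8},
        privileged=True)
    eng.create_domain("PROMs", parent="visit 2")
    eng.create_domain("visit 1 data", parent="visit 1")

    t = lambda day: datetime(2024, 1, day, tzinfo=timezone.utc)
    eng.update_domain("visit 1", {"validity.end": t(20)})
    eng.update_domain("visit 1 data",
                      {"validity.start": t(2), "validity.end": t(25)})
    return eng, t
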