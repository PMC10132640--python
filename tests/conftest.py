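import numpy as np
import pytest

from paleoiso.foodweb import reference_food_groups
from paleoiso.qc import reference_specimens


@pytest.fixture(scope="session")
def groups():
    """The packaged five-group source matrix."""
    return reference_food_groups()


@pytest.fixture(scope="session")
def specimens():
    """The packaged specimen chemistry/isotope table."""
    return reference_specimens()


@pytest.fixture(scope="session")
def ortiz_specimens(specimens):
    return [s for s in specimens if s.burial_id.startswith("B")]
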